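"""Gene-by-sample count matrix container with TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Non-negative integer read counts for genes (rows) by samples (columns).

    ``counts`` is a pandas DataFrame indexed by gene_id with one column per
    sample_id; ``lengths_bp`` is a Series of per-gene transcript lengths
    aligned to the same index.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene_ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.lengths_bp.isna().any():
            missing = self.lengths_bp.index[self.lengths_bp.isna()].tolist()
            raise ValueError(f"missing gene lengths for: {missing[:5]}")
        if (self.lengths_bp < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        self.lengths_bp = self.lengths_bp.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CountMatrix(self.counts[sample_ids].copy(), self.lengths_bp.copy())

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths_bp)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if "length_bp" not in df.columns:
            raise ValueError("count TSV must have a 'length_bp' second column")
        lengths = df.pop("length_bp")
        return cls(df, lengths)
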