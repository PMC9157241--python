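"""The curated acetylation-regulator catalog and key-regulator selection.

The catalog enumerates the 13 known mouse/human lysine acetyltransferases
(Kat1/Hat1 through Kat8, Atat1, Esco1/2) and 20 deacetylases: the
Zn2+-dependent classical family Hdac1-11, the NAD+-dependent sirtuin family
Sirt1-7, and the two transcription factors with reported deacetylase
activity, Lef1 and Tcf7 (TCF1).  Symbols use mouse-style capitalization;
an alias table covers the human-style and historical names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import pandas as pd

ROLES = ("acetyltransferase", "deacetylase")
FAMILIES = ("KAT", "HDAC", "SIRT", "TF_deacetylase")


@dataclass(frozen=True)
class RegulatorEntry:
    symbol: str
    role: str
    family: str
    aliases: tuple[str, ...] = ()


@dataclass
class RegulatorCatalog:
    entries: list[RegulatorEntry]

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate symbols in catalog")
        for e in self.entries:
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r} for {e.symbol}")
            if e.family not in FAMILIES:
                raise ValueError(f"unknown family {e.family!r} for {e.symbol}")
            if e.family == "KAT" and e.role != "acetyltransferase":
                raise ValueError(f"KAT-family entry {e.symbol} must be a transferase")
            if e.family in ("HDAC", "SIRT", "TF_deacetylase") and e.role != "deacetylase":
                raise ValueError(f"{e.family} entry {e.symbol} must be a deacetylase")

    def symbols(self, role: str | None = None, family: str | None = None) -> list[str]:
        out = self.entries
        if role is not None:
            out = [e for e in out if e.role == role]
        if family is not None:
            out = [e for e in out if e.family == family]
        return [e.symbol for e in out]

    def resolve(self, name: str) -> str | None:
        """Primary symbol for a symbol or alias (case-insensitive)."""
        low = name.lower()
        for e in self.entries:
            if e.symbol.lower() == low:
                return e.symbol
            if any(a.lower() == low for a in e.aliases):
                return e.symbol
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "symbol": [e.symbol for e in self.entries],
                "role": [e.role for e in self.entries],
                "family": [e.family for e in self.entries],
                "aliases": [";".join(e.aliases) for e in self.entries],
            }
        )


def build_catalog() -> RegulatorCatalog:
    """Load the shipped regulator catalog (13 transferases, 20 deacetylases)."""
    ref = resources.files("acetrend").joinpath("data/regulators.tsv")
    entries: list[RegulatorEntry] = []
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            aliases = tuple(
                a for a in (row.get("aliases") or "").split(";") if a
            )
            entries.append(
                RegulatorEntry(row["symbol"], row["role"], row["family"], aliases)
            )
    return RegulatorCatalog(entries)


def venn_regions(sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Disjoint Venn regions for 2-4 labelled sets.

    Region labels join the member set labels with '&' (e.g. 'A&B' is the
    part of A intersect B outside every other set); all 2^k - 1 regions are
    returned, possibly empty, and their union equals the union of inputs.
    """
    labels = list(sets)
    if not (2 <= len(labels) <= 4):
        raise ValueError("venn_regions supports 2 to 4 sets")
    regions: dict[str, set[str]] = {}
    for mask in range(1, 2 ** len(labels)):
        inside = [l for i, l in enumerate(labels) if mask >> i & 1]
        outside = [l for l in labels if l not in inside]
        region = set.intersection(*(sets[l] for l in inside))
        for l in outside:
            region = region - sets[l]
        regions["&".join(inside)] = region
    return regions


def key_regulators(assignments_by_location: dict[str, pd.DataFrame]) -> set[str]:
    """Genes in module 1 with a directional call in every phase, everywhere.

    Mirrors the key-regulator selection: within each location's module
    table, keep module-1 genes whose dev/inj/reg calls are all non-nc, then
    intersect across locations.
    """
    if not assignments_by_location:
        raise ValueError("no module assignments given")
    selected: set[str] | None = None
    for df in assignments_by_location.values():
        keep = df[
            (df["module"] == 1)
            & (df["dev"] != "nc")
            & (df["inj"] != "nc")
            & (df["reg"] != "nc")
        ]
        genes = set(keep["gene_id"])
        selected = genes if selected is None else selected & genes
    return selected or set()
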