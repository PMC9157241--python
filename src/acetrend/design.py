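"""Study design: samples, timepoints, and the endpoint comparison windows.

The canonical design mirrors a mouse sciatic-nerve expression study with two
arms: a developmental series sampled at 11 timepoints from embryonic day 20
to postnatal month 12, and a crush-injury series sampled at the uninjured
nerve (N) plus five post-operative days, separately for the proximal and
distal nerve stumps.  Each phase of the analysis (development, injury,
regeneration) is tested between the two endpoints of its comparison window
rather than with a time-course model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Process = Literal["development", "injury"]
Location = Literal["none", "proximal", "distal"]
Phase = Literal["development", "injury", "regeneration"]

#: Developmental series: embryonic day 20, postnatal days, postnatal months.
DEV_TIMEPOINTS: tuple[str, ...] = (
    "E20", "S1d", "S4d", "S7d", "S14d", "S21d",
    "S1m", "S3m", "S6m", "S9m", "S12m",
)

#: Injury series: uninjured nerve (N) then post-crush days.
INJURY_TIMEPOINTS: tuple[str, ...] = ("N", "C1d", "C3d", "C7d", "C14d", "C21d")

#: Post-operative observation timepoints (excludes the uninjured baseline).
POSTOP_TIMEPOINTS: tuple[str, ...] = INJURY_TIMEPOINTS[1:]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    process: Process
    timepoint: str
    location: Location
    replicate: int


@dataclass
class StudyDesign:
    """An ordered collection of samples with design-level invariants."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids in design: {dup}")
        for s in self.samples:
            if s.process == "development" and s.location != "none":
                raise ValueError(
                    f"development sample {s.sample_id} must have location 'none'"
                )
            if s.process == "injury" and s.location not in ("proximal", "distal"):
                raise ValueError(
                    f"injury sample {s.sample_id} must be proximal or distal"
                )
            if s.replicate < 1:
                raise ValueError(f"replicate must be >= 1 ({s.sample_id})")

    def samples_for(
        self,
        process: Process | None = None,
        timepoint: str | None = None,
        location: Location | None = None,
    ) -> list[Sample]:
        out = self.samples
        if process is not None:
            out = [s for s in out if s.process == process]
        if timepoint is not None:
            out = [s for s in out if s.timepoint == timepoint]
        if location is not None:
            out = [s for s in out if s.location == location]
        return list(out)

    def sample_ids(self, **kwargs) -> list[str]:
        return [s.sample_id for s in self.samples_for(**kwargs)]

    def timepoints(self, process: Process, location: Location | None = None) -> list[str]:
        seen: list[str] = []
        for s in self.samples_for(process=process, location=location):
            if s.timepoint not in seen:
                seen.append(s.timepoint)
        return seen

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "process": [s.process for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "location": [s.location for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StudyDesign":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"sample_id", "process", "timepoint", "location", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        return cls(
            [
                Sample(
                    sample_id=str(r.sample_id),
                    process=str(r.process),
                    timepoint=str(r.timepoint),
                    location=str(r.location),
                    replicate=int(r.replicate),
                )
                for r in df.itertuples()
            ]
        )


@dataclass(frozen=True)
class ComparisonWindow:
    """An endpoint pair defining one phase's differential test."""

    comparison_id: str
    phase: Phase
    group_a: tuple[str, Location]  # (timepoint, location)
    group_b: tuple[str, Location]


def canonical_windows(location: Location = "distal") -> dict[Phase, ComparisonWindow]:
    """The three canonical endpoint windows.

    Development is shared between locations; injury (N -> C1d) and
    regeneration (C7d -> C14d) are per nerve-stump location.
    """
    return {
        "development": ComparisonWindow(
            "development", "development", ("S1d", "none"), ("S6m", "none")
        ),
        "injury": ComparisonWindow(
            f"injury-{location}", "injury", ("N", location), ("C1d", location)
        ),
        "regeneration": ComparisonWindow(
            f"regeneration-{location}", "regeneration",
            ("C7d", location), ("C14d", location),
        ),
    }


def canonical_design(n_replicates: int = 3) -> StudyDesign:
    """Developmental series plus the injury series at both stump locations."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    samples: list[Sample] = []
    for tp in DEV_TIMEPOINTS:
        for r in range(1, n_replicates + 1):
            samples.append(Sample(f"{tp}.r{r}", "development", tp, "none", r))
    for loc in ("distal", "proximal"):
        for tp in INJURY_TIMEPOINTS:
            for r in range(1, n_replicates + 1):
                samples.append(Sample(f"{tp}.{loc[0]}.r{r}", "injury", tp, loc, r))
    return StudyDesign(samples)
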