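"""Sample sheet handling: samples mapped to timepoint, replicate and diurnal phase.

The experimental design is a synchronized diurnal time course: each timepoint
(in hours, possibly half-hour resolution) is sampled in replicate, and each
timepoint belongs to one cell-cycle phase (Light G1, S-M, Dark G1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LIGHT_G1 = "LightG1"
SM = "SM"
DARK_G1 = "DarkG1"
PHASES = (LIGHT_G1, SM, DARK_G1)


def default_phase(timepoint: float) -> str:
    """Phase of a timepoint under the standard partition of the diurnal cycle.

    TP1-TP10 are Light G1, TP11-TP15 (including half-hour points) are S-M,
    TP16-TP24 are Dark G1.
    """
    if timepoint <= 10:
        return LIGHT_G1
    if timepoint <= 15:
        return SM
    return DARK_G1


def format_timepoint(timepoint: float) -> str:
    """Render a timepoint as a column label: 3 -> 'TP3', 11.5 -> 'TP11.5'."""
    if float(timepoint) == int(timepoint):
        return f"TP{int(timepoint)}"
    return f"TP{timepoint:g}"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    timepoint: float
    replicate: str
    phase: str


class SampleSheet:
    """Ordered collection of samples with timepoint/replicate/phase structure."""

    def __init__(self, samples: list[Sample]):
        if not samples:
            raise ValueError("sample sheet is empty")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        self.samples = list(samples)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "timepoint", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        samples = []
        for row in df.itertuples(index=False):
            tp = float(row.timepoint)
            phase = getattr(row, "phase", None) or default_phase(tp)
            samples.append(Sample(row.sample_id, tp, str(row.replicate), phase))
        return cls(samples)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "timepoint": s.timepoint,
                    "replicate": s.replicate,
                    "phase": s.phase,
                }
                for s in self.samples
            ]
        ).to_csv(path, sep="\t", index=False)

    @property
    def timepoints(self) -> list[float]:
        """Distinct timepoints in ascending order."""
        return sorted({s.timepoint for s in self.samples})

    @property
    def timepoint_labels(self) -> list[str]:
        return [format_timepoint(t) for t in self.timepoints]

    def samples_at(self, timepoint: float) -> list[Sample]:
        hits = [s for s in self.samples if s.timepoint == timepoint]
        if not hits:
            raise ValueError(f"no samples at timepoint {timepoint}")
        return hits

    def phase_of(self, timepoint: float) -> str:
        return self.samples_at(timepoint)[0].phase

    def phase_map(self) -> dict[float, str]:
        return {t: self.phase_of(t) for t in self.timepoints}
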