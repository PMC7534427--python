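"""Events-by-timepoints matrix container shared by the PSI and PIR pipelines."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class SplicingMatrix:
    """PSI or PIR values, rows = events, columns = ordered timepoint labels.

    ``pseudo`` records the pseudo-count already applied to the stored values
    (PSI: missing cells replaced by it; PIR: added to every non-missing
    cell). Missing cells that remain are NaN and export as 'NA'.
    """

    values: pd.DataFrame
    metric: str  # "PSI" or "PIR"
    pseudo: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="event_id")

    @classmethod
    def from_tsv(cls, path, metric: str, pseudo: float) -> "SplicingMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(values=df, metric=metric, pseudo=pseudo)
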