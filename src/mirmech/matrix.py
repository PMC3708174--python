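"""Expression matrices with replicate structure.

Rows are features (genes, miRNAs or proteins), columns are individual
measurement runs named ``<sample>_r<k>`` (e.g. ``S1_r2``).  A replicate map
assigns each column to its biological sample (cell line); a scale tag records
whether values are raw counts, depth-normalized counts, or log2 abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

SCALES = ("counts", "normalized", "log2")


def replicate_map_from_columns(columns) -> dict[str, str]:
    """Derive sample grouping from ``<sample>_r<k>`` column names.

    Columns without an ``_r<k>`` suffix form their own single-replicate group.
    """
    out = {}
    for c in columns:
        name = str(c)
        stem, sep, tail = name.rpartition("_r")
        if sep and stem and tail.isdigit():
            out[name] = stem
        else:
            out[name] = name
    return out


@dataclass
class ExpressionMatrix:
    data: pd.DataFrame
    replicate_map: Mapping[str, str] = field(default=None)
    scale: str = "counts"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups[:5]}")
        if self.replicate_map is None:
            self.replicate_map = replicate_map_from_columns(self.data.columns)
        missing = [c for c in self.data.columns if str(c) not in self.replicate_map]
        if missing:
            raise ValueError(f"replicate map does not cover columns: {missing[:5]}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")

    @property
    def features(self):
        return self.data.index

    @property
    def samples(self) -> list[str]:
        """Distinct biological samples, in first-appearance column order."""
        seen = []
        for c in self.data.columns:
            g = self.replicate_map[str(c)]
            if g not in seen:
                seen.append(g)
        return seen

    def columns_for(self, sample: str) -> list[str]:
        return [str(c) for c in self.data.columns if self.replicate_map[str(c)] == sample]

    def copy_with(self, data: pd.DataFrame, scale: str | None = None,
                  replicate_map=None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=data,
            replicate_map=(replicate_map_from_columns(data.columns)
                           if replicate_map is None else replicate_map),
            scale=self.scale if scale is None else scale,
        )

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, scale: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(data=df, scale=scale)
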