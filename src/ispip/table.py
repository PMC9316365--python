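"""The per-residue score table — the central exchange format.

One row per residue: protein id, residue key (chain, resnum, icode), one
column per upstream predictor with a normalized likelihood in [0, 1], and an
optional binary interface label.  Serialized as tab-delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoreTable", "normalize_scores"]

ID_COLUMNS = ["protein_id", "chain", "resnum", "icode"]


@dataclass
class ScoreTable:
    """Per-residue predictor scores, optionally labelled.

    Parameters
    ----------
    frame:
        Tidy table with columns ``protein_id, chain, resnum, icode``,
        one numeric column per predictor, and optionally ``label``.
    predictors:
        Registry of predictor column names, in model input order.  Defaults
        to every non-id, non-label column of ``frame``.
    """

    frame: pd.DataFrame
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score table missing id columns: {missing}")
        if not self.predictors:
            self.predictors = [
                c for c in self.frame.columns if c not in ID_COLUMNS + ["label"]
            ]
        for col in self.predictors:
            if col not in self.frame.columns:
                raise ValueError(f"predictor column {col!r} absent from table")
            if not pd.api.types.is_numeric_dtype(self.frame[col]):
                raise ValueError(f"predictor column {col!r} is not numeric")
            bad = self.frame.index[self.frame[col].isna()]
            if len(bad):
                raise ValueError(
                    f"predictor column {col!r} has missing scores at rows {list(bad[:3])}"
                )
        dup = self.frame.duplicated(subset=ID_COLUMNS)
        if dup.any():
            raise ValueError(
                f"duplicate (protein, residue) rows, e.g. row {int(np.flatnonzero(dup)[0])}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def has_labels(self) -> bool:
        return "label" in self.frame.columns and self.frame["label"].notna().all()

    def X(self) -> np.ndarray:
        return self.frame[self.predictors].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        if not self.has_labels:
            raise ValueError("score table carries no labels")
        y = self.frame["label"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        return y.astype(int)

    def groups(self) -> np.ndarray:
        """Protein id per row — the grouping unit for CV splitting."""
        return self.frame["protein_id"].to_numpy()

    def protein_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["protein_id"]))

    def subset(self, protein_ids: Iterable[str]) -> "ScoreTable":
        wanted = set(protein_ids)
        sub = self.frame[self.frame["protein_id"].isin(wanted)].reset_index(drop=True)
        return ScoreTable(sub, predictors=list(self.predictors))

    def degenerate_proteins(self) -> list[str]:
        """Labelled proteins lacking one of the two classes."""
        if not self.has_labels:
            return []
        out = []
        for pid, part in self.frame.groupby("protein_id", sort=False):
            if part["label"].nunique() < 2:
                out.append(pid)
        return out

    # -- io ----------------------------------------------------------------
    @classmethod
    def read(cls, path_or_buffer, sep: str = "\t", predictors: Sequence[str] | None = None) -> "ScoreTable":
        df = pd.read_csv(path_or_buffer, sep=sep, dtype={"protein_id": str, "chain": str})
        if "icode" in df.columns:
            df["icode"] = df["icode"].fillna("").astype(str)
        return cls(df, predictors=list(predictors) if predictors else [])

    def write(self, path_or_buffer, sep: str = "\t") -> None:
        self.frame.to_csv(path_or_buffer, sep=sep, index=False)


def normalize_scores(table: ScoreTable, mode: str = "none") -> ScoreTable:
    """Normalize predictor columns to [0, 1].

    ``none`` asserts the scores are already in range; ``minmax_global``
    rescales each column over the whole table; ``minmax_per_protein``
    rescales within each protein.  Constant columns map to 0.5.
    """
    if mode not in ("none", "minmax_global", "minmax_per_protein"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    frame = table.frame.copy()

    def _minmax(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            return pd.Series(0.5, index=col.index)
        return (col - lo) / (hi - lo)

    for col in table.predictors:
        if mode == "none":
            vals = frame[col]
            if (vals < 0).any() or (vals > 1).any():
                bad = int(vals.index[(vals < 0) | (vals > 1)][0])
                raise ValueError(
                    f"column {col!r} outside [0,1] at row {bad}; use a minmax mode"
                )
        elif mode == "minmax_global":
            frame[col] = _minmax(frame[col])
        else:
            frame[col] = frame.groupby("protein_id", sort=False)[col].transform(_minmax)
    return ScoreTable(frame, predictors=list(table.predictors))
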