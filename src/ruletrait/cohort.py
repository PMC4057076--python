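"""Subject-level cohort container.

A :class:`MarkerTable` holds baseline markers (continuous or categorical,
possibly with missing values), a binary onset outcome, and optionally
time-to-onset with an event indicator for survival validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["MarkerTable", "read_cohort"]


@dataclass
class MarkerTable:
    """Subjects x named markers, plus outcome and optional survival columns.

    Parameters
    ----------
    data
        One row per subject. Must contain every column named in
        ``marker_cols`` and ``outcome_col`` (and ``time_col``/``event_col``
        when given). The index serves as the subject identifier.
    marker_cols
        Names of the candidate risk-marker columns.
    outcome_col
        Binary (0/1) onset indicator column.
    time_col, event_col
        Optional nonnegative follow-up time and binary event indicator.
    """

    data: pd.DataFrame
    marker_cols: list[str] = field(default_factory=list)
    outcome_col: str = "outcome"
    time_col: str | None = None
    event_col: str | None = None

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        missing = [c for c in [*self.marker_cols, self.outcome_col] if c not in cols]
        for c in (self.time_col, self.event_col):
            if c is not None and c not in cols:
                missing.append(c)
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise SchemaError(f"duplicated subject ids: {dupes[:5]}")
        out = self.data[self.outcome_col]
        if out.isna().any():
            raise SchemaError(f"missing values in outcome column {self.outcome_col!r}")
        if not np.isin(out.to_numpy(), [0, 1]).all():
            bad = sorted(set(out) - {0, 1})
            raise SchemaError(f"non-binary outcome values in {self.outcome_col!r}: {bad}")
        if self.time_col is not None:
            t = self.data[self.time_col].to_numpy(dtype=float)
            if np.nanmin(t) < 0 or not np.isfinite(t[~np.isnan(t)]).all():
                raise SchemaError(f"times in {self.time_col!r} must be finite and nonnegative")
        if self.event_col is not None:
            ev = self.data[self.event_col].dropna()
            if not np.isin(ev.to_numpy(), [0, 1]).all():
                raise SchemaError(f"non-binary event values in {self.event_col!r}")

    # -- accessors -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self):
        return self.data.index

    @property
    def markers(self) -> pd.DataFrame:
        return self.data[self.marker_cols]

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_col].to_numpy(dtype=int)

    @property
    def time(self) -> np.ndarray | None:
        if self.time_col is None:
            return None
        return self.data[self.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray | None:
        if self.event_col is None:
            return None
        return self.data[self.event_col].to_numpy(dtype=int)

    def numeric_markers(self) -> pd.DataFrame:
        """Markers as a float matrix suitable for threshold rules.

        Categorical / object columns are expanded into 0/1 indicator columns
        named ``marker=level`` (levels sorted for determinism); numeric
        columns pass through. Missing values stay ``NaN`` in both cases.
        """
        out: dict[str, pd.Series] = {}
        for col in self.marker_cols:
            s = self.data[col]
            if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
                out[col] = s.astype(float)
            else:
                levels = sorted(s.dropna().unique(), key=str)
                for lev in levels:
                    ind = (s == lev).astype(float)
                    ind[s.isna()] = np.nan
                    out[f"{col}={lev}"] = ind
        return pd.DataFrame(out, index=self.data.index)

    def subset(self, idx) -> "MarkerTable":
        """Row subset (positional or boolean) preserving column roles."""
        sel = self.data.iloc[idx] if not isinstance(idx, pd.Index) else self.data.loc[idx]
        return MarkerTable(
            sel.copy(), list(self.marker_cols), self.outcome_col, self.time_col, self.event_col
        )

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        # %.17g guarantees binary round-trip of doubles through text
        self.data.to_csv(path, index_label="subject_id", float_format="%.17g")

    @classmethod
    def from_csv(
        cls,
        path,
        outcome_col: str = "outcome",
        time_col: str | None = None,
        event_col: str | None = None,
        marker_cols: list[str] | None = None,
    ) -> "MarkerTable":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if marker_cols is None:
            reserved = {outcome_col, time_col, event_col}
            marker_cols = [c for c in df.columns if c not in reserved]
        return cls(df, marker_cols, outcome_col, time_col, event_col)


def read_cohort(
    path,
    outcome_col: str = "outcome",
    time_col: str | None = None,
    event_col: str | None = None,
    marker_cols: list[str] | None = None,
) -> MarkerTable:
    """Read a delimited cohort file and validate column roles.

    Empty cells become missing values (never zero). Non-binary outcomes and
    negative times raise :class:`~ruletrait.errors.SchemaError`.
    """
    return MarkerTable.from_csv(
        path,
        outcome_col=outcome_col,
        time_col=time_col,
        event_col=event_col,
        marker_cols=marker_cols,
    )
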