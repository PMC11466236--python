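"""Two-wave panel data: container, CSV I/O, validation, sample accounting.

File format (wide, one row per subject)::

    subject_id,gender,t1_N1,...,t1_A6,t2_N1,...,t2_A6

``gender`` is coded 0 = boy, 1 = girl.  Symptom scores are integers on
each node's ordinal scale (default 0-4).  Rows with one or more missing
or out-of-range scores are *flagged* as incomplete — never silently
dropped — and excluded from the analysis set (listwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SymptomCatalog, default_catalog
from .errors import ConsistencyError, InputError, SchemaError, ValidationError

GENDER_BOY = 0
GENDER_GIRL = 1
_VALID_GENDERS = (GENDER_BOY, GENDER_GIRL)


@dataclass
class PanelDataset:
    """Subjects x (covariates + wave-1 scores + wave-2 scores).

    ``t1`` and ``t2`` are float DataFrames with columns in catalog order;
    missing entries are NaN.  ``incomplete`` marks rows carrying at least
    one missing or out-of-range score; the *analysis set* is the
    complement (listwise deletion).
    """

    subject_ids: list[str]
    gender: np.ndarray
    t1: pd.DataFrame
    t2: pd.DataFrame
    catalog: SymptomCatalog
    incomplete: np.ndarray = field(default=None)  # bool per subject

    def __post_init__(self):
        n = len(self.subject_ids)
        self.gender = np.asarray(self.gender, dtype=int)
        if self.incomplete is None:
            self.incomplete = np.zeros(n, dtype=bool)
        self.incomplete = np.asarray(self.incomplete, dtype=bool)
        ids = self.catalog.node_ids
        for name, tab in (("t1", self.t1), ("t2", self.t2)):
            if list(tab.columns) != ids:
                raise ValidationError(f"{name} columns do not match catalog order")
            if len(tab) != n:
                raise ValidationError(f"{name} has {len(tab)} rows, expected {n}")
        if len(self.gender) != n or len(self.incomplete) != n:
            raise ValidationError("gender/incomplete length mismatch")

    # -- sizes -------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_analyzed(self) -> int:
        return int((~self.incomplete).sum())

    # -- views -------------------------------------------------------------
    def analysis_set(self) -> "PanelDataset":
        """Complete-case subset (listwise deletion applied)."""
        keep = ~self.incomplete
        return self._subset(keep)

    def subset_by_gender(self, code: int) -> "PanelDataset":
        keep = (~self.incomplete) & (self.gender == code)
        return self._subset(keep)

    def _subset(self, keep: np.ndarray) -> "PanelDataset":
        idx = np.flatnonzero(keep)
        return PanelDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            gender=self.gender[idx],
            t1=self.t1.iloc[idx].reset_index(drop=True),
            t2=self.t2.iloc[idx].reset_index(drop=True),
            catalog=self.catalog,
            incomplete=np.zeros(len(idx), dtype=bool),
        )

    def scores(self, wave: int) -> np.ndarray:
        """Score matrix (n_subjects x n_nodes) for wave 1 or 2."""
        if wave not in (1, 2):
            raise InputError(f"wave must be 1 or 2, got {wave}")
        return (self.t1 if wave == 1 else self.t2).to_numpy(dtype=float)


def _required_columns(catalog: SymptomCatalog) -> list[str]:
    cols = ["subject_id", "gender"]
    cols += [f"t1_{nid}" for nid in catalog.node_ids]
    cols += [f"t2_{nid}" for nid in catalog.node_ids]
    return cols


def read_panel_csv(path: str | Path, catalog: SymptomCatalog | None = None) -> PanelDataset:
    """Read and validate a wide-format two-wave panel CSV.

    Rows with missing or out-of-range symptom scores are flagged
    incomplete (listwise deletion); fractional scores or unknown gender
    codes raise :class:`ValidationError` with the offending row index.
    """
    catalog = catalog or default_catalog()
    path = Path(path)
    if not path.exists():
        raise InputError(f"panel file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in _required_columns(catalog):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    gender_raw = pd.to_numeric(df["gender"], errors="coerce")
    bad = ~gender_raw.isin(_VALID_GENDERS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {i}: unknown gender code {df['gender'].iloc[i]!r} "
            f"(expected {GENDER_BOY}=boy, {GENDER_GIRL}=girl)"
        )

    n = len(df)
    incomplete = np.zeros(n, dtype=bool)
    tables = {}
    for wave in (1, 2):
        cols = [f"t{wave}_{nid}" for nid in catalog.node_ids]
        block = df[cols].apply(pd.to_numeric, errors="coerce")
        # fractional values are malformed data, not ordinal responses
        frac = block.notna() & (block != block.round())
        if frac.to_numpy().any():
            i = int(np.flatnonzero(frac.any(axis=1))[0])
            raise ValidationError(f"row {i}: non-integer symptom score at wave {wave}")
        lo = np.array([nd.scale_min for nd in catalog.nodes], dtype=float)
        hi = np.array([nd.scale_max for nd in catalog.nodes], dtype=float)
        vals = block.to_numpy(dtype=float)
        out_of_range = np.isfinite(vals) & ((vals < lo) | (vals > hi))
        incomplete |= np.isnan(vals).any(axis=1) | out_of_range.any(axis=1)
        tab = pd.DataFrame(vals, columns=catalog.node_ids)
        tables[wave] = tab
    return PanelDataset(
        subject_ids=df["subject_id"].astype(str).tolist(),
        gender=gender_raw.to_numpy(dtype=int),
        t1=tables[1],
        t2=tables[2],
        catalog=catalog,
        incomplete=incomplete,
    )


def write_panel_csv(data: PanelDataset, path: str | Path) -> Path:
    """Write a PanelDataset back to the wide CSV format (round-trip safe)."""
    path = Path(path)
    out = {"subject_id": data.subject_ids, "gender": data.gender}
    for wave, tab in ((1, data.t1), (2, data.t2)):
        for nid in data.catalog.node_ids:
            col = tab[nid]
            # integers where present, blank where missing
            out[f"t{wave}_{nid}"] = col.map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
    pd.DataFrame(out).to_csv(path, index=False)
    return path


def _trunc2(x: float) -> float:
    """Truncate toward zero at two decimals (the convention the reported
    sample percentages follow: 403/884 -> 45.58)."""
    return math.trunc(x * 100) / 100


@dataclass(frozen=True)
class ExclusionReport:
    """Sample-filtering (exclusion/retention) accounting."""

    n_invited: int
    n_excluded: int
    exclusion_reasons: dict[str, int]
    n_analyzed: int
    retention_pct: float
    gender_counts: dict[int, int]
    pct_boys: float


def exclusion_report(
    n_invited: int,
    exclusions: dict[str, int],
    analyzed: PanelDataset,
) -> ExclusionReport:
    """Build the exclusion/retention report for a recruitment wave.

    ``n_analyzed`` is the analysis-set size of ``analyzed`` and must equal
    ``n_invited`` minus the total exclusion count.
    """
    n_excluded = int(sum(exclusions.values()))
    if n_excluded < 0 or any(v < 0 for v in exclusions.values()):
        raise ConsistencyError("exclusion counts must be non-negative")
    if n_invited < n_excluded:
        raise ConsistencyError(
            f"n_invited ({n_invited}) < total exclusions ({n_excluded})"
        )
    n_analyzed = analyzed.n_analyzed
    if n_analyzed != n_invited - n_excluded:
        raise ConsistencyError(
            f"analysis set has {n_analyzed} subjects but n_invited - excluded "
            f"= {n_invited - n_excluded}"
        )
    analysis = analyzed.analysis_set()
    counts = {
        GENDER_BOY: int((analysis.gender == GENDER_BOY).sum()),
        GENDER_GIRL: int((analysis.gender == GENDER_GIRL).sum()),
    }
    retention = _trunc2(100.0 * n_analyzed / n_invited) if n_invited else 0.0
    pct_boys = _trunc2(100.0 * counts[GENDER_BOY] / n_analyzed) if n_analyzed else 0.0
    return ExclusionReport(
        n_invited=int(n_invited),
        n_excluded=n_excluded,
        exclusion_reasons=dict(exclusions),
        n_analyzed=n_analyzed,
        retention_pct=retention,
        gender_counts=counts,
        pct_boys=pct_boys,
    )
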