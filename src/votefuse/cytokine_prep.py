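"""Cytokine QC cascade and control-anchored standardization.

The QC cascade runs in a fixed order on raw concentrations:

1. measurement-failure filter — drop an analyte when the fraction of missing
   cells exceeds ``max_missing_frac`` (strictly greater than, default 0.05);
2. zero filter — among survivors, drop when the fraction of exact-zero
   concentrations (over all samples, zeros counted among non-missing cells)
   exceeds ``max_zero_frac``;
3. significance selection — among survivors, a pooled-variance two-sided
   two-sample Student's t-test of case vs control raw concentrations; drop
   when p > alpha.

The kept-analyte list is frozen on the training set.  Standardization is
anchored on controls: n_ij = (c_ij - m_i) / s_i with m_i, s_i the mean and
sample SD (n-1 denominator) of the *control* samples of the data set being
standardized — controls are assumed to behave consistently across assay
conditions, so (m_i, s_i) are refit per data set.  Missing cells map to 0.0
(the control mean) after standardization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CASE, CONTROL, RawCytokineTable, ValidationError

KEPT = "kept"
DROPPED_MISSING = "dropped_missing"
DROPPED_ZERO = "dropped_zero"
DROPPED_NONSIG = "dropped_nonsig"


@dataclass
class CytokineQcReport:
    """Per-analyte QC status and statistics (one row per input analyte)."""

    table: pd.DataFrame  # columns: status, missing_frac, zero_frac, t_statistic, p_value

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["status"] == KEPT])

    def n_with_status(self, status: str) -> int:
        return int((self.table["status"] == status).sum())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="analyte")


@dataclass
class StandardizationParams:
    """Control-only mean/SD per analyte for one data set."""

    m: pd.Series
    s: pd.Series

    def __post_init__(self):
        if (self.s <= 0).any():
            bad = list(self.s.index[self.s <= 0])
            raise ValidationError(f"degenerate analytes with control SD<=0: {bad}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"m": self.m.to_dict(), "s": self.s.to_dict()}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(pd.Series(d["m"]), pd.Series(d["s"]))


@dataclass
class CytokinePanel:
    """Standardized samples x kept-analytes values (finite everywhere)."""

    values: pd.DataFrame
    qc: CytokineQcReport
    params: StandardizationParams

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("standardized panel contains non-finite values")


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def qc_missing_filter(
    table: RawCytokineTable, max_frac: float = 0.05
) -> pd.DataFrame:
    df = table.concentrations
    frac = df.isna().mean(axis=0)
    status = pd.Series(
        np.where(frac > max_frac, DROPPED_MISSING, KEPT), index=df.columns
    )
    return pd.DataFrame({"status": status, "missing_frac": frac})


def qc_zero_filter(
    table: RawCytokineTable, analytes: Sequence[str], max_frac: float = 0.05
) -> pd.DataFrame:
    df = table.concentrations[list(analytes)]
    frac = df.eq(0).sum(axis=0) / len(df)
    status = pd.Series(np.where(frac > max_frac, DROPPED_ZERO, KEPT), index=df.columns)
    return pd.DataFrame({"status": status, "zero_frac": frac})


def t_select(
    table: RawCytokineTable,
    labels: pd.Series,
    analytes: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled-variance two-sided Student's t selection on raw concentrations."""
    rows = {}
    for a in analytes:
        col = table.concentrations[a]
        x = col[labels == CASE].dropna()
        y = col[labels == CONTROL].dropna()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"analyte {a!r}: <2 values in a group; dropped as non-significant")
            rows[a] = (DROPPED_NONSIG, np.nan, np.nan)
            continue
        t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(p):  # zero pooled variance with equal means
            t, p = 0.0, 1.0
        rows[a] = (KEPT if p <= alpha else DROPPED_NONSIG, float(t), float(p))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["status", "t_statistic", "p_value"]
    )


def run_qc(
    table: RawCytokineTable,
    labels: pd.Series,
    max_missing_frac: float = 0.05,
    max_zero_frac: float = 0.05,
    alpha: float = 0.05,
) -> CytokineQcReport:
    """Full cascade: missing filter -> zero filter -> t selection."""
    rep = qc_missing_filter(table, max_missing_frac)
    rep["zero_frac"] = np.nan
    rep["t_statistic"] = np.nan
    rep["p_value"] = np.nan

    survivors = list(rep.index[rep["status"] == KEPT])
    zero = qc_zero_filter(table, survivors, max_zero_frac)
    rep.loc[survivors, "status"] = zero["status"]
    rep.loc[survivors, "zero_frac"] = zero["zero_frac"]

    survivors = list(rep.index[rep["status"] == KEPT])
    sig = t_select(table, labels, survivors, alpha)
    rep.loc[survivors, "status"] = sig["status"]
    rep.loc[survivors, "t_statistic"] = sig["t_statistic"]
    rep.loc[survivors, "p_value"] = sig["p_value"]
    return CytokineQcReport(rep)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def fit_standardization(
    table: RawCytokineTable, labels: pd.Series, analytes: Sequence[str]
) -> StandardizationParams:
    """Control-only mean and sample SD (n-1) per kept analyte."""
    ctrl = table.concentrations.loc[labels == CONTROL, list(analytes)]
    if (ctrl.notna().sum(axis=0) < 2).any():
        bad = list(ctrl.columns[ctrl.notna().sum(axis=0) < 2])
        raise ValidationError(f"analytes with <2 control values: {bad}")
    return StandardizationParams(ctrl.mean(axis=0), ctrl.std(axis=0, ddof=1))


def standardize(
    table: RawCytokineTable,
    params: StandardizationParams,
    qc: CytokineQcReport | None = None,
) -> CytokinePanel:
    """Elementwise (c - m) / s on the kept analytes; missing cells -> 0.0."""
    analytes = list(params.m.index)
    df = table.concentrations[analytes]
    values = (df - params.m) / params.s
    values = values.fillna(0.0)
    if qc is None:
        rep = pd.DataFrame(
            {"status": KEPT, "missing_frac": df.isna().mean(axis=0)}, index=analytes
        )
        qc = CytokineQcReport(rep)
    return CytokinePanel(values, qc, params)


def prepare_panel(
    table: RawCytokineTable,
    labels: pd.Series,
    kept_analytes: Sequence[str] | None = None,
    max_missing_frac: float = 0.05,
    max_zero_frac: float = 0.05,
    alpha: float = 0.05,
) -> CytokinePanel:
    """Convenience: QC (training) or frozen analyte list (test) + standardize.

    Pass ``kept_analytes=None`` on the training set to run the full cascade;
    pass the training set's kept list for a test set — the selection is
    frozen, but (m_i, s_i) are refit on the test set's own controls.
    """
    if kept_analytes is None:
        qc = run_qc(table, labels, max_missing_frac, max_zero_frac, alpha)
        kept = qc.kept
    else:
        qc = None
        kept = list(kept_analytes)
    params = fit_standardization(table, labels, kept)
    return standardize(table, params, qc)
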