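"""Quality control: measurement filters, outlier detection, method reconciliation.

Measurements are discarded when they meet one or more of five criteria:
(1) measurement temperature below 15 or above 35 degC, or not reported;
(2) irradiance below 300 umol m-2 s-1; (3) measurement CO2 concentration
below 300 or above 500 umol mol-1; (4) unphysical Fick's-law CO2 drawdown
(A_n/g_m above 300 or below 10 umol mol-1); (5) statistical outliers.

Outliers are found in two strict steps: extreme values above 2 mol m-2 s-1
(herbaceous) or 1 mol m-2 s-1 (woody; ferns are grouped with woody plants,
whose low g_m range they share) are removed first; then, separately per PFT,
the surviving g_m,25 values are log-transformed and values outside
[Q1 - 1.5 IQR, Q3 + 1.5 IQR] are flagged (type-7 linear-interpolation
quartiles).

Where one set of plants was measured with several methods, curve-fitting
estimates are discarded in favour of the other method; two non-curve-fitting
methods are averaged.

Filters never raise: they classify rows and log reasons.  All thresholds are
config-overridable; the defaults are the reference values above.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import HERBACEOUS_PFTS, Method, PFT

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "apply_measurement_filters",
    "detect_outliers",
    "reconcile_methods",
    "run_qc",
]

logger = logging.getLogger(__name__)

DETERMINISTIC_CRITERIA = ("temperature", "irradiance", "co2", "drawdown")


@dataclass(frozen=True)
class FilterThresholds:
    """Exclusion thresholds; defaults are the reference filter set."""

    T_min: float = 15.0
    T_max: float = 35.0
    PPFD_min: float = 300.0
    CO2_min: float = 300.0
    CO2_max: float = 500.0
    drawdown_min: float = 10.0
    drawdown_max: float = 300.0
    extreme_herbaceous: float = 2.0   # mol m-2 s-1
    extreme_woody: float = 1.0        # mol m-2 s-1; also applied to ferns
    iqr_multiplier: float = 1.5
    min_group_size: int = 4           # below this, the IQR step is skipped

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterThresholds":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class FilterReport:
    """Per-criterion exclusion bookkeeping for one QC pass.

    A row may trip several criteria (every reason is logged) but contributes
    once to the retained/excluded arithmetic.
    """

    n_input: int = 0
    n_excluded_by: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    excluded_rows: dict[int, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_rows)

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport(n_input=self.n_input)
        merged.n_excluded_by = dict(self.n_excluded_by)
        for k, v in other.n_excluded_by.items():
            merged.n_excluded_by[k] = merged.n_excluded_by.get(k, 0) + v
        merged.excluded_rows = {k: list(v) for k, v in self.excluded_rows.items()}
        for k, v in other.excluded_rows.items():
            merged.excluded_rows.setdefault(k, []).extend(v)
        merged.n_retained = merged.n_input - len(merged.excluded_rows)
        merged.notes = self.notes + other.notes
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_by": self.n_excluded_by,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "excluded_rows": {str(k): v for k, v in self.excluded_rows.items()},
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name in df.columns:
        return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    return np.full(len(df), np.nan)


def apply_measurement_filters(
    df: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the deterministic measurement-condition filters (criteria 1-4).

    Expects a unit- and pressure-standardised frame (``gm`` in mol m-2 s-1);
    the drawdown criterion uses A_n/g_m at the measurement temperature.
    Missing temperature excludes a row ("or not reported"); missing PPFD or
    CO2 does not exclude — such rows are retained and noted in the report.
    Returns (retained frame, report).
    """
    th = thresholds or FilterThresholds()
    n = len(df)
    report = FilterReport(n_input=n)

    T = _col(df, "T_meas")
    ppfd = _col(df, "PPFD")
    co2 = _col(df, "CO2_meas")
    An = _col(df, "An")
    gm = _col(df, "gm")
    with np.errstate(invalid="ignore", divide="ignore"):
        drawdown = np.where(gm > 0, An / gm, np.nan)

    bad = {
        "temperature": ~np.isfinite(T) | (T < th.T_min) | (T > th.T_max),
        "irradiance": np.isfinite(ppfd) & (ppfd < th.PPFD_min),
        "co2": np.isfinite(co2) & ((co2 < th.CO2_min) | (co2 > th.CO2_max)),
        "drawdown": np.isfinite(drawdown)
        & ((drawdown > th.drawdown_max) | (drawdown < th.drawdown_min)),
    }

    index = df.index.to_numpy()
    for criterion, mask in bad.items():
        report.n_excluded_by[criterion] = int(mask.sum())
        for idx in index[mask]:
            report.excluded_rows.setdefault(int(idx), []).append(criterion)

    n_missing_ppfd = int((~np.isfinite(ppfd)).sum())
    n_missing_co2 = int((~np.isfinite(co2)).sum())
    if n_missing_ppfd:
        report.notes.append(f"{n_missing_ppfd} rows with missing PPFD retained")
    if n_missing_co2:
        report.notes.append(f"{n_missing_co2} rows with missing CO2_meas retained")

    any_bad = np.zeros(n, dtype=bool)
    for mask in bad.values():
        any_bad |= mask
    report.n_retained = int((~any_bad).sum())
    return df.loc[~any_bad], report


def _growth_form(pft: PFT | str) -> str:
    return "herbaceous" if PFT(pft) in HERBACEOUS_PFTS else "woody"


def detect_outliers(
    gm_25: Sequence[float] | np.ndarray,
    pft: Sequence[str],
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Two-step outlier detection on 25 degC-standardised g_m.

    Step 1 flags extreme values above the growth-form threshold (2 mol m-2
    s-1 herbaceous, 1 mol m-2 s-1 woody/fern).  Step 2, per PFT on the
    step-1 survivors, log-transforms the values and flags those outside the
    Tukey fences Q1 - k IQR / Q3 + k IQR on the log scale (k = 1.5,
    type-7 quartiles).  Groups smaller than ``min_group_size`` skip step 2.

    Returns a frame with boolean ``outlier`` and string ``reason``
    (``extreme`` / ``iqr`` / ``""``), aligned with the input order.
    """
    th = thresholds or FilterThresholds()
    gm_25 = np.asarray(gm_25, dtype=float)
    pft_arr = np.asarray([PFT(p).value for p in pft])
    if len(gm_25) != len(pft_arr):
        raise ValueError("gm_25 and pft must have equal length")

    reason = np.full(len(gm_25), "", dtype=object)
    limits = np.array(
        [
            th.extreme_herbaceous if _growth_form(p) == "herbaceous" else th.extreme_woody
            for p in pft_arr
        ]
    )
    present = np.isfinite(gm_25)
    extreme = present & (gm_25 > limits)
    reason[extreme] = "extreme"

    for group in np.unique(pft_arr):
        in_group = present & ~extreme & (pft_arr == group)
        values = gm_25[in_group]
        if len(values) < th.min_group_size:
            if len(values):
                logger.info(
                    "IQR step skipped for PFT %s (n=%d < %d)",
                    group, len(values), th.min_group_size,
                )
            continue
        logv = np.log(values)
        q1, q3 = np.quantile(logv, [0.25, 0.75])  # type-7 linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - th.iqr_multiplier * iqr, q3 + th.iqr_multiplier * iqr
        flagged = (logv < lo) | (logv > hi)
        idx = np.flatnonzero(in_group)[flagged]
        reason[idx] = "iqr"

    return pd.DataFrame({"outlier": reason != "", "reason": reason})


def reconcile_methods(
    measurements: Iterable[tuple[Method | str, float]]
) -> tuple[float, str]:
    """Collapse multi-method g_m estimates for one set of plants to one value.

    Curve-fitting plus exactly one other method -> the other method's value;
    two non-curve-fitting methods -> their arithmetic mean; a single entry ->
    itself.  Combinations beyond these (three or more non-curve-fitting
    methods, or curve-fitting plus several others) take the mean of the
    non-curve-fitting values and are reported as such.

    Returns (g_m, rule) where rule names the branch applied.
    """
    entries = [(Method(m), float(v)) for m, v in measurements]
    if not entries:
        raise ValueError("no measurements to reconcile")
    methods = [m for m, _ in entries]
    if len(set(methods)) != len(methods):
        raise ValueError("methods must be distinct within one plant set")
    if len(entries) == 1:
        return entries[0][1], "single"
    non_cf = [v for m, v in entries if m is not Method.curve_fitting]
    if not non_cf:  # curve_fitting only (cannot occur with distinct methods > 1)
        return entries[0][1], "single"
    if len(entries) == 2 and len(non_cf) == 1:
        return non_cf[0], "prefer_non_curve_fitting"
    if len(entries) == 2:
        return float(np.mean(non_cf)), "mean_of_two"
    warnings.warn(
        "more than two methods for one plant set; taking the mean of the "
        "non-curve-fitting values (beyond the reference rule set)",
        stacklevel=2,
    )
    return float(np.mean(non_cf)), "mean_beyond_rules"


def run_qc(
    df: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    gm25_column: str = "gm_25",
) -> tuple[pd.DataFrame, FilterReport]:
    """Measurement filters followed by the two-step outlier screen.

    Outlier detection runs on the filter survivors only (the steps are
    ordered); rows without a g_m,25 value or with PFT ``other`` pass the
    outlier screen untouched.  Returns (retained frame, merged report).
    """
    th = thresholds or FilterThresholds()
    retained, report = apply_measurement_filters(df, th)

    usable = retained[gm25_column].notna() if gm25_column in retained else pd.Series(
        False, index=retained.index
    )
    sub = retained.loc[usable]
    out_report = FilterReport(n_input=report.n_input)
    if len(sub):
        flags = detect_outliers(
            sub[gm25_column].to_numpy(dtype=float), sub["pft"].astype(str), th
        )
        for pos, (is_out, why) in enumerate(zip(flags["outlier"], flags["reason"])):
            if is_out:
                idx = int(sub.index[pos])
                key = "outlier_extreme" if why == "extreme" else "outlier_iqr"
                out_report.excluded_rows.setdefault(idx, []).append(key)
                out_report.n_excluded_by[key] = out_report.n_excluded_by.get(key, 0) + 1
    merged = report.merge(out_report)
    keep = ~retained.index.isin(list(out_report.excluded_rows))
    return retained.loc[keep], merged
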