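"""Stabilized inverse-probability-of-treatment weights and balance
diagnostics.

The raw weight of a patient-visit is the running product, over that
patient's visits so far, of numerator-model state probabilities divided by
denominator-model state probabilities.  With the numerator set identically
to 1 the weights are unstabilized (plain inverse probabilities).  Weights
are truncated at a cap (default 20) so single observations cannot dominate
the weighted analysis; the cap is conventional and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, SplitTime, split_time_categories
from .errors import ValidationError

__all__ = [
    "WeightSeries",
    "compute_weights",
    "truncate",
    "balance_diagnostics",
    "mean_abs_standardized_difference",
]

DEFAULT_CAP = 20.0


@dataclass
class WeightSeries:
    """Per-visit weights aligned with a cohort's visit table.

    ``table`` has columns patient_id, t, raw, truncated.  ``cap`` is the
    truncation point (``inf`` when untruncated), ``stabilized`` records
    whether a numerator model was used.
    """

    table: pd.DataFrame
    cap: float
    stabilized: bool

    @property
    def raw(self) -> pd.Series:
        return self.table["raw"]

    @property
    def truncated(self) -> pd.Series:
        return self.table["truncated"]

    @property
    def n_truncated(self) -> int:
        return int((self.table["raw"] > self.cap).sum())


def compute_weights(
    p_denominator: pd.DataFrame,
    p_numerator: pd.DataFrame | None = None,
    cap: float = DEFAULT_CAP,
) -> WeightSeries:
    """Cumulative-product weights from per-visit state probabilities.

    Inputs are the frames from
    :func:`~jdmsm.potm.predict_treatment_probabilities` (columns
    patient_id, t, p_state), row-aligned on (patient_id, t).  Passing
    ``p_numerator=None`` yields unstabilized weights.  The result is
    already truncated at ``cap`` (``np.inf`` disables truncation).
    """
    den = p_denominator
    if (den["p_state"] <= 0).any():
        raise ValidationError("denominator probability of 0; cannot weight")
    if p_numerator is None:
        ratio = 1.0 / den["p_state"].to_numpy()
        stabilized = False
    else:
        num = p_numerator
        same = (
            len(num) == len(den)
            and np.array_equal(num["patient_id"].to_numpy(), den["patient_id"].to_numpy())
            and np.allclose(num["t"].to_numpy(), den["t"].to_numpy())
        )
        if not same:
            raise ValidationError("numerator and denominator risk sets do not match")
        ratio = num["p_state"].to_numpy() / den["p_state"].to_numpy()
        stabilized = True
    table = den[["patient_id", "t"]].copy()
    table["raw"] = pd.Series(ratio, index=den.index).groupby(den["patient_id"]).cumprod()
    table["truncated"] = np.minimum(table["raw"], cap)
    return WeightSeries(table, float(cap), stabilized)


def truncate(weights: WeightSeries, cap: float = DEFAULT_CAP) -> WeightSeries:
    """Re-truncate raw weights at ``cap`` (monotone and idempotent)."""
    if cap <= 0:
        raise ValidationError("truncation cap must be positive")
    table = weights.table.copy()
    table["truncated"] = np.minimum(table["raw"], cap)
    return WeightSeries(table, float(cap), weights.stabilized)


def _wmean_ci(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean with a normal-approximation 95% CI."""
    sw = w.sum()
    m = float((w * x).sum() / sw)
    var = float((w**2 * (x - m) ** 2).sum() / sw**2)
    half = 1.96 * np.sqrt(var)
    return m, m - half, m + half


def balance_diagnostics(
    cohort: CohortTable,
    weights: WeightSeries,
    measure: str = "pga",
    grid=np.arange(0.0, 25.0, 3.0),
) -> pd.DataFrame:
    """Weighted vs unweighted group means of a score over early follow-up.

    Within each time-since-diagnosis bin the 'never/not-yet treated'
    patient-visits are compared with treated patients at the visit where
    their CYC course starts.  Effective weighting moves the two groups'
    weighted means closer together than the unweighted ones, which is the
    visual check that the pseudo-population has balanced confounders.
    Empty cells are flagged (``n`` = 0, means NaN), never fabricated.
    """
    merged = cohort.merged()
    w = weights.table
    if len(w) != len(merged) or not np.allclose(w["t"].to_numpy(), merged["t"].to_numpy()):
        raise ValidationError("weights are not aligned with the cohort's visits")
    cats = split_time_categories(merged["t"], merged["cyc_start"])
    never = np.asarray(cats) == SplitTime.NEVER_NOT_YET.value
    started = (merged["t"] >= merged["cyc_start"]).fillna(False).to_numpy()
    first_on = started & ~(
        pd.Series(started)
        .groupby(merged["patient_id"].to_numpy())
        .shift(1, fill_value=False)
        .to_numpy(dtype=bool)
    )
    rows = []
    for lo, hi in zip(grid[:-1], grid[1:]):
        in_bin = (merged["t"] >= lo) & (merged["t"] < hi)
        for group, sel in (("never_not_yet", never), ("cyc_start", first_on)):
            pick = (in_bin & sel & merged[measure].notna()).to_numpy()
            x = merged.loc[pick, measure].to_numpy(dtype=float)
            wt = w.loc[pick, "truncated"].to_numpy(dtype=float)
            if pick.sum() == 0:
                rows.append(dict(bin_lo=lo, bin_hi=hi, group=group, n=0, mean=np.nan,
                                 ci_low=np.nan, ci_high=np.nan, wmean=np.nan,
                                 wci_low=np.nan, wci_high=np.nan, empty=True))
                continue
            m, mlo, mhi = _wmean_ci(x, np.ones_like(x))
            wm, wlo, whi = _wmean_ci(x, wt)
            rows.append(dict(bin_lo=lo, bin_hi=hi, group=group, n=int(pick.sum()), mean=m,
                             ci_low=mlo, ci_high=mhi, wmean=wm, wci_low=wlo,
                             wci_high=whi, empty=False))
    return pd.DataFrame(rows)


def mean_abs_standardized_difference(diagnostics: pd.DataFrame, min_n: int = 5):
    """Average absolute between-group difference (in units of the pooled
    unweighted spread) across bins where both groups are populated; returned
    for the unweighted and the weighted means."""
    ud, wd = [], []
    for _, sub in diagnostics.groupby(["bin_lo", "bin_hi"]):
        if len(sub) != 2 or (sub["n"] < min_n).any():
            continue
        a, b = sub.iloc[0], sub.iloc[1]
        spread = np.sqrt(
            ((a["ci_high"] - a["ci_low"]) / (2 * 1.96)) ** 2 * a["n"]
            + ((b["ci_high"] - b["ci_low"]) / (2 * 1.96)) ** 2 * b["n"]
        ) / np.sqrt(2)
        if not np.isfinite(spread) or spread == 0:
            continue
        ud.append(abs(a["mean"] - b["mean"]) / spread)
        wd.append(abs(a["wmean"] - b["wmean"]) / spread)
    if not ud:
        raise ValidationError("no bin has both groups populated")
    return float(np.mean(ud)), float(np.mean(wd))
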