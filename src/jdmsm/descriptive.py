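"""Unadjusted descriptive battery: 2x2 group comparisons, rank tests,
Friedman repeated-measures analysis over nominal time points, signed-rank
post hocs with Bonferroni correction, and median/IQR change summaries.

These mirror the conventional first-pass analysis of a treated subgroup:
compare demographic and clinical features between treatment groups, then
test whether disease-activity scores change across visits matched to
nominal 0/6/12/24-month time points after the start of treatment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, nearest_visit
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "TestResult",
    "two_by_two_test",
    "rank_sum_test",
    "signed_rank_test",
    "signed_rank_posthoc",
    "friedman_test",
    "change_summary",
    "ChangeSummary",
    "bonferroni_threshold",
]

NOMINAL_MONTHS = (0, 6, 12, 24)


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    n_used: int


def two_by_two_test(a: int, b: int, c: int, d: int, method: str = "chi2_cc") -> TestResult:
    """Compare two proportions from the 2x2 table [[a, b], [c, d]].

    ``chi2_cc`` is Pearson's chi-square with the Yates continuity
    correction (df = 1); ``fisher`` is the exact test with the two-sided p
    defined as the total probability of tables no more probable than the
    observed one (the probability-mass convention of R's fisher.test).
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any() or counts.sum() <= 0:
        raise ValidationError("counts must be nonnegative with a positive total")
    n = int(counts.sum())
    if method == "chi2_cc":
        if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            raise ValidationError("chi-square test undefined with a zero margin")
        stat, p, df, _ = stats.chi2_contingency(counts, correction=True)
        return TestResult(float(stat), int(df), float(p), "chi-square (continuity corrected)", n)
    if method == "fisher":
        orat, p = stats.fisher_exact(counts, alternative="two-sided")
        return TestResult(float(orat), None, float(p), "Fisher exact (two-sided)", n)
    raise ValidationError(f"unknown method '{method}'")


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments of the
    pooled mid-ranks; ties handled exactly."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, ntot = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (ntot + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(ntot), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return float(w_obs), hits / total


def rank_sum_test(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum comparison of independent groups.

    Exact enumeration when the combined sample size is at most 10,
    otherwise the normal approximation with tie correction and continuity
    correction.  All values tied across both samples gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n = x.size + y.size
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(0.0, None, 1.0, "rank-sum (degenerate: all values tied)", n)
    if n <= 10:
        w, p = _exact_rank_sum_p(x, y)
        return TestResult(w, None, p, "rank-sum (exact)", n)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), None, float(res.pvalue), "rank-sum (normal approx.)", n)


def _signed_rank_core(d: np.ndarray) -> tuple[float, float, str]:
    """Signed-rank statistic (W+) and two-sided p.  Zero differences are
    dropped before ranking (classical convention); exact sign-flip
    enumeration for up to 15 nonzero differences, tie-corrected normal
    approximation beyond."""
    d = d[d != 0]
    nz = d.size
    if nz == 0:
        return 0.0, 1.0, "signed-rank (all differences zero)"
    r = stats.rankdata(np.abs(d))
    w_plus = r[d > 0].sum()
    mu = r.sum() / 2.0
    if nz <= 15:
        bits = (np.arange(2**nz)[:, None] >> np.arange(nz)) & 1
        sums = bits @ r
        p = float(np.mean(np.abs(sums - mu) >= abs(w_plus - mu) - 1e-9))
        return float(w_plus), p, "signed-rank (exact)"
    sd = np.sqrt((r**2).sum() / 4.0)  # mid-ranks make this the tie-corrected variance
    z = (w_plus - mu) / sd
    return float(w_plus), float(2 * stats.norm.sf(abs(z))), "signed-rank (normal approx.)"


def signed_rank_test(differences) -> TestResult:
    """Paired Wilcoxon signed-rank test on a vector of differences."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValidationError("no paired differences supplied")
    w, p, method = _signed_rank_core(d)
    return TestResult(w, None, p, method, int((d != 0).sum()))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValidationError("number of tests m must be at least 1")
    return alpha / m


def signed_rank_posthoc(wide: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise signed-rank post hocs between all column pairs of a
    patients x time-points table, Bonferroni-corrected.

    Each pair uses its pairwise-complete rows.  Returns one row per pair
    with the statistic, p, the alpha/m threshold and a significance flag.
    """
    cols = list(wide.columns)
    pairs = list(itertools.combinations(cols, 2))
    thr = bonferroni_threshold(alpha, len(pairs))
    rows = []
    for c1, c2 in pairs:
        sub = wide[[c1, c2]].dropna()
        if sub.empty:
            rows.append((c1, c2, 0, np.nan, np.nan, thr, False))
            continue
        res = signed_rank_test(sub[c2] - sub[c1])
        rows.append((c1, c2, len(sub), res.statistic, res.p_value, thr, res.p_value < thr))
    return pd.DataFrame(
        rows,
        columns=["time_a", "time_b", "n_pairs", "statistic", "p_value", "threshold", "significant"],
    )


def _friedman_statistic(mat: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square; returns (statistic, denominator).
    A zero denominator means every block is internally constant."""
    n, k = mat.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    col = ranks.sum(axis=0)
    num = (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum()
    den = ((ranks - (k + 1) / 2.0) ** 2).sum()
    return (0.0 if den == 0 else num / den), den


def friedman_test(block_matrix, method: str = "asymptotic") -> TestResult:
    """Friedman's nonparametric repeated-measures test on an n-blocks x
    k-conditions matrix of complete cases.

    Mid-ranks are used within blocks and the statistic carries the tie
    correction.  ``method='asymptotic'`` refers the statistic to
    chi-square with k-1 df (the standard large-sample analysis);
    ``method='exact'`` enumerates all (k!)^n equally likely within-block
    orderings of the observed values (guarded to small problems).
    """
    mat = np.asarray(block_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 3:
        raise ValidationError("block matrix must be n x k with k >= 3")
    if np.isnan(mat).any():
        raise ValidationError("block matrix must contain complete cases only")
    n, k = mat.shape
    if n < 2:
        raise InsufficientDataError("at least 2 complete blocks required")
    stat, den = _friedman_statistic(mat)
    if den == 0:
        return TestResult(0.0, k - 1, 1.0, "Friedman (degenerate: constant blocks)", n)
    if method == "asymptotic":
        p = float(stats.chi2.sf(stat, k - 1))
        return TestResult(float(stat), k - 1, p, "Friedman (chi-square approx.)", n)
    if method == "exact":
        total = math.factorial(k) ** n
        if total > 200_000:
            raise ValidationError(
                f"exact Friedman enumeration infeasible for (k!)^n = {total}; use asymptotic"
            )
        perms = list(itertools.permutations(range(k)))
        hits = 0
        for assignment in itertools.product(perms, repeat=n):
            permuted = np.stack([mat[i, list(pm)] for i, pm in enumerate(assignment)])
            s, _ = _friedman_statistic(permuted)
            if s >= stat - 1e-9:
                hits += 1
        return TestResult(float(stat), k - 1, hits / total, "Friedman (exact permutation)", n)
    raise ValidationError(f"unknown method '{method}'")


@dataclass
class ChangeSummary:
    """Per-nominal-time medians/IQRs plus the aligned per-patient values.

    ``table`` has one row per nominal month (n, median, quartiles, missing
    fraction among treated patients); ``wide`` is the patients x nominal
    months value table feeding the Friedman test (complete rows) and the
    signed-rank post hocs (pairwise-complete rows).
    """

    measure: str
    table: pd.DataFrame
    wide: pd.DataFrame

    @property
    def complete_blocks(self) -> np.ndarray:
        return self.wide.dropna().to_numpy(dtype=float)


def change_summary(
    cohort: CohortTable,
    measure: str,
    nominal_months=NOMINAL_MONTHS,
    window: float = 2.0,
) -> ChangeSummary:
    """Align treated patients' visits to nominal months after CYC start and
    summarise the chosen measure at each time point.

    For each treated patient and nominal month the closest visit within
    ``window`` months is used (ties to the earlier visit); a patient counts
    as missing at a time point if no visit qualifies or the score is
    missing there.
    """
    if measure not in cohort.visits.columns:
        raise ValidationError(f"unknown measure '{measure}'")
    treated = cohort.patients[cohort.patients["cyc_start"].notna()]
    if treated.empty:
        raise InsufficientDataError("no treated patients in cohort")
    values = {}
    for _, pat in treated.iterrows():
        pid = pat["patient_id"]
        pv = cohort.visits[cohort.visits["patient_id"] == pid]
        row = {}
        for m in nominal_months:
            visit = nearest_visit(pv, m, window=window, origin=pat["cyc_start"])
            row[m] = np.nan if visit is None else visit[measure]
        values[pid] = row
    wide = pd.DataFrame.from_dict(values, orient="index")[list(nominal_months)]
    rows = []
    for m in nominal_months:
        col = wide[m]
        obs = col.dropna()
        rows.append(
            dict(
                nominal_month=m,
                n=len(obs),
                median=obs.median() if len(obs) else np.nan,
                q1=obs.quantile(0.25) if len(obs) else np.nan,
                q3=obs.quantile(0.75) if len(obs) else np.nan,
                missing_frac=col.isna().mean(),
            )
        )
    return ChangeSummary(measure, pd.DataFrame(rows), wide)
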