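"""Equivalence statistics: Wilcoxon TOST, Hodges-Lehmann estimates, Bonferroni,
Kendall tau-b, Kruskal-Wallis eta-squared, and TOST sample-size calculation.

Equivalence between two paired arms (e.g. left radial vs left carotid) is
declared by two one-sided tests (TOST) on the paired differences d = x - y
against a practical-equivalence margin delta > 0:

    H0_lower: center(d) <= -delta   tested on d + delta, alternative 'greater'
    H0_upper: center(d) >= +delta   tested on d - delta, alternative 'less'

each with a Wilcoxon signed-rank test; p_TOST = max(p_lower, p_upper), and
equivalence is declared when the Bonferroni-adjusted p_TOST <= alpha.  The
signed-rank p-values use the exact null distribution for small tie-free
samples and otherwise the normal approximation with tie correction and a
+-0.5 continuity correction — the behavior of the standard R implementation
this battery mirrors.  The location estimate is the Hodges-Lehmann
pseudo-median (median of Walsh averages of d) with a 95% confidence interval
from signed-rank inversion.

Effect sizes and screens: Kendall's tau-b (|tau| > 0.2 marginal, > 0.4
moderate, reported when adjusted p <= 0.05) for continuous covariates, and
Kruskal-Wallis with eta^2 = (H - k + 1)/(n - k) for categorical factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._constants import ARTERY_PAIRS, FEATURE_COLUMNS
from .optics import ParameterError

__all__ = [
    "DEFAULT_EQUIVALENCE_THRESHOLDS",
    "EquivalenceResult",
    "CorrelationResult",
    "signed_rank_p",
    "wilcox_tost",
    "bonferroni_adjust",
    "kendall_tau",
    "kruskal_eta2",
    "kruskal_eta2_from_h",
    "tost_sample_size",
    "suggest_threshold",
    "run_equivalence_battery",
]

#: Practical-equivalence margins per parameter, in the parameter's units.
#: These are the study's published thresholds and are shipped as immutable
#: defaults; ``suggest_threshold`` exposes an SD-based rule for new data,
#: which does not reproduce every default.
DEFAULT_EQUIVALENCE_THRESHOLDS: dict[str, float] = {
    "bh_max_pct_change_hbt_pct": 3.7,
    "bh_max_pct_change_sto2_pct": 3.2,
    "db_mean_osc_time_hbt_s": 2.1,
    "db_mean_osc_time_sto2_s": 1.4,
    "db_mean_pkpk_hbt_uM": 1.2,
    "db_mean_pkpk_sto2_pct": 0.5,
}

_EXACT_MAX_N = 25  # exact signed-rank null for tie-free samples up to this n


@dataclass(frozen=True)
class EquivalenceResult:
    pair: tuple[str, str]
    parameter: str
    n: int
    delta: float
    p_lower: float
    p_upper: float
    p_tost: float
    p_adjusted: float
    mod: float               # Hodges-Lehmann pseudo-median of paired differences
    ci95: tuple[float, float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.mod <= self.ci95[1]):
            raise AssertionError("MoD must lie inside its confidence interval")

    @property
    def equivalent(self) -> bool:
        return self.p_adjusted <= self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    tau: float
    p_adjusted: float

    @property
    def classification(self) -> str:
        if not np.isfinite(self.tau) or self.p_adjusted > 0.05:
            return "none"
        a = abs(self.tau)
        if a > 0.4:
            return "moderate"
        if a > 0.2:
            return "marginal"
        return "none"


# --------------------------------------------------------------------------
# Wilcoxon signed rank
# --------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> np.ndarray:
    """Counts of the null signed-rank statistic W+ over 0..n(n+1)/2."""
    total = n * (n + 1) // 2
    c = np.zeros(total + 1)
    c[0] = 1.0
    for r in range(1, n + 1):
        c[r:] = c[r:] + c[:-r]
    return c


@lru_cache(maxsize=64)
def _signed_rank_sf(n: int) -> np.ndarray:
    """sf[w] = P(W+ >= w) under the null, exact."""
    c = _signed_rank_counts(n)
    return np.cumsum(c[::-1])[::-1] / c.sum()


@lru_cache(maxsize=64)
def _signed_rank_cdf(n: int) -> np.ndarray:
    c = _signed_rank_counts(n)
    return np.cumsum(c) / c.sum()


def signed_rank_p(
    values: np.ndarray, alternative: str, method: str = "auto"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for H0: center(values) = 0.

    Zeros are dropped (Wilcoxon's convention).  ``method='auto'`` uses the
    exact null distribution for tie-free samples with n <= 25 and otherwise
    the normal approximation with tie-corrected variance and a 0.5 continuity
    correction; 'exact'/'approx' force a path (exact requires no ties).
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    n = len(v)
    if n == 0:
        return 1.0
    absv = np.abs(v)
    ranks = sps.rankdata(absv)
    w = float(ranks[v > 0].sum())
    has_ties = len(np.unique(absv)) != n

    use_exact = (method == "exact") or (method == "auto" and not has_ties and n <= _EXACT_MAX_N)
    if use_exact:
        if has_ties:
            raise ParameterError("exact signed-rank p undefined with tied ranks")
        wi = int(round(w))
        if alternative == "greater":
            return float(_signed_rank_sf(n)[wi])
        if alternative == "less":
            return float(_signed_rank_cdf(n)[wi])
        raise ParameterError("alternative must be 'greater' or 'less'")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if has_ties:
        _, counts = np.unique(absv, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0 if alternative == "greater" and w <= mean else (
            1.0 if alternative == "less" and w >= mean else 0.5
        )
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w - mean - 0.5) / sd
        return float(sps.norm.sf(z))
    if alternative == "less":
        z = (w - mean + 0.5) / sd
        return float(sps.norm.cdf(z))
    raise ParameterError("alternative must be 'greater' or 'less'")


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(d))
    return np.sort((d[i] + d[j]) / 2.0)


def _hl_ci(d: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Hodges-Lehmann pseudo-median and signed-rank-inversion CI."""
    walsh = _walsh_averages(d)
    mod = float(np.median(walsh))
    n = len(d)
    total = n * (n + 1) // 2
    alpha2 = (1.0 - conf) / 2.0
    if n <= 50:
        cdf = _signed_rank_cdf(n)
        k = int(np.searchsorted(cdf, alpha2, side="right"))  # largest k: P(W<=k-1)<=a/2
    else:
        mean = n * (n + 1) / 4.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(max(0, math.floor(mean + sps.norm.ppf(alpha2) * sd)))
    k = min(max(k, 0), total // 2)
    lo = walsh[k] if k < len(walsh) else walsh[0]
    hi = walsh[total - 1 - k] if total - 1 - k < len(walsh) else walsh[-1]
    return mod, float(min(lo, mod)), float(max(hi, mod))


def wilcox_tost(
    x: np.ndarray,
    y: np.ndarray,
    delta: float,
    alpha: float = 0.05,
    m: int = 1,
    pair: tuple[str, str] = ("x", "y"),
    parameter: str = "",
    method: str = "auto",
) -> EquivalenceResult:
    """Continuity-corrected Wilcoxon TOST equivalence test on paired samples.

    ``delta`` is the practical-equivalence margin (> 0); ``m`` the Bonferroni
    multiplicity applied to p_TOST.  Requires n >= 4 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    if delta <= 0:
        raise ParameterError("equivalence threshold delta must be positive")
    d = x - y
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 4:
        raise ParameterError("need at least 4 complete pairs")
    if np.ptp(d) == 0:
        # all differences identical: degenerate, decide by position vs margins
        inside = abs(d[0]) < delta
        p = 0.0 if inside else 1.0
        mod = float(d[0])
        return EquivalenceResult(
            pair=pair, parameter=parameter, n=n, delta=delta,
            p_lower=p, p_upper=p, p_tost=p,
            p_adjusted=bonferroni_adjust(p, m), mod=mod, ci95=(mod, mod),
            alpha=alpha,
        )
    p_lower = signed_rank_p(d + delta, "greater", method)
    p_upper = signed_rank_p(d - delta, "less", method)
    p_tost = max(p_lower, p_upper)
    mod, lo, hi = _hl_ci(d, 1.0 - 2 * 0.025)
    return EquivalenceResult(
        pair=pair, parameter=parameter, n=n, delta=delta,
        p_lower=p_lower, p_upper=p_upper, p_tost=p_tost,
        p_adjusted=bonferroni_adjust(p_tost, m), mod=mod, ci95=(lo, hi),
        alpha=alpha,
    )


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m*p); m is the number of tests in the family."""
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must be in [0, 1]")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return min(1.0, m * p)


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b with tie handling; (tau, p).  NaN tau for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ParameterError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_eta2_from_h(h: float, k: int, n: int) -> float:
    """Kruskal's eta^2 effect size: (H - k + 1)/(n - k), floored at 0."""
    if n <= k:
        raise ParameterError("total sample size must exceed the number of groups")
    return max(0.0, (h - k + 1) / (n - k))


def kruskal_eta2(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Tie-corrected Kruskal-Wallis H, p-value, and eta^2 effect size."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        raise ParameterError("need at least 2 non-empty groups")
    n = sum(len(g) for g in groups)
    if n <= k:
        raise ParameterError("total sample size must exceed the number of groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, 0.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p), kruskal_eta2_from_h(float(h), k, n)


def tost_sample_size(
    sd_diff: float,
    delta: float,
    power: float = 0.8,
    alpha: float = 0.05,
    true_diff: float = 0.0,
    max_n: int = 100000,
) -> int:
    """Smallest n with parametric paired-TOST power >= target.

    Power of the two one-sided t-tests on paired differences with SD
    ``sd_diff``, margin ``delta`` and true mean difference ``true_diff``,
    evaluated with the noncentral-t distribution:
    power = P(T >= t_{1-a,n-1}; ncp+) + P(T <= -t_{1-a,n-1}; ncp-) - 1.
    """
    if sd_diff <= 0:
        raise ParameterError("sd_diff must be positive")
    if not (0.0 < power < 1.0):
        raise ParameterError("power must be in (0, 1)")
    if delta <= abs(true_diff):
        raise ParameterError("equivalence margin must exceed |true difference|")

    def _power(n: int) -> float:
        df = n - 1
        se = sd_diff / math.sqrt(n)
        tcrit = sps.t.ppf(1.0 - alpha, df)
        ncp_lo = (true_diff + delta) / se
        ncp_hi = (true_diff - delta) / se
        pw = sps.nct.sf(tcrit, df, ncp_lo) + sps.nct.cdf(-tcrit, df, ncp_hi) - 1.0
        return max(0.0, pw)

    for n in range(4, max_n + 1):
        if _power(n) >= power:
            return n
    raise ParameterError("required sample size exceeds max_n")


def suggest_threshold(x: np.ndarray, y: np.ndarray, rule: str = "max_sd") -> float:
    """SD-based margin rule for new datasets (default: max of the arm SDs).

    Note: this pluggable rule does not reproduce every shipped default in
    ``DEFAULT_EQUIVALENCE_THRESHOLDS``; those remain the authoritative
    margins for the standard battery.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rule == "max_sd":
        return float(max(np.nanstd(x, ddof=1), np.nanstd(y, ddof=1)))
    if rule == "sd_diff":
        return float(np.nanstd(x - y, ddof=1))
    raise ParameterError(f"unknown threshold rule {rule!r}")


# --------------------------------------------------------------------------
# Cohort-level battery
# --------------------------------------------------------------------------

_VITALS = ("systolic_bp_mmHg", "diastolic_bp_mmHg", "heart_rate_bpm")
_FACTORS = ("sex_assigned_at_birth", "race_group", "skin_tone")


def run_equivalence_battery(
    features: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    thresholds: dict[str, float] | None = None,
    m: int | None = None,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> dict[str, pd.DataFrame]:
    """Run the full statistical battery on a cohort feature table.

    For each of the six parameters and four artery pairs, subjects with both
    locations present enter the paired Wilcoxon TOST at the parameter's
    margin, Bonferroni-adjusted by the number of pairs tested per parameter
    (m = 4 by default).  With a profiles table, Kendall correlations of
    features against vitals/anatomy and Kruskal-Wallis effect sizes against
    demographic factors are added.

    Returns dict with 'equivalence', 'correlations', 'group_effects' frames;
    comparisons with fewer than ``min_pairs`` complete pairs are reported as
    skipped.
    """
    thresholds = thresholds or DEFAULT_EQUIVALENCE_THRESHOLDS
    rows = []
    if len(features) == 0:
        import warnings

        warnings.warn("empty feature table: no comparisons run", stacklevel=2)
    wide = (
        features.pivot(index="subject_id", columns="location", values=list(FEATURE_COLUMNS))
        if len(features)
        else pd.DataFrame()
    )
    for param in FEATURE_COLUMNS:
        mult = m if m is not None else len(ARTERY_PAIRS)
        for loc_a, loc_b in ARTERY_PAIRS:
            base = {
                "parameter": param, "location_a": loc_a, "location_b": loc_b,
                "delta": thresholds[param],
            }
            if len(features) == 0:
                rows.append({**base, "n": 0, "skipped": True,
                             "skip_reason": "empty feature table"})
                continue
            try:
                sub = wide[param][[loc_a, loc_b]].dropna()
            except KeyError:
                rows.append({**base, "n": 0, "skipped": True,
                             "skip_reason": "location missing"})
                continue
            if len(sub) < min_pairs:
                rows.append({**base, "n": len(sub), "skipped": True,
                             "skip_reason": f"fewer than {min_pairs} complete pairs"})
                continue
            res = wilcox_tost(
                sub[loc_a].to_numpy(), sub[loc_b].to_numpy(),
                delta=thresholds[param], alpha=alpha, m=mult,
                pair=(loc_a, loc_b), parameter=param,
            )
            rows.append(
                {
                    **base, "n": res.n, "skipped": False, "skip_reason": "",
                    "p_lower": res.p_lower, "p_upper": res.p_upper,
                    "p_tost": res.p_tost, "p_adjusted": res.p_adjusted,
                    "mod": res.mod, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                    "equivalent": res.equivalent,
                }
            )
    equivalence = pd.DataFrame(rows)

    corr_rows, effect_rows = [], []
    if profiles is not None and len(features):
        merged = features.merge(profiles, on="subject_id", how="left")
        anatomy_cols = [c for c in profiles.columns if c.endswith("_mm") and "bp" not in c]
        for param in FEATURE_COLUMNS:
            tests = []
            for loc, grp in merged.groupby("location"):
                covs = list(_VITALS)
                if "carotid" in loc:
                    side = loc.split("_")[0]
                    covs += [c for c in anatomy_cols if c.startswith(side)]
                for cov in covs:
                    g = grp[[param, cov]].dropna()
                    if len(g) < 3 or np.ptp(g[param]) == 0 or np.ptp(g[cov]) == 0:
                        continue
                    tau, p = kendall_tau(g[param].to_numpy(), g[cov].to_numpy())
                    tests.append((loc, cov, tau, p))
            mult = max(1, len(tests))
            for loc, cov, tau, p in tests:
                p_adj = bonferroni_adjust(p, mult) if np.isfinite(p) else float("nan")
                cr = CorrelationResult((f"{param}@{loc}", cov), tau, p_adj)
                corr_rows.append(
                    {
                        "parameter": param, "location": loc, "covariate": cov,
                        "tau": tau, "p_adjusted": p_adj,
                        "classification": cr.classification,
                    }
                )
            factor_tests = []
            for loc, grp in merged.groupby("location"):
                for factor in _FACTORS:
                    groups = [
                        g[param].dropna().to_numpy()
                        for _, g in grp.groupby(factor)
                    ]
                    groups = [g for g in groups if len(g) > 0]
                    n_total = sum(len(g) for g in groups)
                    if len(groups) < 2 or n_total <= len(groups):
                        continue
                    h, p, eta2 = kruskal_eta2(groups)
                    factor_tests.append((loc, factor, h, p, eta2))
            mult = max(1, len(factor_tests))
            for loc, factor, h, p, eta2 in factor_tests:
                effect_rows.append(
                    {
                        "parameter": param, "location": loc, "factor": factor,
                        "H": h, "p_adjusted": bonferroni_adjust(p, mult),
                        "eta2": eta2,
                    }
                )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["parameter", "location", "covariate", "tau", "p_adjusted",
                 "classification"],
    )
    group_effects = pd.DataFrame(
        effect_rows,
        columns=["parameter", "location", "factor", "H", "p_adjusted", "eta2"],
    )
    return {
        "equivalence": equivalence,
        "correlations": correlations,
        "group_effects": group_effects,
    }
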