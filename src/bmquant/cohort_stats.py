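"""Cohort-level statistical validation.

Implements the analysis plan applied to the per-patient burden table:
Spearman rank correlation (MTV/TLG vs marrow infiltration and
beta2-microglobulin), Wilcoxon rank-sum for high- vs standard-risk
cytogenetics, Jonckheere-Terpstra ordered trend across visual groups A/B/C
(and ISS / R-ISS stages), and ROC analysis of MTV/TLG against the 60%
plasma-cell dichotomy with the cut point maximizing sensitivity +
specificity.

Rank tests switch to exact permutation enumeration when the pooled sample
size is at most 12; otherwise tie-corrected normal approximations are used.
All tests are two-sided unless stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendTestResult",
    "RocResult",
    "spearman_corr",
    "wilcoxon_rank_sum",
    "jonckheere_terpstra",
    "roc_analysis",
    "run_validation",
    "benjamini_hochberg",
]

EXACT_N_MAX = 12


@dataclass(frozen=True)
class TrendTestResult:
    """Jonckheere-Terpstra trend test outcome."""

    jt_statistic: float
    p_value: float
    method: str  # "normal_approx" | "exact_permutation"
    group_sizes: tuple[int, ...]
    alternative: str

    def __post_init__(self) -> None:
        max_jt = sum(
            self.group_sizes[i] * self.group_sizes[j]
            for i in range(len(self.group_sizes))
            for j in range(i + 1, len(self.group_sizes))
        )
        if not (0.0 <= self.jt_statistic <= max_jt + 1e-9):
            raise ValueError("JT statistic outside [0, sum n_i n_j]")


@dataclass(frozen=True)
class RocResult:
    """ROC summary at the sensitivity+specificity-optimal observed cut point."""

    auc: float
    ci_95: tuple[float, float]
    p_vs_half: float
    cut_point: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t approximation (n-2 df).

    rho is the Pearson correlation of average ranks.  A constant input
    vector leaves rho undefined: returns ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (average ranks for ties).

    Returns the rank sum of the first sample and its p value: exact
    enumeration of all group labelings when n_a + n_b <= 12, otherwise a
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    if n <= EXACT_N_MAX:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n), na)]
        )
        dev = np.abs(sums - mu)
        p = float(np.mean(dev >= abs(w_obs - mu) - 1e-12))
        return w_obs, p

    ties = _tie_counts(pooled)
    tie_term = np.sum(ties**3 - ties) / (n * (n - 1.0))
    var = na * nb / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:  # all observations identical
        return w_obs, 1.0
    z = (w_obs - mu) / np.sqrt(var)
    return w_obs, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u = groups[i][:, None]
            v = groups[j][None, :]
            jt += np.sum(u < v) + 0.5 * np.sum(u == v)
    return float(jt)


def jonckheere_terpstra(
    groups: list, alternative: str = "two_sided"
) -> TrendTestResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    ``groups`` is an ordered list of samples (the hypothesised ordering).
    JT counts, over all ordered group pairs (i < j), pairs with u < v plus
    half the ties.  Exact permutation when pooled n <= 12; otherwise a
    tie-corrected normal approximation (Hollander & Wolfe variance).
    """
    if alternative not in ("increasing", "decreasing", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("all groups must be nonempty")
    sizes = tuple(int(g.size) for g in gs)
    n = sum(sizes)
    jt_obs = _jt_statistic(gs)
    mu = (n * n - sum(s * s for s in sizes)) / 4.0

    if n <= EXACT_N_MAX:
        pooled = np.concatenate(gs)
        stats_all = _enumerate_jt(pooled, sizes)
        if alternative == "increasing":
            p = float(np.mean(stats_all >= jt_obs - 1e-12))
        elif alternative == "decreasing":
            p = float(np.mean(stats_all <= jt_obs + 1e-12))
        else:
            p = float(np.mean(np.abs(stats_all - mu) >= abs(jt_obs - mu) - 1e-12))
        return TrendTestResult(jt_obs, min(1.0, p), "exact_permutation", sizes, alternative)

    pooled = np.concatenate(gs)
    ties = _tie_counts(pooled)
    t1 = ties * (ties - 1) * (2 * ties + 5)
    t2 = ties * (ties - 1) * (ties - 2)
    t3 = ties * (ties - 1)
    s1 = np.array([s * (s - 1) * (2 * s + 5) for s in sizes], dtype=float)
    s2 = np.array([s * (s - 1) * (s - 2) for s in sizes], dtype=float)
    s3 = np.array([s * (s - 1) for s in sizes], dtype=float)
    var = (
        (n * (n - 1) * (2 * n + 5) - s1.sum() - t1.sum()) / 72.0
        + s2.sum() * t2.sum() / (36.0 * n * (n - 1) * (n - 2))
        + s3.sum() * t3.sum() / (8.0 * n * (n - 1))
    )
    if var <= 0:
        return TrendTestResult(jt_obs, 1.0, "normal_approx", sizes, alternative)
    z = (jt_obs - mu) / np.sqrt(var)
    if alternative == "increasing":
        p = stats.norm.sf(z)
    elif alternative == "decreasing":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return TrendTestResult(jt_obs, float(min(1.0, p)), "normal_approx", sizes, alternative)


def _enumerate_jt(pooled: np.ndarray, sizes: tuple[int, ...]) -> np.ndarray:
    """JT statistic under every distinct assignment of pooled values to groups."""
    out: list[float] = []

    def rec(avail: tuple[int, ...], gi: int, chosen: list[np.ndarray]) -> None:
        if gi == len(sizes) - 1:
            groups = chosen + [pooled[list(avail)]]
            out.append(_jt_statistic(groups))
            return
        for idx in combinations(avail, sizes[gi]):
            rest = tuple(i for i in avail if i not in idx)
            rec(rest, gi + 1, chosen + [pooled[list(idx)]])

    rec(tuple(range(pooled.size)), 0, [])
    return np.asarray(out)


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the empirical ROC curve (ties handled by the trapezoid)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # collapse tied thresholds: keep last index of each run of equal scores
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def roc_analysis(
    scores,
    binary_labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC of ``scores`` against binary labels (1 = positive class).

    AUC by the trapezoidal rule (equal to Mann-Whitney U/(n1 n0) with ties
    counted half); 95% CI by seeded stratified bootstrap; p value for
    AUC = 0.5 via the two-sided rank-sum test on the scores by class.  The
    reported cut point is the smallest observed threshold maximizing
    sensitivity + specificity, classifying ``score >= cut`` as positive.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binary_labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D vectors")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    auc = _auc_trapezoid(scores, labels)

    # optimal observed cut point: score >= t positive
    thresholds = np.unique(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = (-np.inf, np.inf)
    best_stats = (0.0, 0.0, 0.0)
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, float(t))
            acc = (np.sum(pos >= t) + np.sum(neg < t)) / labels.size
            best_stats = (sens, spec, float(acc))

    _, p_half = wilcoxon_rank_sum(pos, neg)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    boot_aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=n_pos, replace=True)
        ni = rng.choice(neg_idx, size=n_neg, replace=True)
        idx = np.concatenate([pi, ni])
        boot_aucs[b] = _auc_trapezoid(scores[idx], labels[idx])
    ci = (float(np.quantile(boot_aucs, 0.025)), float(np.quantile(boot_aucs, 0.975)))

    return RocResult(
        auc=auc,
        ci_95=ci,
        p_vs_half=p_half,
        cut_point=best[1],
        sensitivity=best_stats[0],
        specificity=best_stats[1],
        accuracy=best_stats[2],
        n_pos=n_pos,
        n_neg=n_neg,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up FDR)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


REQUIRED_COLUMNS = (
    "bm_infiltration_pct",
    "beta2_microglobulin",
    "visual_group",
    "cytogenetic_risk",
)


def run_validation(
    cohort: pd.DataFrame,
    approaches: tuple[str, ...] | None = None,
    infiltration_cutoff: float = 60.0,
    seed: int = 0,
    n_boot: int = 2000,
    adjust: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full statistical validation over a cohort table.

    Per approach: Spearman of MTV/TLG vs infiltration % and vs
    beta2-microglobulin; JT trend of MTV/TLG across visual groups A/B/C;
    Wilcoxon rank-sum of MTV/TLG for high- vs standard-risk cytogenetics;
    ROC of MTV/TLG against the ``infiltration >= cutoff`` dichotomy.
    Returns a dict of DataFrames keyed ``correlations``, ``trend``,
    ``cytogenetics``, ``roc_mtv``, ``roc_tlg``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if approaches is None:
        approaches = tuple(
            c.removeprefix("mtv_approach_")
            for c in cohort.columns
            if c.startswith("mtv_approach_")
        )
    if not approaches:
        raise ValueError("cohort table has no mtv_approach_<id> columns")
    for aid in approaches:
        for col in (f"mtv_approach_{aid}", f"tlg_approach_{aid}"):
            if col not in cohort.columns:
                raise ValueError(f"cohort table is missing required columns: ['{col}']")

    infil = cohort["bm_infiltration_pct"].to_numpy(dtype=float)
    b2m = cohort["beta2_microglobulin"].to_numpy(dtype=float)
    group = cohort["visual_group"].to_numpy()
    risk = cohort["cytogenetic_risk"].to_numpy()
    dichot = (infil >= infiltration_cutoff).astype(int)

    corr_rows, trend_rows, cyto_rows, roc_mtv_rows, roc_tlg_rows = [], [], [], [], []
    for aid in approaches:
        mtv = cohort[f"mtv_approach_{aid}"].to_numpy(dtype=float)
        tlg = cohort[f"tlg_approach_{aid}"].to_numpy(dtype=float)

        row = {"approach": aid}
        for name, vals in (("mtv", mtv), ("tlg", tlg)):
            r_i, p_i = spearman_corr(vals, infil)
            r_b, p_b = spearman_corr(vals, b2m)
            row[f"{name}_median"] = float(np.median(vals))
            row[f"{name}_min"] = float(vals.min())
            row[f"{name}_max"] = float(vals.max())
            row[f"{name}_r_infiltration"] = r_i
            row[f"{name}_p_infiltration"] = p_i
            row[f"{name}_r_b2m"] = r_b
            row[f"{name}_p_b2m"] = p_b
        corr_rows.append(row)

        for name, vals in (("mtv", mtv), ("tlg", tlg)):
            ordered = [vals[group == g] for g in ("A", "B", "C") if np.any(group == g)]
            if len(ordered) >= 2:
                res = jonckheere_terpstra(ordered, alternative="two_sided")
                trend_rows.append(
                    {
                        "approach": aid,
                        "variable": name,
                        "jt_statistic": res.jt_statistic,
                        "p_value": res.p_value,
                        "method": res.method,
                        "group_sizes": "/".join(str(s) for s in res.group_sizes),
                    }
                )

        hi = risk == "high"
        lo = risk == "standard"
        if hi.any() and lo.any():
            for name, vals in (("mtv", mtv), ("tlg", tlg)):
                w, p = wilcoxon_rank_sum(vals[hi], vals[lo])
                cyto_rows.append(
                    {
                        "approach": aid,
                        "variable": name,
                        "rank_sum_high_risk": w,
                        "p_value": p,
                        "n_high": int(hi.sum()),
                        "n_standard": int(lo.sum()),
                    }
                )

        if 0 < dichot.sum() < dichot.size:
            for name, vals, sink in (
                ("mtv", mtv, roc_mtv_rows),
                ("tlg", tlg, roc_tlg_rows),
            ):
                roc = roc_analysis(vals, dichot, n_boot=n_boot, seed=seed)
                sink.append(
                    {
                        "approach": aid,
                        "auc": roc.auc,
                        "ci_low": roc.ci_95[0],
                        "ci_high": roc.ci_95[1],
                        "p_vs_half": roc.p_vs_half,
                        "cut_point": roc.cut_point,
                        "sensitivity": roc.sensitivity,
                        "specificity": roc.specificity,
                        "accuracy": roc.accuracy,
                    }
                )

    correlations = pd.DataFrame(corr_rows)
    if adjust == "bh":
        pcols = [c for c in correlations.columns if c.startswith(("mtv_p_", "tlg_p_"))]
        flat = correlations[pcols].to_numpy().ravel()
        correlations[pcols] = benjamini_hochberg(flat).reshape(-1, len(pcols))

    return {
        "correlations": correlations,
        "trend": pd.DataFrame(trend_rows),
        "cytogenetics": pd.DataFrame(cyto_rows),
        "roc_mtv": pd.DataFrame(roc_mtv_rows),
        "roc_tlg": pd.DataFrame(roc_tlg_rows),
    }
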