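"""The study's statistical battery over group-labeled values.

Thin, contract-level wrappers: Wilcoxon rank-sum (Mann-Whitney U),
two-sample Kolmogorov-Smirnov, Fisher's exact test (exact for 2x2,
seeded Monte-Carlo for r x c), one-way ANOVA with Tukey HSD, and the
empirical CDF. All tests are two-sided. Results come back as small
named tuples; a tidy-TSV writer serializes batches of comparisons.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class TestResult(NamedTuple):
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]


def _two_groups(a, b, name: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"{name}: both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError(f"{name}: values must be finite")
    return a, b


def rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact enumeration for small samples without ties, midrank +
    normal approximation with continuity correction otherwise."""
    a, b = _two_groups(a, b, "rank_sum")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_rank_sum", (a.size, b.size))


def signed_rank(a, b) -> TestResult:
    """Paired Wilcoxon signed-rank (non-default variant)."""
    a, b = _two_groups(a, b, "signed_rank")
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_signed_rank", (a.size, b.size))


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b|;
    exact p for small samples, asymptotic otherwise."""
    a, b = _two_groups(a, b, "ks_two_sample")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "ks_two_sample", (a.size, b.size))


def fisher_exact(table, n_mc: int = 100_000, seed: int = 0) -> TestResult:
    """Two-sided Fisher's exact test on an r x c contingency table.

    2x2 tables use the exact hypergeometric sum of tables no more
    probable than the observed one. Larger tables use a seeded
    Monte-Carlo estimate: sample tables with fixed margins (Patefield)
    and count those with probability <= observed; the +1/(n+1)
    correction keeps the estimate a valid p-value. A zero row/column
    margin is degenerate and returns p = 1."""
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D nonnegative integer array")
    n = int(t.sum())
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate margin (all-zero row/column); p = 1")
        return TestResult(float("nan"), 1.0, "fisher_exact", (n,))
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(float(t[0, 0]), float(p), "fisher_exact", (n,))
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    logp_obs = dist.logpmf(t)
    rng = np.random.default_rng(seed)
    samples = dist.rvs(n_mc, random_state=rng)
    logp_samples = np.array([dist.logpmf(s) for s in samples])
    hits = int((logp_samples <= logp_obs + 1e-9).sum())
    p = (hits + 1) / (n_mc + 1)
    return TestResult(float(np.exp(logp_obs)), float(p),
                      "fisher_exact_mc", (n,))


class AnovaResult(NamedTuple):
    F: float
    p: float
    tukey: pd.DataFrame
    n: tuple[int, ...]


def anova_tukey(groups: dict[str, "np.ndarray"]) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD adjusted pairwise comparisons.

    ``groups`` maps label -> values (each n >= 2). Zero within-group
    variance everywhere leaves F undefined (NaN)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    values = list(arrays.values())
    within_ss = sum(((v - v.mean()) ** 2).sum() for v in values)
    if within_ss == 0:
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"])
        return AnovaResult(float("nan"), float("nan"), tukey,
                           tuple(v.size for v in values))
    F, p = sps.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    hsd = pairwise_tukeyhsd(flat, labels)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj"]]
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    return AnovaResult(float(F), float(p), tukey, tuple(v.size for v in values))


def anova_oneway(groups: dict[str, "np.ndarray"]) -> TestResult:
    """One-way ANOVA F test alone (no post-hoc); the p-value is
    identical to :func:`anova_tukey`'s omnibus p."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    F, p = sps.f_oneway(*values)
    return TestResult(float(F), float(p), "anova_oneway",
                      tuple(v.size for v in values))


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: (sorted unique support, cumulative
    fractions ending at 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf needs >= 1 value")
    support, counts = np.unique(v, return_counts=True)
    return support, np.cumsum(counts) / v.size


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the pipeline)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def results_frame(named_results: dict[str, TestResult]) -> pd.DataFrame:
    rows = [
        {"comparison": name, "statistic": r.statistic, "p": r.p,
         "method": r.method, "n": "/".join(str(x) for x in r.n)}
        for name, r in named_results.items()
    ]
    return pd.DataFrame(rows, columns=["comparison", "statistic", "p", "method", "n"])


def write_results(named_results: dict[str, TestResult], path) -> None:
    results_frame(named_results).to_csv(path, sep="\t", index=False)
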