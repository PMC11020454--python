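"""Shared statistical primitives.

All tests are two-sided throughout the package. The three primitives here —
paired t-test, Benjamini–Hochberg step-up adjustment, and one-way ANOVA with
Dunnett many-to-one comparisons — carry exact contracts because every other
module delegates its inference to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, InvalidParameterError, InvalidReferenceError

__all__ = ["TestResult", "paired_t", "bh_adjust", "dunnett"]


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    df: float
    p: float
    test_name: str
    tails: str = "two-sided"
    group_summaries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "test_name": self.test_name,
            "tails": self.tails,
            "group_summaries": self.group_summaries,
        }


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test on matched observations.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b, df = n - 1, sd with ddof=1.

    Raises
    ------
    InvalidParameterError
        Unequal lengths or fewer than two pairs.
    DegenerateTestError
        Zero variance of the pairwise differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise InvalidParameterError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=float(p),
        test_name="paired_t",
        group_summaries={
            "n": int(n),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "mean_diff": float(d.mean()),
        },
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR).

    For sorted p_(1) <= ... <= p_(m):
    padj_(i) = min_{j >= i} min(1, m * p_(j) / j), returned in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("p must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dunnett(
    groups: dict,
    control_label,
    n_mc: int = 100_000,
    seed: int = 20231,
) -> dict:
    """One-way ANOVA with Dunnett's many-to-one comparisons to a control.

    Pooled-variance statistics t_k = (mean_k - mean_ctrl) /
    (s_p * sqrt(1/n_k + 1/n_ctrl)). Family-wise adjusted two-sided p-values
    come from the Dunnett multivariate-t distribution, evaluated by seeded
    Monte Carlo: draws of max_i |T_i| under the null, where T has the
    equicorrelated structure corr(T_i, T_j) = rho_i*rho_j with
    rho_k = sqrt(n_k / (n_k + n_ctrl)).

    Returns
    -------
    dict
        label -> TestResult (adjusted p in ``p``), plus ``"_anova"`` with the
        overall F-test and ``"_mc"`` with the Monte Carlo settings and the
        half-width tolerance ~ 1.96*sqrt(p(1-p)/n_mc).
    """
    if control_label not in groups:
        raise InvalidReferenceError(f"control label {control_label!r} not in groups")
    if len(groups) < 2:
        raise InvalidParameterError("need the control plus at least one comparison group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidParameterError(f"group {k!r} has n < 2")

    ctrl = arrays[control_label]
    others = [k for k in arrays if k != control_label]
    ns = {k: v.size for k, v in arrays.items()}
    n_total = sum(ns.values())
    k_groups = len(arrays)
    df = n_total - k_groups
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    if ss_within == 0:
        raise DegenerateTestError("zero pooled within-group variance")
    s2p = ss_within / df

    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    f_stat = (ss_between / (k_groups - 1)) / s2p
    f_p = stats.f.sf(f_stat, k_groups - 1, df)

    t_stats = {}
    for k in others:
        se = np.sqrt(s2p * (1.0 / ns[k] + 1.0 / ctrl.size))
        t_stats[k] = (arrays[k].mean() - ctrl.mean()) / se

    # Null draws of the Dunnett statistic vector: T_i = (Z_i*rho'_i + W*rho_i)/S
    # gives corr(T_i, T_j) = rho_i*rho_j; S^2 ~ chi2(df)/df shared.
    rng = np.random.default_rng(seed)
    rho = np.array([np.sqrt(ns[k] / (ns[k] + ctrl.size)) for k in others])
    z = rng.standard_normal((n_mc, len(others)))
    w = rng.standard_normal((n_mc, 1))
    s = np.sqrt(rng.chisquare(df, size=(n_mc, 1)) / df)
    t_null = (z * np.sqrt(1.0 - rho**2) + w * rho) / s
    max_abs = np.abs(t_null).max(axis=1)

    results = {}
    for k in others:
        p_adj = float((max_abs >= abs(t_stats[k])).mean())
        results[k] = TestResult(
            statistic=float(t_stats[k]),
            df=float(df),
            p=p_adj,
            test_name="dunnett",
            group_summaries={
                "mean": float(arrays[k].mean()),
                "n": ns[k],
                "control_mean": float(ctrl.mean()),
                "control_n": ctrl.size,
            },
        )
    results["_anova"] = TestResult(
        statistic=float(f_stat),
        df=float(df),
        p=float(f_p),
        test_name="one_way_anova_F",
        group_summaries={"df_between": k_groups - 1, "df_within": df},
    )
    results["_mc"] = {"n_mc": n_mc, "seed": seed, "p_tolerance": float(1.96 * np.sqrt(0.25 / n_mc))}
    return results
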