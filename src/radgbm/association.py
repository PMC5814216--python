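"""Radiomic-genomic and radiomic-outcome association statistics.

Screens every (radiomic feature, genomic entity) pair with tie-aware
Spearman correlation, compares features between patient groups with the
Mann-Whitney U test, regresses phenotypes on mutation/CNV status per gene,
adjusts p-values by Benjamini-Hochberg, and contrasts cluster survival with
Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "spearman_screen",
    "mannwhitney_test",
    "variant_effect_regression",
    "bh_adjust",
    "km_logrank",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t-approximation on n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return p


def spearman_screen(
    radiomic: pd.DataFrame,
    genomic: pd.DataFrame,
    rho_min: float = 0.6,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Tie-aware Spearman screen of features (columns of ``radiomic``,
    patients as rows) against entities (rows of ``genomic``, patients as
    columns).

    Returns the records passing ``|rho| > rho_min`` and ``p < p_max``, with
    BH-adjusted p computed over *all* tested pairs. Pairs with a constant
    vector on either side are skipped and counted in ``attrs['n_skipped']``.
    """
    radiomic = pd.DataFrame(radiomic)
    genomic = pd.DataFrame(genomic)
    shared = [p for p in radiomic.index if p in genomic.columns]
    n = len(shared)
    if n < 5:
        raise ValueError(f"need >=5 shared patients, got {n}")
    r = radiomic.loc[shared]
    g = genomic[shared]

    r_ranks = r.rank(axis=0).to_numpy(dtype=float)  # midranks over patients
    g_ranks = g.rank(axis=1).to_numpy(dtype=float).T
    r_sd = r_ranks.std(axis=0)
    g_sd = g_ranks.std(axis=0)
    ok_r = r_sd > 0
    ok_g = g_sd > 0
    n_skipped = int((~ok_r).sum() * genomic.shape[0] + ok_r.sum() * (~ok_g).sum())

    rz = (r_ranks[:, ok_r] - r_ranks[:, ok_r].mean(axis=0)) / r_sd[ok_r]
    gz = (g_ranks[:, ok_g] - g_ranks[:, ok_g].mean(axis=0)) / g_sd[ok_g]
    rho = rz.T @ gz / n  # features x entities
    pvals = _spearman_p(rho, n)
    adj = bh_adjust(pvals.ravel()).reshape(pvals.shape)

    feats = radiomic.columns[ok_r]
    ents = genomic.index[ok_g]
    fi, ei = np.nonzero((np.abs(rho) > rho_min) & (pvals < p_max))
    records = pd.DataFrame(
        {
            "radiomic_feature": feats[fi],
            "genomic_entity": ents[ei],
            "rho": rho[fi, ei],
            "p_value": pvals[fi, ei],
            "adjusted_p": adj[fi, ei],
            "n_used": n,
        }
    )
    records.attrs["n_skipped"] = n_skipped
    records.attrs["n_tested"] = int(rho.size)
    return records


def _mw_exact_two_sided(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    idx = range(len(pooled))
    u_values = []
    for comb in itertools.combinations(idx, n_x):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        a, b = pooled[sel], pooled[~sel]
        u_values.append(np.sum(a[:, None] > b[None, :]))
    u_values = np.asarray(u_values, dtype=float)
    p_le = np.mean(u_values <= u_obs)
    p_ge = np.mean(u_values >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mannwhitney_test(values, group_a_ids, group_b_ids):
    """Two-sided Mann-Whitney U test of a feature between two groups.

    Exact by enumeration when the combined n is <= 12 and tie-free;
    otherwise a normal approximation with tie and continuity corrections.
    Returns ``(U, p)`` with U counted for group A.
    """
    values = pd.Series(values)
    x = values.loc[list(group_a_ids)].to_numpy(dtype=float)
    y = values.loc[list(group_b_ids)].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(x) + len(y)
    if n < 4:
        raise ValueError("need a combined sample of >=4")
    u = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    if n <= 12 and not has_ties:
        return u, _mw_exact_two_sided(x, y, u)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return u, p


def variant_effect_regression(phenotype, indicator):
    """OLS of a radiomic phenotype on a mutation/CNV indicator.

    Returns a dict with slope, SE, two-sided p and a ``testable`` flag; a
    constant indicator (or fewer than 3 carriers for a binary one) is
    reported untestable rather than raising, mirroring the instability of
    per-gene tests at small carrier counts.
    """
    y = np.asarray(pd.Series(phenotype), dtype=float)
    x = np.asarray(pd.Series(indicator), dtype=float)
    if len(y) != len(x):
        raise ValueError("phenotype and indicator lengths differ")
    if len(y) < 4:
        raise ValueError("need n >= 4")
    result = {"coefficient": np.nan, "se": np.nan, "p_value": np.nan, "n_used": len(y)}
    unique = np.unique(x)
    binary = unique.size == 2 and set(unique) <= {0.0, 1.0}
    if unique.size < 2 or (binary and min((x == 0).sum(), (x == 1).sum()) < 3):
        result["testable"] = False
        return result
    fit = stats.linregress(x, y)
    result.update(
        coefficient=float(fit.slope),
        se=float(fit.stderr),
        p_value=float(fit.pvalue),
        testable=True,
    )
    return result


def km_logrank(survival: pd.DataFrame) -> dict:
    """Kaplan-Meier medians with 95% CIs per group, and the k-group log-rank test.

    ``survival`` needs columns time, event, group. Raises when no events
    are observed or fewer than two groups are present.
    """
    surv = pd.DataFrame(survival)
    groups = sorted(surv["group"].unique())
    if int(surv["event"].sum()) == 0:
        raise ValueError("no events observed; survival contrast undefined")
    summaries = {}
    for g in groups:
        sub = surv[surv["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        summaries[g] = {
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
            "median": float(kmf.median_survival_time_),
            "ci_low": lo,
            "ci_high": hi,
        }
    if len(groups) < 2:
        return {"groups": summaries, "logrank_stat": np.nan, "logrank_p": np.nan}
    test = multivariate_logrank_test(
        surv["time"], surv["group"], surv["event"].astype(bool)
    )
    return {
        "groups": summaries,
        "logrank_stat": float(test.test_statistic),
        "logrank_p": float(test.p_value),
    }
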