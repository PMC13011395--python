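"""Two-group differential-feature selection.

Wilcoxon rank-sum (exact by enumeration for small tie-free inputs,
normal approximation with tie and continuity corrections otherwise),
Benjamini-Hochberg adjustment, pseudo-count fold change, covariate-
adjusted linear-model validation, Fisher exact occurrence tests for KO
carriage, and descriptive host/family summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from virome_ap.profiling import AbundanceMatrix, VOTUCatalog

logger = logging.getLogger(__name__)

EXACT_N_MAX = 12  # exact Wilcoxon enumeration limit (C(12,6) = 924 splits)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank-sum statistic of ``x``, two-sided p).  Exact p by
    enumerating all label assignments when n_x + n_y <= 12 and the pooled
    data are tie-free; otherwise the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0

    ties = np.unique(pooled).size < n
    if n <= EXACT_N_MAX and not ties:
        dev = abs(w - mu)
        hits = total = 0
        rank_values = np.arange(1, n + 1, dtype=float)
        for combo in itertools.combinations(range(n), nx):
            ws = rank_values[list(combo)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-12:
                hits += 1
        return w, hits / total

    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, float(min(1.0, 2.0 * stats.norm.sf(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change(mean_a: float, mean_b: float, epsilon: float = 1e-8) -> float:
    """Pseudo-counted ratio of group means: (mean_a + eps) / (mean_b + eps)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be nonnegative")
    return (mean_a + epsilon) / (mean_b + epsilon)


def select_differential(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    group_col: str = "group",
    fc_min: float = 1.2,
    q_max: float = 0.05,
    abund_min: float = 1e-4,
    epsilon: float = 1e-8,
) -> pd.DataFrame:
    """Per-feature Wilcoxon + BH + fold-change + mean-abundance filters.

    Direction (``"<A>-enriched"`` / ``"<B>-enriched"`` / ``"ns"``) is set
    only when q < q_max AND FC outside [1/fc_min, fc_min] AND overall mean
    abundance > abund_min.  Group A is the alphabetically first label.
    """
    groups = sorted(meta.loc[m.sample_ids, group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    ga, gb = groups
    lab = meta.loc[m.sample_ids, group_col].to_numpy()
    in_a, in_b = lab == ga, lab == gb
    if in_a.sum() < 3 or in_b.sum() < 3:
        logger.warning("a group has fewer than 3 samples; tests run but are underpowered")

    xa, xb = m.values[in_a], m.values[in_b]
    rows = []
    for j, fid in enumerate(m.feature_ids):
        stat, p = wilcoxon_rank_sum(xa[:, j], xb[:, j])
        rows.append((fid, xa[:, j].mean(), xb[:, j].mean(), p))
    tab = pd.DataFrame(rows, columns=["feature_id", "mean_a", "mean_b", "p_raw"])
    tab["fold_change"] = [
        fold_change(a, b, epsilon) for a, b in zip(tab["mean_a"], tab["mean_b"])
    ]
    tab["q_bh"] = bh_adjust(tab["p_raw"].to_numpy())
    overall_mean = m.values.mean(axis=0)
    passes = (
        (tab["q_bh"] < q_max)
        & ((tab["fold_change"] > fc_min) | (tab["fold_change"] < 1.0 / fc_min))
        & (overall_mean > abund_min)
    )
    direction = np.where(
        passes & (tab["fold_change"] > 1.0), f"{ga}-enriched",
        np.where(passes, f"{gb}-enriched", "ns"),
    )
    tab["direction"] = direction
    tab.attrs["group_a"] = ga
    tab.attrs["group_b"] = gb
    tab.attrs["thresholds"] = {"fc_min": fc_min, "q_max": q_max, "abund_min": abund_min}
    return tab


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep_cols: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, keep_cols + [j]]
        if np.linalg.matrix_rank(trial) == len(keep_cols) + 1:
            keep_cols.append(j)
        else:
            logger.warning("dropping collinear covariate %s", names[j])
    return x[:, keep_cols], [names[j] for j in keep_cols]


def covariate_validate(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    diff_table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    group_col: str = "group",
    q_max: float = 0.05,
) -> pd.Series:
    """Covariate-adjusted OLS check of the rank-test selections.

    Arcsine-square-root transformed relative abundances are regressed on a
    group indicator plus covariates; a feature is *validated* when the BH-
    adjusted group-coefficient p is below ``q_max`` and the coefficient
    sign agrees with the rank-test direction.
    """
    meta = meta.loc[m.sample_ids]
    ga = diff_table.attrs.get("group_a", sorted(meta[group_col].unique())[0])
    group_ind = (meta[group_col] == ga).to_numpy(dtype=float)

    cov_cols = []
    cov_names = []
    for c in covariates:
        if c not in meta.columns:
            raise KeyError(f"covariate {c!r} missing from metadata")
        col = meta[c]
        if col.dtype == object:
            col = pd.Categorical(col).codes.astype(float)
        cov_cols.append(np.asarray(col, dtype=float))
        cov_names.append(c)
    n = len(m.sample_ids)
    design = np.column_stack([np.ones(n), group_ind] + cov_cols)
    design, kept = _drop_collinear(design, ["intercept", "group"] + cov_names)
    if "group" not in kept:
        raise ValueError("group indicator is collinear with covariates")
    gi = kept.index("group")

    y = np.arcsin(np.sqrt(np.clip(m.values, 0.0, 1.0)))
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - design.shape[1]
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[gi, gi], 0.0))
    beta = coef[gi]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(se > 0, p, 1.0)  # zero-variance feature -> never validated
    q = bh_adjust(p)

    diff = diff_table.set_index("feature_id").loc[m.feature_ids]
    wants_a = diff["direction"] == f"{ga}-enriched"
    wants_b = diff["direction"].str.endswith("-enriched") & ~wants_a
    sign_ok = np.where(wants_a, beta > 0, np.where(wants_b, beta < 0, False))
    validated = (q < q_max) & sign_ok
    return pd.Series(validated, index=m.feature_ids, name="validated")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    if n == 0:
        return 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()))


def amg_occurrence_test(
    enriched_a: set[str],
    enriched_b: set[str],
    cat: VOTUCatalog,
    min_rate: float = 0.05,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """KO carriage contrast between two disjoint vOTU sets.

    Per KO: a 2x2 table of carriage among set-A vs set-B members, two-
    sided Fisher exact p, BH over all tested KOs; only KOs with carriage
    rate above ``min_rate`` in at least one set and q < q_max are
    reported.
    """
    if not enriched_a or not enriched_b:
        raise ValueError("both enriched sets must be non-empty")
    if enriched_a & enriched_b:
        raise ValueError("enriched sets must be disjoint")
    missing = (enriched_a | enriched_b) - set(cat.votu_ids)
    if missing:
        raise KeyError(f"unknown vOTU id(s): {sorted(missing)[:5]}")

    kos_a = Counter(ko for v in enriched_a for ko in cat.df.loc[v, "ko_set"])
    kos_b = Counter(ko for v in enriched_b for ko in cat.df.loc[v, "ko_set"])
    na, nb = len(enriched_a), len(enriched_b)
    all_kos = sorted(set(kos_a) | set(kos_b))
    rows = []
    for ko in all_kos:
        ca, cb = kos_a.get(ko, 0), kos_b.get(ko, 0)
        p = fisher_exact_two_sided(ca, na - ca, cb, nb - cb)
        enriched_in = "A" if ca / na >= cb / nb else "B"
        rows.append((ko, ca, na, cb, nb, p, enriched_in))
    tab = pd.DataFrame(
        rows, columns=["ko_id", "count_a", "n_a", "count_b", "n_b", "p_fisher", "enriched_in"]
    )
    if tab.empty:
        tab["q_bh"] = []
        return tab
    tab["q_bh"] = bh_adjust(tab["p_fisher"].to_numpy())
    rate_ok = (tab["count_a"] / tab["n_a"] > min_rate) | (tab["count_b"] / tab["n_b"] > min_rate)
    return tab[rate_ok & (tab["q_bh"] < q_max)].reset_index(drop=True)


def host_family_summary(diff_table: pd.DataFrame, cat: VOTUCatalog) -> dict[str, pd.DataFrame]:
    """Descriptive counts of host genus / family / lifestyle per direction."""
    sel = diff_table[diff_table["direction"] != "ns"]
    ids = sel["feature_id"]
    ann = cat.df.reindex(ids)
    out = {}
    for key, col in (("host_genus", "host_genus"), ("family", "family"), ("lifestyle", "lifestyle")):
        labels = ann[col].astype(object).where(ann[col].notna(), "unknown")
        out[key] = pd.crosstab(labels, sel["direction"].to_numpy())
        out[key].index.name = key
    return out
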