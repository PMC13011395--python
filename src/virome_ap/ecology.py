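"""Alpha diversity, sample-accumulation rarefaction, beta-diversity
distances, principal coordinates analysis and PERMANOVA.

All estimators are implemented from first principles on numpy arrays.
Shannon entropy uses the natural log; permutation p-values carry the
(count + 1)/(n_perm + 1) correction so p is never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from virome_ap.differential import bh_adjust
from virome_ap.profiling import AbundanceMatrix

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "jaccard")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.d[np.ix_(idx, idx)], self.metric)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    pct_explained: np.ndarray  # per positive axis, sums to 100
    sample_ids: list[str]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def alpha_diversity(m: AbundanceMatrix) -> pd.DataFrame:
    """Observed richness, Shannon (natural log) and Simpson (1 - sum p^2)."""
    obs = m.presence.sum(axis=1)
    shannon = np.zeros(len(m.sample_ids))
    simpson = np.zeros(len(m.sample_ids))
    for i in range(len(m.sample_ids)):
        p = m.values[i][m.values[i] > 0]
        if p.size == 0:
            logger.warning("sample %s is empty; diversity set to 0", m.sample_ids[i])
            continue
        shannon[i] = float(-(p * np.log(p)).sum())
        simpson[i] = float(1.0 - (p**2).sum())
    return pd.DataFrame(
        {"observed": obs, "shannon": shannon, "simpson": simpson},
        index=pd.Index(m.sample_ids, name="sample_id"),
    )


def rarefaction_curve(
    m: AbundanceMatrix,
    group_mask: np.ndarray | None = None,
    n_orders: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean cumulative richness over random sample orderings.

    Entry k-1 is the expected number of distinct present features among
    the first k samples, averaged over ``n_orders`` shuffles.
    """
    if group_mask is None:
        group_mask = np.ones(len(m.sample_ids), dtype=bool)
    pres = m.presence[np.asarray(group_mask, dtype=bool)]
    ng = pres.shape[0]
    if ng < 1:
        raise ValueError("rarefaction needs at least one sample")
    rng = np.random.default_rng(seed)
    acc = np.zeros(ng)
    for _ in range(n_orders):
        order = rng.permutation(ng)
        cum = np.logical_or.accumulate(pres[order], axis=0)
        acc += cum.sum(axis=1)
    return acc / n_orders


def distance_matrix(m: AbundanceMatrix, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (abundance) or Jaccard (presence) dissimilarity.

    A pair of all-zero samples is assigned distance 0 by convention.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    n = len(m.sample_ids)
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        x = m.values
        for i in range(n):
            diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
            tot = (x[i] + x[i + 1 :]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(tot > 0, diff / tot, 0.0)
            if np.any(tot == 0):
                logger.warning("all-zero sample pair(s); distance set to 0 by convention")
            d[i, i + 1 :] = row
    else:
        p = m.presence.astype(np.float64)
        inter = p @ p.T
        counts = p.sum(axis=1)
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, 1.0 - inter / union, 0.0)
        d = np.triu(jac, k=1)
    d = d + d.T
    return DistanceMatrix(list(m.sample_ids), d, metric)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical multidimensional scaling via Gower double-centering.

    Coordinates are produced for positive eigenvalues only; negative
    eigenvalues are reported unchanged (no Lingoes/Cailliez correction),
    and percent-explained is taken over the positive part.
    """
    n = len(dm.sample_ids)
    if n < 2:
        raise ValueError("pcoa needs at least 2 samples")
    a = -0.5 * dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = np.abs(evals).max() * 1e-10 if evals.size else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=coords, eigenvalues=evals, pct_explained=pct, sample_ids=list(dm.sample_ids)
    )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) in Anderson's distance form."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based pseudo-F test with label-permutation p-value."""
    labels = np.asarray(labels)
    if len(labels) != len(dm.sample_ids):
        raise ValueError("labels length mismatch")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("permanova requires at least two groups")
    n = len(labels)
    d2 = dm.d**2
    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(n)]
        _, ss_w = _permanova_ss(d2, perm_codes, a)
        ss_b = ss_total - ss_w
        f_perm = (ss_b / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p), n_permutations=n_perm)


def permanova_exact(dm: DistanceMatrix, labels) -> PermanovaResult:
    """Exact permutation p by full enumeration (small n only)."""
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(labels)
    if n > 9:
        raise ValueError("full enumeration is limited to n <= 9")
    d2 = dm.d**2
    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        pc = codes[list(perm)]
        _, ss_w = _permanova_ss(d2, pc, a)
        ss_b = ss_total - ss_w
        f_p = (ss_b / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
        total += 1
        if f_p >= f_obs:
            hits += 1
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p=hits / total, n_permutations=total
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA on every unordered group pair with BH-adjusted p."""
    labels = np.asarray(labels)
    groups = sorted(np.unique(labels))
    rows = []
    rng = np.random.default_rng(seed)
    for ga, gb in itertools.combinations(groups, 2):
        mask = (labels == ga) | (labels == gb)
        sub_ids = [s for s, keep in zip(dm.sample_ids, mask) if keep]
        sub = dm.subset(sub_ids)
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append((ga, gb, res.pseudo_F, res.R2, res.p, res.n_permutations))
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "pseudo_F", "R2", "p", "n_permutations"]
    )
    out["q_bh"] = bh_adjust(out["p"].to_numpy())
    return out
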