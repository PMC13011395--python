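"""Synthetic cohort generator with planted ground truth.

Produces a viral catalog, case/control abundance matrices, sample
metadata with severity/etiology strata and clinical variables, read
alignments consistent with the profiler, and the planted-effect ground
truth needed to score every downstream stage offline.

Abundance model: log-normal relative abundances with independent
Bernoulli zero-inflation.  Differential features receive a group-mean
log2 shift of ``planted_log2fc``; monotone features receive a per-
severity-rank shift; planted correlation edges are realised through a
shared latent Gaussian with Pearson r chosen so the induced Spearman
rho matches ``planted_edge_rho``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from virome_ap.profiling import ALIGNMENT_COLUMNS, AbundanceMatrix, VOTUCatalog

CLINICAL_NAMES = [
    "WBC", "NEUT_pct", "ALT", "AST", "GGT", "ALP", "TB", "DB", "CHOL", "TG", "GLU",
]

FAMILY_POOL = [
    "Microviridae", "Winoviridae", "Peduoviridae", "Guelinviridae",
    "Retroviridae", "Herelleviridae", "Phycodnaviridae", "Casjensviridae",
    "Siphoviridae", "Myoviridae",
]

HOST_GENUS_POOL = [
    "Bacteroides", "Parabacteroides", "Escherichia", "Faecalibacterium",
    "Blautia_A", "Faecalicatena", "Roseburia", "Prevotella", "Enterococcus",
    "Clostridium",
]

HOST_FAMILY_OF_GENUS = {
    "Bacteroides": "Bacteroidaceae",
    "Parabacteroides": "Tannerellaceae",
    "Escherichia": "Enterobacteriaceae",
    "Faecalibacterium": "Ruminococcaceae",
    "Blautia_A": "Lachnospiraceae",
    "Faecalicatena": "Lachnospiraceae",
    "Roseburia": "Lachnospiraceae",
    "Prevotella": "Prevotellaceae",
    "Enterococcus": "Enterococcaceae",
    "Clostridium": "Clostridiaceae",
}

SEVERITY_LEVELS = ["MAP", "MSAP", "SAP"]
# cohort class balance used for default severity assignment
SEVERITY_WEIGHTS = np.array([38, 25, 19], dtype=float)
ETIOLOGY_LEVELS = ["ABP", "AHP", "APN", "other"]
ETIOLOGY_WEIGHTS = np.array([51, 12, 7, 12], dtype=float)


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic cohort.  Equal seeds give bit-identical output."""

    n_ap: int = 50
    n_hc: int = 50
    n_votus: int = 200
    n_bacteria: int = 40
    n_clinical: int = 11
    frac_differential: float = 0.15
    planted_log2fc: float = 2.0
    frac_monotone: float = 0.10
    sparsity: float = 0.30
    dispersion: float = 1.0
    n_planted_edges: int = 10
    planted_edge_rho: float = 0.7
    unassigned_family_frac: float = 0.85
    reads_per_sample: int = 20_000
    read_length: int = 100
    frac_secondary: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ap", "n_hc", "n_votus", "n_bacteria", "n_clinical"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_differential", "frac_monotone", "sparsity",
                     "unassigned_family_frac", "frac_secondary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 < self.planted_edge_rho < 1.0:
            raise ValueError("planted_edge_rho must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted effects: which features carry which signal."""

    differential_votus: dict[str, str] = field(default_factory=dict)
    monotone_votus: dict[str, str] = field(default_factory=dict)
    planted_edges: set[tuple[str, str, str]] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "differential_votus": self.differential_votus,
            "monotone_votus": self.monotone_votus,
            "planted_edges": sorted(list(e) for e in self.planted_edges),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            differential_votus=payload["differential_votus"],
            monotone_votus=payload["monotone_votus"],
            planted_edges={tuple(e) for e in payload["planted_edges"]},
        )


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_catalog(cfg: SyntheticConfig) -> VOTUCatalog:
    """Random vOTU catalog: lengths in [2 kb, 100 kb], mostly family-unassigned."""
    rng = _rng(cfg, 0)
    n = cfg.n_votus
    width = len(str(n))
    ids = [f"vOTU_{i + 1:0{width}d}" for i in range(n)]
    lengths = rng.integers(2_000, 100_001, size=n)
    unassigned = rng.random(n) < cfg.unassigned_family_frac
    families = np.where(unassigned, "unassigned", rng.choice(FAMILY_POOL, size=n))
    lifestyles = rng.choice(["lytic", "temperate", "unknown"], size=n, p=[0.45, 0.35, 0.20])
    completeness = np.round(rng.uniform(50.0, 100.0, size=n), 2)
    has_host = rng.random(n) < 0.6
    genus_draw = rng.choice(HOST_GENUS_POOL, size=n)
    host_genus = [g if h else None for g, h in zip(genus_draw, has_host)]
    host_family = [HOST_FAMILY_OF_GENUS[g] if g is not None else None for g in host_genus]
    ko_pool = [f"K{i:05d}" for i in range(1, 201)]
    n_kos = rng.integers(0, 21, size=n)
    ko_sets = [
        frozenset(rng.choice(ko_pool, size=k, replace=False)) if k else frozenset()
        for k in n_kos
    ]
    df = pd.DataFrame(
        {
            "genome_length": lengths,
            "family": families,
            "lifestyle": lifestyles,
            "completeness": completeness,
            "host_genus": host_genus,
            "host_family": host_family,
            "ko_set": ko_sets,
        },
        index=pd.Index(ids, name="votu_id"),
    )
    return VOTUCatalog(df)


def _proportional_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n into len(weights) classes."""
    quota = n * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="mergesort")
    base[order[:rem]] += 1
    return base


def generate_cohort(
    cfg: SyntheticConfig, cat: VOTUCatalog
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, GroundTruth]:
    """Viral + bacterial abundance matrices, metadata and ground truth.

    Raises ``ValueError`` when ``frac_differential`` is nonzero but rounds
    to fewer than one planted feature.
    """
    if len(cat) != cfg.n_votus:
        raise ValueError("catalog size does not match config")
    n_diff = round(cfg.frac_differential * cfg.n_votus)
    if cfg.frac_differential > 0 and n_diff < 1:
        raise ValueError("frac_differential * n_votus < 1: no differential feature to plant")
    rng = _rng(cfg, 1)

    n = cfg.n_ap + cfg.n_hc
    samples = [f"AP_{i + 1:03d}" for i in range(cfg.n_ap)] + [
        f"HC_{i + 1:03d}" for i in range(cfg.n_hc)
    ]
    is_ap = np.array([s.startswith("AP_") for s in samples])

    # --- metadata -----------------------------------------------------
    severity = np.array([""] * n, dtype=object)
    sev_counts = _proportional_counts(cfg.n_ap, SEVERITY_WEIGHTS)
    sev_labels = np.repeat(SEVERITY_LEVELS, sev_counts)
    rng.shuffle(sev_labels)
    severity[is_ap] = sev_labels
    etiology = np.array([""] * n, dtype=object)
    eti_counts = _proportional_counts(cfg.n_ap, ETIOLOGY_WEIGHTS)
    eti_labels = np.repeat(ETIOLOGY_LEVELS, eti_counts)
    rng.shuffle(eti_labels)
    etiology[is_ap] = eti_labels

    meta = pd.DataFrame(
        {
            "group": np.where(is_ap, "AP", "HC"),
            "severity": severity,
            "etiology": etiology,
            "age": np.round(rng.normal(52.0, 12.0, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "bmi": np.round(rng.normal(23.5, 3.0, size=n), 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # --- planted feature assignment ----------------------------------
    votu_ids = np.array(cat.votu_ids)
    perm = rng.permutation(cfg.n_votus)
    diff_idx = perm[:n_diff]
    n_mono = round(cfg.frac_monotone * cfg.n_votus)
    mono_idx = perm[n_diff : n_diff + n_mono]
    free_idx = perm[n_diff + n_mono :]

    truth = GroundTruth()
    half = n_diff // 2
    ap_enriched = diff_idx[:half] if n_diff else diff_idx
    hc_enriched = diff_idx[half:]
    for i in ap_enriched:
        truth.differential_votus[votu_ids[i]] = "AP-enriched"
    for i in hc_enriched:
        truth.differential_votus[votu_ids[i]] = "HC-enriched"
    mono_half = n_mono // 2
    mono_inc = mono_idx[:mono_half] if n_mono else mono_idx
    mono_dec = mono_idx[mono_half:]
    for i in mono_inc:
        truth.monotone_votus[votu_ids[i]] = "increasing"
    for i in mono_dec:
        truth.monotone_votus[votu_ids[i]] = "decreasing"

    # --- latent log-normal viral abundances ---------------------------
    ln2 = math.log(2.0)
    base_mu = rng.normal(0.0, 1.0, size=cfg.n_votus)
    # planted features sit at typical abundance so the planted mass cannot
    # dominate per-sample totals and bleed compositional fold changes into
    # the null features
    base_mu[diff_idx] = 0.0
    base_mu[mono_idx] = 0.0
    z_virus = rng.normal(0.0, 1.0, size=(n, cfg.n_votus))
    log_ab = base_mu[None, :] + cfg.dispersion * z_virus

    shift = cfg.planted_log2fc * ln2
    log_ab[np.ix_(is_ap, ap_enriched)] += shift
    log_ab[np.ix_(~is_ap, hc_enriched)] += shift

    sev_rank = np.zeros(n)
    for r, lev in enumerate(SEVERITY_LEVELS, start=1):
        sev_rank[severity == lev] = r
    centered = np.where(is_ap, sev_rank - 2.0, 0.0)  # MAP:-1, MSAP:0, SAP:+1
    step = shift  # planted_log2fc per severity step
    for i in mono_inc:
        log_ab[:, i] += step * centered
    for i in mono_dec:
        log_ab[:, i] -= step * centered

    # --- planted correlation edges ------------------------------------
    # Pearson r on latent Gaussians chosen so Spearman ~= planted_edge_rho
    r_latent = 2.0 * math.sin(math.pi * cfg.planted_edge_rho / 6.0)
    n_edges = cfg.n_planted_edges
    if n_edges > len(free_idx):
        raise ValueError("not enough non-planted vOTUs to carry planted edges")
    edge_virus = free_idx[:n_edges]
    clin_names = (CLINICAL_NAMES + [f"CLIN_{i:02d}" for i in range(12, 100)])[: cfg.n_clinical]
    bact_ids = [f"sp_{i + 1:03d}" for i in range(cfg.n_bacteria)]

    bact_mu = rng.normal(0.0, 1.0, size=cfg.n_bacteria)
    z_bact = rng.normal(0.0, 1.0, size=(n, cfg.n_bacteria))

    clin_base = rng.normal(0.0, 1.0, size=(n, cfg.n_clinical))
    clin_mean = rng.uniform(1.0, 100.0, size=cfg.n_clinical)
    clin_sd = clin_mean * 0.2

    edge_targets: list[tuple[str, str, str]] = []
    for k, vi in enumerate(edge_virus):
        zv = z_virus[:, vi]
        sign = "+" if k % 2 == 0 else "-"
        r_signed = r_latent if sign == "+" else -r_latent
        if k < cfg.n_clinical:  # virus-clinical edge
            ci = k
            eps = clin_base[:, ci]
            clin_base[:, ci] = r_signed * zv + math.sqrt(1 - r_latent**2) * eps
            edge_targets.append((votu_ids[vi], clin_names[ci], sign))
        else:  # virus-bacterium edge
            bi = (k - cfg.n_clinical) % cfg.n_bacteria
            eps = z_bact[:, bi]
            z_bact[:, bi] = r_signed * zv + math.sqrt(1 - r_latent**2) * eps
            edge_targets.append((votu_ids[vi], bact_ids[bi], sign))
    truth.planted_edges = set(edge_targets)
    edge_feature_idx = set(edge_virus.tolist())

    clinical = clin_mean[None, :] + clin_sd[None, :] * clin_base
    for j, name in enumerate(clin_names):
        meta[name] = np.round(clinical[:, j], 3)

    # --- zero inflation and normalization -----------------------------
    abund = np.exp(log_ab)
    if cfg.sparsity > 0:
        zeros = rng.random(abund.shape) < cfg.sparsity
        # keep planted-edge carriers dense so the planted rho survives
        for i in edge_feature_idx:
            zeros[:, i] = False
        abund[zeros] = 0.0
    viral = AbundanceMatrix(
        sample_ids=samples, feature_ids=votu_ids.tolist(), values=abund, level="votu"
    ).renormalized()

    bact_ab = np.exp(bact_mu[None, :] + cfg.dispersion * z_bact)
    bacterial = AbundanceMatrix(
        sample_ids=samples, feature_ids=bact_ids, values=bact_ab, level="species"
    ).renormalized()

    return viral, bacterial, meta, truth


def generate_alignments(
    cfg: SyntheticConfig,
    cat: VOTUCatalog,
    abundance: AbundanceMatrix,
) -> pd.DataFrame:
    """Per-sample alignment records consistent with the profiler.

    Primary read counts per vOTU are multinomial with probabilities
    proportional to abundance x genome length (the profiler divides by
    length again, so quantification round-trips).  A ``frac_secondary``
    fraction of reads additionally gets a tied secondary hit on another
    vOTU to exercise best-hit resolution.  Returns a DataFrame with
    :data:`ALIGNMENT_COLUMNS` plus a boolean ``secondary`` column.
    """
    if list(abundance.feature_ids) != list(cat.votu_ids):
        raise ValueError("abundance features do not match catalog")
    rng = _rng(cfg, 2)
    lengths = cat.genome_lengths.to_numpy(dtype=np.int64)
    votu_ids = np.array(cat.votu_ids)
    frames = []
    for si, sample in enumerate(abundance.sample_ids):
        weights = abundance.values[si] * lengths
        total = weights.sum()
        if total == 0:
            continue
        counts = rng.multinomial(cfg.reads_per_sample, weights / total)
        votu_col = np.repeat(np.arange(len(votu_ids)), counts)
        rng.shuffle(votu_col)
        n_reads = votu_col.size
        L = lengths[votu_col]
        starts = (rng.random(n_reads) * (L - cfg.read_length + 1)).astype(np.int64)
        read_ids = np.array([f"{sample}_r{i + 1}" for i in range(n_reads)])
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "read_id": read_ids,
                    "votu_id": votu_ids[votu_col],
                    "start": starts,
                    "end": starts + cfg.read_length,
                    "score": float(cfg.read_length),
                    "secondary": False,
                }
            )
        )
        if cfg.frac_secondary > 0 and len(votu_ids) > 1:
            n_sec = int(round(cfg.frac_secondary * n_reads))
            if n_sec:
                pick = rng.choice(n_reads, size=n_sec, replace=False)
                other = rng.integers(0, len(votu_ids) - 1, size=n_sec)
                other = np.where(other >= votu_col[pick], other + 1, other)
                L2 = lengths[other]
                s2 = (rng.random(n_sec) * (L2 - cfg.read_length + 1)).astype(np.int64)
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample,
                            "read_id": read_ids[pick],
                            "votu_id": votu_ids[other],
                            "start": s2,
                            "end": s2 + cfg.read_length,
                            "score": float(cfg.read_length),
                            "secondary": True,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS + ["secondary"])
    out = pd.concat(frames, ignore_index=True)
    return out[ALIGNMENT_COLUMNS + ["secondary"]]


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
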