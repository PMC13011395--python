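"""Severity-gradient analysis.

Cumulative abundance of feature sets across ordered severity strata and
detection of features whose abundance changes monotonically along the
gradient (strictly ordered group means plus a significant Spearman
trend).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from virome_ap.classifier import CVSpec, cross_validated_auc, feature_count_curve
from virome_ap.differential import bh_adjust
from virome_ap.network import spearman
from virome_ap.profiling import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class SeverityOrder:
    """Ordered severity labels mapped to strictly increasing ranks."""

    labels: list[str] = field(default_factory=lambda: ["MAP", "MSAP", "SAP"])

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least two ordered levels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("severity labels must be unique")

    @property
    def ranks(self) -> dict[str, int]:
        return {lab: i + 1 for i, lab in enumerate(self.labels)}

    def reversed(self) -> "SeverityOrder":
        return SeverityOrder(list(reversed(self.labels)))


def cumulative_set_abundance(
    m: AbundanceMatrix,
    feature_set: set[str],
    meta: pd.DataFrame,
    order: SeverityOrder | None = None,
    severity_col: str = "severity",
) -> pd.DataFrame:
    """Per-sample summed abundance over a feature set, tagged by severity."""
    if not feature_set:
        raise ValueError("feature set is empty")
    missing = feature_set - set(m.feature_ids)
    if missing:
        raise KeyError(f"features not in matrix: {sorted(missing)[:5]}")
    order = order or SeverityOrder()
    cols = [m.feature_ids.index(f) for f in sorted(feature_set)]
    sums = m.values[:, cols].sum(axis=1)
    sev = meta.loc[m.sample_ids, severity_col]
    out = pd.DataFrame(
        {"cumulative_abundance": sums, "severity": sev.to_numpy()},
        index=pd.Index(m.sample_ids, name="sample_id"),
    )
    return out[out["severity"].isin(order.labels)]


def detect_monotone(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    order: SeverityOrder | None = None,
    q_max: float = 0.05,
    severity_col: str = "severity",
) -> pd.DataFrame:
    """Features with strictly ordered severity-group means and a
    BH-significant Spearman trend of abundance vs severity rank."""
    order = order or SeverityOrder()
    sev = meta.loc[m.sample_ids, severity_col]
    present_levels = [lab for lab in order.labels if (sev == lab).sum() > 0]
    if len(present_levels) < len(order.labels):
        logger.warning(
            "severity level(s) absent: %s; proceeding on available levels",
            sorted(set(order.labels) - set(present_levels)),
        )
    if len(present_levels) < 2:
        raise ValueError("need at least two severity levels with samples")
    ranks = order.ranks
    in_scope = sev.isin(present_levels).to_numpy()
    sev_rank = sev[in_scope].map(ranks).to_numpy(dtype=float)
    x = m.values[in_scope]

    rows = []
    for j, fid in enumerate(m.feature_ids):
        vals = x[:, j]
        means = {lab: vals[sev[in_scope] == lab].mean() for lab in present_levels}
        seq = [means[lab] for lab in present_levels]
        increasing = all(a < b for a, b in zip(seq, seq[1:]))
        decreasing = all(a > b for a, b in zip(seq, seq[1:]))
        rho, p = spearman(vals, sev_rank)
        rows.append((fid, means, increasing, decreasing, rho, p))
    tab = pd.DataFrame(
        rows, columns=["feature_id", "group_means", "increasing", "decreasing", "trend_rho", "trend_p"]
    )
    tab["trend_q"] = bh_adjust(tab["trend_p"].fillna(1.0).to_numpy())
    tab["monotone_direction"] = np.where(
        tab["increasing"] & (tab["trend_q"] < q_max), "increasing",
        np.where(tab["decreasing"] & (tab["trend_q"] < q_max), "decreasing", "none"),
    )
    return tab.drop(columns=["increasing", "decreasing"])


def severity_models(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    selected: list[str],
    cv_spec: CVSpec | None = None,
    order: SeverityOrder | None = None,
    control_label: str = "HC",
    group_col: str = "group",
    severity_col: str = "severity",
    ks: list[int] | None = None,
):
    """One classifier per severity level vs the control group.

    Returns a dict severity-label -> report dict with the cross-validated
    AUC report and (optionally) the feature-count curve.
    """
    order = order or SeverityOrder()
    cv_spec = cv_spec or CVSpec()
    meta = meta.loc[m.sample_ids]
    cols = [m.feature_ids.index(f) for f in selected]
    reports = {}
    for lab in order.labels:
        mask = ((meta[severity_col] == lab) | (meta[group_col] == control_label)).to_numpy()
        if (meta[severity_col] == lab).sum() < cv_spec.n_folds:
            logger.warning("severity %s has fewer samples than folds; skipped", lab)
            continue
        X = pd.DataFrame(
            m.values[mask][:, cols],
            index=np.array(m.sample_ids)[mask],
            columns=selected,
        )
        y = (meta.loc[X.index, severity_col] == lab).to_numpy(dtype=int)
        report = cross_validated_auc(X, y, cv_spec)
        entry = {"report": report}
        if ks:
            entry["feature_curve"] = feature_count_curve(X, y, cv_spec, ks)
        reports[lab] = entry
    return reports
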