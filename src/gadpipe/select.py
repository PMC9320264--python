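"""ANOVA-based feature screening and connectivity summaries.

Each feature column is tested with a one-way ANOVA between the two groups
(with two groups, F equals the squared pooled-variance t statistic and both
tests share a p-value); columns with p below the threshold are retained.
No multiple-testing correction is applied by default, mirroring the common
mass-univariate screening practice; an optional Benjamini-Hochberg mode is
available.  Epochs are treated as independent samples by default; because
50 %-overlap epochs from one subject are strongly dependent, a
``per_subject`` mode first averages epochs within subject and tests the
independent subject means instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .montage import FRONTAL_CHANNELS
from .features import FeatureColumn, FeatureTable


@dataclass
class SelectionResult:
    """Per-feature p-values and the retained mask at threshold ``alpha``."""

    p_values: np.ndarray
    mask: np.ndarray
    alpha: float
    columns: list[FeatureColumn]
    group_labels: tuple[str, str]
    per_subject: bool = False
    fdr: bool = False
    counts: pd.DataFrame = field(default=None)  # retained per (kind, band)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def band_mask(self, band: str) -> np.ndarray:
        """Retained-feature mask restricted to one rhythm band."""
        return self.mask & np.array([c.band == band for c in self.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [c.name for c in self.columns],
                "kind": [c.kind for c in self.columns],
                "band": [c.band for c in self.columns],
                "channels": ["-".join(c.channels) for c in self.columns],
                "p": self.p_values,
                "retained": self.mask,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _group_arrays(table: FeatureTable, per_subject: bool):
    groups = table.row_meta["group"].to_numpy()
    labels = tuple(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    if per_subject:
        df = pd.DataFrame(table.values)
        df["subject_id"] = table.row_meta["subject_id"].to_numpy()
        df["group"] = groups
        agg = df.groupby(["group", "subject_id"], sort=False).mean()
        g = agg.index.get_level_values("group").to_numpy()
        vals = agg.to_numpy()
        parts = tuple(vals[g == lab] for lab in labels)
    else:
        parts = tuple(table.values[groups == lab] for lab in labels)
    for lab, p in zip(labels, parts):
        if p.shape[0] < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    return labels, parts


def anova_select(
    table: FeatureTable,
    alpha: float = 0.05,
    per_subject: bool = False,
    fdr: bool = False,
) -> SelectionResult:
    """One-way ANOVA per feature column; retain columns with p < alpha.

    Constant columns (zero pooled variance) are assigned p = 1 and never
    retained.  With ``fdr=True`` the Benjamini-Hochberg adjusted p-values
    are thresholded instead of the raw ones.
    """
    labels, (a, b) = _group_arrays(table, per_subject)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(a, b, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    stacked = np.concatenate([a, b], axis=0)
    degenerate = np.var(stacked, axis=0) == 0
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0

    p_thresh = p
    if fdr:
        p_thresh = false_discovery_adjust(p)
    mask = p_thresh < alpha

    counts = (
        pd.DataFrame(
            {
                "kind": [c.kind for c in table.columns],
                "band": [c.band for c in table.columns],
                "retained": mask,
            }
        )
        .groupby(["kind", "band"], sort=False)["retained"]
        .sum()
        .reset_index()
    )
    return SelectionResult(
        p_values=p,
        mask=mask,
        alpha=alpha,
        columns=list(table.columns),
        group_labels=labels,
        per_subject=per_subject,
        fdr=fdr,
        counts=counts,
    )


def false_discovery_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def frontal_edge_ratio(
    selected: SelectionResult,
    frontal: frozenset[str] | set[str] = FRONTAL_CHANNELS,
) -> float:
    """Fraction of retained connectivity edges touching a frontal channel."""
    retained_pli = [
        c
        for c, keep in zip(selected.columns, selected.mask)
        if keep and c.kind == "PLI"
    ]
    if not retained_pli:
        raise ValueError("no retained PLI features: frontal ratio undefined")
    touching = sum(1 for c in retained_pli if set(c.channels) & set(frontal))
    return touching / len(retained_pli)


def direction_summary(table: FeatureTable, selected: SelectionResult) -> pd.DataFrame:
    """Sign of the patient-minus-control mean difference per retained feature.

    The first group label encountered in the table ("GAD" in synthetic
    cohorts) is treated as the patient group.  Returns one row per retained
    feature with columns (feature, kind, band, channels, diff, sign).
    """
    lab_pos, lab_neg = selected.group_labels
    groups = table.row_meta["group"].to_numpy()
    mean_pos = table.values[groups == lab_pos].mean(axis=0)
    mean_neg = table.values[groups == lab_neg].mean(axis=0)
    diff = mean_pos - mean_neg
    rows = [
        {
            "feature": c.name,
            "kind": c.kind,
            "band": c.band,
            "channels": "-".join(c.channels),
            "diff": diff[i],
            "sign": int(np.sign(diff[i])),
        }
        for i, (c, keep) in enumerate(zip(selected.columns, selected.mask))
        if keep
    ]
    return pd.DataFrame(
        rows, columns=["feature", "kind", "band", "channels", "diff", "sign"]
    )
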