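"""Global normalization and screen quality metrics.

Quality is judged by separation of control gene sets: common essential genes
(positive controls, expected near -1 after scaling) and per-line negative
controls.  When an expression matrix is available the negative controls are
that line's unexpressed genes (expression < 0.01), whose knockout should be
inert; otherwise a reference nonessential list is used.

Metrics: NNMD (null-normalized median difference — the only metric here
sensitive to rank-preserving transformations), the unexpressed false
positive rate (fraction of a line's unexpressed genes scoring in its most
depleted 15%, 15% being the typical prevalence of true dependencies), and
precision-recall of the essential controls (PR AUC and recall at 90%
precision, scoring by negated gene effect).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .screen_data import GeneEffectMatrix

logger = logging.getLogger("chronokit")

UNEXPRESSED_THRESHOLD = 0.01
DEFAULT_DEPLETED_FRACTION = 0.15


@dataclasses.dataclass
class ControlSets:
    """Reference gene lists (and optional expression) for normalization/QC."""

    essential_genes: list
    nonessential_genes: list
    expression: pd.DataFrame | None = None  # cell line x gene, linear scale

    def __post_init__(self) -> None:
        overlap = set(self.essential_genes) & set(self.nonessential_genes)
        if overlap:
            raise ValueError(
                f"control lists overlap: {sorted(overlap)[:5]}"
            )

    def unexpressed(self, cell_line, genes) -> pd.Index:
        """Genes with expression < 0.01 in the given line, within ``genes``."""
        if self.expression is None:
            raise ValueError("no expression matrix provided")
        row = self.expression.loc[cell_line].reindex(genes)
        return row.index[row < UNEXPRESSED_THRESHOLD]


def normalize_global(
    matrix: GeneEffectMatrix | pd.DataFrame, controls: ControlSets
) -> GeneEffectMatrix:
    """One global affine map sending control medians-of-medians to (0, -1).

    Per cell line, take the median gene effect of the nonessential and of
    the essential controls; shift and scale the whole matrix so the median
    over lines of the former is 0 and of the latter is -1.  A positive-slope
    affine map commutes with medians, so the postcondition is exact.
    """
    frame = getattr(matrix, "data", matrix)
    ess = frame.columns.intersection(pd.Index(controls.essential_genes))
    ness = frame.columns.intersection(pd.Index(controls.nonessential_genes))
    if len(ess) == 0 or len(ness) == 0:
        raise ValueError("need at least one essential and one nonessential control gene")
    m_ess = frame[ess].median(axis=1).median()
    m_ness = frame[ness].median(axis=1).median()
    if m_ness <= m_ess:
        raise ValueError(
            "nonessential and essential control medians do not separate "
            f"({m_ness:.4g} <= {m_ess:.4g}); global scale undefined"
        )
    # direct division keeps the control medians exact: (m_ess-m_ness)/(m_ness-m_ess) == -1
    out = (frame - m_ness) / (m_ness - m_ess)
    return GeneEffectMatrix(data=out, normalization="globally_scaled")


def nnmd(positive_scores, negative_scores) -> float:
    """(median(pos) - median(neg)) / MAD(neg); more negative = better.

    MAD is the raw median absolute deviation (no consistency constant).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both control sets must be nonempty")
    mad = np.median(np.abs(neg - np.median(neg)))
    if mad == 0:
        raise ValueError("negative controls have zero median absolute deviation")
    return float((np.median(pos) - np.median(neg)) / mad)


def unexpressed_false_positive_rate(
    matrix: GeneEffectMatrix | pd.DataFrame,
    controls: ControlSets,
    depleted_fraction: float = DEFAULT_DEPLETED_FRACTION,
) -> tuple[pd.Series, float]:
    """Fraction of each line's unexpressed genes in its most-depleted tail.

    Membership in the tail is by rank: the ``floor(depleted_fraction * n)``
    lowest-scoring genes of the line.  Lines without unexpressed genes get
    NaN and are excluded from the pooled rate (total false positives over
    total unexpressed genes across lines).
    """
    frame = getattr(matrix, "data", matrix)
    rates = {}
    fp_total = unexpr_total = 0
    for line in frame.index:
        scores = frame.loc[line].dropna()
        unexpr = controls.unexpressed(line, scores.index)
        if len(unexpr) == 0:
            rates[line] = np.nan
            continue
        k = int(np.floor(depleted_fraction * len(scores)))
        depleted = scores.nsmallest(k).index
        fp = len(depleted.intersection(unexpr))
        rates[line] = fp / len(unexpr)
        fp_total += fp
        unexpr_total += len(unexpr)
    pooled = fp_total / unexpr_total if unexpr_total else np.nan
    return pd.Series(rates, name="unexpressed_fp_rate"), float(pooled)


def essential_recall_metrics(
    matrix: GeneEffectMatrix | pd.DataFrame,
    controls: ControlSets,
    precision_target: float = 0.90,
) -> pd.DataFrame:
    """Per-line PR AUC and recall at 90% precision for essential controls.

    Positives are the essential control genes; negatives are the line's
    unexpressed genes; the ranking score is the negated gene effect (deeper
    depletion = higher score).  Average precision is used as the PR AUC
    (step interpolation; tied scores share a threshold).  Lines lacking
    either class give NaN with a warning.
    """
    frame = getattr(matrix, "data", matrix)
    rows = {}
    ess = pd.Index(controls.essential_genes)
    for line in frame.index:
        scores = frame.loc[line].dropna()
        pos = scores.index.intersection(ess)
        neg = controls.unexpressed(line, scores.index).difference(ess)
        if len(pos) == 0 or len(neg) == 0:
            logger.warning("line %r lacks a control class; metrics are NaN", line)
            rows[line] = {"pr_auc": np.nan, "recall_at_90_precision": np.nan}
            continue
        labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        y = np.r_[-scores[pos].to_numpy(), -scores[neg].to_numpy()]
        auc = float(average_precision_score(labels, y))
        precision, recall, _ = precision_recall_curve(labels, y)
        feasible = precision[:-1] >= precision_target  # last point is (p=1, r=0)
        recall90 = float(recall[:-1][feasible].max()) if feasible.any() else 0.0
        rows[line] = {"pr_auc": auc, "recall_at_90_precision": recall90}
    return pd.DataFrame.from_dict(rows, orient="index")


def qc_report(
    matrix: GeneEffectMatrix | pd.DataFrame,
    controls: ControlSets,
    depleted_fraction: float = DEFAULT_DEPLETED_FRACTION,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-line QC table (NNMD, FP rate, PR AUC, recall@90) plus pooled summary."""
    frame = getattr(matrix, "data", matrix)
    ess = frame.columns.intersection(pd.Index(controls.essential_genes))
    per_line = {}
    for line in frame.index:
        scores = frame.loc[line].dropna()
        if controls.expression is not None:
            neg = controls.unexpressed(line, scores.index).difference(ess)
        else:
            neg = scores.index.intersection(pd.Index(controls.nonessential_genes))
        try:
            value = nnmd(scores[scores.index.intersection(ess)], scores[neg])
        except ValueError:
            value = np.nan
        per_line[line] = value
    report = pd.DataFrame({"nnmd": pd.Series(per_line)})
    if controls.expression is not None:
        fp_rates, pooled_fp = unexpressed_false_positive_rate(
            frame, controls, depleted_fraction
        )
        report["unexpressed_fp_rate"] = fp_rates
        report = report.join(essential_recall_metrics(frame, controls))
        pooled = pd.Series(
            {
                "nnmd_median": report["nnmd"].median(),
                "unexpressed_fp_rate_pooled": pooled_fp,
                "pr_auc_median": report["pr_auc"].median(),
                "recall_at_90_precision_median": report["recall_at_90_precision"].median(),
            }
        )
    else:
        pooled = pd.Series({"nnmd_median": report["nnmd"].median()})
    return report, pooled
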