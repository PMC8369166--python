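"""Cohort prediction, responder evaluation, and TMB integration.

Prediction on a new cohort derives the views from its expression matrix,
averages each view-ensemble's 100 run-models per task, and reports the
ensemble score as the mean over views of the task-averaged predictions.
Evaluation covers tie-corrected ROC/AUC, Wilcoxon group comparisons with
an r = Z / sqrt(n) effect size, and two schemes for blending in tumor
mutational burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tmelearn.io import GeneExpressionMatrix, PriorKnowledgeBundle
from tmelearn.training import ModelEnsemble
from tmelearn import views as views_mod

logger = logging.getLogger(__name__)

TMB_CLASSES = ("L", "M", "H")
TMB_CLASS_VALUES = {"L": 0.0, "M": 0.5, "H": 1.0}


class EvaluationError(ValueError):
    pass


@dataclass
class PredictionResult:
    per_task: dict[str, pd.DataFrame]  # view -> samples × tasks
    per_view: pd.DataFrame  # samples × views, task-averaged
    ensemble: pd.Series  # samples
    evaluation: dict = field(default_factory=dict)


def derive_views(
    expr: GeneExpressionMatrix,
    priors: PriorKnowledgeBundle,
    which: list[str] | None = None,
    lr_frequencies: dict[str, float] | None = None,
    tpm_threshold: float = 10.0,
    exclude_genes: list[str] | None = None,
) -> dict[str, views_mod.ViewMatrix]:
    """Compute the requested views (default: all five) for a cohort."""
    which = list(which) if which else ["cellfrac", "pathways", "tfs", "lrpairs", "ccpairs"]
    out: dict[str, views_mod.ViewMatrix] = {}
    filtered_db = None
    if "lrpairs" in which or "ccpairs" in which:
        filtered_db = views_mod.derive_tme_lr_pairs(priors.lr_database, tpm_threshold)
    if "cellfrac" in which:
        out["cellfrac"] = views_mod.deconvolve_cell_fractions(expr, priors.cell_signature)
    if "pathways" in which:
        out["pathways"] = views_mod.compute_pathway_activity(
            expr, priors.pathway_model, exclude_genes
        )
    if "tfs" in which:
        out["tfs"] = views_mod.compute_tf_activity(expr, priors.regulons)
    if "lrpairs" in which:
        out["lrpairs"] = views_mod.group_lr_features(
            views_mod.compute_lr_view(expr, filtered_db)
        )
    if "ccpairs" in which:
        if lr_frequencies is None:
            raise EvaluationError(
                "CC view needs stored LR frequencies; compute them on a "
                "reference cohort with compute_lr_frequencies"
            )
        out["ccpairs"] = views_mod.compute_cc_view(
            expr, filtered_db, lr_frequencies, tpm_threshold
        )
    return out


def predict_cohort(
    ensembles: dict[str, ModelEnsemble],
    expr_new: GeneExpressionMatrix,
    priors: PriorKnowledgeBundle,
    lr_frequencies: dict[str, float] | None = None,
    tpm_threshold: float = 10.0,
    exclude_genes: list[str] | None = None,
) -> PredictionResult:
    """Predict immune response for a new cohort from per-view ensembles."""
    if not ensembles:
        raise EvaluationError("no model ensembles given")
    if lr_frequencies is None:
        for ens in ensembles.values():
            if "lr_frequencies" in ens.metadata:
                lr_frequencies = ens.metadata["lr_frequencies"]
                break
    derived = derive_views(expr_new, priors, list(ensembles),
                           lr_frequencies, tpm_threshold, exclude_genes)
    per_task: dict[str, pd.DataFrame] = {}
    per_view_cols = {}
    for view_name, ensemble in ensembles.items():
        preds = ensemble.predict(derived[view_name].values)
        per_task[view_name] = preds
        per_view_cols[view_name] = preds.mean(axis=1)
    per_view = pd.DataFrame(per_view_cols)
    ensemble_score = per_view.mean(axis=1)
    return PredictionResult(per_task=per_task, per_view=per_view, ensemble=ensemble_score)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _positives(labels: np.ndarray) -> np.ndarray:
    if labels.dtype.kind in "UOS":
        return labels.astype(str) == "R"
    return labels.astype(float) == 1.0


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = _positives(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points sweeping the threshold from high to low."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = _positives(labels)
    order = np.argsort(-scores, kind="stable")
    pos = pos[order].astype(float)
    tps = np.cumsum(pos)
    fps = np.cumsum(1.0 - pos)
    # collapse threshold ties
    distinct = np.r_[np.nonzero(np.diff(scores[order]))[0], len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / tps[-1]]
    fpr = np.r_[0.0, fps[distinct] / fps[-1]]
    return fpr, tpr


def average_roc(curves: list[tuple[np.ndarray, np.ndarray]],
                grid_size: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Vertically average ROC curves on a fixed false-positive-rate grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return grid, np.mean(tprs, axis=0)


def task_auc_summary(per_task_scores: pd.DataFrame, labels) -> dict:
    """Per-task AUC plus mean ± SD across tasks (and the averaged ROC)."""
    aucs = {t: roc_auc(per_task_scores[t], labels) for t in per_task_scores.columns}
    curves = [roc_curve(per_task_scores[t], labels) for t in per_task_scores.columns]
    grid, mean_tpr = average_roc(curves)
    return {
        "per_task_auc": aucs,
        "mean_auc": float(np.mean(list(aucs.values()))),
        "sd_auc": float(np.std(list(aucs.values()))),
        "mean_roc": {"fpr": grid.tolist(), "tpr": mean_tpr.tolist()},
    }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def compare_groups(values, groups, paired: bool = False,
                   alternative: str | None = None) -> tuple[float, float]:
    """Wilcoxon comparison of two groups with an effect size.

    Unpaired data uses the rank-sum (Mann-Whitney) test, two-sided by
    default, exact for small tie-free samples and normal-approximated with
    continuity correction otherwise.  Paired data uses the signed-rank test,
    one-sided by default.  The effect size is r = Z / sqrt(n) with n the
    total number of observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise EvaluationError("exactly two groups required")
    a, b = values[groups == uniq[0]], values[groups == uniq[1]]
    n = len(values)
    if np.all(values == values[0]):
        logger.warning("all observations tied; p = 1, effect size 0")
        return 1.0, 0.0
    if paired:
        if len(a) != len(b):
            raise EvaluationError("paired comparison needs equal group sizes")
        if len(a) < 2:
            raise EvaluationError("need at least 2 pairs")
        alt = alternative or "greater"
        diffs = a - b
        if np.all(diffs == 0):
            return 1.0, 0.0
        res = stats.wilcoxon(a, b, alternative=alt)
        p = float(res.pvalue)
        z = _signed_rank_z(diffs)
    else:
        if len(a) < 2 or len(b) < 2:
            raise EvaluationError("need at least 2 observations per group")
        alt = alternative or "two-sided"
        method = "exact" if (n <= 25 and len(np.unique(values)) == n) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alt, method=method)
        p = float(res.pvalue)
        z = _rank_sum_z(a, b)
    return p, float(z / np.sqrt(n))


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Normal-approximation Z for the Mann-Whitney U with tie correction."""
    n1, n2 = len(a), len(b)
    all_v = np.concatenate([a, b])
    ranks = stats.rankdata(all_v)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(all_v, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 0.0
    return (u - mu) / np.sqrt(var)


def _signed_rank_z(diffs: np.ndarray) -> float:
    """Normal-approximation Z for the Wilcoxon signed-rank statistic."""
    d = diffs[diffs != 0]
    n = len(d)
    if n == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts ** 3 - counts).sum()) / 48.0
    if var == 0:
        return 0.0
    return (w_plus - mu) / np.sqrt(var)


# ---------------------------------------------------------------------------
# TMB integration
# ---------------------------------------------------------------------------


def tmb_classify(tmb: pd.Series | None = None,
                 classes: pd.Series | None = None) -> pd.Series:
    """Assign L/M/H TMB classes by tertile split (or pass classes through).

    Ties are broken by stable sample order; the lower third is L, the middle
    M, the upper H.
    """
    if classes is not None:
        bad = set(classes.unique()) - set(TMB_CLASSES)
        if bad:
            raise EvaluationError(f"unknown TMB classes: {sorted(bad)}")
        return classes.astype(str)
    if tmb is None or len(tmb) < 3:
        raise EvaluationError("need at least 3 TMB values (or explicit classes)")
    values = tmb.to_numpy(dtype=float)
    if (values < 0).any():
        raise EvaluationError("TMB values must be non-negative")
    if np.all(values == values[0]):
        logger.warning("all TMB values equal; tertile split is order-determined")
    order = np.argsort(values, kind="stable")
    out = np.empty(len(values), dtype=object)
    for label, chunk in zip(TMB_CLASSES, np.array_split(order, 3)):
        out[chunk] = label
    return pd.Series(out, index=tmb.index)


def integrate_tmb_penalty(p_easier: pd.Series, tmb_class: pd.Series,
                          gamma: float) -> pd.Series:
    """Penalized score: P_i = P_easier_i + c * gamma, c in {-1, 0, +1}."""
    if gamma < 0:
        raise EvaluationError("gamma must be non-negative")
    c = tmb_class.map({"L": -1.0, "M": 0.0, "H": 1.0})
    if c.isna().any():
        raise EvaluationError("TMB classes must be L/M/H")
    return p_easier + c.loc[p_easier.index] * gamma


def minmax_scale(values: pd.Series) -> pd.Series:
    lo, hi = values.min(), values.max()
    if hi == lo:
        logger.warning("constant predictions; min-max scaling maps all to 0.5")
        return pd.Series(0.5, index=values.index)
    return (values - lo) / (hi - lo)


def integrate_tmb_weighted(p_easier: pd.Series, tmb_class: pd.Series,
                           eta: float) -> pd.Series:
    """Weighted average: P_i = (1 - eta) * scaled(P_easier) + eta * TMB_i.

    The model score is min-max scaled to [0, 1] within the cohort; TMB
    classes map L -> 0, M -> 0.5, H -> 1.
    """
    if not 0.0 <= eta <= 1.0:
        raise EvaluationError("eta must be in [0, 1]")
    scaled = minmax_scale(p_easier)
    tmb_value = tmb_class.map(TMB_CLASS_VALUES)
    if tmb_value.isna().any():
        raise EvaluationError("TMB classes must be L/M/H")
    return (1.0 - eta) * scaled + eta * tmb_value.loc[p_easier.index]


# ---------------------------------------------------------------------------
# Response labels
# ---------------------------------------------------------------------------

DEFAULT_RESPONSE_MAPPING = {"CR": "R", "PR": "R", "SD": "NR", "PD": "NR"}


def map_response_labels(clinical: pd.Series,
                        mapping: dict[str, str] | None = None) -> pd.Series:
    """Map clinical annotations (e.g. RECIST classes) to R/NR labels."""
    mapping = mapping or DEFAULT_RESPONSE_MAPPING
    unmapped = sorted(set(clinical.astype(str).unique()) - set(mapping))
    if unmapped:
        raise EvaluationError(f"unmapped response annotations: {unmapped}")
    mapped = clinical.astype(str).map(mapping)
    bad = sorted(set(mapped.unique()) - {"R", "NR"})
    if bad:
        raise EvaluationError(f"mapping must target R/NR, got: {bad}")
    return mapped
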