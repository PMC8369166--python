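"""Transcriptome-based immune-response proxy scores (the learning tasks).

A :class:`~tmelearn.io.ScoreDefinition` dispatches to one of five scoring
forms; :func:`compute_task_matrix` assembles one column per definition and
:func:`select_tasks` keeps the mutually correlated subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from tmelearn.io import GeneExpressionMatrix, ScoreDefinition

logger = logging.getLogger(__name__)


class ScoreError(ValueError):
    pass


def _transformed(expr: GeneExpressionMatrix, transform: str) -> pd.DataFrame:
    if transform == "log2_tpm":
        return expr.log2_tpm()
    if transform == "tpm":
        return expr.tpm
    raise ScoreError(f"unknown expression transform {transform!r}")


def _present(expr: GeneExpressionMatrix, genes: list[str], name: str) -> list[str]:
    present = [g for g in genes if g in expr.tpm.index]
    absent = [g for g in genes if g not in expr.tpm.index]
    if absent:
        logger.warning("score %s: %d/%d genes absent from expression", name,
                       len(absent), len(genes))
    return present


def score_geometric_mean(expr: GeneExpressionMatrix, genes: list[str],
                         pseudocount: float = 0.01) -> pd.Series:
    """Geometric mean of (TPM + pseudocount) over the present genes."""
    present = _present(expr, genes, "geometric_mean")
    if not present:
        raise ScoreError("geometric_mean: no gene present")
    logs = np.log(expr.tpm.loc[present] + pseudocount)
    return np.exp(logs.mean(axis=0))


def rank_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalize each gene (row) across samples to [0, 1].

    Average ranks for ties, mapped as (rank - 1) / (n - 1) so the minimum is
    0 and the maximum 1; a single sample maps to 0.5.
    """
    n = values.shape[1]
    if n == 1:
        return pd.DataFrame(0.5, index=values.index, columns=values.columns)
    ranks = np.apply_along_axis(stats.rankdata, 1, values.to_numpy(dtype=float))
    return pd.DataFrame((ranks - 1.0) / (n - 1.0), index=values.index, columns=values.columns)


def score_weighted_mean(
    expr: GeneExpressionMatrix,
    genes: list[str],
    weights: list[float] | None = None,
    transform: str = "log2_tpm",
    rank_normalize_genes: bool = False,
) -> pd.Series:
    """Weighted mean of (optionally rank-normalized) transformed expression.

    Returns ``sum_g w_g x_g / sum_g w_g`` per sample; default weights are 1.
    """
    if weights is None:
        weights = [1.0] * len(genes)
    pairs = [(g, w) for g, w in zip(genes, weights) if g in expr.tpm.index]
    if not pairs:
        raise ScoreError("weighted_mean: no gene present")
    present = [g for g, _ in pairs]
    _present(expr, genes, "weighted_mean")  # logging only
    w = np.array([wt for _, wt in pairs], dtype=float)
    if w.sum() == 0:
        raise ScoreError("weighted_mean: weights sum to zero over present genes")
    values = _transformed(expr, transform).loc[present]
    if rank_normalize_genes:
        values = rank_normalize(values)
    return pd.Series(w @ values.to_numpy() / w.sum(), index=expr.sample_ids)


def score_pair_logic(expr: GeneExpressionMatrix,
                     gene_pairs: list[tuple[str, str]]) -> pd.Series:
    """Count of pairs with expr[g1] > expr[g2] (strict; ties never count)."""
    evaluable = [(a, b) for a, b in gene_pairs
                 if a in expr.tpm.index and b in expr.tpm.index]
    skipped = len(gene_pairs) - len(evaluable)
    if skipped:
        logger.warning("pair_logic: skipping %d pairs with absent genes", skipped)
    if not evaluable:
        raise ScoreError("pair_logic: no evaluable pair")
    counts = np.zeros(expr.n_samples)
    for a, b in evaluable:
        counts += (expr.tpm.loc[a].to_numpy() > expr.tpm.loc[b].to_numpy())
    return pd.Series(counts, index=expr.sample_ids)


def score_pc1(
    expr: GeneExpressionMatrix,
    genes: list[str],
    anchor_scores: pd.DataFrame | None = None,
    transform: str = "log2_tpm",
) -> pd.Series:
    """First principal component of the gene submatrix, sign-anchored.

    Genes are centered across samples; the per-sample PC1 projection is the
    score.  Because the PC sign is arbitrary it is flipped when the Pearson
    correlation with the mean of the anchor task columns is negative; a zero
    correlation keeps the computed sign (with a warning).
    """
    present = _present(expr, genes, "pc1")
    if len(present) < 2:
        raise ScoreError("pc1: needs at least 2 present genes")
    if expr.n_samples < 3:
        raise ScoreError("pc1: needs at least 3 samples")
    sub = _transformed(expr, transform).loc[present].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ScoreError("pc1: zero-variance gene submatrix")
    # rows = genes, columns = samples; PC1 scores live along the sample axis
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = s[0] * vt[0]
    if anchor_scores is not None and anchor_scores.shape[1] > 0:
        anchor = anchor_scores.loc[expr.sample_ids].mean(axis=1).to_numpy(dtype=float)
        if np.std(anchor) > 0 and np.std(scores) > 0:
            r = np.corrcoef(scores, anchor)[0, 1]
            if r < 0:
                scores = -scores
            elif r == 0:
                logger.warning("pc1: anchor correlation exactly 0; keeping computed sign")
    return pd.Series(scores, index=expr.sample_ids)


def score_one(expr: GeneExpressionMatrix, definition: ScoreDefinition,
              anchor_scores: pd.DataFrame | None = None) -> pd.Series:
    d = definition
    if d.form == "geometric_mean":
        return score_geometric_mean(expr, d.genes, d.pseudocount)
    if d.form == "weighted_mean":
        return score_weighted_mean(expr, d.genes, d.weights, d.transform, False)
    if d.form == "rank_normalized_mean":
        return score_weighted_mean(expr, d.genes, d.weights, d.transform, True)
    if d.form == "pair_logic":
        return score_pair_logic(expr, d.gene_pairs)
    if d.form == "pc1":
        return score_pc1(expr, d.genes, anchor_scores, d.transform)
    raise ScoreError(f"unknown form {d.form!r}")


def compute_task_matrix(expr: GeneExpressionMatrix,
                        score_definitions: list[ScoreDefinition]) -> pd.DataFrame:
    """Samples × tasks matrix, one column per score definition.

    PC1-form scores are computed last so their sign anchors can reference
    other task columns.  Definitions whose genes are entirely absent are
    dropped with a warning.  Columns are not standardized here.
    """
    if not score_definitions:
        raise ScoreError("empty score definition list")
    names = [d.name for d in score_definitions]
    if len(set(names)) != len(names):
        raise ScoreError("duplicate score definition names")
    columns: dict[str, pd.Series] = {}
    deferred = []
    for d in score_definitions:
        if d.form == "pc1":
            deferred.append(d)
            continue
        try:
            columns[d.name] = score_one(expr, d)
        except ScoreError as exc:
            logger.warning("dropping task %s: %s", d.name, exc)
    for d in deferred:
        anchors = None
        if d.sign_anchor:
            anchor_cols = [c for c in d.sign_anchor if c in columns]
            if anchor_cols:
                anchors = pd.DataFrame({c: columns[c] for c in anchor_cols})
        try:
            columns[d.name] = score_one(expr, d, anchors)
        except ScoreError as exc:
            logger.warning("dropping task %s: %s", d.name, exc)
    if not columns:
        raise ScoreError("no computable task")
    ordered = [n for n in names if n in columns]
    return pd.DataFrame({n: columns[n] for n in ordered}, index=expr.sample_ids)


def median_task_correlations(tasks: pd.DataFrame) -> pd.Series:
    """Per task, the median Pearson correlation with all other tasks.

    Constant columns correlate undefined; treated as 0 with a warning.
    """
    values = tasks.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        logger.warning("constant task columns treated as correlation 0: %s",
                       list(tasks.columns[constant]))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    medians = {}
    q = tasks.shape[1]
    for i, name in enumerate(tasks.columns):
        others = np.delete(corr[i], i)
        medians[name] = float(np.median(others)) if q > 1 else 0.0
    return pd.Series(medians)


def select_tasks(cohort_tasks: pd.DataFrame | list[pd.DataFrame],
                 threshold: float = 0.4) -> list[str]:
    """Keep tasks whose median (over cohorts) of the per-cohort median
    Pearson correlation with all other tasks exceeds ``threshold``."""
    if isinstance(cohort_tasks, pd.DataFrame):
        cohort_tasks = [cohort_tasks]
    if not cohort_tasks or cohort_tasks[0].shape[1] < 3:
        raise ScoreError("select_tasks needs at least 3 tasks")
    per_cohort = pd.DataFrame([median_task_correlations(t) for t in cohort_tasks])
    across = per_cohort.median(axis=0)
    return [name for name in cohort_tasks[0].columns if across[name] > threshold]
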