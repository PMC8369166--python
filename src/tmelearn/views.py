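"""The five system-based signatures ("views") of the tumor microenvironment.

Each view turns a genes × samples expression matrix plus one prior-knowledge
component into a samples × features matrix:

* ``cellfrac`` — immune cell fractions by non-negative least-squares
  deconvolution on a cell-type signature matrix.
* ``pathways`` — pathway activities as weighted sums of z-scored
  perturbation-response signature genes.
* ``tfs`` — transcription-factor activities as normalized enrichment
  scores over rank-transformed target expression.
* ``lrpairs`` — ligand-receptor pair weights, min log2(TPM+1) over the
  pair's constituent genes.
* ``ccpairs`` — cell-cell interaction scores: per ordered (sender,
  receiver) aggregated cell-type pair, the sum of inverse reference-cohort
  frequencies of the active ligand-receptor pairs assigned to it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tmelearn.io import GeneExpressionMatrix, LRDatabase

logger = logging.getLogger(__name__)

VIEW_NAMES = ("cellfrac", "pathways", "tfs", "lrpairs", "ccpairs", "external")


class ViewError(ValueError):
    pass


@dataclass
class ViewMatrix:
    """Samples × features matrix for one view."""

    view_name: str
    values: pd.DataFrame  # samples × features

    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view_name not in VIEW_NAMES:
            raise ViewError(f"unknown view name {self.view_name!r}")
        if self.values.columns.duplicated().any():
            raise ViewError("duplicate feature ids")
        missing = self.values.isna().any(axis=0)
        if missing.any():
            dropped = list(self.values.columns[missing])
            logger.info("view %s: dropping %d features with missing values: %s",
                        self.view_name, len(dropped), dropped[:10])
            self.values = self.values.loc[:, ~missing]
            self.provenance.setdefault("dropped_missing", []).extend(dropped)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Cell fractions
# ---------------------------------------------------------------------------


def deconvolve_cell_fractions(
    expr: GeneExpressionMatrix,
    signature: pd.DataFrame,
    cd4_label: str = "CD4",
    treg_label: str = "Treg",
    other_label: str = "Other",
) -> ViewMatrix:
    """Estimate immune cell fractions per sample by NNLS deconvolution.

    Solves, per sample, non-negative least squares of the bulk TPM profile
    on the signature columns over the signature genes.  Fractions are
    rescaled so their sum is at most 1, ``other`` is 1 minus the immune
    total, and the non-regulatory CD4 column is reported as CD4 + Treg
    (Treg is kept as a separate column as well).
    """
    genes = signature.index.intersection(expr.tpm.index)
    if genes.empty:
        raise ViewError("no overlap between expression genes and signature genes")
    A = signature.loc[genes].to_numpy(dtype=float)
    B = expr.tpm.loc[genes].to_numpy(dtype=float)
    cell_types = list(signature.columns)
    fractions = np.zeros((expr.n_samples, len(cell_types)))
    for s in range(expr.n_samples):
        b = B[:, s]
        if not np.any(expr.tpm.iloc[:, s].to_numpy()):
            raise ViewError(f"sample {expr.sample_ids[s]!r} is all zeros; fractions undefined")
        coef, _ = optimize.nnls(A, b)
        total = coef.sum()
        if total > 1.0:
            coef = coef / total
        fractions[s] = coef
    out = pd.DataFrame(fractions, index=expr.sample_ids, columns=cell_types)
    out[other_label] = 1.0 - out[cell_types].sum(axis=1)
    if cd4_label in out.columns and treg_label in out.columns:
        out[cd4_label] = out[cd4_label] + out[treg_label]
    return ViewMatrix(view_name="cellfrac", values=out,
                      provenance={"signature_genes_used": int(len(genes))})


# ---------------------------------------------------------------------------
# Pathway activity
# ---------------------------------------------------------------------------


def zscore_genes(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples with population SD.

    Constant genes map to all-zero rows.
    """
    values = log_expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=log_expr.index, columns=log_expr.columns)


def compute_pathway_activity(
    expr: GeneExpressionMatrix,
    pathway_model: pd.DataFrame,
    exclude_genes: list[str] | None = None,
) -> ViewMatrix:
    """Pathway scores as weighted sums of z-scored signature genes.

    ``score(sample, pathway) = sum_g w[g, pathway] * z[g, sample]`` over the
    model genes present in the expression matrix, after removing
    ``exclude_genes`` from the model (e.g. genes used by the immune-response
    proxy scores, to avoid circularity).
    """
    model = pathway_model
    excluded = []
    if exclude_genes:
        excluded = [g for g in exclude_genes if g in model.index]
        model = model.drop(index=excluded)
    genes = model.index.intersection(expr.tpm.index)
    dropped_pathways = []
    if genes.empty:
        logger.warning("pathway model has no genes left after exclusion/intersection")
        values = pd.DataFrame(index=expr.sample_ids, columns=[], dtype=float)
        return ViewMatrix(view_name="pathways", values=values,
                          provenance={"excluded_genes": len(excluded),
                                      "dropped_pathways": list(model.columns)})
    model = model.loc[genes]
    # pathways whose every weighted gene vanished
    nonzero = (model != 0).any(axis=0)
    dropped_pathways = list(model.columns[~nonzero])
    if dropped_pathways:
        logger.warning("pathways with zero surviving genes dropped: %s", dropped_pathways)
    model = model.loc[:, nonzero]
    z = zscore_genes(expr.log2_tpm().loc[genes])
    scores = z.T.to_numpy() @ model.to_numpy()
    values = pd.DataFrame(scores, index=expr.sample_ids, columns=list(model.columns))
    return ViewMatrix(
        view_name="pathways",
        values=values,
        provenance={"excluded_genes": len(excluded), "dropped_pathways": dropped_pathways},
    )


# ---------------------------------------------------------------------------
# TF activity
# ---------------------------------------------------------------------------


def _rank_to_normal(column: np.ndarray) -> np.ndarray:
    """Map one sample's expression vector to normal scores via mid-quantiles."""
    ranks = stats.rankdata(column, method="average")
    q = (ranks - 0.5) / len(column)
    return stats.norm.ppf(q)


def compute_tf_activity(
    expr: GeneExpressionMatrix,
    regulons: pd.DataFrame,
    confidence_keep: set[str] = frozenset({"A", "B"}),
    min_targets: int = 5,
) -> ViewMatrix:
    """TF activity as a normalized enrichment score over target ranks.

    Per sample, expression is rank-transformed to quantiles (average ranks
    for ties), mapped through the standard normal quantile function, and
    each TF scores ``NES = sum_t mor_t * z_t / sqrt(n_targets)`` over its
    targets present in the expression matrix.  Regulons are filtered to
    high-confidence interactions first; TFs with fewer than ``min_targets``
    present targets are dropped.
    """
    reg = regulons[regulons["confidence"].isin(confidence_keep)]
    if reg.empty:
        raise ViewError("no regulons left after confidence filtering")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    log_expr = expr.log2_tpm().to_numpy(dtype=float)
    Z = np.apply_along_axis(_rank_to_normal, 0, log_expr)  # genes × samples

    nes_cols: dict[str, np.ndarray] = {}
    dropped = []
    for tf, grp in reg.groupby("tf", sort=True):
        present = grp[grp["target"].isin(gene_index)]
        if len(present) < min_targets:
            dropped.append(str(tf))
            continue
        idx = [gene_index[t] for t in present["target"]]
        mor = present["mor"].to_numpy(dtype=float)
        nes_cols[str(tf)] = mor @ Z[idx, :] / np.sqrt(len(idx))
    if dropped:
        logger.warning("TFs dropped (<%d present targets): %s", min_targets, dropped[:10])
    if not nes_cols:
        raise ViewError("no TF passed the minimum-target filter")
    values = pd.DataFrame(nes_cols, index=expr.sample_ids)
    return ViewMatrix(view_name="tfs", values=values,
                      provenance={"dropped_tfs": dropped, "min_targets": min_targets})


# ---------------------------------------------------------------------------
# Ligand-receptor pairs
# ---------------------------------------------------------------------------


def _genes_pass(ct_expr: pd.DataFrame, genes: tuple[str, ...], cell_type: str,
                threshold: float) -> bool:
    """All ``genes`` at or above threshold in ``cell_type`` (missing gene fails)."""
    for g in genes:
        if g not in ct_expr.columns or ct_expr.at[cell_type, g] < threshold:
            return False
    return True


def derive_tme_lr_pairs(lr_database: LRDatabase, tpm_threshold: float = 10.0) -> LRDatabase:
    """Filter the LR database to pairs plausibly present in the TME.

    A pair is kept iff (a) every ligand gene and every receptor gene reaches
    ``tpm_threshold`` in at least one cell type of the prior, and (b) there
    is at least one ordered (sender, receiver) cell-type pair — autocrine
    allowed — with all ligand genes expressed in the sender and all receptor
    genes expressed in the receiver.
    """
    ct = lr_database.celltype_expression
    cell_types = list(ct.index)
    kept = []
    for pair_id, lig, rec in lr_database.pairs:
        every_gene_expressed = all(
            g in ct.columns and (ct[g] >= tpm_threshold).any() for g in (*lig, *rec)
        )
        if not every_gene_expressed:
            continue
        paired = any(
            _genes_pass(ct, lig, sender, tpm_threshold)
            and _genes_pass(ct, rec, receiver, tpm_threshold)
            for sender in cell_types
            for receiver in cell_types
        )
        if paired:
            kept.append((pair_id, lig, rec))
    if not kept:
        logger.warning("no LR pair passed the TME filter at %.3g TPM", tpm_threshold)
    return LRDatabase(
        pairs=kept,
        celltype_expression=lr_database.celltype_expression,
        aggregation_map=lr_database.aggregation_map,
        aggregated_types=lr_database.aggregated_types,
    )


def compute_lr_view(expr: GeneExpressionMatrix, filtered_db: LRDatabase) -> ViewMatrix:
    """LR pair weights: min of log2(TPM+1) over all constituent genes.

    Genes absent from the expression matrix are treated as unexpressed, so
    any pair involving one gets weight 0 (logged).
    """
    if not filtered_db.pairs:
        raise ViewError("empty LR database")
    log_expr = expr.log2_tpm()
    have = set(log_expr.index)
    cols = {}
    missing_any = []
    for pair_id, lig, rec in filtered_db.pairs:
        genes = (*lig, *rec)
        if all(g in have for g in genes):
            cols[pair_id] = log_expr.loc[list(genes)].min(axis=0).to_numpy()
        else:
            missing_any.append(pair_id)
            cols[pair_id] = np.zeros(expr.n_samples)
    if missing_any:
        logger.warning("LR pairs with genes absent from expression get weight 0: %s",
                       missing_any[:10])
    values = pd.DataFrame(cols, index=expr.sample_ids)
    return ViewMatrix(view_name="lrpairs", values=values,
                      provenance={"pairs_missing_genes": missing_any})


def group_lr_features(view: ViewMatrix) -> ViewMatrix:
    """Merge LR feature columns with identical value vectors across samples.

    Pairs sharing their limiting gene carry identical weights in every
    sample; merging them reduces the feature count.  The merged feature name
    joins the constituent names with ``_`` in lexicographic order.
    """
    if view.view_name != "lrpairs":
        raise ViewError("group_lr_features expects the lrpairs view")
    groups: dict[bytes, list[str]] = {}
    for name in view.values.columns:
        key = view.values[name].to_numpy().tobytes()
        groups.setdefault(key, []).append(name)
    cols = {}
    merged = []
    for members in groups.values():
        members = sorted(members)
        name = "_".join(members)
        cols[name] = view.values[members[0]].to_numpy()
        if len(members) > 1:
            merged.append(name)
    values = pd.DataFrame(cols, index=view.values.index)
    prov = dict(view.provenance)
    prov["merged_groups"] = merged
    return ViewMatrix(view_name="lrpairs", values=values, provenance=prov)


# ---------------------------------------------------------------------------
# Cell-cell interactions
# ---------------------------------------------------------------------------


def cc_feature_names(aggregated_types: list[str]) -> list[str]:
    """All ordered sender->receiver aggregated-type pairs, autocrine included."""
    return [f"{s}->{r}" for s, r in itertools.product(aggregated_types, repeat=2)]


def assign_pairs_to_cc(filtered_db: LRDatabase, tpm_threshold: float = 10.0
                       ) -> dict[str, set[tuple[str, str]]]:
    """Static map pair_id -> set of (sender_agg, receiver_agg) assignments.

    A pair is assigned to (sender, receiver) when, in the cell-type
    expression prior, all its ligand genes pass the threshold in the sender
    and all receptor genes in the receiver; cell types are then aggregated.
    """
    ct = filtered_db.celltype_expression
    amap = filtered_db.aggregation_map
    missing = set(ct.index) - set(amap)
    if missing:
        raise ViewError(f"cell types without an aggregation: {sorted(missing)}")
    assignment: dict[str, set[tuple[str, str]]] = {}
    for pair_id, lig, rec in filtered_db.pairs:
        senders = [c for c in ct.index if _genes_pass(ct, lig, c, tpm_threshold)]
        receivers = [c for c in ct.index if _genes_pass(ct, rec, c, tpm_threshold)]
        assignment[pair_id] = {(amap[s], amap[r]) for s in senders for r in receivers}
    return assignment


def patient_active_pairs(expr: GeneExpressionMatrix, db: LRDatabase,
                         tpm_threshold: float = 10.0) -> pd.DataFrame:
    """Boolean samples × pairs table: all constituent genes >= threshold in bulk."""
    active = {}
    for pair_id, lig, rec in db.pairs:
        genes = [g for g in (*lig, *rec)]
        if all(g in expr.tpm.index for g in genes):
            active[pair_id] = (expr.tpm.loc[genes] >= tpm_threshold).all(axis=0).to_numpy()
        else:
            active[pair_id] = np.zeros(expr.n_samples, dtype=bool)
    return pd.DataFrame(active, index=expr.sample_ids)


def compute_lr_frequencies(reference_expr: GeneExpressionMatrix, db: LRDatabase,
                           tpm_threshold: float = 10.0) -> dict[str, float]:
    """Per-pair fraction of reference-cohort samples in which the pair is active."""
    active = patient_active_pairs(reference_expr, db, tpm_threshold)
    return {pid: float(f) for pid, f in active.mean(axis=0).items()}


def compute_cc_view(
    expr: GeneExpressionMatrix,
    filtered_db: LRDatabase,
    reference_frequencies: dict[str, float] | GeneExpressionMatrix,
    tpm_threshold: float = 10.0,
) -> ViewMatrix:
    """Cell-cell interaction scores per ordered aggregated-type pair.

    ``score(sample, sender->receiver)`` is the sum over LR pairs assigned to
    that (sender, receiver) — and active in the sample's bulk profile — of
    the inverse of the pair's reference-cohort frequency.  Rare interactions
    thus weigh more.  Pairs never active in the reference (frequency 0) are
    excluded.  ``reference_frequencies`` may be a stored frequency mapping
    or a reference cohort to compute them from.
    """
    if isinstance(reference_frequencies, GeneExpressionMatrix):
        reference_frequencies = compute_lr_frequencies(
            reference_frequencies, filtered_db, tpm_threshold
        )
    assignment = assign_pairs_to_cc(filtered_db, tpm_threshold)
    active = patient_active_pairs(expr, filtered_db, tpm_threshold)
    features = cc_feature_names(filtered_db.aggregated_types)
    values = pd.DataFrame(0.0, index=expr.sample_ids, columns=features)
    for pair_id, cc_set in assignment.items():
        f = reference_frequencies.get(pair_id, 0.0)
        if f <= 0.0 or not cc_set or pair_id not in active.columns:
            continue
        contribution = active[pair_id].to_numpy(dtype=float) / f
        for sender, receiver in cc_set:
            values[f"{sender}->{receiver}"] += contribution
    return ViewMatrix(
        view_name="ccpairs",
        values=values,
        provenance={"tpm_threshold": tpm_threshold,
                    "frequencies": dict(reference_frequencies)},
    )
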