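"""Seeded generators for prior knowledge, expression cohorts, and
immunotherapy response labels.

The generated data carries the statistical structure the pipeline assumes —
cell mixtures with Dirichlet fractions, spiked pathway/TF/ligand-receptor
signal, and binary responder labels driven by a latent immune-activity
variable — together with the ground truth needed for recovery tests.

Gene names encode their role so cohorts can be rebuilt from a bundle alone:
``MK_<celltype>_<i>`` cell-type markers, ``OTH_<i>`` the unclassified-cell
profile, ``PW_<pathway>_<i>`` pathway-responsive genes, ``TG_<tf>_<i>`` TF
targets, ``LG_<i>``/``RC_<i>`` ligands and receptors, ``BG_<i>`` background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmelearn import constants
from tmelearn.io import (
    GeneExpressionMatrix,
    LRDatabase,
    PriorKnowledgeBundle,
    ScoreDefinition,
)

MARKERS_PER_CELLTYPE = 12
OTHER_BLOCK_SIZE = 15
GENES_PER_PATHWAY = 8
TARGETS_PER_TF = 6
TPM_SUM = 1_000_000.0


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated cohort."""

    fractions: pd.DataFrame  # samples × (cell types + Other), sums to 1
    pathway_activities: pd.DataFrame  # samples × pathways
    tf_activities: pd.DataFrame  # samples × TFs
    lr_active: pd.DataFrame  # samples × pairs, bool
    latent_immune_activity: pd.Series
    responder_probability: pd.Series | None = None
    params: dict = field(default_factory=dict)


def _celltype_names(n: int) -> list[str]:
    base = list(constants.IMMUNE_CELL_TYPES)
    if n <= len(base):
        return base[:n]
    return base + [f"CT{i}" for i in range(len(base), n)]


def _pathway_names(n: int) -> list[str]:
    base = list(constants.PATHWAYS)
    if n <= len(base):
        return base[:n]
    return base + [f"PWY{i}" for i in range(len(base), n)]


def make_priors(
    n_genes: int = 2000,
    n_celltypes: int = 10,
    n_pathways: int = 14,
    n_tfs: int = 20,
    n_lr_pairs: int = 30,
    seed: int = 0,
) -> PriorKnowledgeBundle:
    """Generate a self-consistent prior-knowledge bundle.

    Marker blocks are disjoint across cell types; every LR pair passes the
    10 TPM cell-type filter for at least one (sender, receiver) by
    construction.
    """
    if min(n_celltypes, n_pathways, n_tfs, n_lr_pairs) < 1:
        raise ValueError("all component counts must be positive")
    rng = np.random.default_rng(seed)
    cts = _celltype_names(n_celltypes)
    pathways = _pathway_names(n_pathways)
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]

    marker_genes = [f"MK_{ct}_{i:03d}" for ct in cts for i in range(MARKERS_PER_CELLTYPE)]
    other_genes = [f"OTH_{i:03d}" for i in range(OTHER_BLOCK_SIZE)]
    pathway_genes = {p: [f"PW_{p}_{i:03d}" for i in range(GENES_PER_PATHWAY)] for p in pathways}
    tf_targets = {tf: [f"TG_{tf}_{i:03d}" for i in range(TARGETS_PER_TF)] for tf in tfs}
    # every 5th pair gets a two-gene ligand complex
    lr_genes: list[str] = []
    pairs = []
    for i in range(n_lr_pairs):
        lig = (f"LG_{i:03d}",) if i % 5 else (f"LG_{i:03d}", f"LGb_{i:03d}")
        rec = (f"RC_{i:03d}",)
        pairs.append((f"pair{i:03d}", lig, rec))
        lr_genes.extend([*lig, *rec])
    used = (
        len(marker_genes) + len(other_genes)
        + n_pathways * GENES_PER_PATHWAY + n_tfs * TARGETS_PER_TF + len(lr_genes)
    )
    if used + 50 > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for the requested blocks ({used} needed)")
    background_genes = [f"BG_{i:04d}" for i in range(n_genes - used)]

    # cell signature: disjoint high-expression marker blocks + common background
    sig_genes = marker_genes + background_genes[:50]
    signature = pd.DataFrame(0.0, index=sig_genes, columns=cts)
    bg_base = rng.uniform(0.5, 2.0, size=50)
    for c, ct in enumerate(cts):
        block = [f"MK_{ct}_{i:03d}" for i in range(MARKERS_PER_CELLTYPE)]
        signature.loc[block, ct] = rng.uniform(50.0, 150.0, size=len(block))
        signature.loc[background_genes[:50], ct] = bg_base * rng.uniform(0.8, 1.2)
    signature = signature / signature.sum(axis=0) * TPM_SUM

    # sparse pathway weight matrix
    pw_index = [g for p in pathways for g in pathway_genes[p]]
    pathway_model = pd.DataFrame(0.0, index=pw_index, columns=pathways)
    for p in pathways:
        w = rng.normal(1.0, 0.3, size=GENES_PER_PATHWAY)
        w[rng.random(GENES_PER_PATHWAY) < 0.2] *= -1.0
        pathway_model.loc[pathway_genes[p], p] = w

    regulons = pd.DataFrame(
        [
            {
                "tf": tf,
                "target": g,
                "mor": -1 if rng.random() < 0.25 else 1,
                "confidence": "A" if rng.random() < 0.5 else "B",
            }
            for tf in tfs
            for g in tf_targets[tf]
        ]
    )

    # cell-type expression prior: two fine types per aggregated type; each
    # pair is expressed by one (sender, receiver) fine-type combination
    agg_types = list(constants.AGGREGATED_CELL_TYPES)
    fine_types = [f"{agg}|{s}" for agg in agg_types for s in ("a", "b")]
    aggregation_map = {ft: ft.split("|")[0] for ft in fine_types}
    ct_expr = pd.DataFrame(1.0, index=fine_types,
                           columns=sorted(set(lr_genes)))
    for i, (pid, lig, rec) in enumerate(pairs):
        sender = fine_types[(2 * i) % len(fine_types)]
        receiver = fine_types[(2 * i + 3) % len(fine_types)]
        for g in lig:
            ct_expr.at[sender, g] = rng.uniform(30.0, 80.0)
        for g in rec:
            ct_expr.at[receiver, g] = rng.uniform(30.0, 80.0)
    lr_db = LRDatabase(
        pairs=pairs,
        celltype_expression=ct_expr,
        aggregation_map=aggregation_map,
        aggregated_types=agg_types,
    )

    score_definitions = _make_score_definitions(cts, pathways, background_genes)
    return PriorKnowledgeBundle(
        cell_signature=signature,
        pathway_model=pathway_model,
        regulons=regulons,
        lr_database=lr_db,
        score_definitions=score_definitions,
    )


def _make_score_definitions(cts, pathways, background_genes) -> list[ScoreDefinition]:
    cd8 = "CD8" if "CD8" in cts else cts[0]
    nk = "NK" if "NK" in cts else cts[-1]
    cd8_markers = [f"MK_{cd8}_{i:03d}" for i in range(MARKERS_PER_CELLTYPE)]
    nk_markers = [f"MK_{nk}_{i:03d}" for i in range(MARKERS_PER_CELLTYPE)]
    pw0 = [f"PW_{pathways[0]}_{i:03d}" for i in range(GENES_PER_PATHWAY)]
    pw1 = [f"PW_{pathways[1 % len(pathways)]}_{i:03d}" for i in range(GENES_PER_PATHWAY)]
    return [
        ScoreDefinition(name="cytolytic", form="geometric_mean", genes=cd8_markers[:2]),
        ScoreDefinition(name="effector_mean", form="weighted_mean",
                        genes=cd8_markers[2:6] + nk_markers[:2]),
        ScoreDefinition(name="ifn_like", form="weighted_mean",
                        genes=cd8_markers[6:9] + pw0[:3],
                        weights=[1.0, 1.0, 1.0, 0.5, 0.5, 0.5]),
        ScoreDefinition(name="rank_sig", form="rank_normalized_mean",
                        genes=cd8_markers[9:12] + nk_markers[2:5]),
        ScoreDefinition(name="checkpoint_pairs", form="pair_logic",
                        gene_pairs=[(g, b) for g, b in zip(cd8_markers[:4],
                                                           background_genes[:4])]),
        ScoreDefinition(name="immune_pc1", form="pc1",
                        genes=cd8_markers[:6] + nk_markers[:4] + pw1[:2],
                        sign_anchor=["cytolytic", "effector_mean"]),
    ]


def make_cohort(
    priors: PriorKnowledgeBundle,
    n_samples: int = 300,
    dirichlet_alpha: np.ndarray | float | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    spike_sd: float = 0.6,
) -> tuple[GeneExpressionMatrix, SyntheticTruth]:
    """Generate a bulk TPM cohort from a synthetic prior bundle.

    Bulk profiles are signature × Dirichlet cell fractions plus an
    unclassified-cell profile, with pathway/TF/LR structure spiked into the
    dedicated gene blocks, multiplicative lognormal noise (sigma =
    ``noise_sd``), and per-sample renormalization to 1e6.

    A per-sample immune factor couples the views the way the pipeline
    assumes: it tilts the CD8/NK shares of the Dirichlet draw, loads on the
    spiked pathway and TF activities, and raises the ligand-receptor
    activation probability.  The factor is stored as the latent immune
    activity that drives responder labels.
    """
    rng = np.random.default_rng(seed)
    sig = priors.cell_signature
    cts = list(sig.columns)
    n_ct = len(cts)
    pathways = list(priors.pathway_model.columns)
    tfs = sorted(priors.regulons["tf"].unique())
    samples = [f"S{i:04d}" for i in range(n_samples)]

    if dirichlet_alpha is None:
        alpha = np.r_[np.full(n_ct, 1.0), 5.0]  # immune types + Other
    elif np.isscalar(dirichlet_alpha):
        alpha = np.full(n_ct + 1, float(dirichlet_alpha))
    else:
        alpha = np.asarray(dirichlet_alpha, dtype=float)
        if alpha.shape != (n_ct + 1,):
            raise ValueError(f"dirichlet_alpha must have length {n_ct + 1}")
    immune_factor = rng.normal(size=n_samples)
    fractions = rng.dirichlet(alpha, size=n_samples)  # samples × (n_ct + 1)
    # tilt the cytotoxic compartments toward the immune factor, staying on
    # the simplex; the realized (stored) fractions remain exact ground truth
    tilt = np.zeros(n_ct + 1)
    for ct, s in (("CD8", 0.8), ("NK", 0.4)):
        if ct in cts:
            tilt[cts.index(ct)] = s
    fractions = fractions * np.exp(np.outer(immune_factor, tilt))
    fractions /= fractions.sum(axis=1, keepdims=True)

    # assemble bulk on the union of all gene blocks
    all_genes = list(sig.index)
    other_genes = [f"OTH_{i:03d}" for i in range(OTHER_BLOCK_SIZE)]
    pw_genes = list(priors.pathway_model.index)
    tg_genes = list(priors.regulons["target"].unique())
    lr_genes = sorted({g for _, lig, rec in priors.lr_database.pairs for g in (*lig, *rec)})
    extra_bg = [f"BG_{i:04d}" for i in range(50, 150)]
    genes = list(dict.fromkeys(all_genes + other_genes + pw_genes + tg_genes + lr_genes + extra_bg))
    bulk = pd.DataFrame(0.0, index=genes, columns=samples)

    # immune mixture; the unclassified ("Other") compartment is filled in
    # last so each noiseless column sums to exactly 1e6
    mix = sig.to_numpy() @ fractions[:, :n_ct].T  # sig genes × samples
    bulk.loc[sig.index] += mix

    # spiked pathway activity, loaded on the immune factor
    pw_act = 0.6 * immune_factor[:, None] + 0.8 * rng.normal(size=(n_samples, len(pathways)))
    pw_base = rng.uniform(5.0, 20.0, size=len(pw_genes))
    pw_matrix = np.outer(pw_base, np.ones(n_samples))
    for p_idx, p in enumerate(pathways):
        rows = [i for i, g in enumerate(pw_genes) if g.startswith(f"PW_{p}_")]
        pw_matrix[rows] *= np.exp(spike_sd * pw_act[:, p_idx])[None, :]
    bulk.loc[pw_genes] += pw_matrix

    # spiked TF activity (sign follows the mode of regulation)
    tf_act = 0.5 * immune_factor[:, None] + 0.87 * rng.normal(size=(n_samples, len(tfs)))
    tg_base = rng.uniform(5.0, 20.0, size=len(tg_genes))
    tg_matrix = np.outer(tg_base, np.ones(n_samples))
    mor = priors.regulons.set_index("target")["mor"]
    tf_index = {tf: i for i, tf in enumerate(tfs)}
    reg_tf = priors.regulons.set_index("target")["tf"]
    for i, g in enumerate(tg_genes):
        t_idx = tf_index[reg_tf[g]]
        tg_matrix[i] *= np.exp(spike_sd * mor[g] * tf_act[:, t_idx])
    bulk.loc[tg_genes] += tg_matrix

    # ligand-receptor activity states (bulk TPM above/below the 10 threshold)
    pair_ids = [p[0] for p in priors.lr_database.pairs]
    p_active = 1.0 / (1.0 + np.exp(-immune_factor))
    lr_state = rng.random((n_samples, len(pair_ids))) < p_active[:, None]
    lr_matrix = np.full((len(lr_genes), n_samples), 1.0)
    gene_row = {g: i for i, g in enumerate(lr_genes)}
    for j, (pid, lig, rec) in enumerate(priors.lr_database.pairs):
        high = np.where(lr_state[:, j], rng.uniform(30.0, 60.0, n_samples), 1.0)
        for g in (*lig, *rec):
            lr_matrix[gene_row[g]] = np.maximum(lr_matrix[gene_row[g]], high)
    bulk.loc[lr_genes] += lr_matrix

    bulk.loc[extra_bg] += np.outer(rng.uniform(1.0, 10.0, len(extra_bg)), np.ones(n_samples))

    # the accessory blocks above (pathway/TF/LR/background genes) count as
    # part of the unclassified compartment; the OTH block absorbs whatever
    # remains of its budget so noiseless columns total exactly TPM_SUM
    accessory_sum = bulk.sum(axis=0).to_numpy()  # everything but OTH so far minus mixture
    other_budget = fractions[:, n_ct] * TPM_SUM
    mixture_sum = mix.sum(axis=0)
    remainder = np.maximum(other_budget - (accessory_sum - mixture_sum), 0.0)
    bulk.loc[other_genes] += np.outer(
        np.full(OTHER_BLOCK_SIZE, 1.0 / OTHER_BLOCK_SIZE), remainder
    )

    if noise_sd > 0:
        bulk *= np.exp(noise_sd * rng.normal(size=bulk.shape))
    bulk = bulk / bulk.sum(axis=0) * TPM_SUM

    frac_df = pd.DataFrame(fractions, index=samples,
                           columns=cts + [constants.OTHER_CELLS_LABEL])
    pw_df = pd.DataFrame(pw_act, index=samples, columns=pathways)
    tf_df = pd.DataFrame(tf_act, index=samples, columns=tfs)
    lr_df = pd.DataFrame(lr_state, index=samples, columns=pair_ids)
    latent = pd.Series(immune_factor, index=samples)
    truth = SyntheticTruth(
        fractions=frac_df,
        pathway_activities=pw_df,
        tf_activities=tf_df,
        lr_active=lr_df,
        latent_immune_activity=latent,
        params={"n_samples": n_samples, "noise_sd": noise_sd, "seed": seed,
                "spike_sd": spike_sd, "dirichlet_alpha": list(np.asarray(alpha))},
    )
    return GeneExpressionMatrix(tpm=bulk), truth


def _standardize(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


def make_icb_labels(
    truth: SyntheticTruth,
    effect_size: float = 2.0,
    prevalence: float = 0.4,
    seed: int = 0,
) -> pd.Series:
    """Sample R/NR labels from a logistic model on the latent activity.

    The intercept is set (by bisection) so the mean responder probability
    hits the target prevalence.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z = _standardize(truth.latent_immune_activity).to_numpy()

    def mean_prob(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b + effect_size * z)))))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_prob(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    intercept = (lo + hi) / 2.0
    prob = 1.0 / (1.0 + np.exp(-(intercept + effect_size * z)))
    labels = np.where(rng.random(len(z)) < prob, "R", "NR")
    truth.responder_probability = pd.Series(prob, index=truth.latent_immune_activity.index)
    return pd.Series(labels, index=truth.latent_immune_activity.index)
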