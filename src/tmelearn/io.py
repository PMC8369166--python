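"""Input/output: expression matrices, prior-knowledge files, score
definitions, and trained-model serialization.

File conventions
----------------
* Expression: TSV/CSV, genes as rows, header row of sample IDs, first
  column gene symbols.  A ``transpose`` flag accepts samples-as-rows files.
* Gene sets: GMT (name, description, genes...).
* Regulons: TSV with columns ``tf``, ``target``, ``mor``, ``confidence``.
* LR database: a TSV of pairs (``pair_id``, ``ligand_genes``,
  ``receptor_genes``; multi-gene complexes ";"-joined), a TSV cell-type ×
  gene TPM table, and a TSV aggregation map (``cell_type``,
  ``aggregated_type``).
* Bundle config: YAML naming the component paths.
* Models: self-describing JSON.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MODEL_FORMAT = "tmelearn-model"
MODEL_VERSION = 1

#: Offline HGNC validity rule: non-empty, not NA, restricted character set.
HGNC_PATTERN = re.compile(r"^[A-Za-z0-9@_.\-]+$")

_NA_SYMBOLS = frozenset({"", "NA", "N/A", "NAN", "NULL", "?"})


class PriorIOError(Exception):
    """Raised for unreadable, malformed, or inconsistent input files."""


class ModelVersionError(PriorIOError):
    """Raised when a serialized model's version does not match."""


def is_valid_hgnc(symbol: object) -> bool:
    """Check a gene symbol against the offline validity rule."""
    if not isinstance(symbol, str):
        return False
    if symbol.strip().upper() in _NA_SYMBOLS:
        return False
    return HGNC_PATTERN.match(symbol.strip()) is not None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionMatrix:
    """Genes × samples expression with TPM and optionally raw counts."""

    tpm: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            raise PriorIOError("duplicate gene symbols in TPM matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise PriorIOError("negative TPM values")
        if self.counts is not None:
            if not self.tpm.index.equals(self.counts.index) or not self.tpm.columns.equals(
                self.counts.columns
            ):
                raise PriorIOError("counts and TPM axes are inconsistent")
            if (self.counts.to_numpy() < 0).any():
                raise PriorIOError("negative count values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def log2_tpm(self) -> pd.DataFrame:
        """log2(TPM + 1), genes × samples."""
        return np.log2(self.tpm + 1.0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneExpressionMatrix":
        counts = self.counts[list(sample_ids)] if self.counts is not None else None
        return GeneExpressionMatrix(tpm=self.tpm[list(sample_ids)], counts=counts)


@dataclass
class ScoreDefinition:
    """One immune-response proxy score (a learning task)."""

    name: str
    form: str  # geometric_mean | weighted_mean | rank_normalized_mean | pair_logic | pc1
    genes: list[str] = field(default_factory=list)
    weights: list[float] | None = None
    gene_pairs: list[tuple[str, str]] = field(default_factory=list)
    transform: str = "log2_tpm"  # log2_tpm | tpm
    pseudocount: float = 0.01
    sign_anchor: list[str] = field(default_factory=list)

    _FORMS = ("geometric_mean", "weighted_mean", "rank_normalized_mean", "pair_logic", "pc1")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise PriorIOError(f"unknown score form {self.form!r} for {self.name!r}")
        if self.form == "pair_logic":
            if not self.gene_pairs:
                raise PriorIOError(f"score {self.name!r}: pair_logic requires gene_pairs")
        elif not self.genes:
            raise PriorIOError(f"score {self.name!r}: form {self.form!r} requires genes")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise PriorIOError(f"score {self.name!r}: weights/genes length mismatch")


@dataclass
class LRDatabase:
    """Ligand-receptor pair annotations plus a cell-type expression prior."""

    pairs: list[tuple[str, tuple[str, ...], tuple[str, ...]]]
    celltype_expression: pd.DataFrame  # cell types × genes, TPM
    aggregation_map: dict[str, str]
    aggregated_types: list[str]

    def __post_init__(self) -> None:
        for pair_id, lig, rec in self.pairs:
            if not lig or not rec:
                raise PriorIOError(f"LR pair {pair_id!r} has an empty ligand or receptor set")
        if len(set(self.aggregated_types)) != len(self.aggregated_types):
            raise PriorIOError("duplicate aggregated cell types")
        missing = set(self.aggregation_map) - set(self.celltype_expression.index)
        if missing:
            raise PriorIOError(
                f"aggregation_map cell types absent from celltype_expression: {sorted(missing)}"
            )
        known = set(self.celltype_expression.columns)
        for pair_id, lig, rec in self.pairs:
            absent = [g for g in (*lig, *rec) if g not in known]
            if absent:
                logger.warning(
                    "LR pair %s: genes %s absent from cell-type expression; "
                    "pair retained but inert for CC assignment",
                    pair_id,
                    absent,
                )

    @property
    def pair_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    def pair_genes(self, pair_id: str) -> tuple[str, ...]:
        for pid, lig, rec in self.pairs:
            if pid == pair_id:
                return (*lig, *rec)
        raise KeyError(pair_id)


@dataclass
class PriorKnowledgeBundle:
    """Everything the view derivation needs besides expression."""

    cell_signature: pd.DataFrame  # genes × cell types, TPM-scale, >= 0
    pathway_model: pd.DataFrame  # genes × pathways, real weights
    regulons: pd.DataFrame  # columns tf, target, mor, confidence
    lr_database: LRDatabase
    score_definitions: list[ScoreDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_signature.columns.duplicated().any():
            raise PriorIOError("duplicate cell-type names in signature matrix")
        if (self.cell_signature.to_numpy() < 0).any():
            raise PriorIOError("negative values in cell signature matrix")
        if self.pathway_model.columns.duplicated().any():
            raise PriorIOError("duplicate pathway names")
        required = {"tf", "target", "mor", "confidence"}
        if not required.issubset(self.regulons.columns):
            raise PriorIOError(f"regulon table must have columns {sorted(required)}")
        if not set(self.regulons["mor"].unique()).issubset({-1, 1}):
            raise PriorIOError("regulon mode of regulation must be -1 or +1")
        sizes = self.regulons.groupby("tf").size()
        if (sizes < 1).any():
            raise PriorIOError("every regulon needs at least one target")

    def overlap_report(self, expr: GeneExpressionMatrix) -> dict[str, dict[str, float]]:
        """Gene-symbol intersection of each prior component with ``expr``."""
        have = set(expr.gene_ids)
        report = {}
        components = {
            "cell_signature": set(self.cell_signature.index),
            "pathway_model": set(self.pathway_model.index),
            "regulon_targets": set(self.regulons["target"]),
            "lr_genes": {
                g for _, lig, rec in self.lr_database.pairs for g in (*lig, *rec)
            },
        }
        for name, genes in components.items():
            n = len(genes & have)
            report[name] = {
                "n_genes": len(genes),
                "n_present": n,
                "fraction": n / len(genes) if genes else 0.0,
            }
        return report


# ---------------------------------------------------------------------------
# Expression loading
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, fmt: str | None = None, transpose: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PriorIOError(f"file not found: {path}")
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except OSError as exc:
        raise PriorIOError(f"cannot read {path}: {exc}") from exc
    if transpose:
        df = df.T
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise PriorIOError(
            f"non-numeric value in {path} at row {df.index[row]!r}, column {df.columns[col]!r}"
        )
    return out.astype(float)


def _clean_gene_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Drop invalid symbols, average rows sharing a symbol."""
    symbols = [str(s).strip() if s is not None and not pd.isna(s) else "" for s in df.index]
    valid = [is_valid_hgnc(s) for s in symbols]
    n_dropped = len(valid) - sum(valid)
    if n_dropped:
        dropped = sorted({s for s, v in zip(symbols, valid) if not v})
        logger.info("dropped %d rows with invalid gene symbols: %s", n_dropped, dropped[:10])
    df = df.loc[valid]
    df.index = [s for s, v in zip(symbols, valid) if v]
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    # sort for a canonical, input-order-independent row order
    return df.sort_index()


def load_expression(
    path: str | Path,
    fmt: str | None = None,
    counts_path: str | Path | None = None,
    scaled_abundance: bool = False,
    transpose: bool = False,
) -> GeneExpressionMatrix:
    """Load a genes × samples expression file into a :class:`GeneExpressionMatrix`.

    Rows with an invalid HGNC symbol are dropped; rows sharing a symbol are
    replaced by their arithmetic mean.  With ``scaled_abundance=True`` the
    values are interpreted as scaled abundances and multiplied by 1,000,000
    to obtain TPM.
    """
    tpm = _clean_gene_rows(_to_numeric(_read_table(path, fmt, transpose), path))
    if scaled_abundance:
        tpm = tpm * 1_000_000.0
    if tpm.empty:
        raise PriorIOError(f"expression matrix {path} is empty after symbol cleanup")
    counts = None
    if counts_path is not None:
        counts = _clean_gene_rows(_to_numeric(_read_table(counts_path, fmt, transpose), counts_path))
        genes = tpm.index.intersection(counts.index)
        tpm, counts = tpm.loc[genes], counts.loc[genes, tpm.columns]
    return GeneExpressionMatrix(tpm=tpm, counts=counts)


# ---------------------------------------------------------------------------
# Prior knowledge loading
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [genes]}``."""
    path = Path(path)
    if not path.exists():
        raise PriorIOError(f"file not found: {path}")
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise PriorIOError(f"malformed GMT line {ln} in {path}: need name, description, genes")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def _parse_gene_list(token: str) -> tuple[str, ...]:
    genes = tuple(g.strip() for g in str(token).split(";") if g.strip())
    return genes


def load_lr_database(
    pairs_path: str | Path,
    celltype_expression_path: str | Path,
    aggregation_path: str | Path,
) -> LRDatabase:
    pairs_df = _read_table(pairs_path)
    pairs_df = pairs_df.reset_index()
    needed = {"pair_id", "ligand_genes", "receptor_genes"}
    if not needed.issubset(pairs_df.columns):
        raise PriorIOError(f"LR pair table must have columns {sorted(needed)}")
    pairs = [
        (str(r.pair_id), _parse_gene_list(r.ligand_genes), _parse_gene_list(r.receptor_genes))
        for r in pairs_df.itertuples()
    ]
    ct_expr = _to_numeric(_read_table(celltype_expression_path), celltype_expression_path)
    agg_df = _read_table(aggregation_path).reset_index()
    if not {"cell_type", "aggregated_type"}.issubset(agg_df.columns):
        raise PriorIOError("aggregation map must have columns cell_type, aggregated_type")
    aggregation_map = dict(zip(agg_df["cell_type"].astype(str), agg_df["aggregated_type"].astype(str)))
    aggregated_types = list(dict.fromkeys(aggregation_map.values()))
    return LRDatabase(
        pairs=pairs,
        celltype_expression=ct_expr,
        aggregation_map=aggregation_map,
        aggregated_types=aggregated_types,
    )


def load_score_definitions(path: str | Path) -> list[ScoreDefinition]:
    """Load score definitions from a YAML file (list of mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise PriorIOError(f"score definition file {path} must contain a YAML list")
    defs = []
    for entry in raw:
        entry = dict(entry)
        if "gene_pairs" in entry:
            entry["gene_pairs"] = [tuple(p) for p in entry["gene_pairs"]]
        defs.append(ScoreDefinition(**entry))
    return defs


def load_priors(config_path: str | Path) -> PriorKnowledgeBundle:
    """Load a full prior-knowledge bundle from a YAML config of paths.

    Expected keys: ``cell_signature``, ``pathway_model``, ``regulons``,
    ``lr_pairs``, ``lr_celltype_expression``, ``lr_aggregation``,
    ``score_definitions`` (optional).  Relative paths resolve against the
    config file's directory.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise PriorIOError(f"config not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, Mapping):
        raise PriorIOError("priors config must be a YAML mapping")
    base = config_path.parent
    required_keys = ("cell_signature", "pathway_model", "regulons", "lr_pairs",
                     "lr_celltype_expression", "lr_aggregation")
    absent = [k for k in required_keys if k not in cfg]
    if absent:
        raise PriorIOError(f"priors config missing required components: {absent}")

    def _resolve(key: str, required: bool = True) -> Path | None:
        if key not in cfg:
            if required:
                raise PriorIOError(f"priors config missing required component {key!r}")
            return None
        return base / str(cfg[key])

    cell_signature = _to_numeric(_read_table(_resolve("cell_signature")), cfg["cell_signature"])
    pathway_model = _to_numeric(_read_table(_resolve("pathway_model")), cfg["pathway_model"])
    regulons = _read_table(_resolve("regulons")).reset_index()
    regulons["mor"] = regulons["mor"].astype(int)
    lr_db = load_lr_database(
        _resolve("lr_pairs"),
        _resolve("lr_celltype_expression"),
        _resolve("lr_aggregation"),
    )
    score_path = _resolve("score_definitions", required=False)
    score_defs = load_score_definitions(score_path) if score_path else []
    return PriorKnowledgeBundle(
        cell_signature=cell_signature,
        pathway_model=pathway_model,
        regulons=regulons,
        lr_database=lr_db,
        score_definitions=score_defs,
    )


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------


def save_model(ensemble, path: str | Path) -> None:
    """Serialize a fitted :class:`~tmelearn.training.ModelEnsemble` to JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "ensemble": ensemble.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a model ensemble saved by :func:`save_model`."""
    from tmelearn.training import ModelEnsemble  # deferred: avoids import cycle

    path = Path(path)
    if not path.exists():
        raise PriorIOError(f"model file not found: {path}")
    payload = json.loads(path.read_text())
    if payload.get("format") != MODEL_FORMAT:
        raise ModelVersionError(f"not a {MODEL_FORMAT} file: {path}")
    version = payload.get("version")
    if version != MODEL_VERSION:
        raise ModelVersionError(
            f"model version mismatch: file has {version!r}, this build reads {MODEL_VERSION!r}"
        )
    return ModelEnsemble.from_dict(payload["ensemble"])
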