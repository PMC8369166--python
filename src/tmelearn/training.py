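"""Randomized cross-validation training, robust-biomarker extraction, and
task clustering.

Training repeats ``n_runs`` times (default 100); each run randomly holds out
``test_frac`` of the samples, standardizes train and test with the training
statistics, tunes/fits the learner, and records per-task test Spearman
correlations.  The resulting :class:`ModelEnsemble` is the unit that gets
serialized, mined for biomarkers, and used for cohort prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from tmelearn.multitask import (
    BEMKLModel,
    RMTLRModel,
    Standardizer,
    bemkl_fit,
    bemkl_predict,
    gaussian_kernel,
    median_sigma,
    rmtlr_cv_tune,
    rmtlr_fit,
    rmtlr_predict,
)
from tmelearn.multitask.bemkl import BEMKLPriors
from tmelearn.views import ViewMatrix

logger = logging.getLogger(__name__)


@dataclass
class CVRun:
    """One randomized train/test split with its fitted model."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    model: RMTLRModel | BEMKLModel
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    test_spearman: np.ndarray  # per task
    x_train: np.ndarray | None = None  # standardized; kept for kernel learners

    def to_dict(self) -> dict:
        return {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "model": self.model.to_dict(),
            "x_standardizer": self.x_standardizer.to_dict(),
            "y_standardizer": self.y_standardizer.to_dict(),
            "test_spearman": self.test_spearman.tolist(),
            "x_train": self.x_train.tolist() if self.x_train is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict, learner: str) -> "CVRun":
        model_cls = RMTLRModel if learner == "rmtlr" else BEMKLModel
        for key in ("x_standardizer", "y_standardizer"):
            if not d.get(key):
                raise ValueError(f"serialized run missing {key}")
        return cls(
            train_idx=np.asarray(d["train_idx"], dtype=int),
            test_idx=np.asarray(d["test_idx"], dtype=int),
            model=model_cls.from_dict(d["model"]),
            x_standardizer=Standardizer.from_dict(d["x_standardizer"]),
            y_standardizer=Standardizer.from_dict(d["y_standardizer"]),
            test_spearman=np.asarray(d["test_spearman"], dtype=float),
            x_train=np.asarray(d["x_train"], dtype=float)
            if d.get("x_train") is not None else None,
        )


@dataclass
class ModelEnsemble:
    """The fitted models from all randomized cross-validation runs."""

    learner: str  # rmtlr | bemkl
    runs: list[CVRun]
    view_names: list[str]
    feature_names: list[str]
    task_names: list[str]
    master_seed: int
    test_frac: float
    n_samples: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def mean_test_spearman(self) -> np.ndarray:
        return np.mean([r.test_spearman for r in self.runs], axis=0)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Average the per-run model predictions on new samples."""
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        total = np.zeros((X.shape[0], len(self.task_names)))
        for run in self.runs:
            total += _predict_one(self.learner, run, X)
        avg = total / self.n_runs
        return pd.DataFrame(avg, index=features.index, columns=self.task_names)

    def to_dict(self) -> dict:
        return {
            "learner": self.learner,
            "runs": [r.to_dict() for r in self.runs],
            "view_names": self.view_names,
            "feature_names": self.feature_names,
            "task_names": self.task_names,
            "master_seed": self.master_seed,
            "test_frac": self.test_frac,
            "n_samples": self.n_samples,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEnsemble":
        learner = d["learner"]
        return cls(
            learner=learner,
            runs=[CVRun.from_dict(r, learner) for r in d["runs"]],
            view_names=list(d["view_names"]),
            feature_names=list(d["feature_names"]),
            task_names=list(d["task_names"]),
            master_seed=int(d["master_seed"]),
            test_frac=float(d["test_frac"]),
            n_samples=int(d["n_samples"]),
            metadata=d.get("metadata", {}),
        )


def _predict_one(learner: str, run: CVRun, X: np.ndarray) -> np.ndarray:
    Xs = run.x_standardizer.transform(X)
    if learner == "rmtlr":
        pred = run.model.beta0[None, :] + Xs @ run.model.beta
    else:
        test_kernels = [
            gaussian_kernel(Xs, run.x_train, sigma) for sigma in run.model.kernel_sigmas
        ]
        pred = bemkl_predict(run.model, test_kernels)
    return run.y_standardizer.inverse_transform(pred)


def combine_views(views: list[ViewMatrix]) -> pd.DataFrame:
    """Merge views column-wise into one samples × features table."""
    if not views:
        raise ValueError("no views given")
    base = views[0].values.index
    for v in views[1:]:
        if set(v.values.index) != set(base):
            raise ValueError("views cover different sample sets")
    frames = [v.values.loc[base] for v in views]
    combined = pd.concat(frames, axis=1)
    if combined.columns.duplicated().any():
        dupes = list(combined.columns[combined.columns.duplicated()])
        raise ValueError(f"duplicate feature names across views: {dupes[:5]}")
    return combined


def run_randomized_cv(
    views: ViewMatrix | list[ViewMatrix],
    tasks: pd.DataFrame,
    learner: str = "rmtlr",
    n_runs: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    rmtlr_params: dict | None = None,
    bemkl_params: dict | None = None,
) -> ModelEnsemble:
    """The randomized cross-validation protocol.

    ``rmtlr_params`` may carry ``tune`` (default True), ``alpha_grid``,
    ``n_lambda``, ``k``, and — when ``tune`` is False — fixed ``lam`` and
    ``alpha``.  ``bemkl_params`` may carry ``priors`` (:class:`BEMKLPriors`)
    and ``n_iter``.  Per-run seeds fan out from the master seed with a
    counter-based scheme, so run r is identical whatever ``n_runs`` is.
    """
    if learner not in ("rmtlr", "bemkl"):
        raise ValueError(f"unknown learner {learner!r}")
    if isinstance(views, ViewMatrix):
        views = [views]
    features = combine_views(views)
    if set(features.index) != set(tasks.index):
        raise ValueError("view and task sample sets differ")
    tasks = tasks.loc[features.index]
    n = features.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    n_test = max(1, int(round(n * test_frac)))
    X_all = features.to_numpy(dtype=float)
    Y_all = tasks.to_numpy(dtype=float)
    rp = dict(rmtlr_params or {})
    bp = dict(bemkl_params or {})

    children = np.random.SeedSequence(seed).spawn(n_runs)
    runs: list[CVRun] = []
    for r in range(n_runs):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(n)
        test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        sx = Standardizer().fit(X_all[train_idx])
        sy = Standardizer().fit(Y_all[train_idx])
        X_tr, X_te = sx.transform(X_all[train_idx]), sx.transform(X_all[test_idx])
        Y_tr, Y_te = sy.transform(Y_all[train_idx]), sy.transform(Y_all[test_idx])
        if learner == "rmtlr":
            if rp.get("tune", True):
                lam, alpha = rmtlr_cv_tune(
                    X_tr, Y_tr,
                    alpha_grid=rp.get("alpha_grid", (0.5,)),
                    n_lambda=rp.get("n_lambda", 10),
                    k=rp.get("k", 5),
                    seed=int(rng.integers(2 ** 31)),
                    convention=rp.get("convention", "as_printed"),
                )
            else:
                lam, alpha = rp["lam"], rp["alpha"]
            model = rmtlr_fit(X_tr, Y_tr, lam, alpha,
                              tol=rp.get("tol", 1e-6),
                              max_iter=rp.get("max_iter", 10_000),
                              convention=rp.get("convention", "as_printed"))
            model.feature_names = list(features.columns)
            model.task_names = list(tasks.columns)
            pred_te = model.beta0[None, :] + X_te @ model.beta
            x_train_kept = None
        else:
            sigma = bp.get("sigma") or median_sigma(X_tr)
            K_tr = gaussian_kernel(X_tr, X_tr, sigma)
            model = bemkl_fit([K_tr], Y_tr,
                              priors=bp.get("priors") or BEMKLPriors(),
                              n_iter=bp.get("n_iter", 200))
            model.kernel_sigmas = [float(sigma)]
            K_te = gaussian_kernel(X_te, X_tr, sigma)
            pred_te = bemkl_predict(model, [K_te])
            x_train_kept = X_tr
        spear = np.array([
            _safe_spearman(Y_te[:, t], pred_te[:, t]) for t in range(Y_all.shape[1])
        ])
        runs.append(CVRun(train_idx=train_idx, test_idx=test_idx, model=model,
                          x_standardizer=sx, y_standardizer=sy,
                          test_spearman=spear, x_train=x_train_kept))
    return ModelEnsemble(
        learner=learner,
        runs=runs,
        view_names=[v.view_name for v in views],
        feature_names=list(features.columns),
        task_names=list(tasks.columns),
        master_seed=seed,
        test_frac=test_frac,
        n_samples=n,
    )


def _safe_spearman(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(y, yhat).statistic
    return float(rho) if np.isfinite(rho) else 0.0


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------


def _weights_vs_zero_pvalue(weights: np.ndarray) -> float:
    """Test the run-weights of one feature/task against zero.

    A two-sample rank-sum against 100 literal zeros is degenerate, so a
    one-sample sign-flip (signed-rank) test is used; all-zero weight
    vectors give p = 1.
    """
    if not np.any(weights):
        return 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.wilcoxon(weights, zero_method="wilcox").pvalue)
    except ValueError:
        return 1.0


def extract_biomarkers(ensemble: ModelEnsemble, p_threshold: float = 0.05) -> pd.DataFrame:
    """Robust-biomarker table from an RMTLR ensemble.

    Per feature and task the run-weights are summarized by their median
    across runs; the feature's ``median_weight`` is the median of those
    per-task medians across tasks.  A feature is ``robust`` when that value
    is non-zero, i.e. the regularization selected it in at least 50% of the
    runs.  Per-task p-values test the run-weights against zero; features
    significant in fewer than half of the tasks get the ``low_consistency``
    flag.  ``across_task_variance`` is the variance of the per-task medians.
    """
    if ensemble.learner != "rmtlr":
        raise ValueError("biomarker extraction needs an RMTLR ensemble")
    W = np.stack([run.model.beta for run in ensemble.runs])  # runs × p × q
    p, q = W.shape[1], W.shape[2]
    per_task_median = np.median(W, axis=0)  # p × q
    median_weight = np.median(per_task_median, axis=1)  # p
    pvals = np.array([
        [_weights_vs_zero_pvalue(W[:, j, t]) for t in range(q)] for j in range(p)
    ])
    n_sig = (pvals < p_threshold).sum(axis=1)
    table = pd.DataFrame(
        {
            "median_weight": median_weight,
            "n_significant_tasks": n_sig,
            "robust": median_weight != 0,
            "low_consistency": n_sig < q / 2,
            "across_task_variance": per_task_median.var(axis=1),
        },
        index=pd.Index(ensemble.feature_names, name="feature"),
    )
    for t, task in enumerate(ensemble.task_names):
        table[f"median_weight_{task}"] = per_task_median[:, t]
        table[f"p_{task}"] = pvals[:, t]
    return table


def per_task_weight_profiles(ensemble: ModelEnsemble) -> pd.DataFrame:
    """Features × tasks matrix of median run-weights."""
    W = np.stack([run.model.beta for run in ensemble.runs])
    return pd.DataFrame(np.median(W, axis=0), index=ensemble.feature_names,
                        columns=ensemble.task_names)


def cluster_tasks(weight_profiles: pd.DataFrame, k: int = 4) -> dict[str, int]:
    """Hierarchically cluster tasks on their feature-weight vectors.

    Distance is 1 - Pearson correlation between per-task weight profiles
    (features × tasks input); average linkage; cut into ``k`` clusters.
    """
    q = weight_profiles.shape[1]
    if q < 2:
        if k == 1 and q == 1:
            return {weight_profiles.columns[0]: 1}
        raise ValueError("need at least 2 tasks")
    if k > q:
        raise ValueError(f"k={k} exceeds the number of tasks ({q})")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(weight_profiles.to_numpy(dtype=float).T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(weight_profiles.columns, (int(v) for v in labels)))
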