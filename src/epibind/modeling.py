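"""Per-bin regression of TF binding affinity on epigenetic features.

Two model families are fitted independently in every bin: multiple linear
regression (MLR) and a bagged random-forest regression (RF).  Accuracy is
estimated by repeated random train/test splits (default: two-thirds train,
50 repeats), scored by the Pearson correlation (PCC) between predicted and
observed affinities on the held-out anchors, together with R².  Feature
contributions come from out-of-bag permutation importance (%IncMSE),
converted to within-bin ranks 1..p so bins can be compared to each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.linear_model import LinearRegression

from ._rng import child_rng
from .forest import BaggedRegressionForest, ForestConfig
from .signal import BinFeatureMatrix

__all__ = [
    "SplitSpec",
    "FittedBinModel",
    "BinEvaluation",
    "ImportanceTable",
    "SingularDesignError",
    "ConstantInputError",
    "split_anchors",
    "fit_bin_model",
    "predict_affinity",
    "pearson_cc",
    "coefficient_of_determination",
    "repeated_cv",
    "oob_permutation_importance",
    "importance_ranks",
    "bin_importance",
    "feature_target_correlations",
]


class SingularDesignError(ValueError):
    """MLR design matrix is rank-deficient; message names the collinear columns."""


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class SplitSpec:
    """Repeated random-split cross-validation plan."""

    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class FittedBinModel:
    bin_index: int
    model_kind: str  # "rf" | "mlr"
    feature_names: list[str]
    predictor: object
    context: tuple[str, str, str] = ("", "", "")  # (cell_line, tf_name, anchor_class)


@dataclass
class BinEvaluation:
    """Per-bin CV outcome; means are over the non-skipped repeats."""

    bin_index: int
    per_repeat_pcc: list[float]
    per_repeat_r2: list[float]
    per_repeat_r2_ss: list[float]
    n_anchors: int
    n_skipped: int = 0

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.per_repeat_pcc))

    @property
    def sd_pcc(self) -> float:
        return float(np.std(self.per_repeat_pcc, ddof=1)) if len(self.per_repeat_pcc) > 1 else 0.0

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_repeat_r2))

    @property
    def mean_r2_ss(self) -> float:
        return float(np.mean(self.per_repeat_r2_ss))


@dataclass
class ImportanceTable:
    bin_index: int
    feature_names: list[str]
    pct_inc_mse: np.ndarray
    ranks: np.ndarray  # permutation of 1..p; 1 = most important
    has_ties: bool = False


# ---------------------------------------------------------------------------
# scoring primitives


def pearson_cc(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson_cc needs two equal-length vectors of size >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.sqrt(ac @ ac), np.sqrt(bc @ bc)
    if na == 0 or nb == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))


def coefficient_of_determination(
    obs: Sequence[float], pred: Sequence[float], mode: str = "squared_pcc"
) -> float:
    """R² either as the squared Pearson correlation of predicted vs observed
    (default) or as 1 - SS_res/SS_tot, which can be negative for a fit worse
    than the mean."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if mode == "squared_pcc":
        return pearson_cc(obs, pred) ** 2
    if mode == "one_minus_ss":
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        if ss_tot == 0:
            raise ConstantInputError("total sum of squares is zero")
        return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    raise ValueError(f"unknown R² mode {mode!r}")


def split_anchors(
    anchor_ids: Sequence[str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Random disjoint train/test partition with |train| = floor(f * n)."""
    n = len(anchor_ids)
    if n < 3:
        raise ValueError("need at least 3 anchors to split")
    n_train = int(np.floor(train_fraction * n))
    perm = rng.permutation(n)
    train = [anchor_ids[i] for i in perm[:n_train]]
    test = [anchor_ids[i] for i in perm[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# model fitting


def _collinear_columns(X: np.ndarray, feature_names: Sequence[str]) -> list[str]:
    design = np.column_stack([np.ones(X.shape[0]), X])
    _, R, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    names = []
    for col in bad:
        names.append("intercept" if col == 0 else feature_names[col - 1])
    return names


def fit_bin_model(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    hyper: ForestConfig | None = None,
    feature_names: Sequence[str] | None = None,
    bin_index: int = 0,
    seed: int = 0,
    context: tuple[str, str, str] = ("", "", ""),
) -> FittedBinModel:
    """Fit one bin's predictor on a complete design matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one y per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X/y contain undefined values")
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(X.shape[1])]

    if kind == "mlr":
        bad = _collinear_columns(X, names)
        if bad:
            raise SingularDesignError(f"singular design; collinear columns: {', '.join(bad)}")
        predictor = LinearRegression().fit(X, y)
    elif kind == "rf":
        predictor = BaggedRegressionForest(hyper or ForestConfig(), seed=seed).fit(X, y)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return FittedBinModel(bin_index, kind, names, predictor, context)


def predict_affinity(model: FittedBinModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature mismatch: model expects {len(model.feature_names)} columns, got {X.shape[1]}"
        )
    return np.asarray(model.predictor.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# repeated-split cross-validation


def repeated_cv(
    matrix: BinFeatureMatrix,
    kind: str,
    spec: SplitSpec,
    hyper: ForestConfig | None = None,
    max_skip_fraction: float = 0.2,
) -> BinEvaluation:
    """Repeated random-split CV of one bin; a pure function of its arguments.

    Every repeat draws its split and its forest seed from a child stream of
    (master_seed, bin, repeat), so bins and repeats are order-independent.
    Repeats whose test target or test predictions are constant (correlation
    undefined) are skipped and counted; the run fails if more than
    ``max_skip_fraction`` of repeats skip.
    """
    ids = matrix.anchor_ids
    index_of = {a: i for i, a in enumerate(ids)}
    pccs: list[float] = []
    r2s: list[float] = []
    r2ss: list[float] = []
    n_skipped = 0
    for rep in range(spec.n_repeats):
        rng = child_rng(spec.master_seed, "cv", matrix.bin_index, rep)
        train_ids, test_ids = split_anchors(ids, spec.train_fraction, rng)
        tr = np.fromiter((index_of[a] for a in train_ids), dtype=int)
        te = np.fromiter((index_of[a] for a in test_ids), dtype=int)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model = fit_bin_model(
                matrix.X[tr], matrix.y[tr], kind, hyper,
                feature_names=matrix.feature_names,
                bin_index=matrix.bin_index, seed=fit_seed,
            )
            pred = predict_affinity(model, matrix.X[te])
            pcc = pearson_cc(matrix.y[te], pred)
            r2ss.append(coefficient_of_determination(matrix.y[te], pred, "one_minus_ss"))
        except ConstantInputError:
            n_skipped += 1
            continue
        pccs.append(pcc)
        r2s.append(pcc**2)
    if n_skipped > max_skip_fraction * spec.n_repeats:
        raise RuntimeError(
            f"bin {matrix.bin_index}: {n_skipped}/{spec.n_repeats} repeats had degenerate "
            "test sets; refusing to report a mean"
        )
    return BinEvaluation(matrix.bin_index, pccs, r2s, r2ss, matrix.n_anchors, n_skipped)


# ---------------------------------------------------------------------------
# importance


def oob_permutation_importance(
    model: FittedBinModel,
    X_train: np.ndarray | None = None,
    y_train: np.ndarray | None = None,
    scale: bool = True,
) -> np.ndarray:
    """%IncMSE of the RF model's features (see the forest engine for the
    tree-level definition).  X_train/y_train may re-supply the training data;
    they must match what the forest was fitted on."""
    if model.model_kind != "rf":
        raise ValueError("permutation importance requires an rf model")
    forest: BaggedRegressionForest = model.predictor  # type: ignore[assignment]
    if X_train is not None:
        if forest.X_ is None or not np.array_equal(np.asarray(X_train, dtype=float), forest.X_):
            raise ValueError("X_train does not match the data the forest was fitted on")
    if y_train is not None:
        if forest.y_ is None or not np.array_equal(np.asarray(y_train, dtype=float), forest.y_):
            raise ValueError("y_train does not match the data the forest was fitted on")
    return forest.permutation_importance(scale=scale)


def importance_ranks(pct_inc_mse: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Within-bin ranks: 1 = largest score; ties broken by feature order.

    Returns the rank vector (a permutation of 1..p) and a flag that is True
    when any two scores tie exactly.
    """
    scores = np.asarray(pct_inc_mse, dtype=float)
    p = scores.size
    order = np.lexsort((np.arange(p), -scores))  # descending score, stable
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    has_ties = np.unique(scores).size < p
    return ranks, has_ties


def bin_importance(
    matrix: BinFeatureMatrix,
    hyper: ForestConfig | None = None,
    seed: int = 0,
    scale: bool = True,
) -> ImportanceTable:
    """Fit an RF on the full bin matrix and rank the features by %IncMSE."""
    model = fit_bin_model(
        matrix.X, matrix.y, "rf", hyper,
        feature_names=matrix.feature_names, bin_index=matrix.bin_index, seed=seed,
    )
    scores = oob_permutation_importance(model, scale=scale)
    ranks, ties = importance_ranks(scores)
    return ImportanceTable(matrix.bin_index, list(matrix.feature_names), scores, ranks, ties)


def feature_target_correlations(matrix: BinFeatureMatrix) -> np.ndarray:
    """Per-feature Pearson correlation with the TF target; NaN marks a
    constant (undefined-correlation) feature column."""
    out = np.full(len(matrix.feature_names), np.nan)
    for j in range(out.size):
        try:
            out[j] = pearson_cc(matrix.X[:, j], matrix.y)
        except ConstantInputError:
            pass
    return out
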