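"""PLS compression of histogram cubes and grid-searched MLP regression.

The regression input for one shape feature and bin count B is the unfolded
samples x (B * n_bands) histogram matrix.  Each sample's histogram vector
is scaled to unit area, mean-centered, compressed to 10 PLS latent
variables against the target (PLS1, one model per target), and fed to a
small two-hidden-layer network trained by Levenberg-Marquardt.  Model
selection scans hidden-layer sizes (2..8 each by default) for every bin
count and keeps the model with the smallest prediction RMSE.

Two selection modes are provided.  The default mirrors common chemometric
practice: unit-area normalization and PLS are fit on all samples and the
winning configuration is the one minimizing RMSEP (test-set RMSE).  That
choice optimistically biases the reported test metrics; ``strict=True``
instead fits centering means, histogram ranges and PLS on the training set
only and selects by validation RMSE (RMSEV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .morphometry import FeatureCube
from .nnet import ANNConfig, TwoHiddenLayerNet, train_ann

__all__ = [
    "SplitIndices", "PLSModel", "RegressionReport", "DatasetSummary",
    "ANNConfig", "normalize_histograms", "normalize_and_center",
    "split_data", "fit_pls", "pls_scores", "train_ann", "evaluate",
    "grid_search", "summarize_targets", "cv_percent",
]


# ---------------------------------------------------------------------------
# data split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitIndices:
    """70/15/15 train/validation/test partition of sample indices."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split sets overlap")


def split_data(n: int, seed: int = 0) -> SplitIndices:
    """Random partition: round(0.70 n) train, round(0.15 n) val, rest test."""
    if n < 3:
        raise ValueError("need n >= 3 for a three-way split")
    n_train = round(0.70 * n)
    n_val = round(0.15 * n)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} leaves an empty split set")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(train=np.sort(perm[:n_train]),
                        val=np.sort(perm[n_train:n_train + n_val]),
                        test=np.sort(perm[n_train + n_val:]),
                        seed=seed)


# ---------------------------------------------------------------------------
# histogram normalization and centering
# ---------------------------------------------------------------------------

def normalize_histograms(cube: FeatureCube) -> np.ndarray:
    """Unfold to samples x (bins * bands), band-major, rows scaled to sum 1.

    Column order is all bins of band 0, then band 1, ...  Rows with no
    objects anywhere stay all-zero (with a warning).
    """
    values = np.asarray(cube.values, dtype=float)
    X = np.transpose(values, (0, 2, 1)).reshape(values.shape[0], -1)
    sums = X.sum(axis=1, keepdims=True)
    empty = sums[:, 0] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} sample(s) have empty histograms; "
                      "left at zero", stacklevel=2)
    sums[empty] = 1.0
    return X / sums


def normalize_and_center(cube: FeatureCube,
                         train_idx: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area normalization then mean-centering.

    Column means are computed over ``train_idx`` rows when given (leakage-
    safe), otherwise over all samples.  Returns (centered matrix, means).
    """
    if cube.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = normalize_histograms(cube)
    rows = X if train_idx is None else X[np.asarray(train_idx)]
    means = rows.mean(axis=0)
    return X - means, means


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted univariate-response PLS compression."""

    n_lv: int
    x_mean: np.ndarray
    weights: np.ndarray                 # p x n_lv
    loadings: np.ndarray                # p x n_lv
    explained_x_variance: np.ndarray    # cumulative fraction, length n_lv
    _sk: PLSRegression = field(repr=False, default=None)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int = 10) -> PLSModel:
    """Fit PLS1 of a centered X against one target.

    X must already be centered with the training means; y may be on any
    scale.  Raises when ``n_lv`` exceeds the achievable rank of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    rank = np.linalg.matrix_rank(X)
    if n_lv > rank:
        raise ValueError(
            f"n_lv={n_lv} exceeds the rank of the training matrix "
            f"(achievable rank {rank})")
    sk = PLSRegression(n_components=n_lv, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk.fit(X, y)
    T = sk.x_scores_
    P = sk.x_loadings_
    total = float(np.sum((X - X.mean(axis=0)) ** 2))
    explained = np.empty(n_lv)
    recon = np.zeros_like(X)
    Xc = X - X.mean(axis=0)
    for k in range(n_lv):
        recon = recon + np.outer(T[:, k], P[:, k])
        explained[k] = 1.0 - np.sum((Xc - recon) ** 2) / total
    return PLSModel(n_lv=n_lv, x_mean=sk._x_mean, weights=sk.x_weights_,
                    loadings=P, explained_x_variance=explained, _sk=sk)


def pls_scores(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Project (already normalized/centered) samples onto the latent space."""
    return model._sk.transform(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(y_true: np.ndarray, y_pred: np.ndarray
             ) -> tuple[float, float]:
    """(R^2, RMSE).  R^2 is NaN when y_true has zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must share a length >= 2")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        return float("nan"), rmse
    r2 = 1.0 - float(np.sum(resid ** 2)) / sstot
    return r2, rmse


# ---------------------------------------------------------------------------
# dataset summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSummary:
    """Min / Max / Mean / SD / CV% per target column."""

    table: pd.DataFrame

    def as_dict(self) -> dict:
        return self.table.to_dict(orient="index")


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * sd / mean (NaN for zero mean)."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / mean


def summarize_targets(targets: pd.DataFrame) -> DatasetSummary:
    """Per-column min, max, mean, sample SD (ddof=1) and CV%."""
    if len(targets) < 2:
        raise ValueError("need at least 2 rows to summarize")
    rows = {}
    for col in targets.columns:
        v = targets[col].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        rows[col] = {"min": float(v.min()), "max": float(v.max()),
                     "mean": mean, "sd": sd, "cv": cv_percent(mean, sd)}
    return DatasetSummary(pd.DataFrame(rows).T[
        ["min", "max", "mean", "sd", "cv"]])


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    """Best-model record mirroring the study's report table columns."""

    target: str
    feature_name: str
    n_bins: int
    n1l: int
    n2l: int
    epoch_at_best: int
    r2c: float
    r2v: float
    r2p: float
    rmsec: float
    rmsev: float
    rmsep: float

    def as_dict(self) -> dict:
        return {
            "target": self.target, "MSI Features": self.feature_name,
            "Number of Classes in the Histogram": self.n_bins,
            "N1L": self.n1l, "N2L": self.n2l, "Epoch": self.epoch_at_best,
            "R2C": self.r2c, "R2V": self.r2v, "R2P": self.r2p,
            "RMSEC": self.rmsec, "RMSEV": self.rmsev, "RMSEP": self.rmsep,
        }


def config_seed(master_seed: int, index: int) -> int:
    """Deterministic per-configuration seed (SeedSequence hash, < 2^31)."""
    return int(np.random.SeedSequence([int(master_seed), 7919, int(index)])
               .generate_state(1)[0] % (2 ** 31))


def _fit_one(scores, y, split, n1l, n2l, seed, max_epochs):
    cfg = ANNConfig(n1l=n1l, n2l=n2l, seed=seed, max_epochs=max_epochs)
    net, epoch = train_ann(scores[split.train], y[split.train],
                           scores[split.val], y[split.val], cfg)
    r2c, rmsec = evaluate(y[split.train], net.predict(scores[split.train]))
    r2v, rmsev = evaluate(y[split.val], net.predict(scores[split.val]))
    r2p, rmsep = evaluate(y[split.test], net.predict(scores[split.test]))
    return net, epoch, (r2c, r2v, r2p), (rmsec, rmsev, rmsep)


def train_pls_ann(cube: FeatureCube, y: np.ndarray, split: SplitIndices,
                  n1l: int, n2l: int, *, n_lv: int = 10, seed: int = 0,
                  max_epochs: int = 1000, strict: bool = False
                  ) -> tuple[TwoHiddenLayerNet, RegressionReport]:
    """Fit one PLS + network model for a single configuration."""
    y = np.asarray(y, dtype=float)
    train_idx = split.train if strict else None
    X, _ = normalize_and_center(cube, train_idx=train_idx)
    if strict:
        pls = fit_pls(X[split.train], y[split.train], n_lv)
    else:
        pls = fit_pls(X, y, n_lv)
    scores = pls_scores(pls, X)
    net, epoch, r2s, rmses = _fit_one(scores, y, split, n1l, n2l, seed,
                                      max_epochs)
    report = RegressionReport(
        target="", feature_name=cube.feature_name, n_bins=cube.n_bins,
        n1l=n1l, n2l=n2l, epoch_at_best=epoch,
        r2c=r2s[0], r2v=r2s[1], r2p=r2s[2],
        rmsec=rmses[0], rmsev=rmses[1], rmsep=rmses[2])
    return net, report


DEFAULT_GRID = tuple((n1, n2) for n1 in range(2, 9) for n2 in range(2, 9))


def grid_search(cubes: list[FeatureCube], y: np.ndarray,
                split: SplitIndices, *,
                grid: tuple[tuple[int, int], ...] = DEFAULT_GRID,
                n_lv: int = 10, seed: int = 0, max_epochs: int = 1000,
                strict: bool = False, target: str = ""
                ) -> RegressionReport:
    """Two-stage best-model search over bin counts and layer sizes.

    For every histogram cube (one per bin count and feature) each (n1l,
    n2l) in ``grid`` is trained and scored; the per-cube minimum-RMSEP
    model is kept, then the overall winner is the one with the smallest
    RMSEP (RMSEV in strict mode).  Ties break toward fewer neurons
    (n1l + n2l), then fewer bins.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    if not cubes:
        raise ValueError("no feature cubes supplied")
    y = np.asarray(y, dtype=float)
    best: RegressionReport | None = None
    best_key = None
    for cube in cubes:
        train_idx = split.train if strict else None
        X, _ = normalize_and_center(cube, train_idx=train_idx)
        if strict:
            pls = fit_pls(X[split.train], y[split.train], n_lv)
        else:
            pls = fit_pls(X, y, n_lv)
        scores = pls_scores(pls, X)
        for idx, (n1, n2) in enumerate(grid):
            s = config_seed(seed, idx)
            _, epoch, r2s, rmses = _fit_one(scores, y, split, n1, n2, s,
                                            max_epochs)
            selector = rmses[1] if strict else rmses[2]
            key = (selector, n1 + n2, cube.n_bins)
            if best_key is None or key < best_key:
                best_key = key
                best = RegressionReport(
                    target=target, feature_name=cube.feature_name,
                    n_bins=cube.n_bins, n1l=n1, n2l=n2, epoch_at_best=epoch,
                    r2c=r2s[0], r2v=r2s[1], r2p=r2s[2],
                    rmsec=rmses[0], rmsev=rmses[1], rmsep=rmses[2])
    return best
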