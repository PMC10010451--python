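"""First-level model fitting: cross-validated weighted-RDM regression.

Weighting model dimensions before computing a squared-Euclidean RDM is
equivalent to a nonnegative weighted sum of the single-dimension RDMs
(weights enter squared), so the fit is performed directly on RDM pair
vectors: nonnegative L2-penalized regression of the data dissimilarities
on the predictor dissimilarities, with an unpenalized intercept.

To avoid overfitting to the stimulus set, predictions are obtained by
image-level cross-validation: each fold holds out a small stratified test
set of images (by default 8 of 92 — two faces, two body parts, four
inanimate objects), fits on the pairs among training images, and predicts
only the pairs among held-out images.  Folds are repeated until every
image pair has been predicted at least once.  The ridge penalty is chosen
per fold by nested cross-validation over held-out images within the
training set.

Because fold geometry, predictor standardization and the penalized design
matrices depend only on the stimuli and predictors — not on the data —
they are precomputed once in a :class:`CrossValPlan` and reused across
participants, ROIs and time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .rdm_core import PredictorSet, RDMVector, StimulusSet, pair_index

__all__ = [
    "FoldSpec",
    "FitResult",
    "CrossValPrediction",
    "DEFAULT_COMPOSITION",
    "DEFAULT_GRID",
    "make_fold",
    "fold_schedule",
    "fit_nn_ridge",
    "select_lambda",
    "crossval_predict",
    "CrossValPlan",
]

logger = logging.getLogger(__name__)

#: Stratified test-set composition: two faces, two body parts, four inanimate.
DEFAULT_COMPOSITION = {"faces": 2, "bodyparts": 2, "inanimate": 4}

#: Ridge penalty grid (log-spaced; the smallest values make a noiseless,
#: realizable target recoverable essentially unpenalized).
DEFAULT_GRID = tuple(np.logspace(-4, 2, 20))


@dataclass(frozen=True)
class FoldSpec:
    """One outer cross-validation fold: disjoint train/test image-id sets."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets must be disjoint")


@dataclass
class FitResult:
    """A fitted nonnegative ridge model on standardized predictors.

    ``weights`` live in standardized-predictor space; ``weights_original``
    maps them back to the raw predictor scale (w / sd).  Predictors whose
    training-pair standard deviation is zero are dropped from the fit and
    listed in ``dropped``.
    """

    weights: np.ndarray
    intercept: float
    lam: float
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # indices of retained predictor columns
    dropped: tuple[str, ...] = ()

    @property
    def weights_original(self) -> np.ndarray:
        return self.weights / self.sd


@dataclass
class CrossValPrediction:
    """Cross-validated predicted dissimilarities for every image pair."""

    v_hat: np.ndarray  # (n_pairs,)
    coverage: np.ndarray  # (n_pairs,) int, folds in which the pair was tested
    fold_lambdas: np.ndarray  # selected penalty per fold
    mean_weights_original: np.ndarray  # (n_predictors,) mean over folds


def _strata(stimuli: StimulusSet) -> dict[str, np.ndarray]:
    faces = stimuli.face_flag
    bodies = stimuli.bodypart_flag
    inanimate = ~stimuli.animacy
    return {
        "faces": np.flatnonzero(faces),
        "bodyparts": np.flatnonzero(bodies),
        "inanimate": np.flatnonzero(inanimate),
    }


def make_fold(
    stimuli: StimulusSet,
    test_size: int = 8,
    composition: dict[str, int] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FoldSpec:
    """Draw one stratified fold: test images sampled uniformly within strata.

    The default composition holds out two faces, two body parts and four
    inanimate objects (faces pool human and animal faces; body parts pool
    human body parts and animal bodies).
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    if sum(composition.values()) != test_size:
        raise ValueError(
            f"composition {composition} does not sum to test_size={test_size}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    strata = _strata(stimuli)
    test_idx: list[int] = []
    for name, k in composition.items():
        pool = strata.get(name)
        if pool is None:
            raise ValueError(f"unknown stratum '{name}'")
        if k > pool.size:
            raise ValueError(
                f"infeasible composition: need {k} '{name}' images, have {pool.size}"
            )
        test_idx.extend(rng.choice(pool, size=k, replace=False).tolist())
    test = set(test_idx)
    train_ids = tuple(
        sid for i, sid in enumerate(stimuli.image_ids) if i not in test
    )
    test_ids = tuple(stimuli.image_ids[i] for i in sorted(test))
    return FoldSpec(train_ids, test_ids, seed=seed if seed is not None else 0)


def fold_schedule(
    stimuli: StimulusSet,
    seed: int,
    test_size: int = 8,
    composition: dict[str, int] | None = None,
    max_folds: int = 5000,
) -> list[FoldSpec]:
    """Draw folds until every unordered image pair has been in a test set.

    Raises if coverage is not reached within ``max_folds``, reporting how
    many pairs remain uncovered (some pair types can be infeasible under a
    given composition — e.g. two body-part images when the composition
    allows only one).
    """
    n = len(stimuli)
    rows, cols = pair_index(n)
    covered = np.zeros(rows.size, dtype=bool)
    id_to_idx = {sid: i for i, sid in enumerate(stimuli.image_ids)}
    rng = np.random.default_rng(seed)
    folds: list[FoldSpec] = []
    # map (i, j) -> pair position for fast coverage updates
    pair_pos = np.full((n, n), -1, dtype=int)
    pair_pos[rows, cols] = np.arange(rows.size)
    for k in range(max_folds):
        fold = make_fold(stimuli, test_size, composition, rng=rng)
        folds.append(fold)
        t = np.array(sorted(id_to_idx[s] for s in fold.test_ids))
        ii, jj = np.meshgrid(t, t, indexing="ij")
        sel = pair_pos[ii[ii < jj], jj[ii < jj]]
        covered[sel] = True
        if covered.all():
            return folds
    n_left = int((~covered).sum())
    raise RuntimeError(
        f"pair coverage not reached within {max_folds} folds: "
        f"{n_left} of {covered.size} pairs uncovered "
        "(check composition feasibility)"
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means/sds and indices of non-constant columns."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    return mu, sd, kept


def _nn_ridge_solve(y: np.ndarray, A_aug: np.ndarray, n_pairs: int) -> np.ndarray:
    """Solve min ||yc - Xs w||^2 + lam ||w||^2, w >= 0, via augmented NNLS.

    ``A_aug`` stacks the standardized (column-mean-zero) design on top of
    sqrt(lam) * I; the response is the centered y padded with zeros.  The
    intercept is unpenalized and decouples as mean(y) because the design
    columns have zero mean.
    """
    b = np.zeros(A_aug.shape[0])
    b[:n_pairs] = y - y.mean()
    w, _ = nnls(A_aug, b)
    return w


def fit_nn_ridge(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    predictor_names: Sequence[str] | None = None,
) -> FitResult:
    """Nonnegative ridge fit of pair dissimilarities on predictor columns.

    Standardizes ``X`` on the supplied (training) pairs, minimizes
    ``||y - Xs w - b||^2 + lam * ||w||^2`` subject to ``w >= 0`` with the
    intercept ``b`` unpenalized, and returns the fit together with the
    standardization parameters needed to transform new pairs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X must have matching first dimension")
    mu, sd, kept = _standardize(X)
    dropped: tuple[str, ...] = ()
    if kept.size < X.shape[1]:
        names = predictor_names or [f"p{j}" for j in range(X.shape[1])]
        dropped = tuple(names[j] for j in range(X.shape[1]) if j not in set(kept))
        logger.warning("dropping zero-variance predictors: %s", dropped)
    if np.ptp(y) == 0 or kept.size == 0:
        # degenerate target: intercept-only fit
        w_full = np.zeros(X.shape[1])
        return FitResult(w_full, float(y.mean()), lam, mu,
                         np.where(sd > 0, sd, 1.0), kept, dropped)
    Xs = (X[:, kept] - mu[kept]) / sd[kept]
    A_aug = np.vstack([Xs, np.sqrt(lam) * np.eye(kept.size)])
    w = _nn_ridge_solve(y, A_aug, y.size)
    w_full = np.zeros(X.shape[1])
    w_full[kept] = w
    return FitResult(
        weights=w_full,
        intercept=float(y.mean()),
        lam=float(lam),
        mean=mu,
        sd=np.where(sd > 0, sd, 1.0),
        kept=kept,
        dropped=dropped,
    )


def predict_pairs(fit: FitResult, X_new: np.ndarray) -> np.ndarray:
    """Predictions for new pairs using training standardization parameters."""
    Xs = (X_new[:, fit.kept] - fit.mean[fit.kept]) / fit.sd[fit.kept]
    return Xs @ fit.weights[fit.kept] + fit.intercept


def _inner_groups(
    n_images: int, n_inner: int, rng: np.random.Generator,
    strata: Sequence[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Partition (local) image indices into inner-CV groups.

    When strata are given, each stratum is shuffled and dealt round-robin
    so group composition approximates the outer stratification; groups are
    guaranteed at least two images each (else fewer groups are used).
    """
    n_inner = max(2, min(n_inner, n_images // 2))
    groups: list[list[int]] = [[] for _ in range(n_inner)]
    if strata is None:
        order = rng.permutation(n_images)
        for pos, img in enumerate(order):
            groups[pos % n_inner].append(int(img))
    else:
        pos = 0
        for stratum in strata:
            order = rng.permutation(stratum)
            for img in order:
                groups[pos % n_inner].append(int(img))
                pos += 1
    return [np.array(sorted(g)) for g in groups if len(g) >= 2]


class CrossValPlan:
    """Precomputed geometry for cross-validated nonnegative ridge fitting.

    Everything that does not depend on the data vector — fold memberships,
    train/test pair indices, standardized design matrices, their
    ridge-augmented forms for every grid value, and the nested inner-CV
    splits — is computed once here.  :meth:`predict` then maps a data
    vector to its cross-validated prediction.
    """

    def __init__(
        self,
        stimuli: StimulusSet,
        X: np.ndarray,
        schedule: Sequence[FoldSpec],
        grid: Sequence[float] = DEFAULT_GRID,
        inner_folds: int = 5,
        seed: int = 0,
        predictor_names: Sequence[str] | None = None,
    ) -> None:
        grid = [float(g) for g in grid]
        if not grid:
            raise ValueError("penalty grid must be nonempty")
        if any(g < 0 for g in grid):
            raise ValueError("penalty grid values must be nonnegative")
        self.grid = np.array(sorted(grid))
        self.X = np.asarray(X, dtype=float)
        self.n_images = len(stimuli)
        self.names = (
            tuple(predictor_names)
            if predictor_names is not None
            else tuple(f"p{j}" for j in range(self.X.shape[1]))
        )
        rows, cols = pair_index(self.n_images)
        self.n_pairs = rows.size
        if self.X.shape[0] != self.n_pairs:
            raise ValueError("X rows must equal the number of image pairs")
        id_to_idx = {sid: i for i, sid in enumerate(stimuli.image_ids)}
        pair_pos = np.full((self.n_images, self.n_images), -1, dtype=int)
        pair_pos[rows, cols] = np.arange(self.n_pairs)
        pair_pos[cols, rows] = np.arange(self.n_pairs)
        rng = np.random.default_rng(seed)
        strata = _strata(stimuli)

        self.folds: list[dict] = []
        covered = np.zeros(self.n_pairs, dtype=bool)
        for fold in schedule:
            tr = np.array(sorted(id_to_idx[s] for s in fold.train_ids))
            te = np.array(sorted(id_to_idx[s] for s in fold.test_ids))
            tr_pairs = _pairs_within(tr, pair_pos)
            te_pairs = _pairs_within(te, pair_pos)
            covered[te_pairs] = True
            Xtr = self.X[tr_pairs]
            mu, sd, kept = _standardize(Xtr)
            sd_safe = np.where(sd > 0, sd, 1.0)
            if kept.size < self.X.shape[1]:
                logger.warning(
                    "fold drops zero-variance predictors: %s",
                    [self.names[j] for j in range(self.X.shape[1])
                     if j not in set(kept)],
                )
            Xtr_s = (Xtr[:, kept] - mu[kept]) / sd_safe[kept]
            Xte_s = (self.X[te_pairs][:, kept] - mu[kept]) / sd_safe[kept]
            A_aug = [
                np.vstack([Xtr_s, np.sqrt(g) * np.eye(kept.size)])
                for g in self.grid
            ]
            # nested inner CV: partition training images, pairs follow images
            local_strata = [
                np.flatnonzero(np.isin(tr, strata[name]))
                for name in ("faces", "bodyparts", "inanimate")
            ]
            inner = []
            for grp in _inner_groups(tr.size, inner_folds, rng, local_strata):
                held = tr[grp]
                rest = tr[~np.isin(tr, held)]
                itr = _pairs_within(rest, pair_pos)
                ite = _pairs_within(held, pair_pos)
                if itr.size == 0 or ite.size == 0:
                    continue
                Xi = self.X[itr]
                mu_i, sd_i, kept_i = _standardize(Xi)
                sd_i_safe = np.where(sd_i > 0, sd_i, 1.0)
                Xi_s = (Xi[:, kept_i] - mu_i[kept_i]) / sd_i_safe[kept_i]
                Xv_s = (self.X[ite][:, kept_i] - mu_i[kept_i]) / sd_i_safe[kept_i]
                inner.append({
                    "train_pairs": itr,
                    "test_pairs": ite,
                    "A_aug": [
                        np.vstack([Xi_s, np.sqrt(g) * np.eye(kept_i.size)])
                        for g in self.grid
                    ],
                    "X_test": Xv_s,
                })
            self.folds.append({
                "train_pairs": tr_pairs,
                "test_pairs": te_pairs,
                "mu": mu, "sd": sd_safe, "kept": kept,
                "A_aug": A_aug, "X_test": Xte_s,
                "inner": inner,
            })
        if not covered.all():
            missing = int((~covered).sum())
            raise ValueError(
                f"schedule does not cover all pairs: {missing} uncovered"
            )

    # -- per-data-vector work -------------------------------------------

    def select_lambda_fold(self, y: np.ndarray, fold: dict) -> int:
        """Index into the grid minimizing mean held-out squared error.

        ``y`` is the full pair vector; the fold's inner splits hold the
        global pair positions they train and validate on.
        """
        if len(self.grid) == 1:
            return 0
        errs = np.zeros(len(self.grid))
        for inner in fold["inner"]:
            yi = y[inner["train_pairs"]]
            yv = y[inner["test_pairs"]]
            c = yi.mean()
            for g, A in enumerate(inner["A_aug"]):
                w = _nn_ridge_solve(yi, A, yi.size)
                pred = inner["X_test"] @ w + c
                errs[g] += np.mean((yv - pred) ** 2)
        if not fold["inner"]:
            return 0
        # ties go to the larger penalty (grid is sorted ascending)
        best = errs.min()
        return int(np.flatnonzero(np.isclose(errs, best, rtol=1e-12)).max())

    def predict(self, y: np.ndarray) -> CrossValPrediction:
        """Cross-validated prediction of a full data pair vector."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_pairs,):
            raise ValueError("y must be a full pair vector")
        acc = np.zeros(self.n_pairs)
        cov = np.zeros(self.n_pairs, dtype=int)
        lambdas = np.zeros(len(self.folds))
        w_sum = np.zeros(self.X.shape[1])
        for k, fold in enumerate(self.folds):
            ytr = y[fold["train_pairs"]]
            g = self.select_lambda_fold(y, fold)
            lambdas[k] = self.grid[g]
            w = _nn_ridge_solve(ytr, fold["A_aug"][g], ytr.size)
            pred = fold["X_test"] @ w + ytr.mean()
            acc[fold["test_pairs"]] += pred
            cov[fold["test_pairs"]] += 1
            w_full = np.zeros(self.X.shape[1])
            w_full[fold["kept"]] = w / fold["sd"][fold["kept"]]
            w_sum += w_full
        v_hat = acc / cov
        return CrossValPrediction(
            v_hat=v_hat,
            coverage=cov,
            fold_lambdas=lambdas,
            mean_weights_original=w_sum / len(self.folds),
        )

    def predict_many(self, Y: np.ndarray) -> np.ndarray:
        """Cross-validated predictions for a stack of data vectors.

        ``Y`` has shape (n_vectors, n_pairs) — e.g. one row per time point
        of an RDM movie.  Returns an array of the same shape.
        """
        return np.stack([self.predict(row).v_hat for row in Y])


def _pairs_within(imgs: np.ndarray, pair_pos: np.ndarray) -> np.ndarray:
    """Positions of all pairs with both images in ``imgs`` (sorted)."""
    ii, jj = np.meshgrid(imgs, imgs, indexing="ij")
    m = ii < jj
    return np.sort(pair_pos[ii[m], jj[m]])


def select_lambda(
    y: np.ndarray,
    X: np.ndarray,
    stimuli: StimulusSet,
    grid: Sequence[float] = DEFAULT_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> float:
    """Nested-CV penalty selection on a full training stimulus set.

    Splits the images of ``stimuli`` into inner folds, fits on the pairs
    among retained images for every grid value, scores squared error on
    the pairs among held-out images, and returns the grid value with the
    minimum mean error (ties resolved toward the larger penalty).
    """
    # a single degenerate "fold" whose train set is everything; outer pair
    # coverage is irrelevant here, so build the inner machinery directly
    plan = CrossValPlan.__new__(CrossValPlan)
    grid_arr = np.array(sorted(float(g) for g in grid))
    if grid_arr.size == 0:
        raise ValueError("penalty grid must be nonempty")
    if (grid_arr < 0).any():
        raise ValueError("penalty grid values must be nonnegative")
    plan.grid = grid_arr
    plan.X = np.asarray(X, dtype=float)
    n = len(stimuli)
    rows, cols = pair_index(n)
    pair_pos = np.full((n, n), -1, dtype=int)
    pair_pos[rows, cols] = np.arange(rows.size)
    pair_pos[cols, rows] = np.arange(rows.size)
    rng = np.random.default_rng(seed)
    strata = _strata(stimuli)
    tr = np.arange(n)
    local_strata = [strata[name] for name in ("faces", "bodyparts", "inanimate")]
    inner = []
    for grp in _inner_groups(n, inner_folds, rng, local_strata):
        held = tr[grp]
        rest = tr[~np.isin(tr, held)]
        itr = _pairs_within(rest, pair_pos)
        ite = _pairs_within(held, pair_pos)
        if itr.size == 0 or ite.size == 0:
            continue
        Xi = plan.X[itr]
        mu_i, sd_i, kept_i = _standardize(Xi)
        sd_i_safe = np.where(sd_i > 0, sd_i, 1.0)
        Xi_s = (Xi[:, kept_i] - mu_i[kept_i]) / sd_i_safe[kept_i]
        Xv_s = (plan.X[ite][:, kept_i] - mu_i[kept_i]) / sd_i_safe[kept_i]
        inner.append({
            "train_pairs": itr,
            "test_pairs": ite,
            "A_aug": [
                np.vstack([Xi_s, np.sqrt(g) * np.eye(kept_i.size)])
                for g in plan.grid
            ],
            "X_test": Xv_s,
        })
    fold = {"inner": inner}
    g = plan.select_lambda_fold(np.asarray(y, dtype=float), fold)
    return float(plan.grid[g])


def crossval_predict(
    data: RDMVector | np.ndarray,
    predictors: PredictorSet,
    schedule: Sequence[FoldSpec],
    stimuli: StimulusSet,
    grid: Sequence[float] = DEFAULT_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> CrossValPrediction:
    """Cross-validated model prediction of a data RDM vector.

    Per fold: standardize predictors on training pairs, select the penalty
    by nested CV, fit the nonnegative ridge, and predict only the pairs
    among held-out test images; per pair, predictions are averaged over
    the folds that covered it.  Raises if the schedule leaves any pair
    uncovered.
    """
    y = data.v if isinstance(data, RDMVector) else np.asarray(data, float)
    plan = CrossValPlan(
        stimuli, predictors.X, schedule, grid=grid,
        inner_folds=inner_folds, seed=seed, predictor_names=predictors.names,
    )
    return plan.predict(y)
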