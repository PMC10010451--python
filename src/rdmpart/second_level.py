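"""Second-level model fitting: nonnegative GLM variance partitioning.

The cross-validated RDM predictions from the first level become the
predictors of a second-level general linear model fit to the data RDM
with nonnegative least squares plus an unpenalized constant term (the
constant absorbs homogeneous changes in dissimilarity across the whole
RDM).  Model performance is the regression R² of that fit.  The unique
variance of a model class is the R² of the full GLM (all classes) minus
the R² of the reduced GLM that omits the class of interest; because the
reduced feasible set nests inside the full one, unique variance is
nonnegative up to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .rdm_core import RDMMovie, RDMVector

__all__ = [
    "GLMResult",
    "TimeCourse",
    "nnls_glm",
    "total_variance",
    "unique_variance",
    "partition_movie",
    "timecourses_to_frame",
]


@dataclass
class GLMResult:
    """A nonnegative least-squares fit and its explained variance."""

    weights: np.ndarray
    intercept: float
    r2: float


@dataclass
class TimeCourse:
    """Per-participant trajectories of one explained-variance measure.

    ``values`` has shape (n_participants, n_times); ``measure`` is
    ``total_r2``, ``unique_r2`` or ``difference``; ``model`` names the
    model class or submodel the measure refers to.
    """

    times_ms: np.ndarray
    values: np.ndarray
    measure: str
    model: str
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times_ms.size:
            raise ValueError("values must be (participants, times)")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]


def nnls_glm(y: np.ndarray | RDMVector, X: np.ndarray) -> GLMResult:
    """Nonnegative least squares of y on predictor columns + free intercept.

    Minimizes ``||y - Xw - b||^2`` with ``w >= 0`` and ``b`` unconstrained;
    R² is ``1 - SS_res / SS_tot`` with SS_tot about the mean of y.  R² can
    be negative when a nonzero fit extrapolates worse than the mean, and is
    exactly 0 when all weights are zero (intercept-only fit).
    """
    y = y.v if isinstance(y, RDMVector) else np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size or X.shape[1] < 1:
        raise ValueError("X must be (n_pairs, >=1) matching y")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance data vector: R^2 undefined")
    # free intercept decouples after centering both sides
    mu = X.mean(axis=0)
    Xc = X - mu
    yc = y - y.mean()
    w, rnorm = nnls(Xc, yc)
    b = float(y.mean() - mu @ w)
    r2 = 1.0 - rnorm**2 / ss_tot
    return GLMResult(weights=w, intercept=b, r2=float(r2))


def total_variance(
    y: np.ndarray | RDMVector, prediction: np.ndarray | RDMVector
) -> float:
    """Variance explained by one model's cross-validated prediction alone."""
    p = prediction.v if isinstance(prediction, RDMVector) else np.asarray(prediction, float)
    return nnls_glm(y, p[:, None]).r2


def unique_variance(
    y: np.ndarray | RDMVector,
    predictions: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Unique and total variance per model class from nested nonnegative GLMs.

    ``predictions`` maps model names to cross-validated prediction vectors.
    Returns a dict with ``total_r2:<name>`` (reduced GLM with that model
    alone), ``full_r2`` (all models), and ``unique_r2:<name>`` =
    full − reduced-without-that-model.  With two classes the reduced GLM
    without A is simply the GLM on B.
    """
    names = list(predictions)
    if len(names) < 1:
        raise ValueError("need at least one prediction")
    cols = {k: np.asarray(v, dtype=float) for k, v in predictions.items()}
    X_full = np.column_stack([cols[k] for k in names])
    out: dict[str, float] = {}
    full = nnls_glm(y, X_full).r2
    out["full_r2"] = full
    for k in names:
        out[f"total_r2:{k}"] = nnls_glm(y, cols[k][:, None]).r2
        rest = [cols[j] for j in names if j != k]
        if rest:
            reduced = nnls_glm(y, np.column_stack(rest)).r2
        else:
            reduced = 0.0
        out[f"unique_r2:{k}"] = full - reduced
    return out


def partition_movie(
    movies: Sequence[RDMMovie],
    predictions: Mapping[str, Mapping[str, np.ndarray]],
    roi_id: str = "",
) -> dict[str, TimeCourse]:
    """Total and unique variance time courses across participants.

    ``movies`` holds one RDM movie per participant (shared time axis);
    ``predictions[participant_id][model]`` is an (n_times, n_pairs) array
    of cross-validated first-level predictions for that participant (the
    first level is run per time point).  Returns a dict keyed by measure
    name (``total_r2:<model>``, ``unique_r2:<model>``, ``full_r2``) of
    TimeCourse objects with one row per participant.
    """
    if not movies:
        raise ValueError("need at least one movie")
    times = movies[0].times_ms
    for m in movies[1:]:
        if m.times_ms.shape != times.shape or not np.allclose(m.times_ms, times):
            raise ValueError("movies must share the time axis")
    rows: dict[str, list[np.ndarray]] = {}
    for movie in movies:
        pid = movie.participant_id
        preds = predictions[pid]
        model_names = list(preds)
        Y = movie.frame_vectors()
        per_measure: dict[str, np.ndarray] = {
            key: np.zeros(times.size)
            for key in ["full_r2"]
            + [f"total_r2:{k}" for k in model_names]
            + [f"unique_r2:{k}" for k in model_names]
        }
        for t in range(times.size):
            res = unique_variance(
                Y[t], {k: np.asarray(preds[k])[t] for k in model_names}
            )
            for key, val in res.items():
                per_measure[key][t] = val
        for key, vals in per_measure.items():
            rows.setdefault(key, []).append(vals)
    return {
        key: TimeCourse(
            times_ms=times,
            values=np.stack(vals),
            measure=key.split(":")[0],
            model=key.split(":")[1] if ":" in key else "all",
            roi_id=roi_id,
        )
        for key, vals in rows.items()
    }


def timecourses_to_frame(tcs: Mapping[str, TimeCourse]) -> pd.DataFrame:
    """Tidy table (participant, roi, time_ms, measure, model, value)."""
    records = []
    for key, tc in tcs.items():
        for p in range(tc.n_participants):
            for t, time in enumerate(tc.times_ms):
                records.append(
                    {
                        "participant": p,
                        "roi": tc.roi_id,
                        "time_ms": float(time),
                        "measure": tc.measure,
                        "model": tc.model,
                        "value": float(tc.values[p, t]),
                    }
                )
    return pd.DataFrame.from_records(records)
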