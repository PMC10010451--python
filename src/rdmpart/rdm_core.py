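"""Core representational-geometry containers and RDM operations.

A representational dissimilarity matrix (RDM) summarizes a representation
of a stimulus set by the pairwise dissimilarities between the responses it
assigns to the stimuli.  Everything downstream — model construction,
weighted regression, variance partitioning — operates either on full
``n × n`` RDMs or on their canonical vectorization over the ``n(n-1)/2``
unordered stimulus pairs.

Conventions shared by all modules:

* pair order is the row-major upper triangle with ``i < j``
  (``numpy.triu_indices`` order);
* dissimilarities are kept at full floating precision and are never
  rank-transformed;
* every RDM is symmetric with a zero diagonal and finite entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CATEGORIES",
    "ANIMATE_CATEGORIES",
    "FACE_CATEGORIES",
    "BODYPART_CATEGORIES",
    "StimulusSet",
    "FeatureMatrix",
    "RDM",
    "RDMVector",
    "RDMMovie",
    "PredictorSet",
    "rdm_from_dimension",
    "rdm_correlation_distance",
    "vectorize",
    "devectorize",
    "weighted_sum_rdms",
    "pair_index",
]

#: The six object categories of the stimulus set.
CATEGORIES = (
    "human_body",
    "human_face",
    "animal_body",
    "animal_face",
    "natural",
    "manmade",
)

ANIMATE_CATEGORIES = frozenset(
    {"human_body", "human_face", "animal_body", "animal_face"}
)
FACE_CATEGORIES = frozenset({"human_face", "animal_face"})
BODYPART_CATEGORIES = frozenset({"human_body", "animal_body"})

#: Number of images per category in the canonical 92-image set.
DEFAULT_COMPOSITION = {
    "human_body": 12,
    "human_face": 12,
    "animal_body": 12,
    "animal_face": 12,
    "natural": 23,
    "manmade": 21,
}

#: Per-dimension group tags a FeatureMatrix may carry.
DIM_GROUPS = (
    "color",
    "texture",
    "shape",
    "object_part",
    "subordinate",
    "basic",
    "superordinate",
    "dnn_layer",
)


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle (i < j), row-major order."""
    return np.triu_indices(n, k=1)


@dataclass(frozen=True)
class StimulusSet:
    """Object images with category labels.

    The category determines the animacy / face / body-part strata used for
    stratified cross-validation folds: the four human/animal classes are
    animate; faces are the two face classes; body parts are the two body
    classes.
    """

    image_ids: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.image_ids) != len(self.categories):
            raise ValueError("image_ids and categories must have equal length")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image ids must be unique")
        bad = [c for c in self.categories if c not in CATEGORIES]
        if bad:
            raise ValueError(f"unknown categories: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.image_ids)

    @property
    def animacy(self) -> np.ndarray:
        return np.array([c in ANIMATE_CATEGORIES for c in self.categories])

    @property
    def face_flag(self) -> np.ndarray:
        return np.array([c in FACE_CATEGORIES for c in self.categories])

    @property
    def bodypart_flag(self) -> np.ndarray:
        return np.array([c in BODYPART_CATEGORIES for c in self.categories])

    @classmethod
    def from_composition(
        cls, composition: dict[str, int] | None = None
    ) -> "StimulusSet":
        """Build a stimulus set with the given per-category image counts.

        With no argument this yields the canonical 92-image composition
        (12 human body parts, 12 human faces, 12 animal bodies, 12 animal
        faces, 23 natural and 21 manmade objects).
        """
        composition = dict(composition or DEFAULT_COMPOSITION)
        ids: list[str] = []
        cats: list[str] = []
        for cat in CATEGORIES:
            for k in range(composition.get(cat, 0)):
                ids.append(f"{cat}_{k:02d}")
                cats.append(cat)
        return cls(tuple(ids), tuple(cats))


@dataclass(frozen=True)
class FeatureMatrix:
    """Images × model dimensions, values in [0, 1].

    Columns are binary label indicators unless produced by merging
    correlated dimensions, in which case they are elementwise means of
    binary columns.  Each dimension carries a group tag (color, texture,
    shape, object_part, subordinate, basic, superordinate, or dnn_layer).
    """

    image_ids: tuple[str, ...]
    values: np.ndarray  # (n_images, n_dims) float
    dim_names: tuple[str, ...]
    dim_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (images x dimensions)")
        if v.shape != (len(self.image_ids), len(self.dim_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if len(self.dim_groups) != len(self.dim_names):
            raise ValueError("dim_groups length mismatch")
        if not np.isfinite(v).all():
            raise ValueError("feature values must be finite")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("feature values must lie in [0, 1]")
        if len(set(self.dim_names)) != len(self.dim_names):
            raise ValueError("dimension names must be unique")

    @property
    def n_dims(self) -> int:
        return len(self.dim_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.dim_names.index(name)]

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as CSV (image_id column + one column per dim).

        ``sidecar`` (default: path with ``.groups.json`` suffix) receives
        the dim_name → dim_group mapping as JSON.
        """
        path = Path(path)
        df = pd.DataFrame(self.values, columns=list(self.dim_names))
        df.insert(0, "image_id", list(self.image_ids))
        df.to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".groups.json")
        sidecar.write_text(
            json.dumps(dict(zip(self.dim_names, self.dim_groups)), indent=1)
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, sidecar: str | Path | None = None
    ) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".groups.json")
        groups = json.loads(sidecar.read_text())
        names = tuple(df.columns[1:])
        return cls(
            image_ids=tuple(df.iloc[:, 0].astype(str)),
            values=df.iloc[:, 1:].to_numpy(float),
            dim_names=names,
            dim_groups=tuple(groups[n] for n in names),
        )


@dataclass(frozen=True)
class RDM:
    """A symmetric dissimilarity matrix over a condition (stimulus) set."""

    condition_ids: tuple[str, ...]
    d: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.condition_ids)
        if d.shape != (n, n):
            raise ValueError(f"RDM must be {n}x{n}, got {d.shape}")
        if not np.isfinite(d).all():
            raise ValueError("RDM entries must be finite")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diagonal(d), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.condition_ids)

    def vectorize(self) -> "RDMVector":
        return vectorize(self)


@dataclass(frozen=True)
class RDMVector:
    """Upper-triangle vectorization of an RDM (pairs in row-major i < j order)."""

    condition_ids: tuple[str, ...]
    v: np.ndarray  # (n_pairs,)

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "v", v)
        n = len(self.condition_ids)
        if v.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"vector length {v.shape} does not match {n} conditions"
            )

    @property
    def n(self) -> int:
        return len(self.condition_ids)

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        rows, cols = pair_index(self.n)
        return list(zip(rows.tolist(), cols.tolist()))

    def devectorize(self) -> RDM:
        return devectorize(self)


@dataclass(frozen=True)
class RDMMovie:
    """A time-indexed stack of RDMs for one participant and one ROI.

    ``data`` has shape (n_times, n, n); the time axis is uniformly sampled
    (default 2 ms step) with stimulus onset at 0 ms.
    """

    times_ms: np.ndarray
    condition_ids: tuple[str, ...]
    data: np.ndarray  # (t, n, n)
    participant_id: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "data", d)
        if t.ndim != 1 or not (np.diff(t) > 0).all():
            raise ValueError("times_ms must be strictly increasing")
        if t.size > 2 and not np.allclose(np.diff(t), t[1] - t[0]):
            raise ValueError("times_ms must be uniformly sampled")
        n = len(self.condition_ids)
        if d.shape != (t.size, n, n):
            raise ValueError(f"data must be (t, n, n) = ({t.size}, {n}, {n})")

    @property
    def n_times(self) -> int:
        return self.times_ms.size

    def frame(self, k: int) -> RDM:
        return RDM(self.condition_ids, self.data[k])

    def frame_vectors(self) -> np.ndarray:
        """All frames vectorized at once; shape (n_times, n_pairs)."""
        rows, cols = pair_index(len(self.condition_ids))
        return self.data[:, rows, cols]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset(
                "condition_ids",
                data=np.array(self.condition_ids, dtype=h5py.string_dtype()),
            )
            f.create_dataset("rdms", data=self.data)
            f.attrs["participant_id"] = self.participant_id
            f.attrs["roi_id"] = self.roi_id

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RDMMovie":
        with h5py.File(path, "r") as f:
            return cls(
                times_ms=f["times_ms"][()],
                condition_ids=tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["condition_ids"][()]
                ),
                data=f["rdms"][()],
                participant_id=str(f.attrs.get("participant_id", "")),
                roi_id=str(f.attrs.get("roi_id", "")),
            )


@dataclass(frozen=True)
class PredictorSet:
    """Named single-dimension / single-layer RDM vectors used as regressors.

    Each predictor carries a model class (``dnn`` or ``visuo_semantic``)
    and a submodel tag (a feature/category group, or the layer group for
    network predictors).  All predictors share the condition set and hence
    the pair order.
    """

    condition_ids: tuple[str, ...]
    names: tuple[str, ...]
    X: np.ndarray  # (n_pairs, n_predictors)
    model_class: tuple[str, ...]
    submodel: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        n = len(self.condition_ids)
        m = len(self.names)
        if X.shape != (n * (n - 1) // 2, m):
            raise ValueError("X shape inconsistent with conditions/names")
        if len(set(self.names)) != m:
            raise ValueError("predictor names must be unique")
        if len(self.model_class) != m or len(self.submodel) != m:
            raise ValueError("model_class/submodel length mismatch")
        bad = set(self.model_class) - {"dnn", "visuo_semantic"}
        if bad:
            raise ValueError(f"unknown model classes: {sorted(bad)}")

    @property
    def n_predictors(self) -> int:
        return len(self.names)

    def subset(
        self,
        model_class: str | None = None,
        submodel: str | Iterable[str] | None = None,
        exclude_submodel: str | Iterable[str] | None = None,
    ) -> "PredictorSet":
        keep = np.ones(self.n_predictors, dtype=bool)
        if model_class is not None:
            keep &= np.array([c == model_class for c in self.model_class])
        if submodel is not None:
            wanted = {submodel} if isinstance(submodel, str) else set(submodel)
            keep &= np.array([s in wanted for s in self.submodel])
        if exclude_submodel is not None:
            out = (
                {exclude_submodel}
                if isinstance(exclude_submodel, str)
                else set(exclude_submodel)
            )
            keep &= np.array([s not in out for s in self.submodel])
        idx = np.flatnonzero(keep)
        return PredictorSet(
            condition_ids=self.condition_ids,
            names=tuple(self.names[i] for i in idx),
            X=self.X[:, idx],
            model_class=tuple(self.model_class[i] for i in idx),
            submodel=tuple(self.submodel[i] for i in idx),
        )

    @staticmethod
    def concat(parts: Sequence["PredictorSet"]) -> "PredictorSet":
        if not parts:
            raise ValueError("need at least one PredictorSet")
        ids = parts[0].condition_ids
        for p in parts[1:]:
            if p.condition_ids != ids:
                raise ValueError("predictor sets must share condition_ids")
        return PredictorSet(
            condition_ids=ids,
            names=tuple(n for p in parts for n in p.names),
            X=np.hstack([p.X for p in parts]),
            model_class=tuple(c for p in parts for c in p.model_class),
            submodel=tuple(s for p in parts for s in p.submodel),
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            str_t = h5py.string_dtype()
            f.create_dataset("X", data=self.X)
            for key in ("condition_ids", "names", "model_class", "submodel"):
                f.create_dataset(
                    key, data=np.array(getattr(self, key), dtype=str_t)
                )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PredictorSet":
        def dec(arr):
            return tuple(
                s.decode() if isinstance(s, bytes) else str(s) for s in arr
            )

        with h5py.File(path, "r") as f:
            return cls(
                condition_ids=dec(f["condition_ids"][()]),
                names=dec(f["names"][()]),
                X=f["X"][()],
                model_class=dec(f["model_class"][()]),
                submodel=dec(f["submodel"][()]),
            )

    @classmethod
    def from_rdm_vectors(
        cls,
        vectors: Sequence[RDMVector],
        names: Sequence[str],
        model_class: str | Sequence[str],
        submodel: str | Sequence[str],
    ) -> "PredictorSet":
        ids = vectors[0].condition_ids
        m = len(vectors)
        if isinstance(model_class, str):
            model_class = [model_class] * m
        if isinstance(submodel, str):
            submodel = [submodel] * m
        return cls(
            condition_ids=ids,
            names=tuple(names),
            X=np.column_stack([v.v for v in vectors]),
            model_class=tuple(model_class),
            submodel=tuple(submodel),
        )


# ---------------------------------------------------------------------------
# RDM construction operations
# ---------------------------------------------------------------------------


def rdm_from_dimension(
    column: np.ndarray, condition_ids: Sequence[str] | None = None
) -> RDM:
    """Single-dimension RDM: squared difference of per-image values.

    For a binary dimension the dissimilarity between two images is 0 when
    the label is present or absent in both, and 1 when it is present in
    exactly one of the two.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("dimension column must be 1-D with at least 2 images")
    if not np.isfinite(x).all():
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        name = condition_ids[bad] if condition_ids is not None else f"index {bad}"
        raise ValueError(f"non-finite value for image {name}")
    ids = (
        tuple(condition_ids)
        if condition_ids is not None
        else tuple(f"img_{k:03d}" for k in range(x.size))
    )
    d = (x[:, None] - x[None, :]) ** 2
    return RDM(ids, d)


def rdm_correlation_distance(
    activations: np.ndarray,
    method: str = "spearman",
    condition_ids: Sequence[str] | None = None,
) -> RDM:
    """Correlation-distance RDM: 1 minus correlation between response rows.

    ``method='spearman'`` (rank correlation; used for network layer
    activations) or ``method='pearson'`` (used for measured response
    patterns).  Rows with zero variance have no defined correlation and
    raise an error naming the offending image.
    """
    A = np.asarray(activations, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("activations must be 2-D with >= 2 units per image")
    if not np.isfinite(A).all():
        raise ValueError("activations must be finite")
    ids = (
        tuple(condition_ids)
        if condition_ids is not None
        else tuple(f"img_{k:03d}" for k in range(A.shape[0]))
    )
    sd = A.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"zero-variance activation vector for image {ids[bad]}: "
            "correlation distance is undefined"
        )
    if method == "spearman":
        # average ranks for ties, then Pearson on the rank rows
        A = rankdata(A, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    r = np.corrcoef(A)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(ids, d)


def vectorize(rdm: RDM) -> RDMVector:
    """Extract the upper triangle in row-major i < j order."""
    rows, cols = pair_index(rdm.n)
    return RDMVector(rdm.condition_ids, rdm.d[rows, cols])


def devectorize(vec: RDMVector) -> RDM:
    """Rebuild the symmetric matrix from its pair vector (exact round trip)."""
    n = vec.n
    d = np.zeros((n, n))
    rows, cols = pair_index(n)
    d[rows, cols] = vec.v
    d[cols, rows] = vec.v
    return RDM(vec.condition_ids, d)


def weighted_sum_rdms(rdms: Sequence[RDM], weights: Sequence[float]) -> RDM:
    """Entrywise nonnegative weighted sum of RDMs over a shared condition set.

    Scaling a model dimension by ``w`` before computing squared differences
    multiplies its single-dimension RDM by ``w**2``, so a weighted squared-
    Euclidean model RDM equals this sum with weights ``w**2``.
    """
    if not rdms:
        raise ValueError("need at least one RDM")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(rdms),):
        raise ValueError("one weight per RDM required")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    ids = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ids:
            raise ValueError("RDMs must share condition_ids")
    d = np.tensordot(w, np.stack([r.d for r in rdms]), axes=1)
    return RDM(ids, d)
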