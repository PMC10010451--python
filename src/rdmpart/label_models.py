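"""Visuo-semantic model construction from observer labeling experiments.

A visuo-semantic model is built in two stages.  A generation experiment
has observers free-list feature and category labels for each image; a
label is retained if at least ``min_observers`` (default 3 of 15)
produced it for some image.  A validation experiment then has a second
observer group judge, for every image × label cell, whether the label
applies; a cell becomes 1 when at least 75% of validators agree.  The
resulting binary image × dimension matrix is stabilized by iteratively
merging highly correlated dimensions (Pearson r > 0.9, which for binary
vectors equals the phi coefficient), and finally grouped into submodels
(color, texture, shape, object parts; subordinate/basic/superordinate
categories) with one squared-difference RDM per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rdm_core import FeatureMatrix, PredictorSet, rdm_from_dimension, vectorize

__all__ = [
    "GenerationCounts",
    "ValidationJudgments",
    "select_generated_labels",
    "validate_labels",
    "merge_correlated_dimensions",
    "group_submodels",
    "read_count_table",
    "read_exclusion_list",
]


@dataclass(frozen=True)
class GenerationCounts:
    """Per image × candidate label: how many generation observers produced it."""

    image_ids: tuple[str, ...]
    labels: tuple[str, ...]
    counts: np.ndarray  # (n_images, n_labels) int
    n_observers: int = 15

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.image_ids), len(self.labels)):
            raise ValueError("counts shape inconsistent with ids/labels")
        if c.min(initial=0) < 0 or c.max(initial=0) > self.n_observers:
            raise ValueError("counts must lie in [0, n_observers]")


@dataclass(frozen=True)
class ValidationJudgments:
    """Per image × label: how many validation observers ticked the label."""

    image_ids: tuple[str, ...]
    labels: tuple[str, ...]
    agree: np.ndarray  # (n_images, n_labels) int
    n_observers: int = 14

    def __post_init__(self) -> None:
        a = np.asarray(self.agree)
        object.__setattr__(self, "agree", a)
        if a.shape != (len(self.image_ids), len(self.labels)):
            raise ValueError("agree shape inconsistent with ids/labels")
        if a.min(initial=0) < 0 or a.max(initial=0) > self.n_observers:
            raise ValueError("agreement counts must lie in [0, n_observers]")


def select_generated_labels(
    gen: GenerationCounts,
    min_observers: int = 3,
    exclude: Sequence[str] = (),
) -> tuple[str, ...]:
    """Labels generated by at least ``min_observers`` observers for some image.

    ``exclude`` models the manual curation step that removes labels
    inconsistent with the instructions or redundant; it is an explicit
    list, not an algorithm.
    """
    if not 1 <= min_observers <= gen.n_observers:
        raise ValueError(
            f"min_observers must be in [1, {gen.n_observers}], got {min_observers}"
        )
    excluded = set(exclude)
    keep = gen.counts.max(axis=0) >= min_observers
    return tuple(
        lab for lab, k in zip(gen.labels, keep) if k and lab not in excluded
    )


def validate_labels(
    val: ValidationJudgments,
    agreement: float = 0.75,
    dim_groups: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Binary feature matrix from validation agreement.

    A cell is 1 iff the fraction of validators agreeing reaches
    ``agreement`` (default 0.75).  Labels endorsed for no image are
    dropped.  ``dim_groups`` maps labels to their group tag; omitted
    labels default to ``object_part``.
    """
    if not 0.0 < agreement <= 1.0:
        raise ValueError(f"agreement must be in (0, 1], got {agreement}")
    binary = (val.agree / val.n_observers >= agreement).astype(float)
    keep = binary.any(axis=0)
    names = tuple(lab for lab, k in zip(val.labels, keep) if k)
    groups = tuple(
        (dim_groups or {}).get(name, "object_part") for name in names
    )
    return FeatureMatrix(
        image_ids=val.image_ids,
        values=binary[:, keep],
        dim_names=names,
        dim_groups=groups,
    )


def _pairwise_r(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between columns, diagonal masked."""
    r = np.corrcoef(values, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, -np.inf)
    return r


def merge_correlated_dimensions(
    fm: FeatureMatrix, r_threshold: float = 0.9
) -> FeatureMatrix:
    """Iteratively average dimension pairs with correlation above threshold.

    At each step all pairwise Pearson correlations within each dim_group
    are recomputed and the most-correlated pair above ``r_threshold`` is
    replaced by its elementwise mean (so merged columns may be non-binary);
    iteration stops when all within-group correlations are at or below
    threshold.  Merging only within a group keeps submodel sizes
    well-defined.  Ties are broken by merging the lexicographically first
    pair of dimension names.  Each merge removes one dimension, so
    termination is guaranteed.
    """
    if fm.n_dims < 1:
        raise ValueError("need at least one dimension")
    values = fm.values.copy()
    names = list(fm.dim_names)
    groups = list(fm.dim_groups)

    while values.shape[1] > 1:
        sd = values.std(axis=0)
        if (sd == 0).any():
            bad = names[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"constant dimension '{bad}' has no defined correlation")
        r = _pairwise_r(values)
        # mask cross-group pairs
        g = np.array(groups)
        same = g[:, None] == g[None, :]
        r = np.where(same, r, -np.inf)
        rmax = r.max()
        if rmax <= r_threshold:
            break
        # candidate pairs at the max; break ties lexicographically by names
        ii, jj = np.nonzero(np.isclose(r, rmax, rtol=0, atol=1e-12))
        cands = sorted(
            (tuple(sorted((names[a], names[b]))), min(a, b), max(a, b))
            for a, b in zip(ii.tolist(), jj.tolist())
            if a < b
        )
        _, a, b = cands[0]
        merged = (values[:, a] + values[:, b]) / 2.0
        merged_name = f"{names[a]}+{names[b]}"
        values[:, a] = merged
        names[a] = merged_name
        values = np.delete(values, b, axis=1)
        del names[b], groups[b]

    return FeatureMatrix(
        image_ids=fm.image_ids,
        values=values,
        dim_names=tuple(names),
        dim_groups=tuple(groups),
    )


def group_submodels(fm: FeatureMatrix) -> PredictorSet:
    """One squared-difference RDM predictor per dimension, tagged by group.

    All predictors belong to the visuo-semantic model class; the submodel
    tag is the dimension's group, so the full model is the union of the
    submodels and predictor counts add up.
    """
    if fm.n_dims == 0:
        raise ValueError("feature matrix has no dimensions")
    vectors = [
        vectorize(rdm_from_dimension(fm.values[:, j], fm.image_ids))
        for j in range(fm.n_dims)
    ]
    return PredictorSet.from_rdm_vectors(
        vectors,
        names=fm.dim_names,
        model_class="visuo_semantic",
        submodel=fm.dim_groups,
    )


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Delimited text with images as rows (first column) and labels as columns."""
    return pd.read_csv(path, index_col=0)


def read_exclusion_list(path: str | Path) -> tuple[str, ...]:
    """Plain text, one excluded label per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return tuple(s.strip() for s in lines if s.strip())
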