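"""Synthetic fixtures: activations, label experiments, and RDM movies.

The measured data the analysis pipeline consumes are time-resolved RDM
movies per participant and region of interest.  This module generates
such movies from *known* time-varying nonnegative mixtures of predictor
RDMs plus additive noise, so that every downstream stage (cross-validated
weighted regression, variance partitioning, group inference) can be
validated against planted ground truth.  It also generates layered
activation matrices emulating a feedforward or locally recurrent network
hierarchy, and observer labeling experiments emulating the two-stage
construction of visuo-semantic models.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .label_models import GenerationCounts, ValidationJudgments
from .rdm_core import (
    FeatureMatrix,
    PredictorSet,
    RDMMovie,
    StimulusSet,
    rdm_correlation_distance,
    vectorize,
)

__all__ = [
    "LayerSpec",
    "SynthGroundTruth",
    "enumerate_layers",
    "generate_activations",
    "build_dnn_predictors",
    "generate_label_experiment",
    "triangle_curve",
    "generate_rdm_movie",
    "make_reversal_scenario",
]

#: Default epoch matching a 2 ms sampled recording around stimulus onset.
DEFAULT_TIMES_MS = np.arange(-200.0, 1000.0, 2.0)


@dataclass(frozen=True)
class LayerSpec:
    """Architecture of a layered network whose layers become predictors.

    ``feedforward`` yields one layer per area (plus the decoder);
    ``locally_recurrent`` unrolls each area over ``n_timesteps`` internal
    time steps, yielding ``n_areas * n_timesteps`` layers (plus the
    decoder).  With the default four areas and five time steps this gives
    5 and 21 layers respectively, 26 predictors in total.
    """

    architecture: str = "feedforward"
    n_areas: int = 4
    n_timesteps: int = 5
    include_decoder: bool = True
    area_names: tuple[str, ...] = ("V1", "V2", "V4", "IT")

    def __post_init__(self) -> None:
        if self.architecture not in ("feedforward", "locally_recurrent"):
            raise ValueError(f"unknown architecture '{self.architecture}'")
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        if self.architecture == "locally_recurrent" and self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1 for recurrent networks")


def enumerate_layers(spec: LayerSpec) -> list[str]:
    """Ordered layer names for a layered-network specification."""
    areas = list(spec.area_names[: spec.n_areas])
    if len(areas) < spec.n_areas:
        areas += [f"A{k}" for k in range(len(areas), spec.n_areas)]
    if spec.architecture == "feedforward":
        names = list(areas)
    else:
        names = [f"{a}_t{t}" for a in areas for t in range(spec.n_timesteps)]
    if spec.include_decoder:
        names.append("decoder")
    return names


def _layer_depths(spec: LayerSpec) -> np.ndarray:
    """Relative depth in [0, 1] per layer (drives category mixing)."""
    if spec.architecture == "feedforward":
        depths = list(np.linspace(0.0, 0.8, spec.n_areas))
    else:
        depths = [
            (a + t / max(1, spec.n_timesteps)) / spec.n_areas * 0.8
            for a in range(spec.n_areas)
            for t in range(spec.n_timesteps)
        ]
    if spec.include_decoder:
        depths.append(1.0)
    return np.array(depths)


def generate_activations(
    spec: LayerSpec,
    stimuli: StimulusSet,
    n_units: int = 50,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-layer image × unit activation matrices with depth-graded structure.

    Each unit responds to a mixture of an image-specific component and a
    category-prototype component; the categorical share grows with layer
    depth, so deeper layers progressively emphasize category structure —
    the qualitative signature of a trained object-recognition hierarchy.
    Responses are rectified softly (softplus) so no row is constant.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(stimuli)
    cat_codes = np.array(
        [sorted(set(stimuli.categories)).index(c) for c in stimuli.categories]
    )
    image_comp = rng.standard_normal((n, n_units))
    layers = enumerate_layers(spec)
    depths = _layer_depths(spec)
    out: dict[str, np.ndarray] = {}
    for name, depth in zip(layers, depths):
        proto = rng.standard_normal((cat_codes.max() + 1, n_units))
        cat_comp = proto[cat_codes]
        jitter = 0.15 * rng.standard_normal((n, n_units))
        raw = (1.0 - depth) * image_comp + depth * cat_comp + jitter
        out[name] = np.log1p(np.exp(raw))  # softplus keeps rows non-constant
    return out


def build_dnn_predictors(
    activations: Mapping[str, np.ndarray],
    stimuli: StimulusSet,
    submodel: str = "dnn_layer",
) -> PredictorSet:
    """One 1 − Spearman RDM predictor per network layer."""
    names = list(activations)
    vectors = [
        vectorize(
            rdm_correlation_distance(
                activations[n], method="spearman", condition_ids=stimuli.image_ids
            )
        )
        for n in names
    ]
    return PredictorSet.from_rdm_vectors(
        vectors, names=names, model_class="dnn", submodel=submodel
    )


def generate_label_experiment(
    stimuli: StimulusSet,
    n_labels: int = 12,
    n_gen_observers: int = 15,
    n_val_observers: int = 14,
    observer_noise: float = 0.1,
    n_duplicate_labels: int = 2,
    seed: int = 0,
) -> tuple[GenerationCounts, ValidationJudgments, FeatureMatrix]:
    """Simulated two-stage labeling experiment around planted true labels.

    Plants a binary image × label ground truth (category indicators plus
    random feature labels that co-vary with categories), then draws
    per-observer generation counts and validation judgments: an observer
    endorses a true cell with probability ``1 - observer_noise`` and a
    false cell with probability ``observer_noise / 2``.  With zero noise,
    threshold-based validation recovers the planted matrix exactly.
    ``n_duplicate_labels`` planted near-duplicates exercise the
    correlated-dimension merging step.  Returns the counts, the judgments
    and the planted truth.
    """
    if not 0.0 <= observer_noise < 0.5:
        raise ValueError("observer_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(stimuli)
    cats = sorted(set(stimuli.categories))
    truth_cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[str] = []
    for c in cats:  # basic-category indicator labels
        truth_cols.append(np.array([x == c for x in stimuli.categories], float))
        names.append(f"cat_{c}")
        groups.append("basic")
    truth_cols.append(stimuli.animacy.astype(float))
    names.append("animate")
    groups.append("superordinate")
    n_feat = max(0, n_labels - len(names))
    for k in range(n_feat):
        # feature labels: present in ~40% of one category plus spillover
        c = cats[k % len(cats)]
        base = np.array([x == c for x in stimuli.categories], float)
        col = np.where(
            base > 0, rng.random(n) < 0.7, rng.random(n) < 0.15
        ).astype(float)
        if col.sum() == 0:
            col[rng.integers(n)] = 1.0
        truth_cols.append(col)
        names.append(f"feat_{k:02d}")
        groups.append("object_part" if k % 2 == 0 else "shape")
    for k in range(n_duplicate_labels):  # exact duplicates, merged downstream
        truth_cols.append(truth_cols[k].copy())
        names.append(f"{names[k]}_syn")
        groups.append(groups[k])
    truth = np.column_stack(truth_cols)
    planted = FeatureMatrix(
        image_ids=stimuli.image_ids,
        values=truth,
        dim_names=tuple(names),
        dim_groups=tuple(groups),
    )
    p_true = 1.0 - observer_noise
    p_false = observer_noise / 2.0
    p = np.where(truth > 0, p_true, p_false)
    counts = rng.binomial(n_gen_observers, p)
    agree = rng.binomial(n_val_observers, p)
    gen = GenerationCounts(
        stimuli.image_ids, tuple(names), counts, n_observers=n_gen_observers
    )
    val = ValidationJudgments(
        stimuli.image_ids, tuple(names), agree, n_observers=n_val_observers
    )
    return gen, val, planted


# ---------------------------------------------------------------------------
# RDM-movie generation from planted weight curves
# ---------------------------------------------------------------------------


def triangle_curve(
    times_ms: np.ndarray,
    onset_ms: float,
    peak_ms: float,
    end_ms: float,
    amplitude: float,
) -> np.ndarray:
    """Piecewise-linear bump: zero outside [onset, end], peaking at peak_ms."""
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    t = np.asarray(times_ms, dtype=float)
    return amplitude * np.interp(
        t, [onset_ms, peak_ms, end_ms], [0.0, 1.0, 0.0], left=0.0, right=0.0
    )


@dataclass
class SynthGroundTruth:
    """Planted generative state of a synthetic RDM movie set.

    ``weight_curves`` maps predictor names to nonnegative weight
    trajectories sampled on ``times_ms``; the data pair vector at time t
    is ``sum_m w_m(t) x_m + baseline + noise``, noise iid Gaussian per
    pair, participant and time point with standard deviation
    ``noise_sd``.
    """

    times_ms: np.ndarray
    weight_curves: dict[str, np.ndarray]
    noise_sd: float = 0.2
    baseline: float = 0.5
    n_participants: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        for name, w in self.weight_curves.items():
            w = np.asarray(w, dtype=float)
            if w.shape != self.times_ms.shape:
                raise ValueError(f"curve '{name}' not sampled on times_ms")
            if (w < 0).any():
                raise ValueError(f"planted weight curve '{name}' goes negative")
            self.weight_curves[name] = w
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "times_ms": self.times_ms.tolist(),
                    "weight_curves": {
                        k: v.tolist() for k, v in self.weight_curves.items()
                    },
                    "noise_sd": self.noise_sd,
                    "baseline": self.baseline,
                    "n_participants": self.n_participants,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            times_ms=np.array(d["times_ms"]),
            weight_curves={k: np.array(v) for k, v in d["weight_curves"].items()},
            noise_sd=d["noise_sd"],
            baseline=d["baseline"],
            n_participants=d["n_participants"],
            seed=d["seed"],
        )


def generate_rdm_movie(
    truth: SynthGroundTruth,
    predictors: PredictorSet,
    roi_id: str = "",
    noise_mode: str = "pair",
    n_units_per_dim: int = 8,
    pattern_basis: np.ndarray | None = None,
) -> list[RDMMovie]:
    """Multi-participant RDM movies from a planted nonnegative mixture.

    ``noise_mode='pair'`` (default) adds iid Gaussian noise directly to
    the dissimilarities — the error geometry the downstream regression
    assumes.  ``noise_mode='pattern'`` instead builds latent unit
    responses whose loadings follow ``pattern_basis`` (one image-score
    column per predictor), adds unit-level noise, and computes 1 − Pearson
    RDMs, exercising the correlation-distance nonlinearity.
    """
    for name in truth.weight_curves:
        if name not in predictors.names:
            raise ValueError(f"curve '{name}' has no matching predictor")
    rng = np.random.default_rng(truth.seed)
    n_pairs, _ = predictors.X.shape
    n_t = truth.times_ms.size
    W = np.zeros((n_t, predictors.n_predictors))
    for j, name in enumerate(predictors.names):
        if name in truth.weight_curves:
            W[:, j] = truth.weight_curves[name]
    signal = W @ predictors.X.T + truth.baseline  # (n_t, n_pairs)
    movies: list[RDMMovie] = []
    n = len(predictors.condition_ids)
    if noise_mode == "pair":
        for p in range(truth.n_participants):
            noise = truth.noise_sd * rng.standard_normal((n_t, n_pairs))
            frames = np.zeros((n_t, n, n))
            rows, cols = np.triu_indices(n, k=1)
            v = signal + noise
            frames[:, rows, cols] = v
            frames[:, cols, rows] = v
            movies.append(
                RDMMovie(
                    times_ms=truth.times_ms,
                    condition_ids=predictors.condition_ids,
                    data=frames,
                    participant_id=f"p{p:02d}",
                    roi_id=roi_id,
                )
            )
    elif noise_mode == "pattern":
        if pattern_basis is None:
            raise ValueError("pattern mode requires a pattern_basis")
        S = np.asarray(pattern_basis, dtype=float)  # (n_images, n_predictors)
        if S.shape != (n, predictors.n_predictors):
            raise ValueError("pattern_basis must be (n_images, n_predictors)")
        loadings = rng.standard_normal(
            (predictors.n_predictors, n_units_per_dim)
        )
        base = rng.standard_normal((n, n_units_per_dim))
        for p in range(truth.n_participants):
            frames = np.zeros((n_t, n, n))
            for t in range(n_t):
                # sqrt weights: correlation distance scales with squared pattern
                scaled = S * np.sqrt(W[t])[None, :]
                patt = scaled @ loadings + base
                patt = patt + truth.noise_sd * rng.standard_normal(patt.shape)
                frames[t] = rdm_correlation_distance(
                    patt, method="pearson",
                    condition_ids=predictors.condition_ids,
                ).d
            movies.append(
                RDMMovie(
                    times_ms=truth.times_ms,
                    condition_ids=predictors.condition_ids,
                    data=frames,
                    participant_id=f"p{p:02d}",
                    roi_id=roi_id,
                )
            )
    else:
        raise ValueError("noise_mode must be 'pair' or 'pattern'")
    return movies


def make_reversal_scenario(
    stimuli: StimulusSet,
    predictors: PredictorSet,
    seed: int = 0,
    times_ms: np.ndarray | None = None,
    noise_sd: float = 0.2,
    n_participants: int = 10,
    dnn_onset_ms: float = 50.0,
    semantic_onset_ms: float = 140.0,
    signal_sd: float = 0.5,
) -> dict:
    """Two pseudo-ROI movie sets with an early-network/late-semantic reversal.

    ROI-1 loads exclusively on the network-layer predictors with an early
    onset; ROI-2 loads exclusively on the visuo-semantic predictors with a
    later onset.  All planted weights are zero before stimulus onset, so
    the prestimulus window is pure noise around the constant baseline.
    Per-ROI planted amplitudes are scaled so the mixed signal's pair-wise
    standard deviation at the planted peak equals ``signal_sd``.

    Returns a dict with movie lists under ``'roi1'``/``'roi2'`` and the
    planted ground truths under ``'truth_roi1'``/``'truth_roi2'``.
    """
    classes = set(predictors.model_class)
    if classes != {"dnn", "visuo_semantic"}:
        raise ValueError("predictors must contain both model classes")
    if times_ms is None:
        times_ms = DEFAULT_TIMES_MS
    times_ms = np.asarray(times_ms, dtype=float)
    rng = np.random.default_rng(seed)

    def curves_for(model_class: str, onset: float) -> dict[str, np.ndarray]:
        idx = [
            j for j, c in enumerate(predictors.model_class) if c == model_class
        ]
        peak = onset + 60.0
        end = min(onset + 500.0, float(times_ms[-1]))
        amps = 0.5 + rng.random(len(idx))
        curves = {
            predictors.names[j]: triangle_curve(times_ms, onset, peak, end, a)
            for j, a in zip(idx, amps)
        }
        # calibrate amplitudes so the peak-time signal sd over pairs is known
        t_peak = int(np.argmin(np.abs(times_ms - peak)))
        mix = sum(
            curves[predictors.names[j]][t_peak] * predictors.X[:, j]
            for j in idx
        )
        scale = signal_sd / max(np.std(mix), 1e-12)
        return {k: v * scale for k, v in curves.items()}

    truth1 = SynthGroundTruth(
        times_ms=times_ms,
        weight_curves=curves_for("dnn", dnn_onset_ms),
        noise_sd=noise_sd,
        n_participants=n_participants,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth2 = SynthGroundTruth(
        times_ms=times_ms,
        weight_curves=curves_for("visuo_semantic", semantic_onset_ms),
        noise_sd=noise_sd,
        n_participants=n_participants,
        seed=int(rng.integers(2**31 - 1)),
    )
    return {
        "roi1": generate_rdm_movie(truth1, predictors, roi_id="roi1"),
        "roi2": generate_rdm_movie(truth2, predictors, roi_id="roi2"),
        "truth_roi1": truth1,
        "truth_roi2": truth2,
    }
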