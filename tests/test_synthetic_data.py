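"""Synthetic activations, label experiments, and planted RDM movies."""

import numpy as np
import pytest

from rdmpart.label_models import (
    merge_correlated_dimensions,
    validate_labels,
)
from rdmpart.rdm_core import rdm_correlation_distance
from rdmpart.synthetic_data import (
    LayerSpec,
    SynthGroundTruth,
    build_dnn_predictors,
    enumerate_layers,
    generate_activations,
    generate_label_experiment,
    generate_rdm_movie,
    make_reversal_scenario,
    triangle_curve,
)


class TestLayerEnumeration:
    def test_feedforward_four_areas_plus_decoder_is_five(self):
        assert len(enumerate_layers(LayerSpec("feedforward"))) == 5

    def test_recurrent_unrolls_to_21_layers(self):
        names = enumerate_layers(LayerSpec("locally_recurrent"))
        assert len(names) == 21
        assert names[0] == "V1_t0" and names[-1] == "decoder"

    def test_both_architectures_give_26_predictors(self):
        total = len(enumerate_layers(LayerSpec("feedforward"))) + len(
            enumerate_layers(LayerSpec("locally_recurrent"))
        )
        assert total == 26

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec("residual")


class TestActivations:
    def test_same_seed_reproduces_exactly(self, stimuli24):
        spec = LayerSpec("feedforward")
        a = generate_activations(spec, stimuli24, n_units=20, seed=7)
        b = generate_activations(spec, stimuli24, n_units=20, seed=7)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_category_structure_grows_with_depth(self, stimuli24):
        spec = LayerSpec("feedforward")
        acts = generate_activations(spec, stimuli24, n_units=60, seed=3)
        names = enumerate_layers(spec)
        cat = np.array(
            [c1 != c2 for c1 in stimuli24.categories for c2 in stimuli24.categories]
        ).reshape(len(stimuli24), -1)
        rows, cols = np.triu_indices(len(stimuli24), 1)
        cat_vec = cat[rows, cols].astype(float)

        def cat_corr(layer):
            d = rdm_correlation_distance(acts[layer], "spearman").d
            return np.corrcoef(d[rows, cols], cat_vec)[0, 1]

        assert cat_corr(names[-1]) > cat_corr(names[0])

    def test_single_unit_rejected(self, stimuli24):
        with pytest.raises(ValueError):
            generate_activations(LayerSpec(), stimuli24, n_units=1)

    def test_predictor_set_tagged_as_dnn(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, n_units=20, seed=1)
        ps = build_dnn_predictors(acts, stimuli24)
        assert set(ps.model_class) == {"dnn"}
        assert ps.n_predictors == 5


class TestLabelExperiment:
    def test_noiseless_validation_recovers_planted_matrix(self, stimuli24):
        gen, val, planted = generate_label_experiment(
            stimuli24, observer_noise=0.0, seed=11
        )
        fm = validate_labels(
            val, dim_groups=dict(zip(planted.dim_names, planted.dim_groups))
        )
        # labels endorsed nowhere are dropped; surviving ones match exactly
        for name in fm.dim_names:
            assert np.array_equal(fm.column(name), planted.column(name))
        kept = [n for n in planted.dim_names if planted.column(n).any()]
        assert list(fm.dim_names) == kept

    def test_same_seed_reproduces(self, stimuli24):
        a = generate_label_experiment(stimuli24, seed=5)
        b = generate_label_experiment(stimuli24, seed=5)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert np.array_equal(a[1].agree, b[1].agree)

    def test_planted_duplicates_are_merged_away(self, stimuli24):
        gen, val, planted = generate_label_experiment(
            stimuli24, observer_noise=0.0, n_duplicate_labels=2, seed=2
        )
        fm = validate_labels(
            val, dim_groups=dict(zip(planted.dim_names, planted.dim_groups))
        )
        merged = merge_correlated_dimensions(fm)
        assert merged.n_dims <= fm.n_dims - 2


class TestRdmMovie:
    def _truth(self, times, curves, **kw):
        return SynthGroundTruth(times_ms=times, weight_curves=curves, **kw)

    def test_noiseless_single_predictor_frames_equal_predictor(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        ps = build_dnn_predictors(acts, stimuli24)
        times = np.arange(0.0, 20.0, 2.0)
        name = ps.names[0]
        truth = self._truth(
            times, {name: np.ones_like(times)}, noise_sd=0.0, n_participants=2
        )
        movies = generate_rdm_movie(truth, ps)
        expected = ps.X[:, 0] + truth.baseline
        for m in movies:
            assert np.allclose(m.frame_vectors(), expected[None, :])

    def test_noiseless_two_predictor_mixture_is_exact(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        ps = build_dnn_predictors(acts, stimuli24)
        times = np.arange(0.0, 10.0, 2.0)
        truth = self._truth(
            times,
            {
                ps.names[0]: np.full_like(times, 2.0),
                ps.names[1]: np.full_like(times, 3.0),
            },
            noise_sd=0.0,
            n_participants=1,
        )
        m = generate_rdm_movie(truth, ps)[0]
        expected = 2 * ps.X[:, 0] + 3 * ps.X[:, 1] + truth.baseline
        assert np.allclose(m.frame_vectors()[0], expected)

    def test_pair_noise_variance_matches_noise_sd(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        ps = build_dnn_predictors(acts, stimuli24)
        times = np.array([0.0, 2.0])
        truth = self._truth(
            times,
            {ps.names[0]: np.ones_like(times)},
            noise_sd=0.3,
            n_participants=200,
            seed=9,
        )
        movies = generate_rdm_movie(truth, ps)
        stack = np.stack([m.frame_vectors()[0] for m in movies])
        var = stack.var(axis=0, ddof=1).mean()
        assert var == pytest.approx(0.3**2, rel=0.1)

    def test_negative_planted_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SynthGroundTruth(
                times_ms=np.array([0.0, 2.0]),
                weight_curves={"a": np.array([1.0, -0.5])},
            )

    def test_pattern_mode_produces_valid_correlation_rdms(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        ps = build_dnn_predictors(acts, stimuli24)
        times = np.array([0.0, 2.0])
        truth = self._truth(
            times,
            {ps.names[0]: np.ones_like(times)},
            noise_sd=0.2,
            n_participants=1,
        )
        basis = np.random.default_rng(0).random((len(stimuli24), ps.n_predictors))
        m = generate_rdm_movie(
            truth, ps, noise_mode="pattern", pattern_basis=basis
        )[0]
        assert m.data.min() >= 0.0 - 1e-12 and m.data.max() <= 2.0 + 1e-12


class TestReversalScenario:
    def test_triangle_curve_zero_outside_support(self):
        t = np.arange(-100.0, 300.0, 2.0)
        w = triangle_curve(t, 50.0, 100.0, 250.0, 2.0)
        assert np.all(w[t <= 50.0] == 0)
        assert np.all(w[t >= 250.0] == 0)
        assert w[t == 100.0] == pytest.approx(2.0)
        assert np.all(w >= 0)

    def test_baseline_window_is_pure_noise_and_onsets_ordered(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        dnn = build_dnn_predictors(acts, stimuli24)
        gen, val, planted = generate_label_experiment(
            stimuli24, observer_noise=0.0, seed=2
        )
        from rdmpart.label_models import group_submodels
        from rdmpart.rdm_core import PredictorSet

        sem = group_submodels(
            validate_labels(
                val, dim_groups=dict(zip(planted.dim_names, planted.dim_groups))
            )
        )
        ps = PredictorSet.concat([dnn, sem])
        times = np.arange(-100.0, 300.0, 2.0)
        sc = make_reversal_scenario(
            stimuli24, ps, seed=4, times_ms=times, n_participants=2
        )
        for roi in ("roi1", "roi2"):
            truth = sc[f"truth_{roi}"]
            W = np.stack(list(truth.weight_curves.values()))
            assert np.all(W[:, times < 0] == 0)
        # planted network onset in ROI-1 strictly before semantic in ROI-2
        w1 = np.stack(list(sc["truth_roi1"].weight_curves.values())).sum(0)
        w2 = np.stack(list(sc["truth_roi2"].weight_curves.values())).sum(0)
        onset1 = times[np.flatnonzero(w1 > 0)[0]]
        onset2 = times[np.flatnonzero(w2 > 0)[0]]
        assert onset1 < onset2
        # ROI-1 loads only on network predictors, ROI-2 only on semantic
        dnn_names = set(dnn.names)
        assert set(sc["truth_roi1"].weight_curves) <= dnn_names
        assert set(sc["truth_roi2"].weight_curves).isdisjoint(dnn_names)

    def test_requires_both_model_classes(self, stimuli24):
        acts = generate_activations(LayerSpec(), stimuli24, 20, seed=1)
        dnn = build_dnn_predictors(acts, stimuli24)
        with pytest.raises(ValueError, match="both model classes"):
            make_reversal_scenario(stimuli24, dnn, seed=0)
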