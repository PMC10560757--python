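"""Selectivity indices, reliability, SNR and the Pearson helper."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tensor, pearson_oracle
from laminar_decode import (
    LayerProfile,
    dsi,
    generate_population,
    make_stimulus_set,
    neuron_properties,
    orthogonal_and_opposite,
    osi,
    pearson_corr,
    preferred_condition,
    reliability,
    snr,
    trial_average,
)

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestPearson:
    def test_identical_and_anticorrelated(self):
        assert pearson_corr([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_corr([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # covariance formula by hand: r = 3 / (sqrt(2) * sqrt(42/9))
        expected = 3.0 / (math.sqrt(2.0) * math.sqrt(42.0 / 9.0))
        assert pearson_corr([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9820, abs=5e-5)

    def test_zero_variance_convention(self):
        assert pearson_corr([2, 2, 2], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(finite, min_size=2, max_size=12), st.data())
    def test_matches_two_pass_oracle(self, x, data):
        y = data.draw(st.lists(finite, min_size=len(x), max_size=len(x)))
        assert pearson_corr(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)


class TestPreferredCondition:
    def test_argmax_of_trial_means(self):
        stim = make_stimulus_set("custom", {"n_directions": 3, "n_repeats": 1})
        t = make_tensor([[[0.1], [0.9], [0.3]]], stim)
        assert preferred_condition(t, 0) == 1

    def test_tie_breaks_to_lowest_id(self):
        stim = make_stimulus_set("custom", {"n_directions": 2, "n_repeats": 1})
        t = make_tensor([[[0.5], [0.5]]], stim)
        assert preferred_condition(t, 0) == 0

    def test_noiseless_neuron_prefers_nearest_grid_direction(self):
        stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 2})
        profile = LayerProfile(
            n_neurons=40, layer_label="L4", noise_sd=0.0, direction_mix=1.0
        )
        t = generate_population([profile], stim, seed=5, snap_preferred=True)
        pos = {cid: i for i, cid in enumerate(stim.condition_ids)}
        for i in range(t.n_neurons):
            # with the preferred direction on the grid and no noise, the peak
            # response is exactly baseline + gain (the tuning curve at 0 offset)
            means = t.responses[i].mean(axis=1)
            peak = means[pos[preferred_condition(t, i)]]
            assert peak == pytest.approx(profile.baseline + profile.gain, abs=1e-12)
            assert peak == means.max()


class TestSelectivityIndices:
    @pytest.mark.parametrize(
        "func, args, expected",
        [
            (osi, (1.0, 0.0), 1.0),
            (osi, (0.7, 0.7), 0.0),
            (osi, (0.6, 0.2), 0.5),
            (dsi, (1.0, 0.0), 1.0),
            (dsi, (0.4, 0.4), 0.0),
        ],
    )
    def test_worked_examples(self, func, args, expected):
        assert func(*args) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_sentinel(self):
        assert math.isnan(osi(0.5, -0.5))
        assert math.isnan(dsi(0.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.01, max_value=10),
        st.floats(min_value=0.0, max_value=10),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, r_pref, r_other, scale):
        if r_pref + r_other == 0:
            return
        assert osi(r_pref * scale, r_other * scale) == pytest.approx(
            osi(r_pref, r_other), abs=1e-9
        )


class TestReliability:
    def test_identical_trials_give_one(self):
        f = [0.0, 1.0, 2.0, 1.0]
        assert reliability([f, f, f]) == pytest.approx(1.0)

    def test_two_anticorrelated_trials(self):
        f = np.array([0.0, 1.0, 2.0])
        assert reliability([f, -f]) == pytest.approx(-1.0)

    def test_three_trial_mean_of_pairwise_correlations(self):
        f1, f2, f3 = [0, 1, 2], [0, 1, 3], [2, 1, 0]
        expected = (
            pearson_oracle(f1, f2) + pearson_oracle(f1, f3) + pearson_oracle(f2, f3)
        ) / 3.0
        assert reliability([f1, f2, f3]) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            reliability([[1.0, 2.0]])

    @settings(derandomize=True, max_examples=30)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_invariant_to_per_trial_affine_rescale(self, a, b):
        rng = np.random.default_rng(7)
        trials = [rng.normal(size=20) for _ in range(4)]
        rescaled = [a * f + b for f in trials]
        assert reliability(rescaled) == pytest.approx(reliability(trials), abs=1e-9)


class TestSnr:
    def test_zero_noise_is_infinite(self):
        resp = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        assert math.isinf(snr(resp))

    def test_all_zero_is_undefined(self):
        assert math.isnan(snr(np.zeros((2, 3))))

    def test_hand_crafted_example(self):
        # per-stimulus: means 1 and 3, unbiased variances 2 and 2, V = 1
        resp = np.array([[0.0, 2.0], [2.0, 4.0]])
        assert snr(resp) == pytest.approx(4.0, abs=1e-12)

    def test_not_shift_invariant(self):
        rng = np.random.default_rng(3)
        resp = rng.normal(1.0, 0.5, size=(4, 6))
        assert snr(resp + 5.0) != pytest.approx(snr(resp), abs=1e-6)

    def test_pure_noise_mean_near_zero(self):
        # reduced Monte-Carlo; the full 10^4-neuron check runs in the
        # acceptance suite
        rng = np.random.default_rng(11)
        values = [snr(rng.normal(0.0, 1.0, size=(32, 20))) for _ in range(500)]
        values = np.asarray(values)
        sem = values.std(ddof=1) / math.sqrt(values.size)
        assert abs(values.mean()) < 3.0 * sem


class TestOrthogonalAndOpposite:
    def test_eight_direction_grid(self):
        stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 2})
        orth, opp = orthogonal_and_opposite(stim, preferred=0)  # 0 deg
        dirs = {c.condition_id: c.direction_deg for c in stim.conditions}
        assert dirs[opp] == 180.0
        assert sorted(dirs[c] for c in orth) == [90.0, 270.0]

    def test_stringer_grid_opposite(self):
        stim = make_stimulus_set("stringer-dg")
        pref = next(
            c.condition_id for c in stim.conditions if c.direction_deg == 11.25
        )
        _, opp = orthogonal_and_opposite(stim, pref)
        assert (
            next(c.direction_deg for c in stim.conditions if c.condition_id == opp)
            == 191.25
        )

    def test_four_direction_grid_orthogonal_pair(self):
        stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 2})
        pref = next(c.condition_id for c in stim.conditions if c.direction_deg == 90.0)
        orth, _ = orthogonal_and_opposite(stim, pref)
        dirs = {c.condition_id: c.direction_deg for c in stim.conditions}
        assert sorted(dirs[c] for c in orth) == [0.0, 180.0]

    def test_temporal_frequency_held_fixed(self):
        stim = make_stimulus_set("allen-dg")
        pref = stim.find_grating(45.0, 8.0)
        orth, opp = orthogonal_and_opposite(stim, pref)
        conds = {c.condition_id: c for c in stim.conditions}
        assert conds[opp].temporal_frequency_hz == 8.0
        assert all(conds[c].temporal_frequency_hz == 8.0 for c in orth)


class TestNeuronProperties:
    def test_noiseless_direction_tuned_dsi_closed_form(self):
        """With zero noise, pure direction tuning, zero baseline and preferred
        directions snapped onto the grid, DSI follows the closed form
        (1 - e^{-2k}) / (1 + e^{-2k}) from the tuning curve at the preferred
        and opposite directions."""
        kappa = 1.5
        stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 2})
        profile = LayerProfile(
            n_neurons=25,
            layer_label="L4",
            noise_sd=0.0,
            direction_mix=1.0,
            baseline=0.0,
            tuning_kappa=kappa,
        )
        t = generate_population([profile], stim, seed=3, snap_preferred=True)
        props = neuron_properties(t)
        expected = (1.0 - math.exp(-2.0 * kappa)) / (1.0 + math.exp(-2.0 * kappa))
        assert np.allclose(props["dsi"], expected, atol=1e-9)

    def test_reliability_one_for_noiseless_traces(self):
        stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 3})
        profile = LayerProfile(
            n_neurons=5, layer_label="L4", noise_sd=0.0, baseline=0.1
        )
        rec = generate_population(
            [profile], stim, seed=9, emit_traces=True, trace_noise_sd=0.0
        )
        t = trial_average(rec)
        props = neuron_properties(t, traces=rec)
        assert np.allclose(props["reliability"], 1.0, atol=1e-9)

    def test_image_task_has_no_selectivity_indices(self):
        stim = make_stimulus_set("custom", {"n_images": 6, "n_repeats": 4})
        profile = LayerProfile(n_neurons=4, layer_label="L2/3")
        t = generate_population([profile], stim, seed=2)
        props = neuron_properties(t)
        assert props["osi"].isna().all()
        assert props["dsi"].isna().all()
        assert np.isfinite(props["snr"]).all()
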