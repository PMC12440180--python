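"""Generator contracts: determinism, noiseless construction, calibration."""

import numpy as np
import pandas as pd
import pytest

from glomlearn.behavior import session_accuracy
from glomlearn.errors import ParameterError
from glomlearn.synthetic import (
    SyntheticSessionSpec,
    generate_behavior_session,
    generate_density_sections,
    generate_point_maps,
    generate_trial_traces,
    planted_zone_bias,
    pseudorandom_odor_sequence,
    zone_expectations_for_bias,
)

from conftest import make_session


class TestTrialTraces:
    def test_zero_response_traces_constant_at_f0(self):
        ts, _ = make_session(noise_sd=0.0)
        assert np.all(ts.traces == 100.0)

    def test_noiseless_response_peaks_at_planted_amplitude_after_latency(self):
        amps = np.array([[0.5, 0.0]])
        lats = np.array([[3, 0]])
        ts, _ = make_session(n_rois=1, amplitudes=amps, latencies=lats)
        cs_rows = ts.trials_of("CS+")
        trace = ts.traces[cs_rows[0], 0]
        onset = ts.stim_on_frame + 3
        assert trace.max() == pytest.approx(1.5 * 100.0)
        assert np.all(trace[:onset] == 100.0)
        assert trace[onset] == pytest.approx(150.0)

    def test_fixed_seed_reproduces_traces_exactly(self):
        a, _ = make_session(noise_sd=0.05, seed=42)
        b, _ = make_session(noise_sd=0.05, seed=42)
        assert np.array_equal(a.traces, b.traces)
        assert a.trial_table.equals(b.trial_table)

    def test_noise_calibration_matches_noise_sd(self):
        # >= 10,000 pooled baseline frames at amplitude 0
        ts, _ = make_session(
            n_rois=25, n_trials_per_odor=11, noise_sd=0.05, seed=3
        )
        baseline = ts.traces[:, :, : ts.stim_on_frame] / 100.0 - 1.0
        assert baseline.size >= 10_000
        assert baseline.std(ddof=1) == pytest.approx(0.05, rel=0.05)

    def test_odor_sequence_balanced_with_bounded_runs(self):
        rng = np.random.default_rng(5)
        seq = pseudorandom_odor_sequence(35, rng, max_run=3)
        assert seq.count("CS+") == seq.count("CS-") == 35
        run = longest = 1
        for p, c in zip(seq, seq[1:]):
            run = run + 1 if c == p else 1
            longest = max(longest, run)
        assert longest <= 3

    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_rois", 0),
            ("sampling_rate_hz", 11.0),
            ("baseline_s", 0.0),
            ("noise_sd", -0.1),
        ],
    )
    def test_invalid_spec_raises_parameter_error_naming_field(self, field, value):
        with pytest.raises(ParameterError):
            SyntheticSessionSpec(**{field: value})

    def test_latency_outside_stimulus_window_rejected(self):
        with pytest.raises(ParameterError, match="latency"):
            SyntheticSessionSpec(
                n_rois=1, latency_map=np.array([[25, 0]])
            )


class TestPointMaps:
    def test_full_coloc_zero_offset_duplicates_gene1(self):
        pm, truth = generate_point_maps(
            50, grid=(100.0, 100.0), planted_coloc=1.0, radius=0.0, rng_seed=2
        )
        g1 = pm.coords("Gene1")
        g2 = pm.coords("Gene2")
        # each Gene2 pixel coincides with some Gene1 pixel
        from scipy.spatial import cKDTree

        d, _ = cKDTree(g1).query(g2)
        assert np.all(d == 0)
        assert truth.true_coloc_fraction[("Gene1", "Gene2")] == 1.0

    def test_no_planted_coloc_matches_uniform_background(self):
        # brute-force pairwise count on the generated set vs the uniform
        # expectation n1*n2*pi*r^2/area
        pm, _ = generate_point_maps(
            300, grid=(1000.0, 1000.0), planted_coloc=0.0, radius=5.0, rng_seed=7
        )
        g1, g2 = pm.coords("Gene1"), pm.coords("Gene2")
        from scipy.spatial.distance import cdist

        raw = int((cdist(g1, g2) <= 5.0).sum())
        expected = len(g1) * len(g2) * np.pi * 25.0 / 1e6
        assert raw == pytest.approx(expected, abs=4 * np.sqrt(expected) + 1)

    def test_fixed_seed_reproduces_points(self):
        a, _ = generate_point_maps(40, (64.0, 64.0), 0.5, rng_seed=9)
        b, _ = generate_point_maps(40, (64.0, 64.0), 0.5, rng_seed=9)
        assert a.points.equals(b.points)

    def test_bad_proportion_and_grid_rejected(self):
        with pytest.raises(ParameterError):
            generate_point_maps(10, (64.0, 64.0), 1.5)
        from glomlearn.errors import GeometryError

        with pytest.raises(GeometryError):
            generate_point_maps(10, (0.0, 64.0), 0.5)


class TestDensitySections:
    def test_equal_expectations_give_zero_true_bias(self):
        _, truth = generate_density_sections(
            3, ("CS+", "CS-"), (20.0, 20.0), rng_seed=1
        )
        assert truth.true_zone_bias == 0.0

    def test_two_zone_bias_matches_direct_arithmetic(self):
        # (30 CS+, 10 CS-): diff 20, sd ddof=1 of {30, 10} = sqrt(200)
        _, truth = generate_density_sections(
            3, ("CS+", "CS-"), (30.0, 10.0), rng_seed=1
        )
        assert truth.true_zone_bias == pytest.approx(20.0 / np.sqrt(200.0), abs=1e-12)

    def test_fixed_seed_reproduces_counts(self):
        a, _ = generate_density_sections(5, ("CS+", "CS-"), (30.0, 10.0), rng_seed=4)
        b, _ = generate_density_sections(5, ("CS+", "CS-"), (30.0, 10.0), rng_seed=4)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.zone_counts, pb.zone_counts)

    def test_missing_zone_tag_rejected(self):
        with pytest.raises(ParameterError):
            generate_density_sections(3, ("CS+", "neutral"), (10.0, 10.0))

    def test_poisson_zone_means_match_expectations(self):
        means = np.array([60.0, 40.0, 40.0, 30.0])
        profiles, _ = generate_density_sections(
            200, ("CS+", "neutral", "neutral", "CS-"), means, rng_seed=6
        )
        counts = np.vstack([p.zone_counts for p in profiles])
        se = np.sqrt(means / 200)
        assert np.all(np.abs(counts.mean(axis=0) - means) < 3 * se)

    def test_bias_solver_hits_requested_targets(self):
        for b in (-1.0, 0.0, 1.5):
            v, tags = zone_expectations_for_bias(b)
            assert planted_zone_bias(v, tags) == pytest.approx(b, abs=1e-9)
            assert np.all(v >= 0)


class TestBehaviorSession:
    def test_perfect_discrimination_gives_accuracy_one(self):
        table = generate_behavior_session(40, 1.0, 0.0, rng_seed=1)
        assert session_accuracy(table) == 1.0

    def test_lick_everything_gives_zero_cr_rate(self):
        table = generate_behavior_session(40, 1.0, 1.0, rng_seed=1)
        cs_minus = table[table["odor"] == "CS-"]
        assert (cs_minus["outcome"] == "correct_rejection").sum() == 0
        assert session_accuracy(table) == 0.5

    def test_chance_behavior_near_half_accuracy(self):
        accs = [
            session_accuracy(generate_behavior_session(400, 0.5, 0.5, rng_seed=s))
            for s in range(10)
        ]
        # binomial SE per session ~ 0.025; the mean of 10 is much tighter
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_zero_trials_rejected(self):
        with pytest.raises(ParameterError):
            generate_behavior_session(0, 0.5, 0.5)
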