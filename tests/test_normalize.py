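"""Replicate combination, standardization and difference-track algebra."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chiptile as ct
from chiptile.normalize import (
    ReplicateSet,
    align_to_union,
    combine_replicates,
    subtract_tracks,
    zscore,
)
from chiptile.tracks_io import GridMismatchError, ValidationError


def track(values, experiment_id="t"):
    values = np.asarray(values, dtype=float)
    s = np.arange(values.size, dtype=np.int64) * 100
    return ct.ProbeTrack(experiment_id, {"chr1": (s, s + 60, values)})


def vals(t):
    return t.arrays("chr1")[2]


class TestCombineReplicates:
    def test_identical_replicates_are_a_fixed_point(self):
        t = track([0.5, -1.0, 2.0, np.nan])
        out = combine_replicates(
            ReplicateSet.from_tracks("e", [t, track(vals(t))]), center=False
        )
        np.testing.assert_array_equal(vals(out), vals(t))

    def test_zero_weight_replicate_is_ignored(self):
        a, b = track([1.0, 2.0, 3.0]), track([9.0, 9.0, 9.0])
        out = combine_replicates(
            ReplicateSet.from_tracks("e", [a, b], weights=[1.0, 0.0]),
            center=False,
        )
        np.testing.assert_array_equal(vals(out), vals(a))

    def test_equal_weights_give_arithmetic_mean(self):
        out = combine_replicates(
            ReplicateSet.from_tracks(
                "e", [track([1.0, 1.0, 5.0]), track([3.0, 3.0, 5.0])],
                weights=[1.0, 1.0],
            ),
            center=False,
        )
        np.testing.assert_array_equal(vals(out), [2.0, 2.0, 5.0])

    def test_probe_missing_only_when_missing_everywhere(self):
        a = track([1.0, np.nan, np.nan])
        b = track([np.nan, 2.0, np.nan])
        out = combine_replicates(
            ReplicateSet.from_tracks("e", [a, b]), center=False
        )
        v = vals(out)
        assert v[0] == 1.0 and v[1] == 2.0 and np.isnan(v[2])

    def test_grid_mismatch_rejected(self):
        a = track([1.0, 2.0])
        b = ct.ProbeTrack("b", {"chr1": (np.array([5, 105]),
                                         np.array([65, 165]),
                                         np.array([1.0, 2.0]))})
        with pytest.raises(GridMismatchError):
            ReplicateSet.from_tracks("e", [a, b])

    def test_inverse_variance_downweights_noisy_replicate(self, rng):
        truth = rng.normal(0, 1, 500)
        clean = track(truth + rng.normal(0, 0.1, 500))
        noisy = track(truth + rng.normal(0, 1.0, 500))
        out = combine_replicates(
            ReplicateSet.from_tracks("e", [clean, noisy]), center=False
        )
        mse_comb = np.mean((vals(out) - truth) ** 2)
        mse_equal = np.mean(((vals(clean) + vals(noisy)) / 2 - truth) ** 2)
        assert mse_comb < mse_equal

    def test_noise_reduction_beats_best_single_replicate(self):
        # expectation over 20 simulated studies, unit efficiencies
        ratios = []
        for seed in range(20):
            cfg = ct.SimulationConfig(
                noise_sd=0.3, missing_fraction=0.0, efficiencies=(1.0, 1.0),
                seed=seed,
            )
            model = ct.generate_genome(cfg, 60, seed=seed)
            probes = ct.generate_probes(model, cfg)
            arch = ct.DEFAULT_FACTOR_ARCHETYPES["rpd3"]
            tracks, _ = ct.simulate_experiment(model, probes, cfg, arch)
            from chiptile.synthetic import true_signal
            truth = np.concatenate(
                [true_signal(model, probes, arch)[c]
                 for c in sorted(probes.probes)]
            )
            combined = combine_replicates(
                ReplicateSet.from_tracks("e", tracks), center=False
            )
            mse = lambda t: float(np.mean((t.all_values() - truth) ** 2))
            ratios.append(mse(combined) / min(mse(t) for t in tracks))
        assert np.mean(ratios) <= 1.0


class TestAlignToUnion:
    def test_fills_absent_probes_with_nan(self, tmp_path):
        t = track([1.0, np.nan, 3.0])
        path = tmp_path / "t.bedGraph"
        ct.write_track(t, path)  # drops the NaN probe
        back = ct.read_track(path)
        aligned_back, aligned_full = align_to_union([back, t])
        assert aligned_back.same_grid(aligned_full)
        assert np.isnan(aligned_back.arrays("chr1")[2][1])

    def test_conflicting_overlap_rejected(self):
        a = track([1.0])
        b = ct.ProbeTrack("b", {"chr1": (np.array([30]), np.array([90]),
                                         np.array([1.0]))})
        with pytest.raises(GridMismatchError):
            align_to_union([a, b])


class TestZscore:
    def test_closed_form_three_values(self):
        z = vals(zscore(track([1.0, 2.0, 3.0])))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z, expected, atol=1e-12)
        assert z[0] == pytest.approx(-1.224744871391589)

    def test_mean_zero_sd_one_and_missing_preserved(self, rng):
        v = rng.normal(2.0, 5.0, 400)
        v[::17] = np.nan
        z = vals(zscore(track(v)))
        finite = z[~np.isnan(z)]
        assert abs(finite.mean()) < 1e-9
        assert abs(finite.std() - 1.0) < 1e-9
        assert np.array_equal(np.isnan(z), np.isnan(v))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, -1.2, 4.0, 2.2, -0.7])
        np.testing.assert_allclose(
            vals(zscore(track(a * x + b))), vals(zscore(track(x))), atol=1e-9
        )

    def test_rank_preservation(self, rng):
        v = rng.normal(0, 1, 200)
        z = vals(zscore(track(v)))
        np.testing.assert_array_equal(np.argsort(v), np.argsort(z))

    def test_constant_or_empty_track_rejected(self):
        with pytest.raises(ValidationError, match="constant or empty"):
            zscore(track([3.0, 3.0, 3.0]))
        with pytest.raises(ValidationError):
            zscore(track([np.nan, np.nan]))

    def test_robust_variant_is_affine_invariant_too(self):
        x = np.array([0.3, -1.2, 4.0, 2.2, -0.7, 0.0])
        np.testing.assert_allclose(
            vals(zscore(track(3 * x + 1), robust=True)),
            vals(zscore(track(x), robust=True)),
            atol=1e-9,
        )


class TestSubtractTracks:
    def test_self_difference_is_zero(self):
        t = track([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(vals(subtract_tracks(t, t)), 0.0)

    def test_missing_propagates(self):
        a, b = track([1.0, 2.0]), track([0.5, np.nan])
        v = vals(subtract_tracks(a, b))
        assert v[0] == 0.5 and np.isnan(v[1])

    def test_differences_telescope(self, rng):
        a, b, c = (track(rng.normal(0, 1, 50)) for _ in range(3))
        lhs = vals(subtract_tracks(a, b)) + vals(subtract_tracks(b, c))
        np.testing.assert_allclose(lhs, vals(subtract_tracks(a, c)), atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = track([1.0, 2.0])
        b = ct.ProbeTrack("b", {"chr2": (np.array([0, 100]),
                                         np.array([60, 160]),
                                         np.array([1.0, 2.0]))})
        with pytest.raises(GridMismatchError):
            subtract_tracks(a, b)


def test_efficiency_rescaling_invariance_through_full_normalization():
    """z(combine(reps)) is unchanged when a replicate is rescaled (zero noise)."""
    cfg = ct.SimulationConfig(noise_sd=0.0, missing_fraction=0.0,
                              efficiencies=(1.0, 1.0), seed=4)
    model = ct.generate_genome(cfg, 50, seed=4)
    probes = ct.generate_probes(model, cfg)
    arch = ct.DEFAULT_FACTOR_ARCHETYPES["rpd3"]
    (r1, r2), _ = ct.simulate_experiment(model, probes, cfg, arch)
    scaled = r2.with_values(
        {c: 3.5 * r2.arrays(c)[2] for c in r2.chromosomes}
    )
    z_ref = zscore(combine_replicates(ReplicateSet.from_tracks("e", [r1, r2])))
    z_scaled = zscore(
        combine_replicates(ReplicateSet.from_tracks("e", [r1, scaled]))
    )
    for chrom in z_ref.chromosomes:
        np.testing.assert_allclose(
            z_ref.arrays(chrom)[2], z_scaled.arrays(chrom)[2], atol=1e-9
        )
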