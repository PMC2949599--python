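"""Synthetic scenario generators: combs, trains, jitter, contamination."""

import json

import numpy as np
import pytest

from solscm import (
    ScenarioSpec,
    SiteSequence,
    add_jitter,
    contaminate,
    dirac_comb,
    mixture,
    motif_train,
    random_motif_offsets,
)
from solscm.synthgen import add_jitter_labeled


class TestDiracComb:
    def test_counts_by_floor_arithmetic(self):
        assert dirac_comb(10000, 80000).n == 8
        assert dirac_comb(10000, 200000).n == 20

    def test_period_equal_length_single_site(self):
        comb = dirac_comb(500, 500)
        np.testing.assert_array_equal(comb.positions, [0])

    def test_differences_are_multiples_of_spacing(self):
        comb = dirac_comb(700, 10000)
        diffs = np.diff(comb.positions)
        assert (diffs % 700 == 0).all()


class TestMotifTrain:
    def test_single_zero_offset_is_comb(self):
        train = motif_train([0], 1000, 8)
        comb = dirac_comb(1000, 8000)
        np.testing.assert_array_equal(train.positions, comb.positions)

    def test_five_offsets_eight_repeats(self):
        train = motif_train([11, 503, 1207, 4099, 9901], 10000, 8)
        assert train.n == 40
        assert train.length == 80000

    def test_translated_offsets_same_score_at_period(self):
        from solscm import scs_score

        offs = np.array([100, 900, 2500, 4700, 8300])
        a = motif_train(offs, 10000, 8)
        b = motif_train((offs + 3333) % 10000, 10000, 8)
        assert scs_score(b, 10000) == pytest.approx(scs_score(a, 10000), rel=1e-12)

    def test_offsets_outside_period_rejected(self):
        with pytest.raises(ValueError, match="offsets"):
            motif_train([0, 10000], 10000, 2)


class TestRandomMotifOffsets:
    def test_all_internal_spacings_distinct(self):
        rng = np.random.default_rng(1)
        offs = random_motif_offsets(5, 10000, rng)
        diffs = np.abs(offs[:, None] - offs[None, :])[np.triu_indices(5, k=1)]
        circ = np.concatenate([diffs, 10000 - diffs])
        assert np.unique(circ).size == circ.size

    def test_deterministic_under_seed(self):
        a = random_motif_offsets(5, 10000, np.random.default_rng(3))
        b = random_motif_offsets(5, 10000, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestJitter:
    def test_zero_amplitude_identity(self, motif_train_sites):
        sites, _ = motif_train_sites
        out = add_jitter(sites, 0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, sites.positions)

    def test_deterministic_under_seed(self, motif_train_sites):
        sites, _ = motif_train_sites
        a = add_jitter(sites, 1000, np.random.default_rng(9))
        b = add_jitter(sites, 1000, np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_displacements_bounded_by_half_amplitude(self, motif_train_sites):
        sites, _ = motif_train_sites
        out = add_jitter(sites, 1000, np.random.default_rng(10))
        assert out.n == sites.n
        assert np.abs(np.sort(out.positions) - sites.positions).max() <= 500 + 1

    def test_half_width_mode_doubles_range(self, motif_train_sites):
        sites, _ = motif_train_sites
        spreads = []
        for mode in ("full", "half"):
            deltas = []
            for r in range(30):
                out = add_jitter(sites, 400, np.random.default_rng(r), mode=mode)
                if out.n != sites.n:  # rare jitter collision
                    continue
                deltas.append(np.abs(np.sort(out.positions) - sites.positions).max())
            spreads.append(max(deltas))
        assert spreads[0] <= 201
        assert 201 < spreads[1] <= 401


class TestContaminate:
    def test_identity_when_no_changes(self, motif_train_sites):
        sites, _ = motif_train_sites
        out = contaminate(sites, 0, 0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, sites.positions)

    def test_delete_and_replace_keeps_count(self, motif_train_sites):
        sites, _ = motif_train_sites
        out = contaminate(sites, 10, 10, np.random.default_rng(1))
        assert out.n == sites.n
        survivors = np.intersect1d(out.positions, sites.positions)
        assert survivors.size >= sites.n - 10

    def test_cannot_delete_more_than_available(self):
        with pytest.raises(ValueError, match="cannot delete"):
            contaminate(SiteSequence(100, [1, 2, 3]), 4, 0, np.random.default_rng(0))


class TestMixture:
    def test_union_with_labels(self):
        t1 = SiteSequence(1000, [10, 500])
        t2 = SiteSequence(1000, [20, 700])
        mix = mixture(t1, t2)
        np.testing.assert_array_equal(mix.sites.positions, [10, 20, 500, 700])
        np.testing.assert_array_equal(mix.labels, [0, 1, 0, 1])

    def test_overlap_counts_once(self):
        t1 = SiteSequence(1000, [10, 500])
        t2 = SiteSequence(1000, [500, 700])
        mix = mixture(t1, t2)
        assert mix.sites.n == 3
        assert mix.labels[mix.sites.positions == 500][0] == 0

    def test_support_mismatch_rejected(self):
        with pytest.raises(ValueError, match="support"):
            mixture(SiteSequence(1000, [1]), SiteSequence(2000, [1]))

    def test_labeled_jitter_tracks_provenance(self, two_train_mixture):
        mix, _ = two_train_mixture
        out = add_jitter_labeled(mix, 727, np.random.default_rng(5))
        assert out.labels.size == out.sites.n
        # label counts are preserved up to rare collisions
        assert abs(np.sum(out.labels == 0) - np.sum(mix.labels == 0)) <= 1


class TestScenarioSpec:
    def test_json_sidecar_round_trip(self):
        spec = ScenarioSpec(
            kind="motif_train",
            periods=(10000.0,),
            offsets=((11, 503, 1207),),
            repeats=(8,),
            length=80000,
            jitter_amplitude=1000.0,
            seed=42,
        )
        loaded = json.loads(spec.to_json())
        assert loaded["kind"] == "motif_train"
        assert loaded["offsets"] == [[11, 503, 1207]]
        assert loaded["seed"] == 42

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(kind="comb", periods=(-1.0,))
        with pytest.raises(ValueError):
            ScenarioSpec(kind="comb", periods=(100.0,), jitter_amplitude=100.0)
        with pytest.raises(ValueError):
            ScenarioSpec(kind="comb", periods=(100.0,), n_delete=-1)
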