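"""Residue-based validity fusion: algebra, invariants and the decision chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from emgforce.fusion import (
    ModelLibrary,
    SubModelEntry,
    compute_residues,
    compute_validities,
    estimate,
    fuse_outputs,
    fusion_weights,
    normalize_residues,
    run_submodels,
)
from emgforce.hw import HWModel, LinearBlock, StaticNonlinearity, simulate_hw
from emgforce.signals import SignalTrace


def gain_model(g):
    """A static sub-model y = g * u."""
    return HWModel(StaticNonlinearity.identity(),
                   LinearBlock(b=[g], f=[], nk=0),
                   StaticNonlinearity.identity())


def library(*gains, mode="normalised"):
    return ModelLibrary(
        entries=[SubModelEntry(id=i + 1, model=gain_model(g))
                 for i, g in enumerate(gains)],
        fusion_mode=mode,
    )


def residue_arrays(draw):
    shape = draw(st.tuples(st.integers(2, 5), st.integers(1, 2), st.integers(1, 8)))
    return draw(hnp.arrays(np.float64, shape,
                           elements=st.floats(0, 1e3, allow_nan=False)))


residues = st.composite(residue_arrays)()


class TestRunSubmodels:
    def test_single_entry_equals_direct_simulation(self, rng):
        lib = library(2.0)
        u = SignalTrace(rng.standard_normal(50), fs=100.0, kind="normalised")
        out = run_submodels(lib, [u])
        assert out.shape == (1, 1, 50)
        assert np.array_equal(out[0, 0], simulate_hw(lib.entries[0].model, u).samples)

    def test_identical_submodels_identical_outputs(self, rng):
        lib = library(1.5, 1.5, 1.5)
        u = SignalTrace(rng.standard_normal(30), fs=100.0, kind="normalised")
        out = run_submodels(lib, [u, u])
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[1], out[2])


class TestResidues:
    def test_exact_match_gives_zero(self):
        F = np.ones((2, 1, 5))
        err = compute_residues(F, np.ones((1, 5)))
        assert np.array_equal(err, np.zeros_like(F))

    def test_constant_offset(self):
        F = np.ones((2, 1, 5)) + 1.0
        err = compute_residues(F, np.ones((1, 5)))
        assert np.array_equal(err, np.ones_like(F))

    def test_sign_symmetric(self, rng):
        F = rng.standard_normal((3, 2, 10))
        ref = rng.standard_normal((2, 10))
        up = compute_residues(ref[None] + F, ref)
        down = compute_residues(ref[None] - F, ref)
        assert np.allclose(up, down)

    def test_reference_shape_checked(self):
        with pytest.raises(ValueError):
            compute_residues(np.ones((2, 1, 5)), np.ones((2, 5)))


class TestNormaliseResidues:
    @pytest.mark.parametrize("err,expected", [
        ((1.0, 1.0), (0.5, 0.5)),
        ((1.0, 1.0, 2.0), (0.25, 0.25, 0.5)),
        ((0.0, 0.0), (0.5, 0.5)),  # tie rule
    ])
    def test_examples(self, err, expected):
        e = np.asarray(err)[:, None, None]
        out = normalize_residues(e)
        assert np.allclose(out[:, 0, 0], expected)

    def test_single_submodel_rejected(self):
        with pytest.raises(ValueError):
            normalize_residues(np.ones((1, 1, 3)))


class TestValidities:
    def test_example(self):
        mu = compute_validities(np.array([0.25, 0.25, 0.5]))
        assert np.allclose(mu, [0.75, 0.75, 0.5])

    def test_perfect_model_gets_full_validity(self):
        mu = compute_validities(np.array([0.0, 1.0]))
        assert np.array_equal(mu, [1.0, 0.0])


class TestFusionWeights:
    def test_modes_coincide_for_two_submodels(self, rng):
        err = rng.uniform(0, 1, (2, 1, 6))
        mu = compute_validities(normalize_residues(err))
        assert np.allclose(fusion_weights(mu, "unnormalised"),
                           fusion_weights(mu, "normalised"))

    def test_normalised_example(self):
        w = fusion_weights(np.array([0.75, 0.75, 0.5]))
        assert np.allclose(w, [0.375, 0.375, 0.25])

    def test_literal_weights_scale_output_for_three_identical_submodels(self, rng):
        # three identical sub-models each output F*; the literal weights
        # sum to N-1=2, so the literal fusion doubles the output
        lib = library(1.0, 1.0, 1.0)
        u = SignalTrace(rng.uniform(0.5, 1.5, 40), fs=100.0, kind="normalised")
        ref = u
        out_lit = estimate(lib, [u], [ref], mode="unnormalised")
        F_star = u.samples[out_lit.start:]
        assert np.allclose(out_lit.F_m[0].samples, 2.0 * F_star)
        out_norm = estimate(lib, [u], [ref], mode="normalised")
        assert np.allclose(out_norm.F_m[0].samples, F_star)

    def test_switching_selects_most_valid(self):
        mu = np.array([[0.2], [0.9], [0.4]])
        w = fusion_weights(mu, "switching")
        assert np.array_equal(w[:, 0], [0.0, 1.0, 0.0])


class TestFuseOutputs:
    def test_winner_take_all(self, rng):
        F = rng.standard_normal((3, 2, 7))
        w = np.zeros_like(F)
        w[0] = 1.0
        assert np.array_equal(fuse_outputs(F, w), F[0])

    def test_weighted_sum_example(self):
        F = np.array([10.0, 20.0, 30.0])[:, None, None]
        w = np.array([0.375, 0.375, 0.25])[:, None, None]
        assert fuse_outputs(F, w)[0, 0] == pytest.approx(18.75)


class TestEstimate:
    def test_perfect_submodel_reproduced_bit_exactly(self, rng):
        lib = library(1.0, 3.0)
        u = SignalTrace(rng.uniform(0.1, 1.0, 60), fs=100.0, kind="normalised")
        out = estimate(lib, [u], [u])  # sub-model 1 matches the reference
        assert np.array_equal(out.F_m[0].samples, u.samples[out.start:])
        assert np.all(out.validity.w[0, 0] == 1.0)

    def test_exact_generator_beats_distractors(self, rng):
        from emgforce.evaluation import r_squared

        truth = gain_model(1.0)
        lib = library(1.0, 1.7, 0.4)
        u = SignalTrace(rng.uniform(0.1, 1.0, 300), fs=100.0, kind="normalised")
        ref = SignalTrace(simulate_hw(truth, u.samples)
                          + 0.01 * rng.standard_normal(300),
                          fs=100.0, kind="normalised")
        out = estimate(lib, [u], [ref])
        rs = ref.samples[out.start:]
        fused_r2 = r_squared(rs, out.F_m[0].samples)
        for i in (1, 2):  # the distractor entries
            assert fused_r2 >= r_squared(rs, out.F_ij[i, 0])

    def test_single_channel_reduces_cleanly(self, rng):
        lib = library(1.0, 2.0)
        u = SignalTrace(rng.uniform(0.1, 1.0, 40), fs=100.0, kind="normalised")
        out = estimate(lib, [u], [u])
        assert len(out.F_m) == 1
        assert out.validity.w.shape[1] == 1

    def test_reference_count_checked(self, rng):
        lib = library(1.0, 2.0)
        u = SignalTrace(rng.uniform(0.1, 1.0, 40), fs=100.0, kind="normalised")
        with pytest.raises(ValueError):
            estimate(lib, [u, u], [u])


class TestAlgebraicInvariants:
    @settings(max_examples=200, deadline=None)
    @given(residues)
    def test_residue_validity_algebra(self, err):
        N = err.shape[0]
        err_norm = normalize_residues(err)
        mu = compute_validities(err_norm)
        total = err.sum(axis=0)
        active = total > 1e-12
        assert np.allclose(err_norm.sum(axis=0)[active], 1.0)
        assert np.all((mu >= 0) & (mu <= 1 + 1e-12))
        assert np.allclose(mu.sum(axis=0), N - 1)
        # most pertinent sub-model: smallest residue <-> largest validity
        # (compare values, not argmax indices, to be robust to ties)
        amin = np.argmin(err, axis=0)
        mu_at_min = np.take_along_axis(mu, amin[None], axis=0)[0]
        assert np.allclose(mu_at_min[active], mu.max(axis=0)[active])

    @settings(max_examples=100, deadline=None)
    @given(residues)
    def test_normalised_fusion_is_convex(self, err):
        rng = np.random.default_rng(0)
        F = rng.standard_normal(err.shape)
        w = fusion_weights(compute_validities(normalize_residues(err)))
        fused = fuse_outputs(F, w)
        assert np.all(fused <= F.max(axis=0) + 1e-9)
        assert np.all(fused >= F.min(axis=0) - 1e-9)

    @settings(max_examples=100, deadline=None)
    @given(residues, st.floats(0.01, 0.99))
    def test_monotone_pertinence(self, err, shrink):
        # decreasing one sub-model's residue never decreases its weight
        w_before = fusion_weights(compute_validities(normalize_residues(err)))
        err2 = err.copy()
        err2[0] = err2[0] * shrink
        w_after = fusion_weights(compute_validities(normalize_residues(err2)))
        assert np.all(w_after[0] >= w_before[0] - 1e-12)

    @settings(max_examples=100, deadline=None)
    @given(residues)
    def test_permutation_equivariance(self, err):
        rng = np.random.default_rng(1)
        perm = rng.permutation(err.shape[0])
        w = fusion_weights(compute_validities(normalize_residues(err)))
        w_perm = fusion_weights(compute_validities(normalize_residues(err[perm])))
        assert np.allclose(w_perm, w[perm])


class TestLibrarySerialisation:
    def test_round_trip(self, rng, tmp_path):
        lib = library(1.0, 2.0, mode="switching")
        lib.save(tmp_path / "lib.json")
        lib2 = ModelLibrary.load(tmp_path / "lib.json")
        assert lib2.N == 2
        assert lib2.fusion_mode == "switching"
        u = rng.standard_normal(30)
        for e1, e2 in zip(lib.entries, lib2.entries):
            assert np.array_equal(simulate_hw(e1.model, u), simulate_hw(e2.model, u))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            ModelLibrary(entries=[SubModelEntry(id=1, model=gain_model(1.0)),
                                  SubModelEntry(id=1, model=gain_model(2.0))])
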