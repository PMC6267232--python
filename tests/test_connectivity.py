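import numpy as np
import pytest

from mnc import connectivity
from mnc.connectivity import (
    AdjacencyMatrix,
    average_epochs,
    global_mean,
    pli_matrix,
    pli_pair,
    rsn_mean,
    wrap_phase,
)
from mnc.errors import ValidationError
from mnc.spectral import DEFAULT_BANDS, PhaseEpoch

THETA = DEFAULT_BANDS[0]


def adjacency(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple("ABCD"[: values.shape[0]])
    return AdjacencyMatrix(values=values, band=THETA, roi_labels=labels)


class TestPliPair:
    def test_constant_lag_gives_one(self, rng):
        base = rng.uniform(-np.pi, np.pi, 1000)
        assert pli_pair(base + np.pi / 4, base) == 1.0

    def test_symmetric_lag_gives_zero(self):
        base = np.zeros(1000)
        d = np.where(np.arange(1000) % 2 == 0, np.pi / 4, -np.pi / 4)
        assert pli_pair(base + d, base) == 0.0

    def test_exact_zero_and_pi_differences_contribute_nothing(self):
        base = np.zeros(8)
        d = np.array([0.0, np.pi, 0.0, np.pi, np.pi / 3, np.pi / 3, np.pi / 3, np.pi / 3])
        # only the four pi/3 samples carry sign: |4/8| = 0.5
        assert pli_pair(base + d, base) == 0.5

    def test_self_pli_is_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 512)
        assert pli_pair(ph, ph) == 0.0

    def test_matches_bruteforce_formula(self, rng):
        d = rng.uniform(-np.pi, np.pi, 4096)
        # independent one-line oracle on the raw differences
        expected = abs(np.sign(d).sum()) / d.size
        assert pli_pair(d, np.zeros_like(d)) == pytest.approx(expected, abs=1e-15)

    def test_invariant_under_constant_offset(self, rng):
        a = rng.uniform(-np.pi, np.pi, 2048)
        b = rng.uniform(-np.pi, np.pi, 2048)
        ref = pli_pair(a, b)
        for offset in (0.3, 1.1, 2.5, -0.7):
            assert pli_pair(a + offset, b + offset) == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pli_pair(np.zeros(4), np.zeros(5))

    def test_independent_phases_average_near_zero(self, rng):
        vals = [
            pli_pair(rng.uniform(-np.pi, np.pi, 4096), rng.uniform(-np.pi, np.pi, 4096))
            for _ in range(20)
        ]
        assert np.mean(vals) < 0.03


class TestPliMatrix:
    def test_two_rois_match_pli_pair(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 1024))
        mat = pli_matrix(PhaseEpoch(ph, THETA, 0), edge_trim=False)
        assert mat.values[0, 1] == pytest.approx(pli_pair(ph[0], ph[1]), abs=1e-12)

    def test_contract_on_random_phases(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(5, 512))
        mat = pli_matrix(PhaseEpoch(ph, THETA, 0), edge_trim=False)
        v = mat.values
        assert np.array_equal(v, v.T)
        assert np.all(np.diag(v) == 0)
        assert v.min() >= 0 and v.max() <= 1

    def test_permutation_equivariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(5, 512))
        perm = np.array([3, 1, 4, 0, 2])
        m1 = pli_matrix(PhaseEpoch(ph, THETA, 0), edge_trim=False).values
        m2 = pli_matrix(PhaseEpoch(ph[perm], THETA, 0), edge_trim=False).values
        assert np.allclose(m2, m1[np.ix_(perm, perm)], atol=1e-15)

    def test_kernel_agrees_with_pli_pair_on_all_pairs(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(6, 777))
        mat = pli_matrix(PhaseEpoch(ph, THETA, 0), edge_trim=False).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(pli_pair(ph[i], ph[j]), abs=1e-12)

    def test_edge_trim_drops_one_sixteenth_each_side(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 1600))
        trimmed = pli_matrix(PhaseEpoch(ph, THETA, 0), edge_trim=True).values[0, 1]
        manual = pli_pair(ph[0, 100:1500], ph[1, 100:1500])
        assert trimmed == pytest.approx(manual, abs=1e-12)


class TestWrapPhase:
    def test_range_is_half_open_at_minus_pi(self):
        assert wrap_phase(np.pi) == np.pi
        assert wrap_phase(-np.pi) == np.pi  # image of +pi
        assert wrap_phase(3 * np.pi) == pytest.approx(np.pi)
        assert wrap_phase(0.0) == 0.0

    def test_modulo_2pi_safe(self, rng):
        d = rng.uniform(-40, 40, 1000)
        w = wrap_phase(d)
        assert np.all((w > -np.pi) & (w <= np.pi))
        assert np.allclose(np.sin(w), np.sin(d), atol=1e-9)


class TestAverageAndSummaries:
    def test_average_single_is_identity(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(3, 256))
        m = pli_matrix(PhaseEpoch(ph, THETA, 0))
        avg = average_epochs([m])
        assert np.array_equal(avg.values, m.values)
        assert avg.level == "epoch-averaged"

    def test_average_is_entrywise_mean(self):
        a = adjacency([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]], ("A", "B", "C"))
        b = adjacency([[0, 0.4, 0.4], [0.4, 0, 0.4], [0.4, 0.4, 0]], ("A", "B", "C"))
        avg = average_epochs([a, b])
        assert np.allclose(avg.values[0, 1], 0.3)

    def test_average_idempotent_on_identical(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(3, 256))
        m = pli_matrix(PhaseEpoch(ph, THETA, 0))
        avg = average_epochs([m] * 4)
        assert np.allclose(avg.values, m.values, atol=1e-15)

    def test_label_mismatch_rejected(self):
        a = adjacency(np.zeros((3, 3)), ("A", "B", "C"))
        b = adjacency(np.zeros((3, 3)), ("A", "B", "X"))
        with pytest.raises(ValidationError):
            average_epochs([a, b])

    def test_rsn_mean_hand_example(self, toy_atlas):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.1  # AB
        v[0, 2] = v[2, 0] = 0.2  # AC
        v[1, 2] = v[2, 1] = 0.3  # BC
        adj = adjacency(v, toy_atlas.roi_labels)
        assert rsn_mean(adj, toy_atlas, "DMN") == pytest.approx(0.2)

    def test_constant_matrix_gives_constant(self, toy_atlas):
        v = np.full((4, 4), 0.42)
        np.fill_diagonal(v, 0.0)
        adj = adjacency(v, toy_atlas.roi_labels)
        for rsn in ("DMN", "FPN_left", "FPN_right"):
            assert rsn_mean(adj, toy_atlas, rsn) == pytest.approx(0.42)
        assert global_mean(adj) == pytest.approx(0.42)

    def test_full_membership_rsn_equals_global_mean(self, rng):
        from mnc.io import AtlasDefinition

        labels = ("A", "B", "C", "D")
        atlas = AtlasDefinition(labels, {"ALL": labels})
        ph = rng.uniform(-np.pi, np.pi, size=(4, 512))
        adj = pli_matrix(PhaseEpoch(ph, THETA, 0), roi_labels=labels)
        assert rsn_mean(adj, atlas, "ALL") == pytest.approx(global_mean(adj), abs=1e-15)

    def test_global_mean_hand_example(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.1
        v[0, 2] = v[2, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.6
        assert global_mean(adjacency(v, ("A", "B", "C"))) == pytest.approx(0.3)

    def test_singleton_rsn_rejected(self, rng):
        from mnc.io import AtlasDefinition

        labels = ("A", "B", "C")
        atlas = AtlasDefinition(labels, {"ONE": ("A",)})
        ph = rng.uniform(-np.pi, np.pi, size=(3, 128))
        adj = pli_matrix(PhaseEpoch(ph, THETA, 0), roi_labels=labels)
        with pytest.raises(ValidationError):
            rsn_mean(adj, atlas, "ONE")


class TestAdjacencyInvariants:
    def test_asymmetric_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = 0.5
        with pytest.raises(ValidationError):
            adjacency(v, ("A", "B", "C"))

    def test_out_of_range_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 1.5
        with pytest.raises(ValidationError):
            adjacency(v, ("A", "B", "C"))


class TestPliProperties:
    """Invariance properties of the PLI, property-based."""

    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        offset=st.floats(-6.0, 6.0, allow_nan=False).filter(
            lambda v: abs(v) > 1e-6
        ),
    )
    def test_invariant_under_channel_phase_offset(self, seed, offset):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 512)
        b = r.uniform(-np.pi, np.pi, 512)
        # offsets keep differences away from exact 0/pi degeneracy a.s.
        assert pli_pair(a + offset, b + offset) == pytest.approx(
            pli_pair(a, b), abs=1e-12
        )
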