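"""Weight-matrix construction, (R0, K0) normalization and derived matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpshift.matrices import (
    WeightMatrix,
    build_w2,
    build_wt,
    derive_skip_matrices,
    matrix_stats,
    normalize_to,
    read_matrix_tsv,
    write_matrix_tsv,
)
from tpshift.sequence import (
    PAIR_LABELS,
    CodingSequence,
    DinucCountMatrix,
    build_m16,
    build_mt,
)


def _uniform_p2():
    return np.full(16, 1.0 / 16.0)


class TestBuildW2:
    def test_zero_count_cell_matches_closed_form(self):
        counts = np.zeros((3, 16), dtype=int)
        counts[0, 0] = 99  # all mass on one cell so others are zero
        m2 = DinucCountMatrix(counts)
        p = np.array([0.25, 0.25, 0.25, 0.25])
        w = build_w2(m2, p, N=100)
        p2 = 1.0 / 16.0
        expected = -np.sqrt(99 * p2 / (1 - p2))
        assert w.weights[1, 3] == pytest.approx(expected)

    def test_centred_cell_is_zero(self):
        # a cell holding exactly its expected count gets weight 0
        p = np.array([0.25, 0.25, 0.25, 0.25])
        n_total = 161  # (N-1) * p2 = 160/16 = 10 exactly
        counts = np.zeros((3, 16), dtype=int)
        counts[2, 7] = 10
        w = build_w2(DinucCountMatrix(counts), p, N=n_total)
        assert w.weights[2, 7] == 0.0

    def test_uniform_sequences_stay_within_six_sigma(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            seq = CodingSequence(id="u", codes=rng.integers(1, 5, 600).astype(np.int8))
            w = build_w2(build_m16(seq), seq.base_probabilities(), seq.N)
            hits += bool(np.all(np.abs(w.weights) < 6.0))
        assert hits >= 99

    def test_degenerate_pair_probability_gets_zero_weight(self):
        seq = CodingSequence.from_string("atg" * 30)  # no c anywhere
        with pytest.warns(UserWarning):
            w = build_w2(build_m16(seq), seq.base_probabilities(), seq.N)
        c_rows = [n for n in range(16) if "c" in PAIR_LABELS[n]]
        assert np.all(w.weights[:, c_rows] == 0.0)


class TestMatrixStats:
    def test_zero_matrix(self):
        assert matrix_stats(np.zeros((3, 16)), _uniform_p2()) == (0.0, 0.0)

    def test_all_ones_uniform(self):
        r2, kd = matrix_stats(np.ones((3, 16)), _uniform_p2())
        assert r2 == pytest.approx(48.0)
        assert kd == pytest.approx(1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(3, 16))
        p2 = rng.dirichlet(np.ones(16))
        r2, kd = matrix_stats(w, p2)
        r2c, kdc = matrix_stats(3.0 * w, p2)
        assert r2c == pytest.approx(9.0 * r2)
        assert kdc == pytest.approx(3.0 * kd)


class TestNormalizeTo:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_targets_reached_for_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        w = WeightMatrix(
            weights=rng.normal(scale=rng.uniform(0.1, 10), size=(3, 16)),
            p=np.zeros(4),
            p2=rng.dirichlet(np.ones(16)),
        )
        out = normalize_to(w, 1050.0, -1.8)
        r2, kd = matrix_stats(out.weights, out.p2)
        assert r2 == pytest.approx(1050.0, rel=1e-9)
        assert kd == pytest.approx(-1.8, rel=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        w = WeightMatrix(
            weights=rng.normal(size=(3, 16)), p=np.zeros(4), p2=_uniform_p2()
        )
        once = normalize_to(w, 1050.0, -1.8)
        again = normalize_to(
            WeightMatrix(weights=once.weights, p=np.zeros(4), p2=once.p2), 1050.0, -1.8
        )
        assert np.allclose(once.weights, again.weights, atol=1e-9)

    def test_constant_matrix_rejected(self):
        w = WeightMatrix(weights=np.full((3, 16), 2.0), p=np.zeros(4), p2=_uniform_p2())
        with pytest.raises(ValueError):
            normalize_to(w, 1050.0, -1.8)


class TestDerivedMatrices:
    def _oracle(self, w):
        """Naive nested-loop summation, straight from the definitions."""
        skip1 = np.zeros((3, 16))
        skip2 = np.zeros((3, 16))
        boundary = np.zeros((3, 4))
        for x in range(3):
            for i in range(1, 5):
                for l in range(1, 5):
                    n = i + 4 * (l - 1)
                    s1 = 0.0
                    for j in range(1, 5):
                        s1 += (w[x, i + 4 * (j - 1) - 1] + w[x, j + 4 * (l - 1) - 1]) / 2.0
                    skip1[x, n - 1] = 0.25 * s1
                    s2 = 0.0
                    for j in range(1, 5):
                        for k in range(1, 5):
                            s2 += (w[x, i + 4 * (j - 1) - 1] + w[x, k + 4 * (l - 1) - 1]) / 2.0
                    skip2[x, n - 1] = 0.0625 * s2
            for n in range(1, 5):
                boundary[x, n - 1] = 0.25 * sum(
                    w[x, i + 4 * (n - 1) - 1] for i in range(1, 5)
                )
        return skip1, skip2, boundary

    def test_matches_nested_loop_oracle_on_random_input(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            w = rng.normal(scale=5, size=(3, 16))
            der = derive_skip_matrices(w)
            skip1, skip2, boundary = self._oracle(w)
            assert np.allclose(der.skip1, skip1, atol=1e-12)
            assert np.allclose(der.skip2, skip2, atol=1e-12)
            assert np.allclose(der.boundary, boundary, atol=1e-12)

    def test_distinct_integer_cell(self):
        w = np.arange(48, dtype=float).reshape(3, 16)
        der = derive_skip_matrices(w)
        # pair a-a in column 1: 0.25 * sum_j (w(1, 1+4(j-1)) + w(1, j)) / 2
        expected = 0.25 * sum((w[0, 4 * (j - 1)] + w[0, j - 1]) / 2.0 for j in range(1, 5))
        assert der.skip1[0, 0] == pytest.approx(expected)

    def test_constants_are_preserved(self):
        der = derive_skip_matrices(np.full((3, 16), 3.25))
        assert np.allclose(der.skip1, 3.25)
        assert np.allclose(der.skip2, 3.25)
        assert np.allclose(der.boundary, 3.25)

    def test_boundary_row_sums_match_parent(self):
        rng = np.random.default_rng(23)
        w = rng.normal(size=(3, 16))
        der = derive_skip_matrices(w)
        for x in range(3):
            assert der.boundary[x].sum() * 4 == pytest.approx(w[x].sum())


class TestBuildWT:
    def test_uniform_mt_gives_zero_weights(self):
        from tpshift.sequence import TripletCountMatrix

        wt = build_wt(TripletCountMatrix(np.full((3, 4), 25)))
        assert np.allclose(wt.weights, 0.0)

    def test_periodic_repeat_cell_matches_hand_calculation(self):
        mt = build_mt(CodingSequence.from_string("atcgga" * 25))
        wt = build_wt(mt)
        # cell (1, a): count 25, p = x(1)*y(a)/L^2 = 50*50/150^2 = 1/9
        p = 1.0 / 9.0
        expected = (25 - 150 * p) / np.sqrt(150 * p * (1 - p))
        assert wt.weights[0, 0] == pytest.approx(expected)
        assert (wt.weights > 0).sum() == 6
        assert (wt.weights < 0).sum() == 6

    def test_zero_marginal_rejected(self):
        # {atc}_50 never uses g, so y(g) = 0 and WT is undefined
        mt = build_mt(CodingSequence.from_string("atc" * 50))
        with pytest.raises(ValueError):
            build_wt(mt)


def test_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    w = rng.normal(size=(3, 16))
    path = tmp_path / "m.tsv"
    write_matrix_tsv(path, w, fmt="%.12g")
    back = read_matrix_tsv(path)
    assert np.allclose(back, w, atol=1e-10)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("pair")
    assert [ln.split("\t")[0] for ln in lines[1:5]] == ["aa", "ta", "ca", "ga"]
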