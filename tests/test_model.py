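"""DCSBM generator: propensity draws, rate construction, sequence simulation."""

import numpy as np
import pytest

from netsurv import (
    CommunityStructure,
    InvalidInputError,
    InvalidParameterError,
    ShiftSpec,
    apply_shift,
    build_block_matrix,
    compute_rates,
    draw_degree_propensities,
    generate_sequence,
)


class TestDegreePropensities:
    def test_community_sums_match_sizes(self, rng):
        """Identifiability: theta sums to the community size within each block."""
        structure = CommunityStructure((10, 10))
        theta = draw_degree_propensities(structure, 1.0, 3.0, rng)
        for r, size in enumerate(structure.sizes, start=1):
            assert np.isclose(theta.theta[structure.community_slice(r)].sum(),
                              size, rtol=1e-9)

    def test_uneven_communities_normalised_independently(self, rng):
        structure = CommunityStructure((3, 7, 15))
        theta = draw_degree_propensities(structure, 1.0, 3.0, rng)
        sums = [theta.theta[structure.community_slice(r)].sum() for r in (1, 2, 3)]
        assert np.allclose(sums, [3, 7, 15])
        assert (theta.theta > 0).all()

    def test_equal_raw_draws_give_uniform_theta(self, rng):
        """Normalization forces theta_i = 1 when all raw draws coincide."""
        structure = CommunityStructure((10, 10))
        theta = draw_degree_propensities(structure, 1.0, 3.0, rng)
        # rebuild with the normalization applied to a constant vector
        const = np.full(structure.order, 7.3)
        uniform = np.empty_like(const)
        for r in (1, 2):
            sl = structure.community_slice(r)
            uniform[sl] = const[sl] * structure.sizes[r - 1] / const[sl].sum()
        assert np.allclose(uniform, 1.0)
        # and the Pareto draw preserves the same per-community totals
        assert np.isclose(theta.theta.sum(), structure.order)

    def test_pareto_mean_matches_closed_form(self, rng):
        """Raw Pareto(scale 1, shape 3) draws have mean shape/(shape-1) = 1.5."""
        structure = CommunityStructure((100000,))
        theta = draw_degree_propensities(structure, 1.0, 3.0, rng)
        n = structure.order
        # Var = shape / ((shape-1)^2 (shape-2)) = 0.75 for shape 3, scale 1
        se = np.sqrt(0.75 / n)
        assert abs(theta.raw_theta.mean() - 1.5) < 3 * se

    @pytest.mark.parametrize("scale,shape", [(0, 3), (-1, 3), (1, 0), (1, -2)])
    def test_invalid_pareto_parameters_rejected(self, scale, shape, rng):
        with pytest.raises(InvalidParameterError):
            draw_degree_propensities(CommunityStructure((5,)), scale, shape, rng)

    def test_infinite_mean_shape_warns_but_generates(self, rng):
        with pytest.warns(RuntimeWarning):
            theta = draw_degree_propensities(CommunityStructure((5,)), 1.0, 0.9, rng)
        assert np.isclose(theta.theta.sum(), 5)


class TestBlockMatrix:
    @pytest.mark.parametrize("diag,ratio,R,expected", [
        (0.2, 2, 2, [[0.2, 0.1], [0.1, 0.2]]),
        (1.0, 1, 3, [[1, 1, 1], [1, 1, 1], [1, 1, 1]]),
        (0.5, 2, 4, None),  # checked structurally below
    ])
    def test_construction(self, diag, ratio, R, expected):
        P = build_block_matrix(diag, ratio, R)
        if expected is not None:
            assert np.allclose(P.P, expected)
        assert np.allclose(np.diag(P.P), diag)
        off = P.P[~np.eye(R, dtype=bool)]
        assert np.allclose(off, diag / ratio)

    @pytest.mark.parametrize("diag,ratio", [(0, 2), (-1, 2), (1, 0), (1, -1)])
    def test_invalid_parameters(self, diag, ratio):
        with pytest.raises(InvalidParameterError):
            build_block_matrix(diag, ratio, 2)


class TestShift:
    def test_multiplies_only_target_entry(self):
        P = build_block_matrix(1.0, 2.0, 3)
        shifted = apply_shift(P, ShiftSpec(shift_fraction=0.5, shift_time=840))
        assert shifted.P[0, 0] == pytest.approx(1.5)
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 0] = False
        assert (shifted.P[mask] == P.P[mask]).all()

    def test_zero_shift_is_identity(self):
        P = build_block_matrix(0.7, 2.0, 2)
        shifted = apply_shift(P, ShiftSpec(shift_fraction=0.0, shift_time=840))
        assert (shifted.P == P.P).all()

    def test_fraction_for_fixed_anomalous_propensity(self):
        """Shifting a 0.02 baseline to an anomalous propensity of 1.0 needs
        s = 1.0/0.02 - 1 = 49."""
        P = build_block_matrix(0.02, 2.0, 2)
        s = 1.0 / 0.02 - 1
        shifted = apply_shift(P, ShiftSpec(shift_fraction=s, shift_time=840))
        assert shifted.P[0, 0] == pytest.approx(1.0)

    def test_shift_locality_in_rates(self, rng, two_communities, block_2to1):
        """Rates of pairs not entirely inside the target community are
        unchanged by the shift."""
        theta = draw_degree_propensities(two_communities, rng=rng)
        lam0 = compute_rates(theta, block_2to1, two_communities).lam
        shifted = apply_shift(block_2to1, ShiftSpec(1.5, 840))
        lam1 = compute_rates(theta, shifted, two_communities).lam
        inside = np.zeros(20, dtype=bool)
        inside[:10] = True
        pair_inside = np.outer(inside, inside)
        assert (lam1[~pair_inside] == lam0[~pair_inside]).all()
        changed = pair_inside & ~np.eye(20, dtype=bool)
        assert np.allclose(lam1[changed], 2.5 * lam0[changed])


class TestRates:
    def test_unit_factors_give_unit_rate(self):
        structure = CommunityStructure((2,))
        P = build_block_matrix(1.0, 1.0, 1)
        lam = compute_rates(np.ones(2), P, structure).lam
        assert lam[0, 1] == pytest.approx(1.0)

    def test_total_rate_closed_form(self, two_communities):
        """Uniform theta, P_rr = 1, ratio 2: 90 within-pairs at rate 1 plus
        100 between-pairs at rate 0.5 sum to 140."""
        P = build_block_matrix(1.0, 2.0, 2)
        rates = compute_rates(np.ones(20), P, two_communities)
        assert rates.total_rate == pytest.approx(140.0)

    def test_diagonal_is_zero(self, rng, two_communities, block_2to1):
        theta = draw_degree_propensities(two_communities, rng=rng)
        lam = compute_rates(theta, block_2to1, two_communities).lam
        assert (np.diag(lam) == 0).all()
        assert (lam == lam.T).all()

    def test_uniform_theta_reduces_to_plain_sbm(self, two_communities, block_2to1):
        """With equal theta the rate is constant within each block pair."""
        lam = compute_rates(np.ones(20), block_2to1, two_communities).lam
        within = lam[:10, :10][~np.eye(10, dtype=bool)]
        between = lam[:10, 10:]
        assert np.ptp(within) == 0
        assert np.ptp(between) == 0
        assert within[0] == 2 * between[0, 0]

    def test_dimension_mismatch_rejected(self, two_communities, block_2to1):
        with pytest.raises(InvalidInputError):
            compute_rates(np.ones(7), block_2to1, two_communities)
        with pytest.raises(InvalidInputError):
            compute_rates(np.ones(20), build_block_matrix(1, 2, 3), two_communities)


class TestGenerateSequence:
    def test_zero_rates_give_zero_matrices(self, two_communities, block_2to1, rng):
        seq = generate_sequence(two_communities, np.zeros(20), block_2to1,
                                None, 50, rng)
        assert (seq.data == 0).all()

    def test_structural_invariants(self, two_communities, block_2to1, rng):
        theta = draw_degree_propensities(two_communities, rng=rng)
        seq = generate_sequence(two_communities, theta, block_2to1,
                                ShiftSpec(1.5, 30), 60, rng)
        seq.validate()  # symmetric, integer, non-negative, zero-diagonal
        assert len(seq) == 60 and seq.step_width == 1

    def test_shift_time_is_last_baseline_index(self, two_communities, block_2to1):
        """With tau = 845 the periods 1..845 are baseline draws and 846..860
        anomalous: regenerating with the same seed and no shift leaves the
        first 845 matrices identical and changes only later ones."""
        theta = np.ones(20)
        seed = 77
        shifted = generate_sequence(two_communities, theta, block_2to1,
                                    ShiftSpec(5.0, 845), 860,
                                    np.random.default_rng(seed))
        baseline = generate_sequence(two_communities, theta, block_2to1,
                                     None, 860, np.random.default_rng(seed))
        assert (shifted.data[:845] == baseline.data[:845]).all()
        assert (shifted.data[845:] != baseline.data[845:]).any()
        # the final 20-block covering 841..860 holds 5 baseline matrices
        final_block = slice(840, 860)
        same = [(shifted.data[t] == baseline.data[t]).all()
                for t in range(*final_block.indices(860))]
        assert same[:5] == [True] * 5

    def test_mean_total_count_matches_rate_sum(self, two_communities, block_2to1, rng):
        """Total count per matrix averages the closed-form total rate 140."""
        seq = generate_sequence(two_communities, np.ones(20), block_2to1,
                                None, 2000, rng)
        totals = seq.data.sum(axis=(1, 2)) / 2
        se = np.sqrt(140 / 2000)  # Poisson total, variance = mean
        assert abs(totals.mean() - 140) < 3 * se

    def test_poisson_law_per_cell(self, rng):
        """Per-cell sample mean and variance both estimate lambda."""
        structure = CommunityStructure((3, 3))
        P = build_block_matrix(1.0, 2.0, 2)
        lam = compute_rates(np.ones(6), P, structure).lam
        seq = generate_sequence(structure, np.ones(6), P, None, 3000, rng)
        iu, ju = np.triu_indices(6, k=1)
        n = len(seq)
        cells = seq.data[:, iu, ju]
        lam_cells = lam[iu, ju]
        se_mean = np.sqrt(lam_cells / n)
        assert (np.abs(cells.mean(0) - lam_cells) < 4 * se_mean).all()
        # Var(sample variance) ~ (mu4 - sigma^4)/n with mu4 = lam(1 + 3 lam)
        se_var = np.sqrt((lam_cells + 2 * lam_cells**2) / n)
        assert (np.abs(cells.var(0, ddof=1) - lam_cells) < 4 * se_var).all()

    def test_reproducible_from_seed(self, two_communities, block_2to1):
        a = generate_sequence(two_communities, np.ones(20), block_2to1, None,
                              30, np.random.default_rng(5))
        b = generate_sequence(two_communities, np.ones(20), block_2to1, None,
                              30, np.random.default_rng(5))
        assert (a.data == b.data).all()

    def test_invalid_shift_time_rejected(self, two_communities, block_2to1):
        with pytest.raises(InvalidParameterError):
            generate_sequence(two_communities, np.ones(20), block_2to1,
                              ShiftSpec(0.5, 99), 50, np.random.default_rng(0))
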