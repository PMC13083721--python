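"""Dempster-Shafer layer (partition, mass, belief/plausibility, conflict)
and the uncertainty-distribution layer (empirical CDF, entropy, ranking)."""

import numpy as np
import pytest

from ubiqtree.aggregation import DEGENERATE_ENTROPY
from ubiqtree.evidence import (
    MassFunction,
    acquisition_ranking,
    belief,
    build_bpa,
    build_partition,
    conflict,
    gamma_entropy,
    plausibility,
    uncertainty_cdf,
)

GAUSS_ENTROPY = 0.5 * np.log(2 * np.pi * np.e)


class TestPartition:
    def test_equal_width_cells(self):
        part = build_partition(np.array([0.0, 0.3, 1.0]), M=4)
        np.testing.assert_allclose(part.edges, [0, 0.25, 0.5, 0.75, 1.0])
        assert part.cell_of(np.array([0.1, 0.3, 0.74, 1.0])).tolist() == [0, 1, 2, 3]

    def test_degenerate_single_cell(self):
        part = build_partition(np.full(5, 2.0), M=6)
        assert part.degenerate and part.n_cells == 1

    def test_symmetric_range_width(self):
        part = build_partition(np.array([-2.0, 2.0]), M=8)
        assert np.diff(part.edges) == pytest.approx(np.full(8, 0.5))

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            build_partition(np.array([0.0, 1.0]), M=1)

    def test_out_of_range_clamps_with_warning(self):
        part = build_partition(np.array([0.0, 1.0]), M=2)
        with pytest.warns(UserWarning, match="clamping"):
            cells = part.cell_of(np.array([-5.0, 5.0]))
        assert cells.tolist() == [0, 1]


class TestBpa:
    def part(self, M=5):
        return build_partition(np.linspace(0, 1, 11), M=M)

    def cellvals(self, part, cells):
        mids = 0.5 * (part.edges[:-1] + part.edges[1:])
        return np.array([mids[c] for c in cells])

    def test_unanimous_point_evidence(self):
        part = self.part()
        sources = [self.cellvals(part, [2]) for _ in range(7)]
        m = build_bpa(sources, part)
        assert m.masses == {frozenset({2}): pytest.approx(1.0)}

    def test_singleton_proportions(self):
        part = self.part()
        m = build_bpa([self.cellvals(part, [c]) for c in (1, 1, 3, 4)], part)
        assert m.masses[frozenset({1})] == pytest.approx(0.5)
        assert m.masses[frozenset({3})] == pytest.approx(0.25)
        assert m.masses[frozenset({4})] == pytest.approx(0.25)

    def test_set_valued_evidence(self):
        part = self.part()
        m = build_bpa([self.cellvals(part, [1, 2]), self.cellvals(part, [2, 3])], part)
        assert m.masses[frozenset({1, 2})] == pytest.approx(0.5)
        assert m.masses[frozenset({2, 3})] == pytest.approx(0.5)
        assert belief(m, {2}) == 0.0
        assert plausibility(m, {2}) == 1.0

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            build_bpa([], self.part())


class TestBeliefPlausibility:
    def test_frame_normalization(self):
        m = MassFunction({frozenset({0, 1}): 0.4, frozenset({2}): 0.6})
        omega = {0, 1, 2}
        assert belief(m, omega) == pytest.approx(1.0)
        assert plausibility(m, omega) == pytest.approx(1.0)

    def test_bayesian_mass_bel_equals_pl(self):
        m = MassFunction({frozenset({1}): 0.5, frozenset({3}): 0.25, frozenset({4}): 0.25})
        assert belief(m, {1}) == plausibility(m, {1}) == pytest.approx(0.5)

    def test_duality_on_random_masses(self):
        rng = np.random.default_rng(0)
        omega = frozenset(range(6))
        for _ in range(200):
            n_focal = int(rng.integers(1, 6))
            focals = []
            while len(focals) < n_focal:
                fe = frozenset(np.flatnonzero(rng.random(6) < 0.4).tolist())
                if fe:
                    focals.append(fe)
            w = rng.dirichlet(np.ones(len(focals)))
            masses = {}
            for fe, wi in zip(focals, w):
                masses[fe] = masses.get(fe, 0.0) + wi
            m = MassFunction(masses)
            for _ in range(5):
                A = frozenset(np.flatnonzero(rng.random(6) < 0.5).tolist())
                bel, pl = belief(m, A), plausibility(m, A)
                assert 0 <= bel <= pl <= 1 + 1e-12
                assert bel + plausibility(m, omega - A) == pytest.approx(1.0)

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            MassFunction({frozenset({1}): 0.5})
        with pytest.raises(ValueError):
            MassFunction({frozenset(): 1.0})


class TestConflict:
    def part(self, M=4):
        return build_partition(np.linspace(0, 1, 5), M=M)

    def test_bayesian_mass_no_conflict(self):
        m = MassFunction({frozenset({0}): 0.3, frozenset({2}): 0.7})
        assert conflict(m, self.part()) == pytest.approx(0.0)

    def test_total_ambiguity(self):
        m = MassFunction({frozenset({1, 2}): 1.0})
        assert conflict(m, self.part()) == pytest.approx(1.0)

    def test_mixed_mass(self):
        m = MassFunction({frozenset({1}): 0.6, frozenset({1, 2}): 0.4})
        assert conflict(m, self.part()) == pytest.approx(0.4)


class TestBeliefConvergence:
    def test_singleton_belief_converges_to_cell_probability(self):
        # point-evidence sources drawn i.i.d. from a fixed density: singleton
        # belief approaches the true cell probability as sources grow, with
        # strictly shrinking worst-cell error
        rng = np.random.default_rng(3)
        part = build_partition(np.array([-3.0, 3.0]), M=6)
        from scipy.stats import norm

        true_p = np.diff(norm.cdf(part.edges))
        true_p[0] += norm.cdf(part.edges[0])
        true_p[-1] += norm.sf(part.edges[-1])
        import warnings

        errors = []
        for K in (50, 500, 5000):
            draws = rng.normal(size=K)
            with warnings.catch_warnings():
                # tail draws beyond the fixed [-3, 3] frame clamp by design
                warnings.simplefilter("ignore", UserWarning)
                m = build_bpa([np.array([v]) for v in draws], part)
            bel = np.array([belief(m, {j}) for j in range(part.n_cells)])
            errors.append(np.max(np.abs(bel - true_p)))
        assert errors[0] > errors[1] > errors[2]


class TestGamma:
    def test_empirical_cdf_examples(self):
        g = uncertainty_cdf(np.array([1.0, 2.0, 3.0, 4.0]))
        assert g(0.0) == 0.0
        assert g(4.0) == 1.0
        assert g(2.0) == 0.5

    def test_boundary_below_min(self):
        g = uncertainty_cdf(np.array([0.2, 0.9, 0.4]))
        assert g(0.2 - 1.0) == 0.0

    def test_counting_with_ties(self):
        g = uncertainty_cdf(np.array([0.0, 0.0, 10.0]))
        assert g(5.0) == pytest.approx(2 / 3)

    def test_theorem_clauses_on_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(5, 50)))
            g = uncertainty_cdf(x)
            grid = np.linspace(x.min() - 1, x.max() + 1, 101)
            vals = g(grid)
            assert np.all(np.diff(vals) >= 0)  # monotone
            assert g(x.min() - 1e-9) == 0.0
            assert g(x.max()) == 1.0
            assert g(np.median(x)) >= 0.5  # crosses 1/2 at the median

    def test_entropy_closed_forms(self):
        rng = np.random.default_rng(5)
        hu = gamma_entropy(uncertainty_cdf(rng.uniform(0, 1, 5000)))
        hn = gamma_entropy(uncertainty_cdf(rng.normal(0, 1, 5000)))
        assert hu == pytest.approx(0.0, abs=0.05)
        assert hn == pytest.approx(GAUSS_ENTROPY, abs=0.05)

    def test_scale_monotonicity(self):
        rng = np.random.default_rng(6)
        narrow = gamma_entropy(uncertainty_cdf(rng.uniform(0, 0.5, 2000)))
        wide = gamma_entropy(uncertainty_cdf(rng.uniform(0, 2.0, 2000)))
        assert wide > narrow

    def test_zero_spread_sentinel(self):
        g = uncertainty_cdf(np.full(20, 1.5))
        assert g.entropy == DEGENERATE_ENTROPY and g.entropy_degenerate


class TestAcquisitionRanking:
    def test_variance_primary_key(self):
        assert acquisition_ranking([4.0, 1.0], [0.0, 9.9]) == [0, 1]

    def test_entropy_tie_break(self):
        assert acquisition_ranking([1.0, 1.0], [0.3, 1.2]) == [1, 0]

    def test_three_feature_ordering(self):
        assert acquisition_ranking([0.2, 0.9, 0.5], [0.0, 0.0, 0.0]) == [1, 2, 0]

    def test_names_passthrough(self):
        assert acquisition_ranking([0.1, 0.9], [0, 0], ["a", "b"]) == ["b", "a"]
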