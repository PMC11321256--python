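"""Interaction-strength sampling and community-matrix builders."""

import math

import numpy as np
import pytest

from setstab.ensemble import (
    AbundanceVector,
    CommunityMatrix,
    EnsembleConfig,
    apply_abundances,
    build_heterogeneous_set_structured,
    build_heterogeneous_unstructured,
    build_local_symmetric,
    build_set_structured,
    build_unstructured,
    sample_abundances,
    sample_pair,
    sample_pairs,
)
from setstab.structure import sample_membership


def offdiag(M):
    vals = getattr(M, "values", M)
    return vals[~np.eye(vals.shape[0], dtype=bool)]


class TestSamplePairs:
    @pytest.mark.parametrize(
        "kind,check",
        [
            ("mutualistic", lambda f, b: (f >= 0).all() and (b >= 0).all()),
            ("competitive", lambda f, b: (f <= 0).all() and (b <= 0).all()),
            ("exploitative", lambda f, b: (f * b <= 0).all()),
        ],
    )
    def test_sign_constraints(self, kind, check):
        f, b = sample_pairs(kind, 0.5, 5000, seed=0)
        assert check(f, b)

    def test_exploitative_cross_moment(self):
        # E(forward*backward) = -E^2|X| = -2/pi for sigma=1
        f, b = sample_pairs("exploitative", 1.0, 100_000, seed=1)
        prod = f * b
        se = prod.std(ddof=1) / math.sqrt(prod.size)
        assert abs(prod.mean() + 2 / math.pi) < 3 * se

    def test_random_variance(self):
        f, _ = sample_pairs("random", 0.05, 100_000, seed=2)
        assert f.var() == pytest.approx(0.0025, rel=0.05)
        assert abs(f.mean()) < 3 * 0.05 / math.sqrt(f.size)

    def test_mixed_draws_all_four_types(self):
        f, b = sample_pairs("mixed", 1.0, 4000, seed=3)
        prod = f * b
        assert (prod > 0).any() and (prod < 0).any()

    def test_unknown_type_and_bad_sd(self):
        with pytest.raises(ValueError, match="unknown interaction type"):
            sample_pairs("parasitic", 1.0, 10, seed=0)
        with pytest.raises(ValueError, match="positive"):
            sample_pair("random", 0.0, seed=0)


@pytest.fixture
def cfg():
    return EnsembleConfig(
        n_species=100, connectivity=0.5, strength_sd=0.05, n_sets=50, sets_per_species=6
    )


class TestSetStructuredBuilder:
    def test_zero_connectivity_gives_minus_dI(self, cfg):
        c = EnsembleConfig(
            n_species=20, connectivity=0.0, strength_sd=0.05, n_sets=5,
            sets_per_species=2, self_regulation=1.5,
        )
        m = sample_membership(20, 5, 2, 0)
        M = build_set_structured(c, m, 1)
        assert np.array_equal(M.values, -1.5 * np.eye(20))

    def test_diagonal_is_minus_d(self, cfg):
        m = sample_membership(100, 50, 6, 0)
        M = build_set_structured(cfg, m, 1)
        assert (np.diag(M.values) == -cfg.self_regulation).all()

    def test_structural_support(self, cfg):
        # M_ij == 0 whenever i and j share no set, on every draw
        for seed in range(5):
            m = sample_membership(100, 50, 6, seed)
            M = build_set_structured(cfg, m, seed + 100).values
            shared = m.incidence.astype(int) @ m.incidence.T.astype(int)
            np.fill_diagonal(shared, 1)
            assert (M[shared == 0] == 0).all()

    def test_offdiagonal_variance_matches_CK2sigma2_over_G(self, cfg):
        # pooled Var(M_ij) = C K^2 sigma^2 / G for random interactions
        n = 100
        per_draw = np.array([
            offdiag(build_set_structured(cfg, sample_membership(100, 50, 6, s), s + 1)).var()
            for s in range(n)
        ])
        se = per_draw.std(ddof=1) / math.sqrt(n)
        assert abs(per_draw.mean() - 0.5 * 36 / 50 * 0.05**2) < 3 * se

    def test_dimension_mismatch(self, cfg):
        m = sample_membership(50, 50, 6, 0)
        with pytest.raises(ValueError, match="inconsistent"):
            build_set_structured(cfg, m, 0)

    def test_flavor_guard(self, cfg):
        m = sample_membership(100, 50, 6, 0)
        bad = EnsembleConfig(
            n_species=100, connectivity=0.5, strength_sd=0.05, n_sets=50,
            sets_per_species=6, flavor="scale_free_within_set",
        )
        with pytest.raises(ValueError, match="er_within_set"):
            build_set_structured(bad, m, 0)


class TestUnstructuredBuilder:
    def test_full_connectivity_mutualistic_all_positive(self):
        c = EnsembleConfig(
            n_species=30, connectivity=1.0, strength_sd=0.1, n_sets=1,
            sets_per_species=1, interaction_type="mutualistic",
        )
        M = build_unstructured(c, 0)
        assert (offdiag(M) > 0).all()

    def test_two_species_full_connectivity_places_one_pair(self):
        c = EnsembleConfig(
            n_species=2, connectivity=1.0, strength_sd=1.0, n_sets=1, sets_per_species=1
        )
        M = build_unstructured(c, 7).values
        assert M[0, 1] != 0 and M[1, 0] != 0
        assert M[0, 0] == M[1, 1] == -1.0

    def test_offdiagonal_variance_matches_C_sigma2(self):
        c = EnsembleConfig(
            n_species=100, connectivity=0.5, strength_sd=0.05, n_sets=1, sets_per_species=1
        )
        n = 100
        per_draw = np.array([offdiag(build_unstructured(c, s)).var() for s in range(n)])
        se = per_draw.std(ddof=1) / math.sqrt(n)
        assert abs(per_draw.mean() - 0.5 * 0.05**2) < 3 * se


class TestDegenerateEquivalence:
    def test_K_equal_G_equal_1_matches_unstructured(self):
        # one set holding all species: the two ensembles are the same process
        c = EnsembleConfig(
            n_species=30, connectivity=0.4, strength_sd=0.1, n_sets=1, sets_per_species=1
        )
        n = 500
        stats_s, stats_u = [], []
        for s in range(n):
            m = sample_membership(30, 1, 1, s)
            Ms = offdiag(build_set_structured(c, m, s))
            Mu = offdiag(build_unstructured(c, s + n))
            stats_s.append((Ms.mean(), Ms.var(), (Ms != 0).mean()))
            stats_u.append((Mu.mean(), Mu.var(), (Mu != 0).mean()))
        stats_s, stats_u = np.array(stats_s), np.array(stats_u)
        for j in range(3):
            diff = stats_s[:, j].mean() - stats_u[:, j].mean()
            se = math.sqrt(stats_s[:, j].var(ddof=1) / n + stats_u[:, j].var(ddof=1) / n)
            assert abs(diff) < 3 * max(se, 1e-12)


class TestHeterogeneousBuilders:
    def test_support_restricted_to_shared_sets(self):
        c = EnsembleConfig(
            n_species=100, connectivity=0.2, strength_sd=0.05, n_sets=20,
            sets_per_species=3, flavor="scale_free_within_set",
        )
        m = sample_membership(100, 20, 3, 0)
        M = build_heterogeneous_set_structured(c, m, 1).values
        shared = m.incidence.astype(int) @ m.incidence.T.astype(int)
        np.fill_diagonal(shared, 1)
        assert (M[shared == 0] == 0).all()

    def test_unstructured_realized_connectivity(self):
        c = EnsembleConfig(
            n_species=200, connectivity=0.2, strength_sd=0.05, n_sets=1,
            sets_per_species=1, flavor="scale_free_within_set",
        )
        fills = []
        for s in range(30):
            M = build_heterogeneous_unstructured(c, s).values
            fills.append((np.triu(M, 1) != 0).sum() / (200 * 199 / 2))
        assert abs(np.mean(fills) - 0.2) < 0.03

    def test_mutualistic_entries_positive(self):
        c = EnsembleConfig(
            n_species=50, connectivity=0.2, strength_sd=0.05, n_sets=1,
            sets_per_species=1, flavor="scale_free_within_set",
            interaction_type="mutualistic",
        )
        M = build_heterogeneous_unstructured(c, 3)
        off = offdiag(M)
        assert (off[off != 0] > 0).all()


class TestLocalSymmetric:
    def _cfg(self, S, G, K, k):
        return EnsembleConfig(
            n_species=S, connectivity=0.5, strength_sd=0.05, n_sets=G,
            sets_per_species=K, flavor="local_symmetric", average_degree=k,
        )

    @staticmethod
    def _avg_degree(M):
        vals = M.values
        return 2 * (np.triu(vals, 1) != 0).sum() / vals.shape[0]

    def test_K1_overall_degree_near_k(self):
        c = self._cfg(200, 10, 1, 4)
        degs = [self._avg_degree(build_local_symmetric(c, sample_membership(200, 10, 1, s), s)[0])
                for s in range(20)]
        assert abs(np.mean(degs) - 4) < 0.5

    def test_K2_overall_degree_near_2k(self):
        # each species accrues ~k edges per set membership
        c = self._cfg(200, 10, 2, 4)
        degs = [self._avg_degree(build_local_symmetric(c, sample_membership(200, 10, 2, s), s)[0])
                for s in range(20)]
        assert abs(np.mean(degs) - 8) < 1.0

    def test_unstructured_partner_degree_is_k(self):
        c = self._cfg(200, 10, 2, 4)
        degs = [self._avg_degree(build_local_symmetric(c, sample_membership(200, 10, 2, s), s)[1])
                for s in range(20)]
        assert abs(np.mean(degs) - 4) < 0.5

    def test_k_at_least_expected_set_size_rejected(self):
        c = self._cfg(20, 10, 2, 4)  # expected set size S*K/G = 4
        with pytest.raises(ValueError, match="expected set size"):
            build_local_symmetric(c, sample_membership(20, 10, 2, 0), 0)


class TestAbundances:
    def test_unit_is_all_ones(self):
        assert (sample_abundances("unit", 5, 0).values == 1).all()

    def test_uniform_mean(self):
        vals = sample_abundances("uniform", 100_000, 0, params=(0.75, 1.25)).values
        assert vals.mean() == pytest.approx(1.0, abs=3 * 0.5 / math.sqrt(12 * 100_000))
        assert vals.min() > 0

    @pytest.mark.parametrize("dist,params", [
        ("lognormal", ()), ("halfnormal", ()), ("uniform", ()),
    ])
    def test_positivity(self, dist, params):
        assert sample_abundances(dist, 1000, 1, params=params).values.min() > 0

    def test_nonpositive_support_rejected(self):
        with pytest.raises(ValueError, match="0 < low"):
            sample_abundances("uniform", 10, 0, params=(-0.5, 1.0))

    def test_apply_identity_scaling(self):
        J = CommunityMatrix(np.arange(9.0).reshape(3, 3) - 4, role="jacobian")
        out = apply_abundances(J, AbundanceVector(np.ones(3)))
        assert np.array_equal(out.values, J.values)

    def test_apply_doubles_first_row(self):
        J = CommunityMatrix(np.ones((3, 3)), role="jacobian")
        out = apply_abundances(J, AbundanceVector(np.array([2.0, 1.0, 1.0])))
        assert np.array_equal(out.values[0], 2 * np.ones(3))
        assert np.array_equal(out.values[1:], np.ones((2, 3)))

    def test_rowwise_ratio_recovers_abundances(self):
        rng = np.random.default_rng(0)
        J = CommunityMatrix(rng.normal(size=(10, 10)), role="jacobian")
        X = AbundanceVector(rng.uniform(0.75, 1.25, 10))
        out = apply_abundances(J, X).values
        ratio = out / J.values
        assert np.allclose(ratio, X.values[:, None])

    def test_dimension_mismatch(self):
        J = CommunityMatrix(np.eye(3), role="jacobian")
        with pytest.raises(ValueError, match="does not match"):
            apply_abundances(J, AbundanceVector(np.ones(4)))

    def test_builder_scales_diagonal_by_abundance(self):
        c = EnsembleConfig(
            n_species=30, connectivity=0.3, strength_sd=0.05, n_sets=5,
            sets_per_species=2, abundance_dist="uniform", abundance_params=(0.75, 1.25),
        )
        M = build_set_structured(c, sample_membership(30, 5, 2, 0), 1).values
        d = -np.diag(M)
        assert (d >= 0.75).all() and (d <= 1.25).all()


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"strength_sd": 0.0},
        {"self_regulation": -1.0},
        {"connectivity": 1.2},
        {"sets_per_species": 7},
        {"interaction_type": "nope"},
        {"flavor": "nope"},
        {"n_species": 1},
    ])
    def test_invalid_configs(self, kw):
        base = dict(n_species=10, connectivity=0.5, strength_sd=0.1, n_sets=5,
                    sets_per_species=2)
        base.update(kw)
        with pytest.raises(ValueError):
            EnsembleConfig(**base)
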