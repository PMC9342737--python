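import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from partworth import (
    AttributeSpec,
    DesignError,
    SpecError,
    d_efficiency,
    design_diagnostics,
    encode_effects,
    enumerate_full_factorial,
    search_fractional_design,
)
from partworth.design import effects_decode_matrix


def _attrs(level_counts):
    return [
        AttributeSpec(f"a{i}", tuple(f"l{j}" for j in range(k)))
        for i, k in enumerate(level_counts)
    ]


class TestFullFactorial:
    def test_study_catalog_size(self, study, study_catalog):
        # 4 * 3^5 attribute-level combinations
        assert len(study_catalog) == 972

    @pytest.mark.parametrize(
        "level_counts,expected", [((3,), 3), ((2, 2), 4), ((4, 3, 3, 3, 3, 3), 972)]
    )
    def test_count_is_product_of_levels(self, level_counts, expected):
        assert len(enumerate_full_factorial(_attrs(level_counts))) == expected

    def test_two_by_two_covers_every_pair_once(self):
        attrs = _attrs((2, 2))
        combos = {
            tuple(p.assignment.values()) for p in enumerate_full_factorial(attrs)
        }
        assert combos == set(itertools.product(["l0", "l1"], repeat=2))

    @given(st.lists(st.integers(2, 4), min_size=1, max_size=4))
    def test_no_duplicates_and_deterministic_ids(self, level_counts):
        attrs = _attrs(level_counts)
        catalog = enumerate_full_factorial(attrs)
        assert len(catalog) == int(np.prod(level_counts))
        assert [p.profile_id for p in catalog] == list(range(len(catalog)))
        assignments = [tuple(p.assignment.items()) for p in catalog]
        assert len(set(assignments)) == len(assignments)

    def test_empty_attribute_list_rejected(self):
        with pytest.raises(SpecError):
            enumerate_full_factorial([])


class TestEffectsCoding:
    def test_three_level_rows(self):
        attrs = _attrs((3,))
        dm = encode_effects(enumerate_full_factorial(attrs), attrs)
        # intercept + 2 contrast columns; last level coded -1 everywhere
        assert np.allclose(dm.X, [[1, 1, 0], [1, 0, 1], [1, -1, -1]])

    def test_four_level_attribute_has_three_columns(self):
        attrs = _attrs((4,))
        dm = encode_effects(enumerate_full_factorial(attrs), attrs)
        assert dm.n_columns == 1 + 3

    def test_full_factorial_columns_orthogonal(self):
        attrs = _attrs((2, 2))
        dm = encode_effects(enumerate_full_factorial(attrs), attrs)
        gram = dm.X.T @ dm.X
        assert np.allclose(gram, np.diag(np.diag(gram)))
        assert np.allclose(np.diag(gram), dm.n_runs)

    def test_study_design_has_14_columns(self, study, study_catalog):
        attrs, _ = study
        dm = encode_effects(study_catalog, attrs)
        assert dm.n_columns == 1 + (3 + 2 + 2 + 2 + 2 + 2) == 14
        assert set(np.unique(dm.X)) <= {-1.0, 0.0, 1.0}

    def test_decode_matrix_utilities_zero_sum(self):
        attrs = _attrs((4, 3))
        D, row_map = effects_decode_matrix(attrs)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=D.shape[1])
        u = D @ beta
        # per-attribute decoded utilities sum to zero
        assert abs(u[:4].sum()) < 1e-12 and abs(u[4:].sum()) < 1e-12
        assert [a for a, _ in row_map] == ["a0"] * 4 + ["a1"] * 3


class TestDEfficiency:
    def test_full_factorial_vs_itself_is_one(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        dm = encode_effects(cat, small_attrs)
        assert d_efficiency(dm, dm) == pytest.approx(1.0)

    def test_replication_invariance(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        dm = encode_effects(cat, small_attrs)
        doubled = encode_effects(list(cat) + list(cat), small_attrs)
        assert d_efficiency(doubled, dm) == pytest.approx(1.0)

    def test_singular_candidate_scores_zero_with_flag(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        dm = encode_effects(cat, small_attrs)
        # replicating a single profile cannot identify the model
        degenerate = encode_effects([cat[0]] * 6, small_attrs)
        res = d_efficiency(degenerate, dm, return_diagnostics=True)
        assert res.value == 0.0 and res.degenerate

    @given(st.integers(0, 2**31 - 1))
    def test_subsets_never_beat_full_factorial(self, seed):
        attrs = _attrs((3, 2, 2))
        cat = enumerate_full_factorial(attrs)
        full = encode_effects(cat, attrs)
        rng = np.random.default_rng(seed)
        n = rng.integers(full.n_columns, len(cat) + 1)
        idx = rng.choice(len(cat), size=n, replace=False)
        sub = encode_effects([cat[i] for i in idx], attrs)
        assert d_efficiency(sub, full) <= 1.0 + 1e-9


class TestExchangeSearch:
    def test_infeasible_size_rejected(self, study, study_catalog):
        attrs, _ = study
        with pytest.raises(DesignError):
            search_fractional_design(study_catalog, attrs, 13)

    def test_full_size_returns_full_factorial(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        res = search_fractional_design(cat, small_attrs, len(cat), seed=0)
        assert res.d_efficiency == pytest.approx(1.0)
        assert len(res.profiles) == len(cat)

    def test_single_attribute_selects_each_level_once(self):
        attrs = _attrs((3,))
        cat = enumerate_full_factorial(attrs)
        res = search_fractional_design(cat, attrs, 3, restarts=5, seed=0)
        assert {p.assignment["a0"] for p in res.profiles} == {"l0", "l1", "l2"}

    def test_matches_exhaustive_brute_force_on_small_catalogs(self, small_attrs):
        # global optimum by enumerating all subsets; the exchange search with
        # restarts must reach the same determinant
        cat = enumerate_full_factorial(small_attrs)
        full = encode_effects(cat, small_attrs)
        n = 4
        best = -np.inf
        for combo in itertools.combinations(range(len(cat)), n):
            X = full.X[list(combo)]
            sign, ld = np.linalg.slogdet(X.T @ X)
            if sign > 0:
                best = max(best, ld)
        res = search_fractional_design(cat, small_attrs, n, restarts=10, seed=3)
        X = res.matrix.X
        _, ld = np.linalg.slogdet(X.T @ X)
        assert ld == pytest.approx(best, abs=1e-9)

    def test_restart_best_is_monotone_and_seeded(self, study, study_catalog):
        attrs, _ = study
        a = search_fractional_design(study_catalog, attrs, 42, restarts=4, seed=7)
        b = search_fractional_design(study_catalog, attrs, 42, restarts=4, seed=7)
        assert a.restart_best == b.restart_best
        assert [p.profile_id for p in a.profiles] == [p.profile_id for p in b.profiles]
        assert all(
            y >= x for x, y in zip(a.restart_best, a.restart_best[1:])
        )
        # extending the restart stream can only improve the best design
        c = search_fractional_design(study_catalog, attrs, 42, restarts=6, seed=7)
        assert c.restart_best[:4] == a.restart_best
        assert c.d_efficiency >= a.d_efficiency


class TestDiagnostics:
    def test_full_factorial_perfectly_balanced(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        rep = design_diagnostics(cat, small_attrs)
        assert rep.max_pair_deviation == 0.0
        assert not rep.missing_levels
        assert set(rep.level_counts["drug"].values()) == {3}

    def test_missing_level_flagged(self, small_attrs):
        cat = enumerate_full_factorial(small_attrs)
        subset = [p for p in cat if p.assignment["dose"] != "high"]
        rep = design_diagnostics(subset, small_attrs)
        assert ("dose", "high") in rep.missing_levels
        assert rep.level_counts["dose"]["high"] == 0

    def test_counts_match_direct_enumeration(self, study, study_design):
        attrs, _ = study
        rep = design_diagnostics(study_design.profiles, attrs)
        # direct counting oracle for one attribute pair
        a, b = attrs[0], attrs[1]
        for i, la in enumerate(a.levels):
            for j, lb in enumerate(b.levels):
                direct = sum(
                    1
                    for p in study_design.profiles
                    if p.assignment[a.name] == la and p.assignment[b.name] == lb
                )
                assert rep.pair_counts[(a.name, b.name)][i, j] == direct
        assert np.isfinite(rep.max_pair_deviation)
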