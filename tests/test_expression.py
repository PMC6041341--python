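"""PET/PEG classification, lost-orthogroup tabulation and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ortholoss.errors import ValidationError
from ortholoss.expression import (
    ExpressionMatrix,
    enrich,
    pet_matrix,
    principal_genes,
    principal_tissues,
    tabulate_lost_pets,
)
from ortholoss.simulate import simulate_expression


def make_expr(rows: dict[str, list[float]], tissues=None) -> ExpressionMatrix:
    tissues = tissues or [f"t{i}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=tissues))


class TestPrincipalTissues:
    def test_dominant_tissue_is_pet(self):
        e = make_expr({"g1": [10, 1, 1, 1, 1, 1]},
                      tissues=["leaf", "t1", "t2", "t3", "t4", "t5"])
        assert principal_tissues(e, "g1", 2.0).pet_tissues == ("leaf",)

    def test_flat_gene_has_no_pet(self):
        e = make_expr({"g1": [5.0, 5.0, 5.0]})
        assert principal_tissues(e, "g1", 2.0).pet_tissues == ()

    def test_all_zero_gene_has_no_pet(self):
        e = make_expr({"g1": [0.0, 0.0, 0.0]})
        assert principal_tissues(e, "g1", 2.0).pet_tissues == ()

    def test_single_tissue_rejected(self):
        e = make_expr({"g1": [5.0]})
        with pytest.raises(ValidationError, match="two tissues"):
            principal_tissues(e, "g1", 2.0)

    def test_weak_threshold_reading(self):
        # at fold 1.0 the rule is "at least the mean of the others"
        e = make_expr({"g1": [3.0, 2.0, 1.0]})
        assert principal_tissues(e, "g1", 1.0).pet_tissues == ("t0", "t1")

    def test_matches_brute_force(self, rng):
        e, _ = simulate_expression(n_genes=150, noise_cv=0.3, fold=3.0, seed=9)
        mask = pet_matrix(e, 2.0)
        values = e.values
        for gene in e.gene_ids:
            for tissue in e.tissue_ids:
                v = values.at[gene, tissue]
                others = [values.at[gene, t] for t in e.tissue_ids if t != tissue]
                expected = v > 0 and v >= 2.0 * (sum(others) / len(others))
                assert mask.at[gene, tissue] == expected, (gene, tissue)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_row_scaling(self, scale):
        e = make_expr({"g1": [8.0, 1.0, 2.0, 0.5]})
        scaled = make_expr({"g1": [scale * v for v in [8.0, 1.0, 2.0, 0.5]]})
        assert (principal_tissues(e, "g1", 2.0).pet_tissues
                == principal_tissues(scaled, "g1", 2.0).pet_tissues)


class TestPrincipalGenes:
    def test_hand_example(self):
        # focal mean 8 vs other mean 3: 8 ≥ 2×3 → PEG; the flat gene is not
        e = make_expr(
            {"g1": [8.0, 8.0, 3.0, 3.0], "g2": [3.0, 3.0, 3.0, 3.0]},
            tissues=["h1", "h2", "s1", "s2"],
        )
        assert principal_genes(e, ["h1", "h2"], 2.0) == {"g1"}

    def test_equal_means_not_peg_at_two(self):
        e = make_expr({"g1": [4.0, 4.0]}, tissues=["focal", "other"])
        assert principal_genes(e, ["focal"], 2.0) == frozenset()

    def test_recovers_planted_pegs(self):
        e, truth = simulate_expression(n_genes=500, pet_fraction=0.1, fold=10.0,
                                       noise_cv=0.0, seed=3)
        focal = e.tissue_ids[0]
        planted = {g for g, t in truth.pet_tissue.items() if t == focal}
        assert principal_genes(e, [focal], 2.0) == planted

    def test_single_focal_consistent_with_pet(self):
        e, _ = simulate_expression(n_genes=200, noise_cv=0.4, fold=3.0, seed=11)
        tissue = e.tissue_ids[2]
        mask = pet_matrix(e, 2.0)
        via_pet = frozenset(mask.index[mask[tissue]])
        assert principal_genes(e, [tissue], 2.0) == via_pet

    @pytest.mark.parametrize("focal", [[], ["t0", "t1", "t2"]])
    def test_improper_focal_sets_rejected(self, focal):
        e = make_expr({"g1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            principal_genes(e, focal, 2.0)


class TestTabulateLostPets:
    CLASS_MAP = {"leaf": "leaves", "root": "roots", "flower": "flowers",
                 "stem": "other"}

    def test_direct_tabulation(self):
        pets = {"gA": ("root",), "gB": ("leaf",), "gC": ()}
        mapping = {"OG1": ["gA"], "OG2": ["gB"], "OG3": ["gC"]}
        tab = tabulate_lost_pets(["OG1", "OG2", "OG3"], mapping, pets, self.CLASS_MAP)
        assert tab.counts == {"leaves": 1, "roots": 1, "flowers": 0, "other": 0}
        assert tab.n_without_pet == 1
        assert tab.n_unmapped == 0

    def test_multi_class_membership(self):
        pets = {"gA": ("leaf", "root")}
        tab = tabulate_lost_pets(["OG1"], {"OG1": ["gA"]}, pets, self.CLASS_MAP)
        assert tab.counts["leaves"] == 1 and tab.counts["roots"] == 1

    def test_unmapped_orthogroup_tallied_not_fatal(self):
        tab = tabulate_lost_pets(["OGx"], {}, {}, self.CLASS_MAP)
        assert tab.n_unmapped == 1

    def test_uncovered_tissue_rejected(self):
        with pytest.raises(ValidationError, match="class map"):
            tabulate_lost_pets(["OG1"], {"OG1": ["g"]}, {"g": ("petal",)},
                               self.CLASS_MAP)

    def test_planted_class_proportions_recovered(self):
        # 40/30/20/10 planted split across 100 lost orthogroups
        tissues = ["leaf"] * 40 + ["root"] * 30 + ["flower"] * 20 + ["stem"] * 10
        pets = {f"g{i}": (t,) for i, t in enumerate(tissues)}
        mapping = {f"OG{i}": [f"g{i}"] for i in range(100)}
        lost = [f"OG{i}" for i in range(100)]
        tab = tabulate_lost_pets(lost, mapping, pets, self.CLASS_MAP)
        assert tab.pct_of_cohort == {"leaves": 40.0, "roots": 30.0,
                                     "flowers": 20.0, "other": 10.0}
        # every mapped orthogroup is in the cohort → class-universe pct is 100
        assert all(v == 100.0 for v in tab.pct_of_class_universe.values())

    def test_invariant_under_orthogroup_relabeling(self, rng):
        tissues = ["leaf", "root", "flower", "stem"]
        pets = {f"g{i}": (tissues[i % 4],) for i in range(40)}
        mapping = {f"OG{i}": [f"g{i}"] for i in range(40)}
        lost = [f"OG{i}" for i in range(0, 40, 3)]
        tab = tabulate_lost_pets(lost, mapping, pets, self.CLASS_MAP)
        perm = rng.permutation(40)
        relabel = {f"OG{i}": f"XX{perm[i]}" for i in range(40)}
        tab2 = tabulate_lost_pets(
            [relabel[o] for o in lost],
            {relabel[o]: genes for o, genes in mapping.items()},
            pets,
            self.CLASS_MAP,
        )
        assert tab.counts == tab2.counts
        assert tab.universe_counts == tab2.universe_counts


class TestEnrich:
    def test_closed_form_small_case(self):
        universe = [f"g{i}" for i in range(10)]
        query = universe[:5]
        annotation = {"T1": set(universe[:5])}
        rows = enrich(query, universe, annotation)
        assert rows[0].k == 5
        assert rows[0].p_value == pytest.approx(1 / 252, rel=1e-9)

    def test_term_covering_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        rows = enrich(universe[:3], universe, {"ALL": set(universe)})
        assert rows[0].p_value == pytest.approx(1.0)

    def test_q_values_are_step_up_adjusted(self):
        universe = [f"g{i}" for i in range(1000)]
        query = set(universe[:100])
        annotation = {
            "A": set(universe[:30]),
            "B": set(universe[:25] + universe[500:505]),
            "C": set(universe[:20] + universe[500:510]),
        }
        rows = enrich(query, universe, annotation)
        ps = np.array([r.p_value for r in rows])
        qs = np.array([r.q_value for r in rows])
        order = np.argsort(ps)
        m = len(ps)
        expected = np.minimum.accumulate((ps[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(qs[order], np.minimum(expected, 1.0))
        assert (qs >= ps).all()

    def test_bh_adjustment_known_values(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_zero_hit_terms_excluded(self):
        universe = [f"g{i}" for i in range(10)]
        rows = enrich(universe[:3], universe, {"T": {"g9"}})
        assert rows == []

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            enrich([], ["g1"], {})

    def test_matches_permutation_oracle(self, rng):
        # resampling oracle: draw query sets of size n, count P(X >= k)
        universe = [f"g{i}" for i in range(30)]
        term_genes = set(universe[:10])
        query = universe[:5] + universe[20:23]  # k = 5 hits, n = 8
        rows = enrich(query, universe, {"T": term_genes})
        p = rows[0].p_value
        k_obs = rows[0].k
        n_perm = 10_000
        hits = 0
        arr = np.array(universe)
        for _ in range(n_perm):
            sample = rng.choice(arr, size=len(query), replace=False)
            if len(set(sample) & term_genes) >= k_obs:
                hits += 1
        p_hat = hits / n_perm
        se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_perm)
        assert abs(p - p_hat) <= 3 * se + 1e-9
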