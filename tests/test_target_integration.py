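import numpy as np
import pandas as pd
import pytest

from regonset.config import PipelineConfig
from regonset.expression_dynamics import NEGATIVE, POSITIVE, UNCLASSIFIED
from regonset.target_integration import (
    DOWN_IN_NULL,
    UNCHANGED,
    UP_IN_NULL,
    bound_fraction_by_class,
    controlled_target_sets,
    hypergeometric_overlap,
    ko_differential,
    reference_cobinding,
)
from tests.oracles import hypergeom_by_enumeration, hypergeom_exact_upper

KO_COLS = ["het_b1_t1", "het_b1_t2", "het_b2_t1", "het_b2_t2",
           "null_b1_t1", "null_b1_t2", "null_b2_t1", "null_b2_t2"]


def _ko(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=KO_COLS).astype(float)
    df.index.name = "gene_id"
    return df


class TestKoDifferential:
    def test_identical_genotypes_unchanged(self, cfg):
        (rec,) = ko_differential(_ko({"g": [100] * 8}), cfg)
        assert rec.direction == UNCHANGED and rec.fold == pytest.approx(1.0)

    def test_two_fold_drop_with_tiny_variance_called_down(self, cfg):
        het = [200, 201, 199, 200]
        null = [100, 101, 99, 100]
        (rec,) = ko_differential(_ko({"g": het + null}), cfg)
        assert rec.direction == DOWN_IN_NULL and rec.fold == pytest.approx(2.0, rel=1e-2)

    def test_two_fold_rise_called_up(self, cfg):
        (rec,) = ko_differential(_ko({"g": [100, 101, 99, 100, 200, 201, 199, 200]}), cfg)
        assert rec.direction == UP_IN_NULL

    def test_requires_two_biological_replicates(self, cfg):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["het_b1_t1", "null_b1_t1"])
        with pytest.raises(ValueError, match="biological replicates"):
            ko_differential(df, cfg)

    def test_planted_effects_have_correct_point_estimates(self, sim, cfg):
        """On defaults every planted gene's fold estimate lies on the planted side."""
        recs = {r.gene_id: r for r in ko_differential(sim.ko_table, cfg)}
        for g in sim.truth.planted_positive_targets:
            assert recs[g].fold > 1.1
        for g in sim.truth.planted_negative_targets:
            assert recs[g].fold < 1 / 1.1
        unaffected = (
            set(sim.ko_table.index) - set(sim.truth.ko_effect_genes) - {"Runx1"}
        )
        for g in unaffected:
            assert recs[g].direction == UNCHANGED

    def test_effects_above_threshold_are_mostly_recovered(self, cfg):
        """Planted folds clearly above the 1.5 rule are called at high rate.

        Unlike effects planted exactly at the calling threshold (detected
        about half the time by construction), a fold-2 effect should fail
        only when the two-replicate t-test lacks power.
        """
        from regonset.synthetic_data import SimConfig, simulate

        sim2 = simulate(SimConfig(seed=4, ko_fold=2.0))
        recs = ko_differential(sim2.ko_table, cfg)
        down = {r.gene_id for r in recs if r.direction == DOWN_IN_NULL}
        up = {r.gene_id for r in recs if r.direction == UP_IN_NULL}
        pos = set(sim2.truth.planted_positive_targets)
        neg = set(sim2.truth.planted_negative_targets)
        recall = (len(down & pos) + len(up & neg)) / (len(pos) + len(neg))
        assert recall >= 0.8

    def test_direction_labels_respect_both_thresholds(self, sim, cfg):
        for r in ko_differential(sim.ko_table, cfg):
            if r.direction == DOWN_IN_NULL:
                assert r.fold >= cfg.ko_fold and r.p_value < cfg.ko_alpha
            elif r.direction == UP_IN_NULL:
                assert r.fold <= 1 / cfg.ko_fold and r.p_value < cfg.ko_alpha


class TestHypergeometricOverlap:
    def test_full_overlap_forced(self):
        u = {f"g{i}" for i in range(8)}
        res = hypergeometric_overlap(u, u, u)
        assert res.p_hyper == pytest.approx(1.0)

    def test_zero_overlap_p_is_one(self):
        res = hypergeometric_overlap({"a"}, {"b"}, {"a", "b", "c"})
        assert res.overlap == 0 and res.p_hyper == pytest.approx(1.0)

    def test_textbook_case_five_over_210(self):
        universe = [f"g{i}" for i in range(10)]
        a = set(universe[:5])
        b = set(universe[1:5])  # overlap 4, |B| = 4
        res = hypergeometric_overlap(a, b, universe)
        assert res.overlap == 4
        assert res.p_hyper == pytest.approx(5 / 210, rel=1e-12)

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_overlap({"x"}, {"a"}, {"a"})

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            universe = [f"g{i}" for i in range(n)]
            a = {g for g in universe if rng.random() < 0.5}
            nb = int(rng.integers(1, n + 1))
            b = set(rng.choice(universe, size=nb, replace=False))
            res = hypergeometric_overlap(a, b, universe)
            exact = hypergeom_by_enumeration(universe, a, nb, res.overlap)
            assert res.p_hyper == pytest.approx(exact, rel=1e-9)

    def test_matches_closed_form_sum(self):
        universe = [f"g{i}" for i in range(150)]
        a = set(universe[:40])
        b = set(universe[25:75])
        res = hypergeometric_overlap(a, b, universe)
        assert res.p_hyper == pytest.approx(
            hypergeom_exact_upper(150, 40, 50, res.overlap), rel=1e-9
        )

    def test_matches_monte_carlo_within_three_se(self):
        rng = np.random.default_rng(19)
        universe = [f"g{i}" for i in range(200)]
        a = set(universe[:60])
        b = set(rng.choice(universe, size=50, replace=False))
        res = hypergeometric_overlap(a, b, universe)
        n_draws = 100_000
        hits = 0
        arr = np.array(universe)
        for _ in range(n_draws):
            draw = rng.choice(arr, size=50, replace=False)
            if len(a & set(draw)) >= res.overlap:
                hits += 1
        mc = hits / n_draws
        se = max(np.sqrt(mc * (1 - mc) / n_draws), 1e-5)
        assert abs(res.p_hyper - mc) <= 3 * se


class TestControlledSets:
    def test_empty_bound_set_empties_output(self):
        labels = {"a": POSITIVE, "b": NEGATIVE}
        recs = ko_differential(
            _ko({"a": [200, 201, 199, 200, 100, 101, 99, 100],
                 "b": [100, 101, 99, 100, 200, 201, 199, 200]})
        )
        sets = controlled_target_sets(labels, recs, set())
        assert sets.positively_controlled == set()
        assert sets.negatively_controlled == set()

    def test_set_algebra_identities(self, sim, cfg):
        from regonset.peak_annotation import assign_peaks, candidate_targets

        recs = ko_differential(sim.ko_table, cfg)
        labels = {g: POSITIVE for g in sim.truth.planted_positive_targets}
        labels.update({g: NEGATIVE for g in sim.truth.planted_negative_targets})
        bound = candidate_targets(assign_peaks(sim.peaks, sim.genes, cfg))
        sets = controlled_target_sets(labels, recs, bound)
        for venn in (sets.venn_positive, sets.venn_negative):
            triple = venn["a_and_b_and_c"]
            assert triple <= min(venn["a_and_b"], venn["a_and_c"], venn["b_and_c"])
            assert max(venn["a_and_b"], venn["a_and_c"]) <= max(venn["set_a"], venn["set_b"], venn["set_c"])
            assert venn["union"] <= venn["set_a"] + venn["set_b"] + venn["set_c"]
        assert len(sets.positively_controlled) == sets.venn_positive["a_and_b_and_c"]

    def test_recovered_genes_are_planted_and_bound(self, sim, cfg):
        from regonset.peak_annotation import assign_peaks, candidate_targets

        recs = ko_differential(sim.ko_table, cfg)
        labels = {g: POSITIVE for g in sim.truth.planted_positive_targets}
        labels.update({g: NEGATIVE for g in sim.truth.planted_negative_targets})
        bound = candidate_targets(assign_peaks(sim.peaks, sim.genes, cfg))
        sets = controlled_target_sets(labels, recs, bound)
        assert sets.positively_controlled  # some planted targets pass all three
        assert sets.positively_controlled <= set(sim.truth.planted_positive_targets) & bound
        assert sets.negatively_controlled <= set(sim.truth.planted_negative_targets) & bound

    def test_pairwise_membership_without_triple(self):
        labels = {"a": POSITIVE}
        recs = ko_differential(_ko({"a": [100] * 8}))  # unchanged in KO
        sets = controlled_target_sets(labels, recs, {"a"})
        assert sets.positively_controlled == set()
        assert sets.venn_positive["a_and_c"] == 1  # correlated and bound


class TestReferenceCobinding:
    def test_empty_references_zero_fractions(self):
        out = reference_cobinding({"t": {"a", "b"}}, {})
        assert out["t"]["fraction_all"] == 0.0 and out["t"]["fraction_any"] == 0.0

    def test_universe_references_full_fraction(self):
        refs = {"f1": {"a", "b"}, "f2": {"a", "b"}}
        out = reference_cobinding({"t": {"a", "b"}}, refs)
        assert out["t"]["fraction_all"] == 1.0

    def test_constructed_eighty_percent(self):
        targets = {f"g{i}" for i in range(10)}
        refs = {"f1": {f"g{i}" for i in range(8)}, "f2": {f"g{i}" for i in range(8)}}
        out = reference_cobinding({"t": targets}, refs)
        assert out["t"]["fraction_all"] == pytest.approx(0.8)


class TestBoundFractionByClass:
    def test_no_bound_genes(self):
        labels = {"a": POSITIVE, "b": NEGATIVE, "c": UNCLASSIFIED}
        out = bound_fraction_by_class(labels, set())
        assert out == {POSITIVE: 0.0, NEGATIVE: 0.0, UNCLASSIFIED: 0.0}

    def test_empty_class_is_undefined_not_zero(self):
        out = bound_fraction_by_class({"a": POSITIVE}, {"a"})
        assert out[POSITIVE] == 1.0 and out[NEGATIVE] is None

    def test_binding_enriched_in_positive_class(self, sim, cfg):
        from regonset.peak_annotation import assign_peaks, candidate_targets

        bound = candidate_targets(assign_peaks(sim.peaks, sim.genes, cfg))
        labels = {g.gene_id: UNCLASSIFIED for g in sim.genes}
        labels.update({g: POSITIVE for g in sim.truth.planted_positive_targets})
        labels.update({g: NEGATIVE for g in sim.truth.planted_negative_targets})
        out = bound_fraction_by_class(labels, bound)
        assert out[POSITIVE] > out[UNCLASSIFIED]
        assert all(v is None or 0 <= v <= 1 for v in out.values())
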