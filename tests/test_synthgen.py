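"""Determinism, planted-effect bookkeeping, and signal-model faithfulness
of the synthetic-array generator."""

import numpy as np
import pandas as pd
import pytest

from medipchip import synthgen as sg
from medipchip.errors import ValidationError
from medipchip.expression import expression_fold_change
from medipchip.io_formats import CHROMOSOMES
from medipchip.methylation import filter_probes, methylation_fold_ratio


class TestGenerateUniverse:
    def test_single_gene_boundary(self):
        u = sg.generate_universe(1, max_probes_per_island=1, seed=0)
        assert u.n_genes == 1
        assert u.total_meth_probes == 1

    def test_seed_determinism(self):
        a = sg.generate_universe(500, 6, seed=7)
        b = sg.generate_universe(500, 6, seed=7)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_probe_totals_match_exhaustive_recount(self):
        u = sg.generate_universe(500, 6, seed=7)
        assert u.total_meth_probes == sum(int(x) for x in u.genes["n_meth_probes"])
        assert u.genes["n_meth_probes"].between(1, 6).all()
        assert set(u.genes["chromosome"]) == set(CHROMOSOMES)

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            sg.generate_universe(0)
        with pytest.raises(ValidationError):
            sg.generate_universe(5, max_probes_per_island=0)


class TestPlantEffects:
    def test_null_model(self, small_universe):
        t = sg.plant_effects(small_universe, 0.0, 0.0, 0.0, seed=1)
        assert (t.effects["meth_effect"] == 1.0).all()
        assert (t.effects["expr_effect"] == 1.0).all()
        assert not t.effects["coupled"].any()

    def test_saturated_coupling(self, small_universe):
        t = sg.plant_effects(small_universe, 1.0, 0.0, 0.0, effect_fold=2.0, seed=1)
        e = t.effects
        assert e["coupled"].all()
        assert set(e["meth_effect"]) == {2.0, 0.5}
        # coupled genes always perturb the two layers in opposition
        assert (((e["meth_effect"] < 1) & (e["expr_effect"] > 1))
                | ((e["meth_effect"] > 1) & (e["expr_effect"] < 1))).all()

    def test_class_counts_match_rounded_targets(self):
        u = sg.generate_universe(1000, 4, seed=3)
        t = sg.plant_effects(u, 0.1, 0.05, 0.03, seed=9)
        for sex in sg.SEXES:
            counts = t.effects[t.effects["sex"] == sex]["effect_class"].value_counts()
            assert counts.get("coupled_up", 0) + counts.get("coupled_down", 0) == round(0.1 * 1000)
            assert counts.get("meth_only", 0) == round(0.05 * 1000)
            assert counts.get("expr_only", 0) == round(0.03 * 1000)

    def test_fraction_sum_validation(self, small_universe):
        with pytest.raises(ValidationError):
            sg.plant_effects(small_universe, 0.6, 0.3, 0.2)

    def test_enriched_categories_recorded(self, planted_truth):
        assert len(planted_truth.enriched_categories) == 2
        assert planted_truth.enriched_categories <= set(planted_truth.category_ids)


class TestSimulateMethylationArray:
    def test_noiseless_null_folds_are_unity(self, small_universe, noiseless):
        t = sg.plant_effects(small_universe, 0.0, 0.0, 0.0, seed=1)
        probes = sg.simulate_methylation_array(small_universe, t, noiseless, seed=4)
        res = methylation_fold_ratio(probes)
        np.testing.assert_allclose(res["fold_ratio"], 1.0, rtol=1e-12)

    def test_noiseless_effect_exact_on_every_probe(self, small_universe, planted_truth,
                                                   noiseless, noiseless_probes):
        res = methylation_fold_ratio(noiseless_probes)
        truth = planted_truth.for_sex("male")
        for accession, grp in res.groupby("accession"):
            expected = truth.loc[accession, "meth_effect"]
            np.testing.assert_allclose(grp["fold_ratio"], expected, rtol=1e-12)

    def test_byte_identical_tables_for_fixed_seed(self, small_universe, planted_truth):
        noise = sg.NoiseModel()
        a = sg.simulate_methylation_array(small_universe, planted_truth, noise, seed=5)
        b = sg.simulate_methylation_array(small_universe, planted_truth, noise, seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_seeded_noisy_mean_fold_regression(self):
        """Frozen regression: 200 probes of 2.0-fold genes at log-noise 0.1
        average a fold ratio of 2.023051 (and stay inside [1.8, 2.2])."""
        u = sg.generate_universe(160, 4, seed=7)
        t = sg.plant_effects(u, 1.0, 0.0, 0.0, effect_fold=2.0, seed=11)
        noise = sg.NoiseModel(log_sigma_signal=0.1, p_detect_fail=0.0)
        res = methylation_fold_ratio(
            filter_probes(sg.simulate_methylation_array(u, t, noise, seed=21, sex="male"))
        )
        up = res[res["accession"].map(t.for_sex("male")["meth_effect"]) > 1]
        assert len(up) == 200
        mean = float(up["fold_ratio"].mean())
        assert mean == pytest.approx(2.023051, abs=1e-6)
        assert 1.8 <= mean <= 2.2

    def test_detection_failures_respect_probability(self, small_universe, planted_truth):
        noise = sg.NoiseModel(p_detect_fail=0.0)
        probes = sg.simulate_methylation_array(small_universe, planted_truth, noise, seed=6)
        assert (probes["detect_p"] < 0.05).all()

    def test_truth_must_cover_universe(self, small_universe, planted_truth, noiseless):
        bigger = sg.generate_universe(80, 4, seed=7)
        with pytest.raises(ValidationError, match="cover"):
            sg.simulate_methylation_array(bigger, planted_truth, noiseless, seed=1)


class TestSimulateExpressionArray:
    def test_noiseless_null(self, small_universe, noiseless):
        t = sg.plant_effects(small_universe, 0.0, 0.0, 0.0, seed=1)
        er = expression_fold_change(
            sg.simulate_expression_array(small_universe, t, noiseless, seed=4))
        np.testing.assert_allclose(er["fold_change"], 1.0, rtol=1e-12)

    def test_noiseless_planted_fold_exact(self, small_universe, noiseless):
        t = sg.plant_effects(small_universe, 0.0, 0.0, 1.0, effect_fold=1.5, seed=2)
        truth = t.for_sex("male")
        er = expression_fold_change(
            sg.simulate_expression_array(small_universe, t, noiseless, seed=4))
        for accession, grp in er.groupby("accession"):
            np.testing.assert_allclose(
                grp["fold_change"], truth.loc[accession, "expr_effect"], rtol=1e-12)

    def test_seeded_noisy_mean_fold_regression(self):
        """Frozen regression: 125 probes of 2.0-fold genes average 2.024891."""
        u = sg.generate_universe(160, 4, seed=7)
        t = sg.plant_effects(u, 1.0, 0.0, 0.0, effect_fold=2.0, seed=11)
        noise = sg.NoiseModel(log_sigma_signal=0.1, p_detect_fail=0.0)
        er = expression_fold_change(sg.simulate_expression_array(u, t, noise, seed=22, sex="male"))
        up = er[er["accession"].map(t.for_sex("male")["expr_effect"]) > 1]
        assert len(up) == 125
        assert float(up["fold_change"].mean()) == pytest.approx(2.024891, abs=1e-6)


class TestGenerateAnnotations:
    def test_every_category_has_members_and_recount(self, small_universe, planted_truth):
        ann = sg.generate_annotations(small_universe, planted_truth, (3, 8), seed=5)
        cats = ann.categories()
        assert set(cats) == set(planted_truth.category_ids)
        for cid, (_, members) in cats.items():
            # enriched categories keep their coupled core even when it
            # exceeds the drawn size
            core = len(planted_truth.category_cores.get(cid, ()))
            assert 1 <= len(members) <= max(8, core)
            assert set(planted_truth.category_cores.get(cid, ())) <= members
        # membership recount by iterating the forward mapping
        recount: dict[str, int] = {}
        for gene, pairs in ann.records.items():
            for cid, _ in pairs:
                recount[cid] = recount.get(cid, 0) + 1
        assert recount == {cid: len(members) for cid, (_, members) in cats.items()}

    def test_enriched_categories_concentrate_coupled_genes(self, small_universe, planted_truth):
        ann = sg.generate_annotations(small_universe, planted_truth, (8, 12), seed=5)
        coupled = set(planted_truth.effects.loc[planted_truth.effects["coupled"], "accession"])
        cats = ann.categories()
        enriched_frac = np.mean([
            len(members & coupled) / len(members)
            for cid, (_, members) in cats.items()
            if cid in planted_truth.enriched_categories
        ])
        null_frac = np.mean([
            len(members & coupled) / len(members)
            for cid, (_, members) in cats.items()
            if cid not in planted_truth.enriched_categories
        ])
        assert enriched_frac > 2 * null_frac

    def test_single_category_covering_all_genes_is_unenriched(self, small_universe):
        from medipchip.enrichment import run_enrichment

        t = sg.plant_effects(small_universe, 0.0, 0.0, 0.0, n_categories=1, n_enriched=0, seed=1)
        ann = sg.generate_annotations(
            small_universe, t, (small_universe.n_genes, small_universe.n_genes), seed=2)
        flagged = set(list(small_universe.accessions)[:10])
        out = run_enrichment(flagged, ann, small_universe.accessions)
        assert out["enrichment_factor"].iloc[0] == 1.0
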