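"""Synthetic universe generator: determinism, planted structure, calibration."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from comorbnet.synthetic import (
    CovariateModel,
    PlantedPair,
    SynthConfig,
    coupled_universe,
    decoupled_universe,
    gen_claims,
    gen_eqtl_maps,
    gen_gwas_catalog,
    gen_ld_table,
    gen_ontology,
    generate_all,
    null_universe,
)


@pytest.fixture(scope="module")
def small_cfg() -> SynthConfig:
    return SynthConfig(
        seed=7,
        n_diseases=12,
        n_snps=60,
        n_rnas=400,
        n_tissues=3,
        n_patients=4000,
        planted_pairs=(
            PlantedPair(0, 1, shared_rna_count=5, comorbidity_log_odds=math.log(3)),
            PlantedPair(2, 3, shared_rna_count=4, tissue=2),
        ),
    )


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            SynthConfig(n_diseases=0)

    def test_planted_indices_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            PlantedPair(3, 3)

    def test_planted_indices_in_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SynthConfig(n_diseases=5, n_snps=10, planted_pairs=(PlantedPair(0, 7),))

    def test_log_odds_must_be_finite(self):
        with pytest.raises(ValueError, match="finite"):
            PlantedPair(0, 1, comorbidity_log_odds=float("inf"))


class TestGenOntology:
    def test_seed_determinism(self, small_cfg):
        o1 = gen_ontology(small_cfg)
        o2 = gen_ontology(small_cfg)
        assert o1.dag.edges == o2.dag.edges
        assert o1.term_to_codes == o2.term_to_codes
        assert o1.code_map == o2.code_map

    def test_minimal_single_disease_chain(self):
        cfg = SynthConfig(n_diseases=1, n_snps=1, alias_fraction=0.0)
        onto = gen_ontology(cfg)
        g = nx.DiGraph(onto.dag.edges)
        # a root plus one descendant chain down to the coded leaves
        assert nx.is_directed_acyclic_graph(g)
        assert onto.dag.root == "ROOT"
        assert all(len(codes) >= 1 for codes in onto.code_map.values())

    def test_dag_has_no_cycles_and_codes_map_to_leaves(self, small_cfg):
        onto = gen_ontology(small_cfg)
        g = nx.DiGraph(onto.dag.edges)
        assert nx.is_directed_acyclic_graph(g)
        for concept in onto.code_map:
            assert concept in onto.dag.leaves

    def test_every_disease_has_claim_codes(self, small_cfg):
        onto = gen_ontology(small_cfg)
        for term in onto.disease_terms:
            assert onto.claim_codes_for(term)


class TestGenGwasCatalog:
    def test_every_disease_present_and_row_count(self):
        cfg = SynthConfig(n_diseases=10, n_snps=50)
        cat = gen_gwas_catalog(cfg, gen_ontology(cfg))
        assert len(cat) == 50
        assert len(cat.bundles) == 10

    def test_planted_pair_diseases_share_no_snps(self, small_cfg):
        cat = gen_gwas_catalog(small_cfg, gen_ontology(small_cfg))
        for pp in small_cfg.planted_pairs:
            s_i = cat.snps_for(pp.bundle_pair[0])
            s_j = cat.snps_for(pp.bundle_pair[1])
            assert not (s_i & s_j)

    def test_seed_determinism(self, small_cfg):
        onto = gen_ontology(small_cfg)
        c1 = gen_gwas_catalog(small_cfg, onto)
        c2 = gen_gwas_catalog(small_cfg, onto)
        pd.testing.assert_frame_equal(c1.records, c2.records)


class TestGenEqtlMaps:
    def test_planted_overlap_contract(self, small_cfg):
        onto = gen_ontology(small_cfg)
        cat = gen_gwas_catalog(small_cfg, onto)
        tmaps = gen_eqtl_maps(small_cfg, cat)
        pp = small_cfg.planted_pairs[1]  # designated tissue 2
        tmap = tmaps[2]
        r_i = tmap.rnas_for_snps(cat.snps_for(pp.bundle_pair[0]))
        r_j = tmap.rnas_for_snps(cat.snps_for(pp.bundle_pair[1]))
        assert len(r_i & r_j) >= pp.shared_rna_count

    def test_one_map_per_tissue_with_backgrounds(self, small_cfg):
        onto = gen_ontology(small_cfg)
        cat = gen_gwas_catalog(small_cfg, onto)
        tmaps = gen_eqtl_maps(small_cfg, cat)
        assert len(tmaps) == small_cfg.n_tissues
        for tmap in tmaps:
            assert set(tmap.associations["rna_id"]) <= tmap.background_rnas

    def test_seed_determinism(self, small_cfg):
        onto = gen_ontology(small_cfg)
        cat = gen_gwas_catalog(small_cfg, onto)
        m1 = gen_eqtl_maps(small_cfg, cat)
        m2 = gen_eqtl_maps(small_cfg, cat)
        for a, b in zip(m1, m2):
            pd.testing.assert_frame_equal(a.associations, b.associations)
            assert a.background_rnas == b.background_rnas

    def test_null_overlaps_match_hypergeometric_expectation(self):
        # with uniform random wiring the overlap of two diseases' RNA sets
        # is hypergeometric: E[a] = |R||S| / |background|
        obs, exp = [], []
        for seed in range(100):
            cfg = SynthConfig(
                seed=seed, n_diseases=4, n_snps=40, n_rnas=300, n_tissues=1,
                snp_in_tissue_prob=1.0, mean_rnas_per_snp=3.0,
                background_frac=1.0, alias_fraction=0.0,
            )
            cat = gen_gwas_catalog(cfg, gen_ontology(cfg))
            tmap = gen_eqtl_maps(cfg, cat)[0]
            bundles = cat.bundles
            sets = {b: tmap.rnas_for_snps(cat.snps_for(b)) for b in bundles}
            for i, b1 in enumerate(bundles):
                for b2 in bundles[i + 1:]:
                    obs.append(len(sets[b1] & sets[b2]))
                    exp.append(len(sets[b1]) * len(sets[b2]) / len(tmap.background_rnas))
        obs, exp = np.asarray(obs, float), np.asarray(exp, float)
        diff = obs.mean() - exp.mean()
        mc_se = obs.std(ddof=1) / math.sqrt(len(obs))
        assert abs(diff) < 4 * mc_se + 0.05


class TestGenClaims:
    def test_seed_determinism(self, small_cfg):
        onto = gen_ontology(small_cfg)
        d1 = gen_claims(small_cfg, onto, "NIS", dataset_index=0)
        d2 = gen_claims(small_cfg, onto, "NIS", dataset_index=0)
        pd.testing.assert_frame_equal(d1.patients, d2.patients)
        pd.testing.assert_frame_equal(d1.diagnoses, d2.diagnoses)

    def test_datasets_differ_but_share_disease_params(self, small_cfg):
        onto = gen_ontology(small_cfg)
        d1 = gen_claims(small_cfg, onto, "NIS", dataset_index=0)
        d2 = gen_claims(small_cfg, onto, "NEDS", dataset_index=1)
        assert not d1.patients["age"].equals(d2.patients["age"])

    def test_missing_covariate_fraction(self):
        cfg = SynthConfig(seed=1, n_diseases=5, n_snps=20, n_patients=20000)
        onto = gen_ontology(cfg)
        ds = gen_claims(cfg, onto, "NIS", dataset_index=0)
        n_missing = ds.patients[["age", "sex", "race"]].isna().any(axis=1).sum()
        assert 0.005 < n_missing / len(ds.patients) < 0.02

    @staticmethod
    def _crude_or(cfg, pair):
        onto = gen_ontology(cfg)
        ds = gen_claims(cfg, onto, "NIS", dataset_index=0)
        d1, d2 = pair
        codes1 = set(onto.claim_codes_for(d1))
        codes2 = set(onto.claim_codes_for(d2))
        per_pat = ds.diagnoses.groupby("patient_id")["code"].agg(set)
        per_pat = per_pat.reindex(ds.patients["patient_id"], fill_value=frozenset())
        h1 = per_pat.map(lambda s: bool(s & codes1)).to_numpy()
        h2 = per_pat.map(lambda s: bool(s & codes2)).to_numpy()
        a = int((h1 & h2).sum())
        b = int((h1 & ~h2).sum())
        c = int((~h1 & h2).sum())
        d = int((~h1 & ~h2).sum())
        return (a * d) / (b * c)

    def test_planted_log_odds_yields_crude_or_near_three(self):
        cov = CovariateModel(
            prevalence_range=(0.05, 0.05), planted_prevalence_range=(0.05, 0.05)
        )
        cfg = SynthConfig(
            seed=11, n_diseases=4, n_snps=16, n_patients=100_000, covariates=cov,
            planted_pairs=(PlantedPair(0, 1, comorbidity_log_odds=math.log(3)),),
        )
        orat = self._crude_or(cfg, ("Disease_0000", "Disease_0001"))
        assert 2.6 <= orat <= 3.4

    def test_unplanted_pair_crude_or_near_one(self):
        cov = CovariateModel(
            prevalence_range=(0.05, 0.05), planted_prevalence_range=(0.05, 0.05)
        )
        cfg = SynthConfig(seed=12, n_diseases=4, n_snps=16, n_patients=100_000,
                          covariates=cov)
        orat = self._crude_or(cfg, ("Disease_0000", "Disease_0001"))
        assert 0.8 <= orat <= 1.25


class TestGenLdTable:
    def test_within_block_high_ld(self, small_cfg):
        cat = gen_gwas_catalog(small_cfg, gen_ontology(small_cfg))
        ld = gen_ld_table(small_cfg, cat)
        bundle = cat.bundles[0]
        snps = sorted(cat.snps_for(bundle))
        block = snps[: small_cfg.ld_block_size]
        for i, s1 in enumerate(block):
            for s2 in block[i + 1:]:
                assert ld.get(s1, s2) >= 0.8

    def test_self_ld_is_one(self, small_cfg):
        cat = gen_gwas_catalog(small_cfg, gen_ontology(small_cfg))
        ld = gen_ld_table(small_cfg, cat)
        for s in list(cat.all_snps)[:5]:
            assert ld.get(s, s) == 1.0

    def test_cross_block_entries_below_threshold(self, small_cfg):
        cat = gen_gwas_catalog(small_cfg, gen_ontology(small_cfg))
        ld = gen_ld_table(small_cfg, cat)
        by_bundle = {b: sorted(cat.snps_for(b)) for b in cat.bundles}
        k = small_cfg.ld_block_size
        block_of = {}
        for b, snps in by_bundle.items():
            for i, s in enumerate(snps):
                block_of[s] = (b, i // k)
        for (s1, s2), r2 in ld.items():
            if block_of[s1] != block_of[s2]:
                assert r2 < 0.8

    def test_seed_determinism(self, small_cfg):
        cat = gen_gwas_catalog(small_cfg, gen_ontology(small_cfg))
        l1 = gen_ld_table(small_cfg, cat)
        l2 = gen_ld_table(small_cfg, cat)
        assert dict(l1.items()) == dict(l2.items())


class TestGenerateAll:
    def test_full_regeneration_identical(self, small_cfg):
        d1 = generate_all(small_cfg)
        d2 = generate_all(small_cfg)
        pd.testing.assert_frame_equal(d1.catalog.records, d2.catalog.records)
        for a, b in zip(d1.tmaps, d2.tmaps):
            pd.testing.assert_frame_equal(a.associations, b.associations)
        for ds_id in d1.claims:
            pd.testing.assert_frame_equal(
                d1.claims[ds_id].patients, d2.claims[ds_id].patients
            )
        assert d1.molecular_truth == d2.molecular_truth

    def test_truth_sets_reflect_planted_effects(self, small_cfg):
        data = generate_all(small_cfg)
        assert data.molecular_truth == {
            ("Disease_0000", "Disease_0001"),
            ("Disease_0002", "Disease_0003"),
        }
        assert data.comorbid_truth == {("Disease_0000", "Disease_0001")}

    def test_bundles_carry_expanded_claim_codes(self, small_cfg):
        data = generate_all(small_cfg)
        mapped = [b for b in data.bundles if not b.unmapped]
        assert mapped and all(b.claim_codes for b in mapped)


class TestUniverseHelpers:
    def test_null_universe_has_no_planted_pairs(self):
        assert null_universe(0).planted_pairs == ()

    def test_coupled_universe_pairs_are_vertex_disjoint(self):
        cfg = coupled_universe(0, n_diseases=50, n_pairs=10)
        seen = set()
        for pp in cfg.planted_pairs:
            assert pp.disease_i not in seen and pp.disease_j not in seen
            seen.update((pp.disease_i, pp.disease_j))
            assert pp.shared_rna_count > 0
            assert pp.comorbidity_log_odds != 0.0

    def test_decoupled_universe_separates_effects(self):
        cfg = decoupled_universe(0, n_diseases=40, n_molecular=30, n_comorbid=30)
        n_mol = sum(pp.shared_rna_count > 0 for pp in cfg.planted_pairs)
        n_com = sum(pp.comorbidity_log_odds != 0 for pp in cfg.planted_pairs)
        assert n_mol == 30 and n_com == 30
        # independent sampling: coincidental double-planting is allowed but rare
        n_both = sum(
            pp.shared_rna_count > 0 and pp.comorbidity_log_odds != 0
            for pp in cfg.planted_pairs
        )
        assert n_both <= 10
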