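"""Directional comorbidity models: indicators, scan, dataset merging."""

import math

import numpy as np
import pandas as pd
import pytest

from comorbnet.comorbidity import (
    ClaimsDataset,
    DirectionalFit,
    build_indicators,
    comorbidity_scan,
    merge_datasets,
)
from comorbnet.ontology import DiseaseBundle
from comorbnet.synthetic import (
    CovariateModel,
    PlantedPair,
    SynthConfig,
    generate_all,
)


def _bundle(bid, codes):
    return DiseaseBundle(
        bundle_id=bid,
        member_terms=frozenset({bid}),
        ontology_codes=frozenset({f"C_{bid}"}),
        claim_codes=frozenset(codes),
    )


def _tiny_claims():
    patients = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4"],
            "age": [40.0, 60.0, np.nan, 30.0],
            "sex": [0.0, 1.0, 1.0, np.nan],
            "race": ["race0", "race1", "race0", "race0"],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p2", "p4"],
            "code": ["x1", "x1", "y1", "y1"],
        }
    )
    return ClaimsDataset("T", patients, diagnoses)


class TestClaimsDataset:
    def test_duplicate_patient_ids_rejected(self):
        pats = pd.DataFrame(
            {"patient_id": ["p", "p"], "age": [1.0, 2.0], "sex": [0, 1], "race": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            ClaimsDataset("T", pats, pd.DataFrame({"patient_id": [], "code": []}))


class TestBuildIndicators:
    def test_code_membership_sets_indicator(self):
        ds = _tiny_claims()
        data = build_indicators(ds, [_bundle("B1", ["x1"]), _bundle("B2", ["y1"])])
        # p3 (missing age) and p4 (missing sex) are excluded
        assert data.n_excluded == 2
        assert list(data.indicators.index) == ["p1", "p2"]
        assert data.indicators.loc["p1", "B1"] == 1
        assert data.indicators.loc["p1", "B2"] == 0
        assert data.indicators.loc["p2", "B2"] == 1

    def test_bundle_without_claim_codes_flagged_untestable(self):
        ds = _tiny_claims()
        data = build_indicators(ds, [_bundle("B1", ["x1"]), _bundle("B0", [])])
        assert data.untestable == ["B0"]
        assert (data.indicators["B0"] == 0).all()

    def test_empty_dataset_rejected(self):
        ds = ClaimsDataset(
            "E",
            pd.DataFrame({"patient_id": [], "age": [], "sex": [], "race": []}),
            pd.DataFrame({"patient_id": [], "code": []}),
        )
        with pytest.raises(ValueError, match="empty"):
            build_indicators(ds, [_bundle("B1", ["x1"])])

    def test_design_has_intercept_age_sex_race(self):
        ds = _tiny_claims()
        data = build_indicators(ds, [_bundle("B1", ["x1"])])
        assert list(data.design.columns[:3]) == ["const", "age", "sex"]
        assert (data.design["const"] == 1.0).all()
        # standardized age has mean ~0
        assert data.design["age"].mean() == pytest.approx(0.0, abs=1e-12)


def _planted_cfg(seed, log_or=math.log(3.0), n_patients=60_000):
    cov = CovariateModel(
        prevalence_range=(0.05, 0.05), planted_prevalence_range=(0.05, 0.05)
    )
    return SynthConfig(
        seed=seed, n_diseases=6, n_snps=24, n_patients=n_patients, covariates=cov,
        planted_pairs=(PlantedPair(0, 1, comorbidity_log_odds=log_or),)
        if log_or
        else (),
    )


class TestComorbidityScan:
    def test_recovers_planted_conditional_or(self):
        cfg = _planted_cfg(21)
        data = generate_all(cfg)
        fits = comorbidity_scan(data.claims["NIS"], data.bundles)
        pair = ("Disease_0000", "Disease_0001")
        both = [f for f in fits if f.pair == pair]
        assert len(both) == 2  # two directions
        for f in both:
            assert f.converged
            assert 2.6 <= f.odds_ratio <= 3.4
            assert f.fdr < 0.05

    def test_min_cases_excludes_rare_bundles(self):
        cfg = _planted_cfg(22, n_patients=20_000)
        data = generate_all(cfg)
        fits = comorbidity_scan(
            data.claims["NIS"], data.bundles, min_cases=5_000
        )
        assert fits == []  # 5% prevalence cannot reach 5000 of ~20000

    def test_min_cases_validation(self):
        cfg = _planted_cfg(23, n_patients=2_000)
        data = generate_all(cfg)
        with pytest.raises(ValueError, match="min_cases"):
            comorbidity_scan(data.claims["NIS"], data.bundles, min_cases=0)

    def test_direction_labels_cover_both_orientations(self):
        cfg = _planted_cfg(24, n_patients=20_000)
        data = generate_all(cfg)
        fits = comorbidity_scan(data.claims["NIS"], data.bundles)
        by_pair = {}
        for f in fits:
            by_pair.setdefault(f.pair, set()).add(f.response)
        for pair, responses in by_pair.items():
            assert responses == set(pair)

    def test_adjustment_beats_crude_or_under_confounding(self):
        # age drives both diseases hard: the crude 2x2 OR is inflated, the
        # covariate-adjusted estimate stays near the planted conditional OR
        cov = CovariateModel(
            prevalence_range=(0.05, 0.05),
            planted_prevalence_range=(0.05, 0.05),
            age_beta=1.5,
            sex_beta=0.0,
            race_betas=(0.0, 0.0, 0.0),
        )
        cfg = SynthConfig(
            seed=25, n_diseases=4, n_snps=16, n_patients=80_000, covariates=cov,
            planted_pairs=(PlantedPair(0, 1, comorbidity_log_odds=math.log(2.0)),),
        )
        data = generate_all(cfg)
        ds = data.claims["NIS"]
        ind = build_indicators(ds, data.bundles)
        h1 = ind.indicators["Disease_0000"].to_numpy(bool)
        h2 = ind.indicators["Disease_0001"].to_numpy(bool)
        a, b = (h1 & h2).sum(), (h1 & ~h2).sum()
        c, d = (~h1 & h2).sum(), (~h1 & ~h2).sum()
        crude = (a * d) / (b * c)
        fits = comorbidity_scan(ds, data.bundles, indicators=ind)
        adj = [f.odds_ratio for f in fits if f.pair == ("Disease_0000", "Disease_0001")]
        planted = 2.0
        assert crude > planted * 1.15  # confounding inflates the crude estimate
        for orat in adj:
            assert abs(math.log(orat) - math.log(planted)) < abs(
                math.log(crude) - math.log(planted)
            )


def _fit(ds, pair, resp, beta, p, fdr, converged=True):
    return DirectionalFit(
        dataset_id=ds, pair=pair, response=resp,
        exposure=pair[0] if resp == pair[1] else pair[1],
        beta=beta, se=0.1, p_value=p, converged=converged,
        separation=not converged, fdr=fdr,
    )


class TestMergeDatasets:
    def test_significant_in_one_dataset_suffices(self):
        pair = ("A", "B")
        ds1 = [_fit("NIS", pair, "A", math.log(2.5), 1e-6, 1e-5)]
        ds2 = [_fit("NEDS", pair, "A", math.log(1.1), 0.5, 0.8)]
        [res] = merge_datasets([ds1, ds2], fdr_cut=0.05, or_cut=1.5)
        assert res.significant
        assert res.fdr_comorbidity == pytest.approx(1e-5)

    def test_pair_or_is_max_of_directional_ors(self):
        pair = ("A", "B")
        fits = [
            _fit("NIS", pair, "A", math.log(2.0), 1e-4, 1e-3),
            _fit("NIS", pair, "B", math.log(3.5), 1e-5, 1e-4),
        ]
        [res] = merge_datasets([fits])
        assert res.pair_or == pytest.approx(3.5)

    def test_or_cut_and_fdr_must_hold_in_same_record(self):
        pair = ("A", "B")
        fits = [
            _fit("NIS", pair, "A", math.log(1.2), 1e-6, 1e-5),  # strong p, weak OR
            _fit("NIS", pair, "B", math.log(4.0), 0.2, 0.6),  # strong OR, weak p
        ]
        [res] = merge_datasets([fits], fdr_cut=0.05, or_cut=1.5)
        assert not res.significant

    def test_all_fits_nonconverged_drops_pair(self, caplog):
        pair = ("A", "B")
        fits = [_fit("NIS", pair, "A", 25.0, float("nan"), float("nan"), converged=False)]
        import logging

        with caplog.at_level(logging.INFO, logger="comorbnet.comorbidity"):
            out = merge_datasets([fits])
        assert out == []

    def test_no_datasets_rejected(self):
        with pytest.raises(ValueError, match="no datasets"):
            merge_datasets([])

    def test_pair_decision_invariant_to_label_order(self):
        cfg = _planted_cfg(26, n_patients=20_000)
        data = generate_all(cfg)
        fits = comorbidity_scan(data.claims["NIS"], data.bundles)
        [resA] = [
            r for r in merge_datasets([fits])
            if r.pair == ("Disease_0000", "Disease_0001")
        ]
        # relabel: swap the two diseases everywhere
        swapped = []
        for f in fits:
            sw = {"Disease_0000": "Disease_0001", "Disease_0001": "Disease_0000"}
            p = tuple(sorted(sw.get(x, x) for x in f.pair))
            swapped.append(
                DirectionalFit(
                    dataset_id=f.dataset_id, pair=p,
                    response=sw.get(f.response, f.response),
                    exposure=sw.get(f.exposure, f.exposure),
                    beta=f.beta, se=f.se, p_value=f.p_value,
                    converged=f.converged, separation=f.separation, fdr=f.fdr,
                )
            )
        [resB] = [
            r for r in merge_datasets([swapped])
            if r.pair == ("Disease_0000", "Disease_0001")
        ]
        assert resA.significant == resB.significant
        assert resA.pair_or == pytest.approx(resB.pair_or)
        assert resA.fdr_comorbidity == pytest.approx(resB.fdr_comorbidity)
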