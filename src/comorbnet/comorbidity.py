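"""Directional comorbidity scan on claims datasets.

For every unordered pair of disease bundles (D1, D2) two logistic models
are fitted on patient-level indicator data:

    logit P(D1) = b10 + b11*D2 + b12*race + b13*sex + b14*age
    logit P(D2) = b20 + b21*D1 + b22*race + b23*sex + b24*age

The exposure coefficients b11 / b21 quantify the directional comorbidity
risk adjusted for demographic confounders.  p-values from both directions
and all pairs are Benjamini-Hochberg adjusted jointly within a dataset;
results from two independent claims datasets are then merged, a pair being
called comorbid when any direction in any dataset passes the FDR and
odds-ratio cuts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ontology import DiseaseBundle
from .stats import batched_exposure_irls, bh_adjust, irls_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "ClaimsDataset",
    "IndicatorData",
    "DirectionalFit",
    "ComorbidityResult",
    "build_indicators",
    "comorbidity_scan",
    "merge_datasets",
]

REQUIRED_COVARIATES = ("age", "sex", "race")


class ClaimsDataset:
    """Per-patient diagnosis codes plus demographic covariates.

    ``patients`` has columns (patient_id, age, sex, race); missing
    covariates are NaN/None.  ``diagnoses`` is long format
    (patient_id, code).
    """

    def __init__(self, dataset_id: str, patients: pd.DataFrame, diagnoses: pd.DataFrame):
        if patients["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_ids")
        missing_cols = {"patient_id", "age", "sex", "race"} - set(patients.columns)
        if missing_cols:
            raise ValueError(f"patients table missing columns {sorted(missing_cols)}")
        self.dataset_id = dataset_id
        self.patients = patients.reset_index(drop=True)
        self.diagnoses = diagnoses.reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class IndicatorData:
    """Per-patient bundle indicators and covariate design for one dataset.

    Patients with any missing required covariate are excluded up front and
    counted in ``n_excluded``.  ``indicators`` is patients x bundles (0/1);
    ``design`` holds intercept, standardized age, sex, and one-hot race
    with the largest level as reference.  Bundles with no claim codes are
    listed in ``untestable``.
    """

    dataset_id: str
    indicators: pd.DataFrame
    design: pd.DataFrame
    n_excluded: int
    untestable: list[str]

    @property
    def case_counts(self) -> pd.Series:
        return self.indicators.sum(axis=0)


def build_indicators(ds: ClaimsDataset, bundles: list[DiseaseBundle]) -> IndicatorData:
    """Build 0/1 bundle indicators and the covariate design matrix.

    A patient is positive for a bundle when at least one of their billing
    codes belongs to the bundle's claim codes.
    """
    if ds.n_patients == 0:
        raise ValueError(f"dataset {ds.dataset_id} is empty")
    pats = ds.patients
    keep = pats[list(REQUIRED_COVARIATES)].notna().all(axis=1)
    n_excluded = int((~keep).sum())
    kept = pats.loc[keep].set_index("patient_id")

    untestable = [b.bundle_id for b in bundles if not b.claim_codes]
    code_to_bundle: dict[str, list[str]] = {}
    for b in bundles:
        for code in b.claim_codes:
            code_to_bundle.setdefault(code, []).append(b.bundle_id)

    dx = ds.diagnoses[ds.diagnoses["patient_id"].isin(kept.index)]
    hits = (
        dx.assign(bundle=dx["code"].map(code_to_bundle))
        .explode("bundle")
        .dropna(subset=["bundle"])
    )
    bundle_ids = [b.bundle_id for b in bundles]
    mat = np.zeros((len(kept), len(bundle_ids)), dtype=np.int8)
    if len(hits):
        row_of = pd.Series(np.arange(len(kept)), index=kept.index)
        col_of = pd.Series(np.arange(len(bundle_ids)), index=bundle_ids)
        mat[row_of[hits["patient_id"]].to_numpy(), col_of[hits["bundle"]].to_numpy()] = 1
    ind = pd.DataFrame(mat, index=kept.index, columns=bundle_ids)

    age = kept["age"].astype(float)
    age_std = (age - age.mean()) / (age.std(ddof=0) or 1.0)
    race = kept["race"].astype(str)
    ref = race.value_counts().idxmax()
    race_dummies = pd.get_dummies(race, prefix="race", dtype=float)
    race_dummies = race_dummies.drop(columns=f"race_{ref}")
    design = pd.concat(
        [
            pd.Series(1.0, index=kept.index, name="const"),
            age_std.rename("age"),
            kept["sex"].astype(float).rename("sex"),
            race_dummies,
        ],
        axis=1,
    )
    return IndicatorData(
        dataset_id=ds.dataset_id,
        indicators=ind,
        design=design,
        n_excluded=n_excluded,
        untestable=untestable,
    )


@dataclass
class DirectionalFit:
    """One directional logistic fit: ``response ~ exposure + covariates``."""

    dataset_id: str
    pair: tuple[str, str]
    response: str
    exposure: str
    beta: float
    se: float
    p_value: float
    converged: bool
    separation: bool
    fdr: float = float("nan")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def comorbidity_scan(
    ds: ClaimsDataset,
    bundles: list[DiseaseBundle],
    min_cases: int = 100,
    indicators: IndicatorData | None = None,
) -> list[DirectionalFit]:
    """Fit both directional models for every testable bundle pair.

    A bundle is testable when it has claim codes and at least
    ``min_cases`` positive patients (rarer bundles yield separation-prone
    fits).  Exposure-coefficient p-values from both directions of all
    pairs are BH-adjusted jointly; non-converged fits are recorded but
    excluded from the adjustment.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    data = indicators if indicators is not None else build_indicators(ds, bundles)
    counts = data.case_counts
    n = len(data.design)
    testable = [
        b for b in data.indicators.columns
        if b not in data.untestable and min_cases <= counts[b] <= n - min_cases
    ]
    C = np.ascontiguousarray(data.design.to_numpy(dtype=float))
    ind = {b: np.ascontiguousarray(data.indicators[b].to_numpy(dtype=float)) for b in testable}
    k = C.shape[1]

    # covariate-only fit per response disease: warm start for all its pair models
    base_beta: dict[str, np.ndarray] = {}
    for b in testable:
        beta, _, conv, _ = irls_logistic(ind[b], C)
        base_beta[b] = beta if conv else np.zeros(k)

    # one batched IRLS group per response disease: all partner exposures at once
    fits: list[DirectionalFit] = []
    for resp in testable:
        partners = [b for b in testable if b != resp]
        if not partners:
            continue
        E = np.column_stack([ind[b] for b in partners])
        start = np.tile(np.append(base_beta[resp], 0.0), (len(partners), 1))
        beta, se, conv, sep = batched_exposure_irls(ind[resp], C, E, start=start)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[:, k] / se[:, k]
            pvals = 2.0 * norm.sf(np.abs(z))
        for m, expo in enumerate(partners):
            fits.append(
                DirectionalFit(
                    dataset_id=ds.dataset_id,
                    pair=(resp, expo) if resp < expo else (expo, resp),
                    response=resp,
                    exposure=expo,
                    beta=float(beta[m, k]),
                    se=float(se[m, k]),
                    p_value=float(pvals[m]) if conv[m] else float("nan"),
                    converged=bool(conv[m]),
                    separation=bool(sep[m]),
                )
            )
    fits.sort(key=lambda f: (f.pair, f.response))
    ok = [f for f in fits if f.converged and np.isfinite(f.p_value)]
    if ok:
        adj = bh_adjust([f.p_value for f in ok])
        for f, q in zip(ok, adj):
            f.fdr = float(q)
    n_bad = len(fits) - len(ok)
    if n_bad:
        logger.info(
            "%s: %d of %d directional fits non-converged/separated",
            ds.dataset_id, n_bad, len(fits),
        )
    return fits


@dataclass
class ComorbidityResult:
    """Pair-level comorbidity verdict merged across datasets.

    ``pair_or`` is the maximum directional odds ratio among converged
    fits; ``fdr_comorbidity`` the minimum directional FDR over datasets
    (the best p-value is what gets reported).
    """

    pair: tuple[str, str]
    directional: list[DirectionalFit] = field(default_factory=list)
    pair_or: float = float("nan")
    fdr_comorbidity: float = float("nan")
    significant: bool = False


def merge_datasets(
    results_per_dataset: list[list[DirectionalFit]],
    fdr_cut: float = 0.05,
    or_cut: float = 1.5,
) -> list[ComorbidityResult]:
    """Merge directional scans from one or more claims datasets.

    A pair is significant when *any* direction in *any* dataset has
    ``fdr < fdr_cut`` and odds ratio above ``or_cut``.  Pairs whose fits
    all failed to converge are dropped (logged).
    """
    if not results_per_dataset:
        raise ValueError("no datasets scanned")
    by_pair: dict[tuple[str, str], list[DirectionalFit]] = {}
    for fits in results_per_dataset:
        for f in fits:
            by_pair.setdefault(f.pair, []).append(f)
    out: list[ComorbidityResult] = []
    n_dropped = 0
    for pair in sorted(by_pair):
        fits = by_pair[pair]
        ok = [f for f in fits if f.converged]
        if not ok:
            n_dropped += 1
            continue
        pair_or = max(f.odds_ratio for f in ok)
        fdr = min(f.fdr for f in ok)
        sig = any(f.fdr < fdr_cut and f.odds_ratio > or_cut for f in ok)
        out.append(
            ComorbidityResult(
                pair=pair,
                directional=fits,
                pair_or=pair_or,
                fdr_comorbidity=fdr,
                significant=sig,
            )
        )
    if n_dropped:
        logger.info("%d pairs dropped: no converged fit in any dataset", n_dropped)
    return out
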