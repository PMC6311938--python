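"""Synthetic study universe with planted convergence and comorbidity.

Real counterparts of the five inputs (GWAS catalog, per-tissue eQTL
tables, hospital claims, a clinical ontology with code mappings, and a
pairwise LD table) are access-restricted, so every downstream stage is
exercised on generated data with known ground truth:

* *molecular* structure is planted by wiring the GWAS SNPs of selected
  disease pairs to a common set of eQTL RNAs in one designated tissue;
* *clinical* structure is planted as a conditional log-odds between the
  disease indicators of selected pairs in the simulated claims, on top of
  shared demographic confounders (age, sex, race);
* coupling the two plantings on the same pairs creates a universe where
  molecular convergence predicts comorbidity; planting them on disjoint
  pairs (or not at all) creates decoupled / null universes for
  calibration checks.

All generators are deterministic functions of ``SynthConfig.seed``;
independent substreams keep each artifact byte-identical under a fixed
seed regardless of which others are generated.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .comorbidity import ClaimsDataset
from .convergence import EqtlTissueMap, GwasCatalog
from .network import LdTable
from .ontology import DiseaseBundle, OntologyDag, expand_claim_codes, merge_bundles

__all__ = [
    "PlantedPair",
    "CovariateModel",
    "SynthConfig",
    "SyntheticOntology",
    "SyntheticData",
    "gen_ontology",
    "gen_gwas_catalog",
    "gen_eqtl_maps",
    "gen_claims",
    "gen_ld_table",
    "generate_all",
    "null_universe",
    "coupled_universe",
    "decoupled_universe",
]

# substream keys — one per artifact so regeneration is independent
_S_ONTOLOGY, _S_GWAS, _S_EQTL, _S_PARAMS, _S_LD, _S_PAIRS, _S_CLAIMS = 0, 1, 2, 3, 4, 5, 10


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def disease_name(i: int) -> str:
    return f"Disease_{i:04d}"


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth structure planted between two diseases.

    ``shared_rna_count`` > 0 plants molecular convergence in one tissue;
    a non-zero ``comorbidity_log_odds`` plants a conditional association
    between the two disease indicators in the claims data.  Pairs are
    canonical: ``disease_i < disease_j``.
    """

    disease_i: int
    disease_j: int
    shared_rna_count: int = 0
    comorbidity_log_odds: float = 0.0
    tissue: int | None = None

    def __post_init__(self) -> None:
        if self.disease_i == self.disease_j:
            raise ValueError("planted pair indices must be distinct")
        if self.disease_i > self.disease_j:
            raise ValueError("planted pairs must be canonical (disease_i < disease_j)")
        if self.shared_rna_count < 0:
            raise ValueError("shared_rna_count must be >= 0")
        if not math.isfinite(self.comorbidity_log_odds):
            raise ValueError("comorbidity_log_odds must be finite")

    @property
    def bundle_pair(self) -> tuple[str, str]:
        return (disease_name(self.disease_i), disease_name(self.disease_j))


@dataclass(frozen=True)
class CovariateModel:
    """Demographic covariate model of the simulated claims.

    Disease prevalence is drawn log-uniformly per disease from
    ``prevalence_range`` (claims diseases span orders of magnitude in
    frequency); diseases carrying a planted comorbidity draw from the
    upper ``planted_prevalence_range`` so the planted effect is
    observable at realistic sample sizes.  Effects are on the logit
    scale: age per SD of the 18-90 uniform age distribution, sex for the
    0/1 indicator, race per non-reference level (4 levels).  A small
    fraction of patients lacks one required covariate, exercising the
    complete-case exclusion rule.
    """

    prevalence_range: tuple[float, float] = (0.01, 0.10)
    planted_prevalence_range: tuple[float, float] = (0.04, 0.10)
    age_beta: float = 0.3
    sex_beta: float = 0.2
    race_betas: tuple[float, ...] = (0.2, -0.1, 0.1)
    race_probs: tuple[float, ...] = (0.6, 0.2, 0.1, 0.1)
    missing_fraction: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.prevalence_range, self.planted_prevalence_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("prevalence ranges must satisfy 0 < lo <= hi < 1")
        if len(self.race_probs) != len(self.race_betas) + 1:
            raise ValueError("race_probs must have one more level than race_betas")
        if abs(sum(self.race_probs) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SynthConfig:
    """Scale and ground-truth parameters of the synthetic universe.

    Default scale is a reduced echo of the real study universe (hundreds
    of disease bundles with thousands of associated SNPs): tens of
    diseases, ~10 SNPs per disease, a few thousand background RNAs, a
    handful of tissues, tens of thousands of patients per claims dataset.
    """

    seed: int = 0
    n_diseases: int = 40
    n_snps: int = 400
    n_rnas: int = 2000
    n_tissues: int = 5
    n_patients: int = 20_000
    planted_pairs: tuple[PlantedPair, ...] = ()
    covariates: CovariateModel = field(default_factory=CovariateModel)
    ld_block_size: int = 3
    snp_in_tissue_prob: float = 0.85
    mean_rnas_per_snp: float = 2.0
    background_frac: float = 0.9
    intergenic_frac: float = 0.5
    alias_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_diseases", "n_snps", "n_rnas", "n_tissues", "n_patients", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_snps < self.n_diseases:
            raise ValueError("need at least one SNP per disease")
        for pp in self.planted_pairs:
            for idx in (pp.disease_i, pp.disease_j):
                if not (0 <= idx < self.n_diseases):
                    raise ValueError(f"planted disease index {idx} out of range")
            if pp.tissue is not None and not (0 <= pp.tissue < self.n_tissues):
                raise ValueError(f"planted tissue {pp.tissue} out of range")

    def planted_tissue(self, pp: PlantedPair) -> int:
        """Designated tissue of a planted pair (explicit or round-robin)."""
        if pp.tissue is not None:
            return pp.tissue
        return self.planted_pairs.index(pp) % self.n_tissues


@dataclass
class SyntheticOntology:
    """The generated clinical ontology plus its mapping tables."""

    dag: OntologyDag
    term_to_codes: dict[str, set]
    code_map: dict[str, list[str]]
    disease_terms: list[str]
    disease_concepts: dict[str, str]
    class_of: dict[str, str]

    def claim_codes_for(self, term: str) -> list[str]:
        """All claim codes under a disease's concept (descendant closure)."""
        concept = self.disease_concepts[term]
        codes: set = set(self.code_map.get(concept, ()))
        for c in self.dag.descendants(concept):
            codes.update(self.code_map.get(c, ()))
        return sorted(codes)


def gen_ontology(cfg: SynthConfig) -> SyntheticOntology:
    """Generate the rooted disease-concept DAG and its mapping tables.

    Layout: a root, ~one organ-system class node per 10 diseases, one
    concept per disease under a class (occasionally two classes, making
    the graph a proper DAG rather than a tree), and 1-3 leaf concepts per
    disease each carrying a synthetic ICD-like claim code.
    """
    rng = _rng(cfg.seed, _S_ONTOLOGY)
    n = cfg.n_diseases
    n_classes = max(1, math.ceil(n / 10))
    classes = [f"SYS{k:02d}" for k in range(n_classes)]
    edges: list[tuple[str, str]] = [(c, "ROOT") for c in classes]

    term_to_codes: dict[str, set] = {}
    code_map: dict[str, list[str]] = {}
    disease_terms: list[str] = []
    disease_concepts: dict[str, str] = {}
    class_of: dict[str, str] = {}
    cls_idx = rng.integers(0, n_classes, size=n)
    second_parent = rng.random(n) < 0.1
    n_leaves = rng.integers(1, 4, size=n)
    alias_mask = rng.random(n) < cfg.alias_fraction
    for i in range(n):
        term = disease_name(i)
        concept = f"C{i:04d}"
        edges.append((concept, classes[cls_idx[i]]))
        if second_parent[i] and n_classes > 1:
            other = (cls_idx[i] + 1 + rng.integers(0, n_classes - 1)) % n_classes
            edges.append((concept, classes[other]))
        for j in range(n_leaves[i]):
            leaf = f"{concept}.L{j}"
            edges.append((leaf, concept))
            code_map[leaf] = [f"{i:03d}.{j}"]
        term_to_codes[term] = {concept}
        if alias_mask[i]:
            term_to_codes[f"{term} (clinical subtype)"] = {concept}
        disease_terms.append(term)
        disease_concepts[term] = concept
        class_of[term] = classes[cls_idx[i]]
    dag = OntologyDag(edges)
    return SyntheticOntology(
        dag=dag,
        term_to_codes=term_to_codes,
        code_map=code_map,
        disease_terms=disease_terms,
        disease_concepts=disease_concepts,
        class_of=class_of,
    )


def gen_gwas_catalog(cfg: SynthConfig, onto: SyntheticOntology) -> GwasCatalog:
    """Disease -> SNP association table.

    SNPs are partitioned among diseases (each disease gets at least one),
    so the diseases of a planted pair never share a SNP: any RNA-set
    overlap must arise downstream, through the eQTL layer.
    """
    rng = _rng(cfg.seed, _S_GWAS)
    n, m = cfg.n_diseases, cfg.n_snps
    extra = rng.multinomial(m - n, np.full(n, 1.0 / n))
    counts = 1 + extra
    rows = []
    snp_idx = 0
    for i in range(n):
        term = disease_name(i)
        for _ in range(counts[i]):
            rows.append(
                {
                    "bundle_id": term,
                    "snp_id": f"rs{100000 + snp_idx}",
                    "intergenic": bool(rng.random() < cfg.intergenic_frac),
                }
            )
            snp_idx += 1
    return GwasCatalog(pd.DataFrame(rows))


def gen_eqtl_maps(cfg: SynthConfig, catalog: GwasCatalog) -> list[EqtlTissueMap]:
    """Per-tissue SNP -> RNA association tables (pre-thresholded).

    Background wiring is uniform: each SNP present in a tissue regulates
    a Poisson number of RNAs drawn uniformly from the tissue's expressed
    background.  For every planted pair, one SNP of each disease is
    additionally wired to ``shared_rna_count`` common RNAs in the pair's
    designated tissue, so the two diseases' RNA sets overlap there by
    construction.  A nominal p-value column (uniform below the upstream
    0.2 cut) is emitted for interface realism only.
    """
    rng = _rng(cfg.seed, _S_EQTL)
    universe = np.array([f"R{j:05d}" for j in range(cfg.n_rnas)])
    snps = sorted(catalog.all_snps)
    maps: list[EqtlTissueMap] = []
    for t in range(cfg.n_tissues):
        tissue = f"tissue{t:02d}"
        bg_size = max(1, int(round(cfg.background_frac * cfg.n_rnas)))
        background = rng.choice(universe, size=bg_size, replace=False)
        background.sort()
        present = np.array(snps)[rng.random(len(snps)) < cfg.snp_in_tissue_prob]
        k_per_snp = rng.poisson(cfg.mean_rnas_per_snp, size=len(present))
        snp_col: list[str] = []
        rna_col: list[str] = []
        for s, k in zip(present, k_per_snp):
            if k == 0:
                continue
            chosen = rng.choice(background, size=min(k, bg_size), replace=False)
            snp_col.extend([s] * len(chosen))
            rna_col.extend(chosen)
        for pp in cfg.planted_pairs:
            if pp.shared_rna_count == 0 or cfg.planted_tissue(pp) != t:
                continue
            shared = rng.choice(background, size=pp.shared_rna_count, replace=False)
            for idx in (pp.disease_i, pp.disease_j):
                d_snps = sorted(catalog.snps_for(disease_name(idx)))
                anchor = d_snps[rng.integers(0, len(d_snps))]
                snp_col.extend([anchor] * len(shared))
                rna_col.extend(shared)
        df = pd.DataFrame({"snp_id": snp_col, "rna_id": rna_col})
        df["kind"] = np.where(rng.random(len(df)) < 0.3, "cis", "trans")
        df["p_value"] = rng.uniform(0.0, 0.2, size=len(df))
        maps.append(EqtlTissueMap(tissue, df, background))
    return maps


def _disease_params(cfg: SynthConfig) -> np.ndarray:
    """Per-disease prevalence, shared across claims datasets."""
    rng = _rng(cfg.seed, _S_PARAMS)
    cov = cfg.covariates
    lo, hi = cov.prevalence_range
    prev = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_diseases))
    # every disease touched by any planting draws from the upper range, so
    # testability is identical across coupled/decoupled universe designs
    planted = {
        idx for pp in cfg.planted_pairs for idx in (pp.disease_i, pp.disease_j)
    }
    if planted:
        plo, phi = cov.planted_prevalence_range
        draws = np.exp(rng.uniform(np.log(plo), np.log(phi), size=len(planted)))
        for k, idx in enumerate(sorted(planted)):
            prev[idx] = draws[k]
    return prev


def gen_claims(
    cfg: SynthConfig,
    onto: SyntheticOntology,
    dataset_id: str,
    dataset_index: int | None = None,
) -> ClaimsDataset:
    """Simulate one claims dataset (HCUP-like inpatient/ED sample).

    Disease indicators follow the directional logistic model: each
    disease's logit is its base prevalence plus demographic effects, and
    the higher-index disease of a planted pair receives an extra
    ``comorbidity_log_odds`` term from its partner's (centred) indicator,
    so the planted value is the conditional log-odds given covariates.
    Patients positive for a disease receive 1-2 of its claim codes; a
    configurable fraction of patients has one missing covariate.
    """
    if dataset_index is None:
        dataset_index = zlib.crc32(dataset_id.encode()) % 997
    rng = _rng(cfg.seed, _S_CLAIMS + dataset_index)
    cov = cfg.covariates
    n = cfg.n_patients
    nd = cfg.n_diseases

    age = rng.uniform(18.0, 90.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    race = rng.choice(len(cov.race_probs), size=n, p=cov.race_probs)
    age_std = (age - 54.0) / ((90.0 - 18.0) / math.sqrt(12.0))
    race_beta = np.array([0.0, *cov.race_betas])
    race_beta = race_beta - race_beta @ np.asarray(cov.race_probs)
    base_logit = (
        cov.age_beta * age_std
        + cov.sex_beta * (sex - 0.5)
        + race_beta[race]
    )

    prev = _disease_params(cfg)
    parents: dict[int, list[tuple[int, float]]] = {}
    for pp in cfg.planted_pairs:
        if pp.comorbidity_log_odds != 0.0:
            parents.setdefault(pp.disease_j, []).append(
                (pp.disease_i, pp.comorbidity_log_odds)
            )
    indicators = np.zeros((n, nd), dtype=bool)
    for d in range(nd):
        eta = logit(prev[d]) + base_logit
        for src, beta in parents.get(d, ()):
            eta = eta + beta * (indicators[:, src] - prev[src])
        indicators[:, d] = rng.random(n) < expit(eta)

    pat_ids = np.array([f"{dataset_id}_{i:06d}" for i in range(n)])
    dx_pat: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []
    for d in range(nd):
        codes = onto.claim_codes_for(onto.disease_terms[d])
        idx = np.flatnonzero(indicators[:, d])
        if len(idx) == 0 or not codes:
            continue
        codes_arr = np.array(codes)
        dx_pat.append(pat_ids[idx])
        dx_code.append(codes_arr[rng.integers(0, len(codes_arr), size=len(idx))])
        if len(codes_arr) > 1:  # some visits file a second, more specific code
            extra = idx[rng.random(len(idx)) < 0.3]
            if len(extra):
                dx_pat.append(pat_ids[extra])
                dx_code.append(codes_arr[rng.integers(0, len(codes_arr), size=len(extra))])
    diagnoses = pd.DataFrame(
        {
            "patient_id": np.concatenate(dx_pat) if dx_pat else np.array([], dtype=str),
            "code": np.concatenate(dx_code) if dx_code else np.array([], dtype=str),
        }
    ).drop_duplicates()

    age_out = age.copy()
    sex_out = sex.copy()
    race_out = np.array([f"race{r}" for r in race], dtype=object)
    missing = rng.random(n) < cov.missing_fraction
    which = rng.integers(0, 3, size=n)
    age_out[missing & (which == 0)] = np.nan
    sex_out[missing & (which == 1)] = np.nan
    race_out[missing & (which == 2)] = np.nan
    patients = pd.DataFrame(
        {
            "patient_id": pat_ids,
            "age": age_out,
            "sex": sex_out,
            "race": race_out,
        }
    )
    return ClaimsDataset(dataset_id, patients, diagnoses)


def gen_ld_table(cfg: SynthConfig, catalog: GwasCatalog) -> LdTable:
    """Pairwise LD r^2 with planted block structure.

    Each disease's SNPs are chunked into consecutive blocks of
    ``ld_block_size``; within a block r^2 is uniform on [0.8, 1), across
    blocks occasional weak entries below 0.8 are added.
    """
    rng = _rng(cfg.seed, _S_LD)
    ld = LdTable()
    for bundle in catalog.bundles:
        snps = sorted(catalog.snps_for(bundle))
        blocks = [
            snps[k : k + cfg.ld_block_size]
            for k in range(0, len(snps), cfg.ld_block_size)
        ]
        for block in blocks:
            for i, s1 in enumerate(block):
                for s2 in block[i + 1 :]:
                    ld.set(s1, s2, float(rng.uniform(0.8, 1.0 - 1e-9)))
        for bi, b1 in enumerate(blocks):
            for b2 in blocks[bi + 1 :]:
                if rng.random() < 0.1:
                    ld.set(
                        b1[rng.integers(0, len(b1))],
                        b2[rng.integers(0, len(b2))],
                        float(rng.uniform(0.0, 0.6)),
                    )
    return ld


@dataclass
class SyntheticData:
    """A full generated study universe plus its ground truth."""

    config: SynthConfig
    ontology: SyntheticOntology
    bundles: list[DiseaseBundle]
    catalog: GwasCatalog
    tmaps: list[EqtlTissueMap]
    claims: dict[str, ClaimsDataset]
    ld: LdTable
    molecular_truth: frozenset
    comorbid_truth: frozenset

    @property
    def dag(self) -> OntologyDag:
        return self.ontology.dag


DATASET_IDS = ("NIS", "NEDS")


def generate_all(cfg: SynthConfig, dataset_ids=DATASET_IDS) -> SyntheticData:
    """Generate every input the pipeline consumes, plus ground truth."""
    onto = gen_ontology(cfg)
    bundles = merge_bundles(onto.term_to_codes)
    bundles = [
        expand_claim_codes(b, onto.dag, onto.code_map) if not b.unmapped else b
        for b in bundles
    ]
    catalog = gen_gwas_catalog(cfg, onto)
    tmaps = gen_eqtl_maps(cfg, catalog)
    claims = {
        ds_id: gen_claims(cfg, onto, ds_id, dataset_index=i)
        for i, ds_id in enumerate(dataset_ids)
    }
    ld = gen_ld_table(cfg, catalog)
    molecular = frozenset(
        pp.bundle_pair for pp in cfg.planted_pairs if pp.shared_rna_count > 0
    )
    comorbid = frozenset(
        pp.bundle_pair for pp in cfg.planted_pairs if pp.comorbidity_log_odds != 0.0
    )
    return SyntheticData(
        config=cfg,
        ontology=onto,
        bundles=bundles,
        catalog=catalog,
        tmaps=tmaps,
        claims=claims,
        ld=ld,
        molecular_truth=molecular,
        comorbid_truth=comorbid,
    )


def _sample_disjoint_pairs(rng: np.random.Generator, n_diseases: int, n_pairs: int):
    """Vertex-disjoint canonical disease pairs."""
    if 2 * n_pairs > n_diseases:
        raise ValueError("not enough diseases for vertex-disjoint pairs")
    chosen = rng.choice(n_diseases, size=2 * n_pairs, replace=False)
    return [tuple(sorted(chosen[2 * k : 2 * k + 2])) for k in range(n_pairs)]


def null_universe(seed: int, n_diseases: int = 40, **kw) -> SynthConfig:
    """No planted structure at all: every downstream signal is noise."""
    return SynthConfig(seed=seed, n_diseases=n_diseases,
                       n_snps=kw.pop("n_snps", 10 * n_diseases), **kw)


def coupled_universe(
    seed: int,
    n_diseases: int = 200,
    n_pairs: int = 20,
    shared_rna_count: int = 10,
    comorbidity_log_odds: float = math.log(3.0),
    **kw,
) -> SynthConfig:
    """Molecular convergence and comorbidity planted on the same pairs."""
    rng = _rng(seed, _S_PAIRS)
    pairs = tuple(
        PlantedPair(i, j, shared_rna_count=shared_rna_count,
                    comorbidity_log_odds=comorbidity_log_odds)
        for i, j in _sample_disjoint_pairs(rng, n_diseases, n_pairs)
    )
    return SynthConfig(seed=seed, n_diseases=n_diseases,
                       n_snps=kw.pop("n_snps", 10 * n_diseases),
                       planted_pairs=pairs, **kw)


def _sample_pairs(rng: np.random.Generator, n_diseases: int, n_pairs: int):
    """Distinct canonical pairs, vertices free to repeat."""
    all_idx = np.arange(n_diseases * (n_diseases - 1) // 2)
    if n_pairs > len(all_idx):
        raise ValueError("more pairs requested than exist")
    flat = rng.choice(all_idx, size=n_pairs, replace=False)
    pairs = []
    for f in flat:
        # unrank the flat index into the (i, j) upper triangle
        i = 0
        remaining = int(f)
        row = n_diseases - 1
        while remaining >= row:
            remaining -= row
            i += 1
            row -= 1
        pairs.append((i, i + 1 + remaining))
    return pairs


def decoupled_universe(
    seed: int,
    n_diseases: int = 80,
    n_molecular: int = 80,
    n_comorbid: int = 80,
    shared_rna_count: int = 10,
    comorbidity_log_odds: float = math.log(3.0),
    **kw,
) -> SynthConfig:
    """Both kinds of structure planted, but sampled *independently*, so
    convergence carries no information about comorbidity.

    Independent (rather than forced-disjoint) sampling is what makes the
    concordance test's null hold exactly: the two significant sets then
    overlap purely hypergeometrically.  Defaults plant enough pairs for
    the expected chance overlap to be a few pairs, keeping the null
    contingency tables away from degenerate all-zero cells.
    """
    rng = _rng(seed, _S_PAIRS)
    mol = _sample_pairs(rng, n_diseases, n_molecular)
    com = _sample_pairs(rng, n_diseases, n_comorbid)
    merged: dict[tuple[int, int], PlantedPair] = {}
    for i, j in mol:
        merged[(i, j)] = PlantedPair(i, j, shared_rna_count=shared_rna_count)
    for i, j in com:
        prev_pp = merged.get((i, j))
        merged[(i, j)] = PlantedPair(
            i, j,
            shared_rna_count=prev_pp.shared_rna_count if prev_pp else 0,
            comorbidity_log_odds=comorbidity_log_odds,
        )
    pairs = tuple(merged[k] for k in sorted(merged))
    return SynthConfig(seed=seed, n_diseases=n_diseases,
                       n_snps=kw.pop("n_snps", 10 * n_diseases),
                       planted_pairs=pairs, **kw)
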