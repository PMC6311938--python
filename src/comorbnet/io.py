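"""TSV readers and writers for every input and output table.

The dialects deliberately mirror the shapes of the public source files:
a GWAS-catalog-style disease->SNP table, per-tissue pre-thresholded eQTL
association tables, claims tables with semicolon-joined diagnosis codes,
an ontology edge list (child TAB parent), plain mapping tables, and a
sparse LD table.  The synthetic generator writes exactly what these
readers consume, so a pipeline run is file-format-faithful end to end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .comorbidity import ClaimsDataset, ComorbidityResult
from .convergence import EqtlTissueMap, GwasCatalog
from .network import LdTable
from .ontology import OntologyDag

__all__ = [
    "read_gwas_catalog", "write_gwas_catalog",
    "read_eqtl_map", "write_eqtl_map",
    "read_claims", "write_claims",
    "read_ontology_edges", "write_ontology_edges",
    "read_term_map", "write_term_map",
    "read_code_map", "write_code_map",
    "read_ld_table", "write_ld_table",
    "write_convergence_results", "write_comorbidity_results",
    "write_similarity_matrix",
]


def read_gwas_catalog(path) -> GwasCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"bundle_id": str, "snp_id": str})
    df["intergenic"] = df["intergenic"].astype(bool)
    return GwasCatalog(df)


def write_gwas_catalog(catalog: GwasCatalog, path) -> None:
    catalog.records.to_csv(path, sep="\t", index=False)


def read_eqtl_map(path, tissue: str | None = None, background=None) -> EqtlTissueMap:
    """Read one tissue's eQTL table.

    The enrichment background defaults to all RNAs present in the file
    (every expressed eQTL RNA of the tissue); pass ``background``
    explicitly to widen it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "rna_id": str, "kind": str})
    if tissue is None:
        tissue = Path(path).stem
    bg = background if background is not None else sorted(set(df["rna_id"]))
    return EqtlTissueMap(tissue, df, bg)


def write_eqtl_map(tmap: EqtlTissueMap, path) -> None:
    tmap.associations.to_csv(path, sep="\t", index=False)


def read_claims(path, dataset_id: str | None = None) -> ClaimsDataset:
    """Read a claims TSV: patient_id, age, sex, race, codes (';'-joined)."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"patient_id": str, "race": str, "codes": str},
    )
    patients = df[["patient_id", "age", "sex", "race"]]
    codes = df[["patient_id", "codes"]].copy()
    codes["codes"] = codes["codes"].fillna("")
    long = (
        codes.assign(code=codes["codes"].str.split(";"))
        .explode("code")
        .loc[lambda d: d["code"] != "", ["patient_id", "code"]]
        .reset_index(drop=True)
    )
    if dataset_id is None:
        dataset_id = Path(path).stem
    return ClaimsDataset(dataset_id, patients, long)


def write_claims(ds: ClaimsDataset, path) -> None:
    joined = (
        ds.diagnoses.sort_values(["patient_id", "code"])
        .groupby("patient_id")["code"]
        .agg(";".join)
        .rename("codes")
    )
    out = ds.patients.merge(joined, on="patient_id", how="left")
    out.to_csv(path, sep="\t", index=False)


def read_ontology_edges(path) -> OntologyDag:
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    return OntologyDag(list(df.itertuples(index=False, name=None)))


def write_ontology_edges(dag: OntologyDag, path) -> None:
    pd.DataFrame(dag.edges, columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_term_map(path) -> dict[str, set]:
    """term -> ontology-concept set; terms with a blank code map to {}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, set] = {}
    for term, code in df[["term", "code"]].itertuples(index=False, name=None):
        out.setdefault(term, set())
        if code:
            out[term].add(code)
    return out


def write_term_map(term_to_codes: dict[str, set], path) -> None:
    rows = []
    for term in sorted(term_to_codes):
        codes = sorted(term_to_codes[term])
        if not codes:
            rows.append({"term": term, "code": ""})
        for code in codes:
            rows.append({"term": term, "code": code})
    pd.DataFrame(rows, columns=["term", "code"]).to_csv(path, sep="\t", index=False)


def read_code_map(path) -> dict[str, list[str]]:
    """concept -> ordered claim-code list (order carries mapping priority)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for concept, code in df[["concept", "claim_code"]].itertuples(index=False, name=None):
        out.setdefault(concept, []).append(code)
    return out


def write_code_map(code_map: dict[str, list[str]], path) -> None:
    rows = [
        {"concept": concept, "claim_code": code}
        for concept in sorted(code_map)
        for code in code_map[concept]
    ]
    pd.DataFrame(rows, columns=["concept", "claim_code"]).to_csv(
        path, sep="\t", index=False
    )


def read_ld_table(path) -> LdTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp1": str, "snp2": str})
    ld = LdTable()
    for s1, s2, r2 in df[["snp1", "snp2", "r2"]].itertuples(index=False, name=None):
        ld.set(s1, s2, float(r2))
    return ld


def write_ld_table(ld: LdTable, path) -> None:
    rows = [
        {"snp1": s1, "snp2": s2, "r2": r2} for (s1, s2), r2 in sorted(ld.items())
    ]
    pd.DataFrame(rows, columns=["snp1", "snp2", "r2"]).to_csv(
        path, sep="\t", index=False
    )


def write_convergence_results(results, path) -> None:
    rows = [
        {
            "disease1": r.pair[0],
            "disease2": r.pair[1],
            "tissue": r.tissue,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "p_value": r.p_value,
            "fdr_erna": r.fdr_erna,
            "shared_rnas": ";".join(sorted(r.shared_rnas)),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["disease1", "disease2", "tissue", "a", "b", "c", "d",
                 "p_value", "fdr_erna", "shared_rnas"],
    ).to_csv(path, sep="\t", index=False)


def write_comorbidity_results(results: list[ComorbidityResult], path) -> None:
    """Pair-level table with per-dataset directional ORs and FDRs."""
    datasets = sorted({f.dataset_id for r in results for f in r.directional})
    rows = []
    for r in results:
        rec: dict = {"disease1": r.pair[0], "disease2": r.pair[1]}
        for ds in datasets:
            fits = [f for f in r.directional if f.dataset_id == ds]
            for f in fits:
                direction = 1 if f.response == r.pair[0] else 2
                rec[f"{ds}_OR{direction}"] = f.odds_ratio if f.converged else np.nan
                rec[f"{ds}_FDR{direction}"] = f.fdr
        rec["pair_or"] = r.pair_or
        rec["fdr_comorbidity"] = r.fdr_comorbidity
        rec["significant"] = r.significant
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_similarity_matrix(similarities: dict[tuple[str, str], float], path) -> None:
    rows = [
        {"disease1": p[0], "disease2": p[1], "lin_similarity": s}
        for p, s in sorted(similarities.items())
    ]
    pd.DataFrame(rows, columns=["disease1", "disease2", "lin_similarity"]).to_csv(
        path, sep="\t", index=False
    )
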