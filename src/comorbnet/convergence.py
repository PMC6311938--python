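"""eQTL-RNA overlap model: molecular convergence between disease pairs.

For each tissue, a disease's *eQTL RNA set* is the union of RNAs whose
expression is associated (cis or trans) with any SNP linked to the disease
by GWAS.  Two diseases converge molecularly in a tissue when their RNA
sets overlap more than expected by chance given the tissue's expressed
eQTL-RNA background — assessed by a one-sided Fisher exact test, with
Benjamini-Hochberg adjustment within each tissue (FDR_eRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import Contingency2x2, bh_adjust, fisher_exact_2x2

__all__ = [
    "GwasCatalog",
    "EqtlTissueMap",
    "ConvergenceResult",
    "disease_rna_set",
    "convergence_scan",
    "prioritize_convergent",
]


class GwasCatalog:
    """Disease-bundle -> SNP association table (GWAS-catalog style).

    Rows are (bundle_id, snp_id, intergenic); duplicate (bundle, snp)
    rows are collapsed on construction.
    """

    def __init__(self, records: pd.DataFrame):
        required = {"bundle_id", "snp_id", "intergenic"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"catalog missing columns {sorted(missing)}")
        df = records.drop_duplicates(subset=["bundle_id", "snp_id"]).reset_index(drop=True)
        self.records = df
        self._snps_by_bundle: dict[str, frozenset] = {
            b: frozenset(g) for b, g in df.groupby("bundle_id")["snp_id"]
        }

    @property
    def bundles(self) -> list[str]:
        return sorted(self._snps_by_bundle)

    def snps_for(self, bundle_id: str) -> frozenset:
        try:
            return self._snps_by_bundle[bundle_id]
        except KeyError:
            raise KeyError(f"bundle {bundle_id!r} not in catalog") from None

    @property
    def all_snps(self) -> frozenset:
        return frozenset(self.records["snp_id"])

    def __len__(self) -> int:
        return len(self.records)


class EqtlTissueMap:
    """Per-tissue SNP -> RNA eQTL association set.

    ``background_rnas`` is the universe of expressed eQTL RNAs in the
    tissue, the background of the overlap enrichment test.  Every
    association's RNA must belong to it.
    """

    def __init__(self, tissue: str, associations: pd.DataFrame, background_rnas):
        required = {"snp_id", "rna_id", "kind"}
        missing = required - set(associations.columns)
        if missing:
            raise ValueError(f"eQTL map missing columns {sorted(missing)}")
        self.tissue = tissue
        self.associations = associations.drop_duplicates(
            subset=["snp_id", "rna_id"]
        ).reset_index(drop=True)
        self.background_rnas = frozenset(background_rnas)
        assoc_rnas = set(self.associations["rna_id"])
        if not assoc_rnas <= self.background_rnas:
            raise ValueError(
                f"tissue {tissue}: associations reference RNAs outside the background"
            )
        self._snp_to_rnas: dict[str, frozenset] = {
            s: frozenset(g) for s, g in self.associations.groupby("snp_id")["rna_id"]
        }

    def rnas_for_snps(self, snps) -> frozenset:
        out: set = set()
        for s in snps:
            out |= self._snp_to_rnas.get(s, frozenset())
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.associations)


@dataclass
class ConvergenceResult:
    """One disease pair tested in one tissue."""

    pair: tuple[str, str]
    tissue: str
    table: Contingency2x2
    p_value: float
    fdr_erna: float
    shared_rnas: frozenset

    def __post_init__(self) -> None:
        if self.table.a != len(self.shared_rnas):
            raise ValueError("cell a must equal the shared-RNA count")


def disease_rna_set(
    bundle_id: str,
    catalog: GwasCatalog,
    tmap: EqtlTissueMap,
    exclude_snps=frozenset(),
) -> frozenset:
    """Union of tissue RNAs linked to any GWAS SNP of the bundle."""
    snps = catalog.snps_for(bundle_id)
    if exclude_snps:
        snps = snps - frozenset(exclude_snps)
    return tmap.rnas_for_snps(snps)


def convergence_scan(
    catalog: GwasCatalog,
    tmaps,
    alternative: str = "greater",
    bh_scope: str = "per_tissue",
    exclude_shared_snps: bool = False,
) -> list[ConvergenceResult]:
    """Test every unordered disease pair in every tissue for RNA overlap.

    A pair is testable in a tissue only if both diseases have a non-empty
    RNA set there.  The contingency table is::

        a = |R1 & R2|   b = |R1 - R2|
        c = |R2 - R1|   d = |background| - a - b - c

    Parameters
    ----------
    bh_scope : {"per_tissue", "global"}
        Scope of the Benjamini-Hochberg adjustment.  Per-tissue mirrors
        reporting significance tissue by tissue; a global option is
        provided for sensitivity analysis.
    exclude_shared_snps
        Drop SNPs GWAS-associated with *both* diseases of a pair from the
        RNA-set union, so the overlap cannot be driven by a literally
        shared locus.  Off by default.
    """
    tmaps = list(tmaps)
    if not tmaps:
        raise ValueError("need at least one tissue")
    if bh_scope not in ("per_tissue", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")

    bundles = catalog.bundles
    snp_sets = {b: catalog.snps_for(b) for b in bundles}
    per_tissue: list[list[ConvergenceResult]] = []
    for tmap in tmaps:
        rna_sets = {
            b: disease_rna_set(b, catalog, tmap) for b in bundles
        }
        testable = [b for b in bundles if rna_sets[b]]
        bg = len(tmap.background_rnas)
        rows: list[tuple] = []
        for b1, b2 in combinations(testable, 2):
            r1, r2 = rna_sets[b1], rna_sets[b2]
            if exclude_shared_snps:
                shared_snps = snp_sets[b1] & snp_sets[b2]
                if shared_snps:
                    r1 = disease_rna_set(b1, catalog, tmap, exclude_snps=shared_snps)
                    r2 = disease_rna_set(b2, catalog, tmap, exclude_snps=shared_snps)
                    if not r1 or not r2:
                        continue
            shared = r1 & r2
            a = len(shared)
            b_cell = len(r1) - a
            c_cell = len(r2) - a
            d_cell = bg - a - b_cell - c_cell
            if d_cell < 0:
                raise ValueError(
                    f"tissue {tmap.tissue}: background smaller than the union of "
                    f"RNA sets for pair ({b1}, {b2}) — inconsistent map"
                )
            rows.append(((b1, b2), a, b_cell, c_cell, d_cell, shared))
        if not rows:
            per_tissue.append([])
            continue
        if alternative == "greater":
            a_arr = np.array([r[1] for r in rows])
            r1_arr = a_arr + np.array([r[2] for r in rows])
            r2_arr = a_arr + np.array([r[3] for r in rows])
            n_arr = np.array([sum(r[1:5]) for r in rows])
            pvals = sps.hypergeom.sf(a_arr - 1, n_arr, r1_arr, r2_arr)
            pvals = np.clip(pvals, 0.0, 1.0)
        else:
            pvals = np.array(
                [
                    fisher_exact_2x2(
                        Contingency2x2(r[1], r[2], r[3], r[4]), alternative
                    ).p_value
                    for r in rows
                ]
            )
        results = [
            ConvergenceResult(
                pair=row[0],
                tissue=tmap.tissue,
                table=Contingency2x2(row[1], row[2], row[3], row[4]),
                p_value=float(p),
                fdr_erna=float("nan"),
                shared_rnas=frozenset(row[5]),
            )
            for row, p in zip(rows, pvals)
        ]
        per_tissue.append(results)

    if bh_scope == "per_tissue":
        for results in per_tissue:
            if results:
                adj = bh_adjust([r.p_value for r in results])
                for r, q in zip(results, adj):
                    r.fdr_erna = float(q)
    else:
        flat = [r for results in per_tissue for r in results]
        if flat:
            adj = bh_adjust([r.p_value for r in flat])
            for r, q in zip(flat, adj):
                r.fdr_erna = float(q)
    return [r for results in per_tissue for r in results]


def prioritize_convergent(
    results, fdr_cut: float = 0.05
) -> dict[tuple[str, str], int]:
    """Distinct pairs significant in at least one tissue.

    Returns a map pair -> number of distinct tissues in which the pair
    passed ``fdr_erna < fdr_cut`` (the disease-network edge weight).
    A cut of exactly 1.0 is vacuous and returns every tested pair.
    """
    if not (0.0 < fdr_cut <= 1.0):
        raise ValueError(f"fdr_cut {fdr_cut} outside (0, 1]")
    tissues: dict[tuple[str, str], set] = {}
    for r in results:
        if r.fdr_erna < fdr_cut or fdr_cut >= 1.0:
            tissues.setdefault(r.pair, set()).add(r.tissue)
    return {pair: len(ts) for pair, ts in tissues.items()}
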