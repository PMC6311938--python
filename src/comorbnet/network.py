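"""Comorbid-syndrome networks and per-pair mechanism subnetworks.

Two network products:

* the disease-level network — nodes are disease bundles, an edge joins a
  pair that is both molecularly convergent (FDR_eRNA < cut in >= 1
  tissue) and clinically comorbid (FDR_comorbidity < cut, OR above cut),
  weighted by the number of distinct significant tissues;
* per-pair tripartite mechanism networks — disease -> locus -> shared
  RNA, where SNPs of the same disease in strong linkage disequilibrium
  (r^2 >= 0.8) are collapsed into a single locus node.

Both export to GraphML and SIF for downstream visualization tools.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .convergence import GwasCatalog

__all__ = [
    "LdTable",
    "LD_LOCUS_THRESHOLD",
    "collapse_loci",
    "build_disease_network",
    "build_mechanism_network",
    "write_graphml",
    "read_graphml",
    "write_sif",
]

#: r^2 at or above which two same-disease SNPs count as one locus
LD_LOCUS_THRESHOLD = 0.8


class LdTable:
    """Sparse symmetric pairwise linkage-disequilibrium r^2 table.

    Absent entries are 0; the diagonal is implicitly 1.
    """

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if entries:
            for (s1, s2), r2 in entries.items():
                self.set(s1, s2, r2)

    @staticmethod
    def _key(s1: str, s2: str) -> tuple[str, str]:
        return (s1, s2) if s1 <= s2 else (s2, s1)

    def set(self, s1: str, s2: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r^2 {r2} outside [0, 1]")
        if s1 == s2:
            if r2 != 1.0:
                raise ValueError("self-LD must be 1")
            return
        self._r2[self._key(s1, s2)] = float(r2)

    def get(self, s1: str, s2: str) -> float:
        if s1 == s2:
            return 1.0
        return self._r2.get(self._key(s1, s2), 0.0)

    def items(self):
        return self._r2.items()

    def __len__(self) -> int:
        return len(self._r2)


def collapse_loci(
    snps, disease: str, ld: LdTable, threshold: float = LD_LOCUS_THRESHOLD
) -> list[frozenset]:
    """Group a disease's SNPs into loci by LD connected components.

    Two SNPs belong to the same locus when a chain of pairwise
    ``r^2 >= threshold`` links connects them.  Returns the loci as frozen
    SNP sets, sorted for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(snps)
    snps = sorted(g.nodes)
    for i, s1 in enumerate(snps):
        for s2 in snps[i + 1:]:
            if ld.get(s1, s2) >= threshold:
                g.add_edge(s1, s2)
    return sorted((frozenset(c) for c in nx.connected_components(g)), key=sorted)


def _locus_label(disease: str, locus: frozenset) -> str:
    return f"{disease}|{'+'.join(sorted(locus))}"


def build_disease_network(
    convergent_pairs: dict[tuple[str, str], int],
    comorbidity_results,
    fdr_comorbidity_cut: float = 0.05,
    or_cut: float = 1.5,
    class_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Disease network of pairs passing both arms.

    Parameters
    ----------
    convergent_pairs
        pair -> significant-tissue count, from
        :func:`comorbnet.convergence.prioritize_convergent` (already
        thresholded at the convergence FDR cut).
    comorbidity_results
        Merged :class:`~comorbnet.comorbidity.ComorbidityResult` records.
    class_map
        Optional bundle -> disease-class label used as node color class.

    Edge attribute ``weight`` is the distinct-significant-tissue count.
    """
    g = nx.Graph()
    comorbid = {
        r.pair: r
        for r in comorbidity_results
        if r.fdr_comorbidity < fdr_comorbidity_cut and r.pair_or > or_cut
    }
    for pair, n_tissues in sorted(convergent_pairs.items()):
        r = comorbid.get(pair)
        if r is None:
            continue
        d1, d2 = pair
        g.add_edge(
            d1,
            d2,
            weight=int(n_tissues),
            pair_or=float(r.pair_or),
            fdr_comorbidity=float(r.fdr_comorbidity),
        )
    for n in g.nodes:
        g.nodes[n]["node_type"] = "disease"
        g.nodes[n]["disease_class"] = (class_map or {}).get(n, "unclassified")
    return g


def build_mechanism_network(
    pair: tuple[str, str],
    catalog: GwasCatalog,
    tmaps,
    convergence_results,
    ld: LdTable,
    fdr_cut: float = 0.05,
) -> nx.Graph:
    """Tripartite disease -> locus -> shared-RNA network for one pair.

    Only the pair's shared RNAs from tissues where the overlap was
    significant appear, and only loci whose SNPs are eQTL-linked to at
    least one of those RNAs; everything irrelevant to the comorbidity's
    molecular underpinning is left out.  Loci are collapsed per disease
    (LD r^2 >= 0.8); a locus of one disease is never merged with a locus
    of the other.  Edges carry the tissues that support them
    (semicolon-joined in the ``tissues`` attribute).
    """
    d1, d2 = pair
    key = (d1, d2) if d1 <= d2 else (d2, d1)
    sig = [r for r in convergence_results if r.pair == key and r.fdr_erna < fdr_cut]
    if not sig:
        raise ValueError(f"pair {pair} has no tissue with significant RNA overlap")
    shared_by_tissue = {r.tissue: r.shared_rnas for r in sig}
    tmap_by_tissue = {t.tissue: t for t in tmaps}
    missing = set(shared_by_tissue) - set(tmap_by_tissue)
    if missing:
        raise ValueError(f"no tissue map for significant tissues {sorted(missing)}")

    g = nx.Graph()
    for disease in key:
        g.add_node(disease, node_type="disease")

    # locus -> rna support: tissue-resolved eQTL links restricted to shared RNAs
    for disease in key:
        snps = catalog.snps_for(disease)
        loci = collapse_loci(snps, disease, ld)
        for locus in loci:
            locus_id = _locus_label(disease, locus)
            rna_tissues: dict[str, set] = {}
            for tissue, shared in shared_by_tissue.items():
                tmap = tmap_by_tissue[tissue]
                hit = tmap.rnas_for_snps(locus) & shared
                for rna in hit:
                    rna_tissues.setdefault(rna, set()).add(tissue)
            if not rna_tissues:
                continue  # locus irrelevant to the shared mechanism
            g.add_node(
                locus_id,
                node_type="locus",
                disease=disease,
                snps=";".join(sorted(locus)),
            )
            g.add_edge(disease, locus_id, edge_type="gwas")
            for rna, tissues in rna_tissues.items():
                if rna not in g:
                    g.add_node(rna, node_type="rna")
                g.add_edge(
                    locus_id, rna, edge_type="eqtl", tissues=";".join(sorted(tissues))
                )
    return g


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_sif(g: nx.Graph, path) -> None:
    """Simple interaction format: ``source <edge_type> target`` rows."""
    lines = []
    for u, v, data in sorted(g.edges(data=True)):
        rel = data.get("edge_type", "link")
        lines.append(f"{u}\t{rel}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")
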