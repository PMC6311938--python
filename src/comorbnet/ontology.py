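"""Disease-bundle construction and ontology-based semantic similarity.

The disease ontology (a SNOMED-CT-like nomenclature) is a rooted directed
acyclic graph of disease concepts.  It serves three purposes here:

* merging heterogeneous source disease terms into *disease bundles*, the
  unit of pairwise analysis;
* expanding each bundle's concepts to all ontology descendants so the
  bundle captures every claims diagnosis code filed under a more specific
  concept;
* quantifying phenotypic relatedness of two bundles with Lin's similarity
  under the Sanchez intrinsic information-content estimator, used to
  exclude near-identical disease pairs from the concordance test.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDag",
    "DiseaseBundle",
    "SimilarityScore",
    "merge_bundles",
    "expand_claim_codes",
    "sanchez_ic",
    "lin_similarity",
    "bundle_similarity",
]

_TRAILING_QUALIFIER = re.compile(r"\s*\([^()]*\)\s*$")


class OntologyDag:
    """Rooted DAG of disease concepts.

    Edges are stored child -> parent, matching the on-disk edge-list
    orientation.  The DAG must be acyclic with a single root reachable
    from every node.
    """

    def __init__(self, edges: list[tuple[str, str]]):
        g = nx.DiGraph()
        g.add_edges_from(edges)  # child -> parent
        if g.number_of_nodes() == 0:
            raise ValueError("empty ontology")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self._g = g
        self.root: str = roots[0]
        # every node must reach the root
        reachable = nx.ancestors(g, self.root) | {self.root}
        if reachable != set(g.nodes):
            orphans = set(g.nodes) - reachable
            raise ValueError(f"nodes without a path to root: {sorted(orphans)[:5]}")
        self._leaves = frozenset(n for n in g.nodes if g.in_degree(n) == 0)
        self._subsumer_cache: dict[str, frozenset] = {}
        self._ic_cache: dict[str, float] | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    def __contains__(self, concept: str) -> bool:
        return concept in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def _require(self, concept: str) -> None:
        if concept not in self._g:
            raise KeyError(f"concept {concept!r} not in ontology")

    def descendants(self, concept: str) -> set[str]:
        """All concepts below ``concept`` (excluding itself)."""
        self._require(concept)
        return nx.ancestors(self._g, concept)  # edges point child->parent

    def subsumers(self, concept: str) -> frozenset:
        """All ancestors of ``concept`` including itself."""
        self._require(concept)
        cached = self._subsumer_cache.get(concept)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, concept)) | {concept}
            self._subsumer_cache[concept] = cached
        return cached

    def information_content(self) -> dict[str, float]:
        """Sanchez IC for every concept, computed once and cached."""
        if self._ic_cache is None:
            self._ic_cache = {c: sanchez_ic(c, self) for c in self._g.nodes}
        return self._ic_cache

    def leaf_descendants(self, concept: str) -> set[str]:
        """Leaf concepts under ``concept``; the concept itself if a leaf."""
        self._require(concept)
        if concept in self._leaves:
            return {concept}
        return self.descendants(concept) & self._leaves


@dataclass
class DiseaseBundle:
    """A merged group of source disease terms sharing ontology concepts.

    ``claim_codes`` is empty until :func:`expand_claim_codes` runs; bundles
    whose terms mapped to no ontology concept are flagged ``unmapped`` and
    excluded from similarity computation.
    """

    bundle_id: str
    member_terms: frozenset
    ontology_codes: frozenset
    claim_codes: frozenset = frozenset()
    unmapped: bool = False

    def __post_init__(self) -> None:
        if not self.member_terms:
            raise ValueError("bundle must have at least one member term")


@dataclass(frozen=True)
class SimilarityScore:
    pair: tuple[str, str]
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"similarity {self.score} outside [0, 1]")


def _strip_qualifier(term: str) -> str:
    return _TRAILING_QUALIFIER.sub("", term)


def merge_bundles(term_to_codes: dict[str, set]) -> list[DiseaseBundle]:
    """Merge source disease terms into disease bundles.

    Two rules, applied with transitive closure:

    1. terms mapped to an *identical non-empty* set of ontology concepts
       are merged;
    2. terms whose names coincide after removing a single trailing
       parenthetical qualifier (e.g. "Glaucoma" vs "Glaucoma (high
       intraocular pressure)") are merged.

    Terms with an empty concept set become singleton bundles flagged
    unmapped.  Output is deterministic regardless of input dict order.
    """
    terms = sorted(term_to_codes)
    parent: dict[str, str] = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    def union(u: str, v: str) -> None:
        ru, rv = find(u), find(v)
        if ru != rv:
            # keep the lexicographically smaller representative
            if rv < ru:
                ru, rv = rv, ru
            parent[rv] = ru

    by_codeset: dict[frozenset, list[str]] = {}
    by_stripped: dict[str, list[str]] = {}
    for t in terms:
        codes = frozenset(term_to_codes[t])
        if codes:
            by_codeset.setdefault(codes, []).append(t)
        by_stripped.setdefault(_strip_qualifier(t), []).append(t)
    for group in by_codeset.values():
        for other in group[1:]:
            union(group[0], other)
    for group in by_stripped.values():
        for other in group[1:]:
            union(group[0], other)

    clusters: dict[str, list[str]] = {}
    for t in terms:
        clusters.setdefault(find(t), []).append(t)

    bundles = []
    for rep in sorted(clusters):
        members = sorted(clusters[rep])
        codes = frozenset().union(*(term_to_codes[m] for m in members))
        bundles.append(
            DiseaseBundle(
                bundle_id=rep,
                member_terms=frozenset(members),
                ontology_codes=frozenset(codes),
                unmapped=not codes,
            )
        )
    return bundles


def expand_claim_codes(
    bundle: DiseaseBundle,
    dag: OntologyDag,
    code_map: dict[str, list[str]],
) -> DiseaseBundle:
    """Attach claims diagnosis codes to a bundle by descendant closure.

    The bundle's claim codes are the union of mapped codes over its
    ontology concepts *and all their descendants* — the ontology being a
    nomenclature, codes are usually filed under more specific concepts
    than the bundle-level ones.

    A claim code listed under several concepts is an inconsistent
    many-to-many mapping: it is logged and the first-listed concept's
    mapping retained.
    """
    for concept in bundle.ontology_codes:
        if concept not in dag:
            raise KeyError(f"bundle {bundle.bundle_id}: concept {concept!r} not in ontology")
    resolved = _resolve_code_map(code_map)
    concepts: set[str] = set()
    for concept in bundle.ontology_codes:
        concepts.add(concept)
        concepts |= dag.descendants(concept)
    codes: set[str] = set()
    for concept in concepts:
        codes.update(resolved.get(concept, ()))
    if not codes:
        logger.warning("bundle %s maps to no claim codes", bundle.bundle_id)
    return DiseaseBundle(
        bundle_id=bundle.bundle_id,
        member_terms=bundle.member_terms,
        ontology_codes=bundle.ontology_codes,
        claim_codes=frozenset(codes),
        unmapped=bundle.unmapped,
    )


def _resolve_code_map(code_map: dict[str, list[str]]) -> dict[str, list[str]]:
    """Keep each claim code only under its first-listed concept."""
    seen: dict[str, str] = {}
    out: dict[str, list[str]] = {}
    for concept in code_map:
        kept = []
        for code in code_map[concept]:
            if code in seen and seen[code] != concept:
                logger.warning(
                    "claim code %s mapped to both %s and %s; keeping first-listed (%s)",
                    code, seen[code], concept, seen[code],
                )
                continue
            seen.setdefault(code, concept)
            kept.append(code)
        out[concept] = kept
    return out


def sanchez_ic(concept: str, dag: OntologyDag) -> float:
    """Intrinsic information content of a concept (Sanchez estimator).

    IC(c) = -log( (|leaves(c)| / |subsumers(c)| + 1) / (max_leaves + 1) )

    where leaves(c) are the leaf descendants of c (c itself if a leaf),
    subsumers(c) its ancestors including c, and max_leaves the total leaf
    count of the DAG.  Natural logarithm.  IC(root) = 0 exactly.
    """
    n_leaves = len(dag.leaf_descendants(concept))
    n_subsumers = len(dag.subsumers(concept))
    max_leaves = len(dag.leaves)
    return -math.log((n_leaves / n_subsumers + 1.0) / (max_leaves + 1.0))


def _mica_ic(a: str, b: str, dag: OntologyDag, ic: dict[str, float]) -> float:
    common = dag.subsumers(a) & dag.subsumers(b)
    return max(ic[c] for c in common)


def lin_similarity(a: str, b: str, dag: OntologyDag) -> SimilarityScore:
    """Lin's similarity of two concepts.

    score = 2 * IC(MICA) / (IC(a) + IC(b)), where MICA is the common
    ancestor with maximal IC.  Zero when both concepts carry no
    information (IC(a)+IC(b) = 0, e.g. the root with itself).
    """
    ic = dag.information_content()
    denom = ic[a] + ic[b]
    if denom <= 0.0:
        score = 0.0
    else:
        score = 2.0 * _mica_ic(a, b, dag, ic) / denom
    score = min(1.0, max(0.0, score))
    return SimilarityScore(pair=(a, b), score=score)


def bundle_similarity(
    b1: DiseaseBundle, b2: DiseaseBundle, dag: OntologyDag
) -> SimilarityScore:
    """Bundle-level similarity: maximum Lin score over the concept cross
    product.  MAX aggregation is conservative for the downstream
    "similar pair" exclusion — any highly similar concept pair marks the
    two bundles similar.
    """
    if not b1.ontology_codes or not b2.ontology_codes:
        raise ValueError(
            f"bundle similarity needs ontology codes on both bundles "
            f"({b1.bundle_id}, {b2.bundle_id})"
        )
    best = 0.0
    for c1 in sorted(b1.ontology_codes):
        for c2 in sorted(b2.ontology_codes):
            s = lin_similarity(c1, c2, dag).score
            if s > best:
                best = s
    return SimilarityScore(pair=(b1.bundle_id, b2.bundle_id), score=best)
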