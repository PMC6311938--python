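"""End-to-end orchestration: inputs -> convergence -> comorbidity ->
concordance -> networks, with every table written out and a JSON-able
run report of stage counts.

A run consumes either a :class:`~comorbnet.synthetic.SynthConfig` (the
default, self-contained mode) or a dictionary of input file paths in the
TSV dialects of :mod:`comorbnet.io`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import io as cio
from .comorbidity import build_indicators, comorbidity_scan, merge_datasets
from .concordance import (
    build_pair_results,
    concordance_fet,
    robustness_grid,
    similarity_filtered_concordance,
)
from .convergence import convergence_scan, prioritize_convergent
from .network import (
    build_disease_network,
    build_mechanism_network,
    write_graphml,
    write_sif,
)
from .ontology import bundle_similarity, expand_claim_codes, merge_bundles
from .synthetic import SynthConfig, SyntheticData, generate_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_inputs"]


@dataclass
class RunConfig:
    """Cutoffs, options, and the input source of one pipeline run.

    Exactly one of ``synth`` / ``input_paths`` must be set.
    ``input_paths`` keys: ontology_edges, term_map, code_map, gwas,
    eqtl (list of per-tissue TSVs), claims (list of TSVs), ld.
    """

    synth: SynthConfig | None = None
    input_paths: dict | None = None
    fdr_erna: float = 0.05
    fdr_comorbidity: float = 0.05
    or_cut: float = 1.5
    similarity_threshold: float = 0.9
    min_cases: int = 100
    universe: str = "both"
    alternative: str = "greater"
    bh_scope: str = "per_tissue"
    run_grid: bool = False
    max_mechanism_networks: int = 10
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_paths is None):
            raise ValueError("set exactly one of synth / input_paths")
        for name in ("fdr_erna", "fdr_comorbidity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} {v} outside (0, 1]")
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold outside [0, 1]")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


def load_inputs(paths: dict) -> SyntheticData:
    """Load user-supplied TSV inputs into the same container the
    generator produces (ground-truth fields empty)."""
    dag = cio.read_ontology_edges(paths["ontology_edges"])
    term_map = cio.read_term_map(paths["term_map"])
    code_map = cio.read_code_map(paths["code_map"])
    bundles = merge_bundles(term_map)
    bundles = [
        expand_claim_codes(b, dag, code_map) if not b.unmapped else b
        for b in bundles
    ]
    catalog = cio.read_gwas_catalog(paths["gwas"])
    tmaps = [cio.read_eqtl_map(p) for p in paths["eqtl"]]
    claims = {}
    for p in paths["claims"]:
        ds = cio.read_claims(p)
        claims[ds.dataset_id] = ds
    ld = cio.read_ld_table(paths["ld"]) if paths.get("ld") else None
    from .network import LdTable
    from .synthetic import SyntheticOntology

    onto = SyntheticOntology(
        dag=dag, term_to_codes=term_map, code_map=code_map,
        disease_terms=sorted(term_map), disease_concepts={}, class_of={},
    )
    return SyntheticData(
        config=None, ontology=onto, bundles=bundles, catalog=catalog,
        tmaps=tmaps, claims=claims, ld=ld if ld is not None else LdTable(),
        molecular_truth=frozenset(), comorbid_truth=frozenset(),
    )


def _stage(report: dict, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    report.setdefault("timings_s", {})[name] = round(t1 - t0, 3)
    return t1


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report dictionary.

    When ``cfg.outdir`` is set, every stage's table plus the report JSON
    and network exports are written there.
    """
    report: dict = {
        "options": {
            "fdr_erna": cfg.fdr_erna,
            "fdr_comorbidity": cfg.fdr_comorbidity,
            "or_cut": cfg.or_cut,
            "similarity_threshold": cfg.similarity_threshold,
            "min_cases": cfg.min_cases,
            "universe": cfg.universe,
            "alternative": cfg.alternative,
            "bh_scope": cfg.bh_scope,
        }
    }
    outdir = Path(cfg.outdir) if cfg.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    try:
        if cfg.synth is not None:
            data = generate_all(cfg.synth)
            report["options"]["seed"] = cfg.synth.seed
        else:
            data = load_inputs(cfg.input_paths)
    except Exception as exc:
        raise RuntimeError(f"[inputs] {exc}") from exc
    bundle_by_id = {b.bundle_id: b for b in data.bundles}
    report["bundles"] = {
        "n_bundles": len(data.bundles),
        "n_unmapped": sum(b.unmapped for b in data.bundles),
        "n_without_claim_codes": sum(
            not b.claim_codes for b in data.bundles if not b.unmapped
        ),
    }
    t0 = _stage(report, "inputs", t0)

    try:
        conv_results = convergence_scan(
            data.catalog, data.tmaps,
            alternative=cfg.alternative, bh_scope=cfg.bh_scope,
        )
        convergent = prioritize_convergent(conv_results, cfg.fdr_erna)
    except Exception as exc:
        raise RuntimeError(f"[convergence] {exc}") from exc
    tested_per_tissue: dict[str, int] = {}
    for r in conv_results:
        tested_per_tissue[r.tissue] = tested_per_tissue.get(r.tissue, 0) + 1
    report["convergence"] = {
        "n_tests": len(conv_results),
        "tested_pairs_per_tissue": dict(sorted(tested_per_tissue.items())),
        "n_convergent_pairs": len(convergent),
    }
    t0 = _stage(report, "convergence", t0)

    try:
        scans = []
        comorb_stage: dict = {}
        for ds_id in sorted(data.claims):
            ds = data.claims[ds_id]
            ind = build_indicators(ds, data.bundles)
            fits = comorbidity_scan(
                ds, data.bundles, min_cases=cfg.min_cases, indicators=ind
            )
            scans.append(fits)
            comorb_stage[ds_id] = {
                "n_patients": ds.n_patients,
                "n_excluded_missing_covariates": ind.n_excluded,
                "n_directional_fits": len(fits),
                "n_converged": sum(f.converged for f in fits),
            }
        merged = merge_datasets(scans, fdr_cut=cfg.fdr_comorbidity, or_cut=cfg.or_cut)
    except Exception as exc:
        raise RuntimeError(f"[comorbidity] {exc}") from exc
    comorb_stage["n_pairs_merged"] = len(merged)
    comorb_stage["n_comorbid"] = sum(r.significant for r in merged)
    report["comorbidity"] = comorb_stage
    t0 = _stage(report, "comorbidity", t0)

    try:
        pairs = build_pair_results(conv_results, merged)
        both = [p for p in pairs if p.tested_in_both]
        report["pairs"] = {
            "n_pairs_any_arm": len(pairs),
            "n_tested_both_arms": len(both),
            "n_convergent_in_universe": sum(
                p.convergent_at(cfg.fdr_erna) for p in both
            ),
            "n_comorbid_in_universe": sum(
                p.comorbid_at(cfg.fdr_comorbidity, cfg.or_cut) for p in both
            ),
        }
        try:
            conc = concordance_fet(
                pairs, cfg.fdr_erna, cfg.fdr_comorbidity, cfg.or_cut,
                universe=cfg.universe, alternative=cfg.alternative,
            )
            report["concordance"] = {
                "a_both": conc.table.a,
                "b_convergent_only": conc.table.b,
                "c_comorbid_only": conc.table.c,
                "d_neither": conc.table.d,
                "odds_ratio": conc.odds_ratio,
                "p_value": conc.p_value,
                "n_universe": conc.n_universe,
                "degenerate": False,
            }
        except ValueError as exc:
            report["concordance"] = {"degenerate": True, "detail": str(exc)}
        grid = None
        if cfg.run_grid:
            grid = robustness_grid(pairs, universe=cfg.universe)
            ok = grid.cells[~grid.cells["degenerate"]]
            report["grid"] = {
                "n_cells": len(grid.cells),
                "n_degenerate": int(grid.cells["degenerate"].sum()),
                "max_odds_ratio": float(ok["odds_ratio"].max()) if len(ok) else None,
            }
        sims = None
        if not report["concordance"].get("degenerate"):
            uni = {p.pair for p in both} if cfg.universe == "both" else {
                p.pair for p in pairs
            }
            sims = {}
            for d1, d2 in sorted(uni):
                b1, b2 = bundle_by_id.get(d1), bundle_by_id.get(d2)
                if b1 is None or b2 is None or not b1.ontology_codes or not b2.ontology_codes:
                    sims[(d1, d2)] = 0.0
                else:
                    sims[(d1, d2)] = bundle_similarity(b1, b2, data.dag).score
            try:
                filt = similarity_filtered_concordance(
                    pairs, sims, threshold=cfg.similarity_threshold,
                    fdr_e=cfg.fdr_erna, fdr_c=cfg.fdr_comorbidity,
                    or_cut=cfg.or_cut, universe=cfg.universe,
                    alternative=cfg.alternative,
                )
                report["concordance_similarity_filtered"] = {
                    "n_excluded_similar": conc.n_universe - filt.n_universe,
                    "odds_ratio": filt.odds_ratio,
                    "p_value": filt.p_value,
                    "n_universe": filt.n_universe,
                    "degenerate": False,
                }
            except ValueError as exc:
                report["concordance_similarity_filtered"] = {
                    "degenerate": True,
                    "detail": str(exc),
                }
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[concordance] {exc}") from exc
    t0 = _stage(report, "concordance", t0)

    try:
        dnet = build_disease_network(
            convergent, merged,
            fdr_comorbidity_cut=cfg.fdr_comorbidity, or_cut=cfg.or_cut,
            class_map=data.ontology.class_of or None,
        )
        mech_nets = {}
        edges_by_weight = sorted(
            dnet.edges(data=True), key=lambda e: (-e[2]["weight"], e[0], e[1])
        )
        for u, v, _ in edges_by_weight[: cfg.max_mechanism_networks]:
            pair = (u, v) if u <= v else (v, u)
            mech_nets[pair] = build_mechanism_network(
                pair, data.catalog, data.tmaps, conv_results, data.ld,
                fdr_cut=cfg.fdr_erna,
            )
        report["network"] = {
            "n_nodes": dnet.number_of_nodes(),
            "n_edges": dnet.number_of_edges(),
            "n_mechanism_networks": len(mech_nets),
        }
    except Exception as exc:
        raise RuntimeError(f"[network] {exc}") from exc
    t0 = _stage(report, "network", t0)

    if outdir is not None:
        cio.write_convergence_results(conv_results, outdir / "convergence.tsv")
        cio.write_comorbidity_results(merged, outdir / "comorbidity.tsv")
        if sims is not None:
            cio.write_similarity_matrix(sims, outdir / "similarity.tsv")
        if grid is not None:
            grid.cells.to_csv(outdir / "concordance_grid.tsv", sep="\t", index=False)
        write_graphml(dnet, outdir / "disease_network.graphml")
        write_sif(dnet, outdir / "disease_network.sif")
        for (d1, d2), g in mech_nets.items():
            stem = f"mechanism_{d1}_{d2}".replace(" ", "_")
            write_graphml(g, outdir / f"{stem}.graphml")
        # timings vary run to run; the persisted report must be reproducible
        persisted = {k: v for k, v in report.items() if k != "timings_s"}
        (outdir / "report.json").write_text(
            json.dumps(persisted, indent=2, sort_keys=True) + "\n"
        )
    return report
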