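"""Concordance between molecular convergence and clinical comorbidity.

The headline question: are disease pairs with significantly overlapping
eQTL-RNA sets overrepresented among pairs observed as comorbid in the
claims data?  Answered by a Fisher exact test on the 2x2 classification
(convergent x comorbid) of the pair universe, with a robustness grid over
both FDR cutoffs and an ontology-similarity-filtered sensitivity variant
that drops near-identical disease pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import Contingency2x2, fisher_exact_2x2

__all__ = [
    "PairResult",
    "ConcordanceResult",
    "ConcordanceGrid",
    "build_pair_results",
    "concordance_fet",
    "robustness_grid",
    "similarity_filtered_concordance",
    "DEFAULT_ERNA_GRID",
    "DEFAULT_COMORBIDITY_GRID",
]

#: default robustness-grid axes: log-spaced FDR cutoffs from very
#: stringent up to the conventional 0.05
DEFAULT_ERNA_GRID = tuple(np.geomspace(1e-18, 0.05, 7))
DEFAULT_COMORBIDITY_GRID = tuple(np.geomspace(1e-11, 0.05, 6))


@dataclass
class PairResult:
    """Both arms' evidence for one disease pair.

    ``tissue_fdr`` maps tissue -> FDR_eRNA for every tissue where the
    pair was testable (empty when untested in the molecular arm);
    ``fdr_comorbidity`` / ``pair_or`` come from the merged claims scan
    (NaN when untested there).  Significance at any cutoff is recomputed
    from these, so one PairResult list serves the whole robustness grid.
    """

    pair: tuple[str, str]
    tissue_fdr: dict[str, float] = field(default_factory=dict)
    fdr_comorbidity: float = float("nan")
    pair_or: float = float("nan")

    @property
    def tested_convergence(self) -> bool:
        return bool(self.tissue_fdr)

    @property
    def tested_comorbidity(self) -> bool:
        return not math.isnan(self.fdr_comorbidity)

    @property
    def tested_in_both(self) -> bool:
        return self.tested_convergence and self.tested_comorbidity

    @property
    def best_fdr_erna(self) -> float:
        return min(self.tissue_fdr.values()) if self.tissue_fdr else float("nan")

    def tissue_count_at(self, fdr_cut: float) -> int:
        return sum(1 for q in self.tissue_fdr.values() if q < fdr_cut)

    def convergent_at(self, fdr_cut: float) -> bool:
        return self.tissue_count_at(fdr_cut) >= 1

    def comorbid_at(self, fdr_cut: float, or_cut: float) -> bool:
        return (
            self.tested_comorbidity
            and self.fdr_comorbidity < fdr_cut
            and self.pair_or > or_cut
        )


def build_pair_results(convergence_results, comorbidity_results) -> list[PairResult]:
    """Join the per-tissue molecular scan with the merged claims scan."""
    by_pair: dict[tuple[str, str], PairResult] = {}

    def entry(pair):
        if pair not in by_pair:
            by_pair[pair] = PairResult(pair=pair)
        return by_pair[pair]

    for r in convergence_results:
        entry(r.pair).tissue_fdr[r.tissue] = r.fdr_erna
    for r in comorbidity_results:
        e = entry(r.pair)
        e.fdr_comorbidity = r.fdr_comorbidity
        e.pair_or = r.pair_or
    return [by_pair[p] for p in sorted(by_pair)]


@dataclass(frozen=True)
class ConcordanceResult:
    """One convergent-x-comorbid enrichment test."""

    table: Contingency2x2
    odds_ratio: float
    p_value: float
    fdr_erna_cut: float
    fdr_comorbidity_cut: float
    or_cut: float
    n_universe: int


def _select_universe(pairs, universe: str) -> list[PairResult]:
    if universe == "both":
        return [p for p in pairs if p.tested_in_both]
    if universe == "union":
        return [p for p in pairs if p.tested_convergence or p.tested_comorbidity]
    if universe == "all":
        return list(pairs)
    raise ValueError(f"unknown universe option {universe!r}")


def concordance_fet(
    pairs,
    fdr_e: float = 0.05,
    fdr_c: float = 0.05,
    or_cut: float = 1.5,
    universe: str = "both",
    alternative: str = "greater",
) -> ConcordanceResult:
    """Fisher exact test of convergent pairs among comorbid pairs.

    The universe defaults to pairs testable in *both* arms; pairs outside
    a test's coverage count as non-significant under the ``union`` and
    ``all`` options.  Raises on an empty universe or a degenerate margin
    (all or none of the universe significant on either axis).
    """
    selected = _select_universe(pairs, universe)
    if not selected:
        raise ValueError("empty pair universe")
    a = b = c = d = 0
    for p in selected:
        conv = p.convergent_at(fdr_e)
        com = p.comorbid_at(fdr_c, or_cut)
        if conv and com:
            a += 1
        elif conv:
            b += 1
        elif com:
            c += 1
        else:
            d += 1
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(
            f"degenerate concordance margin (a={a}, b={b}, c={c}, d={d}): "
            "a cutoff flags all or none of the universe"
        )
    table = Contingency2x2(a, b, c, d)
    res = fisher_exact_2x2(table, alternative=alternative)
    return ConcordanceResult(
        table=table,
        odds_ratio=res.odds_ratio,
        p_value=res.p_value,
        fdr_erna_cut=fdr_e,
        fdr_comorbidity_cut=fdr_c,
        or_cut=or_cut,
        n_universe=len(selected),
    )


@dataclass
class ConcordanceGrid:
    """Long-format robustness surface over cutoff combinations.

    ``cells`` has one row per (fdr_e, fdr_c, or_cut) with the contingency
    counts, OR and p; degenerate cells carry NaN statistics rather than
    failing the grid.
    """

    cells: pd.DataFrame

    def at(self, fdr_e: float, fdr_c: float, or_cut: float) -> pd.Series:
        m = self.cells
        row = m[
            np.isclose(m["fdr_e"], fdr_e)
            & np.isclose(m["fdr_c"], fdr_c)
            & np.isclose(m["or_cut"], or_cut)
        ]
        if row.empty:
            raise KeyError((fdr_e, fdr_c, or_cut))
        return row.iloc[0]


def robustness_grid(
    pairs,
    fdr_e_grid=DEFAULT_ERNA_GRID,
    fdr_c_grid=DEFAULT_COMORBIDITY_GRID,
    or_cuts=(1.5, 3.0),
    universe: str = "both",
) -> ConcordanceGrid:
    """Concordance FET at every cutoff combination."""
    fdr_e_grid = list(fdr_e_grid)
    fdr_c_grid = list(fdr_c_grid)
    or_cuts = list(or_cuts)
    if not (fdr_e_grid and fdr_c_grid and or_cuts):
        raise ValueError("empty grid axis")
    rows = []
    for fe, fc, oc in itertools.product(fdr_e_grid, fdr_c_grid, or_cuts):
        rec = {"fdr_e": fe, "fdr_c": fc, "or_cut": oc}
        try:
            r = concordance_fet(pairs, fe, fc, oc, universe=universe)
            rec.update(
                a=r.table.a, b=r.table.b, c=r.table.c, d=r.table.d,
                odds_ratio=r.odds_ratio, p_value=r.p_value, degenerate=False,
            )
        except ValueError:
            rec.update(
                a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                odds_ratio=np.nan, p_value=np.nan, degenerate=True,
            )
        rows.append(rec)
    return ConcordanceGrid(cells=pd.DataFrame(rows))


def similarity_filtered_concordance(
    pairs,
    similarities: dict[tuple[str, str], float],
    threshold: float = 0.9,
    **fet_kwargs,
) -> ConcordanceResult:
    """Concordance after excluding near-identical disease pairs.

    Disease bundles sharing a highly similar ontology concept (Lin score
    above ``threshold``) could be comorbid and convergent simply because
    they are the same disease under two names; dropping them tests
    whether the enrichment survives.  Every universe pair must have a
    similarity entry (either orientation).
    """
    universe = fet_kwargs.get("universe", "both")
    selected = _select_universe(pairs, universe)
    kept = []
    for p in selected:
        s = similarities.get(p.pair, similarities.get((p.pair[1], p.pair[0])))
        if s is None:
            raise KeyError(f"no similarity score for pair {p.pair}")
        if s <= threshold:
            kept.append(p)
    return concordance_fet(kept, **fet_kwargs)
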