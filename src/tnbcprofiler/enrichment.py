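"""Gene-set over-representation tests for PCA modules.

A module (e.g. the 250 probes with the lowest loadings on a component) is
collapsed to unique gene symbols and tested against each set of a
collection by the one-sided hypergeometric (Fisher's exact, enrichment
tail) test, BH-FDR-adjusted across the collection.  For GO-style DAGs the
"elim" decorrelation is available: terms are tested children-first, and a
term significant below the elimination threshold has its annotated genes
removed from all ancestors before those are tested, so a parent is not
called significant merely because a specific child is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, GoDag

__all__ = ["EnrichmentResult", "fisher_enrichment", "go_elim_enrichment"]

#: elimination threshold for the DAG-aware procedure
DEFAULT_ELIM_THRESHOLD = 0.01


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int
    set_size: int
    selection_size: int
    overlap: int
    odds_direction: str  # "enriched" or "depleted" point direction
    p: float
    fdr: float = np.nan
    classic_p: float = np.nan  # only for the DAG procedure
    note: str = ""

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.selection_size):
            raise ValueError("overlap exceeds set or selection size")


def _hypergeom_upper(overlap: int, universe: int, set_size: int,
                     selection: int) -> float:
    """P(X >= overlap), X ~ Hypergeom(universe, set_size, selection)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, selection))


def _direction(overlap: int, universe: int, set_size: int,
               selection: int) -> str:
    expected = set_size * selection / universe if universe else 0.0
    return "enriched" if overlap >= expected else "depleted"


def fisher_enrichment(
    selection: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
) -> list[EnrichmentResult]:
    """One-sided enrichment of each gene set in the selection.

    ``selection`` and ``universe`` are gene symbols (probe lists must be
    collapsed to genes upstream so a gene counts once however many of its
    probes were selected).  Sets are intersected with the universe first;
    sets disjoint from it are reported with a note and no test.  BH-FDR is
    computed across the tested sets.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    selection = {g.upper() for g in selection} & universe
    results: list[EnrichmentResult] = []
    tested_idx: list[int] = []
    for name in collection:
        members = collection[name] & universe
        if not members:
            results.append(EnrichmentResult(
                set_name=name, universe_size=len(universe), set_size=0,
                selection_size=len(selection), overlap=0,
                odds_direction="enriched", p=np.nan,
                note="set disjoint from universe; skipped"))
            continue
        overlap = len(members & selection)
        p = _hypergeom_upper(overlap, len(universe), len(members),
                             len(selection))
        results.append(EnrichmentResult(
            set_name=name, universe_size=len(universe), set_size=len(members),
            selection_size=len(selection), overlap=overlap,
            odds_direction=_direction(overlap, len(universe), len(members),
                                      len(selection)),
            p=p))
        tested_idx.append(len(results) - 1)
    if tested_idx:
        ps = [results[i].p for i in tested_idx]
        fdr = multipletests(ps, method="fdr_bh")[1]
        for i, q in zip(tested_idx, fdr):
            results[i].fdr = float(q)
    return results


def go_elim_enrichment(
    selection: set[str] | list[str],
    dag: GoDag,
    universe: set[str] | list[str],
    elim_threshold: float = DEFAULT_ELIM_THRESHOLD,
) -> list[EnrichmentResult]:
    """DAG-aware enrichment with child-driven elimination.

    Terms are processed in reverse topological order (every child before
    its parents).  Each term is tested by the one-sided hypergeometric test
    on its currently remaining annotation; when its (elim) p-value falls
    below ``elim_threshold``, all genes annotated to the term are removed
    from every ancestor's annotation before those ancestors are tested.
    Both the classic p (no elimination) and the elim p are reported; with a
    flat DAG or a threshold of 0 the two coincide.  FDR is computed over
    the elim p-values.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    selection = {g.upper() for g in selection} & universe
    eliminated: dict[str, set] = {tid: set() for tid in dag.topological_order()}
    results: list[EnrichmentResult] = []
    for tid in dag.topological_order():
        annotated = dag.annotations[tid] & universe
        remaining = annotated - eliminated[tid]
        classic_p = _hypergeom_upper(len(annotated & selection), len(universe),
                                     len(annotated), len(selection)) \
            if annotated else np.nan
        if not annotated:
            results.append(EnrichmentResult(
                set_name=tid, universe_size=len(universe), set_size=0,
                selection_size=len(selection), overlap=0,
                odds_direction="enriched", p=np.nan, classic_p=np.nan,
                note="no annotated genes in universe; skipped"))
            continue
        overlap = len(remaining & selection)
        elim_p = _hypergeom_upper(overlap, len(universe), len(remaining),
                                  len(selection)) if remaining else 1.0
        if elim_p < elim_threshold:
            for anc in dag.ancestors(tid):
                eliminated[anc] |= remaining
        results.append(EnrichmentResult(
            set_name=tid, universe_size=len(universe), set_size=len(remaining),
            selection_size=len(selection), overlap=overlap,
            odds_direction=_direction(overlap, len(universe),
                                      max(len(remaining), 1), len(selection)),
            p=elim_p, classic_p=classic_p))
    tested = [r for r in results if not np.isnan(r.p)]
    if tested:
        fdr = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, fdr):
            r.fdr = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame mirroring the usual report columns."""
    return pd.DataFrame([vars(r) for r in results]).set_index("set_name")
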