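"""Hypergeometric over-representation analysis and the cross-route
pathway co-occurrence intersection.

For a query cluster of ``n`` genes drawn from a universe of ``N`` genes,
the probability of seeing at least the achieved overlap ``k`` with a
pathway of ``K`` universe genes is the upper tail of the hypergeometric
distribution.  Raw p-values are thresholded (no multiple-testing
correction, matching the raw p < 0.05 convention of classic
over-representation reports); a Benjamini-Hochberg q-value is attached
for information only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class PathwayCollection:
    """Named gene sets plus the background universe used for testing."""

    pathways: Mapping[str, frozenset]
    universe: frozenset
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise EnrichmentError("empty universe")
        for name, genes in self.pathways.items():
            if not genes:
                raise EnrichmentError(f"pathway {name!r} is empty")

    def restricted(self, name: str) -> frozenset:
        """Pathway genes intersected with the universe."""
        return frozenset(self.pathways[name]) & self.universe


@dataclass
class EnrichmentResult:
    source_clade: str
    pathway_name: str
    overlap_genes: frozenset
    overlap_count: int
    p_value: float
    q_value: float


# ----------------------------------------------------------------------
def overrepresentation_test(
    query: Iterable,
    collection: PathwayCollection,
    threshold: float = 0.05,
    min_overlap: int = 2,
    source_clade: str = "",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of a gene cluster against every
    pathway; rows kept iff overlap >= ``min_overlap`` and p <= ``threshold``,
    sorted ascending by p (name breaks ties).

    Query genes outside the universe are dropped with a logged warning;
    duplicates are ignored.
    """
    universe = collection.universe
    query_set = set(query)
    outside = query_set - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
    query_set &= universe
    big_n = len(universe)
    n = len(query_set)

    names = sorted(collection.pathways)
    pvals = np.ones(len(names))
    overlaps: list[frozenset] = []
    for j, name in enumerate(names):
        members = collection.restricted(name)
        overlap = frozenset(query_set & members)
        overlaps.append(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        pvals[j] = stats.hypergeom.sf(len(overlap) - 1, big_n, len(members), n)
    qvals = stats.false_discovery_control(pvals) if len(pvals) else pvals

    results = [
        EnrichmentResult(
            source_clade=source_clade,
            pathway_name=name,
            overlap_genes=overlaps[j],
            overlap_count=len(overlaps[j]),
            p_value=float(pvals[j]),
            q_value=float(qvals[j]),
        )
        for j, name in enumerate(names)
        if len(overlaps[j]) >= min_overlap and pvals[j] <= threshold
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_name))
    return results


# ----------------------------------------------------------------------
@dataclass
class CoOccurrence:
    """Pathway co-occurrence between the two clustering routes.

    ``matrix[d, s]`` counts pathways significant in dendrogram clade
    ``d`` and SOM clade ``s``; ``shared`` lists each co-occurring pathway
    with the union of its overlap genes, flagging genes found by both
    routes.
    """

    matrix: pd.DataFrame
    shared: pd.DataFrame  # columns: pathway, gene, in_dend, in_som, in_both


def co_occurring_pathways(
    dend_results: Mapping[str, Sequence[EnrichmentResult]],
    som_results: Mapping[str, Sequence[EnrichmentResult]],
) -> CoOccurrence:
    dend_labels = list(dend_results)
    som_labels = list(som_results)
    mat = pd.DataFrame(0, index=pd.Index(dend_labels, name="dend_clade"),
                       columns=pd.Index(som_labels, name="som_clade"))

    dend_names: dict[str, set] = {d: {r.pathway_name for r in res}
                                  for d, res in dend_results.items()}
    som_names: dict[str, set] = {s: {r.pathway_name for r in res}
                                 for s, res in som_results.items()}
    for d in dend_labels:
        for s in som_labels:
            mat.loc[d, s] = len(dend_names[d] & som_names[s])

    all_dend = set().union(*dend_names.values()) if dend_names else set()
    all_som = set().union(*som_names.values()) if som_names else set()
    co_pathways = sorted(all_dend & all_som)

    def _route_genes(results: Mapping[str, Sequence[EnrichmentResult]], pathway: str) -> set:
        genes: set = set()
        for res in results.values():
            for r in res:
                if r.pathway_name == pathway:
                    genes |= r.overlap_genes
        return genes

    rows = []
    for pathway in co_pathways:
        g_dend = _route_genes(dend_results, pathway)
        g_som = _route_genes(som_results, pathway)
        for gene in sorted(g_dend | g_som):
            rows.append(
                (pathway, gene, gene in g_dend, gene in g_som,
                 gene in g_dend and gene in g_som)
            )
    shared = pd.DataFrame(rows, columns=["pathway", "gene", "in_dend", "in_som", "in_both"])
    return CoOccurrence(matrix=mat, shared=shared)
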