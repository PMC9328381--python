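"""Hypergeometric over-representation of gene lists against gene-set
collections (GO-style GMT files), plus the prior-coexpression evidence check
for hub genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import FormatError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe.

    ``terms`` maps term id -> member gene set; ``names`` carries the optional
    human-readable description from the GMT second column.
    """

    terms: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: set[str], min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every term with a new universe and apply size bounds."""
        out: dict[str, set[str]] = {}
        for term, genes in self.terms.items():
            members = genes & universe
            if len(members) >= min_size and (max_size is None or len(members) <= max_size):
                out[term] = members
        return GeneSetCollection(out, set(universe), {t: self.names.get(t, t) for t in out})


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (term, description, genes... per tab-separated line)."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    all_genes: set[str] = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {line_no}: expected term, description and >= 1 gene")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in terms:
            raise FormatError(f"GMT line {line_no}: duplicate term {term!r}")
        terms[term] = set(genes)
        names[term] = desc
        all_genes |= terms[term]
    return GeneSetCollection(terms, universe if universe is not None else all_genes, names)


def hypergeometric_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    min_term_size: int = 10,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each term.

    Terms are first restricted to the collection's universe and filtered by
    size; query genes outside the universe are dropped with a warning.  The
    returned table carries raw P values and Benjamini-Hochberg q values,
    sorted ascending by P (ties by term id).
    """
    universe = collection.universe
    outside = query - universe
    if outside:
        logger.warning("dropping %d query gene(s) outside the universe", len(outside))
    query = query & universe
    if not query:
        raise PipelineError("query is empty after restriction to the universe")
    restricted = collection.restrict(universe, min_term_size, max_term_size)
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(restricted.terms):
        members = restricted.terms[term]
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, n_universe, len(members), n_query))
        rows.append({
            "term": term,
            "name": restricted.names.get(term, term),
            "overlap": k,
            "term_size": len(members),
            "query_size": n_query,
            "universe_size": n_universe,
            "p_value": p,
        })
    if not rows:
        raise PipelineError("no gene set survives the size filter")
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def read_evidence_pairs(path: str | Path) -> set[frozenset[str]]:
    """Read a two-column TSV of unordered gene pairs with prior coexpression
    evidence (the offline stand-in for a public-repository coexpression
    lookup)."""
    pairs: set[frozenset[str]] = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"evidence line {line_no}: expected two tab-separated gene ids")
        a, b = parts[0].strip(), parts[1].strip()
        if a != b:
            pairs.add(frozenset((a, b)))
    return pairs


def prior_coexpression_fraction(
    hub_sets: dict[str, list[str] | set[str]],
    evidence: set[frozenset[str]],
) -> tuple[dict[str, float], float]:
    """Fraction of hub genes with at least one evidence partner in the same hub set.

    Returns the per-module fractions and the overall fraction across all hub
    genes.  Modules with an empty hub set are skipped with a warning.
    """
    per_module: dict[str, float] = {}
    supported_total = 0
    n_total = 0
    for module, hubs in hub_sets.items():
        hubs = list(hubs)
        if not hubs:
            logger.warning("module %s has an empty hub set; skipped", module)
            continue
        hub_set = set(hubs)
        supported = sum(
            1 for g in hubs
            if any(frozenset((g, other)) in evidence for other in hub_set if other != g)
        )
        per_module[module] = supported / len(hubs)
        supported_total += supported
        n_total += len(hubs)
    overall = supported_total / n_total if n_total else 0.0
    return per_module, overall
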