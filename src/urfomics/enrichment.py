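"""Over-representation analysis of gene sets against a GMT catalog.

Each feature's positive-specific gene set is tested term by term with an
upper-tail hypergeometric test; the universe is the set of all genes
annotated in the catalog.  Raw p < threshold defines the main "function
set" of a feature; Benjamini-Hochberg adjusted p is available for
stricter validation-style calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "bh_adjust",
    "enrich_feature",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe of all annotated genes."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.terms.items():
            if not genes:
                raise ValueError(f"empty term {name!r}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Read a tab-separated GMT file (term, description, genes...)."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            terms[name] = frozenset(genes)
            descriptions[name] = desc
    if not terms:
        raise ValueError(f"no terms parsed from {path}")
    return GeneSetCollection(terms=terms, descriptions=descriptions)


def write_gmt(catalog: GeneSetCollection, path: Path | str) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.terms.items():
            desc = (catalog.descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def hypergeometric_test(
    query_size: int, term_size: int, universe_size: int, overlap: int
) -> float:
    """Upper-tail hypergeometric p = P(X >= overlap).

    X counts how many of ``query_size`` draws (without replacement from a
    universe of ``universe_size`` genes, ``term_size`` of which are in
    the term) land in the term.
    """
    n, K, N, x = query_size, term_size, universe_size, overlap
    if not (0 <= x <= min(n, K)) or n > N or K > N:
        raise ValueError(
            f"inconsistent counts: query={n}, term={K}, universe={N}, overlap={x}"
        )
    return float(min(1.0, sps.hypergeom.sf(x - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    term: str
    overlap: int
    gene_ratio: float  # overlap / query size
    p_value: float
    p_adjusted: float
    enriched: bool


def enrich_feature(
    genes: set[str],
    catalog: GeneSetCollection,
    p_threshold: float = 0.05,
    adjust: bool = False,
    feature: str = "",
) -> list[EnrichmentResult]:
    """Test one feature's gene set against every catalog term.

    Genes outside the catalog universe are dropped with a warning;
    ``enriched`` is raw p < threshold by default, or BH-adjusted p <
    threshold when ``adjust`` is set.  Results sorted by p.
    """
    universe = catalog.universe
    query = set(genes) & universe
    dropped = len(set(genes)) - len(query)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe dropped",
                      stacklevel=2)
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    N, n = len(universe), len(query)
    names, pvals, overlaps = [], [], []
    for name, term_genes in catalog.terms.items():
        x = len(query & term_genes)
        names.append(name)
        overlaps.append(x)
        pvals.append(hypergeometric_test(n, len(term_genes), N, x))
    padj = bh_adjust(pvals)
    out = []
    for name, x, p, pa in zip(names, overlaps, pvals, padj):
        crit = pa if adjust else p
        out.append(
            EnrichmentResult(
                feature=feature,
                term=name,
                overlap=x,
                gene_ratio=x / n,
                p_value=float(p),
                p_adjusted=float(pa),
                enriched=bool(crit < p_threshold),
            )
        )
    return sorted(out, key=lambda r: r.p_value)
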