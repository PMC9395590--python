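"""Over-representation analysis of gene sets against user-supplied term maps.

Plain upper-tail hypergeometric test per term (P[X >= k] for k selected
genes in a term of K universe genes, selection size n, universe N) with BH
adjustment across terms. Term-to-gene maps are ordinary two-column TSV
files, so no ontology database access is required; the universe is an
explicit required argument.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["EnrichmentResult", "enrich", "read_term_map"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str | None
    k: int  # selected genes in term
    n: int  # selected set size
    K: int  # universe genes in term
    N: int  # universe size
    p: float
    q: float


def enrich(
    selected,
    universe,
    term_map: dict[str, set],
    alpha: float = 0.05,
    term_names: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``selected`` within ``universe``.

    Term gene sets are intersected with the universe first. Results are BH
    adjusted across all tested terms and sorted by q then p then term id.
    """
    selected = set(selected)
    universe = set(universe)
    if not universe or not selected:
        raise ValidationError("selected and universe must be non-empty")
    if not selected <= universe:
        raise ValidationError("selected gene set must be a subset of the universe")

    N, n = len(universe), len(selected)
    rows = []
    for term_id, genes in term_map.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P[X >= k]
        rows.append((term_id, k, K, min(1.0, max(p, 0.0))))
    if not rows:
        return []
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=(term_names or {}).get(tid),
            k=k, n=n, K=K, N=N, p=p, q=float(q),
        )
        for (tid, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def read_term_map(path) -> dict[str, set]:
    """Two-column TSV (term_id, gene_id) -> term -> gene set."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            term, gene = line.rstrip("\n").split("\t")[:2]
            out.setdefault(term, set()).add(gene)
    return out
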