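"""Hypergeometric term enrichment of a candidate-gene list.

For a term annotating M of the N background genes, with n candidate genes
in the background and m of them carrying the term, the enrichment P-value
is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)  =  Pr(X >= m)

for X hypergeometric. The background is the set of genes with at least one
annotation — genes nothing is known about cannot be enriched or depleted.
P-values are Bonferroni-corrected over the testable terms (M >= 1), and a
term is significant when the corrected value is <= alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

DEFAULT_ALPHA = 0.05

ENRICH_COLUMNS = ["term", "N", "n", "M", "m", "p_value", "p_adjusted", "significant"]


@dataclass(frozen=True)
class EnrichmentCounts:
    N: int  # background genes (with any annotation)
    n: int  # candidates inside the background
    M: int  # background genes annotated to the term
    m: int  # candidates annotated to the term

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need M, n <= N: {self}")
        if not 0 <= self.m <= min(self.n, self.M):
            raise ValueError(f"need m <= min(n, M): {self}")


def hypergeom_pvalue(c: EnrichmentCounts) -> float:
    """Upper-tail Pr(X >= m); the survival function is evaluated in log space
    by scipy, so tiny tails do not underflow to garbage."""
    if c.m == 0:
        return 1.0
    return float(hypergeom.sf(c.m - 1, c.N, c.M, c.n))


def enrich(
    candidates: Sequence[str],
    term_map: Mapping[str, set[str] | Sequence[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test every annotated term against a candidate list.

    Returns a table sorted by adjusted P with columns term, N, n, M, m,
    p_value, p_adjusted, significant. Terms annotating no background gene
    are dropped and do not inflate the Bonferroni multiplier.
    """
    term_sets = {t: set(g) for t, g in term_map.items()}
    background = set().union(*term_sets.values()) if term_sets else set()
    cand = set(candidates) & background
    if not candidates:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    testable = {t: g for t, g in term_sets.items() if g}
    n_tests = len(testable)
    rows = []
    for term, members in testable.items():
        c = EnrichmentCounts(
            N=len(background), n=len(cand), M=len(members), m=len(cand & members)
        )
        p = hypergeom_pvalue(c)
        p_adj = min(1.0, p * n_tests)
        rows.append((term, c.N, c.n, c.M, c.m, p, p_adj, p_adj <= alpha))
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    return df.sort_values(["p_adjusted", "p_value", "term"]).reset_index(drop=True)


def read_annotations(path) -> dict[str, set[str]]:
    """Flat two-column (gene, term) TSV -> term -> gene-set map."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term"}.issubset(df.columns):
        raise ValueError(f"{path}: needs 'gene_id' and 'term' columns")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.term, set()).add(r.gene_id)
    return out
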