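"""Exact enrichment statistics for motif presence and GO terms.

Two exact tests are provided.  Fisher's two-sided exact test on a disjoint
2x2 table follows the classical ≤-probability rule (every table with the same
margins whose hypergeometric probability is at most that of the observed
table, with a 1e-7 relative tolerance on the comparison, contributes to p) —
the same convention as R's fisher.test.  GO-term enrichment uses the
hypergeometric upper tail.  Multiple testing is corrected per analysis family
with Benjamini-Hochberg.

The reported background proportion and percent increase for a gene set use
the *full-genome* proportion (set included), so the printed percentages are
directly comparable to whole-genome occurrence figures, while the test itself
is computed on the disjoint 2x2 (background minus the set in cells c and d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

# Relative tolerance on the pmf comparison in the two-sided rule, as used by
# R's fisher.test.
_FISHER_REL_TOL_NUM = 10_000_001
_FISHER_REL_TOL_DEN = 10_000_000

# Below this grand total the two-sided p is computed with exact integers.
_EXACT_N_LIMIT = 2000


class EnrichmentError(ValueError):
    """Raised for invalid enrichment inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """Disjoint 2x2 table: a/b = set genes with/without the feature,
    c/d = (background minus set) genes with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("contingency counts must be non-negative")


@dataclass
class EnrichmentResult:
    feature: str
    k_set: int
    n_set: int
    k_bg: int
    n_bg: int
    prop_set: float
    prop_bg: float
    percent_increase: float
    odds_ratio: float
    p: float
    p_adj: float


RESULT_COLUMNS = [
    "feature",
    "k_set",
    "n_set",
    "k_bg",
    "n_bg",
    "prop_set",
    "prop_bg",
    "percent_increase",
    "odds_ratio",
    "p",
    "p_adj",
]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c > 0:
        return (a * d) / (b * c)
    if a * d > 0:
        return math.inf
    return math.nan


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test: (odds_ratio, p).

    The odds ratio is the sample odds ratio a*d / b*c, reported as infinity
    when b*c = 0 with a*d > 0 and NaN when both products vanish.  For small
    tables the p-value is an exact rational computed with integer binomial
    coefficients; large tables switch to a log-space evaluation.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    grand = a + b + c + d
    odds = _odds_ratio(a, b, c, d)
    if grand == 0:
        return odds, 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - grand)
    hi = min(row1, col1)
    if lo == hi:
        return odds, 1.0
    if grand <= _EXACT_N_LIMIT:
        weights = [
            math.comb(row1, x) * math.comb(grand - row1, col1 - x)
            for x in range(lo, hi + 1)
        ]
        observed = weights[a - lo]
        total = sum(weights)
        threshold = observed * _FISHER_REL_TOL_NUM
        included = sum(
            w for w in weights if w * _FISHER_REL_TOL_DEN <= threshold
        )
        p = included / total
    else:
        x = np.arange(lo, hi + 1)
        logw = (
            gammaln(row1 + 1)
            - gammaln(x + 1)
            - gammaln(row1 - x + 1)
            + gammaln(grand - row1 + 1)
            - gammaln(col1 - x + 1)
            - gammaln(grand - row1 - col1 + x + 1)
        )
        log_obs = logw[a - lo]
        mask = logw <= log_obs + math.log1p(
            _FISHER_REL_TOL_NUM / _FISHER_REL_TOL_DEN - 1.0
        )
        p = float(np.exp(logsumexp(logw[mask]) - logsumexp(logw)))
    return odds, min(p, 1.0)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated in log space.

    N: background size, K: background genes with the feature, n: draws
    (set size), k: observed successes in the set.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(
            f"impossible margins: N={N}, K={K}, n={n}, k={k}"
        )
    if k > K or n - k > N - K:
        raise EnrichmentError(
            f"impossible margins: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_increase(prop_set: float, prop_bg: float) -> float:
    """100 * (prop_set / prop_bg - 1); requires a positive background."""
    if prop_bg <= 0:
        raise EnrichmentError("background proportion must be positive")
    return 100.0 * (prop_set / prop_bg - 1.0)


def _feature_enrichment_rows(
    gene_set: frozenset[str],
    background: frozenset[str],
    features: Sequence[tuple[str, frozenset[str]]],
) -> pd.DataFrame:
    """Shared 2x2 machinery: one Fisher row per (name, genes-with-feature)."""
    n_set = len(gene_set)
    n_bg = len(background)
    rest = background - gene_set
    rows = []
    for name, with_feature in features:
        k_set = len(gene_set & with_feature)
        k_rest = len(rest & with_feature)
        table = ContingencyTable(
            a=k_set, b=n_set - k_set, c=k_rest, d=len(rest) - k_rest
        )
        odds, p = fisher_exact_two_sided(table)
        k_all = k_set + k_rest
        prop_set = k_set / n_set if n_set else math.nan
        prop_bg = k_all / n_bg if n_bg else math.nan
        pct = (
            percent_increase(prop_set, prop_bg) if prop_bg > 0 else math.nan
        )
        rows.append(
            {
                "feature": name,
                "k_set": k_set,
                "n_set": n_set,
                "k_bg": k_all,
                "n_bg": n_bg,
                "prop_set": prop_set,
                "prop_bg": prop_bg,
                "percent_increase": pct,
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "p_adj"])
    result["p_adj"] = benjamini_hochberg(result["p"]) if len(result) else []
    return result[RESULT_COLUMNS]


def motif_set_enrichment(
    gene_set: Iterable[str],
    presence_table: pd.DataFrame,
    feature_kind: str,
    background_genes: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of motif presence in a gene set vs the genome.

    ``feature_kind`` selects single-motif presence ("single") or adjacent
    pair presence ("adjacent_pair").  One row per motif in the presence
    table; BH correction across motifs.  Reported prop_bg / percent_increase
    use the full-genome proportion; the test uses the disjoint 2x2.
    """
    from . import motifs as _motifs

    gene_set = frozenset(gene_set)
    background = frozenset(background_genes)
    if not background:
        raise EnrichmentError("empty background")
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:5]
        raise EnrichmentError(f"gene set not within background, e.g. {extra}")
    covered = set(presence_table["gene_id"])
    missing = gene_set - covered
    if missing:
        raise EnrichmentError(
            f"genes absent from presence table, e.g. {sorted(missing)[:5]}"
        )
    names = sorted(presence_table["motif"].unique())
    features = [
        (
            name,
            _motifs.genes_with_feature(presence_table, name, feature_kind)
            & background,
        )
        for name in names
    ]
    return _feature_enrichment_rows(gene_set, background, features)


class GOCycleError(ValueError):
    """Raised when the term-parent graph contains a cycle."""


def propagate_go(
    gene2term: Mapping[str, Iterable[str]],
    term_parents: Mapping[str, Iterable[str]],
) -> dict[str, frozenset[str]]:
    """Close each gene's annotation over the ancestor relation.

    ``term_parents`` maps a term to its direct parents (DAG edges); cycles
    raise :class:`GOCycleError` naming the offending path.
    """
    ancestors: dict[str, frozenset[str]] = {}
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(term: str, path: list[str]) -> frozenset[str]:
        state = color.get(term, WHITE)
        if state == GRAY:
            cycle = path[path.index(term) :] + [term]
            raise GOCycleError(f"cycle in term parents: {' -> '.join(cycle)}")
        if state == BLACK:
            return ancestors[term]
        color[term] = GRAY
        result: set[str] = set()
        for parent in term_parents.get(term, ()):
            result.add(parent)
            result |= visit(parent, path + [term])
        color[term] = BLACK
        ancestors[term] = frozenset(result)
        return ancestors[term]

    for term in term_parents:
        visit(term, [])

    closed: dict[str, frozenset[str]] = {}
    for gene, terms in gene2term.items():
        full: set[str] = set()
        for term in terms:
            full.add(term)
            full |= visit(term, [])
        closed[gene] = frozenset(full)
    return closed


def go_enrichment(
    gene_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    term_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of a gene set vs the background.

    ``annotations`` should already be ancestor-propagated (see
    :func:`propagate_go`).  Terms with no annotated gene in the set are not
    tested; when ``term_universe`` (e.g. a GO slim) is given, testing is
    restricted to it.  BH correction across tested terms.
    """
    gene_set = frozenset(gene_set)
    background = frozenset(background_genes)
    if not background:
        raise EnrichmentError("empty background")
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:5]
        raise EnrichmentError(f"gene set not within background, e.g. {extra}")
    universe = frozenset(term_universe) if term_universe is not None else None

    term_bg: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            if universe is not None and term not in universe:
                continue
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in gene_set:
                term_set[term] = term_set.get(term, 0) + 1

    N, n = len(background), len(gene_set)
    rows = []
    for term in sorted(term_set):
        k, K = term_set[term], term_bg[term]
        p = hypergeometric_upper_tail(N, K, n, k)
        prop_set = k / n
        prop_bg = K / N
        odds = _odds_ratio(k, n - k, K - k, N - K - (n - k))
        rows.append(
            {
                "feature": term,
                "k_set": k,
                "n_set": n,
                "k_bg": K,
                "n_bg": N,
                "prop_set": prop_set,
                "prop_bg": prop_bg,
                "percent_increase": percent_increase(prop_set, prop_bg),
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "p_adj"])
    result["p_adj"] = benjamini_hochberg(result["p"]) if len(result) else []
    result = result[RESULT_COLUMNS]
    return result.sort_values(["p", "feature"], kind="mergesort").reset_index(
        drop=True
    )


def read_gene2term(path) -> dict[str, set[str]]:
    """Read a (gene_id, term_id) TSV into {gene: {terms}}."""
    table = pd.read_csv(path, sep="\t")
    gene_col, term_col = table.columns[:2]
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(table[gene_col], table[term_col]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping


def read_term_parents(path) -> dict[str, set[str]]:
    """Read a (child, parent) TSV into {child: {parents}}."""
    table = pd.read_csv(path, sep="\t")
    child_col, parent_col = table.columns[:2]
    mapping: dict[str, set[str]] = {}
    for child, parent in zip(table[child_col], table[parent_col]):
        mapping.setdefault(str(child), set()).add(str(parent))
    return mapping
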