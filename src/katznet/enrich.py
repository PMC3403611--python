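"""Hypergeometric gene-set enrichment, overlap tests, and abundance summaries.

Drawing ``n`` query genes from a background of ``N`` genes of which ``K``
carry an annotation, the overlap count follows the hypergeometric law

    f(i) = C(K, i) C(N-K, n-i) / C(N, n)

and the enrichment p-value is the upper tail P(X >= k) = 1 - sum_{i<k} f(i).
Raw p-values are compared against a significance level alpha (no multiple-
testing correction by default; an optional Benjamini-Hochberg mode exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Subnetwork

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "AbundanceSummary",
    "ABUNDANCE_LEVELS",
    "hypergeom_pmf",
    "hypergeom_tail_p",
    "enrich",
    "overlap_subnetwork",
    "abundance_distribution",
]

ABUNDANCE_LEVELS = ("negative", "weak", "moderate", "strong")
#: levels counted as "detected" in tissue-abundance summaries
DETECTED_LEVELS = frozenset({"weak", "moderate", "strong"})


@dataclass
class GeneSetCollection:
    """Annotation terms: term id -> (display name, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


def _check_triple(N: int, K: int, n: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")


def hypergeom_pmf(i: int, N: int, K: int, n: int) -> float:
    """P(X = i) for the overlap of an n-draw with K marked items among N.

    Out-of-support ``i`` returns 0; the computation runs in log space via
    scipy for numerical stability at genome-scale N.
    """
    _check_triple(N, K, n)
    if i < max(0, n + K - N) or i > min(n, K):
        return 0.0
    return float(stats.hypergeom.pmf(i, N, K, n))


def hypergeom_tail_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail enrichment p-value P(X >= k) = 1 - sum_{i=0}^{k-1} f(i)."""
    _check_triple(N, K, n)
    if k <= max(0, n + K - N):
        return 1.0
    if k > min(n, K):
        return 0.0
    return float(min(1.0, max(0.0, stats.hypergeom.sf(k - 1, N, K, n))))


@dataclass
class EnrichmentRecord:
    """One annotation term's enrichment against the query.

    N: background size; K: term members in the background; n: query size;
    k: overlap of query and term within the background.
    """

    term_id: str
    name: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    significant: bool
    q_value: float | None = None

    def as_dict(self) -> dict:
        d = {
            "term_id": self.term_id,
            "name": self.name,
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "p_value": self.p_value,
            "significant": self.significant,
        }
        if self.q_value is not None:
            d["q_value"] = self.q_value
        return d


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
    include_zero_overlap: bool = False,
    bh_adjust: bool = False,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of every term against the query.

    Query genes outside the background are clipped with a warning.  Records
    come back sorted by ascending p (term id as tie-break); ``significant``
    compares the raw p (or the BH q when ``bh_adjust``) against ``alpha``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene set is empty")
    query = set(query_genes)
    outside = query - bg
    if outside:
        warnings.warn(
            f"{len(outside)} query genes absent from the background were clipped",
            stacklevel=2,
        )
        query &= bg
    N, n = len(bg), len(query)
    records = []
    for term_id, (name, members) in sorted(collection.terms.items()):
        members_bg = members & bg
        K = len(members_bg)
        k = len(members_bg & query)
        if k == 0 and not include_zero_overlap:
            continue
        if K == 0:
            continue
        p = hypergeom_tail_p(k, N, K, n)
        records.append(
            EnrichmentRecord(
                term_id=term_id, name=name, N=N, K=K, n=n, k=k,
                p_value=p, significant=p <= alpha,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term_id))
    if bh_adjust and records:
        qvals = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, qvals):
            r.q_value = float(q)
            r.significant = q <= alpha
    return records


def records_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame.from_records([r.as_dict() for r in records])


@dataclass
class OverlapResult:
    """Overlap of the disease subnetwork with a reference gene collection."""

    overlap_nodes: frozenset[str]
    composition_tests: dict[str, EnrichmentRecord] = field(default_factory=dict)


def overlap_subnetwork(
    sub: Subnetwork,
    reference_genes: Iterable[str],
    inner_core_genes: Iterable[str] = (),
    seed_genes: Iterable[str] = (),
) -> OverlapResult:
    """Map subnetwork nodes onto a reference set and test the overlap's makeup.

    With the subnetwork's node set as background, two hypergeometric tests
    ask whether the overlap over-represents (a) inner-core nodes and (b)
    non-seed nodes — the pattern expected when the propagation pulls a
    coherent functional core around scattered seeds.
    """
    nodes = set(sub.nodes)
    overlap = nodes & set(reference_genes)
    N, n = len(nodes), len(overlap)
    tests: dict[str, EnrichmentRecord] = {}
    for label, marked in (
        ("inner_core", nodes & set(inner_core_genes)),
        ("non_seed", nodes - set(seed_genes)),
    ):
        K = len(marked)
        k = len(overlap & marked)
        if N == 0:
            continue
        p = hypergeom_tail_p(k, N, K, n)
        tests[label] = EnrichmentRecord(
            term_id=label, name=f"overlap composition: {label}",
            N=N, K=K, n=n, k=k, p_value=p, significant=p <= 0.001,
        )
    return OverlapResult(overlap_nodes=frozenset(overlap), composition_tests=tests)


@dataclass
class AbundanceSummary:
    """Tissue-abundance composition of a node set on the four-level scale."""

    coverage: float
    counts: dict[str, int]
    fractions: dict[str, float]
    detected_fraction: float
    n_nodes: int
    n_covered: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(ABUNDANCE_LEVELS),
                "count": [self.counts[lv] for lv in ABUNDANCE_LEVELS],
                "fraction": [self.fractions[lv] for lv in ABUNDANCE_LEVELS],
            }
        )


def abundance_distribution(
    sub: Subnetwork | Iterable[str], table: Mapping[str, str]
) -> AbundanceSummary:
    """Distribution of abundance levels over the subnetwork's nodes.

    ``coverage`` is the fraction of nodes present in the table at all;
    ``detected_fraction`` is the fraction of *all* nodes whose level is
    weak, moderate or strong (negative and absent both count as
    undetected).
    """
    nodes = list(sub.nodes) if isinstance(sub, Subnetwork) else list(sub)
    bad = {lv for lv in table.values() if lv not in ABUNDANCE_LEVELS}
    if bad:
        raise ValueError(f"unknown abundance levels: {sorted(bad)}")
    counts = {lv: 0 for lv in ABUNDANCE_LEVELS}
    covered = 0
    for g in nodes:
        lv = table.get(g)
        if lv is not None:
            covered += 1
            counts[lv] += 1
    n = len(nodes)
    detected = sum(counts[lv] for lv in ABUNDANCE_LEVELS if lv in DETECTED_LEVELS)
    return AbundanceSummary(
        coverage=covered / n if n else 0.0,
        counts=counts,
        fractions={lv: (c / covered if covered else 0.0) for lv, c in counts.items()},
        detected_fraction=detected / n if n else 0.0,
        n_nodes=n,
        n_covered=covered,
    )

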