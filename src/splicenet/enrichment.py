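"""Gene-set overrepresentation by the one-sided Fisher's exact (hypergeometric) test.

For a DEG list of size n drawn from a universe of N genes, a term with K
members in the universe and k members overlapping the list is scored by the
upper hypergeometric tail

    p = sum_{i >= k} C(K, i) * C(N-K, n-i) / C(N, n),

Bonferroni-adjusted over the m tested terms.  The reference universe is the
filtered array gene list by default.  A per-term direction summary (up /
down / mixed) follows a simple majority rule over the overlapping DEGs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Named gene sets (e.g. GO cellular-component terms) over a universe."""

    terms: dict[str, frozenset]
    universe: frozenset
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(m) for t, m in self.terms.items()}
        self.universe = frozenset(self.universe)
        for term, members in self.terms.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.terms)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric configuration {(k, K, n, N)}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_overrepresentation(
    deg_list: Iterable,
    annotations: AnnotationSet,
    deg_directions: Mapping | None = None,
    universe: Iterable | None = None,
    direction_majority: float = 0.5,
) -> pd.DataFrame:
    """Score every annotation term for overrepresentation in a DEG list.

    Parameters
    ----------
    deg_list
        Genes of interest; members outside the universe are dropped with
        a warning.
    annotations
        Term -> member sets.  Terms with no member in the universe are
        skipped and excluded from the Bonferroni multiplicity m.
    deg_directions
        Optional gene -> direction ("up"/"down", or a signed log2FC).
        Drives the per-term direction summary: "up" ("down") when more
        than ``direction_majority`` of the overlapping DEGs share the
        sign, else "mixed".
    universe
        Reference gene universe; defaults to the annotation universe.

    Returns a DataFrame sorted by raw p (ties by term id) with columns
    term_id, k, K, n, N, fold_enrichment, p, p_bonferroni, direction.
    """
    uni = frozenset(universe) if universe is not None else annotations.universe
    if not uni:
        raise ValueError("empty reference universe")
    degs = set(deg_list)
    outside = degs - uni
    if outside:
        log.warning("dropping %d DEGs outside the universe", len(outside))
        degs &= uni
    if not degs:
        raise ValueError("empty DEG list (after restriction to the universe)")
    N, n = len(uni), len(degs)

    tested = {t: members & uni for t, members in annotations.terms.items()}
    tested = {t: m for t, m in tested.items() if m}
    m = len(tested)
    if m == 0:
        raise ValueError("no annotation term overlaps the universe")

    rows = []
    for term, members in tested.items():
        K = len(members)
        overlap = members & degs
        k = len(overlap)
        p = hypergeom_tail(k, K, n, N)
        rows.append({
            "term_id": term,
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "fold_enrichment": (k / n) / (K / N),
            "p": p,
            "p_bonferroni": min(1.0, p * m),
            "direction": _direction(overlap, deg_directions, direction_majority),
        })
    out = pd.DataFrame(rows).sort_values(["p", "term_id"], kind="stable")
    return out.reset_index(drop=True)


def _direction(overlap: set, directions: Mapping | None, majority: float) -> str:
    if directions is None or not overlap:
        return "mixed"
    signs = []
    for gene in overlap:
        d = directions.get(gene)
        if d is None:
            continue
        if isinstance(d, str):
            signs.append(1 if d == "up" else -1 if d == "down" else 0)
        else:
            signs.append(1 if d > 0 else -1 if d < 0 else 0)
    if not signs:
        return "mixed"
    up = sum(1 for s in signs if s > 0) / len(signs)
    down = sum(1 for s in signs if s < 0) / len(signs)
    if up > majority:
        return "up"
    if down > majority:
        return "down"
    return "mixed"
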