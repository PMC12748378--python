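"""Database-agnostic overrepresentation analysis (ORA).

Takes a query gene list and a user-supplied collection of named gene sets
(typically parsed from GMT) and scores each set with the upper-tail
hypergeometric probability of the observed overlap, BH-adjusted across the
collection.  No term database is bundled; the gene universe defaults to
the union of all set members unless declared explicitly, and the universe
choice is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import InputError
from .stratify import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe.

    Sets are harmonized to the universe on construction (members outside
    the universe are dropped).  The universe defaults to the union of all
    members.
    """

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()
    descriptions: dict[str, str] = field(default_factory=dict)
    universe_source: str = "union-of-sets"

    def __post_init__(self):
        if len(set(self.sets)) != len(self.sets):
            raise InputError("gene set names must be unique")
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
            self.universe_source = "union-of-sets"
        else:
            self.universe = frozenset(self.universe)
            self.universe_source = "declared"
        self.sets = {
            name: frozenset(members) & self.universe
            for name, members in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class ORARow:
    """Overrepresentation outcome for one gene set."""

    name: str
    overlap: int        # k
    set_size: int       # K
    query_size: int     # n
    universe_size: int  # N
    p: float            # P(X >= k), hypergeometric upper tail
    q: float            # BH-adjusted
    significant: bool   # q < alpha


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` genes are drawn without replacement
    from a universe of ``N`` containing ``K`` set members.  Computed via
    the survival function (log-space internally), so small tails do not
    underflow.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[ORARow]:
    """Score every set in the collection against a query gene list.

    Duplicate query genes are dropped; query genes outside the universe
    are excluded from counting (their number is reported in the error if
    nothing remains).  BH adjustment runs across all sets in the
    collection; rows come back sorted by (q, p, name).
    """
    raw = list(query)
    q_genes = frozenset(raw)
    inside = q_genes & collection.universe
    if not inside:
        raise InputError(
            f"query is empty after universe intersection "
            f"({len(q_genes)} of {len(q_genes)} genes outside the universe)"
        )
    n_out = len(q_genes) - len(inside)
    if n_out:
        logger.info("ora: %d query genes outside the universe ignored", n_out)

    N = len(collection.universe)
    n = len(inside)
    names, pvals, ks, Ks = [], [], [], []
    for name, members in collection.sets.items():
        k = len(inside & members)
        names.append(name)
        ks.append(k)
        Ks.append(len(members))
        pvals.append(hypergeom_tail(k, len(members), n, N))
    qvals = bh_adjust(pvals)
    rows = [
        ORARow(
            name=name, overlap=k, set_size=K, query_size=n,
            universe_size=N, p=p, q=float(qv), significant=bool(qv < alpha),
        )
        for name, k, K, p, qv in zip(names, ks, Ks, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.q, r.p, r.name))
    return rows


def ora_to_frame(rows: list[ORARow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.name for r in rows],
            "overlap": [r.overlap for r in rows],
            "set_size": [r.set_size for r in rows],
            "query_size": [r.query_size for r in rows],
            "universe_size": [r.universe_size for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def top_terms(rows: list[ORARow], n: int = 10) -> list[ORARow]:
    """Display-layer truncation to the n best-ranked terms.

    Applied only when presenting results; the full table is always what
    gets stored.
    """
    return rows[:n]
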