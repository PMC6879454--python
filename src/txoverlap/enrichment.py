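"""Gene-set over-representation analysis (hypergeometric upper tail).

For a query list of size n drawn from a background universe of N genes, a set
with K members in the universe and k members hitting the query is scored with
P[X >= k], X ~ Hypergeometric(N, K, n), computed stably via the survival
function in log space. Benjamini-Hochberg adjustment is applied across all
tested sets. The universe defaults to all annotated genes of the platform and
must be chosen explicitly: it materially changes every p-value.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .datatypes import ConfigError, GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term", "description", "count", "pct", "p_value", "benjamini"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(population N, successes K, draws n)."""
    if not (0 <= k <= min(K, n)):
        raise ConfigError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ConfigError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(
    query: set[str] | frozenset[str],
    collection: GeneSetCollection,
    universe: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, against ``universe``.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe do not count toward K. One row per set with >= 1
    query hit; BH across all tested sets; rows sorted ascending by p, ties by
    term id. Columns mirror the Term/Count/%/P-value/Benjamini report schema.
    """
    if not universe:
        raise ConfigError("empty universe")
    if len(collection) == 0:
        raise ConfigError("need >= 1 gene set")
    universe = frozenset(universe)
    query_in = frozenset(query) & universe
    dropped = len(frozenset(query)) - len(query_in)
    if dropped:
        logger.warning("%d query gene(s) outside the universe dropped", dropped)
    N, n = len(universe), len(query_in)

    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & universe
        K = len(members)
        k = len(members & query_in)
        if k == 0 or K == 0:
            continue
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "count": k,
                "pct": 100.0 * k / n if n else 0.0,
                "p_value": hypergeom_upper_tail(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows)
    df["benjamini"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS]
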