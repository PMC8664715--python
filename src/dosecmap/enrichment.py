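"""Over-representation analysis (ORA) of target gene sets against a
gene-set library: hypergeometric upper-tail test, Benjamini–Hochberg
correction, a rank-deviation combined score, and signed output ranges so
up- and down-target pathways plot on opposite sides of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .targets import TargetGeneSet

logger = logging.getLogger(__name__)

__all__ = ["GeneSetLibrary", "EnrichmentResult", "hypergeom_p", "bh_adjust",
           "enrich"]


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named term -> gene-set mapping over a background universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "universe", frozenset(self.universe))
        clean = {}
        for name, genes in self.terms.items():
            gset = frozenset(genes)
            if not gset:
                raise ParameterError(f"term {name!r} has no genes")
            if not gset <= self.universe:
                raise ParameterError(
                    f"term {name!r} has genes outside the universe")
            clean[name] = gset
        object.__setattr__(self, "terms", clean)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """ORA outcome for one library term."""

    term: str
    k: int          # overlap
    K: int          # term size
    n: int          # query size
    N: int          # universe size
    p: float
    q: float
    combined: float
    signed_combined: float
    direction: str = "up"


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated via
    the survival function in log space; ``k = 0`` returns exactly 1."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ParameterError(f"impossible margins k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1, input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _overlap_pvals(member: np.ndarray, term_sizes: np.ndarray,
                   query_mask: np.ndarray, n_universe: int) -> tuple[np.ndarray,
                                                                     np.ndarray]:
    """Overlap counts and hypergeometric p-values of every term against one
    or many query columns.  ``member``: terms x genes boolean matrix."""
    ks = member @ query_mask  # (n_terms,) or (n_terms, n_queries)
    n_query = query_mask.sum(axis=0)
    p = stats.hypergeom.sf(ks - 1,
                           n_universe,
                           term_sizes[:, None] if ks.ndim == 2 else term_sizes,
                           n_query)
    p = np.where(ks == 0, 1.0, p)
    return ks, p


def enrich(
    targets: TargetGeneSet,
    lib: GeneSetLibrary,
    direction: str = "up",
    n_null: int = 200,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """ORA of one direction of a target gene set against the library.

    For every term with overlap k >= 1 the hypergeometric upper-tail p and
    its BH q-value are reported together with a combined score
    ``(-ln p) * zrank``, where ``zrank`` is the term's rank improvement over
    its expected rank under ``n_null`` seeded random queries of the same
    size (a rank-based correction in the style of the Enrichr webtool).
    ``signed_combined`` is ``+|combined|`` for up-target runs and
    ``-|combined|`` for down-target runs, giving the signed plotting ranges.
    Results are sorted by q, then p, then term name.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    query = targets.up_targets if direction == "up" else targets.down_targets
    genes_in = frozenset(query) & lib.universe
    if len(genes_in) < len(frozenset(query)):
        logger.warning("%d query genes outside the universe were dropped",
                       len(frozenset(query)) - len(genes_in))
    if not genes_in:
        return []

    universe = sorted(lib.universe)
    gene_idx = {g: i for i, g in enumerate(universe)}
    n_universe = len(universe)
    term_names = sorted(lib.terms)
    member = np.zeros((len(term_names), n_universe), dtype=np.int64)
    for ti, name in enumerate(term_names):
        member[ti, [gene_idx[g] for g in lib.terms[name]]] = 1
    term_sizes = member.sum(axis=1)

    q_mask = np.zeros(n_universe, dtype=np.int64)
    q_mask[[gene_idx[g] for g in genes_in]] = 1
    ks, p_obs = _overlap_pvals(member, term_sizes, q_mask, n_universe)

    # observed ranks by ascending p (average ties), as in rank-based webtool scoring
    obs_rank = stats.rankdata(p_obs)

    # null ranks from random queries of the same size
    rng = np.random.default_rng(seed)
    n_q = int(q_mask.sum())
    null_mask = np.zeros((n_universe, n_null), dtype=np.int64)
    for j in range(n_null):
        null_mask[rng.choice(n_universe, size=n_q, replace=False), j] = 1
    _, p_null = _overlap_pvals(member, term_sizes, null_mask, n_universe)
    null_ranks = np.apply_along_axis(stats.rankdata, 0, p_null)
    mean_rank = null_ranks.mean(axis=1)
    sd_rank = null_ranks.std(axis=1)

    keep = np.flatnonzero(ks >= 1)
    q_adj = np.ones(len(term_names))
    if keep.size:
        q_adj[keep] = bh_adjust(p_obs[keep])

    results = []
    for ti in keep:
        zrank = ((mean_rank[ti] - obs_rank[ti]) / sd_rank[ti]
                 if sd_rank[ti] > 0 else 0.0)
        comb = float(-np.log(p_obs[ti]) * zrank)
        signed = abs(comb) if direction == "up" else -abs(comb)
        results.append(EnrichmentResult(
            term=term_names[ti], k=int(ks[ti]), K=int(term_sizes[ti]),
            n=n_q, N=n_universe, p=float(p_obs[ti]), q=float(q_adj[ti]),
            combined=comb, signed_combined=signed, direction=direction))
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results
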