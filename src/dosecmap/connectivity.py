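"""Connectivity scoring of a directional query signature against a database
of drug perturbation profiles.

Each profile is a z-score vector over a fixed "landmark" gene universe
(L1000-style).  Two scorers are provided:

* ``signed_jaccard`` — same-direction set overlaps minus cross-direction
  overlaps between the query's up/down sets and the profile's top/bottom
  gene sets, normalised to [-1, 1]; this emulates the up/down-set scoring
  of L1000FWD-class query services.
* ``wks_connectivity`` — an unweighted Kolmogorov–Smirnov enrichment score
  of each query half in the profile's z-ranking, combined CMap-style.

Significance is assessed by a seeded permutation null (random query pairs
of matched sizes), from which a two-sided p-value, a z-statistic and a
combined score ``zstat * (-log10 p)`` are derived; the sign of the combined
score carries the pro/anti direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ContractViolation, ParameterError
from .signature import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationProfile",
    "SignatureDatabase",
    "ConnectivityResult",
    "profile_top_sets",
    "signed_jaccard",
    "wks_connectivity",
    "permutation_null",
    "combined_score",
    "query_database",
]


@dataclass
class PerturbationProfile:
    """One drug x dose x duration x replicate condition.

    ``values`` holds per-gene z-scores aligned to ``universe`` (shared with
    the owning database, so profiles stay lightweight).
    """

    drug_id: str
    dose_um: float
    duration_h: float
    replicate: int
    universe: tuple[str, ...]
    values: np.ndarray
    cell_context: str = "iNSC"
    profile_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.universe),):
            raise ContractViolation(
                f"profile {self.drug_id}: {self.values.shape[0]} z-scores for "
                f"{len(self.universe)} landmark genes")
        if not np.all(np.isfinite(self.values)):
            raise ContractViolation(f"profile {self.drug_id}: non-finite z-scores")
        if not self.dose_um > 0:
            raise ContractViolation(f"dose must be positive, got {self.dose_um}")
        if self.replicate < 1:
            raise ContractViolation("replicate index must be >= 1")
        if not self.profile_id:
            self.profile_id = (f"{self.drug_id}|{self.dose_um:g}uM|"
                               f"{self.duration_h:g}h|r{self.replicate}")

    @property
    def z(self) -> dict[str, float]:
        """Gene symbol -> z-score view (materialised on demand)."""
        return dict(zip(self.universe, self.values.tolist()))


@dataclass
class SignatureDatabase:
    """Landmark universe plus the perturbation profiles defined over it."""

    universe: tuple[str, ...]
    profiles: list[PerturbationProfile] = field(default_factory=list)

    def __post_init__(self):
        self.universe = tuple(self.universe)
        if len(set(self.universe)) != len(self.universe):
            raise ContractViolation("landmark universe contains duplicate symbols")
        for p in self.profiles:
            if tuple(p.universe) != self.universe:
                raise ContractViolation(
                    f"profile {p.profile_id} not keyed to the database universe")

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class ConnectivityResult:
    """Per-profile connectivity outcome."""

    profile: PerturbationProfile
    score: float
    p: float
    zstat: float
    combined: float


def _alpha_rank(universe: Sequence[str]) -> np.ndarray:
    """Position of each universe symbol in ascending alphabetical order."""
    order = np.argsort(np.asarray(universe, dtype=object), kind="stable")
    rank = np.empty(len(universe), dtype=np.int64)
    rank[order] = np.arange(len(universe))
    return rank


def profile_top_sets(profile: PerturbationProfile, n_top: int = 50
                     ) -> tuple[frozenset[str], frozenset[str]]:
    """Discretise a z-vector into its up (highest-z) and down (lowest-z) sets.

    Ties at the boundary break by ascending symbol order, and the up set is
    filled before the down set so the result is deterministic and disjoint.
    """
    n = len(profile.universe)
    if n_top < 1:
        raise ParameterError("n_top must be >= 1")
    if 2 * n_top > n:
        raise ParameterError(f"n_top={n_top} too large for universe of {n}")
    alpha = _alpha_rank(profile.universe)
    v = profile.values
    # lexsort: last key is primary
    up_order = np.lexsort((alpha, -v))
    up_idx = up_order[:n_top]
    taken = np.zeros(n, dtype=bool)
    taken[up_idx] = True
    down_order = np.lexsort((alpha, v))
    down_idx = down_order[~taken[down_order]][:n_top]
    syms = np.asarray(profile.universe, dtype=object)
    return frozenset(syms[up_idx]), frozenset(syms[down_idx])


def _jaccard(a: frozenset | set, b: frozenset | set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def signed_jaccard(q_up: Iterable[str], q_down: Iterable[str],
                   s_up: Iterable[str], s_down: Iterable[str]) -> float:
    """Directional Jaccard connectivity in [-1, 1].

    ``(J(q_up,s_up) + J(q_down,s_down) - J(q_up,s_down) - J(q_down,s_up))/2``
    with ``J(∅,∅) = 0``: +1 means the profile mimics the query exactly,
    -1 that it reverses it exactly.
    """
    qu, qd, su, sd = map(frozenset, (q_up, q_down, s_up, s_down))
    if qu & qd:
        raise ContractViolation("query up/down sets overlap")
    if su & sd:
        raise ContractViolation("profile up/down sets overlap")
    return (_jaccard(qu, su) + _jaccard(qd, sd)
            - _jaccard(qu, sd) - _jaccard(qd, su)) / 2.0


def _ks_es(hit_ranks: np.ndarray, n_universe: int) -> float:
    """Unweighted KS enrichment score from sorted 1-based hit ranks.

    a = max_j (j/t - V(j)/N), b = max_j (V(j)/N - (j-1)/t);
    ES = a if a >= b else -b.
    """
    t = hit_ranks.size
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - hit_ranks / n_universe))
    b = float(np.max(hit_ranks / n_universe - (j - 1) / t))
    return a if a >= b else -b


def _rank_map(profile: PerturbationProfile) -> dict[str, int]:
    """Gene -> 1-based rank by descending z (ties by ascending symbol)."""
    alpha = _alpha_rank(profile.universe)
    order = np.lexsort((alpha, -profile.values))
    return {profile.universe[i]: r + 1 for r, i in enumerate(order)}


def _wks_from_ranks(rank_of: dict[str, int], n_universe: int,
                    q_up: Iterable[str], q_down: Iterable[str]) -> float:
    qu, qd = frozenset(q_up), frozenset(q_down)
    if qu & qd:
        raise ContractViolation("query up/down sets overlap")
    if not qu or not qd:
        raise ParameterError("both query halves must be non-empty")
    for g in sorted(qu | qd):
        if g not in rank_of:
            raise ParameterError(f"query gene {g!r} absent from the landmark universe")
    es_up = _ks_es(np.sort([rank_of[g] for g in qu]), n_universe)
    es_down = _ks_es(np.sort([rank_of[g] for g in qd]), n_universe)
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def wks_connectivity(q_up: Iterable[str], q_down: Iterable[str],
                     profile: PerturbationProfile) -> float:
    """CMap-style KS connectivity in [-1, 1].

    Enrichment scores of the two query halves in the profile's descending
    z-ranking are combined as ``(ES_up - ES_down)/2`` when they disagree in
    sign (concordant with either direction of the query) and 0 otherwise.
    """
    return _wks_from_ranks(_rank_map(profile), len(profile.universe),
                           q_up, q_down)


def _null_query_indices(rng: np.random.Generator, n_perm: int, n_universe: int,
                        n_up: int, n_down: int) -> tuple[np.ndarray, np.ndarray]:
    """n_perm random disjoint (up, down) index sets of the requested sizes.

    The k = n_up + n_down smallest of N iid uniform keys form a uniform
    random k-subset; re-sorting the chosen keys makes the up/down split
    uniform as well.
    """
    k = n_up + n_down
    keys = rng.random((n_perm, n_universe))
    part = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sub = np.take_along_axis(keys, part, axis=1)
    order = np.argsort(sub, axis=1, kind="stable")
    part = np.take_along_axis(part, order, axis=1)
    return part[:, :n_up], part[:, n_up:k]


def _p_z_from_null(null: np.ndarray, observed: float) -> tuple[float, float]:
    sd = float(null.std())
    if sd == 0.0:
        return 1.0, 0.0
    p = (1.0 + int(np.count_nonzero(np.abs(null) >= abs(observed)))) / (null.size + 1.0)
    zstat = (observed - float(null.mean())) / sd
    return p, zstat


def permutation_null(
    score_fn: Callable[[frozenset[str], frozenset[str]], float],
    profile: PerturbationProfile,
    q_sizes: tuple[int, int],
    n_perm: int = 999,
    seed: int | np.random.SeedSequence = 0,
    observed: float | None = None,
) -> tuple[float, float]:
    """Two-sided permutation p-value and z-statistic for an observed score.

    Draws ``n_perm`` random disjoint query pairs of the given sizes from the
    profile's universe (seeded, reproducible) and scores each with
    ``score_fn(q_up, q_down)``.  ``p = (1 + #{|null| >= |observed|}) /
    (n_perm + 1)`` (add-one smoothing, so p is never 0) and
    ``zstat = (observed - mean) / sd``; a degenerate null (sd = 0) yields
    ``(1.0, 0.0)``.
    """
    n_up, n_down = q_sizes
    n = len(profile.universe)
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99 for usable p-value resolution")
    if n_up < 1 or n_down < 1 or n_up + n_down > n:
        raise ParameterError(f"infeasible query sizes {q_sizes} for universe of {n}")
    if observed is None:
        raise ParameterError("observed score is required")
    rng = np.random.default_rng(seed)
    up_idx, down_idx = _null_query_indices(rng, n_perm, n, n_up, n_down)
    syms = np.asarray(profile.universe, dtype=object)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = score_fn(frozenset(syms[up_idx[i]]), frozenset(syms[down_idx[i]]))
    return _p_z_from_null(null, observed)


def _jaccard_null_fast(profile: PerturbationProfile,
                       s_up: frozenset[str], s_down: frozenset[str],
                       q_sizes: tuple[int, int], n_perm: int,
                       seed: int | np.random.SeedSequence,
                       observed: float) -> tuple[float, float]:
    """Vectorised twin of ``permutation_null`` for the signed-Jaccard scorer.

    Consumes the random stream exactly as the generic path does and applies
    the same arithmetic, so the two give identical results; kept separate
    purely for speed on large databases.
    """
    n = len(profile.universe)
    n_up, n_down = q_sizes
    rng = np.random.default_rng(seed)
    up_idx, down_idx = _null_query_indices(rng, n_perm, n, n_up, n_down)
    pos = {g: i for i, g in enumerate(profile.universe)}
    su = np.zeros(n, dtype=np.float64)
    su[[pos[g] for g in s_up]] = 1.0
    sd_mask = np.zeros(n, dtype=np.float64)
    sd_mask[[pos[g] for g in s_down]] = 1.0
    i_uu = su[up_idx].sum(axis=1)
    i_ud = sd_mask[up_idx].sum(axis=1)
    i_du = su[down_idx].sum(axis=1)
    i_dd = sd_mask[down_idx].sum(axis=1)
    n_su, n_sd = len(s_up), len(s_down)
    j_uu = i_uu / (n_up + n_su - i_uu)
    j_ud = i_ud / (n_up + n_sd - i_ud)
    j_du = i_du / (n_down + n_su - i_du)
    j_dd = i_dd / (n_down + n_sd - i_dd)
    null = (j_uu + j_dd - j_ud - j_du) / 2.0
    return _p_z_from_null(null, observed)


def combined_score(p: float, zstat: float) -> float:
    """Rank statistic ``zstat * (-log10 p)``; monotone in both inputs and
    signed by direction.  ``p = 1`` maps to exactly 0."""
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"p must lie in (0,1], got {p}")
    if p == 1.0:
        return 0.0
    return zstat * (-math.log10(p))


def query_database(
    db: SignatureDatabase,
    sig: GeneSignature,
    method: str = "signed_jaccard",
    n_top: int = 50,
    n_perm: int = 999,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Score a query signature against every profile in the database.

    The signature must already live in the database namespace; genes outside
    the landmark universe are dropped (warning below 50% coverage, error if
    either half loses all genes).  Per-profile null seeds are derived from
    ``(seed, profile index)``, so results do not depend on iteration order.
    """
    if method not in ("signed_jaccard", "wks"):
        raise ParameterError(f"unknown method {method!r}")
    uni = frozenset(db.universe)
    q_up = sig.up & uni
    q_down = sig.down & uni
    if not q_up or not q_down:
        raise ParameterError(
            "no signature genes found in the landmark universe for the "
            f"{'up' if not q_up else 'down'} half")
    coverage = (len(q_up) + len(q_down)) / len(sig)
    if coverage < 0.5:
        logger.warning("only %.0f%% of signature genes found in the universe",
                       100 * coverage)
    q_sizes = (len(q_up), len(q_down))

    results: list[ConnectivityResult] = []
    for idx, profile in enumerate(db.profiles):
        if method == "signed_jaccard":
            s_up, s_down = profile_top_sets(profile, n_top)

            def score_fn(a, b, _su=s_up, _sd=s_down):
                return signed_jaccard(a, b, _su, _sd)
        else:
            rank_of = _rank_map(profile)
            n_uni = len(profile.universe)

            def score_fn(a, b, _r=rank_of, _n=n_uni):
                return _wks_from_ranks(_r, _n, a, b)

        observed = score_fn(q_up, q_down)
        child = np.random.SeedSequence([int(seed), idx])
        if method == "signed_jaccard":
            p, zstat = _jaccard_null_fast(profile, s_up, s_down, q_sizes,
                                          n_perm, child, observed)
        else:
            p, zstat = permutation_null(score_fn, profile, q_sizes,
                                        n_perm=n_perm, seed=child,
                                        observed=observed)
        results.append(ConnectivityResult(profile=profile, score=observed,
                                          p=p, zstat=zstat,
                                          combined=combined_score(p, zstat)))
    return results
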