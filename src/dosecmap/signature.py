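"""Compilation of a directional (up/down) gene signature from
differential-expression tables, and mapping between gene namespaces.

The query signature represents a biological transition — here the
early-to-late oligodendrocyte lineage progression — as two disjoint gene
sets: genes induced late in the lineage (direction +1, "pro") and genes of
early progenitor stages (direction -1).  Differential-expression calls from
several independent datasets are thresholded on fold change and FDR,
collapsed to Boolean membership, and genes whose direction conflicts across
datasets are discarded so the signature keeps a clean bipartite structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import ContractViolation, EmptySignatureError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialExpressionRecord",
    "GeneSignature",
    "OrthologMap",
    "MappingReport",
    "filter_de_genes",
    "booleanize",
    "map_namespace",
]


def _norm(symbol: str) -> str:
    """Canonical symbol form: uppercase (mouse Mbp and human MBP compare equal)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One gene's differential-expression call in one dataset.

    ``effect`` is the signed log2 fold change of the late-stage versus
    early-stage contrast; ``fdr`` the FDR-adjusted p-value.
    """

    gene: str
    effect: float
    fdr: float
    dataset_id: str = ""

    def __post_init__(self):
        if not self.gene:
            raise ContractViolation("gene symbol must be non-empty")
        if not (0.0 <= self.fdr <= 1.0):
            raise ContractViolation(f"fdr must lie in [0,1], got {self.fdr}")


@dataclass(frozen=True)
class GeneSignature:
    """Directional query signature: disjoint up (+1) and down (-1) gene sets."""

    up: frozenset[str]
    down: frozenset[str]
    namespace: str = ""

    def __post_init__(self):
        object.__setattr__(self, "up", frozenset(_norm(g) for g in self.up))
        object.__setattr__(self, "down", frozenset(_norm(g) for g in self.down))
        if self.up & self.down:
            raise ContractViolation(
                f"up/down sets overlap: {sorted(self.up & self.down)[:5]}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


@dataclass(frozen=True)
class OrthologMap:
    """Source-namespace symbol -> set of target-namespace symbols.

    Empty target sets are never stored; a missing key means "unmapped".
    """

    pairs: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for src, targets in self.pairs.items():
            tset = frozenset(_norm(t) for t in targets)
            if tset:
                clean[_norm(src)] = tset
        object.__setattr__(self, "pairs", clean)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MappingReport:
    """Bookkeeping from a namespace conversion."""

    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0
    collisions: int = 0  # cross-direction clashes created by the mapping


def filter_de_genes(
    records: list[DifferentialExpressionRecord],
    fc_threshold: float = 1.8,
    fdr_threshold: float = 0.05,
) -> list[tuple[str, int]]:
    """Select significantly, strongly regulated genes from one DE table.

    A record passes iff ``fdr < fdr_threshold`` and
    ``|effect| > log2(fc_threshold)`` — both strict, and the fold-change
    threshold is applied two-sidedly so that both signature directions are
    populated.  Returns ``(gene, direction)`` pairs in input order with
    direction the sign of the effect.  Records with non-finite effects are
    rejected with a logged warning.
    """
    if not (math.isfinite(fc_threshold) and fc_threshold > 1.0):
        raise ParameterError(f"fc_threshold must be finite and > 1, got {fc_threshold}")
    if not (0.0 < fdr_threshold < 1.0):
        raise ParameterError(f"fdr_threshold must lie in (0,1), got {fdr_threshold}")
    log2_cut = math.log2(fc_threshold)
    out: list[tuple[str, int]] = []
    for rec in records:
        if not math.isfinite(rec.effect):
            logger.warning("dropping %s (%s): non-finite effect", rec.gene,
                           rec.dataset_id)
            continue
        if rec.fdr < fdr_threshold and abs(rec.effect) > log2_cut:
            out.append((_norm(rec.gene), 1 if rec.effect > 0 else -1))
    return out


def booleanize(per_dataset_lists: list[list[tuple[str, int]]],
               namespace: str = "") -> GeneSignature:
    """Collapse per-dataset signed gene lists into one Boolean signature.

    Membership is the union across datasets within each direction.  A gene
    called +1 in one dataset and -1 in another ("commonly expressed" with
    conflicting direction) is removed from both sides, which is what
    guarantees the up/down disjointness of the result.
    """
    if not per_dataset_lists:
        raise ParameterError("need at least one dataset list")
    up: set[str] = set()
    down: set[str] = set()
    for lst in per_dataset_lists:
        for gene, direction in lst:
            g = _norm(gene)
            if direction == 1:
                up.add(g)
            elif direction == -1:
                down.add(g)
            else:
                raise ContractViolation(f"direction must be +/-1, got {direction}")
    conflicts = up & down
    if conflicts:
        logger.info("removing %d direction-conflicting genes", len(conflicts))
    up -= conflicts
    down -= conflicts
    if not up and not down:
        raise EmptySignatureError("all genes conflict across datasets; "
                                  "signature is empty")
    return GeneSignature(up=frozenset(up), down=frozenset(down),
                         namespace=namespace)


def map_namespace(
    sig: GeneSignature,
    omap: OrthologMap,
    target_namespace: str = "target",
) -> tuple[GeneSignature, MappingReport]:
    """Translate a signature into another gene namespace (e.g. mouse->human).

    Only symbols with exactly one ortholog are carried over; unmapped and
    one-to-many symbols are dropped (expansion would double-count genes in
    set-overlap scores) and counted in the report.  If two source symbols
    from opposite directions land on the same target symbol the target is
    removed from both sides, preserving disjointness.
    """
    if len(omap) == 0:
        raise ParameterError("ortholog map is empty")

    def convert(genes: frozenset[str]) -> tuple[set[str], int, int]:
        mapped: set[str] = set()
        unmapped = ambiguous = 0
        for g in sorted(genes):
            targets = omap.pairs.get(_norm(g))
            if targets is None:
                unmapped += 1
            elif len(targets) > 1:
                ambiguous += 1
            else:
                mapped.add(next(iter(targets)))
        return mapped, unmapped, ambiguous

    up, un_u, amb_u = convert(sig.up)
    down, un_d, amb_d = convert(sig.down)
    collisions = up & down
    if collisions:
        logger.warning("mapping created %d cross-direction collisions; "
                       "removed from both sides", len(collisions))
    up -= collisions
    down -= collisions
    if not up and not down:
        raise EmptySignatureError("signature empty after namespace mapping")
    report = MappingReport(mapped=len(up) + len(down),
                           unmapped=un_u + un_d,
                           ambiguous=amb_u + amb_d,
                           collisions=len(collisions))
    return GeneSignature(up=frozenset(up), down=frozenset(down),
                         namespace=target_namespace), report
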