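"""Extraction of the genes a drug condition moves up or down beyond a
z threshold ("positive and negative ranges"), optionally restricted to the
query signature, and merging of conditions within a dose band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import PerturbationProfile
from .errors import ParameterError
from .signature import GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["TargetGeneSet", "extract_targets", "merge_conditions"]


@dataclass(frozen=True)
class TargetGeneSet:
    """Signature-relevant genes moved by one drug condition (or band)."""

    drug_id: str
    dose_band: str
    up_targets: frozenset[str]
    down_targets: frozenset[str]
    restricted: bool = False

    def __post_init__(self):
        if self.up_targets & self.down_targets:
            raise ParameterError("up/down target sets overlap")

    @property
    def all_targets(self) -> frozenset[str]:
        return self.up_targets | self.down_targets


def extract_targets(
    profile: PerturbationProfile,
    sig: GeneSignature,
    z_cutoff: float = 2.0,
    restrict: bool = True,
    dose_band: str = "all",
) -> TargetGeneSet:
    """Threshold a profile into up (z >= +cutoff) and down (z <= -cutoff)
    target genes; with ``restrict`` they are intersected with the query
    signature so only lineage-relevant genes remain."""
    if not z_cutoff > 0:
        raise ParameterError("z_cutoff must be positive")
    syms = np.asarray(profile.universe, dtype=object)
    up = frozenset(syms[profile.values >= z_cutoff])
    down = frozenset(syms[profile.values <= -z_cutoff])
    if restrict:
        relevant = sig.genes
        up &= relevant
        down &= relevant
    return TargetGeneSet(drug_id=profile.drug_id, dose_band=dose_band,
                         up_targets=up, down_targets=down, restricted=restrict)


def merge_conditions(sets: list[TargetGeneSet]) -> TargetGeneSet:
    """Union target sets of several conditions of the same drug and band.

    Genes landing in both merged directions are dropped from both — the
    same conflict rule the signature compilation applies.
    """
    if not sets:
        raise ParameterError("nothing to merge")
    drug_ids = {s.drug_id for s in sets}
    bands = {s.dose_band for s in sets}
    if len(drug_ids) > 1 or len(bands) > 1:
        raise ParameterError(
            f"cannot merge across drugs {sorted(drug_ids)} / bands {sorted(bands)}")
    up: set[str] = set()
    down: set[str] = set()
    for s in sets:
        up |= s.up_targets
        down |= s.down_targets
    conflicts = up & down
    if conflicts:
        logger.info("merge %s/%s: dropping %d direction-conflicting genes",
                    next(iter(drug_ids)), next(iter(bands)), len(conflicts))
    return TargetGeneSet(drug_id=next(iter(drug_ids)),
                         dose_band=next(iter(bands)),
                         up_targets=frozenset(up - conflicts),
                         down_targets=frozenset(down - conflicts),
                         restricted=all(s.restricted for s in sets))
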