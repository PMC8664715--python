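"""Synthetic study generator.

Emulates, at desk scale, the inputs of a dose-stratified connectivity
screen: differential-expression tables over an "early vs late
oligodendrocyte lineage" contrast in a mouse-style namespace, an ortholog
map into the landmark (human-style) namespace, an L1000-like perturbation
database with planted pro, anti and dose-flip compounds among null drugs,
and a gene-set library with one term planted inside the signature.

Every generator is a pure function of its configuration and seed, so all
outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PerturbationProfile, SignatureDatabase
from .enrichment import GeneSetLibrary
from .errors import ParameterError
from .signature import GeneSignature, OrthologMap

__all__ = [
    "PlantSpec",
    "SimConfig",
    "make_universe",
    "source_symbol",
    "make_ortholog_map",
    "make_de_tables",
    "make_perturbation_db",
    "make_geneset_library",
    "SimulatedStudy",
    "simulate_study",
]


@dataclass(frozen=True)
class PlantSpec:
    """One planted compound.

    ``mode``: 'pro' shifts signature-up genes by +effect and signature-down
    genes by -effect at every dose; 'anti' is the mirror image; 'dose_flip'
    acts pro at the low doses and anti at the high doses; 'null' leaves the
    background untouched.  Doses in µM, duration in hours, triplicates by
    default.
    """

    drug_id: str
    mode: str = "pro"
    effect: float = 2.0
    low_doses: tuple[float, ...] = (0.37, 3.3)
    high_doses: tuple[float, ...] = (10.0,)
    duration_h: float = 24.0
    n_replicates: int = 3

    def __post_init__(self):
        if self.mode not in ("pro", "anti", "dose_flip", "null"):
            raise ParameterError(f"unknown plant mode {self.mode!r}")
        if not (math.isfinite(self.effect) and self.effect > 0):
            raise ParameterError("plant effect must be finite and positive")
        if self.mode != "null" and not (self.low_doses or self.high_doses):
            raise ParameterError(f"plant {self.drug_id}: no doses given")


def _default_plants() -> tuple[PlantSpec, ...]:
    return (PlantSpec("PRO-DRUG", mode="pro"),
            PlantSpec("ANTI-DRUG", mode="anti"),
            PlantSpec("FLIP-DRUG", mode="dose_flip"))


@dataclass(frozen=True)
class SimConfig:
    """Study-level configuration; the defaults are the study conditions.

    Null compounds are screened in triplicate at two doses within a single
    concentration regime each (alternating low {0.37, 3.3} µM and high
    {10, 20} µM across drugs), emulating libraries where most compounds are
    profiled in one dose regime while the planted dose-flip compound spans
    both.
    """

    n_landmark: int = 978
    n_null_drugs: int = 300
    noise_sd: float = 1.0
    plants: tuple[PlantSpec, ...] = field(default_factory=_default_plants)
    seed: int = 0
    n_sig_up: int = 50
    n_sig_down: int = 50
    n_noise_genes: int = 200
    n_conflict_genes: int = 5
    n_datasets: int = 3
    map_coverage: float = 0.9
    map_ambiguous: float = 0.05
    n_terms: int = 100
    term_size: tuple[int, int] = (10, 50)
    planted_term_size: int = 20

    def __post_init__(self):
        if self.n_landmark < self.n_sig_up + self.n_sig_down:
            raise ParameterError("universe smaller than the planted signature")
        if not self.noise_sd > 0:
            raise ParameterError("noise_sd must be positive")


def make_universe(n: int, seed: int = 0) -> tuple[str, ...]:
    """Deterministic landmark symbols G000001..; the seed is accepted for
    interface uniformity but the symbols are not random."""
    if n < 10:
        raise ParameterError("universe must hold at least 10 genes")
    return tuple(f"G{i:06d}" for i in range(1, n + 1))


def source_symbol(gene: str) -> str:
    """Mouse-style source-namespace symbol for a landmark gene."""
    return "M" + gene.lower().capitalize()  # e.g. G000001 -> MG000001


def make_ortholog_map(universe: tuple[str, ...], coverage: float = 0.9,
                      ambiguous: float = 0.05, seed: int = 0) -> OrthologMap:
    """Source->target symbol map: a ``coverage`` fraction of genes map 1:1,
    an ``ambiguous`` fraction map 1:2 (and are therefore dropped on
    conversion), the rest are absent from the map."""
    if not (0 <= coverage <= 1 and 0 <= ambiguous <= 1):
        raise ParameterError("fractions must lie in [0,1]")
    if coverage + ambiguous > 1:
        raise ParameterError("coverage + ambiguous must not exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.random(len(universe))
    pairs: dict[str, frozenset[str]] = {}
    for g, x in zip(universe, u):
        if x < coverage:
            pairs[source_symbol(g)] = frozenset({g})
        elif x < coverage + ambiguous:
            pairs[source_symbol(g)] = frozenset({g, g + "P"})
    return OrthologMap(pairs=pairs)


def make_de_tables(
    sig: GeneSignature,
    n_noise_genes: int = 200,
    n_conflict_genes: int = 0,
    n_datasets: int = 3,
    effect_lognorm: tuple[float, float] = (-0.5, 0.5),
    fdr_range: tuple[float, float] = (1e-6, 0.04),
    fc_threshold: float = 1.8,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Differential-expression tables that embed a known signature.

    Every dataset contains the full planted signature with
    ``|log2FC| = log2(fc_threshold) + LogNormal(effect_lognorm)`` (always
    above threshold, correct sign) and FDR inside ``fdr_range`` (below
    threshold).  Noise genes fail at least one filter: half get sub-threshold
    effects, half super-threshold FDR.  Conflict genes pass the filters with
    opposite signs in alternating datasets, so signature compilation must
    remove them.  Columns: gene, log2fc, fdr, dataset.
    """
    if n_datasets < 1:
        raise ParameterError("need at least one dataset")
    rng = np.random.default_rng(seed)
    base = math.log2(fc_threshold)
    mu, sd = effect_lognorm
    planted = ([(g, 1) for g in sorted(sig.up)]
               + [(g, -1) for g in sorted(sig.down)])
    noise = [f"MNOISE{i:05d}" for i in range(1, n_noise_genes + 1)]
    conflict = [f"MCONF{i:05d}" for i in range(1, n_conflict_genes + 1)]
    tables = []
    for d in range(n_datasets):
        rows = []
        for g, direction in planted:
            eff = direction * (base + rng.lognormal(mu, sd))
            rows.append((g, eff, rng.uniform(*fdr_range), f"DS{d + 1}"))
        for g in noise:
            if rng.random() < 0.5:  # sub-threshold effect, any fdr
                eff = rng.uniform(-base, base) * 0.999
                fdr = rng.uniform(0.0, 1.0)
            else:  # strong effect but non-significant
                eff = rng.normal(0, 2 * base)
                fdr = rng.uniform(fdr_threshold * 1.2, 1.0)
            rows.append((g, eff, fdr, f"DS{d + 1}"))
        for i, g in enumerate(conflict):
            sign = 1 if (i + d) % 2 == 0 else -1
            eff = sign * (base + rng.lognormal(mu, sd))
            rows.append((g, eff, rng.uniform(*fdr_range), f"DS{d + 1}"))
        tables.append(pd.DataFrame(rows,
                                   columns=["gene", "log2fc", "fdr", "dataset"]))
    return tables


def _plant_conditions(spec: PlantSpec) -> list[tuple[float, int]]:
    """(dose, pro(+1)/anti(-1)) pairs for a plant, in deterministic order."""
    conds = []
    if spec.mode == "pro":
        sign_low = sign_high = +1
    elif spec.mode == "anti":
        sign_low = sign_high = -1
    elif spec.mode == "dose_flip":
        sign_low, sign_high = +1, -1
    else:
        sign_low = sign_high = 0
    for dose in spec.low_doses:
        conds.append((dose, sign_low))
    for dose in spec.high_doses:
        conds.append((dose, sign_high))
    return conds


def make_perturbation_db(cfg: SimConfig, sig: GeneSignature
                         ) -> SignatureDatabase:
    """L1000-style database: iid Normal(0, noise_sd) background z-scores per
    gene per profile, with the planted compounds' signature genes shifted by
    ±effect according to their mode.  Null drug i is profiled in triplicate
    at two doses of a single band (low {0.37, 3.3} for even i, high
    {10, 20} for odd i)."""
    universe = make_universe(cfg.n_landmark, cfg.seed)
    uni_set = set(universe)
    missing = (sig.up | sig.down) - uni_set
    if missing:
        raise ParameterError(
            f"plant signature genes outside the universe: {sorted(missing)[:5]}")
    idx = {g: i for i, g in enumerate(universe)}
    up_idx = np.array(sorted(idx[g] for g in sig.up), dtype=int)
    down_idx = np.array(sorted(idx[g] for g in sig.down), dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    profiles: list[PerturbationProfile] = []

    def add(drug: str, dose: float, duration: float, rep: int, shift: float):
        z = rng.normal(0.0, cfg.noise_sd, cfg.n_landmark)
        if shift:
            z[up_idx] += shift
            z[down_idx] -= shift
        profiles.append(PerturbationProfile(
            drug_id=drug, dose_um=dose, duration_h=duration, replicate=rep,
            universe=universe, values=z))

    for spec in cfg.plants:
        for dose, sign in _plant_conditions(spec):
            for rep in range(1, spec.n_replicates + 1):
                add(spec.drug_id, dose, spec.duration_h, rep, sign * spec.effect)
    for i in range(cfg.n_null_drugs):
        doses = (0.37, 3.3) if i % 2 == 0 else (10.0, 20.0)
        for dose in doses:
            for rep in range(1, 4):
                add(f"NULL{i + 1:04d}", dose, 24.0, rep, 0.0)
    return SignatureDatabase(universe=universe, profiles=profiles)


def make_geneset_library(
    universe: tuple[str, ...],
    n_terms: int = 100,
    term_size: tuple[int, int] = (10, 50),
    planted_term: frozenset[str] | None = None,
    seed: int = 0,
) -> GeneSetLibrary:
    """Random gene-set library plus one planted term (named PLANTED_TERM)
    drawn from the signature so enrichment of a pro-compound's targets can
    recover it."""
    lo, hi = term_size
    if hi > len(universe):
        raise ParameterError("term size exceeds the universe")
    if planted_term is not None and not planted_term:
        raise ParameterError("planted term must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    uni = np.asarray(universe, dtype=object)
    terms: dict[str, frozenset[str]] = {}
    if planted_term is not None:
        if not planted_term <= set(universe):
            raise ParameterError("planted term has genes outside the universe")
        terms["PLANTED_TERM"] = frozenset(planted_term)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM{t + 1:04d}"] = frozenset(
            uni[rng.choice(len(uni), size=size, replace=False)])
    return GeneSetLibrary(terms=terms, universe=frozenset(universe))


@dataclass(frozen=True)
class SimulatedStudy:
    """All artefacts of one simulated screen, plus the planted truth."""

    config: SimConfig
    universe: tuple[str, ...]
    signature_source: GeneSignature   # planted truth, mouse-style namespace
    signature_target: GeneSignature   # planted truth, landmark namespace
    de_tables: list[pd.DataFrame]
    ortholog_map: OrthologMap
    database: SignatureDatabase
    library: GeneSetLibrary

    def provenance(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "planted": {
                "signature_up": sorted(self.signature_target.up),
                "signature_down": sorted(self.signature_target.down),
                "plants": [dataclasses.asdict(p) for p in self.config.plants],
                "planted_term": "PLANTED_TERM",
            },
        }


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a complete, internally consistent synthetic study.

    The true signature is a random draw of ``n_sig_up + n_sig_down``
    landmark genes; the DE tables carry its mouse-style image, the ortholog
    map converts back (with realistic losses), the perturbation database
    plants compound effects on the full true signature, and the library's
    planted term is a subset of the signature's up genes.
    """
    universe = make_universe(cfg.n_landmark, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    picks = rng.choice(cfg.n_landmark, size=cfg.n_sig_up + cfg.n_sig_down,
                       replace=False)
    uni = np.asarray(universe, dtype=object)
    sig_target = GeneSignature(up=frozenset(uni[picks[:cfg.n_sig_up]]),
                               down=frozenset(uni[picks[cfg.n_sig_up:]]),
                               namespace="landmark")
    sig_source = GeneSignature(
        up=frozenset(source_symbol(g) for g in sig_target.up),
        down=frozenset(source_symbol(g) for g in sig_target.down),
        namespace="mouse")
    de_tables = make_de_tables(sig_source, n_noise_genes=cfg.n_noise_genes,
                               n_conflict_genes=cfg.n_conflict_genes,
                               n_datasets=cfg.n_datasets,
                               seed=int(np.random.SeedSequence(
                                   [int(cfg.seed), 4]).generate_state(1)[0]
                                   % (2 ** 31)))
    omap = make_ortholog_map(universe, coverage=cfg.map_coverage,
                             ambiguous=cfg.map_ambiguous,
                             seed=int(np.random.SeedSequence(
                                 [int(cfg.seed), 5]).generate_state(1)[0]
                                 % (2 ** 31)))
    db = make_perturbation_db(cfg, sig_target)
    planted_term = frozenset(sorted(sig_target.up)[:cfg.planted_term_size])
    library = make_geneset_library(universe, n_terms=cfg.n_terms,
                                   term_size=cfg.term_size,
                                   planted_term=planted_term, seed=cfg.seed)
    return SimulatedStudy(config=cfg, universe=universe,
                          signature_source=sig_source,
                          signature_target=sig_target,
                          de_tables=de_tables, ortholog_map=omap,
                          database=db, library=library)
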