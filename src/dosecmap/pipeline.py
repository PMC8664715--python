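"""In-memory composition of the full screen: simulate -> build signature ->
map -> query -> rank -> flag.  Mirrors the ``run-all`` CLI command without
touching disk; used for replicate studies and calibration checks."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .connectivity import ConnectivityResult, query_database
from .io import de_records
from .ranking import BipartiteFlag, flag_bipartite, pool_duplicates, top_tables
from .signature import GeneSignature, booleanize, filter_de_genes, map_namespace
from .simulate import SimConfig, SimulatedStudy, simulate_study

__all__ = ["ScreenOutcome", "build_signature_from_tables", "run_screen"]


@dataclass
class ScreenOutcome:
    study: SimulatedStudy
    signature: GeneSignature
    results: list[ConnectivityResult]
    banded: pd.DataFrame
    pro: pd.DataFrame
    anti: pd.DataFrame
    flags: list[BipartiteFlag]

    @property
    def bipartite_drugs(self) -> list[str]:
        return [f.drug_id for f in self.flags if f.is_bipartite]


def build_signature_from_tables(study: SimulatedStudy,
                                cfg: PipelineConfig) -> GeneSignature:
    per_dataset = [filter_de_genes(de_records(t), cfg.fc_threshold,
                                   cfg.fdr_threshold)
                   for t in study.de_tables]
    sig = booleanize(per_dataset, namespace="source")
    sig, _ = map_namespace(sig, study.ortholog_map)
    return sig


def run_screen(sim: SimConfig, cfg: PipelineConfig | None = None
               ) -> ScreenOutcome:
    """Run the whole desk-side screen for one simulated study."""
    cfg = cfg or PipelineConfig()
    study = simulate_study(sim)
    sig = build_signature_from_tables(study, cfg)
    results = query_database(study.database, sig, method=cfg.method,
                             n_top=cfg.n_top, n_perm=cfg.n_perm,
                             seed=cfg.seed)
    restrict = (None if cfg.pool_order == "pool_then_rank"
                else max(cfg.k_pro, cfg.k_anti))
    banded = pool_duplicates(results, "drug_dose_band", cfg.dose_boundary_um,
                             restrict_to_top=restrict)
    pro, anti = top_tables(banded, cfg.k_pro, cfg.k_anti)
    flags = flag_bipartite(pro, anti, banded)
    return ScreenOutcome(study=study, signature=sig, results=results,
                         banded=banded, pro=pro, anti=anti, flags=flags)
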