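#!/usr/bin/env python
"""Generate the synthetic screen inputs.

Writes the study's raw materials to results/sim/: differential-expression
tables for the early-vs-late oligodendrocyte lineage contrast (mouse-style
namespace), the mouse->human ortholog map, the L1000-style perturbation
database (978 landmark genes; 300 null compounds in triplicate at two
doses each; planted pro, anti and dose-flip compounds at effect 2.0
z-units), and a gene-set library with one term planted inside the
signature.
"""

import argparse
import json
from pathlib import Path

from dosecmap import SimConfig, io, simulate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    study = simulate_study(SimConfig(seed=args.seed))
    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_de_tables(study.de_tables, args.outdir / "de_tables.tsv")
    io.write_ortholog_map(study.ortholog_map, args.outdir / "ortholog_map.tsv")
    io.write_database_tsv(study.database, args.outdir / "database.tsv",
                          args.outdir / "profiles.tsv")
    io.write_library_gmt(study.library, args.outdir / "library.gmt")
    (args.outdir / "provenance.json").write_text(
        json.dumps(study.provenance(), indent=1) + "\n")

    print(f"universe: {len(study.universe)} landmark genes")
    print(f"profiles: {len(study.database)} "
          f"({len({p.drug_id for p in study.database.profiles})} drugs)")
    print(f"planted signature: {len(study.signature_target.up)} up / "
          f"{len(study.signature_target.down)} down")
    print(f"wrote inputs to {args.outdir}")


if __name__ == "__main__":
    main()
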