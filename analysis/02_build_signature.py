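#!/usr/bin/env python
"""Compile the directional oligodendrogenesis signature.

Reads the DE tables from results/sim/, applies the screen's thresholds
(FDR < 5%, fold change > 1.8, both strict), collapses the datasets into a
Boolean up/down signature with cross-dataset conflict removal, and maps it
into the landmark namespace through the ortholog table.  Writes
signature.json/.gmt and the mapping report under results/.
"""

import argparse
import json
from pathlib import Path

from dosecmap import booleanize, filter_de_genes, io, map_namespace


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    tables = io.read_de_tables(args.indir / "de_tables.tsv")
    per_dataset = [filter_de_genes(io.de_records(t), 1.8, 0.05)
                   for t in tables]
    for t, lst in zip(tables, per_dataset):
        print(f"dataset {t.dataset.iloc[0]}: {len(t)} records, "
              f"{len(lst)} pass thresholds")
    sig = booleanize(per_dataset, namespace="source")
    print(f"compiled signature: {len(sig.up)} up / {len(sig.down)} down")

    omap = io.read_ortholog_map(args.indir / "ortholog_map.tsv")
    sig, report = map_namespace(sig, omap)
    print(f"after ortholog mapping: {len(sig.up)} up / {len(sig.down)} down "
          f"({report.unmapped} unmapped, {report.ambiguous} ambiguous, "
          f"{report.collisions} collisions dropped)")

    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_signature_json(sig, args.outdir / "signature.json")
    io.write_signature_gmt(sig, args.outdir / "signature.gmt")
    (args.outdir / "mapping_report.json").write_text(
        json.dumps(report.__dict__, indent=1) + "\n")


if __name__ == "__main__":
    main()
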