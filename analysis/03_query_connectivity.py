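#!/usr/bin/env python
"""Query the perturbation database with the signature.

Scores every profile with the signed-Jaccard scorer over its top/bottom 50
landmark genes, attaches a 199-permutation two-sided p-value and
z-statistic, and the combined score z * (-log10 p).  Writes
results/connectivity.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from dosecmap import io, query_database


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=199)
    args = ap.parse_args()

    db = io.read_database_tsv(args.indir / "database.tsv",
                              args.indir / "profiles.tsv")
    sig = io.read_signature_json(args.outdir / "signature.json")
    results = query_database(db, sig, method="signed_jaccard", n_top=50,
                             n_perm=args.n_perm, seed=args.seed)
    io.write_results(results, args.outdir / "connectivity.tsv")

    combined = np.array([r.combined for r in results])
    print(f"scored {len(results)} profiles")
    print(f"combined score range: {combined.min():.2f} .. {combined.max():.2f}")
    best = max(results, key=lambda r: r.combined)
    worst = min(results, key=lambda r: r.combined)
    print(f"most pro-correlating profile:  {best.profile.profile_id} "
          f"(score {best.score:.3f}, p {best.p:.3g})")
    print(f"most anti-correlating profile: {worst.profile.profile_id} "
          f"(score {worst.score:.3f}, p {worst.p:.3g})")


if __name__ == "__main__":
    main()
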