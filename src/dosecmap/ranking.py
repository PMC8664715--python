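"""Pooling of replicate/condition-level connectivity results into per-drug
(or per drug x dose-band) rankings, top pro/anti tables, and detection of
dose-bipartite compounds — drugs that mimic the query at one concentration
band and reverse it at the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityResult
from .errors import ParameterError

__all__ = [
    "BipartiteFlag",
    "dose_band",
    "pool_duplicates",
    "top_tables",
    "flag_bipartite",
    "RANKED_COLUMNS",
]

RANKED_COLUMNS = ["drug_id", "dose_band", "n_conditions", "mean_score",
                  "mean_zstat", "pooled_p", "mean_combined", "rank"]


@dataclass(frozen=True)
class BipartiteFlag:
    """Dose-bipartite call for one drug.

    ``low_rank_pro``/``high_rank_anti`` are 1-based positions within the pro
    and anti top tables (0 = absent); ``orientation`` records which band is
    the pro-correlating one.
    """

    drug_id: str
    low_rank_pro: int
    high_rank_anti: int
    is_bipartite: bool
    orientation: str = "low_pro_high_anti"


def dose_band(dose_um: float, boundary_um: float = 5.0) -> str:
    """Band a concentration: 'low' strictly below the boundary, else 'high'."""
    if not boundary_um > 0:
        raise ParameterError("dose boundary must be positive")
    return "low" if dose_um < boundary_um else "high"


def _fisher_p(pvals: np.ndarray) -> float:
    """Fisher's combination: -2*sum(ln p) against chi-square with 2k d.f."""
    stat = -2.0 * float(np.log(pvals).sum())
    return float(stats.chi2.sf(stat, 2 * pvals.size))


def pool_duplicates(
    results: list[ConnectivityResult] | pd.DataFrame,
    group_by: str = "drug_dose_band",
    dose_boundary: float = 5.0,
    restrict_to_top: int | None = None,
) -> pd.DataFrame:
    """Pool duplicate conditions and rank.

    Scores, z-statistics and combined scores are arithmetic means within
    each group; p-values are pooled with Fisher's method (the conditions are
    independent experiments).  The table is sorted by mean combined score
    descending — pro-correlating compounds first — with ties broken by
    smaller pooled p, then drug id.

    ``results`` may be ConnectivityResult objects or a results DataFrame
    with columns drug_id, dose_um, score, p, zstat, combined.
    ``restrict_to_top`` selects rank-then-pool semantics: only conditions
    whose per-condition |combined| falls in the top N of its sign are pooled.
    Default is pool-then-rank (all conditions).
    """
    if group_by not in ("drug", "drug_dose_band"):
        raise ParameterError(f"unknown group_by {group_by!r}")
    if isinstance(results, pd.DataFrame):
        df = results[["drug_id", "dose_um", "score", "p", "zstat",
                      "combined"]].copy()
    else:
        df = pd.DataFrame(
            [(r.profile.drug_id, r.profile.dose_um, r.score, r.p, r.zstat,
              r.combined) for r in results],
            columns=["drug_id", "dose_um", "score", "p", "zstat", "combined"])
    if df.empty:
        raise ParameterError("no connectivity results to pool")
    if not np.all(np.isfinite(df[["score", "p", "zstat", "combined"]].to_numpy())):
        raise ParameterError("non-finite connectivity values cannot be pooled")
    if restrict_to_top is not None:
        pos = df[df.combined > 0].nlargest(restrict_to_top, "combined")
        neg = df[df.combined < 0].nsmallest(restrict_to_top, "combined")
        df = pd.concat([pos, neg])
        if df.empty:
            raise ParameterError("no conditions left after top-N restriction")
    if group_by == "drug_dose_band":
        df["dose_band"] = [dose_band(d, dose_boundary) for d in df.dose_um]
    else:
        df["dose_band"] = "all"

    grouped = df.groupby(["drug_id", "dose_band"], sort=True)
    out = grouped.agg(
        n_conditions=("score", "size"),
        mean_score=("score", "mean"),
        mean_zstat=("zstat", "mean"),
        mean_combined=("combined", "mean"),
    ).reset_index()
    out["pooled_p"] = [
        _fisher_p(g["p"].to_numpy()) for _, g in grouped
    ]
    out = out.sort_values(
        by=["mean_combined", "pooled_p", "drug_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[RANKED_COLUMNS]


def top_tables(table: pd.DataFrame, k_pro: int = 25, k_anti: int = 15
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cut the ranked table into the pro and anti top lists.

    The pro table holds the ``k_pro`` most positive mean combined scores,
    the anti table the ``k_anti`` most negative; rows of the wrong sign are
    never included, so short tables are possible.
    """
    if k_pro < 1 or k_anti < 1:
        raise ParameterError("k_pro and k_anti must be >= 1")
    pro = (table[table.mean_combined > 0]
           .sort_values(["mean_combined", "pooled_p", "drug_id"],
                        ascending=[False, True, True], kind="stable")
           .head(k_pro).reset_index(drop=True))
    anti = (table[table.mean_combined < 0]
            .sort_values(["mean_combined", "pooled_p", "drug_id"],
                         ascending=[True, True, True], kind="stable")
            .head(k_anti).reset_index(drop=True))
    return pro, anti


def flag_bipartite(pro_table: pd.DataFrame, anti_table: pd.DataFrame,
                   banded_table: pd.DataFrame) -> list[BipartiteFlag]:
    """Flag drugs whose low and high dose bands land in opposite top tables.

    Requires tables built with ``group_by='drug_dose_band'``.  A drug is
    bipartite iff one band appears in the pro top table and the other band
    in the anti top table; the orientation (which band is pro) is recorded.
    """
    for t in (pro_table, anti_table, banded_table):
        if "dose_band" not in t.columns or (len(t) and
                                            (t.dose_band == "all").any()):
            raise ParameterError("bipartite flagging requires dose-banded tables")

    def positions(t: pd.DataFrame) -> dict[tuple[str, str], int]:
        return {(row.drug_id, row.dose_band): i + 1
                for i, row in enumerate(t.itertuples())}

    pro_pos = positions(pro_table)
    anti_pos = positions(anti_table)
    drugs = sorted({d for d, _ in pro_pos} | {d for d, _ in anti_pos})
    flags: list[BipartiteFlag] = []
    for d in drugs:
        lp = pro_pos.get((d, "low"), 0)
        ha = anti_pos.get((d, "high"), 0)
        hp = pro_pos.get((d, "high"), 0)
        la = anti_pos.get((d, "low"), 0)
        if lp and ha:
            flags.append(BipartiteFlag(d, lp, ha, True, "low_pro_high_anti"))
        elif hp and la:
            flags.append(BipartiteFlag(d, hp, la, True, "high_pro_low_anti"))
        else:
            flags.append(BipartiteFlag(d, lp, ha, False))
    return flags
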