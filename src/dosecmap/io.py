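"""Readers and writers for the pipeline's plain-text formats.

Formats: DE tables (TSV), directional signatures (two-line GMT and JSON),
ortholog maps (two-column TSV), perturbation databases (dense gene x
profile TSV, or MatrixMarket triplets, each with a profile-metadata
sidecar), connectivity results / ranked tables (TSV), top-table reports
(JSON), gene-set libraries and target sets (GMT), and 2-D coordinates
(TSV).  Writers use fixed float formatting and ``\\n`` newlines so that a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .connectivity import ConnectivityResult, PerturbationProfile, SignatureDatabase
from .enrichment import EnrichmentResult, GeneSetLibrary
from .errors import FormatError
from .ranking import BipartiteFlag
from .signature import DifferentialExpressionRecord, GeneSignature, OrthologMap
from .targets import TargetGeneSet

FLOAT_FMT = "%.10g"

DE_COLUMNS = ["gene", "log2fc", "fdr", "dataset"]
META_COLUMNS = ["profile_id", "drug_id", "dose_um", "duration_h", "replicate",
                "cell_context"]
RESULT_COLUMNS = ["profile_id", "drug_id", "dose_um", "duration_h",
                  "replicate", "score", "p", "zstat", "combined"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", str(path))
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse TSV: {exc}", str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing}", str(path),
                          line=1)
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


# ---------------------------------------------------------------- DE tables

def write_de_tables(tables: list[pd.DataFrame], path: str | Path) -> None:
    _write_tsv(pd.concat(tables, ignore_index=True)[DE_COLUMNS], path)


def read_de_tables(path: str | Path) -> list[pd.DataFrame]:
    """One DataFrame per dataset label, in order of first appearance."""
    df = _read_tsv(path, DE_COLUMNS)
    bad = df.index[df[["log2fc", "fdr"]].isna().any(axis=1)]
    if len(bad):
        raise FormatError("NaN cell in numeric column", str(path),
                          line=int(bad[0]) + 2)
    return [g.reset_index(drop=True)
            for _, g in df.groupby("dataset", sort=False)]


def de_records(table: pd.DataFrame) -> list[DifferentialExpressionRecord]:
    return [DifferentialExpressionRecord(gene=str(r.gene), effect=float(r.log2fc),
                                         fdr=float(r.fdr),
                                         dataset_id=str(r.dataset))
            for r in table.itertuples()]


# ---------------------------------------------------------------- signatures

def write_signature_json(sig: GeneSignature, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"up": sorted(sig.up), "down": sorted(sig.down),
         "namespace": sig.namespace}, indent=1) + "\n")


def read_signature_json(path: str | Path) -> GeneSignature:
    try:
        obj = json.loads(Path(path).read_text())
        return GeneSignature(up=frozenset(obj["up"]),
                             down=frozenset(obj["down"]),
                             namespace=obj.get("namespace", ""))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"bad signature JSON: {exc}", str(path)) from exc


def write_signature_gmt(sig: GeneSignature, path: str | Path,
                        name: str = "SIG") -> None:
    write_gmt({f"{name}_UP": frozenset(sig.up),
               f"{name}_DN": frozenset(sig.down)}, path,
              description=sig.namespace or "na")


def read_signature_gmt(path: str | Path, name: str = "SIG") -> GeneSignature:
    terms, _ = read_gmt(path)
    try:
        return GeneSignature(up=terms[f"{name}_UP"], down=terms[f"{name}_DN"])
    except KeyError as exc:
        raise FormatError(f"signature GMT lacks line {exc}", str(path)) from exc


# ---------------------------------------------------------------- GMT

def write_gmt(terms: dict[str, frozenset[str]], path: str | Path,
              description: str = "na") -> None:
    lines = []
    for name in sorted(terms):
        genes = sorted(terms[name])
        if not genes:
            raise FormatError(f"term {name!r} has no genes")
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Returns (term -> genes, term -> description)."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", str(path))
    terms: dict[str, frozenset[str]] = {}
    descs: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError("GMT line needs name, description and >= 1 gene",
                              str(path), line=i)
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"term {name!r} has no genes", str(path), line=i)
        if name in terms:
            raise FormatError(f"duplicate term {name!r}", str(path), line=i)
        terms[name] = frozenset(genes)
        descs[name] = desc
    return terms, descs


def write_library_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    write_gmt(dict(lib.terms), path)


def read_library_gmt(path: str | Path,
                     universe: frozenset[str] | None = None) -> GeneSetLibrary:
    terms, _ = read_gmt(path)
    if universe is None:
        universe = frozenset().union(*terms.values())
    return GeneSetLibrary(terms=terms, universe=universe)


def write_target_sets_gmt(sets: list[TargetGeneSet], path: str | Path) -> None:
    """One line per drug + band + direction, e.g. ``FLIP-DRUG|low|UP``.
    Directions with no genes are omitted (GMT forbids empty sets)."""
    terms = {}
    for s in sets:
        if s.up_targets:
            terms[f"{s.drug_id}|{s.dose_band}|UP"] = s.up_targets
        if s.down_targets:
            terms[f"{s.drug_id}|{s.dose_band}|DN"] = s.down_targets
    write_gmt(terms, path)


def read_target_sets_gmt(path: str | Path,
                         restricted: bool = True) -> list[TargetGeneSet]:
    terms, _ = read_gmt(path)
    grouped: dict[tuple[str, str], dict[str, frozenset[str]]] = {}
    for name, genes in terms.items():
        try:
            drug, band, direction = name.split("|")
        except ValueError as exc:
            raise FormatError(f"bad target-set name {name!r}", str(path)) from exc
        grouped.setdefault((drug, band), {})[direction] = genes
    return [TargetGeneSet(drug_id=d, dose_band=b,
                          up_targets=parts.get("UP", frozenset()),
                          down_targets=parts.get("DN", frozenset()),
                          restricted=restricted)
            for (d, b), parts in sorted(grouped.items())]


# ---------------------------------------------------------------- ortholog map

def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    lines = ["source\ttarget"]
    for src in sorted(omap.pairs):
        for tgt in sorted(omap.pairs[src]):
            lines.append(f"{src}\t{tgt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = _read_tsv(path, ["source", "target"])
    pairs: dict[str, set[str]] = {}
    for r in df.itertuples():
        pairs.setdefault(str(r.source), set()).add(str(r.target))
    return OrthologMap(pairs={k: frozenset(v) for k, v in pairs.items()})


# ---------------------------------------------------------------- database

def _metadata_frame(db: SignatureDatabase) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.profile_id, p.drug_id, p.dose_um, p.duration_h, p.replicate,
          p.cell_context) for p in db.profiles],
        columns=META_COLUMNS)


def _profiles_from_meta(meta: pd.DataFrame, universe: tuple[str, ...],
                        matrix: np.ndarray) -> list[PerturbationProfile]:
    return [PerturbationProfile(
        drug_id=str(r.drug_id), dose_um=float(r.dose_um),
        duration_h=float(r.duration_h), replicate=int(r.replicate),
        cell_context=str(r.cell_context), profile_id=str(r.profile_id),
        universe=universe, values=matrix[:, j])
        for j, r in enumerate(meta.itertuples())]


def write_database_tsv(db: SignatureDatabase, matrix_path: str | Path,
                       meta_path: str | Path) -> None:
    mat = pd.DataFrame(
        np.column_stack([p.values for p in db.profiles]) if db.profiles
        else np.empty((len(db.universe), 0)),
        columns=[p.profile_id for p in db.profiles])
    mat.insert(0, "gene", list(db.universe))
    _write_tsv(mat, matrix_path)
    _write_tsv(_metadata_frame(db), meta_path)


def read_database_tsv(matrix_path: str | Path,
                      meta_path: str | Path) -> SignatureDatabase:
    mat = _read_tsv(matrix_path, ["gene"])
    genes = mat["gene"].astype(str).tolist()
    dup = pd.Series(genes).duplicated()
    if dup.any():
        raise FormatError(f"duplicate gene row {genes[int(dup.idxmax())]!r}",
                          str(matrix_path), line=int(dup.idxmax()) + 2)
    values = mat.drop(columns="gene").to_numpy(dtype=float)
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise FormatError("NaN cell in z-score matrix", str(matrix_path),
                          line=row + 2)
    meta = _read_tsv(meta_path, META_COLUMNS)
    if list(meta.profile_id.astype(str)) != list(mat.columns[1:]):
        raise FormatError("metadata rows do not match matrix columns",
                          str(meta_path))
    universe = tuple(genes)
    return SignatureDatabase(universe=universe,
                             profiles=_profiles_from_meta(meta, universe, values))


def write_database_mtx(db: SignatureDatabase, directory: str | Path) -> None:
    """MatrixMarket triplet encoding: matrix.mtx + genes.tsv + profiles.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dense = (np.column_stack([p.values for p in db.profiles]) if db.profiles
             else np.empty((len(db.universe), 0)))
    mmwrite(str(directory / "matrix.mtx"), coo_matrix(dense))
    (directory / "genes.tsv").write_text(
        "\n".join(db.universe) + "\n")
    _write_tsv(_metadata_frame(db), directory / "profiles.tsv")


def read_database_mtx(directory: str | Path) -> SignatureDatabase:
    directory = Path(directory)
    genes = [ln for ln in (directory / "genes.tsv").read_text().splitlines()
             if ln]
    if len(set(genes)) != len(genes):
        raise FormatError("duplicate gene row", str(directory / "genes.tsv"))
    values = np.asarray(mmread(str(directory / "matrix.mtx")).todense(),
                        dtype=float)
    meta = _read_tsv(directory / "profiles.tsv", META_COLUMNS)
    universe = tuple(genes)
    return SignatureDatabase(universe=universe,
                             profiles=_profiles_from_meta(meta, universe, values))


# ---------------------------------------------------------------- results

def results_frame(results: list[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.profile.profile_id, r.profile.drug_id, r.profile.dose_um,
          r.profile.duration_h, r.profile.replicate, r.score, r.p, r.zstat,
          r.combined) for r in results],
        columns=RESULT_COLUMNS)


def write_results(results: list[ConnectivityResult], path: str | Path) -> None:
    _write_tsv(results_frame(results), path)


def read_results(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, RESULT_COLUMNS)
    if df[["score", "p", "zstat", "combined"]].isna().any().any():
        raise FormatError("NaN cell in results table", str(path))
    return df


def write_ranked_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table, path)


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    from .ranking import RANKED_COLUMNS
    return _read_tsv(path, RANKED_COLUMNS)


def write_top_report(pro: pd.DataFrame, anti: pd.DataFrame,
                     flags: list[BipartiteFlag], path: str | Path) -> None:
    obj = {"pro": pro.to_dict(orient="records"),
           "anti": anti.to_dict(orient="records"),
           "bipartite": [dataclasses.asdict(f) for f in flags]}
    Path(path).write_text(json.dumps(obj, indent=1, default=float) + "\n")


def read_top_report(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"bad report JSON: {exc}", str(path)) from exc


# ---------------------------------------------------------------- enrichment

def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results],
                      columns=["term", "k", "K", "n", "N", "p", "q",
                               "combined", "signed_combined", "direction"])
    _write_tsv(df, path)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["term", "k", "K", "n", "N", "p", "q",
                            "combined", "signed_combined", "direction"])


# ---------------------------------------------------------------- coordinates

def write_coordinates(labels: tuple[str, ...], coords: np.ndarray,
                      path: str | Path) -> None:
    bands = [lb.split(":")[-1] if ":" in lb else "" for lb in labels]
    df = pd.DataFrame({"label": labels, "x": coords[:, 0], "y": coords[:, 1],
                       "dose_band": bands})
    _write_tsv(df, path)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["label", "x", "y", "dose_band"])
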