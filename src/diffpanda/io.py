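"""Readers and writers for every file format the pipeline touches.

All tabular formats are tab-delimited UTF-8 with '.' decimal separators;
gene sets use the standard GMT dialect; drug-signature databases are
JSON (``{"drug": {"up": [...], "down": [...]}}``) with an equivalent
long-format TSV. A ``.gz`` suffix is handled transparently everywhere.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .containers import (
    DrugSignatureDB,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    PPIMatrix,
    PriorNetwork,
    RegulatoryNetwork,
    Signature,
    validate_covariates,
)

_FLOAT_FMT = "%.17g"  # full double precision for round-tripping


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# expression + covariates


def read_expression_matrix(path: str | Path, kind: str = "counts") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene IDs, header row of
    sample IDs). Duplicate gene IDs are retained (with a warning) for
    later collapsing; any non-numeric cell is a located error."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns (missing header?)")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].map(np.isreal) | df[col].isna()]
            row = bad[0] if len(bad) else df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
        if df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise FormatError(f"{path}: missing value at gene {row!r}, sample {col!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), kind=kind)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate TSV (first column sample IDs; must contain a
    two-level ``diagnosis`` column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.index = df.index.astype(str)
    return validate_covariates(df)


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    df = covariates.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# priors


def read_prior_edges(path: str | Path) -> PriorNetwork:
    """Read a 3-column motif edge list (tf, gene, weight) into a dense
    binary TF x gene matrix over the union of listed names; positive
    weights are coerced to 1, absent pairs are 0."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "gene", "weight"],
                     dtype={"tf": str, "gene": str}, comment="#")
    if len(df) == 0:
        raise FormatError(f"{path}: no edges")
    dup = df.duplicated(subset=["tf", "gene"], keep=False)
    if dup.any():
        groups = df[dup].groupby(["tf", "gene"])["weight"].nunique()
        conflicting = groups[groups > 1]
        if len(conflicting):
            pair = conflicting.index[0]
            raise FormatError(f"{path}: conflicting duplicate edge {pair}")
        df = df.drop_duplicates(subset=["tf", "gene"])
    if not np.issubdtype(df["weight"].dtype, np.number) or df["weight"].isna().any():
        raise FormatError(f"{path}: non-numeric motif weight")
    tfs = sorted(df["tf"].unique())
    genes = sorted(df["gene"].unique())
    mat = pd.DataFrame(0.0, index=tfs, columns=genes)
    hits = df[df["weight"] > 0]
    mat.values[
        mat.index.get_indexer(hits["tf"]), mat.columns.get_indexer(hits["gene"])
    ] = 1.0
    return PriorNetwork(mat)


def write_prior_edges(prior: PriorNetwork, path: str | Path) -> None:
    """Write only the present (weight 1) motif edges as a 3-column TSV."""
    tf_idx, gene_idx = np.nonzero(prior.weights.to_numpy())
    with _open_text(path, "wt") as fh:
        for t, g in zip(tf_idx, gene_idx):
            fh.write(f"{prior.tf_names[t]}\t{prior.gene_names[g]}\t1\n")


def read_ppi_table(path: str | Path, threshold: float = 0.7) -> PPIMatrix:
    """Read a STRING-style TSV (tf_a, tf_b, combined score in [0, 1])
    and binarise: 1 iff score >= threshold, symmetrised, unit diagonal."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf_a", "tf_b", "score"],
                     dtype={"tf_a": str, "tf_b": str}, comment="#")
    if len(df) == 0:
        raise FormatError(f"{path}: no interactions")
    scores = df["score"].to_numpy()
    if not np.issubdtype(scores.dtype, np.number) or np.isnan(scores).any():
        raise FormatError(f"{path}: non-numeric PPI score")
    if scores.min() < 0 or scores.max() > 1:
        bad = df.iloc[int(np.argmax((scores < 0) | (scores > 1)))]
        raise FormatError(
            f"{path}: score {bad['score']} outside [0, 1] for ({bad['tf_a']}, {bad['tf_b']})"
        )
    tfs = sorted(set(df["tf_a"]) | set(df["tf_b"]))
    mat = pd.DataFrame(0.0, index=tfs, columns=tfs)
    keep = df[df["score"] >= threshold]
    ia = mat.index.get_indexer(keep["tf_a"])
    ib = mat.index.get_indexer(keep["tf_b"])
    mat.values[ia, ib] = 1.0
    mat.values[ib, ia] = 1.0
    np.fill_diagonal(mat.values, 1.0)
    return PPIMatrix(mat, threshold_applied=threshold)


def write_ppi_table(ppi: PPIMatrix, path: str | Path) -> None:
    """Write the upper triangle (including self-edges) as a 3-column TSV."""
    arr = ppi.scores.to_numpy()
    names = ppi.tf_names
    with _open_text(path, "wt") as fh:
        for i in range(len(names)):
            for j in range(i, len(names)):
                fh.write(f"{names[i]}\t{names[j]}\t{_FLOAT_FMT % arr[i, j]}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated
    (name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate member {m!r} in set {name!r}",
                                  stacklevel=2)
                seen[m] = None
            sets[name] = list(seen)
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# networks (long-format TSV, dense contract)


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write every (tf, gene, weight) triple at full double precision."""
    arr = net.weights.to_numpy()
    with _open_text(path, "wt") as fh:
        fh.write("tf\tgene\tweight\n")
        for i, tf in enumerate(net.tf_names):
            for j, gene in enumerate(net.gene_names):
                fh.write(f"{tf}\t{gene}\t{_FLOAT_FMT % arr[i, j]}\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a long-format network TSV; every TF x gene pair must be
    present exactly once (dense contract)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"tf": str, "gene": str})
    if list(df.columns) != ["tf", "gene", "weight"]:
        raise FormatError(f"{path}: expected columns tf, gene, weight")
    if df.duplicated(subset=["tf", "gene"]).any():
        raise FormatError(f"{path}: duplicate (tf, gene) pairs")
    mat = df.pivot(index="tf", columns="gene", values="weight")
    if mat.isna().any().any():
        tf = mat.index[mat.isna().any(axis=1)][0]
        gene = mat.columns[mat.isna().loc[tf]][0]
        raise FormatError(f"{path}: missing pair ({tf!r}, {gene!r}); network must be dense")
    return RegulatoryNetwork(mat.astype(float))


# ---------------------------------------------------------------------------
# drug-signature databases


def read_drug_db(path: str | Path) -> DrugSignatureDB:
    """Read a drug DB from JSON (``drug -> {up, down}``) or from a
    long-format TSV with columns (drug, direction, tf)."""
    path = Path(path)
    suffixes = [s for s in path.suffixes if s != ".gz"]
    if suffixes and suffixes[-1] == ".json":
        with _open_text(path) as fh:
            raw = json.load(fh)
        drugs = {}
        for name, entry in raw.items():
            drugs[name] = Signature(name=name, positive=list(entry.get("up", [])),
                                    negative=list(entry.get("down", [])))
        if not drugs:
            raise FormatError(f"{path}: empty drug database")
        return DrugSignatureDB(drugs=drugs)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if not {"drug", "direction", "tf"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns drug, direction, tf")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise FormatError(f"{path}: unknown direction values {sorted(bad)}")
    drugs = {}
    for name, group in df.groupby("drug", sort=False):
        drugs[str(name)] = Signature(
            name=str(name),
            positive=group.loc[group["direction"] == "up", "tf"].tolist(),
            negative=group.loc[group["direction"] == "down", "tf"].tolist(),
        )
    if not drugs:
        raise FormatError(f"{path}: empty drug database")
    return DrugSignatureDB(drugs=drugs)


def write_drug_db(db: DrugSignatureDB, path: str | Path) -> None:
    """Write JSON or long-format TSV depending on the file suffix."""
    path = Path(path)
    suffixes = [s for s in path.suffixes if s != ".gz"]
    if suffixes and suffixes[-1] == ".json":
        payload = {
            name: {"up": sig.positive, "down": sig.negative}
            for name, sig in db.drugs.items()
        }
        with _open_text(path, "wt") as fh:
            json.dump(payload, fh, indent=1)
    else:
        with _open_text(path, "wt") as fh:
            fh.write("drug\tdirection\ttf\n")
            for name, sig in db.drugs.items():
                for tf in sig.positive:
                    fh.write(f"{name}\tup\t{tf}\n")
                for tf in sig.negative:
                    fh.write(f"{name}\tdown\t{tf}\n")


def read_signature(path: str | Path) -> Signature:
    """Read a signature JSON ``{"positive": [...], "negative": [...]}``."""
    with _open_text(path) as fh:
        raw = json.load(fh)
    return Signature(name=raw.get("name", Path(path).stem),
                     positive=list(raw["positive"]), negative=list(raw["negative"]))


def write_signature(sig: Signature, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        json.dump({"name": sig.name, "positive": sig.positive,
                   "negative": sig.negative}, fh, indent=1)
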