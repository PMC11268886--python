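"""Readers and writers for every delimited artifact the pipeline touches.

All tables are plain TSV/CSV.  Missing-value tokens accepted on input are
the empty string, ``NA`` and ``NaN`` (case-insensitive); output always
writes the empty string for missing cells.  Parsing is locale-independent
(decimal point only).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    FLAG_COLUMNS,
    DesignTable,
    PeptideMatrix,
    ValidationError,
)

_NA_TOKENS = ["", "NA", "Na", "na", "nA", "NaN", "NAN", "nan", "NAn", "naN"]

#: logical -> default header names of a peptide report
DEFAULT_PEPTIDE_COLUMNS = {
    "sequence": "sequence",
    "charge": "charge",
    "protein": "protein",
    "gene": "gene",
    "biotinylated": "biotinylated",
    "phospho": "phospho",
    "contaminant": "contaminant",
    "nontarget_species": "nontarget_species",
}

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


def sniff_delimiter(path: str | Path, default: str = "\t") -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return default


def _parse_flag(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValidationError(f"unparseable flag value {value!r} in {where}")


def read_peptide_report(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> PeptideMatrix:
    """Read a delimited peptide intensity report.

    Parameters
    ----------
    path : path
        Delimited file with one row per precursor.
    columns : mapping, optional
        Overrides for the logical->actual header mapping
        (see :data:`DEFAULT_PEPTIDE_COLUMNS`); exporter schemas vary.
    sep : str, optional
        Delimiter; sniffed from the file when omitted.

    Every header not claimed by the column mapping is treated as a sample
    column.  Empty/NA cells become missing values.
    """
    path = Path(path)
    if sep is None:
        sep = sniff_delimiter(path)
    colmap = dict(DEFAULT_PEPTIDE_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(
        path, sep=sep, keep_default_na=False, na_values=_NA_TOKENS, dtype=object
    )
    present = {k: v for k, v in colmap.items() if v in raw.columns}
    if "sequence" not in present or "protein" not in present:
        raise ValidationError(
            f"{path.name}: required columns "
            f"{colmap['sequence']!r}/{colmap['protein']!r} not found"
        )
    meta_headers = set(present.values())
    sample_cols = [c for c in raw.columns if c not in meta_headers]
    if not sample_cols:
        raise ValidationError(f"{path.name}: no sample columns found")

    ann = pd.DataFrame(index=raw.index)
    ann["sequence"] = raw[present["sequence"]].astype(str)
    ann["protein"] = raw[present["protein"]].astype(str)
    if "gene" in present:
        ann["gene"] = raw[present["gene"]].astype(str)
    if "charge" in present:
        ann["charge"] = raw[present["charge"]].astype(int)
    for flag in FLAG_COLUMNS:
        if flag in present:
            ann[flag] = [
                _parse_flag(v, f"column {present[flag]!r} row {i + 2}")
                for i, v in enumerate(raw[present[flag]])
            ]

    X = pd.DataFrame(index=raw.index)
    for c in sample_cols:
        try:
            X[c] = pd.to_numeric(raw[c], errors="raise")
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path.name}: non-numeric intensity in sample column {c!r}: {exc}"
            ) from exc
    matrix = PeptideMatrix(ann, X)
    return matrix


def write_peptide_report(matrix: PeptideMatrix, path: str | Path) -> None:
    """Write a report that :func:`read_peptide_report` round-trips exactly."""
    ann = matrix.annotations
    out = pd.DataFrame(index=ann.index)
    out["sequence"] = ann["sequence"]
    if "charge" in ann.columns:
        out["charge"] = ann["charge"]
    out["protein"] = ann["protein"]
    out["gene"] = ann["gene"]
    for flag in FLAG_COLUMNS:
        out[flag] = ann[flag].astype(int)
    for s in matrix.samples:
        out[s] = matrix.intensities[s]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def read_design(
    path: str | Path,
    experimental: str | None = None,
    control: str | None = None,
    sep: str | None = None,
) -> DesignTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design file not found: {path}")
    if sep is None:
        sep = sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype={"sample": str, "group": str})
    return DesignTable.from_frame(frame, experimental, control)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# -- protein-protein interaction edge lists ---------------------------------


def read_edge_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a STRING-format edge list (protein1, protein2, combined_score).

    Scores on the STRING 0-1000 integer dialect are rescaled to [0, 1]
    (auto-detected from the maximum value).  Self-loops are dropped and
    duplicate unordered pairs collapsed to their maximum score.
    """
    path = Path(path)
    if sep is None:
        sep = sniff_delimiter(path, default=" ")
    frame = pd.read_csv(path, sep=sep)
    cols = {c.lstrip("#").lower(): c for c in frame.columns}
    try:
        a = frame[cols.get("protein1", cols.get("node1"))].astype(str)
        b = frame[cols.get("protein2", cols.get("node2"))].astype(str)
        score = pd.to_numeric(frame[cols.get("combined_score", cols.get("score"))])
    except KeyError as exc:
        raise ValidationError(
            f"{path.name}: expected protein1/protein2/combined_score headers"
        ) from exc
    if score.max() > 1.0:
        score = score / 1000.0
    if score.min() < 0 or score.max() > 1:
        raise ValidationError(f"{path.name}: scores outside [0, 1] after rescale")
    edges = pd.DataFrame({"protein_a": a, "protein_b": b, "score": score})
    edges = edges[edges["protein_a"] != edges["protein_b"]]
    lo = edges[["protein_a", "protein_b"]].min(axis=1)
    hi = edges[["protein_a", "protein_b"]].max(axis=1)
    edges = pd.DataFrame({"protein_a": lo, "protein_b": hi, "score": edges["score"]})
    edges = (
        edges.groupby(["protein_a", "protein_b"], as_index=False, sort=True)["score"]
        .max()
    )
    return edges.reset_index(drop=True)


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_network_sif(graph: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: one ``nodeA <relation> nodeB`` line per edge."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('source', 'pp')}\t{b}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\n")


def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


# -- generic results tables --------------------------------------------------


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table with deterministic column order and formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=_NA_TOKENS)


# -- kinase PSSMs and background site windows --------------------------------


def read_pssms(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read kinase position-specific scoring matrices.

    JSON layout ``{kinase: {offset: {residue: log_odds}}}`` or a long TSV
    with columns (kinase, offset, residue, score).  Returns one DataFrame
    per kinase, residues as rows and integer window offsets as columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            blob = json.load(fh)
        out = {}
        for kinase, mat in blob.items():
            frame = pd.DataFrame(
                {int(off): pd.Series(res) for off, res in mat.items()}
            ).fillna(0.0)
            out[kinase] = frame[sorted(frame.columns)]
        return out
    frame = pd.read_csv(path, sep="\t")
    out = {}
    for kinase, sub in frame.groupby("kinase", sort=False):
        mat = sub.pivot(index="residue", columns="offset", values="score").fillna(0.0)
        mat.columns = mat.columns.astype(int)
        out[str(kinase)] = mat[sorted(mat.columns)]
    return out


def write_pssms(pssms: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    blob = {
        kinase: {
            str(off): {str(res): float(mat.loc[res, off]) for res in mat.index}
            for off in mat.columns
        }
        for kinase, mat in pssms.items()
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1, sort_keys=True)


def read_background_windows(path: str | Path) -> list[str]:
    """Read background phosphosite windows from a FASTA-like file."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_background_windows(windows: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            fh.write(f">site{i:04d}\n{w}\n")
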