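"""Enriched-protein interaction network, phosphopeptide filtering and
kinase-motif percentile gating.

The network has gene-labelled nodes for every enriched protein, edges of
two provenances: ``external`` edges taken from a user-supplied scored
interaction list (kept when both endpoints are enriched and the score
reaches the cutoff, 0.7 by default), and ``in_data`` edges derived from
the proximity-labelling evidence itself -- the bait connected to every
enriched protein with a directly detected biotinylated peptide.

Phosphopeptides are narrowed in three nested stages: all quantified
phosphopeptides; those passing the same FC/FDR gates as proteins (tested
at the peptide level); and those on proteins with direct biotinylated
peptide evidence.  Candidate sites are then scored against kinase
position-specific scoring matrices and emitted as kinase->substrate
pairs when their percentile rank against a background site set strictly
exceeds the cutoff (90 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ValidationError
from .rollup import ThresholdParams, enrichment_call

#: neutral padding symbol for windows that extend past protein termini
PAD = "_"


def build_network(
    results: pd.DataFrame,
    external_edges: pd.DataFrame | None = None,
    score_cutoff: float = 0.7,
    bait: str = "Rac1",
    include_bait_edges: bool = True,
) -> tuple[nx.Graph, pd.DataFrame, list[str]]:
    """Assemble the enriched-protein interaction network.

    Parameters
    ----------
    results : DataFrame
        Protein results with ``gene``, ``enriched`` and
        ``biotinylated_evidence`` columns.
    external_edges : DataFrame, optional
        Scored undirected edges (``protein_a``, ``protein_b``, ``score``
        in [0, 1]), gene-labelled.  Edges naming genes absent from the
        results are skipped with a warning.
    score_cutoff : float
        Minimum external score; edges with score >= cutoff are kept.
    bait : str
        Node label for the bait protein used for in-data edges.
    include_bait_edges : bool
        Connect the bait to enriched proteins with direct biotinylated
        peptide evidence (the interaction evidence the data itself
        carries); disable to emit external edges only.

    Returns the graph, a node table, and skipped-edge warnings.
    """
    enriched = results.loc[results["enriched"]]
    known_genes = set(results["gene"])
    node_genes = list(dict.fromkeys(enriched["gene"]))
    graph = nx.Graph()
    for gene in sorted(node_genes):
        row = enriched.loc[enriched["gene"] == gene].iloc[0]
        graph.add_node(
            gene,
            enriched=True,
            biotinylated=bool(row["biotinylated_evidence"]),
            bait=False,
        )
    warnings_list: list[str] = []
    if external_edges is not None:
        for rec in external_edges.itertuples(index=False):
            a, b, score = rec.protein_a, rec.protein_b, float(rec.score)
            if a not in known_genes or b not in known_genes:
                msg = f"external edge ({a}, {b}) references unknown gene; skipped"
                warnings_list.append(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            if a == b:
                continue
            if score >= score_cutoff and graph.has_node(a) and graph.has_node(b):
                graph.add_edge(a, b, score=score, source="external", color="blue")
    if include_bait_edges:
        targets = sorted(
            set(enriched.loc[enriched["biotinylated_evidence"], "gene"]) - {bait}
        )
        if targets:
            graph.add_node(bait, enriched=False, biotinylated=True, bait=True)
            for gene in targets:
                graph.add_edge(bait, gene, score=np.nan, source="in_data",
                               color="red")
    nodes = pd.DataFrame(
        [
            {"gene": n, **graph.nodes[n], "degree": graph.degree(n)}
            for n in sorted(graph.nodes)
        ]
    )
    return graph, nodes, warnings_list


class PhosphoChainResult(NamedTuple):
    all_peptides: pd.DataFrame
    enriched_peptides: pd.DataFrame
    biotinylated_protein_peptides: pd.DataFrame
    counts: tuple[int, int, int]
    warnings: list[str]


def phospho_filter_chain(
    phospho: pd.DataFrame,
    results: pd.DataFrame,
    thresholds: ThresholdParams | None = None,
) -> PhosphoChainResult:
    """Narrow phosphopeptides to high-confidence candidates in three stages.

    ``phospho`` carries peptide-level differential statistics (``fc``,
    ``q`` -- or a precomputed ``enriched`` flag) and a ``protein`` column;
    ``results`` supplies per-protein ``biotinylated_evidence``.  Stage
    sets are nested by construction: set3 is a subset of set2 is a subset
    of set1.  Peptides mapped to proteins absent from the results stay in
    set1 but are excluded from sets 2-3 with a warning.
    """
    thresholds = thresholds or ThresholdParams()
    if "protein" not in phospho.columns:
        raise ValidationError("phospho table requires a 'protein' column")
    set1 = phospho.reset_index(drop=True)
    warnings_list: list[str] = []
    known = set(results["protein"])
    mapped = set1["protein"].isin(known)
    unknown = sorted(set(set1.loc[~mapped, "protein"]))
    if unknown:
        msg = (
            f"{len(unknown)} phosphopeptide protein(s) absent from results, "
            f"excluded from enrichment stages: {unknown[:5]!r}"
        )
        warnings_list.append(msg)
        warnings.warn(msg, stacklevel=2)
    if "enriched" in set1.columns:
        pep_enriched = set1["enriched"].astype(bool)
    else:
        pep_enriched = pd.Series(
            [
                enrichment_call(f, q, thresholds)
                for f, q in zip(set1["fc"], set1["q"])
            ],
            index=set1.index,
        )
    set2 = set1.loc[pep_enriched & mapped]
    biotin = results.set_index("protein")["biotinylated_evidence"]
    has_biotin = set2["protein"].map(biotin).eq(True)
    set3 = set2.loc[has_biotin.to_numpy()]
    counts = (len(set1), len(set2), len(set3))
    assert set(set3.index) <= set(set2.index) <= set(set1.index)
    return PhosphoChainResult(set1, set2, set3, counts, warnings_list)


@dataclass
class KinasePSSM:
    """A kinase specificity matrix over a window of offsets round the site.

    ``matrix`` has amino-acid rows and integer offset columns (default
    window -5..+4 with the phosphoacceptor at offset 0).  ``background``
    is the collection of windowed sequences used for percentile ranking.
    """

    name: str
    matrix: pd.DataFrame
    background: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = self.matrix.copy()
        self.matrix.columns = [int(c) for c in self.matrix.columns]
        self.matrix = self.matrix[sorted(self.matrix.columns)]

    @property
    def offsets(self) -> list[int]:
        return list(self.matrix.columns)

    def window_length(self) -> int:
        return len(self.offsets)

    def score(self, window: str) -> float:
        """Sum of log-odds entries for the residues at each window offset.

        The window must cover the matrix offsets with the phosphoacceptor
        at offset 0; padding symbols and residues missing from the matrix
        score 0 (neutral).
        """
        offsets = self.offsets
        center = -min(offsets)
        if len(window) != len(offsets):
            raise ValidationError(
                f"window {window!r} length {len(window)} != "
                f"matrix window {len(offsets)}"
            )
        total = 0.0
        for off in offsets:
            residue = window[center + off]
            if residue == PAD or residue not in self.matrix.index:
                continue
            total += float(self.matrix.loc[residue, off])
        return total

    def percentile(self, window: str) -> float:
        """Percent of background sites scoring strictly below this window."""
        if not len(self.background):
            raise ValidationError(
                f"kinase {self.name!r} has an empty background site list"
            )
        s = self.score(window)
        below = sum(1 for bg in self.background if self.score(bg) < s)
        return 100.0 * below / len(self.background)


def extract_window(
    sequence: str, position: int, offsets: Sequence[int] = range(-5, 5)
) -> str:
    """Windowed subsequence around a 1-based site, padded at the termini."""
    if position < 1 or position > len(sequence):
        raise ValidationError(
            f"site position {position} outside protein of length {len(sequence)}"
        )
    chars = []
    for off in offsets:
        i = position - 1 + off
        chars.append(sequence[i] if 0 <= i < len(sequence) else PAD)
    return "".join(chars)


def kinase_percentile_gate(
    sites: pd.DataFrame,
    pssms: Sequence[KinasePSSM] | Mapping[str, KinasePSSM],
    percentile_cutoff: float = 90.0,
) -> pd.DataFrame:
    """Score each (kinase, site) pair and keep percentiles strictly above cutoff.

    ``sites`` needs ``window`` plus identifying columns (``gene``,
    ``position``, ``residue`` when present are carried through).  The
    declared phosphoacceptor residue, if given, must match the window
    center.  Returns the emitted directed kinase->site pairs.
    """
    if isinstance(pssms, Mapping):
        pssms = list(pssms.values())
    if "window" not in sites.columns:
        raise ValidationError("site table requires a 'window' column")
    rows = []
    for rec in sites.reset_index(drop=True).itertuples(index=False):
        window = rec.window
        if hasattr(rec, "residue") and isinstance(rec.residue, str):
            for pssm in pssms[:1]:
                center = -min(pssm.offsets)
                if window[center] != rec.residue:
                    raise ValidationError(
                        f"declared residue {rec.residue!r} does not match "
                        f"window center of {window!r}"
                    )
        for pssm in pssms:
            s = pssm.score(window)
            pct = pssm.percentile(window)
            if pct > percentile_cutoff:
                rows.append(
                    {
                        "kinase": pssm.name,
                        "gene": getattr(rec, "gene", ""),
                        "position": getattr(rec, "position", np.nan),
                        "residue": getattr(rec, "residue", ""),
                        "window": window,
                        "score": s,
                        "percentile": pct,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "kinase", "gene", "position", "residue", "window",
            "score", "percentile",
        ],
    )
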