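"""Synthetic data generators emulating the pipeline's inputs.

The peptide simulator produces a DIA-style precursor report with the
statistical structure the analysis assumes: log-normal protein and
peptide intensities, multiplicative within-group replicate noise,
bait-specific spike-in proteins with a known fold change, group-independent
contaminant proteins (keratin/avidin analogues), intensity-dependent
(MNAR, logistic in log-intensity) plus completely-random dropout, and
biotinylated/phosphorylated peptide flags.  The behavioral simulator
produces timestamped maze entry sequences with a tunable alternation
tendency.

Identical configuration and seed produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import EntrySequence
from .containers import DesignTable, PeptideMatrix, ValidationError

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class ProteomicsSimConfig:
    """Generative settings for a synthetic DIA peptide report.

    Intensities follow a hierarchical log-normal model: a protein
    baseline on the log10 scale, a peptide-level multiplicative offset,
    and per-replicate noise with coefficient of variation
    ``cv_within_group``.  ``spike_fc`` multiplies the experimental-group
    intensities of spiked proteins only.
    """

    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (8, 18)
    n_replicates_per_group: int = 3
    log_mean_intensity: float = 6.0       # log10 of the typical peptide
    log_sd_between_proteins: float = 0.6  # log10 spread of protein baselines
    log_sd_between_peptides: float = 0.4  # log10 spread of peptide offsets
    cv_within_group: float = 0.15
    spike_fraction: float = 0.04
    spike_fc: float = 2.0
    dropout_mnar_midpoint: float = 1e4    # intensity at 50% MNAR dropout
    dropout_mnar_slope: float = 4.0       # logistic steepness per log10 unit
    dropout_mcar_rate: float = 0.01
    contaminant_fraction: float = 0.05
    frac_biotinylated: float = 0.01
    frac_phospho: float = 0.011
    charge_states: tuple[int, ...] = (2, 3)
    group_labels: tuple[str, str] = ("CA", "DN")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "spike_fraction",
            "dropout_mcar_rate",
            "contaminant_fraction",
            "frac_biotinylated",
            "frac_phospho",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.spike_fc <= 0:
            raise ValidationError("spike_fc must be > 0")
        for name in ("n_proteins", "n_replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValidationError("invalid peptides_per_protein range")
        if not self.charge_states:
            raise ValidationError("charge_states must be non-empty")


@dataclass
class BehaviorSimConfig:
    """Settings for synthetic maze entry sequences."""

    n_arms: int = 3
    n_entries: int = 30
    p_alternate: float = 0.5
    session_duration: float = 300.0
    n_mice_per_group: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_alternate <= 1.0:
            raise ValidationError("p_alternate must be in [0, 1]")
        if self.n_arms < 2:
            raise ValidationError("n_arms must be >= 2")
        if self.n_entries < 0:
            raise ValidationError("n_entries must be >= 0")


def design_for(config: ProteomicsSimConfig) -> DesignTable:
    """The sample design table matching a simulated report."""
    expt, ctrl = config.group_labels
    rows = []
    for group in (expt, ctrl):
        for r in range(1, config.n_replicates_per_group + 1):
            rows.append({"sample": f"{group}_{r}", "group": group,
                         "replicate": r})
    return DesignTable(pd.DataFrame(rows), expt, ctrl)


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    """Unique tryptic-looking peptide sequences."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 17))
        s = "".join(rng.choice(_AMINO_ACIDS, size=length)) + \
            ("K" if rng.random() < 0.5 else "R")
        if s in seen:
            continue
        seen.add(s)
        seqs.append(s)
    return seqs


def simulate_peptide_report(
    config: ProteomicsSimConfig,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Generate a precursor report and the ground-truth protein table.

    Returns the peptide x sample matrix (one row per peptide x charge,
    missing cells where dropout occurred) and a truth table with columns
    (protein, gene, true_fc, spiked, contaminant).
    """
    rng = np.random.default_rng(config.seed)
    design = design_for(config)
    expt = config.group_labels[0]
    samples = list(design.table["sample"])
    is_expt = np.array([design.table["group"].iloc[i] == expt
                        for i in range(len(samples))])

    n_prot = config.n_proteins
    n_contam = int(round(config.contaminant_fraction * n_prot))
    contaminant = np.zeros(n_prot, dtype=bool)
    contaminant[:n_contam] = True
    # contaminant analogues: keratin-like, avidin-like (bait-derived) and a
    # non-target-species share
    nontarget = np.zeros(n_prot, dtype=bool)
    proteins, genes = [], []
    for i in range(n_prot):
        if contaminant[i]:
            kind = i % 3
            if kind == 0:
                proteins.append(f"CON_KRT{i:04d}")
                genes.append(f"Krt{i:04d}")
            elif kind == 1:
                proteins.append(f"CON_AVID{i:04d}")
                genes.append(f"Avid{i:04d}")
            else:
                proteins.append(f"XEN_{i:04d}")
                genes.append(f"Xen{i:04d}")
                nontarget[i] = True
                contaminant[i] = False
        else:
            proteins.append(f"P{i:05d}")
            genes.append(f"Gene{i:04d}")

    eligible = np.flatnonzero(~(contaminant | nontarget))
    n_spike = int(round(config.spike_fraction * eligible.size))
    spiked = np.zeros(n_prot, dtype=bool)
    if config.spike_fc != 1.0 and n_spike:
        chosen = rng.choice(eligible, size=n_spike, replace=False)
        spiked[chosen] = True
    true_fc = np.where(spiked, config.spike_fc, 1.0)

    truth = pd.DataFrame(
        {
            "protein": proteins,
            "gene": genes,
            "true_fc": true_fc,
            "spiked": spiked,
            "contaminant": contaminant | nontarget,
        }
    )

    lo, hi = config.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=n_prot)
    prot_base = rng.normal(
        config.log_mean_intensity, config.log_sd_between_proteins, size=n_prot
    )
    total_peps = int(n_peps.sum())
    pep_protein_idx = np.repeat(np.arange(n_prot), n_peps)
    pep_log10 = prot_base[pep_protein_idx] + rng.normal(
        0.0, config.log_sd_between_peptides, size=total_peps
    )
    sequences = _random_sequences(rng, total_peps)
    biotin = rng.random(total_peps) < config.frac_biotinylated
    phospho = rng.random(total_peps) < config.frac_phospho

    sigma = np.sqrt(np.log1p(config.cv_within_group**2))
    base = 10.0 ** pep_log10
    fc_per_pep = true_fc[pep_protein_idx]
    means = base[:, None] * np.where(is_expt[None, :], fc_per_pep[:, None], 1.0)
    noise = rng.normal(0.0, sigma, size=means.shape)
    values = means * np.exp(noise)

    # split each peptide across one or two charge states
    charges_avail = np.array(sorted(config.charge_states))
    n_charges = rng.integers(1, min(2, charges_avail.size) + 1, size=total_peps)
    rows_ann, rows_int = [], []
    for j in range(total_peps):
        k = int(n_charges[j])
        zs = rng.choice(charges_avail, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k)) if k > 1 else np.ones(1)
        for z, w in zip(np.sort(zs), weights):
            rows_ann.append(
                {
                    "sequence": sequences[j],
                    "charge": int(z),
                    "protein": proteins[pep_protein_idx[j]],
                    "gene": genes[pep_protein_idx[j]],
                    "biotinylated": bool(biotin[j]),
                    "phospho": bool(phospho[j]),
                    "contaminant": bool(contaminant[pep_protein_idx[j]]),
                    "nontarget_species": bool(nontarget[pep_protein_idx[j]]),
                }
            )
            rows_int.append(values[j] * w)

    ann = pd.DataFrame(rows_ann)
    X = pd.DataFrame(np.vstack(rows_int), columns=samples)

    # dropout: logistic MNAR in log10 intensity, plus independent MCAR
    v = X.to_numpy()
    with np.errstate(divide="ignore", over="ignore"):
        z = config.dropout_mnar_slope * (
            np.log10(np.maximum(v, 1e-300))
            - np.log10(config.dropout_mnar_midpoint)
        )
        p_mnar = 1.0 / (1.0 + np.exp(z))
    drop = (rng.random(v.shape) < p_mnar) | (
        rng.random(v.shape) < config.dropout_mcar_rate
    )
    v[drop] = np.nan
    X = pd.DataFrame(v, columns=samples)
    return PeptideMatrix(ann, X), truth


def simulate_entry_sequence(config: BehaviorSimConfig) -> EntrySequence:
    """Generate one maze session of timestamped arm entries.

    Arm choice: with probability ``p_alternate`` the mouse picks
    uniformly among arms not visited in the last ``n_arms - 1`` entries
    (a fresh arm), otherwise uniformly among recently visited arms other
    than the current one.  No two consecutive entries share an arm and
    timestamps are strictly increasing within the session.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_entries, config.n_arms
    arms_all = list(range(1, k + 1))
    arms: list[int] = []
    for i in range(n):
        if not arms:
            arms.append(int(rng.choice(arms_all)))
            continue
        current = arms[-1]
        recent = set(arms[-(k - 1):])
        fresh = [a for a in arms_all if a not in recent]
        stale = [a for a in arms_all if a in recent and a != current]
        if not fresh or not stale:
            choices = [a for a in arms_all if a != current]
            arms.append(int(rng.choice(choices)))
        elif rng.random() < config.p_alternate:
            arms.append(int(rng.choice(fresh)))
        else:
            arms.append(int(rng.choice(stale)))
    times = np.sort(rng.uniform(0.0, config.session_duration, size=n))
    # enforce strict monotonicity against (measure-zero) ties
    for i in range(1, n):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], np.inf)
    return EntrySequence(arms, list(times), config.session_duration)


# -- synthetic kinase resources (for end-to-end runs without external data) --


def simulate_phospho_sites(
    matrix: PeptideMatrix, seed: int = 0, window: range = range(-5, 5)
) -> pd.DataFrame:
    """Invent phosphosite records for the phospho-flagged peptides.

    Real site localization comes from the search engine and is taken as
    given by the pipeline; this helper makes windowed S/T/Y sites so the
    kinase gate can be exercised on synthetic runs.
    """
    rng = np.random.default_rng(seed)
    ann = matrix.annotations
    phos = ann.loc[ann["phospho"]]
    rows = []
    width = len(list(window))
    center = -min(window)
    for rec in phos.itertuples(index=False):
        residue = str(rng.choice(["S", "T", "Y"], p=[0.75, 0.2, 0.05]))
        chars = rng.choice(_AMINO_ACIDS, size=width)
        chars[center] = residue
        rows.append(
            {
                "sequence": rec.sequence,
                "protein": rec.protein,
                "gene": rec.gene,
                "position": int(rng.integers(center + 1, 400)),
                "residue": residue,
                "window": "".join(chars),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sequence", "protein", "gene", "position", "residue", "window"],
    )


def simulate_pssms(
    n_kinases: int = 3,
    n_background: int = 60,
    seed: int = 0,
    window: range = range(-5, 5),
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Random log-odds kinase matrices and a shared background site list."""
    rng = np.random.default_rng(seed)
    offsets = list(window)
    pssms = {}
    for i in range(n_kinases):
        mat = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(len(_AMINO_ACIDS), len(offsets))),
            index=list(_AMINO_ACIDS),
            columns=offsets,
        )
        pssms[f"KIN{i + 1}"] = mat
    center = -min(offsets)
    background = []
    for _ in range(n_background):
        chars = rng.choice(_AMINO_ACIDS, size=len(offsets))
        chars[center] = rng.choice(["S", "T", "Y"])
        background.append("".join(chars))
    return pssms, background
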