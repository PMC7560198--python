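"""Synthetic secretome data with planted ground truth.

Emulates the statistical structure of a cell-type-resolved LFQ secretome
experiment at desk scale:

* log-normal protein abundances (log2 intensities drawn from a Gaussian);
* a planted fraction of cell-type-specifically secreted proteins with a
  fixed log2 enrichment in their cell type;
* replicate noise;
* intensity-dependent left-censored missingness — each measurement is
  observed with probability ``logistic((latent - censor_mid) * censor_slope)``,
  so low-abundance proteins drop out preferentially (MNAR), which is exactly
  the regime the down-shifted-Gaussian imputation targets.  A hard-threshold
  censoring mode is also available;
* UniProt-style keyword/topology annotation structure (soluble secreted,
  single-pass transmembrane, GPI-anchored) with random protein sequences;
* tryptic digests of the single-pass TM proteins restricted to their
  ectodomains, with a small leakage rate of intracellular peptides and
  optional planted non-tryptic cleavage sites;
* a fluid (CSF-like) table mixing the cell-type profiles.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AnnotationRecord,
    IntensityTable,
    PeptideRecord,
    Sample,
    SampleDesign,
    TopologySegment,
    TERMINUS,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_secretome",
    "generate_annotations_topology",
    "generate_peptides",
    "generate_fluid",
    "tryptic_digest",
    "write_simulation",
]

DEFAULT_GROUPS = ("astrocyte", "microglia", "neuron", "oligodendrocyte")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the study conditions.

    Four brain cell types with six biological replicates each; log2
    abundances centred at 25 with SD 2 (typical LFQ dynamic range);
    30% of proteins planted as cell-type-specific with an eight-fold (log2 = 3)
    enrichment, comfortably above the five-fold calling threshold; replicate
    SD 0.5; logistic detection centred at log2 intensity 22 with slope 1.5.
    """

    n_proteins: int = 2000
    groups: tuple = DEFAULT_GROUPS
    n_replicates: int = 6
    base_mean: float = 25.0
    base_sd: float = 2.0
    frac_cts: float = 0.3
    effect_log2: float = float(np.log2(8))
    replicate_sd: float = 0.5
    censor_mid: float = 22.0
    censor_slope: float = 1.5
    hard_censoring: bool = False
    frac_secreted: float = 0.45
    frac_single_tm: float = 0.40
    frac_gpi: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cts", "frac_secreted", "frac_single_tm", "frac_gpi"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_secreted + self.frac_single_tm + self.frac_gpi > 1.0 + 1e-9:
            raise ValueError("annotation fractions must sum to <= 1")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside every generated table."""

    config: SimConfig
    protein_ids: list
    specific_group: pd.Series  # group name or None per protein
    true_means: pd.DataFrame  # latent log2 mean per protein x group
    annotation_class: pd.Series | None = None  # soluble/single_tm/gpi/other
    keywords: dict = field(default_factory=dict)
    detect_prob: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "protein_ids": list(self.protein_ids),
            "specific_group": {
                p: g for p, g in self.specific_group.items() if g is not None
            },
            "true_means": self.true_means.round(6).to_dict(orient="index"),
            "annotation_class": (
                self.annotation_class.to_dict()
                if self.annotation_class is not None
                else None
            ),
        }
        return json.dumps(payload, indent=1, default=list)


def _design(groups, n_replicates) -> SampleDesign:
    return SampleDesign(
        Sample(sample_id=f"{g}_{r}", group=g, replicate=r)
        for g in groups
        for r in range(1, n_replicates + 1)
    )


def generate_secretome(config: SimConfig) -> tuple[IntensityTable, SimTruth]:
    """Generate a raw-scale secretome table and its planted truth.

    For protein ``i``, group ``g``, replicate ``r`` the latent log2
    intensity is ``base_i + effect * 1[g == cts_i] + Normal(0, replicate_sd^2)``;
    the measurement is observed with probability
    ``logistic((latent - censor_mid) * censor_slope)`` (or iff latent >=
    censor_mid in hard mode) and recorded as ``2**latent``.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    n = config.n_proteins
    groups = list(config.groups)
    protein_ids = [f"SYN{i:05d}" for i in range(n)]

    base = rng.normal(config.base_mean, config.base_sd, size=n)
    n_cts = int(round(config.frac_cts * n))
    cts_idx = rng.choice(n, size=n_cts, replace=False)
    cts_group = np.full(n, None, dtype=object)
    cts_group[cts_idx] = rng.choice(groups, size=n_cts)

    true_means = pd.DataFrame(
        {
            g: base + config.effect_log2 * (cts_group == g)
            for g in groups
        },
        index=protein_ids,
    )

    design = _design(groups, config.n_replicates)
    latent = np.empty((n, len(design)))
    for j, s in enumerate(design.samples):
        latent[:, j] = true_means[s.group].to_numpy() + rng.normal(
            0.0, config.replicate_sd, size=n
        )
    if config.hard_censoring:
        observed = latent >= config.censor_mid
    else:
        p_detect = 1.0 / (
            1.0 + np.exp(-(latent - config.censor_mid) * config.censor_slope)
        )
        observed = rng.random(latent.shape) < p_detect
    if not observed.any():
        raise ValueError("degenerate config: every measurement censored")

    raw = np.where(observed, np.power(2.0, latent), np.nan)
    table = IntensityTable(
        pd.DataFrame(raw, index=pd.Index(protein_ids, name="protein_id"),
                     columns=design.sample_ids),
        design,
        scale="raw",
    )
    detect_prob = pd.DataFrame(
        1.0
        / (1.0 + np.exp(-(true_means.to_numpy() - config.censor_mid)
                        * config.censor_slope)),
        index=protein_ids,
        columns=groups,
    )
    truth = SimTruth(
        config=config,
        protein_ids=protein_ids,
        specific_group=pd.Series(cts_group, index=protein_ids, name="specific_group"),
        true_means=true_means,
        detect_prob=detect_prob,
    )
    return table, truth


# ---------------------------------------------------------------------------
# annotations, sequences, topology
# ---------------------------------------------------------------------------

def generate_annotations_topology(
    truth: SimTruth,
    min_length: int = 200,
    max_length: int = 800,
) -> tuple[list[AnnotationRecord], dict[str, str]]:
    """Random sequences plus keyword/topology annotation per protein.

    Annotation classes are drawn by the configured fractions: soluble
    secreted (secreted + glycoprotein keywords, no topology), single-pass TM
    (extracellular / 21-residue TM / intracellular segments with random
    type-I or type-II orientation), GPI-anchored (entirely extracellular),
    and "other" (cytoplasmic).  Populates ``truth.annotation_class``.
    """
    config = truth.config
    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    classes = rng.choice(
        ["soluble", "single_tm", "gpi", "other"],
        size=len(truth.protein_ids),
        p=[
            config.frac_secreted,
            config.frac_single_tm,
            config.frac_gpi,
            1.0 - config.frac_secreted - config.frac_single_tm - config.frac_gpi,
        ],
    )
    records: list[AnnotationRecord] = []
    sequences: dict[str, str] = {}
    aa = np.array(list(AMINO_ACIDS))
    for pid, cls in zip(truth.protein_ids, classes):
        length = int(rng.integers(min_length, max_length + 1))
        seq = "".join(rng.choice(aa, size=length))
        sequences[pid] = seq
        if cls == "soluble":
            keywords = {"secreted", "glycoprotein"}
            topology = ()
        elif cls == "single_tm":
            keywords = {"membrane", "transmembrane_single_pass", "glycoprotein"}
            tm_start = int(rng.integers(60, length - 60))
            tm = TopologySegment("transmembrane", tm_start, tm_start + 20)
            if rng.random() < 0.5:  # type I: extracellular N-terminus
                topology = (
                    TopologySegment("extracellular", 1, tm_start - 1),
                    tm,
                    TopologySegment("intracellular", tm_start + 21, length),
                )
            else:  # type II
                topology = (
                    TopologySegment("intracellular", 1, tm_start - 1),
                    tm,
                    TopologySegment("extracellular", tm_start + 21, length),
                )
        elif cls == "gpi":
            keywords = {"gpi_anchor", "glycoprotein"}
            topology = (TopologySegment("extracellular", 1, length),)
        else:
            keywords = {"cytoplasm"}
            topology = ()
        records.append(
            AnnotationRecord(
                protein_id=pid,
                keywords=keywords,
                topology=topology,
                sequence_length=length,
            )
        )
    truth.annotation_class = pd.Series(classes, index=truth.protein_ids,
                                       name="annotation_class")
    truth.keywords = {r.protein_id: set(r.keywords) for r in records}
    return records, sequences


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 30,
) -> list[tuple[int, int]]:
    """In-silico tryptic peptides as (start, end), 1-based inclusive.

    Cuts after every K/R (no proline exception), allows up to
    ``missed_cleavages`` missed cut sites, and filters by length.
    """
    cut_after = [m.end() for m in re.finditer("[KR]", sequence)]
    boundaries = [0] + [c for c in cut_after if c < len(sequence)] + [len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            if min_length <= end - start + 1 <= max_length:
                peptides.append((start, end))
    return peptides


def _to_record(pid: str, seq: str, start: int, end: int) -> PeptideRecord:
    return PeptideRecord(
        protein_id=pid,
        sequence=seq[start - 1 : end],
        start=start,
        end=end,
        aa_before=seq[start - 2] if start > 1 else TERMINUS,
        aa_after=seq[end] if end < len(seq) else TERMINUS,
    )


def generate_peptides(
    sequences: dict[str, str],
    annotations: list[AnnotationRecord],
    seed: int = 0,
    leakage: float = 0.001,
    planted_cuts: dict[str, int] | None = None,
    missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 30,
) -> list[PeptideRecord]:
    """Digest the single-pass TM proteins into ectodomain peptides.

    Fully tryptic peptides lying entirely in the extracellular segment are
    emitted; peptides lying in the intracellular segment leak through with
    probability ``leakage`` (emulating trace contamination); TM-spanning
    peptides are dropped.  ``planted_cuts`` maps protein id -> residue
    position after which an endogenous protease cut is planted: the two
    peptides abutting that cut (tryptic on their far side) are added, each
    carrying one non-tryptic terminus.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    planted_cuts = planted_cuts or {}
    by_id = {a.protein_id: a for a in annotations}
    records: list[PeptideRecord] = []
    for pid, record in by_id.items():
        if "transmembrane_single_pass" not in record.keywords:
            continue
        seq = sequences[pid]
        extra = record.segments("extracellular")
        intra = record.segments("intracellular")
        for start, end in tryptic_digest(seq, missed_cleavages, min_length, max_length):
            if any(s.contains(start, end) for s in extra):
                records.append(_to_record(pid, seq, start, end))
            elif any(s.contains(start, end) for s in intra):
                if rng.random() < leakage:
                    records.append(_to_record(pid, seq, start, end))
        cut = planted_cuts.get(pid)
        if cut is not None:
            records.extend(_planted_cut_peptides(
                pid, seq, cut, min_length, max_length))
    return records


def pick_cleavage_site(
    sequence: str,
    rng: np.random.Generator | None = None,
    min_length: int = 6,
    max_length: int = 30,
    region: tuple[int, int] | None = None,
) -> int | None:
    """A position after which a plantable endogenous cut exists.

    Valid positions have a non-K/R residue at the cut (so the resulting
    termini are non-tryptic) and tryptic neighbours far enough away that
    both released peptides pass the length filter.  ``region`` restricts
    candidates to a 1-based inclusive residue window (e.g. a juxtamembrane
    stretch).  Returns None when no position qualifies.
    """
    cut_ends = [m.end() for m in re.finditer("[KR]", sequence)]
    lo, hi = region if region else (1, len(sequence) - 1)
    candidates = []
    for cut in range(max(lo, min_length + 1), min(hi, len(sequence) - 1) + 1):
        if sequence[cut - 1] in "KR":
            continue
        prev = max((c for c in cut_ends if c < cut), default=0)
        nxt = next((c for c in cut_ends if c > cut), len(sequence))
        if (min_length <= cut - prev <= max_length
                and min_length <= nxt - cut <= max_length):
            candidates.append(cut)
    if not candidates:
        return None
    if rng is None:
        return candidates[0]
    return int(candidates[int(rng.integers(len(candidates)))])


def _planted_cut_peptides(pid: str, seq: str, cut: int,
                          min_length: int, max_length: int) -> list[PeptideRecord]:
    """Semi-tryptic peptides released by an endogenous cut after residue ``cut``."""
    if not (1 <= cut < len(seq)):
        raise ValueError(f"planted cut {cut} outside {pid} (length {len(seq)})")
    out = []
    # peptide starting at cut+1, ending at the next tryptic site
    nxt = next((m.end() for m in re.finditer("[KR]", seq)
                if m.end() > cut), len(seq))
    if min_length <= nxt - cut <= max_length:
        out.append(_to_record(pid, seq, cut + 1, nxt))
    # peptide ending at cut, starting after the previous tryptic site
    prev = max((m.end() for m in re.finditer("[KR]", seq) if m.end() < cut),
               default=0)
    if min_length <= cut - prev <= max_length:
        out.append(_to_record(pid, seq, prev + 1, cut))
    return out


# ---------------------------------------------------------------------------
# fluid (CSF-like) table
# ---------------------------------------------------------------------------

def generate_fluid(
    truth: SimTruth,
    weights: dict[str, float] | None = None,
    n_replicates: int = 4,
    frac_from_resource: float = 0.65,
    group_name: str = "csf",
    seed: int | None = None,
) -> IntensityTable:
    """A fluid secretome as a weighted mixture of the cell-type profiles.

    A fraction ``frac_from_resource`` of fluid proteins is drawn from the
    resource; the remainder are fluid-exclusive proteins with fresh
    accessions and independent abundances.  Each fluid protein's latent log2
    mean is ``log2(sum_g w_g * 2**mu_ig)``; replicate noise and the same
    logistic censoring model then apply.
    """
    config = truth.config
    rng = np.random.Generator(np.random.PCG64(
        config.seed + 2 if seed is None else seed))
    groups = list(truth.true_means.columns)
    if weights is None:
        weights = {g: 1.0 / len(groups) for g in groups}
    w = np.array([weights.get(g, 0.0) for g in groups])
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()

    n_res = int(round(frac_from_resource * len(truth.protein_ids)))
    picked = sorted(rng.choice(len(truth.protein_ids), size=n_res, replace=False))
    res_ids = [truth.protein_ids[i] for i in picked]
    mixture = np.log2(
        (np.power(2.0, truth.true_means.loc[res_ids].to_numpy()) * w).sum(axis=1)
    )
    n_ext = int(round(n_res * (1.0 - frac_from_resource) / max(frac_from_resource, 1e-9)))
    ext_ids = [f"EXT{i:05d}" for i in range(n_ext)]
    ext_means = rng.normal(config.base_mean, config.base_sd, size=n_ext)

    ids = res_ids + ext_ids
    means = np.concatenate([mixture, ext_means])
    design = _design([group_name], n_replicates)
    latent = means[:, None] + rng.normal(0.0, config.replicate_sd,
                                         size=(len(ids), n_replicates))
    p_detect = 1.0 / (1.0 + np.exp(-(latent - config.censor_mid)
                                   * config.censor_slope))
    observed = rng.random(latent.shape) < p_detect
    raw = np.where(observed, np.power(2.0, latent), np.nan)
    return IntensityTable(
        pd.DataFrame(raw, index=pd.Index(ids, name="protein_id"),
                     columns=design.sample_ids),
        design,
        scale="raw",
    )


# ---------------------------------------------------------------------------
# full simulation bundle on disk
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full input bundle and write it under ``outdir``.

    Writes protein-group TSV, design YAML, annotation TSV, FASTA, peptide
    TSV, fluid TSV + design, and the truth JSON.  Returns the path map.
    """
    from . import io_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = generate_secretome(config)
    annotations, sequences = generate_annotations_topology(truth)
    peptides = generate_peptides(sequences, annotations, seed=config.seed + 3)
    fluid = generate_fluid(truth)

    paths = {
        "protein_groups": outdir / "protein_groups.tsv",
        "design": outdir / "design.yaml",
        "annotations": outdir / "annotations.tsv",
        "fasta": outdir / "proteins.fasta",
        "peptides": outdir / "peptides.tsv",
        "fluid": outdir / "fluid.tsv",
        "fluid_design": outdir / "fluid_design.yaml",
        "truth": outdir / "truth.json",
    }
    io_tables.write_protein_groups(table, paths["protein_groups"])
    io_tables.write_design(table.design, paths["design"])
    io_tables.write_annotations(annotations, paths["annotations"])
    io_tables.write_fasta(sequences, paths["fasta"])
    io_tables.write_peptides(peptides, paths["peptides"])
    io_tables.write_protein_groups(fluid, paths["fluid"])
    io_tables.write_design(fluid.design, paths["fluid_design"])
    paths["truth"].write_text(truth.to_json())
    return paths
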