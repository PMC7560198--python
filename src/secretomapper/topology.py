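"""Peptide-to-ectodomain mapping, shed-vs-soluble classes, cleavage calls.

Secretome samples should contain the *extracellular* portions of membrane
proteins: a shed single-pass transmembrane protein contributes peptides from
its ectodomain, essentially never from its cytosolic tail.  Mapping every
identified peptide of single-pass TM proteins onto the protein's annotated
topology is therefore a purity QC — a high ectodomain fraction confirms the
sample holds shed ectodomains rather than membrane debris or lysed cells.

Shed-vs-soluble classification is purely annotation-driven: single-pass TM
and GPI-anchored proteins found in a secretome are (candidate) shedding
substrates; proteins with a secreted keyword and no membrane anchor are
conventionally secreted.

Cleavage calling inspects peptide termini: trypsin cuts after Lys/Arg, so a
peptide terminus not explained by trypsin (or the protein's natural
terminus) marks an endogenous protease cleavage site — the semi-tryptic
peptide nominates the cut position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import AnnotationRecord, PeptideRecord, TERMINUS

logger = logging.getLogger(__name__)

__all__ = [
    "map_peptides",
    "classify_secretion",
    "shed_soluble_counts",
    "call_cleavage",
    "CleavageCall",
]

REGIONS = ("ectodomain", "transmembrane_spanning", "intracellular", "unresolved")


def _map_one(peptide: PeptideRecord, record: AnnotationRecord) -> str:
    """Region of one peptide on one single-pass TM protein's topology."""
    if record.sequence_length and peptide.end > record.sequence_length:
        logger.warning(
            "%s peptide %s ends at %d beyond sequence length %d",
            peptide.protein_id, peptide.sequence, peptide.end,
            record.sequence_length,
        )
        return "unresolved"
    span = (peptide.start, peptide.end)
    tm = record.segments("transmembrane")
    if any(seg.overlaps(*span) for seg in tm):
        # overlap with the membrane-spanning segment wins, even if the
        # peptide also reaches into the ectodomain — keeps the ectodomain
        # fraction strict
        return "transmembrane_spanning"
    extra = record.segments("extracellular")
    intra = record.segments("intracellular")

    def covered_by(segments) -> bool:
        # contiguous coverage of the peptide interval by same-kind segments
        pos = peptide.start
        for seg in sorted(segments, key=lambda s: s.start):
            if seg.start <= pos <= seg.end:
                pos = seg.end + 1
                if pos > peptide.end:
                    return True
        return False

    if covered_by(extra):
        return "ectodomain"
    if covered_by(intra):
        return "intracellular"
    return "unresolved"


def map_peptides(
    peptides: list[PeptideRecord],
    annotations: list[AnnotationRecord],
) -> pd.DataFrame:
    """Map peptides of single-pass TM proteins onto their topology.

    Returns one row per peptide with its ``region``; peptides of proteins
    without usable single-pass topology are ``unresolved``.  Summary
    fractions over resolved peptides are in ``result.attrs["fractions"]``
    (they sum to 1) and the headline ectodomain fraction in
    ``attrs["ectodomain_fraction"]``.
    """
    by_id = {a.protein_id: a for a in annotations}
    rows = []
    for pep in peptides:
        record = by_id.get(pep.protein_id)
        if record is None or "transmembrane_single_pass" not in record.keywords:
            region = "unresolved"
        else:
            region = _map_one(pep, record)
        rows.append((pep.protein_id, pep.sequence, pep.start, pep.end, region))
    result = pd.DataFrame(
        rows, columns=["protein_id", "sequence", "start", "end", "region"]
    )
    resolved = result[result["region"] != "unresolved"]
    fractions = {r: 0.0 for r in REGIONS[:3]}
    if len(resolved):
        fractions.update(
            (resolved["region"].value_counts() / len(resolved)).to_dict()
        )
    result.attrs["fractions"] = fractions
    result.attrs["ectodomain_fraction"] = fractions["ectodomain"]
    result.attrs["n_resolved"] = int(len(resolved))
    return result


# ---------------------------------------------------------------------------
# shed vs soluble
# ---------------------------------------------------------------------------

def classify_secretion(annotations: list[AnnotationRecord]) -> pd.Series:
    """Annotation-driven secretion class per protein.

    ``shed_membrane`` — single-pass TM or GPI-anchored (the ectodomain found
    in a secretome was proteolytically released); ``soluble_secreted`` —
    secreted keyword without a membrane anchor; ``other`` — everything else.
    """
    classes = {}
    for rec in annotations:
        if {"transmembrane_single_pass", "gpi_anchor"} & rec.keywords:
            classes[rec.protein_id] = "shed_membrane"
        elif "secreted" in rec.keywords:
            classes[rec.protein_id] = "soluble_secreted"
        else:
            classes[rec.protein_id] = "other"
    return pd.Series(classes, name="secretion_class")


def shed_soluble_counts(
    classes: pd.Series,
    counts: pd.DataFrame,
    annotations: list[AnnotationRecord],
    min_detected: int = 5,
    glyco_only: bool = True,
    restrict_to: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group shed/soluble composition of the detected secretome.

    For each group, proteins detected in >= ``min_detected`` of its
    replicates (optionally restricted to glycoproteins, or to a per-protein
    specificity call via ``restrict_to``) are tallied by secretion class;
    percentages are relative to shed + soluble within the group.
    """
    glyco = {a.protein_id for a in annotations if "glycoprotein" in a.keywords}
    rows = []
    for g in counts.columns:
        detected = counts.index[counts[g] >= min_detected]
        if glyco_only:
            detected = [p for p in detected if p in glyco]
        if restrict_to is not None:
            detected = [p for p in detected if restrict_to.get(p) == g]
        cls = classes.reindex(detected).fillna("other")
        n_shed = int((cls == "shed_membrane").sum())
        n_sol = int((cls == "soluble_secreted").sum())
        denom = n_shed + n_sol
        rows.append(
            (
                g,
                n_shed,
                n_sol,
                100.0 * n_shed / denom if denom else float("nan"),
                100.0 * n_sol / denom if denom else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["group", "n_shed", "n_soluble", "pct_shed", "pct_soluble"]
    ).set_index("group")


# ---------------------------------------------------------------------------
# cleavage calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageCall:
    peptide: PeptideRecord
    n_term_tryptic: bool
    c_term_tryptic: bool
    specificity: str  # tryptic | semi_tryptic | non_tryptic
    nominated_cleavage_position: int | None

    def __post_init__(self) -> None:
        expected = {2: "tryptic", 1: "semi_tryptic", 0: "non_tryptic"}[
            int(self.n_term_tryptic) + int(self.c_term_tryptic)
        ]
        if self.specificity != expected:
            raise ValueError("specificity inconsistent with terminus flags")


def call_cleavage(
    peptide: PeptideRecord,
    protein_sequence: str,
    cut_before_proline: bool = True,
) -> CleavageCall:
    """Classify a peptide's termini as tryptic or endogenous cleavage.

    A terminus is tryptic when the residue preceding it (``aa_before`` for
    the N-terminus, the peptide's own last residue for the C-terminus) is K
    or R, or when the terminus coincides with the protein's terminus.  By
    default cleavage before proline still counts as tryptic (matching a
    lenient search configuration); set ``cut_before_proline=False`` to apply
    the classical proline exception.

    A semi-tryptic peptide nominates its non-tryptic boundary as the
    cleavage position: the residue *before* the peptide (``start - 1``) for
    N-terminal non-specificity, the peptide's last residue (``end``) for
    C-terminal.
    """
    start, end = peptide.start, peptide.end
    if end > len(protein_sequence):
        raise ValueError(
            f"peptide {peptide.sequence} ({start}-{end}) exceeds protein "
            f"length {len(protein_sequence)}"
        )
    if protein_sequence[start - 1 : end] != peptide.sequence:
        raise ValueError(
            f"peptide sequence {peptide.sequence} does not match protein at "
            f"{start}-{end}"
        )
    if start > 1 and peptide.aa_before not in (TERMINUS, ""):
        if peptide.aa_before != protein_sequence[start - 2]:
            raise ValueError(
                f"aa_before {peptide.aa_before!r} mismatches sequence residue "
                f"{protein_sequence[start - 2]!r} at position {start - 1}"
            )
    if end < len(protein_sequence) and peptide.aa_after not in (TERMINUS, ""):
        if peptide.aa_after != protein_sequence[end]:
            raise ValueError(
                f"aa_after {peptide.aa_after!r} mismatches sequence residue "
                f"{protein_sequence[end]!r} at position {end + 1}"
            )

    def tryptic_cut(prev_residue: str, next_residue: str | None) -> bool:
        if prev_residue not in ("K", "R"):
            return False
        if not cut_before_proline and next_residue == "P":
            return False
        return True

    if start == 1:
        n_tryptic = True
    else:
        n_tryptic = tryptic_cut(protein_sequence[start - 2], peptide.sequence[0])
    if end == len(protein_sequence):
        c_tryptic = True
    else:
        c_tryptic = tryptic_cut(peptide.sequence[-1], protein_sequence[end])

    n_flags = int(n_tryptic) + int(c_tryptic)
    specificity = {2: "tryptic", 1: "semi_tryptic", 0: "non_tryptic"}[n_flags]
    nominated = None
    if specificity == "semi_tryptic":
        nominated = start - 1 if not n_tryptic else end
    return CleavageCall(
        peptide=peptide,
        n_term_tryptic=n_tryptic,
        c_term_tryptic=c_tryptic,
        specificity=specificity,
        nominated_cleavage_position=nominated,
    )
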