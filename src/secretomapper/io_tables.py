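"""Readers and writers for the tabular formats the pipeline consumes.

Two protein-group dialects are supported:

``maxquant``
    MaxQuant ``proteinGroups.txt``-style: intensities in ``LFQ intensity
    <sample>`` columns, decoys flagged in ``Reverse``, contaminants in
    ``Potential contaminant``, site-only identifications in ``Only identified
    by site`` (all flagged with ``+``).  Zero intensities mean "not
    quantified" and become missing.

``plain``
    A header row of ``protein_id`` plus one column per sample id; empty
    cells, ``NaN`` text, or 0 mean missing.

All other inputs (peptides, annotations, interactions, disease associations)
are plain TSVs with documented schemas; FASTA is read/written with Biopython.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AnnotationRecord,
    DiseaseAssociation,
    IntensityTable,
    InteractionTable,
    PeptideRecord,
    Sample,
    SampleDesign,
    TopologySegment,
)

logger = logging.getLogger(__name__)

MAXQUANT_ID_COLUMNS = ("Majority protein IDs", "Protein IDs", "protein_id")
MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


@dataclass
class LoadReport:
    """Bookkeeping of a protein-group ingestion."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: dict = field(default_factory=dict)  # reason -> count

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> SampleDesign:
    """Read a YAML (or TOML) mapping ``sample_id -> {group, replicate}``."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        raw = tomllib.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: design file must map sample_id to group/replicate")
    samples = [
        Sample(sample_id=str(sid), group=str(spec["group"]), replicate=int(spec["replicate"]))
        for sid, spec in raw.items()
    ]
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str | Path) -> None:
    raw = {
        s.sample_id: {"group": s.group, "replicate": s.replicate}
        for s in design.samples
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# protein groups
# ---------------------------------------------------------------------------

def _first_accession(group_id: str) -> str:
    """Primary accession of a semicolon-joined protein-group id."""
    return group_id.split(";")[0].strip()


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    dialect: str = "plain",
) -> IntensityTable:
    """Read a protein-group LFQ table and bind it to ``design``.

    Returns a raw-scale :class:`IntensityTable`; zeros and empty cells become
    missing.  In the ``maxquant`` dialect, decoy / contaminant / site-only
    rows are dropped.  The load report is emitted to the module logger and
    attached to the returned table as ``table.load_report``.
    """
    if dialect not in ("plain", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    report = LoadReport(rows_read=len(df))

    id_col = next((c for c in MAXQUANT_ID_COLUMNS if c in df.columns), None)
    if id_col is None:
        raise ValueError(
            f"{path}: no protein identifier column (expected one of "
            f"{MAXQUANT_ID_COLUMNS})"
        )

    if dialect == "maxquant":
        for flag in MAXQUANT_FLAG_COLUMNS:
            if flag in df.columns:
                mask = df[flag].fillna("").str.strip() == "+"
                if mask.any():
                    report.drop(flag, int(mask.sum()))
                    df = df[~mask]
        col_for = {s: f"LFQ intensity {s}" for s in design.sample_ids}
    else:
        col_for = {s: s for s in design.sample_ids}

    missing_cols = [c for s, c in col_for.items() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing sample column(s) {missing_cols}")

    group_ids = df[id_col].astype(str)
    accessions = group_ids.map(_first_accession)
    if accessions.duplicated().any():
        dup = sorted(accessions[accessions.duplicated()].unique())
        raise ValueError(f"{path}: duplicate protein ids {dup}")

    values = (
        df[[col_for[s] for s in design.sample_ids]]
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
    )
    n_zero = int(np.nansum(values == 0))
    values[values == 0] = np.nan  # zero on raw scale means "not quantified"

    data = pd.DataFrame(values, index=pd.Index(accessions, name="protein_id"),
                        columns=design.sample_ids)
    report.rows_kept = len(data)
    logger.info(
        "read %s: %d rows read, %d kept, dropped per reason %s, %d zeros -> missing",
        path, report.rows_read, report.rows_kept, report.dropped or "{}", n_zero,
    )
    table = IntensityTable(
        data,
        design,
        scale="raw",
        protein_groups=dict(zip(accessions, group_ids)),
    )
    table.load_report = report
    return table


def write_protein_groups(table: IntensityTable, path: str | Path) -> None:
    """Write the plain dialect (missing as empty cells) losslessly."""
    out = table.data.copy()
    out.insert(0, "protein_id", table.protein_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

PEPTIDE_COLUMNS = ("protein_id", "sequence", "start", "end", "aa_before", "aa_after")


def read_peptides(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide TSV; invalid rows are rejected with counted warnings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing peptide column(s) {missing}")
    records: list[PeptideRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                PeptideRecord(
                    protein_id=row.protein_id,
                    sequence=row.sequence,
                    start=int(row.start),
                    end=int(row.end),
                    aa_before=row.aa_before,
                    aa_after=row.aa_after,
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected peptide row (%s)", path, exc)
    if n_rejected:
        logger.warning("%s: rejected %d invalid peptide rows", path, n_rejected)
    return records


def write_peptides(records: list[PeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.protein_id, r.sequence, r.start, r.end, r.aa_before, r.aa_after)
            for r in records
        ],
        columns=PEPTIDE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_topology(text: str) -> tuple[TopologySegment, ...]:
    """Parse ``kind:start-end`` segments joined by ``;`` (empty -> none)."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return ()
    segments = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        kind, span = part.split(":")
        start, end = span.split("-")
        segments.append(TopologySegment(kind=kind.strip(), start=int(start), end=int(end)))
    return tuple(segments)


def _format_topology(segments) -> str:
    return ";".join(f"{s.kind}:{s.start}-{s.end}" for s in segments)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV (protein_id, keywords, topology, sequence_length).

    Keywords are ``;``-separated; unknown keywords are preserved as opaque
    tags.  Records violating topology invariants (overlap, out-of-bounds,
    single-pass with != 1 TM segment) are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "keywords", "topology", "sequence_length"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing annotation column {col!r}")
    records: list[AnnotationRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        kw_text = "" if pd.isna(row.keywords) else str(row.keywords)
        keywords = {k.strip() for k in kw_text.split(";") if k.strip()}
        try:
            records.append(
                AnnotationRecord(
                    protein_id=row.protein_id,
                    keywords=keywords,
                    topology=_parse_topology(row.topology),
                    sequence_length=int(row.sequence_length),
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected annotation row (%s)", path, exc)
    if n_rejected:
        logger.warning("%s: rejected %d invalid annotation rows", path, n_rejected)
    return records


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                r.protein_id,
                ";".join(sorted(r.keywords | r.extra_tags)),
                _format_topology(r.topology),
                r.sequence_length,
            )
            for r in records
        ],
        columns=["protein_id", "keywords", "topology", "sequence_length"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interactions / disease
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path) -> InteractionTable:
    """Read binary interaction pairs; self-pairs dropped, (b,a) of an
    existing (a,b) de-duplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing interaction column {col!r}")
    table = InteractionTable()
    n_skipped = 0
    for row in df.itertuples(index=False):
        source = getattr(row, "source", "")
        if not table.add(row.protein_a, row.protein_b, "" if pd.isna(source) else source):
            n_skipped += 1
    if n_skipped:
        logger.info("%s: skipped %d duplicate/self pairs", path, n_skipped)
    return table


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    pd.DataFrame(list(table), columns=["protein_a", "protein_b", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_disease(path: str | Path) -> list[DiseaseAssociation]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "disease": str})
    for col in ("protein_id", "disease", "evidence_index"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing disease column {col!r}")
    records: list[DiseaseAssociation] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                DiseaseAssociation(
                    protein_id=row.protein_id,
                    disease=row.disease,
                    evidence_index=float(row.evidence_index),
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected disease row (%s)", path, exc)
    if n_rejected:
        logger.warning("%s: rejected %d invalid disease rows", path, n_rejected)
    return records


def write_disease(records: list[DiseaseAssociation], path: str | Path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.disease, r.evidence_index) for r in records],
        columns=["protein_id", "disease", "evidence_index"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
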