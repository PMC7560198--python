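"""Core value types shared across the pipeline.

The central container is :class:`IntensityTable`, a protein-by-sample matrix
of label-free quantification (LFQ) intensities with an explicit missing state
(NaN) and a bound experimental design.  Detection ("was this protein quantified
in this sample at all?") is tracked separately from the numeric values so that
missing-value imputation never contaminates replicate-presence bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "SampleDesign",
    "IntensityTable",
    "TopologySegment",
    "AnnotationRecord",
    "PeptideRecord",
    "InteractionTable",
    "DiseaseAssociation",
    "ParameterSet",
]

#: Region kinds a membrane-topology segment may carry.
SEGMENT_KINDS = ("extracellular", "transmembrane", "intracellular", "signal_peptide")

#: Annotation keywords the classifier understands; anything else is carried
#: through as an opaque tag but never used for classification.
KNOWN_KEYWORDS = frozenset(
    {
        "secreted",
        "membrane",
        "transmembrane_single_pass",
        "gpi_anchor",
        "glycoprotein",
        "cytoplasm",
        "nucleus",
        "extracellular_matrix",
    }
)

#: Marker accepted in peptide tables for "this terminus is the protein terminus".
TERMINUS = "-"


@dataclass(frozen=True)
class Sample:
    """One measured sample: a cell type (or condition) and a replicate number."""

    sample_id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


class SampleDesign:
    """An ordered collection of samples with unique ids.

    Replicate numbers must be unique within each group; every group has at
    least one replicate by construction.
    """

    def __init__(self, samples: Iterable[Sample]):
        self.samples: tuple[Sample, ...] = tuple(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        seen: dict[tuple[str, int], str] = {}
        for s in self.samples:
            key = (s.group, s.replicate)
            if key in seen:
                raise ValueError(
                    f"replicate {s.replicate} duplicated in group {s.group!r} "
                    f"({seen[key]} vs {s.sample_id})"
                )
            seen[key] = s.sample_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        """Group names in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.group not in out:
                out.append(s.group)
        return out

    def columns_for(self, group: str) -> list[str]:
        cols = [s.sample_id for s in self.samples if s.group == group]
        if not cols:
            raise KeyError(f"unknown group {group!r}; groups are {self.groups}")
        return cols

    def n_replicates(self, group: str) -> int:
        return len(self.columns_for(group))

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleDesign) and self.samples == other.samples

    def __repr__(self) -> str:
        per = {g: self.n_replicates(g) for g in self.groups}
        return f"SampleDesign({per})"


VALID_SCALES = ("raw", "log2", "log10")


class IntensityTable:
    """Protein-by-sample intensity matrix with explicit missingness.

    Parameters
    ----------
    data:
        DataFrame indexed by protein accession, one column per sample in
        ``design`` (same order).  NaN encodes missing.  On the raw scale all
        present values must be strictly positive.
    design:
        The sample design binding columns to (group, replicate).
    scale:
        One of ``raw``, ``log2``, ``log10``.  Scale changes only through the
        explicit transforms in :mod:`secretomapper.preprocess`.
    detected:
        Boolean mask of the *original* detection state, same shape as
        ``data``.  Defaults to ``data.notna()``.  Imputation fills NaNs in
        ``data`` but leaves this mask untouched, so downstream replicate
        counts always refer to genuinely quantified values.
    protein_groups:
        Optional mapping accession -> full semicolon-joined protein-group id
        string, preserved from ingestion.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: SampleDesign,
        scale: str = "raw",
        detected: pd.DataFrame | None = None,
        protein_groups: dict[str, str] | None = None,
    ):
        if scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {scale!r}")
        if list(data.columns) != design.sample_ids:
            raise ValueError(
                "data columns must match design sample_ids in order; "
                f"got {list(data.columns)} vs {design.sample_ids}"
            )
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dup}")
        values = data.to_numpy(dtype=float)
        if scale == "raw" and np.any(values[np.isfinite(values)] <= 0):
            raise ValueError("raw-scale table contains non-positive present values")
        self.data = data.astype(float)
        self.design = design
        self.scale = scale
        if detected is None:
            detected = self.data.notna()
        else:
            if detected.shape != data.shape:
                raise ValueError("detected mask shape mismatch")
            detected = detected.astype(bool)
            detected.index = data.index
            detected.columns = data.columns
        self.detected = detected
        self.protein_groups = dict(protein_groups or {})

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    def group_data(self, group: str) -> pd.DataFrame:
        return self.data[self.design.columns_for(group)]

    def subset(self, protein_ids: Sequence[str]) -> "IntensityTable":
        """Row-subset preserving order of ``protein_ids``."""
        return IntensityTable(
            self.data.loc[list(protein_ids)],
            self.design,
            scale=self.scale,
            detected=self.detected.loc[list(protein_ids)],
            protein_groups={
                p: self.protein_groups[p]
                for p in protein_ids
                if p in self.protein_groups
            },
        )

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "IntensityTable":
        return IntensityTable(
            data,
            self.design,
            scale=self.scale if scale is None else scale,
            detected=self.detected,
            protein_groups=self.protein_groups,
        )

    def __repr__(self) -> str:
        miss = int(self.data.isna().to_numpy().sum())
        return (
            f"IntensityTable({self.n_proteins} proteins x {len(self.design)} samples, "
            f"scale={self.scale}, missing={miss})"
        )


@dataclass(frozen=True)
class TopologySegment:
    """A membrane-topology segment in 1-based inclusive residue coordinates."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment bounds {self.start}-{self.end}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class AnnotationRecord:
    """UniProt-style keyword and topology annotation for one protein."""

    protein_id: str
    keywords: frozenset = field(default_factory=frozenset)
    topology: tuple = ()
    sequence_length: int = 0
    extra_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.keywords = frozenset(self.keywords)
        self.extra_tags = frozenset(self.extra_tags)
        unknown = self.keywords - KNOWN_KEYWORDS
        if unknown:
            # unknown keywords are preserved but never classified on
            self.extra_tags = self.extra_tags | unknown
            self.keywords = self.keywords & KNOWN_KEYWORDS
        segs = tuple(sorted(self.topology, key=lambda s: s.start))
        for seg in segs:
            if self.sequence_length and seg.end > self.sequence_length:
                raise ValueError(
                    f"{self.protein_id}: segment {seg.kind} {seg.start}-{seg.end} "
                    f"exceeds sequence length {self.sequence_length}"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.protein_id}: overlapping topology segments "
                    f"{a.kind} {a.start}-{a.end} / {b.kind} {b.start}-{b.end}"
                )
        self.topology = segs
        n_tm = sum(1 for s in segs if s.kind == "transmembrane")
        if "transmembrane_single_pass" in self.keywords and n_tm != 1:
            raise ValueError(
                f"{self.protein_id}: transmembrane_single_pass requires exactly "
                f"one TM segment, found {n_tm}"
            )

    def segments(self, kind: str) -> list[TopologySegment]:
        return [s for s in self.topology if s.kind == kind]


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide located in its parent protein (1-based inclusive)."""

    protein_id: str
    sequence: str
    start: int
    end: int
    aa_before: str = TERMINUS
    aa_after: str = TERMINUS

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.protein_id} {self.sequence}: span {self.start}-{self.end} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class InteractionTable:
    """Unordered, de-duplicated binary protein-protein interaction pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str, str]] = ()):
        # canonical key: sorted accession pair; first source tag wins
        self._pairs: dict[tuple[str, str], str] = {}
        for a, b, source in pairs:
            self.add(a, b, source)

    def add(self, a: str, b: str, source: str = "") -> bool:
        """Add a pair; returns False (and ignores) self-pairs and duplicates."""
        if a == b:
            return False
        key = (a, b) if a <= b else (b, a)
        if key in self._pairs:
            return False
        self._pairs[key] = source
        return True

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        key = (a, b) if a <= b else (b, a)
        return key in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        for (a, b), source in self._pairs.items():
            yield a, b, source

    def partners(self, protein_id: str) -> list[tuple[str, str]]:
        """(partner, source) tuples for every pair containing ``protein_id``."""
        out = []
        for (a, b), source in self._pairs.items():
            if a == protein_id:
                out.append((b, source))
            elif b == protein_id:
                out.append((a, source))
        return out


@dataclass(frozen=True)
class DiseaseAssociation:
    """A gene-disease association with a curation evidence index in [0, 1]."""

    protein_id: str
    disease: str
    evidence_index: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.evidence_index <= 1.0):
            raise ValueError(
                f"evidence_index must lie in [0, 1], got {self.evidence_index}"
            )


@dataclass(frozen=True)
class ParameterSet:
    """All analysis thresholds in one place.

    Defaults reproduce the workflow's standard operating point: proteins must
    be quantified in >= 5 of 6 replicates of some cell type; imputation draws
    from a Gaussian down-shifted by 1.8 column SDs with width 0.3 SDs;
    cell-type specificity requires five-fold enrichment over every other cell
    type (2.5-fold for lysate expression specificity); differential abundance
    requires Bonferroni p < 0.05 and |log2 FC| >= 2; the permutation volcano
    uses s0 = 0.1 at FDR 0.05; disease associations need evidence index >= 0.9.
    """

    min_detected: int = 5
    n_replicates: int = 6
    impute_shift: float = 1.8
    impute_width: float = 0.3
    fold_specific: float = 5.0
    fold_lysate: float = 2.5
    da_log2fc_min: float = 2.0
    alpha: float = 0.05
    s0: float = 0.1
    n_perm: int = 250
    ei_min: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_detected <= self.n_replicates):
            raise ValueError("require 0 < min_detected <= n_replicates")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be > 0")
        for name in ("fold_specific", "fold_lysate"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")

    def updated(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)
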