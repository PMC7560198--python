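"""Dynamic-range quartile binning and fluid-to-cell-type origin mapping.

A body-fluid or tissue secretome (e.g. cerebrospinal fluid, cultured brain
slices) is a mixture of the secretomes of its constituent cell types.  Given
a cell-type-resolved secretome resource, each fluid protein can be mapped to
candidate cell types of origin by membership: the cell types whose secretome
robustly contains the protein, refined by the cell-type-specific secretion
call where one exists.  Fluid proteins are ranked by abundance and split
into quartiles (1st = most abundant 25%) so that the composition can be read
along the dynamic range.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import AnnotationRecord, DiseaseAssociation, IntensityTable

logger = logging.getLogger(__name__)

__all__ = ["quartile_bin", "assign_origin", "join_disease"]


def quartile_bin(
    fluid_table: IntensityTable,
    min_detected: int | None = None,
) -> pd.Series:
    """Abundance quartile (1..4) per fluid protein.

    Abundance is the mean log10 intensity over *present* values (no
    imputation enters the ranking).  If ``min_detected`` is given, proteins
    below that replicate count (over all samples) are dropped first.
    Proteins are ranked descending; bin sizes differ by at most one, with
    earlier (more abundant) bins taking the remainder; ties are broken by
    accession so the binning is deterministic.
    """
    if fluid_table.scale != "raw":
        raise ValueError("quartile_bin expects a raw-scale fluid table")
    data = fluid_table.data
    detected = fluid_table.detected
    if min_detected is not None:
        keep = detected.sum(axis=1) >= min_detected
        data = data[keep]
    if data.empty:
        raise ValueError("no proteins pass the fluid replication filter")
    abundance = np.log10(data).mean(axis=1, skipna=True)

    n = len(abundance)
    order = sorted(abundance.index, key=lambda p: (-abundance[p], p))
    if n < 4:
        logger.warning("only %d proteins; single quartile bin", n)
        return pd.Series(1, index=pd.Index(order, name="protein_id"), name="quartile")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    bins = np.repeat(np.arange(1, 5), sizes)
    return pd.Series(bins, index=pd.Index(order, name="protein_id"), name="quartile")


def assign_origin(
    fluid_quartiles: pd.Series,
    resource_counts: pd.DataFrame,
    cts_calls: pd.DataFrame,
    annotations: list[AnnotationRecord] | None = None,
    min_detected: int = 5,
    glyco_only: bool = False,
) -> pd.DataFrame:
    """Map fluid proteins to candidate cell types of origin.

    Parameters
    ----------
    fluid_quartiles:
        Output of :func:`quartile_bin`.
    resource_counts:
        Detection counts of the cell-type secretome resource.
    cts_calls:
        Specificity calls on the resource (``specific_group`` column).
    annotations, glyco_only:
        With ``glyco_only=True``, restrict the fluid set to proteins with a
        glycoprotein keyword before mapping.

    Returns one row per fluid protein: ``quartile``, ``in_resource``,
    ``source_groups`` (cell types whose secretome holds the protein in
    >= ``min_detected`` replicates), ``cts_group`` (or None).  Per-quartile
    composition percentages (a protein counts toward every source group, so
    bars may exceed 100%) are in ``attrs["composition"]``; the
    cell-type-specific proteins per quartile in ``attrs["cts_per_quartile"]``.
    """
    fluid_ids = list(fluid_quartiles.index)
    if glyco_only:
        if annotations is None:
            raise ValueError("glyco_only requires annotations")
        glyco = {a.protein_id for a in annotations if "glycoprotein" in a.keywords}
        fluid_ids = [p for p in fluid_ids if p in glyco]
    groups = list(resource_counts.columns)

    rows = []
    for pid in fluid_ids:
        in_resource = pid in resource_counts.index
        if in_resource:
            c = resource_counts.loc[pid]
            sources = tuple(g for g in groups if c[g] >= min_detected)
        else:
            sources = ()
        cts = None
        if pid in cts_calls.index:
            cts = cts_calls.loc[pid, "specific_group"]
            if cts is not None and cts not in sources:
                # a specificity call requires >= min_detected in its group,
                # so this only triggers on inconsistent inputs
                logger.warning("CTS group %s of %s not among source groups", cts, pid)
        rows.append((pid, int(fluid_quartiles[pid]), in_resource, sources, cts))

    result = pd.DataFrame(
        rows,
        columns=["protein_id", "quartile", "in_resource", "source_groups", "cts_group"],
    ).set_index("protein_id")

    composition: dict[int, dict[str, float]] = {}
    cts_per_quartile: dict[int, dict[str, list[str]]] = {}
    for q, sub in result.groupby("quartile"):
        nq = len(sub)
        composition[int(q)] = {
            g: 100.0 * sum(g in s for s in sub["source_groups"]) / nq for g in groups
        }
        cts_per_quartile[int(q)] = {
            g: sorted(sub.index[sub["cts_group"] == g]) for g in groups
        }
    result.attrs["composition"] = composition
    result.attrs["cts_per_quartile"] = cts_per_quartile
    result.attrs["in_resource_fraction"] = (
        float(result["in_resource"].mean()) if len(result) else math.nan
    )
    return result


def join_disease(
    origin: pd.DataFrame,
    disease: list[DiseaseAssociation],
    ei_min: float = 0.9,
    resource_log2_means: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join curated gene-disease associations onto the origin map.

    Associations with evidence index < ``ei_min`` are dropped.  When
    ``resource_log2_means`` is supplied, each retained row carries the
    protein's relative secretion level per cell type (linear scale, group
    mean divided by the maximum group mean).
    """
    rows = []
    for assoc in disease:
        if assoc.evidence_index < ei_min:
            continue
        if assoc.protein_id not in origin.index:
            continue
        row = {
            "protein_id": assoc.protein_id,
            "disease": assoc.disease,
            "evidence_index": assoc.evidence_index,
            "quartile": int(origin.loc[assoc.protein_id, "quartile"]),
            "cts_group": origin.loc[assoc.protein_id, "cts_group"],
        }
        if (
            resource_log2_means is not None
            and assoc.protein_id in resource_log2_means.index
        ):
            means = resource_log2_means.loc[assoc.protein_id]
            rel = 2.0 ** (means - means.max())
            for g in resource_log2_means.columns:
                row[f"rel_{g}"] = float(rel[g])
        rows.append(row)
    return pd.DataFrame(rows)
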