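"""CNE retention filters and gene association.

Candidate conserved blocks are post-filtered into the analysis set: coding
reference positions are subtracted (splitting a block when the mask
bisects it), and a surviving piece is retained only if its ungapped
reference length is strictly greater than ``min_cne_length`` (the
published "more than 30 bp") and at least ``min_limbed_species`` limbed
species are present (>= 1 non-gap, non-N column — the weakest sensible
reading of "existing").  Retained elements are then linked to every gene
whose TSS lies within ``gene_link_distance`` (1 Mb) of the element on the
same chromosome, distance measured from the nearest element edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestors import encode
from .datamodel import CNEAlignment, DetectionConfig, Species, ValidationError
from .intervals import IntervalSet

logger = logging.getLogger("limbloss")


@dataclass(frozen=True)
class CNEGeneLink:
    cne_id: str
    gene_id: str
    distance: int


def _ref_position_columns(aln: CNEAlignment) -> np.ndarray:
    """Column index of each ungapped reference position (len == end-start)."""
    if aln.ref_species not in aln.sequences:
        raise ValidationError(f"{aln.cne_id}: reference species missing")
    codes = encode(aln.sequences[aln.ref_species])
    return np.nonzero(codes != 4)[0]


def _slice_alignment(
    aln: CNEAlignment, new_id: str, ref_lo: int, ref_hi: int, cols: np.ndarray
) -> CNEAlignment:
    """Sub-element covering reference positions [ref_lo, ref_hi)."""
    c0 = cols[ref_lo - aln.start]
    c1 = cols[ref_hi - 1 - aln.start] + 1
    return CNEAlignment(
        cne_id=new_id, chrom=aln.chrom, start=ref_lo, end=ref_hi,
        ref_species=aln.ref_species,
        sequences={n: s[c0:c1] for n, s in aln.sequences.items()},
        ancestors={n: s[c0:c1] for n, s in aln.ancestors.items()},
    )


def _limbed_present(aln: CNEAlignment, limbed: set[str]) -> int:
    n = 0
    for name in aln.sequences:
        if name in limbed:
            codes = encode(aln.sequences[name])
            if (codes < 4).any():
                n += 1
    return n


def filter_cnes(
    blocks: list[CNEAlignment],
    coding_mask: IntervalSet,
    species: list[Species],
    cfg: DetectionConfig,
) -> tuple[list[CNEAlignment], pd.DataFrame]:
    """Apply the retention filters; return (retained, rejection log).

    The rejection log has one row per discarded piece with the rule that
    failed (``coding_overlap``, ``too_short`` or ``too_few_limbed``).
    Blocks on chromosomes absent from the mask are retained with a
    warning.  Filtering is idempotent: a retained set passes unchanged.
    """
    limbed = {s.name for s in species if not s.is_limbless}
    mask_chroms = coding_mask.chroms()
    retained: list[CNEAlignment] = []
    rejections: list[dict] = []

    for aln in blocks:
        aln.validate()
        if aln.chrom not in mask_chroms and len(coding_mask) > 0:
            logger.warning(
                "%s: chromosome %s absent from coding mask", aln.cne_id, aln.chrom
            )
        pieces = coding_mask.subtract_from(aln.chrom, aln.start, aln.end)
        if not pieces:
            rejections.append(dict(cne_id=aln.cne_id, rule="coding_overlap",
                                   detail="entirely coding"))
            continue
        cols = _ref_position_columns(aln)
        split = len(pieces) > 1 or pieces[0] != (aln.start, aln.end)
        for j, (lo, hi) in enumerate(pieces):
            if len(pieces) > 1:
                pid = f"{aln.cne_id}.{j + 1}"
            else:
                pid = aln.cne_id
            piece = (
                aln if not split else _slice_alignment(aln, pid, lo, hi, cols)
            )
            length = hi - lo
            if length <= cfg.min_cne_length:
                rejections.append(dict(cne_id=pid, rule="too_short",
                                       detail=f"{length} bp"))
                continue
            n_limbed = _limbed_present(piece, limbed)
            if n_limbed < cfg.min_limbed_species:
                rejections.append(dict(cne_id=pid, rule="too_few_limbed",
                                       detail=f"{n_limbed} limbed species"))
                continue
            retained.append(piece)

    log = pd.DataFrame(rejections, columns=["cne_id", "rule", "detail"])
    return retained, log


def associate_genes(
    cnes: list[CNEAlignment], tss_points: IntervalSet, cfg: DetectionConfig
) -> pd.DataFrame:
    """Link every (CNE, gene) pair within the TSS radius on one chromosome.

    Distance is from the nearest element edge to the TSS point, 0 when the
    TSS falls inside the element; the link requires
    ``distance <= gene_link_distance`` (the 1 Mb rule, inclusive).
    """
    tss_by_chrom = tss_points.by_chrom()
    rows = []
    for aln in sorted(cnes, key=lambda a: a.cne_id):
        for pt in tss_by_chrom.get(aln.chrom, []):
            p = pt.start
            if aln.start <= p < aln.end:
                d = 0
            elif p < aln.start:
                d = aln.start - p
            else:
                d = p - (aln.end - 1)
            if d <= cfg.gene_link_distance:
                rows.append(dict(cne_id=aln.cne_id, gene_id=pt.name, distance=d))
    return pd.DataFrame(rows, columns=["cne_id", "gene_id", "distance"])
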