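"""Annotation layers for CNEs and dCNEs.

Three independent annotations: enhancer-like activity from scored signal
tracks (active when a track interval with -log10 p strictly above 2
overlaps the element by >= 1 bp), with pleiotropy defined as activity in
at least two tissues; evolutionary origin dated as the divergence node of
the most distant outgroup genome retaining the element (no outgroup hit
means the element is tetrapod-specific); and a scan of protein
alignments for sites with convergent amino-acid changes in two limbless
lineages against a conserved limbed background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Species, ValidationError, lineages_of
from .intervals import IntervalSet

DEFAULT_ACTIVITY_THRESHOLD = 2.0  # -log10 signal p, strict ">"
DEFAULT_PLEIOTROPY_MIN = 2
TETRAPOD_ORIGIN = "tetrapod_ancestor"


# ---------------------------------------------------------------------------
# enhancer activity / pleiotropy
# ---------------------------------------------------------------------------

def enhancer_activity(
    cne_map: dict[str, tuple[str, int, int] | None],
    signal_tracks: dict[str, IntervalSet],
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Activity matrix: rows cne_id, one bool column per track, plus an
    ``unmapped`` flag for elements without target coordinates (their row
    is all-inactive)."""
    track_names = sorted(signal_tracks)
    rows = []
    for cne_id in sorted(cne_map):
        coords = cne_map[cne_id]
        row: dict = {"cne_id": cne_id, "unmapped": coords is None}
        for name in track_names:
            if coords is None:
                row[name] = False
            else:
                chrom, start, end = coords
                row[name] = signal_tracks[name].overlaps_any(
                    chrom, start, end, min_score=threshold
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=["cne_id", "unmapped"] + track_names)


def pleiotropy_summary(
    activity: pd.DataFrame, pleiotropy_min: int = DEFAULT_PLEIOTROPY_MIN
) -> tuple[pd.DataFrame, float]:
    """Per-element active-tissue counts and the cohort pleiotropic
    fraction among elements active somewhere."""
    tissue_cols = [c for c in activity.columns if c not in ("cne_id", "unmapped")]
    out = activity[["cne_id"]].copy()
    out["n_active_tissues"] = activity[tissue_cols].sum(axis=1).astype(int)
    out["pleiotropic"] = out["n_active_tissues"] >= pleiotropy_min
    active = out[out["n_active_tissues"] > 0]
    fraction = (
        float(active["pleiotropic"].mean()) if len(active) else float("nan")
    )
    return out, fraction


# ---------------------------------------------------------------------------
# evolutionary origin
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginAssignment:
    cne_id: str
    origin: str
    supporting_hits: tuple[str, ...]


def assign_origin(
    presence: pd.DataFrame,
    ladder: list[tuple[str, list[str]]],
    default_origin: str = TETRAPOD_ORIGIN,
) -> pd.DataFrame:
    """Date each element at the divergence node of its deepest
    hit-bearing outgroup.

    ``ladder`` orders clade labels from shallowest (closest to tetrapods)
    to deepest, each with its member outgroup species; ``presence`` is a
    boolean matrix indexed by cne_id with outgroup species columns.
    Elements with no hits at all get ``default_origin``.
    """
    depth_of: dict[str, int] = {}
    label_of_depth: dict[int, str] = {}
    for depth, (label, members) in enumerate(ladder):
        label_of_depth[depth] = label
        for sp in members:
            depth_of[sp] = depth
    unknown = [c for c in presence.columns if c not in depth_of]
    if unknown:
        raise ValidationError(f"outgroup species not on the ladder: {unknown}")
    rows = []
    for cne_id, row in presence.iterrows():
        hits = tuple(sp for sp in presence.columns if bool(row[sp]))
        if hits:
            deepest = max(depth_of[sp] for sp in hits)
            origin = label_of_depth[deepest]
        else:
            origin = default_origin
        rows.append(dict(cne_id=cne_id, origin=origin,
                         supporting_hits=",".join(hits)))
    return pd.DataFrame(rows, columns=["cne_id", "origin", "supporting_hits"])


# ---------------------------------------------------------------------------
# convergent amino-acid sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergentAASite:
    column: int
    limbed_consensus: str
    derived_residues: dict
    flank_conserved: int
    identical_derived: bool

    def __hash__(self) -> int:  # derived_residues is a dict
        return hash((self.column, self.limbed_consensus, self.flank_conserved))


def aa_convergence_scan(
    alignment: dict[str, str],
    species: list[Species],
    lineage_pair: tuple[str, str],
    flank: int = 5,
    min_flank_conserved: int = 7,
) -> list[ConvergentAASite]:
    """Columns with lineage-specific changes against a conserved limbed
    background.

    A site is reported when (a) every limbed species shares one residue,
    (b) in each lineage of ``lineage_pair`` every member carries a
    residue different from that consensus, and (c) at least
    ``min_flank_conserved`` of the 2 x ``flank`` flanking columns are
    fully conserved across limbed species.  A gap anywhere in the limbed
    rows disqualifies a column from being 'conserved'.  Columns within
    ``flank`` of an alignment edge are skipped.
    """
    members = lineages_of(species)
    for lin in lineage_pair:
        if lin not in members:
            raise ValidationError(f"unknown lineage {lin!r}")
        for sp in members[lin]:
            if sp not in alignment:
                raise ValidationError(f"{sp}: missing from the protein alignment")
    limbed = [s.name for s in species if not s.is_limbless and s.name in alignment]
    if not limbed:
        raise ValidationError("no limbed species in the alignment")
    ncol = len(next(iter(alignment.values())))
    for name, seq in alignment.items():
        if len(seq) != ncol:
            raise ValidationError(f"{name}: ragged protein alignment")

    limbed_mat = np.array([list(alignment[sp]) for sp in limbed])
    # a column is 'conserved' iff all limbed residues identical and none a gap
    conserved = np.array([
        len(set(limbed_mat[:, c])) == 1 and limbed_mat[0, c] not in "-X"
        for c in range(ncol)
    ])

    sites: list[ConvergentAASite] = []
    for c in range(flank, ncol - flank):
        if not conserved[c]:
            continue
        consensus = limbed_mat[0, c]
        derived: dict[str, str] = {}
        ok = True
        for lin in lineage_pair:
            residues = {alignment[sp][c] for sp in members[lin]}
            if len(residues) != 1:
                ok = False
                break
            res = residues.pop()
            if res == consensus or res in "-X":
                ok = False
                break
            derived[lin] = res
        if not ok:
            continue
        flank_cols = list(range(c - flank, c)) + list(range(c + 1, c + flank + 1))
        n_cons = int(conserved[flank_cols].sum())
        if n_cons < min_flank_conserved:
            continue
        sites.append(ConvergentAASite(
            column=c, limbed_consensus=consensus, derived_residues=derived,
            flank_conserved=n_cons,
            identical_derived=len(set(derived.values())) == 1,
        ))
    return sites
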