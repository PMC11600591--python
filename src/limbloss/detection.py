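"""The dCNE detector: sliding-window degeneration calls, lineage calls,
convergence classification and per-species degeneration rates.

A limbless species is called degenerated in an element when at least one
window fires under either criterion, windows being laid over the
*ungapped* positions of the reconstructed comparison ancestor (columns
where the ancestor is a gap carry no ancestral base and are skipped when
laying windows):

(i)  short windows (20 bp, 1 bp steps): >= 29 limbed species keep
     >= 18/20 matches to the ancestor while the focal species keeps
     <= 14/20;
(ii) long windows (50 bp): >= 29 limbed species keep >= 30/50 matches
     while the focal window is absent (fully gap/N).

Lineage-level calls then require the lineage minimum (3 snakes,
2 caecilians, 1 for single-species lineages); species without a record in
an element count as not degenerated, so assembly gaps cannot inflate
convergence.  Convergence class is set purely by the number of
degenerated lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd

from .ancestors import IdentityResult, encode, match_columns
from .datamodel import (
    CNEAlignment,
    DetectionConfig,
    Species,
    ValidationError,
    lineages_of,
)

CRITERION_SHORT = "short_identity"
CRITERION_LONG = "long_absence"


@dataclass(frozen=True)
class WindowEvidence:
    cne_id: str
    species: str
    criterion: str
    window_offset: int  # index into the ancestor's ungapped positions
    limbed_support: int
    focal_matches: IdentityResult


@dataclass
class DegenerationCall:
    cne_id: str
    species: str
    degenerated: bool
    evidence: list[WindowEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.degenerated != bool(self.evidence):
            raise ValidationError("degenerated flag must mirror the evidence list")


@dataclass(frozen=True)
class LineageCall:
    cne_id: str
    lineage: str
    n_species_degenerated: int
    degenerated: bool


@dataclass(frozen=True)
class ConvergenceRecord:
    cne_id: str
    degenerated_lineages: frozenset[str]
    klass: str

    @property
    def is_convergent(self) -> bool:
        return len(self.degenerated_lineages) >= 2


def _klass_of(n_lineages: int) -> str:
    if n_lineages == 0:
        return "none"
    if n_lineages == 1:
        return "lineage_specific"
    return f"convergent_{n_lineages}"


# ---------------------------------------------------------------------------
# per-species scanning
# ---------------------------------------------------------------------------

def _window_sums(row_stat: np.ndarray, w: int, step: int) -> np.ndarray:
    """Sliding sums of width w (per row) over the last axis."""
    cum = np.cumsum(row_stat, axis=-1, dtype=np.int32)
    pad = np.zeros(row_stat.shape[:-1] + (1,), dtype=np.int32)
    cum = np.concatenate([pad, cum], axis=-1)
    sums = cum[..., w:] - cum[..., :-w]
    return sums[..., ::step]


def scan_element(
    aln: CNEAlignment, species: list[Species], cfg: DetectionConfig
) -> dict[str, DegenerationCall]:
    """Degeneration call for every limbless species of one element."""
    anc_seq = aln.ancestors.get(cfg.comparison_node)
    if anc_seq is None:
        raise ValidationError(
            f"{aln.cne_id}: comparison node {cfg.comparison_node!r} has no "
            "sequence; run ancestral reconstruction first"
        )
    anc = encode(anc_seq)
    anc_cols = np.nonzero(anc != 4)[0]
    m = len(anc_cols)

    limbed = sorted(s.name for s in species if not s.is_limbless)
    limbless = sorted(s.name for s in species if s.is_limbless)
    present = [n for n in limbed + limbless if n in aln.sequences]
    row_of = {n: i for i, n in enumerate(present)}
    if present and m:
        mat = np.stack([encode(aln.sequences[n]) for n in present])[:, anc_cols]
        anc_sel = anc[anc_cols]
        matches = match_columns(mat, np.broadcast_to(anc_sel, mat.shape))
        gap_n = mat >= 4
    else:
        matches = np.zeros((len(present), 0), dtype=bool)
        gap_n = matches

    limbed_rows = [row_of[n] for n in limbed if n in row_of]

    calls: dict[str, DegenerationCall] = {}
    evidences: dict[str, list[WindowEvidence]] = {n: [] for n in limbless}

    for criterion, w, limbed_min in (
        (CRITERION_SHORT, cfg.window_short, cfg.limbed_conserved_min_short),
        (CRITERION_LONG, cfg.window_long, cfg.limbed_conserved_min_long),
    ):
        if m < w:
            continue
        S = _window_sums(matches, w, cfg.step)
        support = (S[limbed_rows] >= limbed_min).sum(axis=0)
        support_ok = support >= cfg.min_limbed_species
        if criterion == CRITERION_LONG:
            Gap = _window_sums(gap_n, w, cfg.step)
            absent_min = int(np.ceil(cfg.absent_fraction * w))
        for name in limbless:
            if name not in row_of:
                continue
            r = row_of[name]
            if criterion == CRITERION_SHORT:
                focal_ok = S[r] <= cfg.limbless_identity_max_short
            else:
                focal_ok = Gap[r] >= absent_min
            hits = np.nonzero(focal_ok & support_ok)[0]
            for o in hits:
                evidences[name].append(WindowEvidence(
                    cne_id=aln.cne_id, species=name, criterion=criterion,
                    window_offset=int(o) * cfg.step,
                    limbed_support=int(support[o]),
                    focal_matches=IdentityResult(
                        matches=int(S[r, o]), comparable_columns=w,
                        window_offset=int(o) * cfg.step,
                    ),
                ))

    for name in limbless:
        ev = evidences[name]
        calls[name] = DegenerationCall(
            cne_id=aln.cne_id, species=name, degenerated=bool(ev), evidence=ev
        )
    return calls


def scan_species(
    aln: CNEAlignment, focal: Species, species: list[Species], cfg: DetectionConfig
) -> DegenerationCall:
    """Call a single limbless species (thin wrapper over the element scan)."""
    if not focal.is_limbless:
        raise ValidationError(f"{focal.name} is limbed; scanning targets limbless species")
    return scan_element(aln, species, cfg)[focal.name]


def scan_set(
    alns: list[CNEAlignment], species: list[Species], cfg: DetectionConfig
) -> dict[tuple[str, str], DegenerationCall]:
    """Scan a whole element set; keys are (cne_id, species name)."""
    out: dict[tuple[str, str], DegenerationCall] = {}
    for aln in sorted(alns, key=lambda a: a.cne_id):
        for name, call in scan_element(aln, species, cfg).items():
            out[(aln.cne_id, name)] = call
    return out


# ---------------------------------------------------------------------------
# lineage calls / convergence / rates
# ---------------------------------------------------------------------------

def _is_degenerated(value) -> bool:
    """Accept DegenerationCall objects or plain booleans (reloaded TSVs)."""
    if value is None:
        return False
    if isinstance(value, DegenerationCall):
        return value.degenerated
    return bool(value)


def call_lineages(
    calls: dict[tuple[str, str], "DegenerationCall | bool"],
    species: list[Species],
    cfg: DetectionConfig,
) -> list[LineageCall]:
    members = lineages_of(species)
    cne_ids = sorted({cne for cne, _ in calls})
    out: list[LineageCall] = []
    for cne in cne_ids:
        for lineage in sorted(members):
            n = sum(
                1
                for sp in members[lineage]
                if _is_degenerated(calls.get((cne, sp)))
            )
            out.append(LineageCall(
                cne_id=cne, lineage=lineage, n_species_degenerated=n,
                degenerated=n >= cfg.lineage_minimum(lineage),
            ))
    return out


def classify_convergence(
    lineage_calls: list[LineageCall],
) -> tuple[list[ConvergenceRecord], dict]:
    """Convergence class per element plus summary counts.

    The summary holds per-class totals and per-lineage-combination counts
    (the UpSet-style table).
    """
    by_cne: dict[str, set[str]] = {}
    for lc in lineage_calls:
        by_cne.setdefault(lc.cne_id, set())
        if lc.degenerated:
            by_cne[lc.cne_id].add(lc.lineage)
    records = [
        ConvergenceRecord(cne, frozenset(lins), _klass_of(len(lins)))
        for cne, lins in sorted(by_cne.items())
    ]
    class_counts: dict[str, int] = {}
    combo_counts: dict[str, int] = {}
    for rec in records:
        class_counts[rec.klass] = class_counts.get(rec.klass, 0) + 1
        if rec.degenerated_lineages:
            key = "+".join(sorted(rec.degenerated_lineages))
            combo_counts[key] = combo_counts.get(key, 0) + 1
    summary = {
        "n_elements": len(records),
        "n_dcnes": sum(1 for r in records if r.degenerated_lineages),
        "n_convergent": sum(1 for r in records if r.is_convergent),
        "class_counts": dict(sorted(class_counts.items())),
        "combination_counts": dict(sorted(combo_counts.items())),
    }
    return records, summary


def lineage_pair_records(
    records: list[ConvergenceRecord], pair: tuple[str, str]
) -> list[ConvergenceRecord]:
    """Convergent records whose degenerated lineages include both of
    ``pair`` (the unit of the per-combination enrichment tests)."""
    a, b = pair
    return [r for r in records if a in r.degenerated_lineages
            and b in r.degenerated_lineages]


def all_lineage_pairs(species: list[Species]) -> list[tuple[str, str]]:
    return list(_combinations(sorted(lineages_of(species)), 2))


def convergence_rate(
    records: list[ConvergenceRecord],
    calls: dict[tuple[str, str], DegenerationCall],
    species: list[Species],
) -> pd.DataFrame:
    """Per-species rate of convergent dCNE accumulation (elements / Myr).

    A convergent element counts for species *s* when *s* itself is
    degenerated in it; the count is divided by that species' time since
    limb loss.
    """
    convergent = [r for r in records if r.is_convergent]
    rows = []
    for sp in sorted((s for s in species if s.is_limbless), key=lambda s: s.name):
        if not sp.time_since_limb_loss:
            raise ValidationError(f"{sp.name}: missing time since limb loss")
        n = sum(
            1
            for rec in convergent
            if _is_degenerated(calls.get((rec.cne_id, sp.name)))
        )
        rows.append(dict(
            species=sp.name, lineage=sp.lineage, n_convergent=n,
            time_since_limb_loss=sp.time_since_limb_loss,
            rate_per_myr=n / sp.time_since_limb_loss,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# identity profiles for the neutral contrast
# ---------------------------------------------------------------------------

def identity_profiles(
    records: list[ConvergenceRecord],
    alns: list[CNEAlignment],
    species: list[Species],
) -> pd.DataFrame:
    """Full-element identity of each limbless species vs its lineage
    ancestor, grouped for the neutral-evolution contrast.

    Groups: ``non_dcne`` (no degenerated lineage), ``convergent_dcne``
    (>= 2 lineages); lineage-specific elements are labelled
    ``lineage_specific`` and left for the caller to include or drop.
    """
    klass_by_cne = {r.cne_id: r.klass for r in records}
    group_of = {
        "none": "non_dcne",
        "lineage_specific": "lineage_specific",
    }
    rows = []
    for aln in sorted(alns, key=lambda a: a.cne_id):
        klass = klass_by_cne.get(aln.cne_id)
        if klass is None:
            continue
        group = group_of.get(klass, "convergent_dcne")
        for sp in sorted((s for s in species if s.is_limbless), key=lambda s: s.name):
            anc_label = f"{sp.lineage}_ancestor"
            anc_seq = aln.ancestors.get(anc_label)
            if anc_seq is None or sp.name not in aln.sequences:
                continue
            anc = encode(anc_seq)
            cols = np.nonzero(anc != 4)[0]
            if len(cols) == 0:
                continue
            seq = encode(aln.sequences[sp.name])[cols]
            ident = float(match_columns(seq, anc[cols]).sum()) / len(cols)
            rows.append(dict(
                cne_id=aln.cne_id, species=sp.name, lineage=sp.lineage,
                group=group, identity=ident,
            ))
    return pd.DataFrame(rows, columns=["cne_id", "species", "lineage",
                                       "group", "identity"])
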