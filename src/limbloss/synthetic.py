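"""Synthetic study data with known ground truth.

This module emulates the study design the pipeline targets: 31 limbed
tetrapods plus 12 limbless species in four independent limbless lineages
(4 caecilians with limb loss ~192 Mya, 6 snakes ~170 Mya, and two
single-species limbless-lizard lineages ~40 and ~35 Mya), conserved
noncoding elements evolving under a GTR chain at a small fraction of the
neutral rate, degeneration planted in chosen lineages (substitution bursts
to a target identity, or deletions rendered as gap runs), and all feature
fixtures (genes and TSSs, limb-gene subset, enhancer signal tracks,
ortholog intron/exon tables, outgroup presence matrices) with truth
tables for every downstream stage.

Study conditions fixed here (and documented in the methods note): neutral
substitution rate 0.002 subs/site/Myr for every species, CNE conservation
scale 0.02 of neutral (strongly conserved elements, ~98-99% identity to
the tetrapod root in limbed species), element lengths 60-400 bp, planted
burst target identity 0.5.  Same seed implies byte-identical output on any platform;
planted truth self-verifies before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import dendropy

from .datamodel import (
    CNEAlignment,
    Species,
    SpeciesTree,
    TETRAPOD_ANCESTOR,
    ValidationError,
    lineages_of,
)
from .gtr import GTRParams, JC, evolve, rate_matrix, sample_root, transition_matrix
from .ancestors import decode, encode, match_columns
from .intervals import Interval, IntervalSet
from .rng import fork_rng

DEFAULT_RATE = 0.002  # subs/site/Myr, applied to every species
DEFAULT_RATE_SCALE = 0.02  # CNE rate as a fraction of neutral
DEFAULT_LENGTH_RANGE = (60, 400)
DEFAULT_BURST_IDENTITY = 0.5

MODES = ("substitution_burst", "deletion", "none")


def lineage_ancestor_label(lineage: str) -> str:
    return f"{lineage}_ancestor"


# ---------------------------------------------------------------------------
# demo tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSpec:
    n: int
    loss_mya: float
    crown_age: float | None = None  # multi-species lineages only


DEFAULT_LINEAGES: dict[str, LineageSpec] = {
    "caecilian": LineageSpec(4, 192.0, 60.0),
    "snake": LineageSpec(6, 170.0, 90.0),
    "lizard_A": LineageSpec(1, 40.0),
    "lizard_B": LineageSpec(1, 35.0),
}


class _N:
    """Scratch node for newick assembly (age in Myr, leaves at age 0)."""

    def __init__(self, age: float, children: list, label: str | None = None):
        self.age, self.children, self.label = age, children, label

    def newick(self, parent_age: float | None = None) -> str:
        inner = ",".join(
            c.newick(self.age) if isinstance(c, _N) else _leaf_nwk(c, self.age)
            for c in self.children
        )
        lab = self.label or ""
        blen = "" if parent_age is None else f":{parent_age - self.age:.10f}"
        return f"({inner}){lab}{blen}"


def _leaf_nwk(name: str, parent_age: float) -> str:
    return f"{name}:{parent_age:.10f}"


def _ladder(names: list[str], crown_age: float, label: str | None = None) -> _N | str:
    """Pectinate clade over ``names`` with evenly spaced internal ages."""
    if len(names) == 1:
        return names[0]
    k = len(names)
    node: _N | str = names[-1]
    for i in range(k - 2, 0, -1):
        age = crown_age * (k - 1 - i) / (k - 1)
        node = _N(age, [names[i], node])
    return _N(crown_age, [names[0], node], label=label)


def build_demo_tree(
    n_limbed: int = 31,
    lineage_spec: dict[str, LineageSpec] | None = None,
    depth: float = 352.0,
    seed: int = 0,
    substitution_rate: float = DEFAULT_RATE,
) -> tuple[list[Species], SpeciesTree]:
    """Build the ultrametric demo phylogeny (ages in Myr) and manifest.

    Limbless lineages are monophyletic; the tetrapod root and every
    lineage ancestor carry node labels.  The caecilian lineage sits on the
    amphibian side, all other lineages in a squamate-like subtree; each
    single-species lineage is paired with a dedicated limbed partner so
    its labelled stem node exists.  ``seed`` is accepted for interface
    symmetry: the construction is fully deterministic.
    """
    spec = dict(lineage_spec if lineage_spec is not None else DEFAULT_LINEAGES)
    for name, ls in spec.items():
        if ls.n < 1:
            raise ValidationError(f"lineage {name!r}: species count must be >= 1")
        if ls.loss_mya <= 0 or ls.loss_mya >= depth:
            raise ValidationError(f"lineage {name!r}: loss time outside (0, depth)")
    singles = [name for name, ls in sorted(spec.items()) if ls.n == 1 and name != "caecilian"]
    n_partner = len(singles)
    n_amph = 5 if n_limbed >= 29 else max(2, n_limbed // 6)
    n_base = n_limbed - n_amph - n_partner
    if n_base < 2:
        raise ValidationError("n_limbed too small for the demo topology")

    leaves: dict[str, str] = {}  # leaf name -> lineage ("" for limbed)

    def _lineage_leaves(name: str, ls: LineageSpec) -> list[str]:
        out = [f"{name}_{i + 1}" for i in range(ls.n)]
        for leaf in out:
            leaves[leaf] = name
        return out

    amph_names = [f"amphibian_{i + 1}" for i in range(n_amph)]
    base_names = [f"amniote_{i + 1}" for i in range(n_base)]
    partner_names = [f"squamate_{i + 1}" for i in range(n_partner)]
    for leaf in amph_names + base_names + partner_names:
        leaves[leaf] = ""

    # amphibian side
    amph_children: list = [_ladder(amph_names, min(250.0, depth * 0.7))]
    if "caecilian" in spec:
        ls = spec["caecilian"]
        crown = ls.crown_age or 0.4 * ls.loss_mya
        clade = _ladder(
            _lineage_leaves("caecilian", ls), crown,
            label=lineage_ancestor_label("caecilian"),
        )
        if isinstance(clade, str):  # single caecilian: pair with an amphibian
            clade = _N(ls.loss_mya + 5, [clade, amph_names[0]],
                       label=lineage_ancestor_label("caecilian"))
            amph_children = [_ladder(amph_names[1:], min(250.0, depth * 0.7))]
        amph_children.insert(0, clade)
    amph = _N(min(330.0, depth - 5), amph_children)

    # amniote side: base ladder + squamate-like subtree of remaining lineages
    squam_members: list = []
    attach_age = 190.0
    multi = [n for n in sorted(spec) if n != "caecilian" and spec[n].n > 1]
    for name in multi:
        ls = spec[name]
        crown = ls.crown_age or 0.4 * ls.loss_mya
        squam_members.append(
            (_ladder(_lineage_leaves(name, ls), crown,
                     label=lineage_ancestor_label(name)), None)
        )
    for idx, name in enumerate(singles):
        ls = spec[name]
        leaf = _lineage_leaves(name, ls)[0]
        pair_age = min(ls.loss_mya + 5, attach_age - 20)
        squam_members.append(
            (_N(pair_age, [leaf, partner_names[idx]],
                label=lineage_ancestor_label(name)), None)
        )
    if squam_members:
        node, _ = squam_members[-1]
        age = 60.0 + 15.0 * len(squam_members)
        for child, _ in reversed(squam_members[:-1]):
            node = _N(age, [child, node])
            age += 15.0
        squam = node
        amni = _N(min(320.0, depth - 3), [_ladder(base_names, 300.0), squam])
    else:
        amni = _ladder(base_names, min(320.0, depth - 3))

    root = _N(depth, [amph, amni], label=TETRAPOD_ANCESTOR)
    newick = root.newick() + ";"

    species = []
    for leaf, lineage in leaves.items():
        if lineage:
            species.append(
                Species(leaf, "limbless", lineage=lineage,
                        time_since_limb_loss=spec[lineage].loss_mya,
                        substitution_rate=substitution_rate)
            )
        else:
            species.append(
                Species(leaf, "limbed", substitution_rate=substitution_rate)
            )
    species.sort(key=lambda s: s.name)
    tree = SpeciesTree.from_newick(newick, unit="Myr")
    tree.validate_against(species)
    return species, tree


# ---------------------------------------------------------------------------
# CNE simulation
# ---------------------------------------------------------------------------

def _branch_subs_lengths(
    tree: SpeciesTree, species: list[Species], rate_scale: float
) -> dict[int, float]:
    """Expected-substitution length per branch: Myr x mean leaf rate below
    x conservation scale.  Species without a rate use the tree-wide mean."""
    rate_by_name = {s.name: s.substitution_rate for s in species}
    mean_rate = tree.mean_rate(species)
    out: dict[int, float] = {}
    for node in tree.tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        rates = [
            rate_by_name.get(lf.taxon.label) or mean_rate
            for lf in node.leaf_iter()
        ]
        myr = node.edge.length or 0.0
        out[id(node)] = myr * (sum(rates) / len(rates)) * rate_scale
    return out


def simulate_cne_set(
    tree: SpeciesTree,
    species: list[Species],
    n_cnes: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    gtr: GTRParams = JC,
    rate_scale: float = DEFAULT_RATE_SCALE,
    seed: int = 0,
    chrom: str = "chrS",
    spacing: int = 2_500_000,
    ref_species: str | None = None,
) -> list[CNEAlignment]:
    """Simulate ungapped CNE alignments along one reference chromosome.

    The root sequence is drawn from the stationary frequencies; each
    branch evolves by the matrix exponential of the (normalised) GTR rate
    matrix at its expected-substitution length.  True sequences of every
    labelled internal node (tetrapod root, lineage ancestors) are retained
    in ``ancestors``.
    """
    lo, hi = length_range
    if lo < 10 or hi > 10_000 or lo > hi:
        raise ValidationError("length_range must lie within [10, 10000]")
    rng = fork_rng(seed, "simulate_cne_set")
    Q = rate_matrix(gtr)
    blens = _branch_subs_lengths(tree, species, rate_scale)
    pmats = {nid: transition_matrix(Q, d) for nid, d in blens.items()}
    if ref_species is None:
        limbed = [s.name for s in species if not s.is_limbless]
        ref_species = sorted(limbed)[0]

    alns: list[CNEAlignment] = []
    for i in range(n_cnes):
        length = int(rng.integers(lo, hi + 1))
        seqs: dict[int, np.ndarray] = {}
        root = tree.root
        seqs[id(root)] = sample_root(gtr, length, rng)
        leaves: dict[str, str] = {}
        ancestors: dict[str, str] = {}
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is not None:
                parent_seq = seqs[id(node.parent_node)]
                seqs[id(node)] = evolve(parent_seq, pmats[id(node)], rng)
            codes = seqs[id(node)]
            if node.is_leaf():
                leaves[node.taxon.label] = decode(codes)
            elif node.label:
                ancestors[node.label] = decode(codes)
        start = 1_000 + i * spacing
        aln = CNEAlignment(
            cne_id=f"CNE{i + 1:05d}", chrom=chrom, start=start,
            end=start + length, ref_species=ref_species,
            sequences=leaves, ancestors=ancestors,
        )
        aln.validate()
        alns.append(aln)
    return alns


# ---------------------------------------------------------------------------
# planting degeneration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """Request to degrade one element in one lineage (or explicit species)."""

    cne_id: str
    mode: str  # substitution_burst | deletion | none
    lineage: str | None = None
    species: tuple[str, ...] | None = None
    start: int | None = None  # element coordinates (== columns: no indels)
    end: int | None = None
    target_identity: float | None = None  # bursts only


@dataclass(frozen=True)
class PlantTruth:
    cne_id: str
    species: str
    lineage: str
    mode: str
    start: int
    end: int
    target_identity: float | None


MIN_DELETION_SPAN = 50


def plant_degeneration(
    cne_set: list[CNEAlignment],
    truth_spec: list[PlantSpec],
    species: list[Species],
    seed: int = 0,
    min_burst_span: int = 20,
) -> tuple[list[CNEAlignment], pd.DataFrame]:
    """Apply planted degeneration; return modified copies + truth table.

    Substitution bursts rewrite the affected window of each chosen species
    to an exact target identity against the true tetrapod-ancestor
    sequence; deletions replace >= 50 contiguous columns with gaps.
    Every plant is re-measured before being accepted.
    """
    rng = fork_rng(seed, "plant_degeneration")
    by_id = {a.cne_id: a for a in cne_set}
    lineage_members = lineages_of(species)
    species_lineage = {s.name: s.lineage for s in species if s.is_limbless}
    out = {
        a.cne_id: CNEAlignment(
            a.cne_id, a.chrom, a.start, a.end, a.ref_species,
            dict(a.sequences), dict(a.ancestors),
        )
        for a in cne_set
    }
    rows: list[PlantTruth] = []

    for ps in truth_spec:
        if ps.mode not in MODES:
            raise ValidationError(f"unknown plant mode {ps.mode!r}")
        if ps.cne_id not in by_id:
            raise ValidationError(f"unknown cne_id {ps.cne_id!r}")
        if ps.mode == "none":
            continue
        aln = out[ps.cne_id]
        ncol = aln.n_columns
        targets = (
            list(ps.species)
            if ps.species
            else lineage_members.get(ps.lineage or "", [])
        )
        if not targets:
            raise ValidationError(f"{ps.cne_id}: plant names no species")
        start = 0 if ps.start is None else ps.start
        end = ncol if ps.end is None else ps.end
        if not (0 <= start < end <= ncol):
            raise ValidationError(f"{ps.cne_id}: plant interval outside element")
        span = end - start
        root = aln.ancestors.get(TETRAPOD_ANCESTOR)
        if root is None:
            raise ValidationError(f"{ps.cne_id}: no true ancestor retained")
        root_codes = encode(root)

        if ps.mode == "substitution_burst":
            if span < min_burst_span:
                raise ValidationError(
                    f"{ps.cne_id}: burst window {span} < {min_burst_span} columns"
                )
            target = (
                DEFAULT_BURST_IDENTITY
                if ps.target_identity is None
                else ps.target_identity
            )
            if not (0 <= target <= 1):
                raise ValidationError("target identity must be in [0, 1]")
            n_match = int(round(target * span))
            for sp in targets:
                if sp not in aln.sequences:
                    continue
                window = root_codes[start:end].copy()
                mism = rng.choice(span, size=span - n_match, replace=False)
                shift = rng.integers(1, 4, size=len(mism))
                window[mism] = (window[mism] + shift) % 4
                codes = encode(aln.sequences[sp])
                codes[start:end] = window
                # self-verify the planted identity before accepting
                got = int(match_columns(codes[start:end], root_codes[start:end]).sum())
                if got != n_match:
                    raise AssertionError(
                        f"{ps.cne_id}/{sp}: planted {got} matches, wanted {n_match}"
                    )
                aln.sequences[sp] = decode(codes)
                rows.append(PlantTruth(
                    ps.cne_id, sp, species_lineage.get(sp, ""),
                    ps.mode, start, end, n_match / span,
                ))
        else:  # deletion
            if span < MIN_DELETION_SPAN:
                raise ValidationError(
                    f"{ps.cne_id}: deletion span {span} < {MIN_DELETION_SPAN}"
                )
            for sp in targets:
                if sp not in aln.sequences:
                    continue
                codes = encode(aln.sequences[sp])
                codes[start:end] = 4
                if not (codes[start:end] == 4).all():
                    raise AssertionError("deletion plant failed self-check")
                aln.sequences[sp] = decode(codes)
                rows.append(PlantTruth(
                    ps.cne_id, sp, species_lineage.get(sp, ""),
                    ps.mode, start, end, None,
                ))

    truth = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["cne_id", "species", "lineage", "mode", "start", "end",
                 "target_identity"],
    )
    return list(out.values()), truth


# ---------------------------------------------------------------------------
# cohort with planted lineage combinations
# ---------------------------------------------------------------------------

#: deterministic mix of planted lineage combinations (fractions of the
#: cohort); remainder of each lineage stays intact.
DEFAULT_COMBO_PLAN: list[tuple[tuple[str, ...], float]] = [
    ((), 0.40),
    (("caecilian",), 0.10),
    (("snake",), 0.10),
    (("lizard_A",), 0.05),
    (("lizard_B",), 0.05),
    (("caecilian", "snake"), 0.15),
    (("snake", "lizard_A"), 0.03),
    (("caecilian", "lizard_B"), 0.02),
    (("caecilian", "snake", "lizard_A"), 0.06),
    (("caecilian", "snake", "lizard_A", "lizard_B"), 0.04),
]

#: planted member species per lineage: one above the lineage minimum where
#: the lineage is large enough.
PLANT_COUNTS = {"caecilian": 3, "snake": 4}


def plan_cohort_combos(
    cne_ids: list[str], plan: list[tuple[tuple[str, ...], float]] | None = None
) -> dict[str, tuple[str, ...]]:
    """Assign a planted lineage combination to every element,
    deterministically and in the plan's stated proportions."""
    plan = plan if plan is not None else DEFAULT_COMBO_PLAN
    n = len(cne_ids)
    counts = [int(round(frac * n)) for _, frac in plan]
    while sum(counts) > n:
        counts[0] -= 1
    while sum(counts) < n:
        counts[0] += 1
    combos: dict[str, tuple[str, ...]] = {}
    i = 0
    for (combo, _), c in zip(plan, counts):
        for _ in range(c):
            combos[cne_ids[i]] = combo
            i += 1
    return combos


def make_validation_cohort(
    species: list[Species],
    tree: SpeciesTree,
    n_cnes: int = 500,
    seed: int = 0,
    deletion_every: int = 5,
    burst_identity: float = DEFAULT_BURST_IDENTITY,
) -> tuple[list[CNEAlignment], pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Simulate a cohort and plant degeneration per the default combo plan.

    Returns (alignments, truth table, cne_id -> planted lineage combo).
    Every planted lineage gets enough member species to clear its lineage
    minimum; every ``deletion_every``-th planted element uses a deletion,
    the rest whole-element substitution bursts.
    """
    alns = simulate_cne_set(tree, species, n_cnes, seed=seed)
    combos = plan_cohort_combos([a.cne_id for a in alns])
    lineage_members = lineages_of(species)
    specs: list[PlantSpec] = []
    k = 0
    for aln in alns:
        combo = combos[aln.cne_id]
        if not combo:
            continue
        k += 1
        use_deletion = (k % deletion_every == 0) and aln.n_columns >= 2 * MIN_DELETION_SPAN
        for lineage in combo:
            members = sorted(lineage_members[lineage])
            chosen = tuple(members[: PLANT_COUNTS.get(lineage, 1)])
            if use_deletion:
                span = min(aln.n_columns, 80)
                specs.append(PlantSpec(
                    aln.cne_id, "deletion", species=chosen, start=0, end=span,
                ))
            else:
                specs.append(PlantSpec(
                    aln.cne_id, "substitution_burst", species=chosen,
                    target_identity=burst_identity,
                ))
    planted, truth = plant_degeneration(alns, specs, species, seed=seed)
    return planted, truth, combos


# ---------------------------------------------------------------------------
# feature fixtures
# ---------------------------------------------------------------------------

OUTGROUP_LADDER: list[tuple[str, list[str]]] = [
    ("lungfish_tetrapod_ancestor", ["african_lungfish"]),
    ("sarcopterygian_ancestor", ["coelacanth"]),
    ("osteichthyan_ancestor", ["bichir", "spotted_gar", "bowfin", "zebrafish"]),
    ("gnathostome_ancestor", ["elephant_shark", "thorny_skate", "great_white_shark"]),
    ("vertebrate_ancestor", ["hagfish", "lamprey"]),
    ("chordate_ancestor", ["amphioxus"]),
]

ENHANCER_TISSUES = ["limb_E11_5", "limb_E12_5", "forebrain", "heart", "liver"]

FOCAL_ORTHOLOG_SPECIES = ["focal_lungfish", "focal_caecilian", "focal_axolotl"]
LIMITED_SET_SIZES = {"focal_lungfish": 127, "focal_caecilian": 323,
                     "focal_axolotl": 327}
N_SHARED_LIMITED = 49


@dataclass
class FixtureBundle:
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss, is_limb
    limb_genes: list[str]
    coding_mask: IntervalSet
    tracks: dict[str, IntervalSet]
    orthologs: pd.DataFrame  # gene_id, species, intron_len, exon_len
    limited_truth: dict[str, set[str]]  # focal species -> planted limited genes
    shared_limited: set[str]
    outgroup_presence: pd.DataFrame  # index cne_id, columns outgroup species
    origin_truth: pd.DataFrame  # cne_id, origin
    boundary_genes: dict[str, str] = field(default_factory=dict)


def _make_genes(
    alns: list[CNEAlignment],
    combos: dict[str, tuple[str, ...]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    rows = []
    limb_genes: list[str] = []
    boundary: dict[str, str] = {}
    gid = 0

    def _add(cne: CNEAlignment, offset: int, is_limb: bool, tag: str = "") -> str:
        nonlocal gid
        gid += 1
        gene_id = f"{'limbg' if is_limb else 'gene'}{gid:04d}"
        tss = max(0, cne.start + offset)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + 5_000
        else:
            start, end = max(0, tss - 5_000), tss + 1
        rows.append(dict(gene_id=gene_id, chrom=cne.chrom, start=start, end=end,
                         strand=strand, tss=tss, is_limb=is_limb))
        if is_limb:
            limb_genes.append(gene_id)
        if tag:
            boundary[tag] = gene_id
        return gene_id

    for i, aln in enumerate(alns):
        combo = set(combos.get(aln.cne_id, ()))
        limb_prob = 0.8 if {"caecilian", "snake"} <= combo else 0.1
        if rng.random() < limb_prob:
            _add(aln, int(rng.integers(5_000, 400_000)), True)
        if i % 3 == 0:
            _add(aln, -int(rng.integers(5_000, 300_000)), False)
    # boundary pair on the first element: just inside / just outside 1 Mb
    first = alns[0]
    _add(first, (first.end - first.start - 1) + 999_999, False, tag="inside_1mb")
    _add(first, (first.end - first.start - 1) + 1_000_001, False, tag="outside_1mb")
    genes = pd.DataFrame(rows)
    return genes, limb_genes, boundary


def _make_tracks(
    alns: list[CNEAlignment],
    combos: dict[str, tuple[str, ...]],
    rng: np.random.Generator,
) -> dict[str, IntervalSet]:
    tracks: dict[str, list[Interval]] = {t: [] for t in ENHANCER_TISSUES}
    for aln in alns:
        convergent = len(combos.get(aln.cne_id, ())) >= 2
        for tissue in ENHANCER_TISSUES:
            is_limb_tissue = tissue.startswith("limb")
            p = (0.8 if is_limb_tissue else 0.4) if convergent else 0.1
            r = rng.random()
            mid = (aln.start + aln.end) // 2
            if r < p:
                score = float(np.round(2.1 + 3.0 * rng.random(), 3))
                tracks[tissue].append(
                    Interval(aln.chrom, mid - 30, mid + 30, name=aln.cne_id,
                             score=score)
                )
            elif r < p + 0.05:
                # sub-threshold signal straddling the cutoff (score <= 2)
                score = 2.0 if rng.random() < 0.5 else 1.5
                tracks[tissue].append(
                    Interval(aln.chrom, mid - 30, mid + 30, name=aln.cne_id,
                             score=score)
                )
    return {t: IntervalSet(ivs) for t, ivs in tracks.items()}


def _make_orthologs(
    rng: np.random.Generator, n_genes: int = 800
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    ref_species = [f"ref_{i + 1:02d}" for i in range(14)]
    genes = [f"og{i + 1:04d}" for i in range(n_genes)]
    shared = set(genes[:N_SHARED_LIMITED])
    cursor = N_SHARED_LIMITED
    limited: dict[str, set[str]] = {}
    for sp in FOCAL_ORTHOLOG_SPECIES:
        extra = LIMITED_SET_SIZES[sp] - N_SHARED_LIMITED
        limited[sp] = shared | set(genes[cursor : cursor + extra])
        cursor += extra
    if cursor > n_genes:
        raise ValidationError("ortholog universe too small for planted sets")

    rows = []
    for g in genes:
        base_intron = float(rng.integers(2_000, 50_000))
        base_exon = float(rng.integers(900, 3_000))
        for sp in ref_species:
            rows.append(dict(
                gene_id=g, species=sp,
                intron_len=round(base_intron * rng.uniform(0.85, 1.15), 1),
                exon_len=round(base_exon * rng.uniform(0.95, 1.05), 1),
            ))
        for sp in FOCAL_ORTHOLOG_SPECIES:
            if g in limited[sp]:
                # stays strictly below 2x the reference median even at the
                # low end of the per-reference jitter (median >= 0.85 x base)
                factor = rng.uniform(0.5, 1.6)
            else:
                factor = rng.uniform(3.0, 8.0)
            rows.append(dict(
                gene_id=g, species=sp,
                intron_len=round(base_intron * factor, 1),
                exon_len=round(base_exon * rng.uniform(0.95, 1.05), 1),
            ))
    return pd.DataFrame(rows), limited, shared


def _make_origins(
    alns: list[CNEAlignment], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = [lab for lab, _ in OUTGROUP_LADDER] + [TETRAPOD_ANCESTOR]
    # weights loosely follow the published origin spectrum: most elements
    # trace to the gnathostome ancestor
    weights = np.array([0.05, 0.12, 0.16, 0.44, 0.02, 0.01, 0.20])
    weights = weights / weights.sum()
    outgroups = [sp for _, members in OUTGROUP_LADDER for sp in members]
    depth_of = {
        sp: i for i, (_, members) in enumerate(OUTGROUP_LADDER) for sp in members
    }
    presence_rows = []
    truth_rows = []
    for aln in alns:
        origin = labels[int(rng.choice(len(labels), p=weights))]
        if origin == TETRAPOD_ANCESTOR:
            depth = -1
        else:
            depth = next(i for i, (lab, _) in enumerate(OUTGROUP_LADDER)
                         if lab == origin)
        row = {}
        deepest_members = [] if depth < 0 else OUTGROUP_LADDER[depth][1]
        anchor = None if depth < 0 else deepest_members[
            int(rng.integers(len(deepest_members)))
        ]
        for sp in outgroups:
            if depth_of[sp] > depth:
                row[sp] = False
            elif sp == anchor:
                row[sp] = True  # the hit defining the origin is always present
            else:
                row[sp] = bool(rng.random() < 0.8)
        presence_rows.append(dict(cne_id=aln.cne_id, **row))
        truth_rows.append(dict(cne_id=aln.cne_id, origin=origin))
    presence = pd.DataFrame(presence_rows).set_index("cne_id")
    truth = pd.DataFrame(truth_rows)
    return presence, truth


def generate_feature_fixtures(
    tree: SpeciesTree,
    alns: list[CNEAlignment],
    combos: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> FixtureBundle:
    """Generate every downstream fixture with ground truth.

    ``combos`` (cne_id -> planted lineage combination) steers the planted
    associations: limb genes cluster near snake+caecilian convergent
    elements, limb-tissue enhancer tracks cover convergent elements
    preferentially, and 49 ortholog genes are limited-expansion in all
    three large-genome pseudo-species (set sizes 127/323/327).
    """
    combos = combos or {}
    rng = fork_rng(seed, "generate_feature_fixtures")
    genes, limb_genes, boundary = _make_genes(alns, combos, rng)
    tracks = _make_tracks(alns, combos, rng)
    orthologs, limited, shared = _make_orthologs(rng)
    presence, origin_truth = _make_origins(alns, rng)

    # coding mask: exons in the gaps between elements (never overlapping)
    mask = []
    for aln in alns[::4]:
        mask.append(Interval(aln.chrom, aln.end + 2_000, aln.end + 3_200))
    coding_mask = IntervalSet(mask)

    return FixtureBundle(
        genes=genes, limb_genes=limb_genes, coding_mask=coding_mask,
        tracks=tracks, orthologs=orthologs, limited_truth=limited,
        shared_limited=shared, outgroup_presence=presence,
        origin_truth=origin_truth, boundary_genes=boundary,
    )


def write_gene_gff(genes: pd.DataFrame, path) -> None:
    """Write the gene fixture as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g.chrom}\tlimbloss\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
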