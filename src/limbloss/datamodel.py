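"""Core domain types shared across the pipeline.

The unit of analysis is a conserved noncoding element (CNE): a short
noncoding segment conserved across limbed tetrapods, represented here as a
gapped multi-species alignment (:class:`CNEAlignment`) tied to an interval
on a reference genome.  Species metadata (:class:`Species`) records limb
status, lineage membership for the limbless groups (caecilians, snakes and
two single-species limbless-lizard lineages), the time since limb loss and
a per-species neutral substitution rate.  All detection thresholds are
gathered in :class:`DetectionConfig`.

Coordinates are 0-based half-open everywhere; GFF input is converted at the
I/O boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import dendropy

LIMBED = "limbed"
LIMBLESS = "limbless"

GAP = "-"
ALPHABET = "ACGTN-"

#: FASTA record-id prefix used for reconstructed internal-node sequences.
ANCESTOR_PREFIX = "ancestor:"

#: Conventional label for the root node of the tetrapod tree; the default
#: comparison node for identity scoring.
TETRAPOD_ANCESTOR = "tetrapod_ancestor"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class Species:
    """One terminal taxon with its limb-loss metadata.

    Parameters
    ----------
    name:
        Unique identifier, matching a leaf of the species tree.
    limb_status:
        ``"limbed"`` or ``"limbless"``.
    lineage:
        Limbless-lineage label (e.g. ``"caecilian"``, ``"snake"``);
        required iff the species is limbless.
    time_since_limb_loss:
        Myr since limb loss; required (and > 0) iff limbless.
    substitution_rate:
        Neutral rate in substitutions/site/Myr; optional, > 0 if present.
    """

    name: str
    limb_status: str
    lineage: str | None = None
    time_since_limb_loss: float | None = None
    substitution_rate: float | None = None

    def __post_init__(self) -> None:
        if self.limb_status not in (LIMBED, LIMBLESS):
            raise ValidationError(
                f"{self.name}: limb_status must be '{LIMBED}' or '{LIMBLESS}', "
                f"got {self.limb_status!r}"
            )
        if self.limb_status == LIMBLESS:
            if not self.lineage:
                raise ValidationError(f"{self.name}: limbless species need a lineage")
            if self.time_since_limb_loss is None or self.time_since_limb_loss <= 0:
                raise ValidationError(
                    f"{self.name}: limbless species need time_since_limb_loss > 0"
                )
        else:
            if self.lineage is not None:
                raise ValidationError(
                    f"{self.name}: limbed species must not carry a lineage label"
                )
            if self.time_since_limb_loss is not None:
                raise ValidationError(
                    f"{self.name}: limbed species must not carry a limb-loss time"
                )
        if self.substitution_rate is not None and self.substitution_rate <= 0:
            raise ValidationError(f"{self.name}: substitution_rate must be > 0")

    @property
    def is_limbless(self) -> bool:
        return self.limb_status == LIMBLESS


def limbed_names(species: Iterable[Species]) -> list[str]:
    return [s.name for s in species if not s.is_limbless]


def limbless_species(species: Iterable[Species]) -> list[Species]:
    return [s for s in species if s.is_limbless]


def lineages_of(species: Iterable[Species]) -> dict[str, list[str]]:
    """Map lineage label -> member species names (limbless only)."""
    out: dict[str, list[str]] = {}
    for s in species:
        if s.is_limbless:
            out.setdefault(s.lineage, []).append(s.name)
    return out


class SpeciesTree:
    """A rooted phylogeny over the analysed species.

    Wraps a :class:`dendropy.Tree`.  ``unit`` declares whether branch
    lengths are in expected substitutions per site (``"subs"``) or in
    millions of years (``"Myr"``).  Internal nodes of interest (the tetrapod
    root, each limbless-lineage ancestor) carry labels.
    """

    UNITS = ("Myr", "subs")

    def __init__(self, tree: dendropy.Tree, unit: str = "Myr"):
        if unit not in self.UNITS:
            raise ValidationError(f"unit must be one of {self.UNITS}, got {unit!r}")
        if tree.seed_node is None:
            raise ValidationError("tree has no root")
        self.tree = tree
        self.unit = unit

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, unit: str = "Myr") -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        # dendropy attaches internal labels as taxa when
        # suppress_internal_node_taxa=False; normalise to node.label
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.taxon is not None:
                node.label = node.taxon.label
                node.taxon = None
        return cls(tree, unit=unit)

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- accessors ----------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node_by_label(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is not None and node.taxon.label == label:
                    return node
            elif node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, names: Iterable[str]) -> dendropy.Node:
        node = self.tree.mrca(taxon_labels=list(names))
        if node is None:
            raise KeyError(f"no MRCA found for {list(names)}")
        return node

    def label_mrca(self, names: Iterable[str], label: str) -> None:
        self.mrca(names).label = label

    # -- validation ---------------------------------------------------
    def validate_against(self, species: Iterable[Species]) -> None:
        """Check that leaves and species manifest match one-to-one."""
        leaves = set(self.leaf_names)
        manifest = {s.name for s in species}
        if leaves != manifest:
            missing = sorted(manifest - leaves)
            extra = sorted(leaves - manifest)
            raise ValidationError(
                "tree/manifest mismatch: "
                f"in manifest but not tree: {missing}; in tree but not manifest: {extra}"
            )

    def mean_rate(self, species: Iterable[Species]) -> float:
        rates = [s.substitution_rate for s in species if s.substitution_rate]
        if not rates:
            raise ValidationError("no species carries a substitution rate")
        return sum(rates) / len(rates)


@dataclass
class CNEAlignment:
    """One conserved element: gapped per-species sequences on a shared
    column frame, plus (after reconstruction) internal-node sequences.

    ``start``/``end`` locate the element on ``ref_species`` (0-based
    half-open); the ungapped length of the reference row equals
    ``end - start``.  Species absent from the element simply have no entry
    in ``sequences``.
    """

    cne_id: str
    chrom: str
    start: int
    end: int
    ref_species: str
    sequences: dict[str, str]
    ancestors: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def validate(self) -> None:
        if not self.sequences:
            raise ValidationError(f"{self.cne_id}: no sequences")
        ncol = self.n_columns
        for name, seq in list(self.sequences.items()) + list(self.ancestors.items()):
            if len(seq) != ncol:
                raise ValidationError(
                    f"{self.cne_id}: ragged alignment — {name} has {len(seq)} "
                    f"columns, expected {ncol}"
                )
            bad = set(seq.upper()) - set(ALPHABET)
            if bad:
                raise ValidationError(
                    f"{self.cne_id}: {name} contains invalid symbols {sorted(bad)}"
                )
        if self.start >= self.end:
            raise ValidationError(f"{self.cne_id}: start >= end")
        if self.ref_species in self.sequences:
            ungapped = sum(1 for c in self.sequences[self.ref_species] if c != GAP)
            if ungapped != self.end - self.start:
                raise ValidationError(
                    f"{self.cne_id}: ungapped reference length {ungapped} != "
                    f"end - start = {self.end - self.start}"
                )

    def present_species(self) -> list[str]:
        """Species with a record in this element (possibly fully gapped)."""
        return list(self.sequences)

    def aligned_species(self) -> list[str]:
        """Species with at least one non-gap, non-N column."""
        return [
            name
            for name, seq in self.sequences.items()
            if any(c not in "-N" for c in seq.upper())
        ]


@dataclass
class DetectionConfig:
    """All thresholds of the CNE retention and degeneration criteria.

    Defaults reproduce the published criteria: a degenerated call needs
    either (i) a 20 bp window (1 bp steps) where >=29 limbed species keep
    >=18/20 matches to the reconstructed tetrapod-ancestor sequence while
    the focal limbless species keeps <=14/20, or (ii) a 50 bp window where
    >=29 limbed species keep >=30/50 matches and the focal species is
    absent (fully gapped).  Lineage-level calls need >=3 snakes or
    >=2 caecilians (1 for single-species lineages).  CNE retention demands
    ungapped reference length strictly greater than ``min_cne_length`` and
    >=``min_limbed_species`` limbed species present; genes are linked
    within ``gene_link_distance`` of their TSS.
    """

    window_short: int = 20
    step: int = 1
    limbed_conserved_min_short: int = 18
    limbless_identity_max_short: int = 14
    window_long: int = 50
    limbed_conserved_min_long: int = 30
    min_limbed_species: int = 29
    lineage_minima: dict[str, int] = field(
        default_factory=lambda: {"snake": 3, "caecilian": 2}
    )
    default_lineage_minimum: int = 1
    min_cne_length: int = 30  # strict ">"
    gene_link_distance: int = 1_000_000
    absent_fraction: float = 1.0
    comparison_node: str = TETRAPOD_ANCESTOR

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.limbed_conserved_min_short <= self.window_short):
            raise ValidationError("short-window conservation threshold out of range")
        if not (0 < self.limbless_identity_max_short <= self.window_short):
            raise ValidationError("short-window identity ceiling out of range")
        if not (0 < self.limbed_conserved_min_long <= self.window_long):
            raise ValidationError("long-window conservation threshold out of range")
        if self.step < 1:
            raise ValidationError("step must be >= 1")
        for name in ("window_short", "window_long", "min_limbed_species",
                     "min_cne_length", "gene_link_distance",
                     "default_lineage_minimum"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if any(v < 1 for v in self.lineage_minima.values()):
            raise ValidationError("lineage minima must be positive")
        if not (0 < self.absent_fraction <= 1):
            raise ValidationError("absent_fraction must be in (0, 1]")

    def lineage_minimum(self, lineage: str) -> int:
        return self.lineage_minima.get(lineage, self.default_lineage_minimum)

    def to_mapping(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DetectionConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def config_hash(cfg: DetectionConfig) -> str:
    """Stable short hash of a configuration, for run logging."""
    import hashlib
    import json

    buf = _io.StringIO()
    json.dump(cfg.to_mapping(), buf, sort_keys=True)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]
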