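"""Ancestral sequence reconstruction and the identity kernel.

Internal-node sequences are reconstructed per alignment column by Fitch
parsimony over the five states {A, C, G, T, -}: gaps are a fifth character
state, so a deletion shared by a clade is reconstructed as ancestral
absence rather than forcing a base call.  'N' is treated as fully
ambiguous.  The top-down pass is deterministic: the root takes the first
state of its candidate set in the fixed order A < C < G < T < '-', and a
child keeps its parent's state whenever that state is in the child's
candidate set, otherwise takes its own first candidate.

Species that are absent from an element, or fully gap/N, are pruned from
the reconstruction of that element (they carry no signal); internal nodes
above at least one informative leaf still receive sequences, including the
tetrapod-ancestor root and each limbless-lineage ancestor.

:func:`window_identity` is the single match-counting primitive all
detection criteria build on.  It reports absolute counts, never ratios,
because the published thresholds are absolute (18/20, 14/20, 30/50).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .datamodel import CNEAlignment, SpeciesTree, ValidationError

# numeric codes: bases 0-3, gap 4, N 5
CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
DECODE = np.array(list("ACGT-N"))
_LUT = np.full(256, 5, dtype=np.uint8)
for ch, code in CODE.items():
    _LUT[ord(ch)] = code
    _LUT[ord(ch.lower())] = code

# bitmask per state for Fitch; preference order A, C, G, T, '-'
_BITS = np.array([1, 2, 4, 8, 16], dtype=np.uint8)
_FULL = np.uint8(31)


def encode(seq: str) -> np.ndarray:
    """Encode a gapped sequence as uint8 codes (A0 C1 G2 T3 -4 N5)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(DECODE[codes])


class UnreconstructableError(ValidationError):
    """Element has fewer than two informative species."""


@dataclass(frozen=True)
class IdentityResult:
    """Match count over one window of the shared column frame."""

    matches: int
    comparable_columns: int
    window_offset: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.comparable_columns):
            raise ValidationError("matches must lie in [0, comparable_columns]")

    @property
    def fraction(self) -> float:
        return self.matches / self.comparable_columns


def match_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean per-column matches: same base, neither gap nor N.

    Gap or N in either sequence is comparable but never a match (so a
    fully deleted window scores 0 matches out of its full width).
    """
    return (a == b) & (a < 4) & (b < 4)


def window_identity(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, start_col: int, width: int
) -> IdentityResult:
    a = encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode(seq_b) if isinstance(seq_b, str) else seq_b
    if len(a) != len(b):
        raise ValidationError("sequences are not on a shared column frame")
    if start_col < 0 or start_col + width > len(a):
        raise ValidationError(
            f"window [{start_col}, {start_col + width}) outside {len(a)} columns"
        )
    wa, wb = a[start_col : start_col + width], b[start_col : start_col + width]
    return IdentityResult(
        matches=int(match_columns(wa, wb).sum()),
        comparable_columns=width,
        window_offset=start_col,
    )


def identity_fraction(seq_a: str | np.ndarray, seq_b: str | np.ndarray,
                      columns: np.ndarray | None = None) -> float:
    """Full-length identity fraction (matches / comparable columns),
    optionally restricted to ``columns`` of the frame."""
    a = encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode(seq_b) if isinstance(seq_b, str) else seq_b
    if columns is not None:
        a, b = a[columns], b[columns]
    if len(a) == 0:
        raise ValidationError("no comparable columns")
    return float(match_columns(a, b).sum()) / len(a)


def _leaf_masks(codes: np.ndarray) -> np.ndarray:
    """Per-column candidate bitmasks for a leaf (N -> fully ambiguous)."""
    masks = np.where(codes < 5, _BITS[np.minimum(codes, 4)], _FULL)
    return masks.astype(np.uint8)


def _first_state(masks: np.ndarray) -> np.ndarray:
    """First set bit in preference order A, C, G, T, '-'."""
    out = np.full(masks.shape, 4, dtype=np.uint8)
    for state in range(4, -1, -1):
        out = np.where(masks & _BITS[state], np.uint8(state), out)
    return out


def reconstruct_ancestors(
    aln: CNEAlignment,
    tree: SpeciesTree,
    overrides: dict[str, str] | None = None,
) -> CNEAlignment:
    """Fill every internal node of ``tree`` with a parsimony sequence.

    Returns a new :class:`CNEAlignment` whose ``ancestors`` map node labels
    (auto-generated ``node<i>`` where the tree has none) to gapped
    sequences on the element's column frame.  ``overrides`` supplies
    externally produced ancestor sequences verbatim, bypassing parsimony
    for those labels.

    Raises :class:`UnreconstructableError` when fewer than two species
    carry signal (some non-gap, non-N column).
    """
    informative = {
        name for name in aln.aligned_species() if name in set(tree.leaf_names)
    }
    if len(informative) < 2:
        raise UnreconstructableError(
            f"{aln.cne_id}: only {len(informative)} informative species; "
            "element cannot be reconstructed"
        )
    ncol = aln.n_columns
    down: dict[int, np.ndarray] = {}  # node id -> candidate masks (or None)
    order: list[dendropy.Node] = list(tree.tree.postorder_node_iter())

    for node in order:
        if node.is_leaf():
            name = node.taxon.label
            if name in informative:
                down[id(node)] = _leaf_masks(encode(aln.sequences[name]))
        else:
            child_masks = [down[id(c)] for c in node.child_nodes() if id(c) in down]
            if not child_masks:
                continue
            acc = child_masks[0]
            for m in child_masks[1:]:
                inter = acc & m
                acc = np.where(inter > 0, inter, acc | m).astype(np.uint8)
            down[id(node)] = acc

    # top-down refinement
    states: dict[int, np.ndarray] = {}
    labels: dict[int, str] = {}
    auto = 0
    ancestors: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or id(node) not in down:
            continue
        parent = node.parent_node
        if parent is not None and id(parent) in states:
            pstate = states[id(parent)]
            mask = down[id(node)]
            keep = (mask & _BITS[pstate]) > 0
            state = np.where(keep, pstate, _first_state(mask))
        else:
            state = _first_state(down[id(node)])
        states[id(node)] = state
        if node.label:
            label = node.label
        else:
            label = f"node{auto}"
            auto += 1
        labels[id(node)] = label
        ancestors[label] = decode(np.where(state == 4, 4, state).astype(np.intp))

    if overrides:
        for label, seq in overrides.items():
            if len(seq) != ncol:
                raise ValidationError(
                    f"{aln.cne_id}: override for {label!r} has wrong column count"
                )
            ancestors[label] = seq.upper()

    return CNEAlignment(
        cne_id=aln.cne_id, chrom=aln.chrom, start=aln.start, end=aln.end,
        ref_species=aln.ref_species, sequences=dict(aln.sequences),
        ancestors=ancestors,
    )
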