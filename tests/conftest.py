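"""Shared fixtures: the 43-species demo phylogeny and constructed
boundary alignments with prefilled ancestor sequences."""

from __future__ import annotations

import pytest

from limbloss.datamodel import (
    CNEAlignment,
    DetectionConfig,
    Species,
    TETRAPOD_ANCESTOR,
)
from limbloss.synthetic import build_demo_tree


@pytest.fixture(scope="session")
def demo():
    """(species, tree): 31 limbed + 12 limbless in 4 lineages."""
    return build_demo_tree(seed=1)


@pytest.fixture(scope="session")
def demo_species(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_tree(demo):
    return demo[1]


@pytest.fixture()
def cfg():
    return DetectionConfig()


def make_window_alignment(
    species: list[Species],
    width: int = 20,
    n_limbed_conserved: int = 31,
    limbed_matches: int = 20,
    limbed_other_matches: int = 17,
    focal: str = "snake_1",
    focal_matches: int | None = 14,
    focal_absent: bool = False,
    spread_mismatches: bool = False,
) -> CNEAlignment:
    """Single-window element with an exact match-count design.

    The ancestor is all-A; mismatches are written as C.  The first
    ``n_limbed_conserved`` limbed species carry ``limbed_matches`` matches,
    the rest ``limbed_other_matches``.  The focal limbless species gets
    exactly ``focal_matches`` matches (or an all-gap row when
    ``focal_absent``); every other limbless species equals the ancestor.
    ``spread_mismatches`` distributes limbed mismatches evenly (period-5
    pattern) so no short sub-window is accidentally conserved.
    """
    anc = "A" * width

    def row(matches: int) -> str:
        n_mis = width - matches
        if spread_mismatches and n_mis:
            # 2 mismatches per 5 columns until the budget is spent
            chars = []
            left = n_mis
            for i in range(width):
                if left and i % 5 >= 3:
                    chars.append("C")
                    left -= 1
                else:
                    chars.append("A")
            if left:  # fall back for large budgets
                for i in range(width):
                    if left and chars[i] == "A":
                        chars[i] = "C"
                        left -= 1
            return "".join(chars)
        return "A" * matches + "C" * n_mis

    sequences: dict[str, str] = {}
    limbed = [s for s in species if not s.is_limbless]
    for i, sp in enumerate(limbed):
        m = limbed_matches if i < n_limbed_conserved else limbed_other_matches
        sequences[sp.name] = row(m)
    for sp in species:
        if sp.is_limbless:
            if sp.name == focal:
                if focal_absent:
                    sequences[sp.name] = "-" * width
                elif focal_matches is None:
                    sequences[sp.name] = anc
                else:
                    sequences[sp.name] = row(focal_matches)
            else:
                sequences[sp.name] = anc
    aln = CNEAlignment(
        cne_id="CNEtest", chrom="chr1", start=100, end=100 + width,
        ref_species=limbed[0].name, sequences=sequences,
        ancestors={TETRAPOD_ANCESTOR: anc},
    )
    aln.validate()
    return aln
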