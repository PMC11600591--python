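"""The sliding-window detector, lineage calls, convergence and rates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from limbloss.datamodel import CNEAlignment, DetectionConfig, TETRAPOD_ANCESTOR, ValidationError
from limbloss.detection import (
    CRITERION_LONG,
    CRITERION_SHORT,
    ConvergenceRecord,
    call_lineages,
    classify_convergence,
    convergence_rate,
    identity_profiles,
    scan_element,
    scan_species,
)

from _oracles import oracle_scan
from conftest import make_window_alignment


# ---------------------------------------------------------------------------
# criterion boundaries on constructed single-window elements
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("focal_matches,fires", [(13, True), (14, True), (15, False)])
def test_short_criterion_focal_boundary(demo_species, cfg, focal_matches, fires):
    aln = make_window_alignment(demo_species, focal_matches=focal_matches)
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert call.degenerated is fires
    if fires:
        assert call.evidence[0].criterion == CRITERION_SHORT
        assert call.evidence[0].focal_matches.matches == focal_matches


@pytest.mark.parametrize(
    "n_conserved,limbed_matches,fires",
    [(31, 18, True),   # 18/20 counts as conserved
     (31, 17, False),  # 17/20 does not
     (29, 18, True),   # exactly 29 supporting species suffice
     (28, 18, False)],  # 28 do not
)
def test_short_criterion_limbed_support_boundary(
    demo_species, cfg, n_conserved, limbed_matches, fires
):
    aln = make_window_alignment(
        demo_species, n_limbed_conserved=n_conserved,
        limbed_matches=limbed_matches, limbed_other_matches=17,
        focal_matches=10,
    )
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert call.degenerated is fires


@pytest.mark.parametrize("limbed_matches,fires", [(30, True), (29, False)])
def test_long_criterion_boundary(demo_species, cfg, limbed_matches, fires):
    # 50-column element; limbed mismatches spread so no 20-bp sub-window is
    # conserved; focal fully deleted
    aln = make_window_alignment(
        demo_species, width=50, limbed_matches=limbed_matches,
        focal_absent=True, spread_mismatches=True,
    )
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert call.degenerated is fires
    if fires:
        assert {e.criterion for e in call.evidence} == {CRITERION_LONG}


def test_partial_gap_does_not_satisfy_absence(demo_species, cfg):
    aln = make_window_alignment(
        demo_species, width=50, limbed_matches=30, spread_mismatches=True,
        focal_matches=None, focal_absent=True,
    )
    seqs = dict(aln.sequences)
    seqs["snake_1"] = "-" * 49 + "A"
    aln = dataclasses.replace(aln, sequences=seqs)
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert not call.degenerated


def test_identical_focal_never_degenerated(demo_species, cfg):
    aln = make_window_alignment(demo_species, width=60, focal_matches=None,
                                focal_absent=False)
    seqs = dict(aln.sequences)
    seqs["snake_1"] = aln.ancestors[TETRAPOD_ANCESTOR]
    aln = dataclasses.replace(aln, sequences=seqs)
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert not call.degenerated and call.evidence == []


def test_windows_laid_on_ancestor_ungapped_positions(demo_species, cfg):
    """Gap columns of the ancestor are skipped: 19 ancestor bases + 1 gap
    column + 1 base still form one 20-bp window."""
    aln = make_window_alignment(demo_species, width=21, focal_matches=None,
                                focal_absent=False)
    anc = "A" * 10 + "-" + "A" * 10  # 20 ungapped positions over 21 columns
    seqs = {}
    for name, seq in aln.sequences.items():
        seqs[name] = seq[:10] + "-" + seq[10:20]
    # focal: 6 mismatches on ancestor bases -> 14/20
    seqs["snake_1"] = "C" * 6 + "A" * 4 + "-" + "A" * 10
    aln = dataclasses.replace(
        aln, sequences={k: v for k, v in seqs.items()},
        ancestors={TETRAPOD_ANCESTOR: anc},
    )
    call = scan_element(aln, demo_species, cfg)["snake_1"]
    assert call.degenerated
    assert call.evidence[0].focal_matches.matches == 14


def test_missing_ancestor_raises(demo_species, cfg):
    aln = make_window_alignment(demo_species)
    aln = dataclasses.replace(aln, ancestors={})
    with pytest.raises(ValidationError, match="ancestral reconstruction"):
        scan_element(aln, demo_species, cfg)


def test_scan_species_rejects_limbed(demo_species, cfg):
    aln = make_window_alignment(demo_species)
    limbed = next(s for s in demo_species if not s.is_limbless)
    with pytest.raises(ValidationError):
        scan_species(aln, limbed, demo_species, cfg)


# ---------------------------------------------------------------------------
# detector == exhaustive oracle on random instances
# ---------------------------------------------------------------------------

def random_instance(species, rng) -> CNEAlignment:
    """Random gappy alignment with a mix of conserved, diverged, deleted
    and absent species."""
    ncol = int(rng.integers(15, 121))
    bases = np.array(list("ACGT"))
    anc_chars = rng.choice(bases, ncol)
    if rng.random() < 0.3:  # ancestor gap columns
        gap_cols = rng.choice(ncol, size=int(rng.integers(1, max(2, ncol // 8))),
                              replace=False)
        anc_chars[gap_cols] = "-"
    anc = "".join(anc_chars)
    seqs = {}
    for s in species:
        if rng.random() < 0.05:
            continue  # absent species
        p = float(rng.choice([0.0, 0.02, 0.08, 0.4]))
        chars = anc_chars.copy()
        mut = rng.random(ncol) < p
        chars[mut] = rng.choice(bases, int(mut.sum()))
        if rng.random() < 0.25:  # gap run
            start = int(rng.integers(0, ncol))
            span = int(rng.integers(5, 70))
            chars[start : start + span] = "-"
        if rng.random() < 0.05:  # sprinkle Ns
            nn = rng.random(ncol) < 0.05
            chars[nn] = "N"
        seqs[s.name] = "".join(chars)
    ref = next(iter(seqs))
    return CNEAlignment(
        "R1", "chr1", 0, sum(1 for c in seqs[ref] if c != "-"), ref, seqs,
        ancestors={TETRAPOD_ANCESTOR: anc},
    )


def test_detector_equals_oracle_random_instances(demo_species, cfg):
    rng = np.random.default_rng(2024)
    for i in range(150):
        aln = random_instance(demo_species, rng)
        got = {
            name: call.degenerated
            for name, call in scan_element(aln, demo_species, cfg).items()
        }
        want = oracle_scan(aln, demo_species, cfg)
        assert got == want, f"instance {i}"


def test_detector_monotone_in_identity_ceiling(demo_species):
    """Lowering the short-window identity ceiling never adds a
    degenerated species."""
    rng = np.random.default_rng(77)
    for _ in range(25):
        aln = random_instance(demo_species, rng)
        degraded_sets = []
        for ceiling in (16, 14, 12, 8):
            cfg = DetectionConfig(limbless_identity_max_short=ceiling)
            calls = scan_element(aln, demo_species, cfg)
            degraded_sets.append({n for n, c in calls.items() if c.degenerated})
        for bigger, smaller in zip(degraded_sets, degraded_sets[1:]):
            assert smaller <= bigger


def test_detection_independent_of_species_order(demo_species, cfg):
    rng = np.random.default_rng(5)
    aln = random_instance(demo_species, rng)
    shuffled = list(demo_species)[::-1]
    a = {n: c.degenerated for n, c in scan_element(aln, demo_species, cfg).items()}
    b = {n: c.degenerated for n, c in scan_element(aln, shuffled, cfg).items()}
    assert a == b


# ---------------------------------------------------------------------------
# lineage calls and convergence classes
# ---------------------------------------------------------------------------

def _calls_for(species, degenerated_species, cne="c1"):
    return {
        (cne, s.name): (s.name in degenerated_species)
        for s in species if s.is_limbless
    }


@pytest.mark.parametrize(
    "snakes,lineage_called",
    [(2, False), (3, True), (4, True)],
)
def test_snake_lineage_minimum(demo_species, cfg, snakes, lineage_called):
    deg = {f"snake_{i + 1}" for i in range(snakes)}
    lcs = call_lineages(_calls_for(demo_species, deg), demo_species, cfg)
    snake = next(lc for lc in lcs if lc.lineage == "snake")
    assert snake.degenerated is lineage_called
    assert snake.n_species_degenerated == snakes


@pytest.mark.parametrize("caecilians,called", [(1, False), (2, True)])
def test_caecilian_lineage_minimum(demo_species, cfg, caecilians, called):
    deg = {f"caecilian_{i + 1}" for i in range(caecilians)}
    lcs = call_lineages(_calls_for(demo_species, deg), demo_species, cfg)
    caec = next(lc for lc in lcs if lc.lineage == "caecilian")
    assert caec.degenerated is called


def test_single_species_lineage_minimum_one(demo_species, cfg):
    lcs = call_lineages(_calls_for(demo_species, {"lizard_A_1"}),
                        demo_species, cfg)
    assert next(lc for lc in lcs if lc.lineage == "lizard_A").degenerated
    assert not next(lc for lc in lcs if lc.lineage == "lizard_B").degenerated


def test_convergence_classes(demo_species, cfg):
    calls = {}
    calls.update(_calls_for(demo_species, {"caecilian_1", "caecilian_2"}, "c1"))
    calls.update(_calls_for(
        demo_species,
        {"caecilian_1", "caecilian_2", "snake_1", "snake_2", "snake_3"}, "c2"))
    calls.update(_calls_for(
        demo_species,
        {"caecilian_1", "caecilian_2", "snake_1", "snake_2", "snake_3",
         "lizard_A_1", "lizard_B_1"}, "c3"))
    calls.update(_calls_for(demo_species, set(), "c4"))
    records, summary = classify_convergence(
        call_lineages(calls, demo_species, cfg)
    )
    klass = {r.cne_id: r.klass for r in records}
    assert klass == {"c1": "lineage_specific", "c2": "convergent_2",
                     "c3": "convergent_4", "c4": "none"}
    assert summary["combination_counts"]["caecilian+snake"] == 1
    assert summary["n_convergent"] == 2


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def _rate_for(count, time_myr):
    from limbloss.datamodel import Species

    focal = Species("glass", "limbless", lineage="lizard_A",
                    time_since_limb_loss=time_myr)
    records = [
        ConvergenceRecord(f"c{i}", frozenset({"lizard_A", "snake"}),
                          "convergent_2")
        for i in range(count)
    ]
    calls = {(f"c{i}", "glass"): True for i in range(count)}
    df = convergence_rate(records, calls, [focal])
    return float(df.iloc[0]["rate_per_myr"])


def test_printed_rates_recovered():
    """219 convergent elements over 40 Myr and 267 over 35 Myr reproduce
    the published glass-lizard and sand-microteiid rates."""
    assert _rate_for(219, 40.0) == pytest.approx(5.475)
    assert round(_rate_for(267, 35.0), 2) == 7.63


def test_zero_count_rate():
    assert _rate_for(0, 40.0) == 0.0


def test_missing_time_raises():
    from limbloss.datamodel import Species

    with pytest.raises(ValidationError):
        Species("glass", "limbless", lineage="lizard_A",
                time_since_limb_loss=0.0)


# ---------------------------------------------------------------------------
# identity profiles
# ---------------------------------------------------------------------------

def test_identity_profiles_groups_and_values(demo_species, cfg):
    limbed = [s.name for s in demo_species if not s.is_limbless]
    anc = "A" * 100
    seqs = {n: anc for n in limbed}
    for s in demo_species:
        if s.is_limbless:
            seqs[s.name] = anc
    seqs["snake_1"] = "C" * 25 + "A" * 75
    seqs["snake_2"] = "-" * 100
    aln = CNEAlignment(
        "c1", "chr1", 0, 100, limbed[0], seqs,
        ancestors={TETRAPOD_ANCESTOR: anc, "snake_ancestor": anc,
                   "caecilian_ancestor": anc, "lizard_A_ancestor": anc,
                   "lizard_B_ancestor": anc},
    )
    records = [ConvergenceRecord("c1", frozenset({"snake", "caecilian"}),
                                 "convergent_2")]
    prof = identity_profiles(records, [aln], demo_species)
    by_sp = prof.set_index("species")["identity"]
    assert by_sp["snake_1"] == 0.75
    assert by_sp["snake_2"] == 0.0
    assert by_sp["caecilian_1"] == 1.0
    assert (prof["group"] == "convergent_dcne").all()
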