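"""Exact tests, FDR correction and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from limbloss.datamodel import ValidationError
from limbloss.detection import ConvergenceRecord
from limbloss.intervals import Interval, IntervalSet
from limbloss.stats import (
    ContingencyTable2x2,
    bh_fdr,
    compare_identity_groups,
    dcne_limb_gene_test,
    fisher_exact,
    region_set_enrichment,
    term_enrichment,
)

from _oracles import oracle_fisher_two_sided, oracle_hypergeom_upper


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_fisher_proportional_rows():
    res = fisher_exact(ContingencyTable2x2(10, 90, 100, 900))
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_extreme_tables_enumerated():
    # [[5,0],[0,5]]: p = 2 / C(10,5)
    res = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
    assert res.p_value == pytest.approx(2 / 252)
    assert res.odds_ratio == float("inf")
    assert res.odds_ratio_haldane == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
    # [[0,10],[10,0]]: p = 2 / C(20,10)
    res = fisher_exact(ContingencyTable2x2(0, 10, 10, 0))
    assert res.p_value == pytest.approx(2 / 184756)
    assert res.odds_ratio == 0.0


def test_fisher_negative_counts_rejected():
    with pytest.raises(ValidationError):
        ContingencyTable2x2(-1, 2, 3, 4)


def test_fisher_equals_enumeration_exhaustive_small():
    """Implementation agrees with full hypergeometric enumeration for
    every table with total count <= 14."""
    for n in range(1, 15):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    got = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
                    want = oracle_fisher_two_sided(a, b, c, d)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), \
                        (a, b, c, d)


def test_fisher_equals_enumeration_random_margins_to_30():
    rng = np.random.default_rng(42)
    for _ in range(300):
        a, b, c, d = (int(rng.integers(0, 16)) for _ in range(4))
        got = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
        want = oracle_fisher_two_sided(a, b, c, d)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (a, b, c, d)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_hand_computed_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_and_bounds():
    assert bh_fdr([1.0]) == pytest.approx([1.0])
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.2])


def test_bh_permutation_invariance():
    rng = np.random.default_rng(0)
    p = rng.random(50)
    q = bh_fdr(p)
    perm = rng.permutation(50)
    q_perm = bh_fdr(p[perm])
    assert np.allclose(q_perm, q[perm])
    # step-up output dominates input after sorting and is monotone
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

def test_term_enrichment_matches_enumeration():
    universe = [f"g{i}" for i in range(100)]
    term = {f"g{i}" for i in range(10)}
    gene_set = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
    df = term_enrichment(gene_set, {"T": term}, universe)
    want = oracle_hypergeom_upper(5, 100, 10, 10)
    assert df.iloc[0]["p_value"] == pytest.approx(want)
    # cross-check identity: upper tail == 1 - CDF(k-1)
    from scipy.stats import hypergeom

    assert df.iloc[0]["p_value"] == pytest.approx(
        1 - hypergeom.cdf(4, 100, 10, 10)
    )


def test_term_enrichment_degenerate_cases():
    universe = [f"g{i}" for i in range(20)]
    annotations = {"absent": {"zz"}, "all": set(universe)}
    df = term_enrichment(set(universe), annotations, universe)
    # term with no universe genes skipped; set == universe gives p = 1
    assert list(df["term"]) == ["all"]
    assert df.iloc[0]["p_value"] == pytest.approx(1.0)


def test_term_enrichment_zero_overlap():
    universe = [f"g{i}" for i in range(30)]
    df = term_enrichment({"g0"}, {"T": {"g29"}}, universe)
    assert df.iloc[0]["n_overlap"] == 0
    assert df.iloc[0]["p_value"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# limb-gene overlap test
# ---------------------------------------------------------------------------

def _records(combo_by_cne):
    return [
        ConvergenceRecord(c, frozenset(combo),
                          f"convergent_{len(combo)}" if len(combo) >= 2
                          else ("lineage_specific" if combo else "none"))
        for c, combo in combo_by_cne.items()
    ]


def test_limb_gene_test_planted_effect():
    """Elements linked to limb genes degenerate 5x more often in the
    planted combination; the test flags it at q < 0.01."""
    rng = np.random.default_rng(3)
    all_ids = [f"c{i}" for i in range(400)]
    linked = set(all_ids[:200])
    combos = {}
    for cid in all_ids:
        p = 0.5 if cid in linked else 0.1
        combos[cid] = ("caecilian", "snake") if rng.random() < p else ()
    links = pd.DataFrame(
        [{"cne_id": c, "gene_id": "limbg1", "distance": 0} for c in linked]
    )
    df = dcne_limb_gene_test(_records(combos), links, ["limbg1"], all_ids,
                             [("caecilian", "snake"), ("caecilian", "lizard_A")])
    row = df.set_index("combination").loc["caecilian+snake"]
    assert row["q_value"] < 0.01
    empty = df.set_index("combination").loc["caecilian+lizard_A"]
    assert empty["p_value"] == 1.0 and empty["n_foreground"] == 0


def test_limb_gene_test_foreground_equals_background():
    all_ids = [f"c{i}" for i in range(40)]
    combos = {c: ("caecilian", "snake") for c in all_ids}
    links = pd.DataFrame(
        [{"cne_id": c, "gene_id": "limbg1", "distance": 0}
         for c in all_ids[:10]]
    )
    df = dcne_limb_gene_test(_records(combos), links, ["limbg1"], all_ids,
                             [("caecilian", "snake")])
    assert df.iloc[0]["p_value"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# region-set enrichment
# ---------------------------------------------------------------------------

def _universe(n=100):
    return IntervalSet(
        Interval("chr1", i * 1000, i * 1000 + 100, name=f"c{i}") for i in range(n)
    )


def test_region_enrichment_planted_track_ranks_first():
    uni = _universe(100)
    fg = IntervalSet(list(uni)[:20])
    cover = lambda ivs: IntervalSet(
        Interval(iv.chrom, iv.start, iv.end) for iv in ivs
    )
    # planted: covers 80% of foreground, 10% of the rest
    planted = cover(list(fg)[:16] + list(uni)[20:28])
    null = cover(list(uni)[50:60])
    df = region_set_enrichment(fg, uni, {"planted": planted, "null": null})
    df = df.sort_values("q_value").reset_index(drop=True)
    assert df.iloc[0]["region_set"] == "planted"
    assert df.iloc[0]["q_value"] < 0.01


def test_region_enrichment_degenerate_tracks():
    uni = _universe(30)
    fg = IntervalSet(list(uni)[:10])
    everything = IntervalSet([Interval("chr1", 0, 10_000_000)])
    df = region_set_enrichment(
        fg, uni, {"all": everything, "empty": IntervalSet()}
    )
    by = df.set_index("region_set")
    assert by.loc["all", "p_value"] == pytest.approx(1.0)
    assert by.loc["empty", "p_value"] == pytest.approx(1.0)


def test_region_enrichment_foreground_outside_universe():
    uni = _universe(10)
    fg = IntervalSet([Interval("chr9", 0, 50)])
    with pytest.raises(ValidationError):
        region_set_enrichment(fg, uni, {})


def test_null_fisher_false_positive_control():
    """With no planted effect, q < 0.05 discoveries stay within the BH
    guarantee (<= 5% + 3x Monte Carlo error over 200 null tests)."""
    rng = np.random.default_rng(123)
    N, K, F = 500, 100, 50
    ps = []
    for _ in range(200):
        prop = set(rng.choice(N, K, replace=False).tolist())
        fg = set(rng.choice(N, F, replace=False).tolist())
        a = len(prop & fg)
        res = fisher_exact(
            ContingencyTable2x2(a, F - a, K - a, N - F - K + a)
        )
        ps.append(res.p_value)
    q = bh_fdr(ps)
    frac = float((q < 0.05).mean())
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero():
    tests, _ = compare_identity_groups(
        {"a": np.full(10, 0.8), "b": np.full(10, 0.8)}
    )
    assert tests.iloc[0]["t_statistic"] == 0.0
    assert tests.iloc[0]["p_value"] == 1.0


def test_separated_groups_tiny_p():
    rng = np.random.default_rng(4)
    a = rng.normal(0.9, 0.01, 100)
    b = rng.normal(0.7, 0.01, 100)
    tests, hist = compare_identity_groups({"hi": a, "lo": b})
    assert tests.iloc[0]["p_value"] < 1e-10
    assert set(hist["group"]) == {"hi", "lo"}
    assert hist.groupby("group")["count"].sum().eq(100).all()


def test_three_groups_three_pairs():
    g = {k: np.random.default_rng(i).random(5) for i, k in enumerate("abc")}
    tests, _ = compare_identity_groups(g)
    assert len(tests) == 3


def test_singleton_group_rejected():
    with pytest.raises(ValidationError):
        compare_identity_groups({"a": [0.5], "b": [0.1, 0.2]})
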