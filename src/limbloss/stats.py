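"""Exact-test machinery: Fisher/hypergeometric enrichment with the CNE
background, Benjamini-Hochberg FDR, region-set enrichment, flat term
enrichment and Welch comparisons of identity distributions.

Conventions: Fisher p-values are two-sided by probability-mass summation
(the R convention); the odds ratio is the sample ratio ad/bc, with the
Haldane-Anscombe (+0.5) variant reported alongside whenever a cell is
zero.  Region enrichment counts elements (not base pairs), foreground
against the full CNE universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError
from .intervals import IntervalSet


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows foreground / not-foreground, columns property / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    label: str
    odds_ratio: float
    p_value: float
    q_value: float | None = None
    odds_ratio_haldane: float | None = None


def fisher_exact(table: ContingencyTable2x2, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test; sample odds ratio ad/bc."""
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = 0.0
    haldane = None
    if 0 in (a, b, c, d):
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return EnrichmentResult(
        label=label, odds_ratio=float(odds), p_value=float(p),
        odds_ratio_haldane=haldane,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dcne_limb_gene_test(
    records,
    links: pd.DataFrame,
    limb_genes,
    all_cne_ids,
    combinations_to_test: list[tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Overlap of convergent-dCNE-associated genes with limb genes.

    Unit of counting is the CNE.  For each lineage combination the
    foreground is the convergent elements degenerated in (at least) every
    lineage of the combination; the background is the entire CNE set; the
    property is linkage to >= 1 limb-related gene.  BH correction runs
    across combinations.
    """
    limb_genes = set(limb_genes)
    linked = set(
        links.loc[links["gene_id"].isin(limb_genes), "cne_id"]
    )
    universe = sorted(set(all_cne_ids))
    if combinations_to_test is None:
        lineages = sorted({lin for r in records for lin in r.degenerated_lineages})
        combinations_to_test = list(combinations(lineages, 2))
    rows = []
    for combo in combinations_to_test:
        fg = {
            r.cne_id
            for r in records
            if r.is_convergent and set(combo) <= r.degenerated_lineages
        }
        label = "+".join(combo)
        a = sum(1 for c in fg if c in linked)
        b = len(fg) - a
        c = sum(1 for c_ in universe if c_ in linked and c_ not in fg)
        d = len(universe) - len(fg) - c
        if not fg:
            rows.append(dict(combination=label, n_foreground=0, n_linked=0,
                             odds_ratio=float("nan"), p_value=1.0))
            continue
        res = fisher_exact(ContingencyTable2x2(a, b, c, d), label=label)
        rows.append(dict(combination=label, n_foreground=len(fg), n_linked=a,
                         odds_ratio=res.odds_ratio, p_value=res.p_value))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"])
    return df


def region_set_enrichment(
    foreground: IntervalSet,
    universe: IntervalSet,
    region_db: dict[str, IntervalSet],
) -> pd.DataFrame:
    """Element-level region-set enrichment of a foreground within a
    universe of elements, one Fisher test per named region set, BH across
    sets (the region-database enrichment design popularised by LOLA)."""
    uni = list(universe)
    fg_keys = {(iv.chrom, iv.start, iv.end) for iv in foreground}
    uni_keys = {(iv.chrom, iv.start, iv.end) for iv in uni}
    missing = fg_keys - uni_keys
    if missing:
        raise ValidationError(
            f"{len(missing)} foreground elements absent from the universe"
        )
    in_fg = np.array([(iv.chrom, iv.start, iv.end) in fg_keys for iv in uni])
    rows = []
    for name in sorted(region_db):
        track = region_db[name]
        hit = np.array([
            track.overlaps_any(iv.chrom, iv.start, iv.end) for iv in uni
        ])
        a = int((in_fg & hit).sum())
        b = int((in_fg & ~hit).sum())
        c = int((~in_fg & hit).sum())
        d = int((~in_fg & ~hit).sum())
        res = fisher_exact(ContingencyTable2x2(a, b, c, d), label=name)
        rows.append(dict(region_set=name, n_foreground_hit=a,
                         n_universe_hit=a + c, odds_ratio=res.odds_ratio,
                         p_value=res.p_value))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"])
    return df


def term_enrichment(
    gene_set,
    term_annotations: dict[str, set],
    universe_genes,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment over flat annotations.

    For each term with k annotated genes in a universe of N, drawing the
    n-gene study set, p = P[overlap >= observed]; BH across terms; terms
    with q below ``q_threshold`` are flagged significant.
    """
    universe = set(universe_genes)
    genes = set(gene_set)
    if not genes <= universe:
        raise ValidationError("gene set must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for term in sorted(term_annotations):
        members = term_annotations[term] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & genes)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, n_term=K, n_overlap=k, p_value=p))
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "p_value"])
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"])
        df["significant"] = df["q_value"] < q_threshold
    return df


def compare_identity_groups(groups: dict[str, np.ndarray],
                            n_bins: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Welch t-tests between labelled identity distributions.

    Returns (pairwise test table, histogram summary over [0, 1]).
    Zero-variance groups are handled by the Welch limit (t = +-inf when the
    means differ, p = 1 when they coincide); singleton groups are refused.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 observations")
    rows = []
    for a, b in combinations(sorted(arrays), 2):
        x, y = arrays[a], arrays[b]
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                t, p = 0.0, 1.0
            else:
                t, p = float("inf") * np.sign(x.mean() - y.mean()), 0.0
        else:
            t, p = sps.ttest_ind(x, y, equal_var=False)
        rows.append(dict(group_a=a, group_b=b, mean_a=float(x.mean()),
                         mean_b=float(y.mean()), t_statistic=float(t),
                         p_value=float(p)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist_rows = []
    for label in sorted(arrays):
        counts, _ = np.histogram(arrays[label], bins=edges)
        for i, c in enumerate(counts):
            hist_rows.append(dict(group=label, bin_low=float(edges[i]),
                                  bin_high=float(edges[i + 1]), count=int(c)))
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)
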