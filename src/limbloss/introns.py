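"""The limited-intron-expansion screen and its Monte Carlo overlap test.

Large-genome species (lungfish-, caecilian- and axolotl-scale) expand
most introns with the genome, but a subset of genes does not.  The screen
works from a long-format ortholog table (gene, species, total intron bp,
total exon bp): per-gene reference medians are taken over the designated
reference species; genes are dropped when any species' exon length
deviates more than 40% from the median, or when more than 6 species lack
introns entirely; the expansion length is species intron minus the
median, the expansion rate the ratio; and a gene counts as
limited-expansion in a focal species when its intron total is strictly
less than twice the median.

The significance of the k-way intersection of limited-expansion gene
sets is assessed by Monte Carlo: random same-size sets drawn uniformly
without replacement and independently per species from the retained
universe, 100,000 trials by default, summarised as a Z-score and an
add-one-smoothed empirical upper-tail p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import pandas as pd

from .datamodel import ValidationError
from .rng import fork_rng

EXON_DEVIATION_MAX = 0.40  # strict ">"
MAX_INTRONLESS_SPECIES = 6  # strict "more than 6"
LIMITED_MULTIPLIER = 2.0  # strict "<"

ORTHOLOG_COLUMNS = ["gene_id", "species", "intron_len", "exon_len"]


def reference_medians(
    orthologs: pd.DataFrame, reference_species: list[str]
) -> pd.DataFrame:
    """Per-gene median intron/exon length over the reference species
    (non-missing values only)."""
    ref = orthologs[orthologs["species"].isin(reference_species)]
    med = ref.groupby("gene_id")[["intron_len", "exon_len"]].median()
    return med.rename(columns={"intron_len": "median_intron",
                               "exon_len": "median_exon"})


def filter_ortholog_set(
    orthologs: pd.DataFrame, reference_species: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the retention filters; return (retained table, rejection log).

    A gene is rejected when any species' exon length deviates by more
    than 40% from the reference median, when more than 6 species carry no
    intron, or when the median exon length is zero (degenerate record).
    """
    for col in ORTHOLOG_COLUMNS:
        if col not in orthologs.columns:
            raise ValidationError(f"ortholog table lacks column {col!r}")
    med = reference_medians(orthologs, reference_species)
    rejections = []
    keep = []
    for gene, sub in orthologs.groupby("gene_id"):
        if gene not in med.index:
            rejections.append(dict(gene_id=gene, rule="no_reference_data"))
            continue
        median_exon = med.loc[gene, "median_exon"]
        if median_exon == 0:
            rejections.append(dict(gene_id=gene, rule="zero_median_exon"))
            continue
        dev = (sub["exon_len"] - median_exon).abs() / median_exon
        if (dev > EXON_DEVIATION_MAX).any():
            rejections.append(dict(gene_id=gene, rule="exon_deviation"))
            continue
        n_intronless = int((sub["intron_len"] == 0).sum())
        if n_intronless > MAX_INTRONLESS_SPECIES:
            rejections.append(dict(gene_id=gene, rule="intronless_species"))
            continue
        keep.append(gene)
    retained = orthologs[orthologs["gene_id"].isin(keep)].reset_index(drop=True)
    log = pd.DataFrame(rejections, columns=["gene_id", "rule"])
    return retained, log


def expansion_metrics(
    orthologs: pd.DataFrame,
    reference_species: list[str],
    gene_id: str,
    species: str,
) -> tuple[float, float]:
    """(expansion length bp, expansion rate) for one gene in one species:
    intron total minus the reference median, and the ratio."""
    med = reference_medians(orthologs, reference_species)
    if gene_id not in med.index:
        raise ValidationError(f"{gene_id}: no reference median")
    median_intron = float(med.loc[gene_id, "median_intron"])
    if median_intron == 0:
        raise ValidationError(f"{gene_id}: zero median intron length")
    row = orthologs[
        (orthologs["gene_id"] == gene_id) & (orthologs["species"] == species)
    ]
    if row.empty:
        raise ValidationError(f"{gene_id}: no record for {species}")
    intron = float(row["intron_len"].iloc[0])
    return intron - median_intron, intron / median_intron


def limited_expansion_genes(
    orthologs: pd.DataFrame,
    reference_species: list[str],
    focal_species: list[str],
    multiplier: float = LIMITED_MULTIPLIER,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-focal-species limited-expansion gene sets and their k-way
    intersection (intron total strictly below ``multiplier`` x median)."""
    if not focal_species:
        raise ValidationError("focal species list is empty")
    med = reference_medians(orthologs, reference_species)
    sets: dict[str, set[str]] = {}
    for sp in focal_species:
        sub = orthologs[orthologs["species"] == sp].set_index("gene_id")
        if sub.empty:
            raise ValidationError(f"no ortholog records for focal species {sp!r}")
        joined = sub.join(med, how="inner")
        limited = joined.index[
            joined["intron_len"] < multiplier * joined["median_intron"]
        ]
        sets[sp] = set(limited)
    return sets, k_way_intersection(list(sets.values()))


def k_way_intersection(sets: list[set]) -> set:
    """Shared elements of all sets — the single intersection routine used
    by both the observed-data path and the Monte Carlo null."""
    if not sets:
        return set()
    return reduce(lambda a, b: a & b, sets)


@dataclass(frozen=True)
class MCOverlapConfig:
    universe_size: int
    set_sizes: tuple[int, ...] = (127, 323, 327)
    observed_overlap: int = 49
    n_trials: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s > self.universe_size for s in self.set_sizes):
            raise ValidationError("set sizes cannot exceed the universe")
        if self.observed_overlap > min(self.set_sizes):
            raise ValidationError("observed overlap exceeds the smallest set")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


@dataclass
class MCOverlapResult:
    mean: float
    sd: float
    z_score: float
    empirical_p: float
    n_exceedances: int
    n_trials: int
    histogram: dict[int, int] = field(default_factory=dict)
    sd_zero: bool = False


def mc_overlap_test(cfg: MCOverlapConfig) -> MCOverlapResult:
    """Monte Carlo null for the k-way overlap of fixed-size gene sets.

    Each trial draws the sets independently, uniformly without
    replacement, from the universe; the trial statistic is the size of
    the k-way intersection.  Reports the null mean and SD, the Z-score of
    the observed overlap, and an add-one-smoothed empirical upper-tail p
    ((exceedances + 1) / (trials + 1)) so a zero count is never reported
    as p = 0; ``n_exceedances`` preserves the raw count.
    """
    rng = fork_rng(cfg.seed, "mc_overlap_test")
    N = cfg.universe_size
    overlaps = np.empty(cfg.n_trials, dtype=np.int64)
    for t in range(cfg.n_trials):
        sets = [
            set(rng.choice(N, size=s, replace=False).tolist())
            for s in cfg.set_sizes
        ]
        overlaps[t] = len(k_way_intersection(sets))
    mean = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1)) if cfg.n_trials > 1 else 0.0
    if sd == 0:
        z = float("inf") if cfg.observed_overlap > mean else 0.0
        sd_zero = True
    else:
        z = (cfg.observed_overlap - mean) / sd
        sd_zero = False
    n_exc = int((overlaps >= cfg.observed_overlap).sum())
    p = (n_exc + 1) / (cfg.n_trials + 1)
    values, counts = np.unique(overlaps, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return MCOverlapResult(
        mean=mean, sd=sd, z_score=float(z), empirical_p=float(p),
        n_exceedances=n_exc, n_trials=cfg.n_trials, histogram=hist,
        sd_zero=sd_zero,
    )


def expected_overlap(cfg: MCOverlapConfig) -> float:
    """Closed-form null mean: N * prod(n_i / N) (independent inclusion)."""
    N = cfg.universe_size
    prob = 1.0
    for s in cfg.set_sizes:
        prob *= s / N
    return N * prob
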