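"""Independent oracles: exhaustive/brute-force reference implementations
kept deliberately separate from the library's algorithms."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.stats import hypergeom

from limbloss.ancestors import encode
from limbloss.datamodel import CNEAlignment, DetectionConfig, Species


def oracle_scan(
    aln: CNEAlignment, species: list[Species], cfg: DetectionConfig
) -> dict[str, bool]:
    """Exhaustive per-window enumeration of both degeneration criteria.

    Counts matches window by window with direct summation (no sliding
    cumulative sums) — an independent path to the same definition.
    """
    anc = encode(aln.ancestors[cfg.comparison_node])
    anc_cols = np.nonzero(anc != 4)[0]
    enc = {n: encode(s) for n, s in aln.sequences.items()}
    limbed = [s.name for s in species if not s.is_limbless and s.name in enc]
    limbless = [s.name for s in species if s.is_limbless]

    def matches(name: str, cols: np.ndarray) -> int:
        a, b = enc[name][cols], anc[cols]
        return int(((a == b) & (a < 4) & (b < 4)).sum())

    out: dict[str, bool] = {}
    for name in limbless:
        if name not in enc:
            out[name] = False
            continue
        deg = False
        for w, lim_min, crit in (
            (cfg.window_short, cfg.limbed_conserved_min_short, "i"),
            (cfg.window_long, cfg.limbed_conserved_min_long, "ii"),
        ):
            if deg:
                break
            for o in range(0, len(anc_cols) - w + 1, cfg.step):
                cols = anc_cols[o : o + w]
                support = sum(1 for lm in limbed if matches(lm, cols) >= lim_min)
                if support < cfg.min_limbed_species:
                    continue
                if crit == "i":
                    if matches(name, cols) <= cfg.limbless_identity_max_short:
                        deg = True
                        break
                else:
                    gaps = int((enc[name][cols] >= 4).sum())
                    if gaps >= math.ceil(cfg.absent_fraction * w):
                        deg = True
                        break
        out[name] = deg
    return out


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration: sum of all
    table probabilities not exceeding the observed one (R convention)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, r1, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, float(total))


def oracle_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P[overlap >= k] by direct pmf summation."""
    return float(
        sum(hypergeom(N, K, n).pmf(x) for x in range(k, min(K, n) + 1))
    )


def oracle_fitch_min_score(
    topology, leaf_states: dict[str, str], states: str = "ACGT-"
) -> int:
    """Minimum parsimony changes for one column by enumerating every
    internal labelling of a (nested-tuple) topology."""
    internal: list = []

    def collect(node):
        if isinstance(node, tuple):
            internal.append(node)
            for ch in node:
                collect(ch)

    collect(topology)

    def score(node, assign) -> tuple[int, str]:
        if isinstance(node, str):
            return 0, leaf_states[node]
        own = assign[id(node)]
        total = 0
        for ch in node:
            s, st = score(ch, assign)
            total += s + (st != own)
        return total, own

    best = None
    for combo in product(states, repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        total, _ = score(topology, assign)
        best = total if best is None else min(best, total)
    return best
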