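"""General time-reversible (GTR) nucleotide substitution machinery.

The model is the standard continuous-time reversible chain on {A, C, G, T}
with six exchangeabilities and a stationary base-frequency vector.  The
rate matrix is normalised to one expected substitution per site per unit
branch length, so branch lengths are in expected substitutions.  Site
evolution is independent per site (no indels, no rate heterogeneity);
transition probabilities come from the matrix exponential of the rate
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .datamodel import ValidationError

#: exchangeability order: AC, AG, AT, CG, CT, GT
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRParams:
    """Six exchangeabilities (AC, AG, AT, CG, CT, GT) and base frequencies
    (A, C, G, T).  Defaults are Jukes-Cantor: all rates and frequencies
    equal."""

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_frequencies: tuple[float, ...] = (0.25,) * 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or len(self.base_frequencies) != 4:
            raise ValidationError("GTR needs 6 exchangeabilities and 4 frequencies")
        if any(x < 0 for x in self.exchangeabilities):
            raise ValidationError("exchangeabilities must be nonnegative")
        if not any(x > 0 for x in self.exchangeabilities):
            raise ValidationError("at least one exchangeability must be positive")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValidationError("base frequencies must sum to 1")
        if any(f < 0 for f in self.base_frequencies):
            raise ValidationError("base frequencies must be nonnegative")


JC = GTRParams()


def rate_matrix(params: GTRParams) -> np.ndarray:
    """Normalised 4x4 GTR rate matrix Q (rows sum to 0, mean rate 1)."""
    pi = np.asarray(params.base_frequencies, dtype=float)
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(params.exchangeabilities, PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValidationError("degenerate GTR rate matrix")
    return Q / mean_rate


def transition_matrix(Q: np.ndarray, d: float) -> np.ndarray:
    """P(d) = exp(Q d) for branch length d in expected substitutions."""
    if d < 0:
        raise ValidationError("branch length must be nonnegative")
    if d == 0:
        return np.eye(4)
    return expm(Q * d)


def sample_root(params: GTRParams, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a root sequence (codes 0-3) from the stationary frequencies."""
    return rng.choice(4, size=length, p=np.asarray(params.base_frequencies))


def evolve(parent: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence one branch under transition matrix P.

    Gap (4) and N (5) codes pass through unchanged.
    """
    child = parent.copy()
    bases = parent < 4
    if bases.any():
        cum = np.cumsum(P, axis=1)
        u = rng.random(int(bases.sum()))
        rows = cum[parent[bases]]
        child[bases] = (u[:, None] > rows).sum(axis=1).astype(parent.dtype)
    return child


def jc_expected_identity(d: float) -> float:
    """Closed-form expected identity to the ancestor after branch length d
    under Jukes-Cantor: 1/4 + 3/4 * exp(-4 d / 3)."""
    return 0.25 + 0.75 * float(np.exp(-4.0 * d / 3.0))
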