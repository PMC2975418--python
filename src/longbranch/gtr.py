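"""General time-reversible (GTR) nucleotide substitution model.

The model is parameterized by stationary frequencies ``pi`` over
(A, C, G, T) and six exchangeabilities (AC, AG, AT, CG, CT, GT).  The
rate matrix Q has off-diagonals ``Q_ij = r_ij * pi_j`` and is rescaled
so that one unit of branch length equals one expected substitution per
site at stationarity.  Reversibility (detailed balance) makes the
symmetrized matrix ``diag(pi)^1/2 Q diag(pi)^-1/2`` real-symmetric, so
transition matrices are computed through a real eigendecomposition.

Indel parameters ride along on the model because the simulator treats
the indel rate as relative to the substitution rate (lambda = 0.1 means
one indel event per ten substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NUCLEOTIDES = "ACGT"
EXCH_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

__all__ = ["GTRModel", "NUCLEOTIDES", "EXCH_PAIRS", "build_q_matrix", "transition_matrix"]


@dataclass(frozen=True)
class GTRModel:
    """GTR substitution model plus indel parameters.

    Parameters
    ----------
    pi : tuple of four floats
        Stationary frequencies for A, C, G, T.  Must be positive; they
        are renormalized to sum to one exactly.
    exch : tuple of six floats
        Exchangeabilities for AC, AG, AT, CG, CT, GT.  Must be positive.
    indel_rate : float
        Indel events per substitution (lambda); 0 disables indels.
    indel_length_mean : float
        Mean of the geometric indel length distribution, >= 1.
    """

    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exch: tuple[float, float, float, float, float, float] = (1.0,) * 6
    indel_rate: float = 0.0
    indel_length_mean: float = 1.0

    def __post_init__(self):
        pi = tuple(float(x) for x in self.pi)
        exch = tuple(float(x) for x in self.exch)
        if len(pi) != 4 or any(x <= 0 for x in pi):
            raise ValueError(f"pi must be four positive frequencies, got {pi}")
        if abs(sum(pi) - 1.0) > 1e-6:
            raise ValueError(f"pi must sum to 1, got sum {sum(pi)!r}")
        total = sum(pi)
        pi = tuple(x / total for x in pi)
        if len(exch) != 6 or any(x <= 0 for x in exch):
            raise ValueError(f"exch must be six positive rates, got {exch}")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "exch", exch)

    @classmethod
    def jukes_cantor(cls, **kwargs) -> "GTRModel":
        """Equal frequencies, equal exchangeabilities (JC69 limit)."""
        return cls(**kwargs)

    @classmethod
    def zone_study(cls, indel_rate: float = 0.1) -> "GTRModel":
        """The model used for the six-taxon zone-tree simulation study.

        Frequencies 0.2/0.3/0.3/0.2 are stated for A, C, T, G order and
        re-ordered here to the internal (A, C, G, T) convention, i.e.
        pi_A=0.2, pi_C=0.3, pi_G=0.2, pi_T=0.3; exchangeabilities are
        1.5, 3.0, 0.9, 1.2, 2.5, 1.0 for AC, AG, AT, CG, CT, GT; the
        indel rate lambda defaults to 0.1 (one indel per ten
        substitutions).
        """
        return cls(
            pi=(0.2, 0.3, 0.2, 0.3),
            exch=(1.5, 3.0, 0.9, 1.2, 2.5, 1.0),
            indel_rate=indel_rate,
        )

    def q_matrix(self) -> np.ndarray:
        return build_q_matrix(self)

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)


def build_q_matrix(model: GTRModel) -> np.ndarray:
    """Rate matrix with unit expected substitution rate at stationarity."""
    pi = np.asarray(model.pi, dtype=float)
    r = np.zeros((4, 4))
    (r[0, 1], r[0, 2], r[0, 3], r[1, 2], r[1, 3], r[2, 3]) = model.exch
    r = r + r.T
    q = r * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


@lru_cache(maxsize=64)
def _eigensystem(model: GTRModel):
    """Real spectral decomposition of Q via pi-symmetrization.

    Returns (lam, left, right) such that P(t) = (left * exp(lam t)) @ right.
    """
    q = build_q_matrix(model)
    d = np.sqrt(np.asarray(model.pi))
    s = q * d[:, None] / d[None, :]
    s = (s + s.T) / 2.0
    lam, u = np.linalg.eigh(s)
    left = u / d[:, None]
    right = u.T * d[None, :]
    return lam, left, right


def transition_matrix(model: GTRModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clamped at 0."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    lam, left, right = _eigensystem(model)
    p = (left * np.exp(lam * t)) @ right
    return np.clip(p, 0.0, None)
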