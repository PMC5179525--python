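"""GY94-style codon rate matrices and their spectral decomposition.

The instantaneous rate from codon *i* to codon *j* is nonzero only for
single-nucleotide changes and equals

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

(kappa: transition/transversion rate ratio; omega = dN/dS). The chain is
time-reversible with stationary distribution pi, so the symmetrized matrix
D^{1/2} Q D^{-1/2} (D = diag(pi)) admits a real eigendecomposition, which
makes the transition probabilities P(t) = exp(Qt) cheap to evaluate for
many branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geneticcode import IS_NONSYNONYMOUS, IS_TRANSITION, N_CODONS, SINGLE_DIFF


def _check_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have length {N_CODONS}, got shape {pi.shape}")
    if np.any(pi <= 0):
        raise ValueError("codon frequencies must all be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"codon frequencies must sum to 1 (got {pi.sum():.10f})")
    return pi


def equal_frequencies() -> np.ndarray:
    """Uniform frequency over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """61x61 GY94 rate matrix; rows sum to zero.

    With ``scale=True`` the matrix is normalized so the expected number of
    substitutions per codon per unit time is 1. For mixture models use
    :func:`build_class_matrices`, which applies a single mixture-level
    scaling factor to all classes.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = _check_pi(pi)
    q = np.where(SINGLE_DIFF, pi[None, :], 0.0)
    q = q * np.where(IS_TRANSITION, kappa, 1.0)
    q = q * np.where(IS_NONSYNONYMOUS, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -float(pi @ np.diag(q))
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        q /= rate
    return q


def build_class_matrices(
    kappa: float,
    omegas: np.ndarray,
    proportions: np.ndarray,
    pi: np.ndarray,
) -> list[np.ndarray]:
    """Per-class rate matrices sharing one mixture-level scaling.

    Every class matrix is divided by the same factor, chosen so that the
    proportion-weighted expected substitution rate across classes is 1
    (the convention used by codeml for site-class mixtures).
    """
    pi = _check_pi(pi)
    proportions = np.asarray(proportions, dtype=float)
    if np.any(proportions < 0) or abs(proportions.sum() - 1.0) > 1e-8:
        raise ValueError("class proportions must be non-negative and sum to 1")
    qs = [build_rate_matrix(kappa, w, pi, scale=False) for w in np.asarray(omegas, float)]
    rates = np.array([-float(pi @ np.diag(q)) for q in qs])
    mixture_rate = float(proportions @ rates)
    if mixture_rate <= 0:
        raise ValueError("mixture has zero expected substitution rate")
    return [q / mixture_rate for q in qs]


@dataclass
class SpectralMatrix:
    """Eigendecomposition of a reversible rate matrix.

    ``P(t) = left @ diag(exp(eigvals * t)) @ right`` where
    ``left = D^{-1/2} U`` and ``right = U.T D^{1/2}``.
    """

    eigvals: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @classmethod
    def from_rate_matrix(cls, q: np.ndarray, pi: np.ndarray) -> "SpectralMatrix":
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry against round-off
        eigvals, u = np.linalg.eigh(sym)
        return cls(eigvals=eigvals, left=u / sqrt_pi[:, None], right=u.T * sqrt_pi[None, :])

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, small negative round-off clipped."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self.left * np.exp(self.eigvals * t)[None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p
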