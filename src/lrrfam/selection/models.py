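"""Codon site-model specifications (M0, M1a, M2a, M3, M7, M8).

Each model defines how ω = dN/dS varies across alignment sites:

* M0 — one ω shared by all sites.
* M1 (nearly neutral) — two classes: ω0 ∈ (0, 1) with proportion p0, ω1 = 1.
* M2 (positive selection) — M1 plus a third class with ω2 ≥ 1.
* M3 (discrete) — three free ω classes with free proportions.
* M7 (beta) — ω ~ Beta(p, q) on (0, 1), discretized into equal-probability
  categories (category value = mean of its bin).
* M8 (beta & ω) — M7 for a proportion p0 of sites plus one class ωs ≥ 1.

The module maps each model to a bounded free-parameter vector suitable for
box-constrained quasi-Newton optimization. Proportion simplices use a
stick-breaking parameterization so every free parameter lives in a box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc

MODEL_NAMES = ("M0", "M1", "M2", "M3", "M7", "M8")

_EPS = 1e-6


@dataclass(frozen=True)
class FreeParam:
    key: str
    lower: float
    upper: float
    init: float


# free parameters per model, in packing order (kappa always first)
_FREE: dict[str, tuple[FreeParam, ...]] = {
    "M0": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("omega", _EPS, 50.0, 0.4),
    ),
    "M1": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("omega0", _EPS, 1.0 - _EPS, 0.2),
        FreeParam("p0", _EPS, 1.0 - _EPS, 0.7),
    ),
    "M2": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("omega0", _EPS, 1.0 - _EPS, 0.2),
        FreeParam("s0", 0.0, 1.0, 0.6),
        FreeParam("s1", 0.0, 1.0, 0.75),
        FreeParam("omega2", 1.0, 50.0, 2.0),
    ),
    "M3": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("omega0", 0.0, 50.0, 0.05),
        FreeParam("omega1", 0.0, 50.0, 0.3),
        FreeParam("omega2", 0.0, 50.0, 1.0),
        FreeParam("s0", 0.0, 1.0, 1.0 / 3.0),
        FreeParam("s1", 0.0, 1.0, 0.5),
    ),
    "M7": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("p", 0.005, 100.0, 0.5),
        FreeParam("q", 0.005, 100.0, 1.5),
    ),
    "M8": (
        FreeParam("kappa", 0.05, 100.0, 2.0),
        FreeParam("p", 0.005, 100.0, 0.5),
        FreeParam("q", 0.005, 100.0, 1.5),
        FreeParam("p0", 0.0, 1.0, 0.9),
        FreeParam("omega_s", 1.0, 50.0, 2.0),
    ),
}


@dataclass(frozen=True)
class SiteModelSpec:
    """One of the six site models plus shared fitting conventions.

    codon_freq: "F3x4" (position-specific nucleotide frequencies, the
    default) or "equal" (uniform over the 61 sense codons).
    n_beta_categories: discretization resolution for the beta models.
    """

    name: str
    codon_freq: str = "F3x4"
    n_beta_categories: int = 10

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown site model {self.name!r}; choose from {MODEL_NAMES}")
        if self.codon_freq not in ("F3x4", "equal"):
            raise ValueError("codon_freq must be 'F3x4' or 'equal'")
        if self.n_beta_categories < 2:
            raise ValueError("need at least 2 beta categories")

    @property
    def free_params(self) -> tuple[FreeParam, ...]:
        return _FREE[self.name]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def bounds(self) -> list[tuple[float, float]]:
        return [(fp.lower, fp.upper) for fp in self.free_params]

    def default_theta(self) -> np.ndarray:
        return np.array([fp.init for fp in self.free_params])

    def theta_to_params(self, theta: np.ndarray) -> dict[str, float]:
        return {fp.key: float(v) for fp, v in zip(self.free_params, theta)}

    def class_distribution(self, params: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """(omegas, proportions) of the site-class mixture for given parameters."""
        name = self.name
        if name == "M0":
            return np.array([params["omega"]]), np.array([1.0])
        if name == "M1":
            p0 = params["p0"]
            return np.array([params["omega0"], 1.0]), np.array([p0, 1.0 - p0])
        if name == "M2":
            p0, p1, p2 = _stick_break(params["s0"], params["s1"])
            return (
                np.array([params["omega0"], 1.0, params["omega2"]]),
                np.array([p0, p1, p2]),
            )
        if name == "M3":
            p0, p1, p2 = _stick_break(params["s0"], params["s1"])
            return (
                np.array([params["omega0"], params["omega1"], params["omega2"]]),
                np.array([p0, p1, p2]),
            )
        if name == "M7":
            omegas = discretize_beta(params["p"], params["q"], self.n_beta_categories)
            k = self.n_beta_categories
            return omegas, np.full(k, 1.0 / k)
        if name == "M8":
            k = self.n_beta_categories
            omegas = discretize_beta(params["p"], params["q"], k)
            p0 = params["p0"]
            return (
                np.append(omegas, params["omega_s"]),
                np.append(np.full(k, p0 / k), 1.0 - p0),
            )
        raise AssertionError(name)

    def positive_class_mask(self, params: dict[str, float]) -> np.ndarray:
        """Boolean mask over classes with ω strictly above 1."""
        omegas, _ = self.class_distribution(params)
        return omegas > 1.0


def _stick_break(s0: float, s1: float) -> tuple[float, float, float]:
    p0 = s0
    p1 = (1.0 - s0) * s1
    return p0, p1, 1.0 - p0 - p1


def stick_from_proportions(p0: float, p1: float) -> tuple[float, float]:
    """Inverse of the stick-breaking map, for warm starts."""
    s0 = min(max(p0, 0.0), 1.0)
    rest = 1.0 - s0
    s1 = min(max(p1 / rest, 0.0), 1.0) if rest > 0 else 0.0
    return s0, s1


def discretize_beta(p: float, q: float, ncat: int) -> np.ndarray:
    """Equal-probability discretization of Beta(p, q); category value is the
    conditional mean of ω within each bin (the codeml convention)."""
    from scipy.stats import beta as beta_dist

    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    # E[X | a < X <= b] for Beta(p, q) via the regularized incomplete beta of (p+1, q)
    upper_mass = betainc(p + 1.0, q, edges)
    mean = p / (p + q)
    means = mean * np.diff(upper_mass) * ncat
    return np.clip(means, 0.0, 1.0)


NESTED_PAIRS: dict[tuple[str, str], int] = {
    ("M0", "M3"): 4,
    ("M1", "M2"): 2,
    ("M7", "M8"): 2,
}
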