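"""Simulation-based parameter-recovery experiments for the site models.

Each experiment simulates replicate codon alignments on fresh random trees
under a fully specified site model, refits that model, and reports the
replicate estimates. Replicate randomness derives from a single base seed
through numpy's SeedSequence spawning, so the whole experiment is
reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolve import random_tree, simulate_alignment
from .fit import fit_model
from .models import SiteModelSpec


@dataclass
class RecoveryResult:
    model: str
    true_params: dict[str, float]
    estimates: list[dict[str, float]]
    n_replicates: int
    n_taxa: int
    n_codons: int

    def mean(self, key: str) -> float:
        return float(np.mean([e[key] for e in self.estimates]))


def _replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), replicate]))


def m0_recovery(
    omega: float,
    *,
    base_seed: int = 1,
    n_replicates: int = 20,
    n_taxa: int = 8,
    n_codons: int = 300,
    kappa: float = 2.0,
    total_tree_length: float = 2.0,
) -> RecoveryResult:
    """Simulate under M0 with the given ω on random trees and refit M0."""
    spec = SiteModelSpec("M0", codon_freq="equal")
    estimates = []
    for rep in range(1, n_replicates + 1):
        rng = _replicate_rng(base_seed, rep)
        nwk = random_tree(n_taxa, rng, total_length=total_tree_length)
        aln, _ = simulate_alignment(nwk, kappa, [omega], [1.0], n_codons, rng)
        fit = fit_model(aln, nwk, spec, n_starts=1, seed=rep)
        estimates.append({"omega": fit.params["omega"], "kappa": fit.kappa})
    return RecoveryResult("M0", {"omega": omega, "kappa": kappa}, estimates,
                          n_replicates, n_taxa, n_codons)


def m1_recovery(
    omega0: float,
    p0: float,
    *,
    base_seed: int = 1,
    n_replicates: int = 20,
    n_taxa: int = 8,
    n_codons: int = 500,
    kappa: float = 2.0,
    total_tree_length: float = 2.0,
) -> RecoveryResult:
    """Simulate under M1 (nearly neutral) and refit M1."""
    spec = SiteModelSpec("M1", codon_freq="equal")
    estimates = []
    for rep in range(1, n_replicates + 1):
        rng = _replicate_rng(base_seed, rep)
        nwk = random_tree(n_taxa, rng, total_length=total_tree_length)
        aln, _ = simulate_alignment(
            nwk, kappa, [omega0, 1.0], [p0, 1.0 - p0], n_codons, rng
        )
        fit = fit_model(aln, nwk, spec, n_starts=1, seed=rep)
        estimates.append(
            {"omega0": fit.params["omega0"], "p0": fit.params["p0"], "kappa": fit.kappa}
        )
    return RecoveryResult("M1", {"omega0": omega0, "p0": p0, "kappa": kappa},
                          estimates, n_replicates, n_taxa, n_codons)
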