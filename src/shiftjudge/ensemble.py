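"""Boltzmann weighting and conformer averaging of shielding constants.

For a conformer ensemble with relative Gibbs free energies ``E_n`` the
population weight of conformer ``n`` at temperature ``T`` is

    w_n = exp(-E_n / RT) / Σ_m exp(-E_m / RT)

and the ensemble shielding of nucleus ``i`` is the weighted mean
``σ_i = Σ_n w_n σ_n,i``. Energies are shifted by the ensemble minimum
before exponentiation — mathematically an identity, numerically the
standard guard against overflow for any finite input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .model import (
    KCAL_PER_MOL,
    GAS_CONSTANT,
    CandidateStructure,
    Nucleus,
    PipelineConfig,
)


@dataclass
class BoltzmannWeights:
    """Conformer populations of one candidate at one temperature."""

    candidate_id: str
    weights: dict[str, float]
    temperature: float


@dataclass
class AveragedShieldings:
    """Boltzmann-averaged isotropic shieldings (ppm) of one candidate."""

    candidate_id: str
    sigma: dict[Nucleus, float]

    def by_element(self, element: str) -> dict[Nucleus, float]:
        return {n: s for n, s in self.sigma.items() if n.element == element}


def apply_energy_window(
    candidate: CandidateStructure, window: float
) -> CandidateStructure:
    """Drop conformers above ``window`` kcal·mol⁻¹ relative Gibbs energy.

    Energies are re-zeroed first, so the minimum-energy conformer (and any
    degenerate minima) always survives, including at ``window == 0``.
    """
    if window < 0:
        raise ValidationError(f"energy window must be >= 0, got {window}")
    cand = candidate.normalized()
    threshold = window * KCAL_PER_MOL
    kept = [c for c in cand.conformers if c.energy <= threshold]
    return CandidateStructure(cand.candidate_id, cand.compound_id, kept)


def boltzmann_weights(
    energies,
    temperature: float = 298.0,
    gas_constant: float = GAS_CONSTANT,
) -> np.ndarray:
    """Population weights for relative Gibbs energies in J·mol⁻¹.

    Returns an array summing to 1. Weights are translation invariant:
    adding any constant to all energies leaves them unchanged.
    """
    energies = np.asarray(list(energies), dtype=float)
    if energies.size == 0:
        raise InsufficientDataError("empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValidationError("energies must be finite")
    if not temperature > 0:
        raise ValidationError(f"temperature must be > 0, got {temperature}")
    beta = 1.0 / (gas_constant * temperature)
    factors = np.exp(-(energies - energies.min()) * beta)
    return factors / factors.sum()


def candidate_weights(
    candidate: CandidateStructure, config: PipelineConfig
) -> BoltzmannWeights:
    """Boltzmann weights of a candidate's conformers, keyed by conformer id."""
    w = boltzmann_weights(
        [c.energy for c in candidate.conformers],
        temperature=config.temperature,
        gas_constant=config.gas_constant,
    )
    return BoltzmannWeights(
        candidate_id=candidate.candidate_id,
        weights={c.conformer_id: float(wi) for c, wi in zip(candidate.conformers, w)},
        temperature=config.temperature,
    )


def average_shieldings(
    candidate: CandidateStructure, weights: BoltzmannWeights
) -> AveragedShieldings:
    """Per-nucleus weighted mean of shieldings over the ensemble.

    Every averaged value lies in the convex hull of the per-conformer
    values for that nucleus.
    """
    ids = [c.conformer_id for c in candidate.conformers]
    if set(ids) != set(weights.weights):
        raise ValidationError(
            f"weights keyed by {sorted(weights.weights)} do not match "
            f"conformers {sorted(ids)} of candidate {candidate.candidate_id!r}"
        )
    w = np.array([weights.weights[i] for i in ids])
    sigma: dict[Nucleus, float] = {}
    for nucleus in candidate.nuclei():
        values = np.array([c.shieldings[nucleus] for c in candidate.conformers])
        sigma[nucleus] = float(w @ values)
    return AveragedShieldings(candidate.candidate_id, sigma)


def boltzmann_average(
    candidate: CandidateStructure, config: PipelineConfig
) -> AveragedShieldings:
    """Window → weight → average convenience composition."""
    windowed = apply_energy_window(candidate, config.energy_window)
    return average_shieldings(windowed, candidate_weights(windowed, config))
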