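"""Synthetic dataset generator for the verification pipeline.

Emulates the statistical structure of a GIAO-DFT shift-prediction study
without running any quantum chemistry: a true linear shielding–shift law
with negative slope near −1, a conformer ensemble whose relative Gibbs
energies spread over the 0–10 kcal/mol search window, per-conformer
shielding perturbations, per-nucleus Gaussian method noise, optional
masking of experimental entries (unknown shifts), plus decoy structures
with localized large perturbations and deliberate assignment swaps.

Everything is deterministic under the spec's seed (NumPy PCG64 via
``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .model import (
    KCAL_PER_MOL,
    CandidateStructure,
    ConformerRecord,
    ExperimentalTable,
    Nucleus,
    sort_nuclei,
)


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults are the study conditions.

    Per compound: 14 ¹H and 20 ¹³C nuclei (thirteen compounds then give a
    pool close to the ~188 ¹H / 265 ¹³C regime of a full alkaloid-series
    study). True slopes −1.05 with intercepts 31 ppm (¹H) / 185 ppm (¹³C)
    resemble typical GIAO-DFT correlations. Conformer energies are
    exponential (scale 2.5 kcal/mol) truncated to the 0–10 kcal/mol
    window. Per-nucleus noise of 0.15 / 2.0 ppm reproduces residual
    scatter at the few-tenths (¹H) and ~2 ppm (¹³C) level typical of
    scaled DFT shifts for this chemistry.
    """

    n_H: int = 14
    n_C: int = 20
    true_a_H: float = -1.05
    true_b_H: float = 31.0
    true_a_C: float = -1.05
    true_b_C: float = 185.0
    shift_range_H: tuple[float, float] = (2.5, 9.5)
    shift_range_C: tuple[float, float] = (20.0, 170.0)
    n_conformers: int = 5
    energy_scale: float = 2.5
    energy_window: float = 10.0
    conformer_sigma_spread: float = 0.3
    noise_sd_H: float = 0.15
    noise_sd_C: float = 2.0
    mask_fraction: float = 0.0
    seed: int = 0
    compound_id: str = "syn"
    candidate_id: str = "syn"

    def __post_init__(self) -> None:
        for name in ("shift_range_H", "shift_range_C"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValidationError(f"{name} must be a non-degenerate interval, got ({lo}, {hi})")
        for name in ("noise_sd_H", "noise_sd_C", "conformer_sigma_spread"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.mask_fraction < 1:
            raise ValidationError(f"mask_fraction must be in [0, 1), got {self.mask_fraction}")
        if self.n_H < 0 or self.n_C < 0 or self.n_H + self.n_C == 0:
            raise ValidationError("need at least one nucleus")
        if self.n_conformers < 1:
            raise ValidationError("need at least one conformer")
        if self.energy_scale <= 0 or self.energy_window < 0:
            raise ValidationError("energy_scale must be > 0 and energy_window >= 0")

    def true_params(self, element: str) -> tuple[float, float]:
        if element == "H":
            return self.true_a_H, self.true_b_H
        return self.true_a_C, self.true_b_C

    def noise_sd(self, element: str) -> float:
        return self.noise_sd_H if element == "H" else self.noise_sd_C


@dataclass
class GroundTruth:
    """Everything needed to score pipeline output against the simulation."""

    true_shifts: dict[Nucleus, float]
    true_params: dict[str, tuple[float, float]]
    masked: list[Nucleus] = field(default_factory=list)
    decoy_perturbations: dict[Nucleus, float] = field(default_factory=dict)
    swapped_pairs: list[tuple[Nucleus, Nucleus]] = field(default_factory=list)


def _truncated_exponential(rng: np.random.Generator, scale: float, upper: float, size: int) -> np.ndarray:
    """Inverse-CDF sample of Exp(scale) truncated to [0, upper]."""
    u = rng.random(size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CandidateStructure, ExperimentalTable, GroundTruth]:
    """Draw one candidate ensemble + experimental table + ground truth.

    True shifts are uniform within the element's range. Per-conformer
    shielding of nucleus i in conformer n is

        σ_n,i = a·δ_i + b + spread·z_{i,n} + |a|·ε_i

    with z per-conformer standard normal and ε per-nucleus method noise
    shared across conformers. ``noise_sd`` is specified on the chemical
    shift scale (the observable a practitioner quotes residuals in), so
    it enters the shielding through the slope magnitude; the scaled-shift
    residual scatter then approaches ``noise_sd`` for large n. The
    experimental table holds the true shifts with ``mask_fraction`` of
    entries withheld per element.
    """
    rng = np.random.default_rng(spec.seed)
    true_shifts: dict[Nucleus, float] = {}
    for element, count in (("H", spec.n_H), ("C", spec.n_C)):
        lo, hi = spec.shift_range_H if element == "H" else spec.shift_range_C
        values = rng.uniform(lo, hi, size=count)
        for idx, value in enumerate(values, start=1):
            true_shifts[Nucleus(element, f"{element}-{idx}")] = float(value)

    energies_kcal = _truncated_exponential(
        rng, spec.energy_scale, spec.energy_window, spec.n_conformers
    )
    energies_kcal -= energies_kcal.min()
    energies = energies_kcal * KCAL_PER_MOL

    nuclei = sort_nuclei(true_shifts)
    noise = {
        nuc: rng.normal(0.0, spec.noise_sd(nuc.element)) if spec.noise_sd(nuc.element) > 0 else 0.0
        for nuc in nuclei
    }
    conformers: list[ConformerRecord] = []
    for n, energy in enumerate(energies, start=1):
        shieldings: dict[Nucleus, float] = {}
        for nuc in nuclei:
            a, b = spec.true_params(nuc.element)
            perturbation = (
                rng.normal(0.0, spec.conformer_sigma_spread)
                if spec.conformer_sigma_spread > 0
                else 0.0
            )
            shieldings[nuc] = a * true_shifts[nuc] + b + perturbation + abs(a) * noise[nuc]
        conformers.append(ConformerRecord(f"conf-{n}", float(energy), shieldings))
    candidate = CandidateStructure(spec.candidate_id, spec.compound_id, conformers)

    masked: list[Nucleus] = []
    shifts: dict[Nucleus, Optional[float]] = {n: true_shifts[n] for n in nuclei}
    if spec.mask_fraction > 0:
        for element, count in (("H", spec.n_H), ("C", spec.n_C)):
            element_nuclei = [n for n in nuclei if n.element == element]
            k = int(np.floor(spec.mask_fraction * count))
            if k:
                chosen = rng.choice(len(element_nuclei), size=k, replace=False)
                for idx in sorted(chosen):
                    shifts[element_nuclei[idx]] = None
                    masked.append(element_nuclei[idx])
    table = ExperimentalTable(spec.compound_id, shifts)
    truth = GroundTruth(
        true_shifts=true_shifts,
        true_params={"H": spec.true_params("H"), "C": spec.true_params("C")},
        masked=masked,
    )
    return candidate, table, truth


def make_decoy(
    candidate: CandidateStructure,
    truth: GroundTruth,
    k_nuclei: int,
    magnitude: float,
    seed: int,
    element: str = "C",
    candidate_id: Optional[str] = None,
) -> CandidateStructure:
    """Copy a candidate with ``k_nuclei`` shieldings displaced by ±magnitude.

    The displacement is ``magnitude`` ppm on the shift scale, converted to
    the shielding scale through |true slope|, with random sign, applied in
    every conformer — the signature of a locally wrong structural
    hypothesis (a few nuclei far off, the rest intact). Perturbed nuclei
    and their shielding-scale displacements are recorded in ``truth``.
    """
    pool = sort_nuclei(candidate.nuclei(element))
    if not 0 <= k_nuclei < len(pool):
        raise ValidationError(
            f"k_nuclei={k_nuclei} out of range for {len(pool)} {element} nuclei"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(pool), size=k_nuclei, replace=False)
    a_true = abs(truth.true_params[element][0])
    displacements = {
        pool[i]: float(rng.choice([-1.0, 1.0]) * magnitude * a_true)
        for i in sorted(chosen_idx)
    }
    conformers = [
        ConformerRecord(
            c.conformer_id,
            c.energy,
            {n: s + displacements.get(n, 0.0) for n, s in c.shieldings.items()},
        )
        for c in candidate.conformers
    ]
    truth.decoy_perturbations.update(displacements)
    return CandidateStructure(
        candidate_id or f"{candidate.candidate_id}_decoy",
        candidate.compound_id,
        conformers,
    )


def apply_swap(
    table: ExperimentalTable,
    label_pair: tuple[Nucleus, Nucleus],
    truth: Optional[GroundTruth] = None,
) -> ExperimentalTable:
    """Exchange the observed shifts of two same-element assigned nuclei.

    Models an original misassignment; applying the same swap twice is the
    identity. Raises if either label is absent or unassigned.
    """
    first, second = label_pair
    if first.element != second.element:
        raise ValidationError(f"swap pair mixes elements: {first!r}, {second!r}")
    for nucleus in label_pair:
        if nucleus not in table.shifts:
            raise ValidationError(f"swap label {nucleus!r} absent from table")
        if table.shifts[nucleus] is None:
            raise ValidationError(f"swap label {nucleus!r} has no assigned shift")
    shifts = dict(table.shifts)
    shifts[first], shifts[second] = shifts[second], shifts[first]
    if truth is not None:
        truth.swapped_pairs.append((first, second))
    return ExperimentalTable(table.compound_id, shifts, dict(table.groups))
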