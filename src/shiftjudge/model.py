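"""Domain types for NMR chemical-shift structure verification.

The pipeline compares quantum-chemistry isotropic shieldings of one or
more candidate structures (conformer ensembles with relative Gibbs free
energies) against experimental ¹H/¹³C chemical-shift assignment tables.
These dataclasses carry that data with the invariants validated on
construction.

Internal units: energies in J·mol⁻¹ (relative Gibbs free energies),
shieldings and shifts in ppm, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError

#: conversion factors to J·mol⁻¹
KCAL_PER_MOL = 4184.0
HARTREE_PER_MOL = 2_625_499.6

#: molar gas constant, J·K⁻¹·mol⁻¹
GAS_CONSTANT = 8.31446

ELEMENTS = ("H", "C")

#: validation gates for observed shifts, ppm
SHIFT_BOUNDS = {"H": (-2.0, 20.0), "C": (-20.0, 250.0)}


@dataclass(frozen=True, eq=False)
class Nucleus:
    """A nucleus identified by element and atom label (locant style, e.g. ``C-9a``).

    Labels compare case-insensitively; ``Nucleus("C", "c-9A")`` equals
    ``Nucleus("C", "C-9a")``. The compound namespace lives on the table or
    candidate holding the nucleus, not here.
    """

    element: str
    label: str

    def __post_init__(self) -> None:
        element = self.element.strip().upper()
        if element not in ELEMENTS:
            raise ValidationError(
                f"unsupported element {self.element!r}; expected one of {ELEMENTS}"
            )
        label = self.label.strip()
        if not label:
            raise ValidationError("empty atom label")
        object.__setattr__(self, "element", element)
        object.__setattr__(self, "label", label)

    @property
    def key(self) -> tuple[str, str]:
        """Canonical (element, upper-cased label) matching key."""
        return (self.element, self.label.upper())

    def __hash__(self) -> int:
        return hash(self.key)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Nucleus) and self.key == other.key

    def __repr__(self) -> str:
        return f"{self.element}:{self.label}"


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass
class ConformerRecord:
    """One conformer of one candidate: relative Gibbs energy + per-nucleus shieldings.

    ``energy`` is in J·mol⁻¹ relative to the candidate's minimum-energy
    conformer (``None`` while unset, e.g. straight out of a log parser).
    """

    conformer_id: str
    energy: Optional[float]
    shieldings: dict[Nucleus, float]

    def __post_init__(self) -> None:
        if self.energy is not None:
            self.energy = _check_finite(f"energy of conformer {self.conformer_id!r}", self.energy)
        if not self.shieldings:
            raise ValidationError(f"conformer {self.conformer_id!r} has no shieldings")
        for nuc, sigma in self.shieldings.items():
            self.shieldings[nuc] = _check_finite(f"shielding of {nuc!r}", sigma)

    def nuclei(self, element: Optional[str] = None) -> set[Nucleus]:
        if element is None:
            return set(self.shieldings)
        return {n for n in self.shieldings if n.element == element}


@dataclass
class CandidateStructure:
    """A structural hypothesis for a compound: a conformer ensemble.

    All conformers must carry identical nucleus sets. Energies must be set
    and finite; call :meth:`normalized` to re-zero them to the ensemble
    minimum (Boltzmann weights depend only on energy differences, so
    absolute Gibbs energies are accepted).
    """

    candidate_id: str
    compound_id: str
    conformers: list[ConformerRecord]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValidationError(f"candidate {self.candidate_id!r} has no conformers")
        seen: set[str] = set()
        reference = self.conformers[0].nuclei()
        for conf in self.conformers:
            if conf.conformer_id in seen:
                raise ValidationError(
                    f"candidate {self.candidate_id!r}: duplicate conformer id {conf.conformer_id!r}"
                )
            seen.add(conf.conformer_id)
            if conf.energy is None:
                raise ValidationError(
                    f"candidate {self.candidate_id!r}: conformer {conf.conformer_id!r} has no energy"
                )
            if conf.nuclei() != reference:
                diff = conf.nuclei() ^ reference
                raise ValidationError(
                    f"candidate {self.candidate_id!r}: conformer {conf.conformer_id!r} "
                    f"nucleus set differs from siblings (symmetric difference: {sorted(n.key for n in diff)})"
                )

    def nuclei(self, element: Optional[str] = None) -> set[Nucleus]:
        return self.conformers[0].nuclei(element)

    def normalized(self) -> "CandidateStructure":
        """Return a copy with energies re-zeroed to the ensemble minimum."""
        emin = min(c.energy for c in self.conformers)  # type: ignore[type-var]
        return CandidateStructure(
            candidate_id=self.candidate_id,
            compound_id=self.compound_id,
            conformers=[
                ConformerRecord(c.conformer_id, c.energy - emin, dict(c.shieldings))
                for c in self.conformers
            ],
        )


@dataclass
class ExperimentalTable:
    """Per-compound map nucleus → observed shift, with missing entries and
    equivalence groups.

    ``shifts`` values are ppm or ``None`` for unassigned (missing) entries.
    ``groups`` joins equivalent nuclei (e.g. the three N-CH₃ protons) that
    share one observed shift; members must share one element and every
    assigned member must carry the same value.
    """

    compound_id: str
    shifts: dict[Nucleus, Optional[float]]
    groups: dict[str, tuple[Nucleus, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nuc, value in self.shifts.items():
            if value is None:
                continue
            value = _check_finite(f"shift of {nuc!r}", value)
            lo, hi = SHIFT_BOUNDS[nuc.element]
            if not lo <= value <= hi:
                raise ValidationError(
                    f"{self.compound_id}: shift of {nuc!r} = {value} ppm outside [{lo}, {hi}]"
                )
            self.shifts[nuc] = value
        normalized_groups: dict[str, tuple[Nucleus, ...]] = {}
        for label, members in self.groups.items():
            members = tuple(members)
            if len(members) < 2:
                raise ValidationError(f"group {label!r} needs at least 2 members")
            elements = {m.element for m in members}
            if len(elements) != 1:
                raise ValidationError(f"group {label!r} mixes elements {sorted(elements)}")
            for m in members:
                if m not in self.shifts:
                    raise ValidationError(f"group {label!r} member {m!r} absent from table")
            values = [self.shifts[m] for m in members if self.shifts[m] is not None]
            if values and max(values) - min(values) > 1e-9:
                raise ValidationError(
                    f"group {label!r} members carry inconsistent shifts {values}"
                )
            normalized_groups[label] = members
        self.groups = normalized_groups

    def grouped_nuclei(self) -> set[Nucleus]:
        """All nuclei that belong to some equivalence group."""
        return {m for members in self.groups.values() for m in members}

    def group_shift(self, label: str) -> Optional[float]:
        """The single observed shift of a group, or None if unassigned."""
        for member in self.groups[label]:
            value = self.shifts[member]
            if value is not None:
                return value
        return None

    def assigned(self, element: str) -> dict[Nucleus, float]:
        return {
            n: v for n, v in self.shifts.items() if n.element == element and v is not None
        }

    def missing(self, element: Optional[str] = None) -> list[Nucleus]:
        out = [
            n
            for n, v in self.shifts.items()
            if v is None and (element is None or n.element == element)
        ]
        return sorted(out, key=lambda n: n.key)


FIT_SCOPES = ("per_candidate", "pooled")


@dataclass
class PipelineConfig:
    """Tunable parameters of the verification pipeline.

    temperature : K, Boltzmann averaging temperature (default 298).
    gas_constant : J·K⁻¹·mol⁻¹ (8.31446).
    energy_window : kcal·mol⁻¹; conformers above this relative Gibbs energy
        are dropped before weighting (default 10, the usual search window).
    fit_scope : ``per_candidate`` fits the shielding→shift line per
        candidate structure; ``pooled`` fits one line per element across
        the whole dataset.
    outlier_k : flag a nucleus when |residual| > k·RMSD (default 2).
    min_improvement_h / min_improvement_c : ppm; an assignment swap is only
        suggested when it lowers CMAE by more than this (defaults at the
        noise floor of each element's typical CMAE).
    """

    temperature: float = 298.0
    gas_constant: float = GAS_CONSTANT
    energy_window: float = 10.0
    fit_scope: str = "per_candidate"
    outlier_k: float = 2.0
    min_improvement_h: float = 0.02
    min_improvement_c: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")
        if not self.gas_constant > 0:
            raise ValidationError(f"gas_constant must be > 0, got {self.gas_constant}")
        if self.energy_window < 0:
            raise ValidationError(f"energy_window must be >= 0, got {self.energy_window}")
        if self.fit_scope not in FIT_SCOPES:
            raise ValidationError(
                f"fit_scope must be one of {FIT_SCOPES}, got {self.fit_scope!r}"
            )
        if not self.outlier_k > 0:
            raise ValidationError(f"outlier_k must be > 0, got {self.outlier_k}")

    def min_improvement(self, element: str) -> float:
        return self.min_improvement_h if element == "H" else self.min_improvement_c


def sort_nuclei(nuclei: Iterable[Nucleus]) -> list[Nucleus]:
    """Deterministic ordering used throughout reports: by (element, label)."""
    return sorted(nuclei, key=lambda n: n.key)
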