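"""Shared fixtures: small hand-built ensembles and assignment tables."""

from __future__ import annotations

import pytest

from shiftjudge import (
    CandidateStructure,
    ConformerRecord,
    ExperimentalTable,
    Nucleus,
    PipelineConfig,
)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_candidate(
    shifts: dict[Nucleus, float],
    a: float,
    b_h: float = 31.0,
    b_c: float = 185.0,
    energies=(0.0,),
    candidate_id: str = "cand",
    compound_id: str = "cmpd",
    sigma_offsets=None,
) -> CandidateStructure:
    """Candidate whose shieldings follow σ = a·δ + b exactly, per conformer.

    ``sigma_offsets`` optionally adds a per-conformer constant to every
    shielding (to exercise averaging).
    """
    offsets = sigma_offsets or [0.0] * len(energies)
    conformers = []
    for idx, (energy, offset) in enumerate(zip(energies, offsets), start=1):
        shieldings = {
            nuc: a * delta + (b_h if nuc.element == "H" else b_c) + offset
            for nuc, delta in shifts.items()
        }
        conformers.append(ConformerRecord(f"conf-{idx}", energy, shieldings))
    return CandidateStructure(candidate_id, compound_id, conformers)


@pytest.fixture
def linear_system():
    """Exact linear 6-carbon / 4-proton system with its assignment table."""
    shifts = {
        Nucleus("C", f"C-{i}"): float(v)
        for i, v in enumerate([25.0, 60.0, 95.0, 120.0, 145.0, 165.0], start=1)
    }
    shifts.update(
        {Nucleus("H", f"H-{i}"): float(v) for i, v in enumerate([2.8, 4.1, 6.9, 8.5], start=1)}
    )
    candidate = make_candidate(shifts, a=-1.05)
    table = ExperimentalTable("cmpd", dict(shifts))
    return candidate, table, shifts
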