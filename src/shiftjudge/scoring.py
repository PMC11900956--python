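"""CMAE / RMSD / Pearson scoring of candidate structures.

The corrected mean absolute error removes slope/offset bias via the
element's scaling fit before averaging absolute residuals:

    CMAE = (1/n) Σ |δ_exp − (σ − b)/a|

and the root-mean-square deviation is taken between experimental and
scaled calculated shifts:

    RMSD = sqrt((1/n) Σ (δ_exp − δ_calc)²).

On the same residual set RMSD ≥ CMAE always (power-mean inequality).
Statistics are computed per element, never mixing ¹H and ¹³C; "pooled"
statistics pool compounds, not elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ensemble import AveragedShieldings, boltzmann_average
from .errors import InsufficientDataError, ValidationError
from .model import (
    ELEMENTS,
    CandidateStructure,
    ExperimentalTable,
    Nucleus,
    PipelineConfig,
)
from .scaling import ScalingFit, fit_scaling

logger = logging.getLogger(__name__)


def cmae(delta_exp, sigma, fit: ScalingFit) -> float:
    """Corrected mean absolute error, ppm."""
    x = np.asarray(list(delta_exp), dtype=float)
    y = np.asarray(list(sigma), dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty shift list")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if fit.a == 0:
        raise ValidationError("scaling fit has zero slope")
    return float(np.mean(np.abs(x - (y - fit.b) / fit.a)))


def rmsd(delta_exp, delta_calc) -> float:
    """Root-mean-square deviation between experimental and scaled shifts, ppm."""
    x = np.asarray(list(delta_exp), dtype=float)
    y = np.asarray(list(delta_calc), dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty shift list")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2:
        raise InsufficientDataError(f"need >= 2 points for correlation, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InsufficientDataError("zero variance input to correlation")
    return float(stats.pearsonr(xa, ya).statistic)


@dataclass
class ScoreReport:
    """Agreement statistics for one candidate and one element.

    Residuals are δ_exp − δ_calc per matched nucleus (equivalence groups
    appear once, keyed by the group label). When fewer than 2 nuclei
    match, the report is a null report: statistics are ``None`` and
    ``note`` says why.
    """

    candidate_id: str
    element: str
    n: int
    cmae: Optional[float]
    rmsd: Optional[float]
    pearson_r: Optional[float]
    residuals: dict[Nucleus, float] = field(default_factory=dict)
    fit: Optional[ScalingFit] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.cmae is not None and self.rmsd is not None:
            if self.rmsd + 1e-12 < self.cmae:
                raise ValidationError(
                    f"RMSD {self.rmsd} < CMAE {self.cmae}: impossible on one residual set"
                )
        if self.pearson_r is not None and abs(self.pearson_r) > 1 + 1e-12:
            raise ValidationError(f"|pearson_r| > 1: {self.pearson_r}")


def matched_pairs(
    sigma: AveragedShieldings,
    table: ExperimentalTable,
    element: str,
) -> tuple[list[Nucleus], np.ndarray, np.ndarray]:
    """Align averaged shieldings with assigned experimental shifts.

    Equivalence groups contribute a single pair: the group's one observed
    shift against the arithmetic mean of its members' averaged shieldings
    (the conventional treatment of rotationally averaged nuclei such as
    N-CH₃ protons), labelled by the group name. Missing entries and
    experimental labels with no computed counterpart are left out.

    Returns (labels, δ_exp, σ) in deterministic (element, label) order.
    """
    grouped = table.grouped_nuclei()
    pairs: list[tuple[Nucleus, float, float]] = []
    for group_label, members in table.groups.items():
        if members[0].element != element:
            continue
        observed = table.group_shift(group_label)
        if observed is None:
            continue
        if not all(m in sigma.sigma for m in members):
            continue
        mean_sigma = float(np.mean([sigma.sigma[m] for m in members]))
        pairs.append((Nucleus(element, group_label), observed, mean_sigma))
    for nucleus, observed in table.shifts.items():
        if nucleus.element != element or nucleus in grouped or observed is None:
            continue
        if nucleus not in sigma.sigma:
            continue
        pairs.append((nucleus, observed, sigma.sigma[nucleus]))
    pairs.sort(key=lambda p: p[0].key)
    labels = [p[0] for p in pairs]
    d = np.array([p[1] for p in pairs], dtype=float)
    s = np.array([p[2] for p in pairs], dtype=float)
    return labels, d, s


def score_pairs(
    candidate_id: str,
    element: str,
    labels: Sequence[Nucleus],
    delta_exp: np.ndarray,
    sigma: np.ndarray,
    fit: Optional[ScalingFit] = None,
) -> ScoreReport:
    """Score aligned pairs, fitting the scaling per candidate unless given."""
    n = int(len(labels))
    if n < 2:
        logger.info(
            "candidate %s %s: %d matched nuclei, insufficient data", candidate_id, element, n
        )
        return ScoreReport(candidate_id, element, n, None, None, None, {}, None,
                           note="insufficient data")
    if fit is None:
        fit = fit_scaling(delta_exp, sigma, element, scope_id=candidate_id)
    delta_calc = (sigma - fit.b) / fit.a
    residual = delta_exp - delta_calc
    try:
        r = pearson(delta_exp, delta_calc)
    except InsufficientDataError:
        r = None
    return ScoreReport(
        candidate_id=candidate_id,
        element=element,
        n=n,
        cmae=float(np.mean(np.abs(residual))),
        rmsd=float(np.sqrt(np.mean(residual**2))),
        pearson_r=r,
        residuals={lab: float(res) for lab, res in zip(labels, residual)},
        fit=fit,
    )


def score_candidate(
    candidate: CandidateStructure,
    table: ExperimentalTable,
    config: PipelineConfig,
    fits: Optional[dict[str, ScalingFit]] = None,
) -> dict[str, ScoreReport]:
    """Full per-candidate scoring: window → weights → average → fit → score.

    Returns one report per element ({"H": ..., "C": ...}). Pass ``fits``
    to score under externally determined (e.g. pooled) scaling parameters
    instead of refitting per candidate.
    """
    if candidate.compound_id != table.compound_id:
        raise ValidationError(
            f"candidate {candidate.candidate_id!r} is for compound "
            f"{candidate.compound_id!r}, table is for {table.compound_id!r}"
        )
    sigma = boltzmann_average(candidate, config)
    reports: dict[str, ScoreReport] = {}
    for element in ELEMENTS:
        labels, d, s = matched_pairs(sigma, table, element)
        fit = fits.get(element) if fits else None
        reports[element] = score_pairs(candidate.candidate_id, element, labels, d, s, fit=fit)
    return reports


def pooled_scores(
    candidates: Sequence[CandidateStructure],
    tables: dict[str, ExperimentalTable],
    config: PipelineConfig,
) -> tuple[dict[str, ScalingFit], dict[str, ScoreReport], dict[str, dict[str, ScoreReport]]]:
    """One scaling fit per element across all candidates, then score.

    Returns ``(fits, overall, per_candidate)`` where ``overall`` holds the
    dataset-wide CMAE/RMSD/r per element computed from the concatenated
    pairs under the pooled fit (its residual map is empty because nucleus
    labels repeat across compounds), and ``per_candidate`` holds each
    candidate's reports under the same pooled fit.
    """
    collected: dict[str, list[tuple[str, list[Nucleus], np.ndarray, np.ndarray]]] = {
        e: [] for e in ELEMENTS
    }
    for candidate in candidates:
        table = tables[candidate.compound_id]
        sigma = boltzmann_average(candidate, config)
        for element in ELEMENTS:
            labels, d, s = matched_pairs(sigma, table, element)
            collected[element].append((candidate.candidate_id, labels, d, s))
    fits: dict[str, ScalingFit] = {}
    overall: dict[str, ScoreReport] = {}
    for element in ELEMENTS:
        d_all = np.concatenate([d for _, _, d, _ in collected[element]]) if collected[element] else np.array([])
        s_all = np.concatenate([s for _, _, _, s in collected[element]]) if collected[element] else np.array([])
        if d_all.size < 2:
            overall[element] = ScoreReport("pooled", element, int(d_all.size),
                                           None, None, None, {}, None,
                                           note="insufficient data")
            continue
        fit = fit_scaling(d_all, s_all, element, scope_id="pooled")
        fits[element] = fit
        delta_calc = (s_all - fit.b) / fit.a
        residual = d_all - delta_calc
        overall[element] = ScoreReport(
            candidate_id="pooled",
            element=element,
            n=int(d_all.size),
            cmae=float(np.mean(np.abs(residual))),
            rmsd=float(np.sqrt(np.mean(residual**2))),
            pearson_r=pearson(d_all, delta_calc),
            residuals={},
            fit=fit,
        )
    per_candidate: dict[str, dict[str, ScoreReport]] = {}
    for candidate in candidates:
        per_candidate[candidate.candidate_id] = score_candidate(
            candidate, tables[candidate.compound_id], config, fits=fits or None
        )
    return fits, overall, per_candidate
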