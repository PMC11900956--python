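"""Structure discrimination and assignment diagnostics.

Rival structural hypotheses for one compound are ranked by an
element-balanced combined score; nuclei whose residuals stand out from
the candidate's own RMSD are flagged as outliers; pairwise swaps of
experimental assignments that lower the CMAE are proposed; and scaled
shifts are predicted for unassigned nuclei. Together these implement the
structure-revision logic: the wrong hypothesis shows localized large
residuals after scaling, misassigned pairs are recoverable as
CMAE-lowering transpositions, and the fitted line extrapolates to
missing experimental values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble import AveragedShieldings, boltzmann_average
from .errors import InsufficientDataError, PositiveSlopeWarning, ValidationError
from .model import (
    ELEMENTS,
    CandidateStructure,
    ExperimentalTable,
    Nucleus,
    PipelineConfig,
)
from .scaling import ScalingFit, fit_scaling
from .scoring import ScoreReport, cmae, matched_pairs, score_candidate


@dataclass
class RankedCandidate:
    candidate_id: str
    combined_score: float
    reports: dict[str, ScoreReport]


@dataclass
class RankingReport:
    """Candidates of one compound ordered best (lowest combined score) first."""

    compound_id: str
    ranked: list[RankedCandidate]

    @property
    def winner(self) -> str:
        return self.ranked[0].candidate_id


@dataclass
class OutlierFlag:
    nucleus: Nucleus
    residual: float
    z: float
    flagged: bool


@dataclass
class SwapSuggestion:
    """A pairwise exchange of two experimental assignments.

    ``delta_cmae`` is the CMAE change after the trial swap (negative =
    improvement, after refitting the scaling); ``accepted`` marks the
    greedy non-overlapping subset a user would apply.
    """

    element: str
    labels: tuple[Nucleus, Nucleus]
    delta_cmae: float
    accepted: bool


@dataclass
class ShiftPrediction:
    nucleus: Nucleus
    predicted_shift: float
    fit_used: ScalingFit


def _shift_range(table: ExperimentalTable, element: str) -> Optional[float]:
    values = list(table.assigned(element).values())
    if len(values) < 2:
        return None
    r = max(values) - min(values)
    return r if r > 0 else None


def rank_candidates(
    candidates: Sequence[CandidateStructure],
    table: ExperimentalTable,
    config: PipelineConfig,
) -> RankingReport:
    """Rank rival candidates of one compound by combined CMAE.

    The combined score is Σ_e CMAE_e / range_e over elements with a valid
    report, where range_e is the spread of that element's assigned
    experimental shifts — a dimensionless, element-balanced criterion
    (proton and carbon errors each counted as a fraction of their own
    shift range). Each candidate is scored under its own per-candidate
    scaling fit; ties break by RMSD sum, then candidate id.
    """
    if not candidates:
        raise InsufficientDataError("no candidates to rank")
    compound_ids = {c.compound_id for c in candidates}
    if compound_ids != {table.compound_id}:
        raise ValidationError(
            f"candidates span compounds {sorted(compound_ids)}, table is for "
            f"{table.compound_id!r}"
        )
    ranges = {e: _shift_range(table, e) for e in ELEMENTS}
    entries: list[tuple[float, float, str, RankedCandidate]] = []
    for candidate in candidates:
        reports = score_candidate(candidate, table, config)
        score = 0.0
        rmsd_sum = 0.0
        scored = False
        for element in ELEMENTS:
            report = reports[element]
            if report.cmae is None or ranges[element] is None:
                continue
            score += report.cmae / ranges[element]
            rmsd_sum += report.rmsd
            scored = True
        if not scored:
            continue
        entries.append(
            (score, rmsd_sum, candidate.candidate_id,
             RankedCandidate(candidate.candidate_id, score, reports))
        )
    if not entries:
        raise InsufficientDataError(
            f"no scoreable candidate for compound {table.compound_id!r}"
        )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return RankingReport(table.compound_id, [e[3] for e in entries])


def flag_outliers(report: ScoreReport, outlier_k: float = 2.0) -> list[OutlierFlag]:
    """Flag nuclei with |residual| > k·RMSD, ordered by |z| descending.

    z is the residual normalized by the report's own RMSD. A degenerate
    report (RMSD exactly 0) yields no flags.
    """
    if report.n < 3 or report.rmsd is None:
        raise InsufficientDataError(
            f"outlier flagging needs n >= 3 with statistics, got n={report.n}"
        )
    if report.rmsd == 0:
        return []
    flags = [
        OutlierFlag(
            nucleus=nucleus,
            residual=residual,
            z=residual / report.rmsd,
            flagged=abs(residual / report.rmsd) > outlier_k,
        )
        for nucleus, residual in report.residuals.items()
    ]
    flags.sort(key=lambda f: (-abs(f.z), f.nucleus.key))
    return flags


def suggest_reassignments(
    report: ScoreReport,
    sigma: AveragedShieldings,
    table: ExperimentalTable,
    config: PipelineConfig,
) -> list[SwapSuggestion]:
    """Exhaustively evaluate pairwise swaps of experimental assignments.

    Every same-element pair of assigned nuclei is trial-swapped, the
    scaling refit, and the CMAE recomputed. Swaps improving CMAE by more
    than the element's ``min_improvement`` are reported best first;
    ``accepted`` marks a greedy non-overlapping subset (deltas are
    evaluated against the unswapped baseline, not recomputed after each
    acceptance — exact for disjoint transpositions).
    """
    element = report.element
    labels, d, s = matched_pairs(sigma, table, element)
    n = len(labels)
    if n < 4:
        raise InsufficientDataError(
            f"swap search needs >= 4 assigned {element} nuclei, got {n}"
        )
    base_fit = fit_scaling(d, s, element, scope_id=report.candidate_id)
    base_cmae = cmae(d, s, base_fit)
    threshold = config.min_improvement(element)
    found: list[tuple[float, int, int]] = []
    with warnings.catch_warnings():
        # trial swaps explore deliberately scrambled assignments; their
        # degenerate fits are not user-facing
        warnings.simplefilter("ignore", PositiveSlopeWarning)
        for i in range(n):
            for j in range(i + 1, n):
                d_trial = d.copy()
                d_trial[i], d_trial[j] = d_trial[j], d_trial[i]
                trial_fit = fit_scaling(d_trial, s, element, scope_id=report.candidate_id)
                delta = cmae(d_trial, s, trial_fit) - base_cmae
                if delta < -threshold:
                    found.append((delta, i, j))
    found.sort(key=lambda t: (t[0], labels[t[1]].key, labels[t[2]].key))
    used: set[int] = set()
    suggestions: list[SwapSuggestion] = []
    for delta, i, j in found:
        accepted = i not in used and j not in used
        if accepted:
            used.update((i, j))
        suggestions.append(
            SwapSuggestion(element, (labels[i], labels[j]), float(delta), accepted)
        )
    return suggestions


def predict_missing_shifts(
    sigma: AveragedShieldings,
    table: ExperimentalTable,
    fit: ScalingFit,
) -> list[ShiftPrediction]:
    """Predict shifts for unassigned nuclei of the fit's element.

    Each missing nucleus with a computed shielding gets δ = (σ − b)/a
    using the scaling fitted on the assigned nuclei; fully unassigned
    equivalence groups are predicted from their mean member shielding.
    """
    element = fit.element
    grouped = table.grouped_nuclei()
    predictions: list[ShiftPrediction] = []
    for group_label, members in table.groups.items():
        if members[0].element != element or table.group_shift(group_label) is not None:
            continue
        if not all(m in sigma.sigma for m in members):
            continue
        mean_sigma = float(np.mean([sigma.sigma[m] for m in members]))
        predictions.append(
            ShiftPrediction(Nucleus(element, group_label), fit.shift(mean_sigma), fit)
        )
    for nucleus in table.missing(element):
        if nucleus in grouped or nucleus not in sigma.sigma:
            continue
        predictions.append(
            ShiftPrediction(nucleus, fit.shift(sigma.sigma[nucleus]), fit)
        )
    predictions.sort(key=lambda p: p.nucleus.key)
    return predictions


def diagnose_candidate(
    candidate: CandidateStructure,
    table: ExperimentalTable,
    config: PipelineConfig,
) -> dict[str, dict]:
    """One-stop diagnostics: reports, outliers, swaps, predictions per element."""
    sigma = boltzmann_average(candidate, config)
    reports = score_candidate(candidate, table, config)
    out: dict[str, dict] = {}
    for element in ELEMENTS:
        report = reports[element]
        entry: dict = {"report": report, "outliers": [], "swaps": [], "predictions": []}
        if report.cmae is not None:
            if report.n >= 3:
                entry["outliers"] = flag_outliers(report, config.outlier_k)
            if report.n >= 4:
                entry["swaps"] = suggest_reassignments(report, sigma, table, config)
            if report.fit is not None:
                entry["predictions"] = predict_missing_shifts(sigma, table, report.fit)
        out[element] = entry
    return out
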