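"""Readers and writers for the tabular interchange dialect.

Four plain-text tables (TSV or CSV, sniffed from the header line) move
data in and out of the pipeline:

* shieldings: ``candidate_id  conformer_id  atom_label  element  shielding_ppm``
* energies:   ``candidate_id  conformer_id  energy  unit``
  (unit ∈ kJ/mol, kcal/mol, hartree, J/mol; converted to J·mol⁻¹ and
  re-zeroed per candidate — absolute or relative energies both work)
* experimental: ``compound_id  atom_label  element  shift_ppm  group``
  (empty shift = missing/unassigned; group joins equivalent nuclei)
* mapping:    ``candidate_id  compound_id`` (optional; defaults to
  candidate_id == compound_id)

Floats are written with ``repr`` so every number round-trips exactly.
This module also extracts isotropic shieldings from quantum-chemistry
output text ("Isotropic =" per-atom lines).
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .discrimination import RankingReport
from .errors import DialectError, QCParseError, ValidationError
from .model import (
    HARTREE_PER_MOL,
    KCAL_PER_MOL,
    CandidateStructure,
    ConformerRecord,
    ExperimentalTable,
    Nucleus,
    PipelineConfig,
    sort_nuclei,
)
from .scoring import ScoreReport

logger = logging.getLogger(__name__)

ENERGY_UNIT_TO_J = {
    "kj/mol": 1000.0,
    "kcal/mol": KCAL_PER_MOL,
    "hartree": HARTREE_PER_MOL,
    "j/mol": 1.0,
}


@dataclass
class Dataset:
    """Validated candidates and experimental tables ready for scoring."""

    candidates: dict[str, CandidateStructure]
    tables: dict[str, ExperimentalTable]
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _read_table(path: Union[str, Path], required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DialectError(f"file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV/TSV
        raise DialectError(f"{path}: cannot parse as {sep!r}-separated table: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DialectError(f"{path}: missing required columns {missing}; found {list(frame.columns)}")
    return frame


def _to_float(value: str, context: str) -> float:
    try:
        out = float(value)
    except ValueError as exc:
        raise DialectError(f"{context}: not a number: {value!r}") from exc
    if not math.isfinite(out):
        raise DialectError(f"{context}: non-finite value {value!r}")
    return out


def read_shieldings(path: Union[str, Path]) -> dict[tuple[str, str], dict[Nucleus, float]]:
    """Per-(candidate, conformer) nucleus→shielding maps."""
    frame = _read_table(path, ["candidate_id", "conformer_id", "atom_label", "element", "shielding_ppm"])
    out: dict[tuple[str, str], dict[Nucleus, float]] = {}
    for row in frame.itertuples(index=False):
        key = (row.candidate_id.strip(), row.conformer_id.strip())
        nucleus = Nucleus(row.element, row.atom_label)
        target = out.setdefault(key, {})
        if nucleus in target:
            raise DialectError(f"{path}: duplicate shielding for {nucleus!r} in {key}")
        target[nucleus] = _to_float(row.shielding_ppm, f"{path} {key} {nucleus!r}")
    if not out:
        raise DialectError(f"{path}: no shielding rows")
    return out


def read_energies(path: Union[str, Path]) -> dict[tuple[str, str], float]:
    """Per-(candidate, conformer) energies converted to J·mol⁻¹ (not yet re-zeroed)."""
    frame = _read_table(path, ["candidate_id", "conformer_id", "energy", "unit"])
    out: dict[tuple[str, str], float] = {}
    for row in frame.itertuples(index=False):
        key = (row.candidate_id.strip(), row.conformer_id.strip())
        unit = row.unit.strip().lower()
        if unit not in ENERGY_UNIT_TO_J:
            raise DialectError(
                f"{path}: unknown energy unit {row.unit!r}; expected one of "
                f"{sorted(ENERGY_UNIT_TO_J)}"
            )
        if key in out:
            raise DialectError(f"{path}: duplicate energy row for {key}")
        out[key] = _to_float(row.energy, f"{path} {key}") * ENERGY_UNIT_TO_J[unit]
    if not out:
        raise DialectError(f"{path}: no energy rows")
    return out


def read_experimental(path: Union[str, Path]) -> dict[str, ExperimentalTable]:
    """Per-compound assignment tables; empty shift cells become missing entries."""
    frame = _read_table(path, ["compound_id", "atom_label", "element", "shift_ppm"])
    has_group = "group" in frame.columns
    shifts: dict[str, dict[Nucleus, Optional[float]]] = {}
    groups: dict[str, dict[str, list[Nucleus]]] = {}
    for row in frame.itertuples(index=False):
        compound = row.compound_id.strip()
        nucleus = Nucleus(row.element, row.atom_label)
        table = shifts.setdefault(compound, {})
        if nucleus in table:
            raise DialectError(f"{path}: duplicate experimental row for {compound} {nucleus!r}")
        cell = row.shift_ppm.strip()
        table[nucleus] = _to_float(cell, f"{path} {compound} {nucleus!r}") if cell else None
        if has_group:
            label = row.group.strip()
            if label:
                groups.setdefault(compound, {}).setdefault(label, []).append(nucleus)
    if not shifts:
        raise DialectError(f"{path}: no experimental rows")
    return {
        compound: ExperimentalTable(
            compound,
            table,
            {k: tuple(v) for k, v in groups.get(compound, {}).items()},
        )
        for compound, table in shifts.items()
    }


def read_mapping(path: Union[str, Path]) -> dict[str, str]:
    frame = _read_table(path, ["candidate_id", "compound_id"])
    out: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        cid = row.candidate_id.strip()
        if cid in out:
            raise DialectError(f"{path}: duplicate mapping for candidate {cid!r}")
        out[cid] = row.compound_id.strip()
    return out


def read_dataset(
    shieldings_path: Union[str, Path],
    energies_path: Union[str, Path],
    experimental_path: Union[str, Path],
    mapping_path: Optional[Union[str, Path]] = None,
    config: Optional[PipelineConfig] = None,
) -> Dataset:
    """Assemble and validate a full dataset from the interchange files.

    Energies are converted to J·mol⁻¹ and re-zeroed per candidate.
    Experimental labels with no counterpart in any conformer of any
    candidate mapped to the compound are dropped from the table with a
    warning (they could never be scored).
    """
    config = config or PipelineConfig()
    shieldings = read_shieldings(shieldings_path)
    energies = read_energies(energies_path)
    tables = read_experimental(experimental_path)
    mapping = read_mapping(mapping_path) if mapping_path else None

    missing_energy = sorted(set(shieldings) - set(energies))
    if missing_energy:
        raise DialectError(f"no energy row for conformers {missing_energy}")
    orphan_energy = sorted(set(energies) - set(shieldings))
    if orphan_energy:
        raise DialectError(f"energy rows without shieldings: {orphan_energy}")

    by_candidate: dict[str, list[ConformerRecord]] = {}
    for (candidate_id, conformer_id), sigma in shieldings.items():
        by_candidate.setdefault(candidate_id, []).append(
            ConformerRecord(conformer_id, energies[(candidate_id, conformer_id)], sigma)
        )
    candidates: dict[str, CandidateStructure] = {}
    for candidate_id, conformers in by_candidate.items():
        conformers.sort(key=lambda c: c.conformer_id)
        compound_id = mapping.get(candidate_id, candidate_id) if mapping else candidate_id
        candidates[candidate_id] = CandidateStructure(
            candidate_id, compound_id, conformers
        ).normalized()

    pruned: dict[str, ExperimentalTable] = {}
    for compound_id, table in tables.items():
        computed: set[Nucleus] = set()
        for candidate in candidates.values():
            if candidate.compound_id == compound_id:
                computed |= candidate.nuclei()
        if not computed:
            pruned[compound_id] = table
            continue
        orphans = [n for n in table.shifts if n not in computed]
        if orphans:
            warnings.warn(
                f"compound {compound_id!r}: experimental labels with no computed "
                f"counterpart dropped from scoring: {sorted(n.key for n in orphans)}",
                stacklevel=2,
            )
            logger.warning("compound %s: dropped unmatched labels %s", compound_id, orphans)
            kept = {n: v for n, v in table.shifts.items() if n in computed}
            groups = {
                label: members
                for label, members in table.groups.items()
                if all(m in kept for m in members)
            }
            pruned[compound_id] = ExperimentalTable(compound_id, kept, groups)
        else:
            pruned[compound_id] = table
    return Dataset(candidates=candidates, tables=pruned, config=config)


# ---------------------------------------------------------------------------
# writers

def _fmt(value: float) -> str:
    return repr(float(value))


def write_dataset(
    candidates: dict[str, CandidateStructure],
    tables: dict[str, ExperimentalTable],
    out_dir: Union[str, Path],
    energy_unit: str = "J/mol",
) -> dict[str, Path]:
    """Write shieldings/energies/experimental/mapping interchange files.

    Returns the paths written. Numbers round-trip exactly through
    :func:`read_dataset` (floats are written with full precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unit_key = energy_unit.strip().lower()
    if unit_key not in ENERGY_UNIT_TO_J:
        raise DialectError(f"unknown energy unit {energy_unit!r}")
    factor = ENERGY_UNIT_TO_J[unit_key]

    paths = {
        "shieldings": out_dir / "shieldings.tsv",
        "energies": out_dir / "energies.tsv",
        "experimental": out_dir / "experimental.tsv",
        "mapping": out_dir / "mapping.tsv",
    }
    with open(paths["shieldings"], "w") as fh:
        fh.write("candidate_id\tconformer_id\tatom_label\telement\tshielding_ppm\n")
        for cid in sorted(candidates):
            for conf in candidates[cid].conformers:
                for nucleus in sort_nuclei(conf.shieldings):
                    fh.write(
                        f"{cid}\t{conf.conformer_id}\t{nucleus.label}\t{nucleus.element}\t"
                        f"{_fmt(conf.shieldings[nucleus])}\n"
                    )
    with open(paths["energies"], "w") as fh:
        fh.write("candidate_id\tconformer_id\tenergy\tunit\n")
        for cid in sorted(candidates):
            for conf in candidates[cid].conformers:
                fh.write(f"{cid}\t{conf.conformer_id}\t{_fmt(conf.energy / factor)}\t{energy_unit}\n")
    with open(paths["experimental"], "w") as fh:
        fh.write("compound_id\tatom_label\telement\tshift_ppm\tgroup\n")
        for compound_id in sorted(tables):
            table = tables[compound_id]
            membership = {
                member: label for label, members in table.groups.items() for member in members
            }
            for nucleus in sort_nuclei(table.shifts):
                value = table.shifts[nucleus]
                cell = "" if value is None else _fmt(value)
                fh.write(
                    f"{compound_id}\t{nucleus.label}\t{nucleus.element}\t{cell}\t"
                    f"{membership.get(nucleus, '')}\n"
                )
    with open(paths["mapping"], "w") as fh:
        fh.write("candidate_id\tcompound_id\n")
        for cid in sorted(candidates):
            fh.write(f"{cid}\t{candidates[cid].compound_id}\n")
    return paths


def _flatten_report(report: Union[ScoreReport, RankingReport]) -> dict[str, Optional[float]]:
    """Flat name→number view of a report; the unit written to disk."""
    if isinstance(report, ScoreReport):
        flat: dict[str, Optional[float]] = {
            "n": float(report.n),
            "cmae": report.cmae,
            "rmsd": report.rmsd,
            "pearson_r": report.pearson_r,
        }
        if report.fit is not None:
            flat["fit.a"] = report.fit.a
            flat["fit.b"] = report.fit.b
            flat["fit.n"] = float(report.fit.n)
        for nucleus in sort_nuclei(report.residuals):
            flat[f"residual.{nucleus.element}:{nucleus.label}"] = report.residuals[nucleus]
        return flat
    flat = {}
    for rank, entry in enumerate(report.ranked, start=1):
        flat[f"rank{rank}.{entry.candidate_id}.combined_score"] = entry.combined_score
        for element, rep in entry.reports.items():
            prefix = f"rank{rank}.{entry.candidate_id}.{element}"
            flat[f"{prefix}.n"] = float(rep.n)
            flat[f"{prefix}.cmae"] = rep.cmae
            flat[f"{prefix}.rmsd"] = rep.rmsd
            flat[f"{prefix}.pearson_r"] = rep.pearson_r
    return flat


def write_report(
    report: Union[ScoreReport, RankingReport],
    path: Union[str, Path],
    format: str = "tsv",
) -> Path:
    """Serialize a report to TSV (key/value rows) or JSON.

    Both formats carry identical numeric content at full precision; null
    statistics (insufficient-data reports) serialize as empty cells /
    JSON null.
    """
    path = Path(path)
    flat = _flatten_report(report)
    meta: dict[str, str] = {}
    if isinstance(report, ScoreReport):
        meta = {"kind": "score", "candidate_id": report.candidate_id, "element": report.element}
        if report.note:
            meta["note"] = report.note
    else:
        meta = {"kind": "ranking", "compound_id": report.compound_id, "winner": report.winner}
    if format == "json":
        payload = dict(meta)
        payload["values"] = flat
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for key in sorted(meta):
                fh.write(f"#{key}\t{meta[key]}\n")
            for key in sorted(flat):
                value = flat[key]
                fh.write(f"{key}\t{'' if value is None else _fmt(value)}\n")
    else:
        raise DialectError(f"unknown report format {format!r}; expected tsv or json")
    return path


def read_report(path: Union[str, Path], format: str = "tsv") -> dict[str, Optional[float]]:
    """Read back the flat numeric content written by :func:`write_report`."""
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return {k: (None if v is None else float(v)) for k, v in payload["values"].items()}
    if format == "tsv":
        out: dict[str, Optional[float]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("key\t"):
                raise DialectError(f"{path}: not a report TSV")
            for line in fh:
                key, _, cell = line.rstrip("\n").partition("\t")
                if key.startswith("#"):
                    continue
                out[key] = float(cell) if cell else None
        return out
    raise DialectError(f"unknown report format {format!r}; expected tsv or json")


# ---------------------------------------------------------------------------
# quantum-chemistry log extraction

_SHIELDING_LINE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+(?:\.\d+)?)",
    re.MULTILINE,
)


def parse_qc_log(text: str, candidate_id: str, conformer_id: str) -> ConformerRecord:
    """Extract ¹H/¹³C isotropic shieldings from quantum-chemistry output text.

    Looks for per-atom lines of the form ``<index> <element> Isotropic =
    <value>``; other elements are ignored. Shieldings are keyed by element
    + atom index (``C1``, ``H2``, ...); relabel to locants with the
    caller's atom-index map before matching experimental tables. The
    returned record has no energy (supply it from the thermochemistry
    source).
    """
    shieldings: dict[Nucleus, float] = {}
    seen: set[int] = set()
    for match in _SHIELDING_LINE.finditer(text):
        index = int(match.group(1))
        element = match.group(2).upper()
        if index in seen:
            raise QCParseError(f"duplicate atom index {index} in shielding section")
        seen.add(index)
        if element not in ("H", "C"):
            continue
        shieldings[Nucleus(element, f"{element}{index}")] = float(match.group(3))
    if not seen:
        raise QCParseError("no shielding section found (no 'Isotropic =' per-atom lines)")
    if not shieldings:
        raise QCParseError("shielding section contains no H or C atoms")
    return ConformerRecord(conformer_id, None, shieldings)


def relabel_conformer(
    record: ConformerRecord, index_map: dict[str, str]
) -> ConformerRecord:
    """Map parser keys (``C1``) to locant labels (``C-9a``) via index_map."""
    shieldings: dict[Nucleus, float] = {}
    for nucleus, sigma in record.shieldings.items():
        label = index_map.get(nucleus.label, nucleus.label)
        shieldings[Nucleus(nucleus.element, label)] = sigma
    if len(shieldings) != len(record.shieldings):
        raise ValidationError("index map collapses two atoms onto one label")
    return ConformerRecord(record.conformer_id, record.energy, shieldings)
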