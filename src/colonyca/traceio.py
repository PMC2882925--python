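"""Trace and report serialization.

A trace is stored as two tab-separated files:

* the **sites file** (the path given) — one row per (generation, site):
  ``generation  site_index  thickness  state  quorum``; header comment
  lines carry the format version, the full parameter set, termination
  and thinning metadata;
* the **summary file** (same path with ``.summary.tsv`` appended to the
  stem) — one row per generation: ``generation  extent  biomass  odor``,
  always written for every generation regardless of thinning.

Floating-point values are written with 12 significant digits, which is
what round-trip equality is defined over.  Phenotype reports are written
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .errors import TraceIOError
from .params import ModelParams
from .phenotype import PhenotypeReport
from .state import (STATE_FROM_NAME, STATE_NAMES, CellState, SimulationTrace,
                    Snapshot)

TRACE_VERSION = "colonyca-trace-v1"
FLOAT_FMT = "{:.12g}"

SITE_COLUMNS = ("generation", "site_index", "thickness", "state", "quorum")
SUMMARY_COLUMNS = ("generation", "extent", "biomass", "odor")


def summary_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".summary.tsv")


def _kept_generations(trace: SimulationTrace, thin: int) -> list[int]:
    gens = [s.generation for s in trace.snapshots]
    kept = [g for g in gens if g % thin == 0]
    if gens[-1] not in kept:
        kept.append(gens[-1])  # final state always recorded
    return kept


def write_trace(trace: SimulationTrace, path: str | Path,
                thin: int = 1) -> None:
    """Write a trace (sites + summary file), optionally thinning snapshots
    to every ``thin``-th generation plus the final one."""
    if thin < 1:
        raise TraceIOError(f"thin: must be >= 1, got {thin}")
    path = Path(path)
    kept = set(_kept_generations(trace, thin))

    lines = [f"# {TRACE_VERSION} (colonyca {__version__})"]
    for key, value in trace.params.to_dict().items():
        value = FLOAT_FMT.format(value) if isinstance(value, float) else value
        lines.append(f"# param {key}={value}")
    lines.append(f"# terminated_at="
                 f"{'none' if trace.terminated_at is None else trace.terminated_at}")
    lines.append(f"# thin={thin}")
    lines.append("\t".join(SITE_COLUMNS))
    for snap in trace.snapshots:
        if snap.generation not in kept:
            continue
        for i in range(len(snap.thickness)):
            lines.append("\t".join((
                str(snap.generation), str(i), str(int(snap.thickness[i])),
                STATE_NAMES[CellState(int(snap.state[i]))],
                FLOAT_FMT.format(float(snap.quorum[i])))))
    path.write_text("\n".join(lines) + "\n")

    slines = [f"# {TRACE_VERSION} (colonyca {__version__})",
              "\t".join(SUMMARY_COLUMNS)]
    for snap, extent, biomass, odor in zip(
            trace.snapshots, trace.extent_series, trace.biomass_series,
            trace.odor_series):
        slines.append("\t".join((
            str(snap.generation), str(extent), str(biomass),
            FLOAT_FMT.format(odor))))
    summary_path(path).write_text("\n".join(slines) + "\n")


def _parse_params(lines: Sequence[str], path: Path) -> tuple[dict, Optional[int], int]:
    params: dict = {}
    terminated_at: Optional[int] = None
    thin = 1
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if body.startswith("param "):
            key, _, value = body[len("param "):].partition("=")
            if not value:
                raise TraceIOError(f"{path}:{lineno}: malformed param line")
            params[key.strip()] = float(value) if "." in value or "e" in value \
                else int(value)
        elif body.startswith("terminated_at="):
            value = body.split("=", 1)[1]
            terminated_at = None if value == "none" else int(value)
        elif body.startswith("thin="):
            thin = int(body.split("=", 1)[1])
    return params, terminated_at, thin


def read_trace(path: str | Path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace`.

    Raises :class:`TraceIOError` naming the line where parsing fails.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"trace file not found: {path}")
    lines = path.read_text().splitlines()
    raw_params, terminated_at, _thin = _parse_params(lines, path)
    try:
        params = ModelParams(**raw_params)
    except Exception as exc:
        raise TraceIOError(f"{path}: bad parameter header: {exc}") from exc

    # sites table
    per_gen: dict[int, dict[str, np.ndarray]] = {}
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != SITE_COLUMNS:
                raise TraceIOError(
                    f"{path}:{lineno}: bad column header {fields!r}")
            header_seen = True
            continue
        if len(fields) != 5:
            raise TraceIOError(
                f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            gen, site = int(fields[0]), int(fields[1])
            thickness = int(fields[2])
            state = STATE_FROM_NAME[fields[3]]
            quorum = float(fields[4])
        except (ValueError, KeyError) as exc:
            raise TraceIOError(f"{path}:{lineno}: {exc}") from exc
        rec = per_gen.setdefault(gen, {
            "thickness": np.zeros(params.L, dtype=np.int64),
            "state": np.zeros(params.L, dtype=np.int8),
            "quorum": np.zeros(params.L, dtype=np.float64),
            "seen": np.zeros(params.L, dtype=bool)})
        if not 0 <= site < params.L:
            raise TraceIOError(f"{path}:{lineno}: site {site} out of range")
        rec["thickness"][site] = thickness
        rec["state"][site] = state
        rec["quorum"][site] = quorum
        rec["seen"][site] = True
    if not header_seen:
        raise TraceIOError(f"{path}: no site table found")
    for gen, rec in per_gen.items():
        if not rec["seen"].all():
            missing = int(np.flatnonzero(~rec["seen"])[0])
            raise TraceIOError(
                f"{path}: generation {gen} truncated (site {missing} missing)")

    # summary table
    spath = summary_path(path)
    if not spath.exists():
        raise TraceIOError(f"summary file not found: {spath}")
    extent: dict[int, int] = {}
    biomass: dict[int, int] = {}
    odor: dict[int, float] = {}
    header_seen = False
    for lineno, line in enumerate(spath.read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != SUMMARY_COLUMNS:
                raise TraceIOError(
                    f"{spath}:{lineno}: bad column header {fields!r}")
            header_seen = True
            continue
        if len(fields) != 4:
            raise TraceIOError(
                f"{spath}:{lineno}: expected 4 fields, got {len(fields)}")
        try:
            gen = int(fields[0])
            extent[gen] = int(fields[1])
            biomass[gen] = int(fields[2])
            odor[gen] = float(fields[3])
        except ValueError as exc:
            raise TraceIOError(f"{spath}:{lineno}: {exc}") from exc

    trace = SimulationTrace(params=params, terminated_at=terminated_at)
    for gen in sorted(per_gen):
        rec = per_gen[gen]
        if gen not in odor:
            raise TraceIOError(
                f"{spath}: generation {gen} present in sites file but "
                f"missing from summary")
        trace.snapshots.append(Snapshot(gen, rec["thickness"], rec["state"],
                                        rec["quorum"], odor[gen]))
    for gen in sorted(odor):
        trace.extent_series.append(extent[gen])
        trace.biomass_series.append(biomass[gen])
        trace.odor_series.append(odor[gen])
    return trace


def write_report(report: PhenotypeReport, path: str | Path) -> None:
    """Write a phenotype report as JSON (schema: the to_dict layout,
    plus a format tag)."""
    payload = {"format": "colonyca-report-v1", "version": __version__}
    payload.update(report.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"report file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TraceIOError(f"{path}: invalid JSON: {exc}") from exc
    if payload.get("format") != "colonyca-report-v1":
        raise TraceIOError(f"{path}: not a colonyca report")
    return payload
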