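"""On-disk formats: delimited time series, spike-time lists, results tables.

The interchange format is the delimited-text export used throughout: a
minimal self-describing header of ``# key=value`` lines followed by a
rectangular numeric body.  Time is in seconds, voltage in microvolts, all
files UTF-8.  Tab is the default delimiter; comma is accepted on read.
"""

from __future__ import annotations

import csv
import io
import os

import numpy as np
import pandas as pd

from .core import PHASES, FormatError, Recording, SpikeTrain, log

_RESULT_COLUMNS = ("region", "phase", "metric", "value", "units")


def _parse_header(lines: list[str]) -> dict[str, str]:
    header = {}
    for ln in lines:
        body = ln[1:].strip()
        if "=" in body:
            key, _, val = body.partition("=")
            header[key.strip()] = val.strip()
    return header


def _split_file(path: str) -> tuple[dict[str, str], list[str]]:
    try:
        with open(path, encoding="utf-8") as fh:
            raw = fh.read().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    head = [ln for ln in raw if ln.startswith("#")]
    body = [ln for ln in raw if not ln.startswith("#") and ln.strip()]
    return _parse_header(head), body


def _sniff_delim(line: str) -> str:
    return "\t" if "\t" in line else ","


def write_timeseries(rec: Recording, path: str, delim: str = "\t") -> None:
    """Recording -> header + one column per channel, one row per sample."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fs={rec.fs:.10g}\n")
        fh.write(f"# regions={','.join(rec.regions)}\n")
        fh.write(f"# t_start={rec.t_start:.10g}\n")
        if rec.phase_label:
            fh.write(f"# phase={rec.phase_label}\n")
        fh.write("# units=uV\n")
        np.savetxt(fh, rec.samples.T, fmt="%.8g", delimiter=delim)


def read_timeseries(path: str) -> Recording:
    """Parse a delimited time-series file into a Recording.

    Raises FormatError on a missing fs header, ragged rows, a
    channel-count mismatch, or non-numeric cells (with the row number).
    """
    header, body = _split_file(path)
    if "fs" not in header:
        raise FormatError(f"{path}: missing 'fs' header line")
    fs = float(header["fs"])
    regions = tuple(r for r in header.get("regions", "ch0").split(",") if r)
    t_start = float(header.get("t_start", "0"))
    phase = header.get("phase", "")
    n_ch = len(regions)
    if not body:
        return Recording(regions, np.empty((n_ch, 0)), fs, t_start, phase)
    delim = _sniff_delim(body[0])
    rows = []
    for i, ln in enumerate(body, start=1):
        cells = [c for c in ln.split(delim) if c.strip() != ""]
        if len(cells) != n_ch:
            raise FormatError(
                f"{path}: row {i} has {len(cells)} columns, header declares {n_ch}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {i}") from exc
    samples = np.asarray(rows).T
    if not np.all(np.isfinite(samples)):
        raise FormatError(f"{path}: non-finite sample values")
    return Recording(regions, samples, fs, t_start, phase)


def write_spike_times(trains: list[SpikeTrain], path: str, delim: str = "\t") -> None:
    """Spike trains of one region -> two-column (unit_id, time_s) text."""
    if not trains:
        raise ValueError("no trains to write")
    region = trains[0].region
    if any(tr.region != region for tr in trains):
        raise ValueError("write_spike_times expects a single region per file")
    t0 = min(tr.t_span[0] for tr in trains)
    t1 = max(tr.t_span[1] for tr in trains)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# region={region}\n")
        fh.write(f"# units={','.join(str(tr.unit_id) for tr in trains)}\n")
        fh.write(f"# t_span={t0:.10g},{t1:.10g}\n")
        fh.write("# time_units=s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.unit_id}{delim}{t:.9f}\n")


def read_spike_times(path: str) -> list[SpikeTrain]:
    """Parse a two-column (unit_id, time_s) spike file.

    Times are sorted per unit; exact duplicates are removed with a warning;
    negative times are a format error.  Units listed in the header but
    absent from the body yield empty trains.
    """
    header, body = _split_file(path)
    region = header.get("region", "ch0")
    span = header.get("t_span")
    declared = [int(u) for u in header.get("units", "").split(",") if u.strip()]
    per_unit: dict[int, list[float]] = {u: [] for u in declared}
    delim = _sniff_delim(body[0]) if body else "\t"
    for i, ln in enumerate(body, start=1):
        cells = ln.split(delim)
        if len(cells) != 2:
            raise FormatError(f"{path}: row {i} is not two columns")
        try:
            u, t = int(cells[0]), float(cells[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {i}") from exc
        if t < 0:
            raise FormatError(f"{path}: negative spike time in row {i}")
        per_unit.setdefault(u, []).append(t)
    trains = []
    t_max = max((max(v) for v in per_unit.values() if v), default=0.0)
    if span:
        t0, t1 = (float(x) for x in span.split(","))
    else:
        t0, t1 = 0.0, np.nextafter(t_max, np.inf)
    for u in sorted(per_unit):
        times = np.asarray(per_unit[u])
        if times.size and np.any(np.diff(times) < 0):
            log.warning("%s: unit %d spike times not sorted; sorting", path, u)
            times = np.sort(times)
        deduped = np.unique(times)
        if deduped.size < times.size:
            log.warning(
                "%s: unit %d had %d duplicate spike times; deduplicated",
                path, u, times.size - deduped.size,
            )
        trains.append(SpikeTrain(region, u, deduped, (t0, t1)))
    return trains


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Normalize result rows to the canonical (region, phase, metric) table."""
    df = pd.DataFrame(rows, columns=list(_RESULT_COLUMNS))
    dup = df.duplicated(subset=["region", "phase", "metric"])
    if dup.any():
        raise ValueError("duplicate (region, phase, metric) keys in results")
    bad = set(df["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels in results: {sorted(bad)}")
    return df


def write_results(table: pd.DataFrame, path: str) -> None:
    """Deterministic CSV: fixed column order, stable row order.

    Rows sort by region, then phase in session order, then metric
    alphabetically, so two writes of the same table are byte-identical.
    """
    df = results_table(table.to_dict("records"))
    phase_rank = {p: i for i, p in enumerate(PHASES)}
    df = df.sort_values(
        by=["region", "phase", "metric"],
        key=lambda col: col.map(phase_rank) if col.name == "phase" else col,
        kind="mergesort",
    )
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_RESULT_COLUMNS)
    for row in df.itertuples(index=False):
        writer.writerow(
            [row.region, row.phase, row.metric, f"{row.value:.10g}", row.units]
        )
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such results file: {path}")
    df = pd.read_csv(path)
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_spike_times",
    "write_spike_times",
    "results_table",
    "write_results",
    "read_results",
]
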