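"""Readers and writers for traces, feature tables and mask series.

Traces are plain text, two columns (time_ms, voltage_uV) with '#'-prefixed
header lines carrying the session metadata — diffable and usable as test
goldens. Every writer records the row count so readers can reject silently
truncated files. Feature tables are TSV with a fixed column order; masks
are binary PNGs with a JSON sidecar for day labels and disk geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .features import FEATURE_COLUMNS, KEY_COLUMNS
from .masks import DetachmentMask
from .traces import ERGTrace

_META_KEYS = ("animal", "eye", "session", "step", "kind", "adaptation", "intensity")


def write_trace(trace: ERGTrace, path: str | Path) -> None:
    """Write one averaged trace to a two-column text file, full precision."""
    path = Path(path)
    lines = ["# ergwave-trace v1"]
    for key in _META_KEYS:
        if key in trace.meta:
            lines.append(f"# {key}: {trace.meta[key]}")
    lines.append(f"# rate_hz: {float(trace.rate)!r}")
    lines.append(f"# n_samples: {trace.n}")
    lines.append("# columns: time_ms voltage_uV")
    for t, v in zip(trace.time.tolist(), trace.voltage.tolist()):
        lines.append(f"{t!r} {v!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> ERGTrace:
    """Read a trace file; rejects truncated files and shuffled time grids."""
    path = Path(path)
    meta: dict = {}
    rate = None
    n_samples = None
    times: list[float] = []
    volts: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            key, value = key.strip(), value.strip()
            if key == "rate_hz":
                rate = float(value)
            elif key == "n_samples":
                n_samples = int(value)
            elif key in ("step",):
                meta[key] = int(value)
            elif key in ("intensity",):
                meta[key] = float(value)
            elif key in _META_KEYS:
                meta[key] = value
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        try:
            times.append(float(parts[0]))
            volts.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if rate is None:
        raise FormatError(f"{path}: missing required header 'rate_hz'")
    if n_samples is None:
        raise FormatError(f"{path}: missing required header 'n_samples'")
    if len(times) != n_samples:
        raise FormatError(
            f"{path}: truncated file ({len(times)} rows, header says {n_samples})"
        )
    try:
        return ERGTrace(time=np.array(times), voltage=np.array(volts),
                        rate=rate, meta=meta)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format feature table as TSV with a row-count header."""
    _check_feature_table(table)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ergwave-features v1 rows={len(table)}\n")
        table.to_csv(fh, sep="\t", index=False, columns=FEATURE_COLUMNS)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# ergwave-features"):
            raise FormatError(f"{path}: not an ergwave feature table")
        try:
            expected = int(header.rsplit("rows=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row-count header") from exc
        table = pd.read_csv(fh, sep="\t")
    if list(table.columns) != FEATURE_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(table.columns)}")
    if len(table) != expected:
        raise FormatError(
            f"{path}: truncated file ({len(table)} rows, header says {expected})"
        )
    _check_feature_table(table)
    return table


def _check_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    keys = table[KEY_COLUMNS + ["feature"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].head(3).to_dict("records")
        raise ValidationError(f"duplicate feature rows: {dupes}")


# ---------------------------------------------------------------------------
# cohorts and masks

def write_cohort(traces: list[ERGTrace], outdir: str | Path) -> Path:
    """Write one file per trace plus a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for trace in traces:
        m = trace.meta
        name = (
            f"{m.get('animal', 'NA')}_{m.get('eye', 'NA')}_"
            f"{m.get('session', 'NA')}_step{m.get('step', 0):02d}.txt"
        )
        write_trace(trace, outdir / name)
        entries.append({"file": name, **{k: m.get(k) for k in _META_KEYS if k in m}})
    manifest = {"format": "ergwave-cohort v1", "n_traces": len(entries),
                "traces": entries}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_cohort(outdir: str | Path) -> list[ERGTrace]:
    outdir = Path(outdir)
    mpath = outdir / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"{outdir}: no manifest.json")
    manifest = json.loads(mpath.read_text())
    entries = manifest.get("traces", [])
    if len(entries) != manifest.get("n_traces"):
        raise FormatError(f"{mpath}: manifest trace count mismatch")
    return [read_trace(outdir / e["file"]) for e in entries]


def write_mask_series(masks: list[DetachmentMask], outdir: str | Path) -> Path:
    """Write binary PNG masks plus a JSON sidecar; returns the sidecar path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in masks:
        name = f"mask_day{m.day:03d}.png"
        iio.imwrite(outdir / name, (m.mask.astype(np.uint8) * 255))
        entries.append({
            "file": name, "day": m.day, "center": list(m.center),
            "radius": m.radius, "n_detached": int(m.mask.sum()),
        })
    sidecar = {"format": "ergwave-masks v1", "masks": entries}
    spath = outdir / "masks.json"
    spath.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return spath


def read_mask_series(outdir: str | Path) -> list[DetachmentMask]:
    outdir = Path(outdir)
    spath = outdir / "masks.json"
    if not spath.exists():
        raise FormatError(f"{outdir}: no masks.json sidecar")
    sidecar = json.loads(spath.read_text())
    masks = []
    for entry in sidecar.get("masks", []):
        img = iio.imread(outdir / entry["file"])
        mask = np.asarray(img) > 127
        if int(mask.sum()) != entry["n_detached"]:
            raise FormatError(
                f"{entry['file']}: pixel count does not match sidecar (corrupt?)"
            )
        masks.append(DetachmentMask(mask=mask, center=tuple(entry["center"]),
                                    radius=entry["radius"], day=entry["day"]))
    return sorted(masks, key=lambda m: m.day)
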