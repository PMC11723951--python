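"""File formats: FRAP trace CSVs with JSON sidecars, TIFF stacks, FASTA.

A FRAP series on disk is a tidy CSV with columns ``time_s, roi_id,
mean_intensity`` plus a JSON sidecar (same stem, ``.json``) naming the ROI
roles and the bleach frame.  Image stacks are multi-page TIFFs with a JSON
sidecar carrying pixel size, timestamps and (optionally) simulator
parameters and ground truth.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import FrapSeries, ImagingField

__all__ = [
    "save_frap_series",
    "read_series",
    "save_field_stack",
    "read_field_stack",
    "write_fasta",
    "read_fasta",
    "file_sha256",
    "write_manifest",
]

_ROLES = ("bleach", "nucleus", "background")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_frap_series(series: FrapSeries, path: str | Path) -> Path:
    """Write a series as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    rows = []
    for roi, trace in series.traces.items():
        for t, v in zip(series.times, trace):
            rows.append({"time_s": t, "roi_id": roi, "mean_intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {
        "roles": {r: r for r in series.traces},
        "bleach_index": int(series.bleach_index),
        "roi_kind": series.roi_kind,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path: str | Path) -> FrapSeries:
    """Read a FRAP series CSV (with sidecar) back into a :class:`FrapSeries`.

    Malformed rows are reported with their line numbers; non-monotone time
    vectors and missing role assignments are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side.name}; write one naming the ROI roles "
            "{bleach, nucleus, background} and the bleach frame"
        )
    meta = json.loads(side.read_text())
    for key in ("roles", "bleach_index"):
        if key not in meta:
            raise ValueError(f"sidecar {side.name} lacks required key {key!r}")
    df = pd.read_csv(path)
    required = {"time_s", "roi_id", "mean_intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    bad = df.index[pd.to_numeric(df["mean_intensity"], errors="coerce").isna()].tolist()
    if bad:
        lines = [i + 2 for i in bad]  # +1 header, +1 1-based
        raise ValueError(f"non-numeric mean_intensity at CSV line(s) {lines}")

    role_of = {v: k for k, v in meta["roles"].items()}
    traces: dict[str, np.ndarray] = {}
    times = None
    for roi_id, g in df.groupby("roi_id"):
        g = g.sort_index()
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone times for ROI {roi_id!r}")
        if times is None:
            times = t
        elif not np.array_equal(times, t):
            raise ValueError("ROIs sampled on different time bases")
        role = role_of.get(roi_id, roi_id)
        traces[role] = g["mean_intensity"].to_numpy(dtype=float)
    missing = set(_ROLES) - set(traces)
    if missing:
        raise ValueError(
            f"missing ROI role(s) {sorted(missing)}; map them in the sidecar 'roles'"
        )
    return FrapSeries(
        times=times,
        traces=traces,
        bleach_index=int(meta["bleach_index"]),
        roi_kind=meta.get("roi_kind", "total"),
    )


def save_field_stack(
    frames: list[ImagingField], path: str | Path, extra_meta: dict | None = None
) -> Path:
    """Write frames as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    stack = np.stack([f.data for f in frames]).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {
        "pixel_size_um": frames[0].pixel_size,
        "times_s": [f.time for f in frames],
    }
    if extra_meta:
        sidecar.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_field_stack(path: str | Path) -> list[ImagingField]:
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side.name} for TIFF stack {path.name}"
        )
    meta = json.loads(side.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    times = meta.get("times_s", [0.0] * len(stack))
    px = float(meta["pixel_size_um"])
    return [
        ImagingField(data=np.asarray(fr, dtype=float), pixel_size=px, time=float(t))
        for fr, t in zip(stack, times)
    ]


def write_fasta(records: list[tuple[str, str, str]], path: str | Path) -> Path:
    """Write ``(id, description, sequence)`` triples as FASTA."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``(id, sequence)`` pairs."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, entries: dict) -> Path:
    """Write a run manifest listing every output file with its content hash."""
    out_dir = Path(out_dir)
    files = {
        str(p.relative_to(out_dir)): file_sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {**entries, "files": files}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
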