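"""Serialization of shoeboxes and result tables.

Shoeboxes travel as JSON lines — one object per shoebox with the counts as
a row-major integer array, the mask as a same-shape label array (0 =
background, 1 = foreground), the peak position, and truth metadata for
synthetic data.  A per-pixel CSV export (shoebox_id, x, y, counts, label)
is provided for interoperability.  CSV numbers are written with ``repr``
(17 significant digits) so that equal runs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .simulate import Shoebox

__all__ = [
    "shoebox_to_dict",
    "shoebox_from_dict",
    "write_shoeboxes_jsonl",
    "read_shoeboxes_jsonl",
    "write_pixel_csv",
    "write_csv",
    "write_run_metadata",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def shoebox_to_dict(sb: Shoebox) -> dict:
    return {
        "counts": sb.counts.tolist(),
        "mask": sb.mask.tolist(),
        "peak": [float(sb.peak[0]), float(sb.peak[1])],
        "truth": _jsonable(sb.truth),
    }


def shoebox_from_dict(d: dict) -> Shoebox:
    return Shoebox(
        counts=np.asarray(d["counts"], dtype=np.int64),
        mask=np.asarray(d["mask"], dtype=np.uint8),
        peak=(float(d["peak"][0]), float(d["peak"][1])),
        truth=d.get("truth"),
    )


def write_shoeboxes_jsonl(path, shoeboxes) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sb in shoeboxes:
            fh.write(json.dumps(shoebox_to_dict(sb), sort_keys=True))
            fh.write("\n")


def read_shoeboxes_jsonl(path) -> list[Shoebox]:
    path = Path(path)
    shoeboxes = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                shoeboxes.append(shoebox_from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed shoebox record at line {lineno}: {exc}"
                ) from exc
    return shoeboxes


def fmt(value) -> str:
    """Deterministic cell formatting: repr for floats, str otherwise."""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_csv(path, header, rows) -> None:
    """Write rows with deterministic numeric formatting (byte-stable)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow([fmt(v) for v in row])


def write_pixel_csv(path, shoeboxes) -> None:
    """Per-pixel table: shoebox_id, x, y, counts, label."""
    rows = []
    for i, sb in enumerate(shoeboxes):
        h, w = sb.counts.shape
        for y in range(h):
            for x in range(w):
                rows.append((i, x, y, int(sb.counts[y, x]), int(sb.mask[y, x])))
    write_csv(path, ["shoebox_id", "x", "y", "counts", "label"], rows)


def write_run_metadata(path, config: dict) -> None:
    """Sidecar JSON recording the package version, resolved config and seed."""
    from . import __version__

    path = Path(path)
    meta = {"package": "robustbg", "version": __version__, "config": _jsonable(config)}
    path.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
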