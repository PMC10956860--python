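"""Image and report I/O.

Raster images load through Pillow; RGB input is converted to 8-bit gray with
the BT.601 luma weights (0.299, 0.587, 0.114), rounded half up, which is the
bit-stable convention used throughout the package.  Reports are JSON (single
image) or CSV (batch); masks round-trip as 0/255 single-channel PNG.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

REPORT_SCHEMA_VERSION = 1

BATCH_COLUMNS = [
    "image",
    "j",
    "k",
    "l",
    "m",
    "scar_threshold",
    "latex_threshold",
    "used_fallback",
    "S1",
    "S2",
    "lambda",
    "grade",
]

__all__ = [
    "load_image",
    "save_mask",
    "load_mask",
    "report_dict",
    "write_report",
    "write_batch_csv",
    "load_config",
]


def load_image(path) -> np.ndarray:
    """Load a raster image as a 2-D uint8 gray array.

    Grayscale input passes through unchanged; color input is converted via
    BT.601 luma.  Unsupported or unreadable files raise ``OSError`` naming
    the path.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            if img.mode == "L":
                return np.asarray(img, dtype=np.uint8)
            if img.mode in ("I", "I;16"):
                arr = np.asarray(img)
                if arr.max() > 255:
                    raise OSError(f"{path}: only 8-bit images are supported")
                return arr.astype(np.uint8)
            rgb = np.asarray(img.convert("RGB"), dtype=np.float64)
            luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
            return np.floor(luma + 0.5).astype(np.uint8)  # round half up
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc


def save_mask(mask, path) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def report_dict(result=None, grade=None, metrics=None) -> dict:
    """Assemble the JSON-serializable report for one image."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if result is not None:
        report.update(
            thresholds=list(result.thresholds),
            scar_threshold=result.scar_threshold,
            latex_threshold=result.latex_threshold,
            used_fallback=bool(result.used_fallback),
            fitness=result.fitness,
        )
    if grade is not None:
        report.update(
            S1=grade.latex_area,
            S2=grade.scar_area,
            **{"lambda": grade.ratio},
            grade=grade.grade,
        )
    if metrics is not None:
        report.update(metrics)
    return report


def write_report(report: dict, path, masks: dict | None = None) -> None:
    """Write the JSON report and, optionally, named masks next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for name, mask in (masks or {}).items():
        save_mask(mask, path.parent / f"{path.stem}_{name}.png")


def write_batch_csv(rows, path) -> None:
    """Write batch grading rows (dicts keyed by BATCH_COLUMNS) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=BATCH_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def load_config(path) -> dict:
    """Read a YAML or JSON parameter file (auto-detected) into a flat dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data
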