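"""Readers and writers: NIfTI images, TE sidecars, CSV tables, JSON config.

Echo stacks are stored as NIfTI with the echo index on the third axis
and the TE vector (ms) in a JSON sidecar next to the image, keyed
``te_ms`` (volumetric headers encode echo timing inconsistently across
dialects, so the sidecar is the canonical source).  Masks are unsigned
8-bit images on the same grid; label maps use the integer code table in
:mod:`t2plaque.phantom`.  All coordinates are 0-based row-major.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def _affine(pixel_size_mm: float) -> np.ndarray:
    return np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])


def write_image(path: str | Path, data: np.ndarray, pixel_size_mm: float = 1.0,
                dtype=np.float64) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype).T, _affine(pixel_size_mm))
    nib.save(img, path)
    return path


def read_image(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    return data.T


def write_series(path: str | Path, stack: np.ndarray, te_ms,
                 pixel_size_mm: float = 1.0, noise_sd: float | None = None) -> Path:
    """Write an (n_echo, rows, cols) stack plus its JSON sidecar."""
    path = Path(path)
    stack = np.asarray(stack, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    if stack.shape[0] != len(te):
        raise ValueError("TE vector length does not match echo count")
    # on disk: (cols, rows, echo) so that .T restores (echo, rows, cols)
    img = nib.Nifti1Image(stack.T, _affine(pixel_size_mm))
    nib.save(img, path)
    sidecar = {"te_ms": te.tolist()}
    if noise_sd is not None:
        sidecar["noise_sd"] = float(noise_sd)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_series(path: str | Path):
    """Read an echo stack and its sidecar; returns (stack, te_ms, noise_sd)."""
    path = Path(path)
    stack = np.asarray(nib.load(str(path)).dataobj).T
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing TE sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    te = np.asarray(sidecar["te_ms"], dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(te):
        raise ValueError(
            f"TE count ({len(te)}) does not match echo count ({stack.shape[0]})")
    return stack, te, sidecar.get("noise_sd")


def read_dicom_series(paths) -> tuple[np.ndarray, np.ndarray]:
    """Optional DICOM ingestion: sort single-frame files by EchoTime.

    Returns (stack, te_ms).  NIfTI + sidecar is the canonical path; this
    reader exists for scanner exports.
    """
    import pydicom

    frames = []
    for p in paths:
        ds = pydicom.dcmread(str(p))
        frames.append((float(ds.EchoTime), ds.pixel_array.astype(float)))
    frames.sort(key=lambda x: x[0])
    te = np.array([t for t, _ in frames])
    stack = np.stack([a for _, a in frames])
    return stack, te


def read_training_table(path: str | Path, t2_map: np.ndarray | None = None) -> pd.DataFrame:
    """Read labelled training voxels as a (class_label, t2_ms) table.

    Accepts either columns ``class_label,t2_ms`` or ``class_label,row,col``;
    the coordinate form is resolved against a supplied T2 map.  Rows with
    non-positive T2 or out-of-grid coordinates are rejected with their
    line number.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty training table {path}")
    cols = set(df.columns)
    if {"class_label", "t2_ms"}.issubset(cols):
        bad = df.index[~(df["t2_ms"] > 0)]
        if len(bad):
            raise ValueError(f"non-positive t2_ms at line {bad[0] + 2} of {path}")
        return df[["class_label", "t2_ms"]]
    if {"class_label", "row", "col"}.issubset(cols):
        if t2_map is None:
            raise ValueError("coordinate-form training table needs a T2 map")
        nr, nc = t2_map.shape
        out_rows = []
        for i, rec in df.iterrows():
            r, c = int(rec["row"]), int(rec["col"])
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"coordinates outside grid at line {i + 2} of {path}")
            t2 = float(t2_map[r, c])
            if not np.isfinite(t2) or t2 <= 0:
                raise ValueError(
                    f"training voxel at line {i + 2} has no accepted T2 value")
            out_rows.append(dict(class_label=rec["class_label"], t2_ms=t2))
        return pd.DataFrame(out_rows)
    raise ValueError(
        "training table must have columns (class_label,t2_ms) or (class_label,row,col)")


def read_agreement_table(path: str | Path):
    """Read a square confusion-matrix CSV (first column = rater-A labels)."""
    from .stats import AgreementTable

    df = pd.read_csv(path, index_col=0)
    cats = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != cats:
        raise ValueError("agreement table rows and columns must list the same categories")
    return AgreementTable(categories=cats, counts=df.to_numpy())


def read_ratings(path: str | Path):
    """Read paired ratings CSV with columns rater_a, rater_b."""
    df = pd.read_csv(path)
    if not {"rater_a", "rater_b"}.issubset(df.columns):
        raise ValueError("ratings CSV needs columns rater_a, rater_b")
    return df["rater_a"].astype(str).tolist(), df["rater_b"].astype(str).tolist()
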