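"""File formats: delimited spectral tables and ENVI-style BSQ hypercubes.

Datasets travel as CSV with a header row of wavelengths (nm) plus a final
``scaling_rate_percent`` column and an optional leading ``# region:`` comment.
Hypercubes are written band-sequential (BSQ) float32 binary next to a plain
ENVI-style text header; ground-truth masks as 0/1 CSV grids.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SpectralDataset, WavelengthAxis
from .preprocessing import MSCFit
from .synthetic import HypercubeScene

__all__ = [
    "save_dataset_csv",
    "load_dataset_csv",
    "save_msc_fit_csv",
    "write_envi",
    "read_envi",
    "save_scene",
    "load_scene",
    "save_mask_csv",
    "load_mask_csv",
]

_RESPONSE_COLUMN = "scaling_rate_percent"


def save_dataset_csv(ds: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as CSV: wavelength columns + scaling-rate column."""
    path = Path(path)
    frame = pd.DataFrame(ds.spectra, columns=[f"{w:.14g}" for w in ds.axis.values])
    frame[_RESPONSE_COLUMN] = ds.responses
    with open(path, "w") as fh:
        if ds.region:
            fh.write(f"# region: {ds.region}\n")
        fh.write(f"# reflectance_scale: {ds.reflectance_scale}\n")
        frame.to_csv(fh, index=False)


def load_dataset_csv(path: str | Path) -> SpectralDataset:
    """Read a dataset written by :func:`save_dataset_csv`."""
    path = Path(path)
    region = ""
    scale = "percent"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*(region|reflectance_scale):\s*(\S+)", line)
            if m:
                if m.group(1) == "region":
                    region = m.group(2)
                else:
                    scale = m.group(2)
    frame = pd.read_csv(path, comment="#")
    if _RESPONSE_COLUMN not in frame.columns:
        raise ValueError(f"missing {_RESPONSE_COLUMN!r} column in {path}")
    responses = frame.pop(_RESPONSE_COLUMN).to_numpy()
    axis = WavelengthAxis(np.array([float(c) for c in frame.columns]))
    return SpectralDataset(
        axis=axis,
        spectra=frame.to_numpy(),
        responses=responses,
        region=region,
        reflectance_scale=scale,
    )


def save_msc_fit_csv(fit: MSCFit, path: str | Path) -> None:
    """Serialize an MSC fit: the reference spectrum and per-sample (m, b)."""
    path = Path(path)
    ref = pd.DataFrame({"reference": fit.reference})
    coef = pd.DataFrame({"slope_m": fit.slopes, "intercept_b": fit.intercepts})
    with open(path, "w") as fh:
        fh.write("# msc reference spectrum\n")
        ref.to_csv(fh, index=False)
        fh.write("# per-sample coefficients\n")
        coef.to_csv(fh, index=False)


def write_envi(array: np.ndarray, axis: WavelengthAxis, stem: str | Path) -> None:
    """Write a (rows x cols x bands) array as ``stem.raw`` + ``stem.hdr``.

    Band-sequential float32, little-endian, with the wavelength list in the
    header.
    """
    stem = Path(stem)
    rows, cols, bands = array.shape
    wl = ", ".join(f"{w:.9f}" for w in axis.values)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    stem.with_suffix(".hdr").write_text(header)
    bsq = np.ascontiguousarray(array.transpose(2, 0, 1), dtype="<f4")
    bsq.tofile(stem.with_suffix(".raw"))


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    braced = re.findall(r"(\w[\w ]*?)\s*=\s*\{(.*?)\}", text, flags=re.S)
    for key, val in braced:
        fields[key.strip()] = val
    for line in text.splitlines():
        if "=" in line and "{" not in line:
            key, val = line.split("=", 1)
            fields[key.strip()] = val.strip()
    return fields


def read_envi(stem: str | Path) -> tuple[np.ndarray, WavelengthAxis]:
    """Read an array written by :func:`write_envi`."""
    stem = Path(stem)
    fields = _parse_header(stem.with_suffix(".hdr").read_text())
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only band-sequential (bsq) cubes are supported")
    if fields.get("data type", "4") != "4":
        raise ValueError("only float32 (data type 4) cubes are supported")
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    wl = np.array([float(v) for v in fields["wavelength"].replace(",", " ").split()])
    data = np.fromfile(stem.with_suffix(".raw"), dtype="<f4")
    cube = data.reshape(bands, rows, cols).transpose(1, 2, 0).astype(float)
    return cube, WavelengthAxis(wl)


def save_mask_csv(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, mask.astype(int), fmt="%d", delimiter=",")


def load_mask_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",").astype(bool)


def save_scene(scene: HypercubeScene, directory: str | Path, stem: str) -> None:
    """Write a scene as raw/white/dark ENVI pairs plus a mask CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_envi(scene.cube, scene.axis, directory / stem)
    write_envi(scene.white_frame, scene.axis, directory / f"{stem}_white")
    write_envi(scene.dark_frame, scene.axis, directory / f"{stem}_dark")
    save_mask_csv(scene.scale_mask, directory / f"{stem}_mask.csv")


def load_scene(directory: str | Path, stem: str, region: str = "") -> HypercubeScene:
    """Read a scene written by :func:`save_scene`."""
    directory = Path(directory)
    cube, axis = read_envi(directory / stem)
    white, _ = read_envi(directory / f"{stem}_white")
    dark, _ = read_envi(directory / f"{stem}_dark")
    mask = load_mask_csv(directory / f"{stem}_mask.csv")
    return HypercubeScene(
        cube=cube,
        white_frame=white,
        dark_frame=dark,
        scale_mask=mask,
        region_label=region,
        axis=axis,
    )
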