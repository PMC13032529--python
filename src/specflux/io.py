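"""File I/O: wide CSV spectral tables, JCAMP-DX spectra, cube containers.

The wide CSV layout puts wavenumbers in the first column and one column
per spectrum, headed by the sample id; sample metadata travels in a
separate TSV keyed on ``sample_id``. Hyperspectral cubes are stored as a
binary array with a JSON sidecar describing shape, axis and pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import WavenumberAxis
from .imaging import HyperspectralImage
from .spectra import SpectralDataset, Spectrum


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def write_wide_csv(dataset: SpectralDataset, path, meta_path=None) -> None:
    """Write a dataset as wide CSV (plus a metadata TSV when requested)."""
    df = pd.DataFrame(dataset.intensities.T, columns=dataset.sample_ids)
    df.insert(0, "wavenumber", dataset.wavenumbers)
    df.to_csv(path, index=False, float_format="%.12g")
    if meta_path is not None:
        dataset.meta.to_csv(meta_path, sep="\t", index=False)


def read_wide_csv(path, meta_path=None) -> SpectralDataset:
    """Read a wide CSV written by :func:`write_wide_csv`.

    Raises on duplicate sample columns, ragged rows and non-numeric cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(header) < 2:
        raise ValueError("wide CSV needs a wavenumber column plus sample columns")
    ids = header[1:]
    seen = set()
    for c in ids:
        if c in seen:
            raise ValueError(f"duplicate sample column {c!r}")
        seen.add(c)
    try:
        df = pd.read_csv(path, dtype=float, header=0, names=header)
    except ValueError as exc:
        raise ValueError(f"non-numeric or malformed cell in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"ragged rows or missing values in {path}")
    axis = WavenumberAxis(df.iloc[:, 0].to_numpy())
    X = df.iloc[:, 1:].to_numpy().T
    meta = pd.DataFrame({"sample_id": ids})
    if meta_path is not None:
        ext = pd.read_csv(meta_path, sep="\t")
        if "sample_id" not in ext.columns:
            raise ValueError("metadata table lacks a 'sample_id' column")
        meta = meta.merge(ext, on="sample_id", how="left")
    return SpectralDataset(axis, X, meta)


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_SQZ_DIF_CHARS = set("@ABCDEFGHIabcdefghiJKLMNOPQRjklmnopqr%")


def read_jcamp(path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (AFFN numbers only).

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)``. The
    axis is reconstructed from FIRSTX/LASTX/NPOINTS with XFACTOR/YFACTOR
    applied. Compressed dialects (SQZ/DIF/DUP) are rejected by name.
    """
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ValueError(f"unsupported XYDATA variant {value!r}")
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                break
            else:
                labels[key] = value
        elif mode is not None:
            data_lines.append(line)

    if mode is None:
        raise ValueError("no XYDATA or XYPOINTS block found")
    for line in data_lines:
        bad = _SQZ_DIF_CHARS.intersection(line.replace("E", "").replace("e", ""))
        if bad:
            raise ValueError(
                "compressed JCAMP dialects (SQZ/DIF/DUP) are not supported; "
                f"offending characters: {sorted(bad)}")

    def need(key: str) -> float:
        if key not in labels:
            raise ValueError(f"required JCAMP label ##{key} missing")
        return float(labels[key])

    xfactor = float(labels.get("XFACTOR", 1.0))
    yfactor = float(labels.get("YFACTOR", 1.0))
    meta = {"title": labels.get("TITLE", ""),
            "xunits": labels.get("XUNITS", ""), "yunits": labels.get("YUNITS", "")}

    if mode == "xypoints":
        xs, ys = [], []
        for line in data_lines:
            for pair in line.replace(";", " ").split():
                x, _, y = pair.partition(",")
                xs.append(float(x) * xfactor)
                ys.append(float(y) * yfactor)
        order = np.argsort(xs)
        return Spectrum(WavenumberAxis(np.array(xs)[order]),
                        np.array(ys)[order], meta=meta)

    firstx, lastx = need("FIRSTX"), need("LASTX")
    npoints = int(need("NPOINTS"))
    ys: list[float] = []
    for line in data_lines:
        vals = line.split()
        ys.extend(float(v) for v in vals[1:])  # first number is the line's x
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} points, parsed {len(ys)}")
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.array(ys) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(WavenumberAxis(x.copy()), y.copy(), meta=meta)


# ---------------------------------------------------------------------------
# cube container
# ---------------------------------------------------------------------------

def save_cube(image: HyperspectralImage, prefix) -> tuple[Path, Path]:
    """Save a cube as ``<prefix>.npy`` with a ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    sidecar = prefix.with_suffix(".json")
    np.save(npy, image.cube)
    meta = {
        "shape": list(image.cube.shape),
        "wavenumbers": image.axis.values.tolist(),
        "modality": image.axis.modality,
        "pixel_size_um": image.pixel_size,
    }
    sidecar.write_text(json.dumps(meta))
    if image.valid_mask is not None:
        np.save(prefix.parent / (prefix.name + "_mask.npy"), image.valid_mask)
    return npy, sidecar


def load_cube(prefix) -> HyperspectralImage:
    prefix = Path(prefix)
    cube = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    axis = WavenumberAxis(np.array(meta["wavenumbers"]), modality=meta.get("modality"))
    mask_path = prefix.parent / (prefix.name + "_mask.npy")
    mask = np.load(mask_path) if mask_path.exists() else None
    return HyperspectralImage(cube=cube, axis=axis, valid_mask=mask,
                              pixel_size=meta.get("pixel_size_um", 2.7))


def write_envi_header(image: HyperspectralImage, path) -> None:
    """Minimal ENVI-compatible header for interoperability with
    hyperspectral viewers (band-sequential float64)."""
    nr, nc, nb = image.cube.shape
    lines = [
        "ENVI",
        f"samples = {nc}", f"lines = {nr}", f"bands = {nb}",
        "header offset = 0", "file type = ENVI Standard",
        "data type = 5", "interleave = bsq", "byte order = 0",
        "wavelength units = cm-1",
        "wavelength = {" + ", ".join(f"{v:.4f}" for v in image.axis.values) + "}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
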