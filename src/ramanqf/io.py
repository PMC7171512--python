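"""File I/O for spectra, response curves and dataset manifests.

Native on-disk format
---------------------
A spectrum is a two-column delimited text file (wavenumber cm^-1, counts)
plus a JSON sidecar with the same basename carrying the acquisition
parameters (n, t in ms, I_S in mW) and free-form metadata.  Floats are
written with 17 significant digits so a write/read round trip is
bit-for-bit lossless.

JCAMP-DX files (AFFN ``(XY..XY)`` and ``(X++(Y..Y))`` tables) can be read
for interoperability but are never written.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
import numpy as np
import pandas as pd

from .spectra import (
    AcquisitionParams,
    RawSpectrum,
    ResponseCurve,
    SpectrumValidationError,
    WavenumberAxis,
)

__all__ = [
    "ParseError",
    "read_spectrum",
    "write_spectrum",
    "read_response",
    "write_response",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

_FLOAT_FMT = "%.17g"

#: Required manifest columns; qs / pathology are optional per measurement.
MANIFEST_COLUMNS = ("measurement_id", "path", "n", "t_ms", "power_mW")


class ParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_spectrum(s: RawSpectrum, path: str | Path) -> Path:
    """Write a spectrum and its JSON sidecar; returns the spectrum path."""
    path = Path(path)
    data = np.column_stack([s.axis.values, s.counts])
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter="\t", comments="#",
               header="wavenumber_cm1\tcounts")
    sidecar = {
        "n_repeats": s.params.n_repeats,
        "exposure_time_ms": s.params.exposure_time_ms,
        "laser_power_mw": s.params.laser_power_mw,
        "meta": dict(s.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = re.split(r"[\t, ]+", stripped)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: not numeric: {stripped!r}") from exc
    if not xs:
        raise ParseError(f"{path}: no data rows")
    return np.asarray(xs), np.asarray(ys)


def _canonicalize(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort ascending and average duplicate wavenumbers."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    uniq, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if uniq.size != x.size:
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, y)
        y = sums / counts
        x = uniq
    return x, y


def _load_params(path: Path, params: AcquisitionParams | None) -> tuple[AcquisitionParams, dict]:
    if params is not None:
        return params, {}
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SpectrumValidationError(
            f"no acquisition parameters for {path}: the quality factor needs n, t and I_S; "
            f"provide params= or a sidecar {sidecar.name}"
        )
    blob = json.loads(sidecar.read_text())
    try:
        p = AcquisitionParams(blob["n_repeats"], blob["exposure_time_ms"], blob["laser_power_mw"])
    except KeyError as exc:
        raise SpectrumValidationError(f"{sidecar}: missing acquisition parameter {exc}") from exc
    return p, dict(blob.get("meta", {}))


def read_spectrum(path: str | Path, format: str = "tabular",
                  params: AcquisitionParams | None = None) -> RawSpectrum:
    """Read a spectrum from disk.

    Parameters
    ----------
    path:
        Two-column text file (``tabular``) or a JCAMP-DX file (``jcamp``).
    format:
        ``"tabular"`` (native, with JSON sidecar) or ``"jcamp"`` (import only).
    params:
        Acquisition parameters; required when no sidecar exists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        x, y = _parse_two_columns(path)
    elif format == "jcamp":
        x, y = _read_jcamp_xy(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tabular' or 'jcamp'")
    x, y = _canonicalize(x, y)
    p, meta = _load_params(path, params)
    return RawSpectrum(WavenumberAxis(x), y, p, meta)


def write_response(rc: ResponseCurve, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.column_stack([rc.axis.values, rc.gain]), fmt=_FLOAT_FMT,
               delimiter="\t", comments="#", header="wavenumber_cm1\tgain")
    return path


def read_response(path: str | Path) -> ResponseCurve:
    x, g = _parse_two_columns(Path(path))
    x, g = _canonicalize(x, g)
    return ResponseCurve(WavenumberAxis(x), g)


# --- JCAMP-DX import -------------------------------------------------------

_LDR = re.compile(r"^##(.+?)=(.*)$")


def _read_jcamp_xy(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for AFFN (XY..XY) and (X++(Y..Y)) tables."""
    labels: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    mode: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            m = _LDR.match(line)
            if m:
                key = m.group(1).strip().upper().replace(" ", "")
                val = m.group(2).strip()
                labels[key] = val
                if key in ("XYDATA", "XYPOINTS"):
                    norm = val.replace(" ", "").upper()
                    if "X++" in norm:
                        mode = "xpp"
                    else:
                        mode = "xy"
                elif key == "END":
                    break
                continue
            if mode is not None:
                data_lines.append((lineno, line))
    if mode is None:
        raise ParseError(f"{path}: no ##XYDATA/##XYPOINTS table found")
    xfac = float(labels.get("XFACTOR", 1.0))
    yfac = float(labels.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in data_lines:
        tokens = [t for t in re.split(r"[,;\s]+", line.strip()) if t]
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-AFFN token in data table: {line!r}") from exc
        if mode == "xy":
            if len(values) % 2:
                raise ParseError(f"{path}:{lineno}: odd number of values in (XY..XY) line")
            xs.extend(values[0::2])
            ys.extend(values[1::2])
        else:  # (X++(Y..Y)): first value is the line's X, the rest are Ys
            if len(values) < 2:
                raise ParseError(f"{path}:{lineno}: (X++(Y..Y)) line needs an X and >=1 Y")
            xs.append(values[0])
            ys.append(values[1])
            # subsequent Ys advance X by the nominal spacing
            npoints = float(labels.get("NPOINTS", 0) or 0)
            if npoints >= 2 and "FIRSTX" in labels and "LASTX" in labels:
                dx = (float(labels["LASTX"]) - float(labels["FIRSTX"])) / (npoints - 1)
            else:
                dx = float(labels.get("DELTAX", 1.0) or 1.0)
            for k, v in enumerate(values[2:], start=1):
                xs.append(values[0] + k * dx)
                ys.append(v)
    return np.asarray(xs) * xfac, np.asarray(ys) * yfac


# --- manifests --------------------------------------------------------------


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a dataset manifest as a tab-delimited table."""
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"manifest missing required columns: {missing}")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"manifest {path} missing required columns: {missing}")
    return df


def read_manifest_spectra(manifest: pd.DataFrame, root: str | Path) -> list[RawSpectrum]:
    """Load every spectrum referenced by a manifest, in manifest order."""
    root = Path(root)
    spectra = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        spectra.append(read_spectrum(p))
    return spectra
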