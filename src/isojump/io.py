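"""Plain-text readers/writers for spectra, melt series and transients.

All formats are simple delimited text with ``#``-prefixed metadata headers so
files remain diffable and round-trip exactly enough for analysis (float
repr with 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import RangeError

__all__ = [
    "read_manifest", "read_melt_series", "read_spectrum", "read_transient",
    "write_manifest", "write_melt_series", "write_spectrum", "write_transient",
]


def _write_with_header(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
    return meta


def write_spectrum(spectrum, path, extra_meta=None) -> None:
    meta = {"type": "spectrum", **dict(spectrum.metadata),
            **dict(extra_meta or {})}
    frame = pd.DataFrame({"wavenumber_cm1": spectrum.wavenumbers,
                          "absorbance": spectrum.absorbance})
    _write_with_header(path, meta, frame)


def read_spectrum(path):
    from .exciton import Spectrum
    meta = _read_header(path)
    frame = pd.read_csv(path, comment="#")
    meta.pop("type", None)
    return Spectrum(frame["wavenumber_cm1"].to_numpy(),
                    frame["absorbance"].to_numpy(), meta)


def write_melt_series(series, path, extra_meta=None) -> None:
    """First column wavenumber, one column per temperature."""
    meta = {"type": "melt", **dict(series.metadata), **dict(extra_meta or {})}
    frame = pd.DataFrame({"wavenumber_cm1": series.grid})
    for i, t in enumerate(series.temperatures):
        frame[f"{t:g}"] = series.spectra[i]
    _write_with_header(path, meta, frame)


def read_melt_series(path):
    from .melt import MeltSeries
    meta = _read_header(path)
    frame = pd.read_csv(path, comment="#")
    grid = frame["wavenumber_cm1"].to_numpy()
    temp_cols = [c for c in frame.columns if c != "wavenumber_cm1"]
    try:
        temps = np.array([float(c) for c in temp_cols])
    except ValueError as err:
        raise RangeError(f"non-numeric temperature column in {path}") from err
    order = np.argsort(temps)
    spectra = np.stack([frame[temp_cols[i]].to_numpy() for i in order])
    meta.pop("type", None)
    return MeltSeries(temps[order], grid, spectra, meta)


def write_transient(transient, path, extra_meta=None) -> None:
    meta = {
        "type": "transient",
        "probe_wn": transient.probe_wn,
        "T_initial": transient.T_initial,
        "T_final": transient.T_final,
        "n_averaged": transient.n_averaged,
        **{k: v for k, v in transient.meta.items()
           if isinstance(v, (int, float, str, bool, type(None)))},
        **dict(extra_meta or {}),
    }
    frame = pd.DataFrame({"time_s": transient.time, "dA_mOD": transient.dA})
    _write_with_header(path, meta, frame)


def read_transient(path):
    from .tjump import Transient
    meta = _read_header(path)
    frame = pd.read_csv(path, comment="#")
    keys = {k: meta.pop(k) for k in ("probe_wn", "T_initial", "T_final",
                                     "n_averaged") if k in meta}
    meta.pop("type", None)
    return Transient(frame["time_s"].to_numpy(), frame["dA_mOD"].to_numpy(),
                     probe_wn=float(keys.get("probe_wn", 0.0)),
                     T_initial=float(keys.get("T_initial", 0.0)),
                     T_final=float(keys.get("T_final", 1.0)),
                     n_averaged=int(keys.get("n_averaged", 1)),
                     meta=meta)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
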