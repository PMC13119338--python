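"""Photon-record file formats and ground-truth sidecars.

Two dialects are supported and round-trip losslessly:

* ``text`` — one photon per line, tab-separated, header
  ``time_s  channel  microtime_ns``, '.' decimal separator, UTF-8.
  Human-readable; used for fixtures.
* ``photon-hdf5`` — a Photon-HDF5-compatible layout
  (``/photon_data/timestamps`` int64 clock ticks, ``detectors``,
  ``nanotimes`` plus the ``timestamps_specs/timestamps_unit`` scalar).

Ground truth from the synthetic generator travels in a flat ``key = value``
sidecar next to the stream it describes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .stream import DEFAULT_CLOCK_RATE, PhotonStream

TEXT_COLUMNS = ("time_s", "channel", "microtime_ns")


class UnsortedInputWarning(UserWarning):
    pass


class EmptyStreamWarning(UserWarning):
    pass


def write_photons_text(stream: PhotonStream, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": stream.timestamps / stream.clock_rate,
            "channel": stream.channel,
            "microtime_ns": stream.microtime,
        }
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# clock_rate_hz={stream.clock_rate:.0f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_photons_text(path, clock_rate: float | None = None) -> PhotonStream:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_rate = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# clock_rate_hz="):
        header_rate = float(first.split("=", 1)[1])
    rate = clock_rate or header_rate or DEFAULT_CLOCK_RATE
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas reports the offset
        raise ValueError(f"malformed photon table {path}: {exc}") from exc
    if len(df) == 0:
        warnings.warn(f"empty photon file {path}", EmptyStreamWarning, stacklevel=2)
        return PhotonStream(np.empty(0, np.int64), np.empty(0, np.uint8),
                            np.empty(0), clock_rate=rate)
    missing = set(TEXT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"photon table {path} lacks columns {sorted(missing)}")
    for col in TEXT_COLUMNS:
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2  # header line + 1-based
            raise ValueError(f"malformed record in {path} at line {line}")
    stream = PhotonStream(
        timestamps=np.round(df["time_s"].to_numpy() * rate).astype(np.int64),
        channel=df["channel"].to_numpy(np.uint8),
        microtime=df["microtime_ns"].to_numpy(np.float64),
        clock_rate=rate,
        metadata={"source": str(path)},
    )
    if not stream.is_sorted():
        warnings.warn(f"unsorted photon records in {path}; sorting",
                      UnsortedInputWarning, stacklevel=2)
        stream = stream.sorted()
    return stream


def write_photons_hdf5(stream: PhotonStream, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps, dtype=np.int64)
        g.create_dataset("detectors", data=stream.channel, dtype=np.uint8)
        g.create_dataset("nanotimes", data=stream.microtime, dtype=np.float64)
        g.create_group("timestamps_specs").create_dataset(
            "timestamps_unit", data=1.0 / stream.clock_rate
        )
        g.create_group("nanotimes_specs").create_dataset("tcspc_unit", data=1e-9)
        f.attrs["metadata"] = json.dumps(stream.metadata, default=str)


def read_photons_hdf5(path) -> PhotonStream:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        unit = float(g["timestamps_specs/timestamps_unit"][()])
        meta = json.loads(f.attrs.get("metadata", "{}"))
        stream = PhotonStream(
            timestamps=g["timestamps"][()],
            channel=g["detectors"][()],
            microtime=g["nanotimes"][()],
            clock_rate=1.0 / unit,
            metadata=meta,
        )
    if not stream.is_sorted():
        warnings.warn(f"unsorted photon records in {path}; sorting",
                      UnsortedInputWarning, stacklevel=2)
        stream = stream.sorted()
    return stream


def read_photons(path, dialect: str = "auto") -> PhotonStream:
    """Load a photon stream; ``dialect`` is ``text``, ``photon-hdf5`` or
    ``auto`` (by file signature)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "photon-hdf5" if h5py.is_hdf5(path) else "text"
    if dialect == "photon-hdf5":
        return read_photons_hdf5(path)
    if dialect == "text":
        return read_photons_text(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_photons(stream: PhotonStream, path, dialect: str = "text") -> None:
    if dialect == "photon-hdf5":
        write_photons_hdf5(stream, path)
    elif dialect == "text":
        write_photons_text(stream, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _flatten(d, prefix=""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        elif isinstance(v, (list, tuple)):
            if all(isinstance(x, dict) for x in v):
                for i, x in enumerate(v):
                    yield from _flatten(x, f"{key}.{i}.")
            else:
                yield key, json.dumps(list(v))
        else:
            yield key, v


def write_sidecar(path, mapping: dict) -> None:
    """Ground-truth sidecar: flat ``key = value`` lines, nested keys dotted."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in _flatten(mapping):
            fh.write(f"{k} = {v}\n")


def read_sidecar(path) -> dict:
    """Read a flat sidecar back as a string->parsed-scalar dict (not
    re-nested)."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            v = v.strip()
            try:
                out[k.strip()] = json.loads(v)
            except json.JSONDecodeError:
                out[k.strip()] = v
    return out
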