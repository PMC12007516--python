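"""Native serialization: binary payload + structured-text sidecar.

A recording is stored as a raw little-endian float32 array
(channel-major, ``<base>.dat``) next to a YAML sidecar (``<base>.yaml``)
holding the sampling rate, channel metadata, provenance and the
optional ground-truth block.  Round trips are bit-exact.  Spectra are
stored in HDF5.  A standard export path (HDF5 container or delimited
text) is provided for interoperability; lossy aspects are logged.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import yaml

from .profiles import ChannelInfo
from .simulate import LfpStream, Recording
from .spectral import SpectrumSet

__all__ = [
    "write_recording",
    "read_recording",
    "write_lfp",
    "read_lfp",
    "write_spectrum",
    "read_spectrum",
    "export_standard",
    "EXPORT_DIALECTS",
]

log = logging.getLogger("perceptmeg.io")

EXPORT_DIALECTS = ("hdf5", "tsv")

_SIDECAR_KEYS = {"format", "fs", "t0", "n_channels", "n_samples",
                 "channels", "provenance", "truth", "clock",
                 "channel_names"}


def _plain(obj):
    """Recursively convert numpy containers to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _base(path) -> Path:
    p = Path(path)
    if p.suffix in (".dat", ".yaml", ".rec"):
        p = p.with_suffix("")
    return p


def write_recording(rec: Recording, path) -> Path:
    """Write a recording (payload + sidecar); returns the base path."""
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(rec.data, dtype="<f4")
    data.tofile(base.with_suffix(".dat"))
    sidecar = {
        "format": "perceptmeg-recording-v1",
        "fs": float(rec.fs),
        "t0": float(rec.t0),
        "n_channels": int(rec.n_channels),
        "n_samples": int(rec.n_samples),
        "channels": [ch.to_dict() for ch in rec.channels],
        "provenance": _plain(rec.provenance),
        "truth": _plain(rec.truth),
    }
    with open(base.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return base


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    base = _base(path)
    with open(base.with_suffix(".yaml")) as fh:
        side = yaml.safe_load(fh)
    extra = set(side) - _SIDECAR_KEYS
    if extra:
        warnings.warn(f"sidecar has unknown keys {sorted(extra)}; ignored",
                      stacklevel=2)
    n_ch, n_s = int(side["n_channels"]), int(side["n_samples"])
    payload = base.with_suffix(".dat")
    expected = n_ch * n_s * 4
    actual = payload.stat().st_size
    if actual != expected:
        raise ValueError(
            f"payload size mismatch for {payload}: sidecar implies "
            f"{expected} bytes ({n_ch} channels x {n_s} samples x 4) "
            f"but file has {actual}"
        )
    if len(side["channels"]) != n_ch:
        raise ValueError(
            f"sidecar channel list has {len(side['channels'])} entries "
            f"but n_channels = {n_ch}"
        )
    data = np.fromfile(payload, dtype="<f4").reshape(n_ch, n_s)
    channels = tuple(ChannelInfo.from_dict(d) for d in side["channels"])
    return Recording(
        data=data, fs=float(side["fs"]), channels=channels,
        t0=float(side.get("t0", 0.0)),
        provenance=side.get("provenance") or {},
        truth=side.get("truth") or {},
    )


def write_lfp(lfp: LfpStream, path) -> Path:
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(lfp.data, dtype="<f4").tofile(base.with_suffix(".dat"))
    sidecar = {
        "format": "perceptmeg-lfp-v1",
        "fs": float(lfp.fs),
        "n_channels": int(lfp.data.shape[0]),
        "n_samples": int(lfp.n_samples),
        "channel_names": list(lfp.channel_names),
        "clock": [float(lfp.clock[0]), float(lfp.clock[1])],
        "truth": _plain(lfp.truth),
    }
    with open(base.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return base


def read_lfp(path) -> LfpStream:
    base = _base(path)
    with open(base.with_suffix(".yaml")) as fh:
        side = yaml.safe_load(fh)
    n_ch, n_s = int(side["n_channels"]), int(side["n_samples"])
    data = np.fromfile(base.with_suffix(".dat"), dtype="<f4")
    if data.size != n_ch * n_s:
        raise ValueError("LFP payload size does not match sidecar")
    return LfpStream(
        data=data.reshape(n_ch, n_s).astype(float),
        fs=float(side["fs"]),
        clock=tuple(side.get("clock", (0.0, 1.0))),
        channel_names=tuple(side.get("channel_names", ("LFP_L", "LFP_R"))),
        truth=side.get("truth") or {},
    )


def write_spectrum(spec: SpectrumSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=spec.freqs)
        f.create_dataset("asd", data=spec.asd)
        f.create_dataset("n_segments_used", data=spec.n_segments_used)
        f.attrs["segment_length"] = spec.segment_length
        names = [getattr(ch, "name", str(ch)) for ch in spec.channels]
        f.create_dataset("channel_names",
                         data=np.array(names, dtype=h5py.string_dtype()))
        meta = [ch.to_dict() if hasattr(ch, "to_dict") else {"name": str(ch)}
                for ch in spec.channels]
        f.attrs["channel_meta"] = json.dumps(_plain(meta))
    return path


def read_spectrum(path) -> SpectrumSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["channel_meta"])
        channels = []
        for d in meta:
            if set(d) >= {"name", "ctype", "units", "position", "orientation"}:
                channels.append(ChannelInfo.from_dict(d))
            else:
                channels.append(d["name"])
        return SpectrumSet(
            freqs=f["freqs"][()],
            asd=f["asd"][()],
            segment_length=float(f.attrs["segment_length"]),
            n_segments_used=f["n_segments_used"][()],
            channels=tuple(channels),
        )


def export_standard(rec: Recording, path, dialect: str = "hdf5") -> Path:
    """Export a recording to an interchange format.

    ``hdf5`` writes a self-describing container readable by any HDF5
    tool; ``tsv`` writes a delimited table (time + one column per
    channel).  The ground-truth block has no standard slot and is
    skipped with a logged notice.
    """
    if dialect not in EXPORT_DIALECTS:
        raise ValueError(
            f"unsupported dialect {dialect!r}; supported: {EXPORT_DIALECTS}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if rec.truth:
        log.info("truth block not exported (no standard slot in %s)", dialect)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = rec.fs
            f.attrs["t0"] = rec.t0
            f.create_dataset("data", data=rec.data)
            sd = h5py.string_dtype()
            f.create_dataset("channel_names",
                             data=np.array(rec.channel_names(), dtype=sd))
            f.create_dataset("channel_types",
                             data=np.array(list(rec.channel_types()), dtype=sd))
            f.create_dataset(
                "channel_units",
                data=np.array([ch.units for ch in rec.channels], dtype=sd))
            f.create_dataset("positions",
                             data=np.array([ch.position for ch in rec.channels]))
            f.create_dataset(
                "orientations",
                data=np.array([ch.orientation for ch in rec.channels]))
        log.info("provenance exported as attributes only (lossy)")
    else:
        header = "time\t" + "\t".join(rec.channel_names())
        t = rec.times()
        table = np.column_stack([t, rec.data.T])
        np.savetxt(path, table, delimiter="\t", header=header, comments="")
        log.info("tsv export drops channel geometry and metadata (lossy)")
    return path
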