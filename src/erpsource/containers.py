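"""On-disk containers: epoched EEG arrays with JSON sidecars, montages,
masks, lead fields and study manifests.

Epoched data are stored as float32 ``.npy`` arrays (trials x channels x
samples) next to a JSON sidecar holding sampling metadata and per-trial
condition labels; the pair round-trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import Montage, RoiMask, RoiMaskSet
from .forward import LeadField

__all__ = [
    "EpochsSet",
    "save_epochs",
    "load_epochs",
    "write_montage_sfp",
    "read_montage_sfp",
    "save_masks",
    "load_masks",
    "save_leadfield",
    "load_leadfield",
    "sha256_of",
]


@dataclass
class EpochsSet:
    """One subject's epoched EEG.

    data : float32 or float64, (n_trials, n_channels, n_samples), microvolts
    conditions : per-trial condition label
    times_ms : sample times relative to stimulus onset
    """

    data: np.ndarray
    conditions: list[str]
    times_ms: np.ndarray
    channel_names: list[str]
    fs_hz: float
    subject_id: str = "S00"
    seed: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be trials x channels x samples")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial is required")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.size != self.data.shape[2]:
            raise ValueError("times_ms must match the sample axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def pick_condition(self, condition: str) -> "EpochsSet":
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        if not idx:
            raise ValueError(f"condition {condition!r} not present")
        return replace(
            self,
            data=self.data[idx],
            conditions=[self.conditions[i] for i in idx],
        )

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return (self.times_ms >= start_ms) & (self.times_ms <= stop_ms)


def save_epochs(epochs: EpochsSet, path: Path) -> None:
    """Write ``<path>.npy`` + ``<path>.json`` (bit-exact round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), epochs.data)
    meta = {
        "subject_id": epochs.subject_id,
        "fs_hz": epochs.fs_hz,
        "t0_ms": float(epochs.times_ms[0]),
        "n_samples": int(epochs.times_ms.size),
        "channel_names": list(epochs.channel_names),
        "conditions": list(epochs.conditions),
        "seed": epochs.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: Path) -> EpochsSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    dt = 1000.0 / meta["fs_hz"]
    times = meta["t0_ms"] + dt * np.arange(meta["n_samples"])
    return EpochsSet(
        data=data,
        conditions=meta["conditions"],
        times_ms=times,
        channel_names=meta["channel_names"],
        fs_hz=meta["fs_hz"],
        subject_id=meta["subject_id"],
        seed=meta["seed"],
    )


def write_montage_sfp(montage: Montage, path: Path, fiducials=None) -> None:
    """Write an .sfp-style text montage: ``label x y z`` per line; fiducial
    lines (if given) carry the conventional ``fid`` prefix."""
    lines = []
    if fiducials:
        for name, p in fiducials.items():
            lines.append(f"fid_{name}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}")
    for lab, p in zip(montage.labels, montage.positions):
        lines.append(f"{lab}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage_sfp(path: Path) -> tuple[dict[str, np.ndarray], list[str], np.ndarray]:
    """Read an .sfp file; returns (fiducials, labels, positions)."""
    fids: dict[str, np.ndarray] = {}
    labels: list[str] = []
    pos: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) != 4:
            continue
        name, xyz = parts[0], [float(v) for v in parts[1:]]
        if name.startswith("fid_"):
            fids[name[4:]] = np.asarray(xyz)
        else:
            labels.append(name)
            pos.append(xyz)
    return fids, labels, np.asarray(pos)


def save_masks(masks: RoiMaskSet, path: Path) -> None:
    payload = {
        m.name: {
            "indices": [int(i) for i in m.indices],
            "hemisphere": m.hemisphere,
            "family": m.family,
        }
        for m in masks
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_masks(path: Path) -> RoiMaskSet:
    payload = json.loads(Path(path).read_text())
    masks = {
        name: RoiMask(
            name,
            np.asarray(d["indices"], dtype=int),
            d["hemisphere"],
            d["family"],
        )
        for name, d in payload.items()
    }
    return RoiMaskSet(masks)


def save_leadfield(lf: LeadField, path: Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), lf.gain)
    meta = {
        "channel_names": lf.channel_names,
        "n_sources": lf.n_sources,
        "truncation_L": lf.truncation_L,
        "reference": lf.reference,
        "shape": list(lf.gain.shape),
        "ordering": "grid-major, xyz within grid",
        "units": "microvolt per nA*m",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_leadfield(path: Path) -> LeadField:
    path = Path(path)
    gain = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    if list(gain.shape) != meta["shape"]:
        raise ValueError("lead field shape does not match its metadata")
    col_sums = np.abs(gain.sum(axis=0))
    scale = np.abs(gain).max() or 1.0
    if col_sums.max() > 1e-9 * scale * gain.shape[0]:
        raise ValueError("lead field is not average-referenced")
    return LeadField(
        gain, meta["channel_names"], meta["n_sources"], meta["truncation_L"],
        meta["reference"],
    )


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
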