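"""Synthetic multi-subject ERP studies with known planted sources.

The generator emulates a child source-memory encoding study: 64-channel
scalp EEG epoched from -100 to 1500 ms at 512 Hz, two trial conditions
(subsequently source-correct vs source-incorrect), an early frontal P2-like
transient and a late sustained positivity (LSW), 1/f + white sensor noise,
and occasional high-amplitude artifact trials.  Condition effects are
planted at designated source-grid patches so every downstream stage can be
checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .containers import EpochsSet, save_epochs, save_masks, sha256_of, write_montage_sfp
from .forward import LeadField
from .geometry import HeadGeometry, Montage, RoiMaskSet, SourceSpace

__all__ = [
    "StudyDesign",
    "ActiveSource",
    "GroundTruth",
    "SubjectTruth",
    "simulate_subject",
    "simulate_study",
    "CONDITIONS",
]

CONDITIONS = ("source_correct", "source_incorrect")


@dataclass(frozen=True)
class StudyDesign:
    """Study-level sampling design."""

    n_subjects: int = 20
    n_trials_per_condition: int = 40
    fs_hz: float = 512.0
    epoch_ms: tuple[float, float] = (-100.0, 1500.0)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("empty study: n_subjects must be >= 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.fs_hz
        n = int(round((self.epoch_ms[1] - self.epoch_ms[0]) / dt)) + 1
        return self.epoch_ms[0] + dt * np.arange(n)


@dataclass(frozen=True)
class ActiveSource:
    """One planted dipolar source with condition-specific amplitudes.

    ``amp_correct`` / ``amp_incorrect`` are plateau (LSW) or peak (P2)
    moments in nA*m; orientation is radial at the grid point.
    """

    grid_index: int
    component: str  # "P2" | "LSW"
    amp_correct: float
    amp_incorrect: float
    latency_ms: float | None = None  # nominal P2 peak; ignored for LSW

    def __post_init__(self):
        if self.component not in ("P2", "LSW"):
            raise ValueError("component must be 'P2' or 'LSW'")
        if self.amp_correct < 0 or self.amp_incorrect < 0:
            raise ValueError("source amplitudes must be non-negative")


@dataclass(frozen=True)
class PlantedEffect:
    """ROI-level effect specification, resolved to grid indices once the
    ROI masks exist (``GroundTruth.resolve``)."""

    roi: str
    component: str  # "P2" | "LSW"
    amp_correct: float
    amp_incorrect: float
    latency_ms: float | None = None
    n_points: int = 3


@dataclass(frozen=True)
class GroundTruth:
    """Full simulation truth record.

    Between-subject structure: each subject draws one P2 latency
    (nominal + N(0, latency_jitter_sd_ms), clipped to 120-250 ms) and, per
    active source, a condition amplitude difference
    ``(amp_correct - amp_incorrect) + N(0, subject_effect_sd)`` so the
    planted paired effect size is ``(amp_correct - amp_incorrect) /
    subject_effect_sd`` in source-amplitude units.
    """

    active_sources: tuple[ActiveSource, ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()
    effect_rois: tuple[str, ...] = ()
    white_sigma_uv: float = 2.0
    pink_sigma_uv: float = 2.0
    one_over_f_exponent: float = 1.0
    artifact_fraction: float = 0.05
    artifact_amplitude_uv: float = 350.0
    latency_jitter_sd_ms: float = 20.0
    subject_effect_sd: float = 0.0
    subject_scale_sd: float = 0.0
    trial_amp_cv: float = 0.1
    p2_fwhm_ms: float = 60.0
    lsw_onset_ms: float = 1100.0
    lsw_slope_ms: float = 40.0

    def __post_init__(self):
        if not (0 <= self.artifact_fraction < 1):
            raise ValueError("artifact fraction must lie in [0, 1)")

    def resolve(self, masks: RoiMaskSet) -> "GroundTruth":
        """Turn ROI-level planted effects into grid-level active sources.

        Each planted effect takes the first ``n_points`` grid points of the
        named ROI mask (deterministic); explicit ``active_sources`` are kept
        as-is.
        """
        unknown = [e.roi for e in self.planted_effects if e.roi not in masks.masks]
        if unknown:
            raise ValueError(f"planted-effect ROIs not in the mask set: {unknown}")
        resolved = list(self.active_sources)
        for e in self.planted_effects:
            idx = masks[e.roi].indices[: e.n_points]
            for gi in idx:
                resolved.append(
                    ActiveSource(
                        int(gi), e.component, e.amp_correct, e.amp_incorrect,
                        e.latency_ms,
                    )
                )
        return replace(
            self,
            active_sources=tuple(resolved),
            effect_rois=tuple(
                dict.fromkeys(
                    list(self.effect_rois) + [e.roi for e in self.planted_effects]
                )
            ),
        )


@dataclass
class SubjectTruth:
    """Realized per-subject parameters (for recovery checks)."""

    subject_id: str
    p2_latency_ms: float
    source_amps: dict[int, tuple[float, float]]  # grid idx -> (correct, incorrect)
    artifact_trials: list[int]
    seed: int


def subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Stable per-subject seed stream derived from the master seed."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_index,))


def _p2_waveform(times_ms, latency_ms, fwhm_ms):
    s = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((times_ms - latency_ms) / s) ** 2)


def _lsw_waveform(times_ms, onset_ms, slope_ms):
    return 1.0 / (1.0 + np.exp(-(times_ms - onset_ms) / slope_ms))


def _pink_noise(rng, shape, n_samples, exponent):
    """Unit-variance 1/f^exponent noise along the last axis via spectral
    shaping of white noise."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * amp, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_subject(
    design: StudyDesign,
    montage: Montage,
    source_space: SourceSpace,
    truth: GroundTruth,
    leadfield: LeadField,
    subject_index: int = 0,
) -> tuple[EpochsSet, SubjectTruth]:
    """Simulate one subject's epoched two-condition EEG.

    Source time courses (Gaussian-bump P2, logistic-onset LSW) at the
    planted grid points are projected through the average-referenced lead
    field; sensor noise and planted artifact trials are added on top.  All
    randomness derives from (master_seed, subject_index).
    """
    if leadfield.gain.shape[0] != montage.n_electrodes:
        raise ValueError("montage channel count does not match the lead field")
    ss = subject_seed(design.master_seed, subject_index)
    rng = np.random.default_rng(ss)
    times = design.times_ms()
    n_samples = times.size
    n_chan = montage.n_electrodes
    n_per = design.n_trials_per_condition
    n_trials = 2 * n_per

    # subject-level draws
    nominal_lat = next(
        (s.latency_ms for s in truth.active_sources
         if s.component == "P2" and s.latency_ms is not None),
        180.0,
    )
    p2_lat = float(
        np.clip(nominal_lat + rng.normal(0.0, truth.latency_jitter_sd_ms), 120.0, 250.0)
    )
    scale = float(np.exp(rng.normal(0.0, truth.subject_scale_sd)))
    source_amps: dict[int, tuple[float, float]] = {}
    per_source_amp: list[tuple[ActiveSource, float, float]] = []
    for src in truth.active_sources:
        delta = src.amp_correct - src.amp_incorrect
        if truth.subject_effect_sd > 0:
            delta = delta + rng.normal(0.0, truth.subject_effect_sd)
        a_inc = max(0.0, scale * src.amp_incorrect)
        a_cor = max(0.0, scale * (src.amp_incorrect + delta))
        per_source_amp.append((src, a_cor, a_inc))
        source_amps[src.grid_index] = (a_cor, a_inc)

    conditions = [CONDITIONS[0]] * n_per + [CONDITIONS[1]] * n_per
    order = rng.permutation(n_trials)
    conditions = [conditions[i] for i in order]

    data = np.zeros((n_trials, n_chan, n_samples), dtype=float)
    # per-source scalp pattern x waveform, with per-trial amplitude jitter
    for src, a_cor, a_inc in per_source_amp:
        if src.component == "P2":
            wave = _p2_waveform(times, p2_lat, truth.p2_fwhm_ms)
        else:
            wave = _lsw_waveform(times, truth.lsw_onset_ms, truth.lsw_slope_ms)
        direction = source_space.positions[src.grid_index]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        pattern = leadfield.block(src.grid_index) @ direction  # uV per nA*m
        base = np.array([a_cor if c == CONDITIONS[0] else a_inc for c in conditions])
        jitter = (
            1.0 + rng.normal(0.0, truth.trial_amp_cv, n_trials)
            if truth.trial_amp_cv > 0
            else np.ones(n_trials)
        )
        amps = np.maximum(0.0, base * jitter)
        data += amps[:, None, None] * pattern[None, :, None] * wave[None, None, :]

    if truth.white_sigma_uv > 0:
        data += truth.white_sigma_uv * rng.standard_normal(data.shape)
    if truth.pink_sigma_uv > 0:
        data += truth.pink_sigma_uv * _pink_noise(
            rng, (n_trials, n_chan), n_samples, truth.one_over_f_exponent
        )

    n_art = int(round(truth.artifact_fraction * n_trials))
    art_trials = sorted(rng.choice(n_trials, size=n_art, replace=False).tolist())
    if n_art:
        # slow half-sine drift, strongest frontally — mimics ocular artifact
        drift = np.sin(np.pi * (times - times[0]) / (times[-1] - times[0]))
        profile = 0.25 + 0.75 * (montage.positions[:, 1] / montage.positions[:, 1].max())
        profile = np.clip(profile, 0.0, None)
        for t in art_trials:
            data[t] += truth.artifact_amplitude_uv * profile[:, None] * drift[None, :]

    sid = f"S{subject_index:02d}"
    epochs = EpochsSet(
        data=data.astype(np.float32),
        conditions=conditions,
        times_ms=times,
        channel_names=list(montage.labels),
        fs_hz=design.fs_hz,
        subject_id=sid,
        seed=int(ss.entropy),
    )
    sub_truth = SubjectTruth(sid, p2_lat, source_amps, art_trials, subject_index)
    return epochs, sub_truth


def simulate_study(
    design: StudyDesign,
    head: HeadGeometry,
    montage: Montage,
    source_space: SourceSpace,
    masks: RoiMaskSet,
    truth: GroundTruth,
    leadfield: LeadField,
    out_dir: Path,
    overwrite: bool = False,
) -> dict:
    """Simulate and write a full study to disk; returns the manifest.

    Layout: ``<out>/S00/epochs.npy+json`` per subject, plus montage.sfp,
    masks.json, truth.json and manifest.json (seeds, truth, SHA-256 file
    hashes).  Rerunning with the same master seed reproduces byte-identical
    arrays.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    write_montage_sfp(montage, out_dir / "montage.sfp", fiducials=head.fiducials)
    save_masks(masks, out_dir / "masks.json")
    truth_payload = asdict(truth)
    truth_payload["active_sources"] = [asdict(s) for s in truth.active_sources]
    (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=1))

    subjects = []
    for i in range(design.n_subjects):
        epochs, st = simulate_subject(
            design, montage, source_space, truth, leadfield, subject_index=i
        )
        sdir = out_dir / st.subject_id
        save_epochs(epochs, sdir / "epochs")
        subjects.append(
            {
                "subject_id": st.subject_id,
                "subject_index": st.seed,
                "p2_latency_ms": st.p2_latency_ms,
                "source_amps": {str(k): list(v) for k, v in st.source_amps.items()},
                "artifact_trials": st.artifact_trials,
                "epochs_sha256": sha256_of(sdir / "epochs.npy"),
            }
        )
    manifest = {
        "design": asdict(design),
        "master_seed": design.master_seed,
        "n_subjects": design.n_subjects,
        "subjects": subjects,
        "files": {
            "montage": sha256_of(out_dir / "montage.sfp"),
            "masks": sha256_of(out_dir / "masks.json"),
            "truth": sha256_of(out_dir / "truth.json"),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
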