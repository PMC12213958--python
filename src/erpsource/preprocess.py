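"""Scalp EEG preprocessing: zero-phase band-pass filtering, bad-channel
detection and spherical-spline interpolation, amplitude-based trial
rejection, average referencing, and subject inclusion rules."""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import fft, signal

from .containers import EpochsSet
from .forward import average_reference_matrix
from .geometry import Montage

__all__ = [
    "PreprocConfig",
    "detect_bad_channels",
    "interpolate_channels",
    "bandpass_filter",
    "apply_average_reference",
    "preprocess",
    "ExclusionReport",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing rules.

    Defaults follow common developmental-ERP practice: 0.1-30 Hz band-pass,
    epochs -100..1500 ms, absolute rejection threshold 200 uV, at most 8
    interpolated channels per subject, at least 10 artifact-free trials per
    condition, average reference.
    """

    highpass_hz: float = 0.1
    lowpass_hz: float = 30.0
    reject_uv: float = 200.0
    max_bad_channels: int = 8
    min_trials_per_condition: int = 10
    reference: str = "average"
    # windowed-sinc transition widths; the low edge is intentionally narrow
    transition_low_hz: float = 0.1
    transition_high_hz: float = 7.5

    def validate(self, fs_hz: float) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz < fs_hz / 2):
            raise ValueError("need 0 < highpass < lowpass < Nyquist")
        if self.reject_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class ExclusionReport:
    subject_id: str
    bad_channels: list[str]
    n_rejected_trials: int
    n_trials_kept: dict[str, int]
    excluded: bool
    reasons: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def detect_bad_channels(
    epochs: EpochsSet, flat_floor_uv2: float = 1e-12, z_thresh: float = 5.0
) -> list[str]:
    """Flag flatlined or abnormally high-variance channels.

    A channel is bad if its pooled variance falls below ``flat_floor_uv2``
    (flatline) or the robust z-score (median/MAD) of its log-variance
    exceeds ``z_thresh``.  Deterministic; an empty list is a valid result.
    """
    if epochs.n_channels < 8:
        raise ValueError("bad-channel detection expects at least 8 channels")
    var = epochs.data.astype(float).var(axis=(0, 2))
    # a channel is "flat" relative to an otherwise live recording; uniformly
    # silent data (e.g. an all-zero null fixture) flags nothing
    flat = (var < flat_floor_uv2) & (np.median(var) >= flat_floor_uv2)
    logv = np.log(np.maximum(var, flat_floor_uv2))
    med = np.median(logv)
    mad = np.median(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.inf
    z = (logv - med) / scale
    noisy = z > z_thresh
    return [epochs.channel_names[i] for i in np.flatnonzero(flat | noisy)]


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos) = 1/(4pi) sum (2n+1)/(n(n+1))^m P_n."""
    out = np.zeros_like(cosang, dtype=float)
    P_prev = np.ones_like(out)
    P = cosang.astype(float).copy()
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1.0)) ** m * P
        P_next = ((2 * n + 1) * cosang * P - n * P_prev) / (n + 1)
        P_prev, P = P, P_next
    return out / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = 4,
    reg: float = 1e-5,
    n_terms: int = 50,
) -> np.ndarray:
    """Spherical-spline interpolation operator (n_bad x n_good).

    Classical thin-plate spline on the sphere (order ``m``, diagonal
    regularization ``reg``) with the constant-offset constraint, so a
    constant field is reproduced exactly.
    """
    gp = good_pos / np.linalg.norm(good_pos, axis=1, keepdims=True)
    bp = bad_pos / np.linalg.norm(bad_pos, axis=1, keepdims=True)
    G = _spline_g(gp @ gp.T, m=m, n_terms=n_terms)
    Gi = _spline_g(bp @ gp.T, m=m, n_terms=n_terms)
    n = gp.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    B = np.zeros((bp.shape[0], n + 1))
    B[:, :n] = Gi
    B[:, n] = 1.0
    return B @ np.linalg.solve(A, np.vstack([np.eye(n), np.zeros((1, n))]))


def interpolate_channels(
    epochs: EpochsSet, montage: Montage, bad_channels: list[str]
) -> EpochsSet:
    """Replace bad-channel samples by spherical-spline interpolation from
    the good channels; good channels are untouched."""
    if not bad_channels:
        return epochs
    names = epochs.channel_names
    unknown = set(bad_channels) - set(names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    bad_idx = np.asarray([names.index(b) for b in bad_channels])
    good_idx = np.asarray([i for i in range(len(names)) if i not in set(bad_idx)])
    if good_idx.size < 4:
        raise ValueError("need at least 4 good channels for interpolation")
    W = interpolation_matrix(
        montage.positions[good_idx], montage.positions[bad_idx]
    )
    data = epochs.data.astype(float).copy()
    data[:, bad_idx, :] = np.einsum("bg,tgs->tbs", W, data[:, good_idx, :])
    return dc_replace(epochs, data=data)


def _design_fir(fs_hz: float, config: PreprocConfig, n_samples: int) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass taps; the length implied by the
    narrow low-edge transition is capped at the epoch length."""
    width = min(config.transition_low_hz, config.transition_high_hz)
    numtaps = int(np.ceil(3.3 * fs_hz / width))
    numtaps = min(numtaps, n_samples - 1)
    if numtaps % 2 == 0:
        numtaps -= 1
    numtaps = max(numtaps, 9)
    return signal.firwin(
        numtaps,
        [config.highpass_hz, config.lowpass_hz],
        pass_zero=False,
        window="hamming",
        fs=fs_hz,
    )


def bandpass_filter(epochs: EpochsSet, config: PreprocConfig) -> EpochsSet:
    """Zero-phase band-pass via a linear-phase FIR applied with mirror
    padding and group-delay compensation (no lag on symmetric inputs)."""
    config.validate(epochs.fs_hz)
    taps = _design_fir(epochs.fs_hz, config, epochs.data.shape[2])
    n_pad = (len(taps) - 1) // 2
    data = epochs.data.astype(float)
    padded = np.pad(data, ((0, 0), (0, 0), (n_pad, n_pad)), mode="reflect")
    n = padded.shape[2]
    nfft = int(fft.next_fast_len(n + len(taps) - 1))
    spec = fft.rfft(padded, nfft, axis=2) * fft.rfft(taps, nfft)
    full = fft.irfft(spec, nfft, axis=2)
    # 'same' segment of the full convolution, then strip the mirror padding
    start = (len(taps) - 1) // 2
    out = full[:, :, start : start + n]
    out = out[:, :, n_pad : n - n_pad] if n_pad else out
    return dc_replace(epochs, data=out)


def reject_trials(epochs: EpochsSet, reject_uv: float) -> tuple[EpochsSet, np.ndarray]:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere."""
    peak = np.abs(epochs.data).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > reject_uv)
    keep = [i for i in range(epochs.n_trials) if i not in set(rejected)]
    kept = dc_replace(
        epochs,
        data=epochs.data[keep],
        conditions=[epochs.conditions[i] for i in keep],
    )
    return kept, rejected


def apply_average_reference(epochs: EpochsSet) -> EpochsSet:
    H = average_reference_matrix(epochs.n_channels)
    data = np.einsum("ij,tjs->tis", H, epochs.data.astype(float))
    return dc_replace(epochs, data=data)


def preprocess(
    epochs: EpochsSet, config: PreprocConfig, montage: Montage
) -> tuple[EpochsSet, ExclusionReport]:
    """Full single-subject preprocessing chain.

    Order: bad-channel detection -> spline interpolation -> zero-phase
    band-pass -> absolute-amplitude trial rejection -> average reference ->
    inclusion rules (max 8 interpolated channels; minimum artifact-free
    trial count per condition).
    """
    config.validate(epochs.fs_hz)
    reasons: list[str] = []
    bad = detect_bad_channels(epochs)
    if len(bad) > config.max_bad_channels:
        reasons.append(
            f"{len(bad)} bad channels exceeds the maximum of {config.max_bad_channels}"
        )
        out = epochs
        rejected = np.asarray([], dtype=int)
    else:
        out = interpolate_channels(epochs, montage, bad)
        out = bandpass_filter(out, config)
        out, rejected = reject_trials(out, config.reject_uv)
        out = apply_average_reference(out)
    counts = {c: out.conditions.count(c) for c in sorted(set(epochs.conditions))}
    for cond, n in counts.items():
        if n < config.min_trials_per_condition and not reasons:
            reasons.append(
                f"only {n} trials in condition {cond!r} "
                f"(minimum {config.min_trials_per_condition})"
            )
    report = ExclusionReport(
        subject_id=epochs.subject_id,
        bad_channels=bad,
        n_rejected_trials=int(rejected.size),
        n_trials_kept=counts,
        excluded=bool(reasons),
        reasons=reasons,
    )
    return out, report
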