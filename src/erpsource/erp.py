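"""Scalp-level ERP component analysis.

Quantifies an early frontal positivity (P2, individual peak latency in
120-250 ms) and a late slow wave (LSW, fixed 1200 ms center) as mean
amplitudes over short windows, re-baselined to the preceding negative-going
segment, then tests the condition effect with a 2 (condition) x 3 (coronal)
x 3 (sagittal) within-subject ANOVA and Tukey-corrected estimated-marginal-
mean contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochsSet
from .geometry import Montage
from .simulate import CONDITIONS

__all__ = [
    "ComponentWindow",
    "collapsed_localizer",
    "locate_p2_window",
    "locate_lsw_window",
    "rebaseline",
    "cluster_means",
    "rm_anova_2x3x3",
    "emm_tukey_posthoc",
    "AnovaResult",
]

CORONAL_LEVELS = ("frontal", "central", "posterior")
SAGITTAL_LEVELS = ("left", "middle", "right")

P2_SEARCH_MS = (120.0, 250.0)
LSW_RANGE_MS = (1100.0, 1500.0)
P2_BASELINE_MS = (130.0, 140.0)
LSW_BASELINE_MS = (610.0, 620.0)
LSW_CENTER_MS = 1200.0


@dataclass(frozen=True)
class ComponentWindow:
    """A short measurement window for one ERP component."""

    component: str  # "P2" | "LSW"
    center_ms: float
    start_ms: float
    stop_ms: float
    baseline_ms: tuple[float, float]
    low_confidence: bool = False
    clipped: bool = False


@dataclass
class AnovaResult:
    """Within-subject ANOVA effects (condition-involving terms only)."""

    effects: pd.DataFrame  # effect, ss, df, ms, ss_err, df_err, F, p
    pooled_error_ms: float
    pooled_error_df: int
    n_subjects: int


def _frontal_mean(epochs: EpochsSet, montage: Montage) -> np.ndarray:
    idx = [i for i, c in enumerate(montage.coronal) if c == "frontal"]
    if not idx:
        raise ValueError("montage has no frontal channels")
    return epochs.data[:, idx, :].astype(float).mean(axis=1)


def collapsed_localizer(
    all_epochs: list[EpochsSet], montage: Montage
) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Grand-average ERP collapsed across trials, conditions and subjects,
    plus advisory P2 / LSW window ranges.

    The grand average pools every trial (subjects weighted by trial count).
    The suggested P2 range is the contiguous positive deflection of the
    frontal-cluster grand average overlapping 120-250 ms; the LSW range
    defaults to 1100-1500 ms.  Both are advisory and config-overridable.
    """
    if not all_epochs:
        raise ValueError("no included subjects")
    total = sum(e.n_trials for e in all_epochs)
    grand = sum(
        e.data.astype(float).sum(axis=0) for e in all_epochs
    ) / float(total)
    times = all_epochs[0].times_ms
    idx = [i for i, c in enumerate(montage.coronal) if c == "frontal"]
    frontal = grand[idx].mean(axis=0)
    in_range = (times >= P2_SEARCH_MS[0]) & (times <= P2_SEARCH_MS[1])
    p2_range = P2_SEARCH_MS
    if np.any(in_range & (frontal > 0)):
        peak = np.flatnonzero(in_range)[np.argmax(frontal[in_range])]
        lo = peak
        while lo > 0 and frontal[lo - 1] > 0:
            lo -= 1
        hi = peak
        while hi < times.size - 1 and frontal[hi + 1] > 0:
            hi += 1
        p2_range = (
            max(float(times[lo]), P2_SEARCH_MS[0]),
            min(float(times[hi]), P2_SEARCH_MS[1]),
        )
    return grand, p2_range, LSW_RANGE_MS


def locate_p2_window(
    epochs: EpochsSet,
    montage: Montage,
    search_range_ms: tuple[float, float] = P2_SEARCH_MS,
    window_ms: float = 50.0,
) -> ComponentWindow:
    """Individual P2 window: median of per-trial frontal peak latencies.

    Per trial, the latency of the maximum of the frontal-cluster mean
    within the search range is found (earliest sample on ties); the window
    is centered on the lower median of those latencies and clipped to the
    epoch.  A flat signal yields a low-confidence flag.
    """
    times = epochs.times_ms
    mask = (times >= search_range_ms[0]) & (times <= search_range_ms[1])
    if not np.any(mask):
        raise ValueError("empty P2 search range")
    sig = _frontal_mean(epochs, montage)[:, mask]
    t_in = times[mask]
    peaks = t_in[np.argmax(sig, axis=1)]  # argmax takes the earliest tie
    low_conf = bool(np.all(np.ptp(sig, axis=1) == 0))
    srt = np.sort(peaks)
    center = float(srt[(len(srt) - 1) // 2])  # lower median for even counts
    start = max(center - window_ms / 2, float(times[0]))
    stop = min(center + window_ms / 2, float(times[-1]))
    clipped = (start != center - window_ms / 2) or (stop != center + window_ms / 2)
    return ComponentWindow("P2", center, start, stop, P2_BASELINE_MS, low_conf, clipped)


def locate_lsw_window(
    window_ms: float = 50.0, epoch_ms: tuple[float, float] = (-100.0, 1500.0)
) -> ComponentWindow:
    """Fixed LSW window: 1200 ms center for all subjects (default 1175-1225)."""
    center = LSW_CENTER_MS
    start = center - window_ms / 2
    stop = center + window_ms / 2
    clipped = False
    if start < epoch_ms[0]:
        start, clipped = epoch_ms[0], True
    if stop > epoch_ms[1]:
        stop, clipped = epoch_ms[1], True
    return ComponentWindow("LSW", center, start, stop, LSW_BASELINE_MS, False, clipped)


def rebaseline(epochs: EpochsSet, window: ComponentWindow) -> EpochsSet:
    """Subtract the per-trial, per-channel mean over the component's
    baseline window (the preceding negative-going segment)."""
    lo, hi = window.baseline_ms
    mask = epochs.time_mask(lo, hi)
    if not np.any(mask):
        raise ValueError("baseline window lies outside the epoch")
    data = epochs.data.astype(float)
    base = data[:, :, mask].mean(axis=2, keepdims=True)
    return dc_replace(epochs, data=data - base)


def cluster_means(
    epochs: EpochsSet, window: ComponentWindow, montage: Montage
) -> pd.DataFrame:
    """Mean amplitude per condition in each coronal x sagittal cell.

    Averages over trials of the condition, window samples, and the cell's
    channels.  Returns a tidy frame: condition, coronal, sagittal, amplitude.
    """
    mask = epochs.time_mask(window.start_ms, window.stop_ms)
    clusters = montage.cluster_channels()
    rows = []
    for cond in sorted(set(epochs.conditions)):
        tr = [i for i, c in enumerate(epochs.conditions) if c == cond]
        seg = epochs.data[tr][:, :, mask].astype(float)
        for cor in CORONAL_LEVELS:
            for sag in SAGITTAL_LEVELS:
                ch = clusters.get((cor, sag))
                if ch is None or ch.size == 0:
                    raise ValueError(f"empty channel cluster ({cor}, {sag})")
                rows.append(
                    {
                        "condition": cond,
                        "coronal": cor,
                        "sagittal": sag,
                        "amplitude": float(seg[:, ch, :].mean()),
                    }
                )
    return pd.DataFrame(rows)


def _amplitude_array(amplitudes: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Tidy frame (subject, condition, coronal, sagittal, amplitude) ->
    balanced 4-D array y[s, c, a, b]."""
    subjects = sorted(amplitudes["subject"].unique())
    y = np.full((len(subjects), 2, 3, 3), np.nan)
    pos = {
        (s, c, a, b): (i, j, k, l)
        for i, s in enumerate(subjects)
        for j, c in enumerate(CONDITIONS)
        for k, a in enumerate(CORONAL_LEVELS)
        for l, b in enumerate(SAGITTAL_LEVELS)
    }
    for _, r in amplitudes.iterrows():
        key = (r["subject"], r["condition"], r["coronal"], r["sagittal"])
        if key not in pos:
            raise ValueError(f"unexpected design cell {key}")
        y[pos[key]] = r["amplitude"]
    if np.isnan(y).any():
        raise ValueError("design is unbalanced: missing cells")
    return y, subjects


def _effect_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares of the pure interaction term over the given axes of a
    balanced full-factorial array (inclusion-exclusion over marginal means)."""
    full_axes = tuple(range(y.ndim))
    other = tuple(a for a in full_axes if a not in axes)
    term = np.zeros([y.shape[a] if a in axes else 1 for a in full_axes])
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            drop = tuple(a for a in full_axes if a not in sub)
            marg = y.mean(axis=drop, keepdims=True)
            term = term + (-1) ** (len(axes) - len(sub)) * marg
    n_other = int(np.prod([y.shape[a] for a in other])) if other else 1
    return float(n_other * np.sum(term**2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal Helmert-style contrast rows."""
    rows = []
    for i in range(1, k):
        row = np.zeros(k)
        row[:i] = 1.0 / i
        row[i] = -1.0
        rows.append(row / np.linalg.norm(row))
    return np.asarray(rows)


def _gg_epsilon(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for a within-subject effect.

    Projects each subject's cell vector onto the effect's orthonormal
    contrast space and applies the standard (tr S)^2 / (d tr S^2) formula
    to the sample covariance of the scores.
    """
    n = y.shape[0]
    mats = []
    for a in range(1, 4):
        k = y.shape[a]
        mats.append(
            _orthonormal_contrasts(k) if a in axes else np.full((1, k), 1.0 / k)
        )
    M = np.kron(np.kron(mats[0], mats[1]), mats[2])  # (d, 18)
    z = y.reshape(n, -1) @ M.T
    S = np.cov(z, rowvar=False).reshape(M.shape[0], M.shape[0])
    d = M.shape[0]
    tr = np.trace(S)
    denom = d * np.trace(S @ S)
    return float(tr**2 / denom) if denom > 0 else 1.0


def rm_anova_2x3x3(
    amplitudes: pd.DataFrame, sphericity_correction: str | None = None
) -> AnovaResult:
    """Univariate within-subject ANOVA on the 2 x 3 x 3 cell means.

    Factors: condition (2), coronal plane (3), sagittal plane (3), all
    within subject; each effect is tested against its interaction with
    subject.  Only condition-involving effects are reported.  No sphericity
    correction is applied by default (condition itself has 1 df);
    ``sphericity_correction='gg'`` applies Greenhouse-Geisser adjusted
    degrees of freedom to the multi-df effects.
    """
    if sphericity_correction not in (None, "gg"):
        raise ValueError("sphericity_correction must be None or 'gg'")
    y, subjects = _amplitude_array(amplitudes)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    S, C, A, B = 0, 1, 2, 3
    effects = {
        "condition": (C,),
        "condition:coronal": (C, A),
        "condition:sagittal": (C, B),
        "condition:coronal:sagittal": (C, A, B),
    }
    rows = []
    pooled_ss = 0.0
    pooled_df = 0
    for name, axes in effects.items():
        df_eff = int(np.prod([y.shape[a] - 1 for a in axes]))
        ss_eff = _effect_ss(y, axes)
        err_axes = (S,) + axes
        df_err = df_eff * (n - 1)
        ss_err = _effect_ss(y, err_axes)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        eps = 1.0
        if sphericity_correction == "gg" and df_eff > 1:
            eps = _gg_epsilon(y, axes)
        if np.isfinite(F):
            p = float(stats.f.sf(F, eps * df_eff, eps * df_err))
        else:
            p = 0.0
        rows.append(
            {
                "effect": name,
                "ss": ss_eff,
                "df": df_eff,
                "ss_err": ss_err,
                "df_err": df_err,
                "F": F,
                "epsilon": eps,
                "p": p,
            }
        )
        pooled_ss += ss_err
        pooled_df += df_err
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table, pooled_ss / pooled_df if pooled_df else np.nan,
                       pooled_df, n)


def emm_tukey_posthoc(
    amplitudes: pd.DataFrame, anova: AnovaResult, by: str = "cell"
) -> pd.DataFrame:
    """Condition contrasts on estimated marginal means, Tukey-corrected.

    ``by='cell'`` contrasts the two conditions within every coronal x
    sagittal cell; ``by='sagittal'`` within each sagittal level (averaging
    coronal).  Standard errors use the pooled condition-involving
    within-subject error; p-values come from the studentized-range
    distribution with k = 2 means (which reduces to the unadjusted paired
    contrast, as a two-level factor needs no multiplicity adjustment).
    """
    y, subjects = _amplitude_array(amplitudes)
    n = len(subjects)
    ms, df = anova.pooled_error_ms, anova.pooled_error_df
    rows = []
    if by == "cell":
        groups = [
            ((cor, sag), y[:, :, k, l])
            for k, cor in enumerate(CORONAL_LEVELS)
            for l, sag in enumerate(SAGITTAL_LEVELS)
        ]
        n_avg = 1
    elif by == "sagittal":
        groups = [((sag,), y[:, :, :, l].mean(axis=2))
                  for l, sag in enumerate(SAGITTAL_LEVELS)]
        n_avg = 3
    else:
        raise ValueError("by must be 'cell' or 'sagittal'")
    for key, cell in groups:
        emm = cell.mean(axis=0)  # (2,) condition means
        diff = float(emm[0] - emm[1])
        se = np.sqrt(2.0 * ms / (n * n_avg))
        t = diff / se if se > 0 else np.nan
        if np.isfinite(t):
            # k = 2 means: the studentized-range p equals the two-sided t p
            # exactly (and is much cheaper to evaluate)
            p = float(2.0 * stats.t.sf(abs(t), df))
        else:
            p = np.nan
        rows.append(
            {
                **{f"level_{i}": k for i, k in enumerate(key)},
                "contrast": f"{CONDITIONS[0]} - {CONDITIONS[1]}",
                "estimate": diff,
                "se": float(se),
                "df": df,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p_tukey": p,
            }
        )
    return pd.DataFrame(rows)
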