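"""Acquisition filter chain and artifact masking.

The recordings are filtered the way the acquisition chain specifies:
0.5–70 Hz bandpass plus a mains notch. Filtering is zero-phase
(forward-backward) with a 4th-order Butterworth bandpass and a biquad
notch so spike morphology and timing are preserved for the detector.

Artifact handling mirrors a manual-review workflow with a deterministic
surrogate: segments are flagged when the instantaneous amplitude exceeds
a robust multiple of the channel's scale, or when a high-frequency (EMG)
band envelope exceeds its own robust threshold. Externally supplied
manual masks are merged in by union downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InputError, ParameterError
from .io_formats import AnnotationTrack, Interval, Recording

__all__ = [
    "PreprocessConfig", "ArtifactConfig",
    "bandpass_notch_filter", "flag_artifacts", "valid_intervals",
    "merge_intervals", "robust_scale",
]


@dataclass
class PreprocessConfig:
    bp_low: float = 0.5          # Hz
    bp_high: float = 70.0        # Hz
    notch_freq: float | None = 60.0  # Hz; None disables the notch
    notch_q: float = 30.0
    filter_order: int = 4
    zero_phase: bool = True


@dataclass
class ArtifactConfig:
    amp_thresh_mult: float = 6.0      # multiples of robust signal scale
    emg_band: tuple[float, float] = (70.0, 250.0)  # Hz, on the unfiltered signal
    emg_thresh_mult: float = 4.0      # multiples of robust high-band envelope
    emg_env_s: float = 0.1            # envelope smoothing window, s
    amp_min_dur_s: float = 0.3        # amplitude-rule runs shorter than this are
                                      # ignored (brief epileptiform transients are
                                      # not movement artifacts)
    amp_gap_s: float = 0.05           # sub-threshold dips shorter than this do
                                      # not split an amplitude-rule run
    pad_s: float = 0.5                # padding around each flagged segment
    min_gap_s: float = 0.5            # merge segments closer than this

    def __post_init__(self):
        if self.amp_thresh_mult <= 0 or self.emg_thresh_mult <= 0:
            raise ParameterError("artifact threshold multipliers must be > 0")
        if self.pad_s < 0:
            raise ParameterError("pad_s must be >= 0")


def robust_scale(x: np.ndarray) -> float:
    """MAD-based robust standard-deviation estimate (MAD × 1.4826)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)) * 1.4826)


def _design_bandpass(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    if cfg.bp_high >= fs / 2:
        raise ParameterError(
            f"bandpass upper edge {cfg.bp_high} Hz must be below Nyquist {fs / 2} Hz")
    if not (0 < cfg.bp_low < cfg.bp_high):
        raise ParameterError("need 0 < bp_low < bp_high")
    return sps.butter(cfg.filter_order, [cfg.bp_low, cfg.bp_high],
                      btype="bandpass", fs=fs, output="sos")


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass_notch_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply the 0.5–70 Hz bandpass and mains notch to every channel.

    Returns a new Recording of identical length and fs. With
    ``zero_phase`` (default) the filters are applied forward-backward,
    which squares their magnitude response and removes group delay.
    """
    cfg = cfg or PreprocessConfig()
    sos_bp = _design_bandpass(cfg, rec.fs)
    sos_notch = None
    if cfg.notch_freq is not None and cfg.bp_low < cfg.notch_freq < cfg.bp_high:
        b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_q, fs=rec.fs)
        sos_notch = sps.tf2sos(b, a)
    out = {}
    for name, x in rec.signals.items():
        y = _apply(sos_bp, x, cfg.zero_phase)
        if sos_notch is not None:
            y = _apply(sos_notch, y, cfg.zero_phase)
        out[name] = y
    return rec.copy_with_signals(out)


def merge_intervals(pairs: list[tuple[float, float]],
                    min_gap: float = 0.0) -> list[tuple[float, float]]:
    """Union of half-open intervals, merging any separated by < min_gap."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for lo, hi in pairs[1:]:
        if lo < merged[-1][1] + min_gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged if hi > lo]


def _runs_above(flag: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample index pairs."""
    if not flag.any():
        return []
    d = np.diff(flag.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if flag[0]:
        starts.insert(0, 0)
    if flag[-1]:
        ends.append(len(flag))
    return list(zip(starts, ends))


def flag_artifacts(rec: Recording, cfg: ArtifactConfig | None = None) -> AnnotationTrack:
    """Flag high-amplitude / EMG-contaminated segments on the raw recording.

    Per channel, samples are flagged where |signal| exceeds
    ``amp_thresh_mult`` × robust scale, or where the rectified
    high-band (EMG) envelope exceeds ``emg_thresh_mult`` × its robust
    scale. Flagged runs are padded by ``pad_s``, merged when separated
    by less than ``min_gap_s``, and unioned across channels onto
    channel ``*``.
    """
    cfg = cfg or ArtifactConfig()
    if rec.n_samples == 0:
        raise InputError("cannot flag artifacts on an empty recording")
    if rec.duration_s <= 2 * cfg.pad_s:
        raise InputError("recording shorter than 2×pad_s")
    fs = rec.fs
    hi = min(cfg.emg_band[1], 0.45 * fs)
    sos_emg = None
    if hi > cfg.emg_band[0]:
        sos_emg = sps.butter(4, [cfg.emg_band[0], hi], btype="bandpass",
                             fs=fs, output="sos")
    env_n = max(1, int(round(cfg.emg_env_s * fs)))
    kernel = np.ones(env_n) / env_n

    min_run = int(round(cfg.amp_min_dur_s * fs))
    pairs: list[tuple[float, float]] = []
    for name, x in rec.signals.items():
        scale = robust_scale(x)
        if scale > 0:
            amp_flag = np.abs(x) > cfg.amp_thresh_mult * scale
        else:
            amp_flag = np.abs(x) > 0  # zero-scale channel: flag any excursion
        # a sustained excursion, not a brief (epileptiform-scale) transient;
        # short supra-threshold runs separated by sub-threshold dips still
        # count when their envelope stays up, so close gaps before timing
        runs = [(a, b) for a, b in _runs_above(amp_flag)]
        closed = merge_intervals([(a / fs, b / fs) for a, b in runs],
                                 min_gap=cfg.amp_gap_s)
        kept = [(lo, hi) for lo, hi in closed if hi - lo >= min_run / fs]
        flag = np.zeros(len(x), dtype=bool)
        if sos_emg is not None:
            emg = sps.sosfiltfilt(sos_emg, x)
            env = np.convolve(np.abs(emg), kernel, mode="same")
            # floor the envelope scale at a fraction of the broadband
            # scale so a cleanly band-limited signal (negligible true
            # high-band energy) is not flagged on its noise floor
            escale = max(robust_scale(env), 0.1 * scale)
            if escale > 0:
                flag |= env > cfg.emg_thresh_mult * escale
        for a, b in _runs_above(flag):
            kept.append((a / fs, b / fs))
        for lo, hi in kept:
            pairs.append((max(0.0, lo - cfg.pad_s),
                          min(rec.duration_s, hi + cfg.pad_s)))

    merged = merge_intervals(pairs, min_gap=cfg.min_gap_s)
    return AnnotationTrack([Interval(lo, hi - lo, "*", "artifact")
                            for lo, hi in merged])


def valid_intervals(duration_s: float,
                    mask: AnnotationTrack | None) -> list[tuple[float, float]]:
    """Complement of the mask union within [0, duration_s).

    Returned intervals are disjoint, sorted, and non-empty; an empty
    list is returned when the mask covers everything.
    """
    if duration_s <= 0:
        return []
    if mask is None or len(mask) == 0:
        return [(0.0, duration_s)]
    covered = merge_intervals(
        [(max(0.0, iv.onset_s), min(duration_s, iv.end_s))
         for iv in mask if iv.onset_s < duration_s and iv.end_s > 0])
    out = []
    cursor = 0.0
    for lo, hi in covered:
        if lo > cursor:
            out.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return out
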