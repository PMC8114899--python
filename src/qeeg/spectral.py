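"""Power spectra with the study's FFT configuration and band aggregation.

The PSD is a Welch average over Hann-windowed segments of 2042 samples
with 50% overlap (the acquisition software's printed configuration; a
power-of-two size can be configured instead). Segments are drawn only
from artifact-free intervals; a segment that would cross an interval
boundary is discarded rather than truncated, so every averaged segment
is uniformly windowed.

Normalization is one-sided density scaling (μV²/Hz) with Hann window
power correction, so the integral of the PSD over frequency equals the
mean signal power (Parseval).

Band aggregation follows the printed band table: δ 0.5–4, θ 5–8,
α 8–12, β 14–29, γ 30–50 Hz, both edges inclusive, membership by FFT
bin center. The printed inter-band gaps (4–5, 12–14, 29–30 Hz) are
preserved, not redistributed. Band power is *integrated* PSD (μV²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "SpectralConfig", "PowerSpectrum", "DEFAULT_BANDS", "BandDefinition",
    "compute_psd", "integrate_band_power", "per_hz_power",
    "power_at_frequencies", "compute_spectrogram",
]

#: Printed band edges in Hz; both edges inclusive, membership by bin center.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (14.0, 29.0),
    "gamma": (30.0, 50.0),
}

BandDefinition = dict[str, tuple[float, float]]

#: Frequency range of the reported total power, Hz.
TOTAL_RANGE = (0.5, 50.0)


@dataclass
class SpectralConfig:
    fft_size: int = 2042          # segment length in samples (printed value)
    window: str = "hann"
    overlap_frac: float = 0.5
    detrend: str = "mean"         # "mean" or "none"

    def __post_init__(self):
        if self.fft_size < 2:
            raise ParameterError("fft_size must be >= 2")
        if not (0 <= self.overlap_frac < 1):
            raise ParameterError("overlap_frac must be in [0, 1)")
        if self.window != "hann":
            raise ParameterError("only the Hann window is supported")
        if self.detrend not in ("mean", "none"):
            raise ParameterError("detrend must be 'mean' or 'none'")


@dataclass
class PowerSpectrum:
    freqs: np.ndarray            # Hz, length fft_size//2 + 1
    psd: np.ndarray              # μV²/Hz
    n_segments: int
    channel: str = ""

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def integrate(self, lo: float, hi: float, *, right_open: bool = False) -> float:
        """Integrated power (μV²) over bins whose center lies in [lo, hi]
        (or [lo, hi) when right_open)."""
        f = self.freqs
        sel = (f >= lo) & ((f < hi) if right_open else (f <= hi))
        return float(np.sum(self.psd[sel]) * self.df)

    def integrate_exact(self, lo: float, hi: float) -> float:
        """Integral of the piecewise-constant PSD over [lo, hi).

        Each FFT bin is a rectangle [f - Δf/2, f + Δf/2) clipped to
        [0, ∞); partial overlaps count fractionally, so disjoint
        intervals are exactly additive.
        """
        df = self.df
        rect_lo = np.maximum(self.freqs - df / 2.0, 0.0)
        rect_hi = self.freqs + df / 2.0
        w = np.clip(np.minimum(rect_hi, hi) - np.maximum(rect_lo, lo), 0.0, None)
        return float(np.sum(self.psd * w))


def _segment_starts(i0: int, i1: int, nper: int, hop: int) -> range:
    if i1 - i0 < nper:
        return range(0)
    return range(i0, i1 - nper + 1, hop)


def _psd_segments(signal: np.ndarray, fs: float, cfg: SpectralConfig,
                  intervals: list[tuple[float, float]] | None):
    """Yield one-sided density-scaled periodograms of each usable segment."""
    x = np.asarray(signal, dtype=float)
    nper = cfg.fft_size
    hop = max(1, int(round(nper * (1 - cfg.overlap_frac))))
    win = sps.get_window("hann", nper, fftbins=True)
    scale = 1.0 / (fs * np.sum(win ** 2))
    if intervals is None:
        intervals = [(0.0, len(x) / fs)]
    segs = []
    centers = []
    for lo, hi in intervals:
        i0 = int(np.ceil(lo * fs - 1e-9))
        i1 = min(len(x), int(np.floor(hi * fs + 1e-9)))
        for s in _segment_starts(i0, i1, nper, hop):
            seg = x[s:s + nper]
            if cfg.detrend == "mean":
                seg = seg - seg.mean()
            spec = np.abs(np.fft.rfft(win * seg)) ** 2 * scale
            spec[1:] *= 2.0
            if nper % 2 == 0:
                spec[-1] /= 2.0
            segs.append(spec)
            centers.append((s + nper / 2) / fs)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, segs, centers


def compute_psd(signal: np.ndarray, fs: float, cfg: SpectralConfig | None = None,
                intervals: list[tuple[float, float]] | None = None,
                channel: str = "") -> PowerSpectrum:
    """Welch PSD (μV²/Hz) restricted to artifact-free intervals.

    ``intervals`` are half-open (start_s, end_s) pairs, e.g. from
    :func:`qeeg.preprocess.valid_intervals`; None means the whole signal.
    Raises :class:`InsufficientDataError` when no interval can hold a
    full segment.
    """
    cfg = cfg or SpectralConfig()
    freqs, segs, _ = _psd_segments(signal, fs, cfg, intervals)
    if not segs:
        avail = 0 if intervals is None else max(
            [0] + [int((hi - lo) * fs) for lo, hi in intervals])
        raise InsufficientDataError(
            f"insufficient clean data: need {cfg.fft_size} contiguous samples, "
            f"longest clean stretch has {avail}",
            required=cfg.fft_size, available=avail)
    psd = np.mean(segs, axis=0)
    return PowerSpectrum(freqs=freqs, psd=psd, n_segments=len(segs), channel=channel)


def integrate_band_power(ps: PowerSpectrum,
                         bands: BandDefinition | None = None) -> dict[str, float]:
    """Integrated power per named band (μV²) plus the 0.5–50 Hz total.

    A bin belongs to a band when its center frequency lies in
    [lo, hi] inclusive; bins in the printed inter-band gaps count
    toward no band (but do count toward the total).
    """
    bands = bands or DEFAULT_BANDS
    fmax = float(ps.freqs[-1])
    out = {}
    for name, (lo, hi) in bands.items():
        if lo >= hi:
            raise ParameterError(f"band {name!r} has lo >= hi")
        if hi > fmax:
            raise ParameterError(
                f"band {name!r} upper edge {hi} Hz exceeds spectrum range {fmax} Hz")
        out[name] = ps.integrate(lo, hi)
    out["total"] = ps.integrate(*TOTAL_RANGE)
    return out


def per_hz_power(ps: PowerSpectrum, max_hz: float = 50.0) -> np.ndarray:
    """Power in 1-Hz bins centered on integers 0..max_hz (μV² each).

    Bin k integrates the piecewise-constant PSD over
    [k-0.5, k+0.5) ∩ [0, ∞); the bins partition the axis and are
    exactly additive. 51 bins at the default, matching the
    per-frequency comparison design.
    """
    if max_hz > ps.freqs[-1]:
        raise ParameterError(
            f"max_hz {max_hz} exceeds Nyquist/spectrum range {ps.freqs[-1]}")
    ks = np.arange(0, int(max_hz) + 1)
    return np.array([ps.integrate_exact(max(k - 0.5, 0.0), k + 0.5) for k in ks])


def power_at_frequencies(ps: PowerSpectrum, freqs_hz=None) -> np.ndarray:
    """Power (μV², over a 1-Hz equivalent width) at discrete frequencies.

    Samples the PSD at the bin nearest each requested frequency
    (default: integers 0..50) and scales by 1 Hz. This is the input
    for the per-frequency genotype × frequency ANOVA: unlike the
    integrated 1-Hz bins of :func:`per_hz_power`, sampled values at
    integer spacing do not share window-leakage boundary bins, so the
    per-frequency observations entering the inferential table are
    statistically independent.
    """
    if freqs_hz is None:
        freqs_hz = np.arange(0, 51)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.max() > ps.freqs[-1]:
        raise ParameterError(
            f"requested frequency {freqs_hz.max()} exceeds spectrum range "
            f"{ps.freqs[-1]}")
    idx = np.round(freqs_hz / ps.df).astype(int)
    return ps.psd[idx] * 1.0


def compute_spectrogram(signal: np.ndarray, fs: float,
                        cfg: SpectralConfig | None = None):
    """Per-segment PSD matrix (freqs × times) with segment center times.

    Columns use the same normalization as :func:`compute_psd`, so the
    column mean over a stationary signal equals the Welch average.
    Returns (freqs, times, Sxx).
    """
    cfg = cfg or SpectralConfig()
    freqs, segs, centers = _psd_segments(signal, fs, cfg, None)
    if not segs:
        raise InsufficientDataError(
            f"signal shorter than one segment ({cfg.fft_size} samples)",
            required=cfg.fft_size, available=len(signal))
    return freqs, np.array(centers), np.column_stack(segs)
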