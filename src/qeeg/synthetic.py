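"""Synthetic WT/AS-like EEG with known ground truth.

The generator produces the statistical structure the analysis assumes,
so every stage — filtering, band power, detection, percent-time,
cohort statistics — can be exercised end-to-end with exact ground
truth and no recordings on disk.

Background EEG is a sum of independent band-limited Gaussian noise
components, one per frequency band, each scaled so its integrated
power matches a per-band target shaped like the study's band-power
tables (WT-like defaults δ 700, θ 220, α 100, β 115, γ 60 μV²). The
AS-like condition multiplies the δ target (default 1.7, the
three-week cortical δ ratio in the published band table). A neonatal
"discontinuous" mode gates the background between full-scale bursts
and 0.2× suppression stretches with exponential segment lengths.

Epileptiform events are injected at Poisson onsets: biphasic spikes
(60–150 ms, peak = 4× background baseline by default) and polyspikes
(4–5 alternating-phase lobes spanning 0.6–1.2 s, so the clean template
crosses the zero line more than twice). Movement/EMG artifacts are
1–5 s bursts of high-amplitude 20–250 Hz noise. Every generator output
is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epileptiform import DetectorConfig, estimate_baseline_amplitude
from .errors import InputError, ParameterError
from .io_formats import (AnnotationTrack, Cycle, Genotype, Interval, Recording,
                         SubjectMeta)
from .spectral import DEFAULT_BANDS, SpectralConfig, compute_psd, integrate_band_power

__all__ = [
    "SynthConfig", "GroundTruth", "Cohort",
    "generate_background", "inject_spike_events", "inject_artifacts",
    "generate_recording", "generate_cohort", "cohort_per_hz_table",
]

#: WT-like per-band background power targets, μV² (band-table magnitudes).
WT_BAND_TARGETS: dict[str, float] = {
    "delta": 700.0, "theta": 220.0, "alpha": 100.0, "beta": 115.0, "gamma": 60.0,
}

DEFAULT_CHANNELS = ("ctx_L", "ctx_R", "hpc")


@dataclass
class SynthConfig:
    fs: float = 2000.0
    duration_s: float = 300.0
    band_power_targets: dict[str, float] = field(
        default_factory=lambda: dict(WT_BAND_TARGETS))
    delta_mult: float = 1.0            # genotype multiplier on the δ target
    spike_rate_per_min: float = 0.0
    polyspike_frac: float = 0.25
    spike_amp_mult: float = 4.0        # peak as multiple of background baseline
    artifact_rate_per_min: float = 0.0
    artifact_amp_mult: float = 10.0    # multiple of background robust scale
    discontinuous: bool = False
    burst_s: float = 3.0               # mean burst length, neonatal mode
    suppression_s: float = 3.0         # mean suppression length
    suppression_scale: float = 0.2
    subject_sigma: float = 0.0         # lognormal sd of per-subject band multipliers
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self):
        if self.delta_mult <= 0:
            raise ParameterError("delta_mult must be > 0")
        if self.spike_rate_per_min < 0 or self.artifact_rate_per_min < 0:
            raise ParameterError("rates must be >= 0")
        if not (0 <= self.polyspike_frac <= 1):
            raise ParameterError("polyspike_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    events: AnnotationTrack
    artifacts: AnnotationTrack
    true_band_powers: dict[str, float]
    seed: int


@dataclass
class Cohort:
    subjects: list[tuple[Recording, GroundTruth]]
    band_table: pd.DataFrame     # rows keyed by subject/genotype/channel/cycle
    per_hz_table: pd.DataFrame   # long format: value, genotype, frequency, subject


def _band_component(rng: np.random.Generator, n: int, fs: float,
                    lo: float, hi: float) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz (unit white-noise input).

    Deliberately not normalized by its realized standard deviation:
    the sample variance of a band with few low-frequency cycles
    fluctuates strongly, and dividing by it would inject that
    fluctuation into every frequency bin as a common factor,
    correlating per-Hz measurements that should be independent.
    """
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


def _effective_targets(cfg: SynthConfig) -> dict[str, float]:
    t = dict(cfg.band_power_targets)
    t["delta"] = t["delta"] * cfg.delta_mult
    return t


@lru_cache(maxsize=64)
def _band_gain(fs: float, band: str) -> float:
    """Expected measured in-band power of a band component per unit
    white-noise input variance.

    Folds together the filter's power gain and the analysis chain's
    capture (the ~1-s Hann segments and per-segment mean detrend lose
    sub-resolution power — δ would undershoot by ~30% otherwise — and
    the bin-center band rule clips the filter skirts). Estimated once
    per (fs, band) on a long fixed reference realization: an ensemble
    constant, deliberately not the subject's own realization, so each
    subject keeps its natural sampling variability around the target.
    """
    lo, hi = DEFAULT_BANDS[band]
    n_ref = int(600.0 * fs)
    band_ix = sorted(DEFAULT_BANDS).index(band)
    ref = _band_component(np.random.default_rng([987654321, band_ix]),
                          n_ref, fs, lo, hi)
    ps = compute_psd(ref, fs, SpectralConfig())
    return ps.integrate(lo, hi)


def generate_background(cfg: SynthConfig, seed: int | None = None) -> np.ndarray:
    """Shaped-noise background hitting the per-band power targets.

    Each band component is drawn from its own child generator so the
    δ multiplier changes only the δ component for a fixed seed.
    Components are scaled by the cached ensemble band gain, so the
    *expected* measured band power equals the target while each
    realization keeps its finite-duration sampling variance.
    """
    seed = cfg.seed if seed is None else seed
    if cfg.duration_s < 10:
        raise ParameterError("duration_s must be >= 10 (two cycles of 0.5 Hz "
                             "plus stable filtering)")
    n = int(round(cfg.duration_s * cfg.fs))
    targets = _effective_targets(cfg)
    out = np.zeros(n)
    for i, (band, power) in enumerate(sorted(targets.items())):
        if power <= 0:
            raise ParameterError(f"band target {band!r} must be > 0")
        lo, hi = DEFAULT_BANDS[band]
        comp = _band_component(np.random.default_rng([seed, i]), n, cfg.fs, lo, hi)
        out += comp * np.sqrt(power / _band_gain(cfg.fs, band))
    return out


def _gate(rng: np.random.Generator, n: int, fs: float, cfg: SynthConfig) -> np.ndarray:
    """Burst/suppression amplitude gate for the neonatal discontinuous mode."""
    gate = np.ones(n)
    t = 0
    burst = True
    while t < n:
        mean = cfg.burst_s if burst else cfg.suppression_s
        seg = max(1, int(round(rng.exponential(mean) * fs)))
        gate[t:t + seg] = 1.0 if burst else cfg.suppression_scale
        t += seg
        burst = not burst
    return gate


def _spike_template(fs: float, dur_s: float, peak: float) -> np.ndarray:
    """Biphasic spike: sharp positive lobe followed by a smaller negative one."""
    n1 = max(2, int(round(dur_s * 0.4 * fs)))
    n2 = max(2, int(round(dur_s * 0.6 * fs)))
    lobe1 = np.sin(np.linspace(0, np.pi, n1)) * peak
    lobe2 = -np.sin(np.linspace(0, np.pi, n2)) * 0.6 * peak
    return np.concatenate([lobe1, lobe2])


def _polyspike_template(rng: np.random.Generator, fs: float, dur_s: float,
                        peak: float, n_lobes: int) -> np.ndarray:
    """4–5 alternating-phase lobes; the clean template crosses zero
    n_lobes − 1 >= 3 times and every lobe reaches the amplitude criterion."""
    lens = rng.uniform(0.8, 1.2, size=n_lobes)
    lens = np.maximum(2, np.round(lens / lens.sum() * dur_s * fs)).astype(int)
    lobes = []
    for i, m in enumerate(lens):
        amp = peak * rng.uniform(0.85, 1.0) * (1 if i % 2 == 0 else -1)
        lobes.append(np.sin(np.linspace(0, np.pi, m)) * amp)
    return np.concatenate(lobes)


def _place_events(rng: np.random.Generator, duration_s: float, rate_per_min: float,
                  len_sampler, forbidden: list[tuple[float, float]],
                  min_gap: float = 0.5) -> list[tuple[float, float]]:
    """Poisson-onset placement avoiding forbidden intervals and each other."""
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    if n_events == 0:
        return []
    mean_len = 1.5
    if n_events * (mean_len + min_gap) > 0.5 * duration_s:
        raise InputError(
            f"event rate too high: {n_events} events will not fit in "
            f"{duration_s:.0f} s without overlap")
    placed: list[tuple[float, float]] = []
    for _ in range(n_events):
        length = len_sampler(rng)
        for _attempt in range(200):
            onset = rng.uniform(0.5, duration_s - length - 0.5)
            span = (onset - min_gap, onset + length + min_gap)
            clash = any(span[0] < hi and span[1] > lo
                        for lo, hi in placed + forbidden)
            if not clash:
                placed.append((onset, onset + length))
                break
        else:
            raise InputError("could not place all events without overlap")
    return sorted(placed)


def inject_spike_events(signal: np.ndarray, fs: float, cfg: SynthConfig,
                        seed: int | None = None,
                        artifacts: AnnotationTrack | None = None,
                        schedule: list[tuple[float, float, str, int]] | None = None,
                        ) -> tuple[np.ndarray, AnnotationTrack]:
    """Add spike/polyspike transients at Poisson onsets; returns ground truth.

    ``schedule`` (onset_s, duration_s, kind, n_lobes) overrides the
    random draw, which lets multichannel composition share event times.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 104729])
    x = np.asarray(signal, dtype=float).copy()
    duration_s = len(x) / fs
    if schedule is None:
        forbidden = artifacts.to_pairs() if artifacts is not None else []
        spans = _place_events(
            rng, duration_s, cfg.spike_rate_per_min,
            lambda r: (r.uniform(0.6, 1.2) if r.uniform() < cfg.polyspike_frac
                       else r.uniform(0.06, 0.15)),
            forbidden)
        schedule = []
        for onset, end in spans:
            length = end - onset
            kind = "polyspike" if length > 0.2 else "spike"
            n_lobes = int(rng.integers(4, 6)) if kind == "polyspike" else 2
            schedule.append((onset, length, kind, n_lobes))
    if not schedule:
        return x, AnnotationTrack([])

    baseline = estimate_baseline_amplitude(x, fs, None, DetectorConfig())
    peak = cfg.spike_amp_mult * baseline
    intervals = []
    for onset, length, kind, n_lobes in schedule:
        if kind == "polyspike":
            tpl = _polyspike_template(np.random.default_rng(
                [seed, 7919, int(onset * 1000)]), fs, length, peak, n_lobes)
        else:
            tpl = _spike_template(fs, length, peak)
        i0 = int(round(onset * fs))
        tpl = tpl[:len(x) - i0]
        x[i0:i0 + len(tpl)] += tpl
        intervals.append(Interval(onset, len(tpl) / fs, "*", kind))
    return x, AnnotationTrack(intervals)


def inject_artifacts(signal: np.ndarray, fs: float, cfg: SynthConfig,
                     seed: int | None = None,
                     schedule: list[tuple[float, float]] | None = None,
                     ) -> tuple[np.ndarray, AnnotationTrack]:
    """Add 1–5 s movement/EMG-like bursts of high-amplitude broadband noise."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 65537])
    x = np.asarray(signal, dtype=float).copy()
    duration_s = len(x) / fs
    if schedule is None:
        spans = _place_events(rng, duration_s, cfg.artifact_rate_per_min,
                              lambda r: r.uniform(1.0, 5.0), [])
        schedule = spans
    if not schedule:
        return x, AnnotationTrack([])
    med = np.median(x)
    scale = float(np.median(np.abs(x - med)) * 1.4826)
    amp = cfg.artifact_amp_mult * max(scale, 1e-12)
    hi = min(250.0, 0.45 * fs)
    sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
    intervals = []
    for onset, end in schedule:
        i0, i1 = int(round(onset * fs)), min(len(x), int(round(end * fs)))
        burst = sps.sosfiltfilt(sos, rng.standard_normal(i1 - i0))
        sd = burst.std()
        if sd > 0:
            burst *= amp / sd
        # taper edges to avoid step discontinuities
        ramp = min(len(burst) // 4, int(0.05 * fs))
        if ramp > 0:
            w = np.ones(len(burst))
            w[:ramp] = np.linspace(0, 1, ramp)
            w[-ramp:] = np.linspace(1, 0, ramp)
            burst *= w
        x[i0:i1] += burst
        intervals.append(Interval(onset, (i1 - i0) / fs, "*", "artifact"))
    return x, AnnotationTrack(intervals)


def generate_recording(cfg: SynthConfig, seed: int | None = None,
                       meta: SubjectMeta | None = None,
                       ) -> tuple[Recording, GroundTruth]:
    """Compose background (+ optional discontinuous gating), spikes, and
    artifacts for the configured channels.

    Event and artifact times are shared across channels (events are
    brain-wide); the background noise is independent per channel.
    """
    seed = cfg.seed if seed is None else seed
    n = int(round(cfg.duration_s * cfg.fs))
    master = np.random.default_rng([seed, 424243])

    # shared schedules drawn once
    art_spans = _place_events(master, cfg.duration_s, cfg.artifact_rate_per_min,
                              lambda r: r.uniform(1.0, 5.0), [])
    spike_spans = _place_events(
        master, cfg.duration_s, cfg.spike_rate_per_min,
        lambda r: (r.uniform(0.6, 1.2) if r.uniform() < cfg.polyspike_frac
                   else r.uniform(0.06, 0.15)),
        art_spans)
    spike_schedule = []
    for onset, end in spike_spans:
        length = end - onset
        kind = "polyspike" if length > 0.2 else "spike"
        n_lobes = int(master.integers(4, 6)) if kind == "polyspike" else 2
        spike_schedule.append((onset, length, kind, n_lobes))
    gate = (_gate(master, n, cfg.fs, cfg) if cfg.discontinuous else None)

    signals = {}
    events_track = AnnotationTrack([])
    artifacts_track = AnnotationTrack([])
    for ci, name in enumerate(cfg.channels):
        ch_seed = [seed, 31 + ci]
        bg = generate_background(cfg, np.random.SeedSequence(ch_seed).generate_state(1)[0] % (2**31))
        if gate is not None:
            bg = bg * gate
        sig, ev = inject_spike_events(bg, cfg.fs, cfg, seed,
                                      schedule=spike_schedule)
        sig, art = inject_artifacts(sig, cfg.fs, cfg, seed, schedule=art_spans)
        signals[name] = sig
        events_track, artifacts_track = ev, art

    meta = meta or SubjectMeta(subject_id=f"synth{seed}")
    rec = Recording(signals=signals, fs=cfg.fs, meta=meta)
    truth = GroundTruth(events=events_track, artifacts=artifacts_track,
                        true_band_powers=_effective_targets(cfg), seed=seed)
    return rec, truth


def _subject_cfg(cfg: SynthConfig, rng: np.random.Generator) -> SynthConfig:
    if cfg.subject_sigma <= 0:
        return cfg
    targets = {b: t * float(rng.lognormal(0.0, cfg.subject_sigma))
               for b, t in cfg.band_power_targets.items()}
    return replace(cfg, band_power_targets=targets)


def generate_cohort(n_per_group: int, wt_cfg: SynthConfig, as_cfg: SynthConfig,
                    seed: int = 0, spectral_cfg: SpectralConfig | None = None,
                    measure_channel: str | None = None,
                    cycle: Cycle = Cycle.light) -> Cohort:
    """Generate a WT and an AS group and measure their band/per-Hz powers.

    Per-subject heterogeneity (``subject_sigma``) multiplies each band
    target by an independent lognormal draw. The emitted tables are
    ready for the stats layer: a band-power table (one row per subject
    × channel) and a long per-Hz table for the genotype × frequency
    ANOVA, measured on ``measure_channel`` (default: first channel).
    """
    if n_per_group < 2:
        raise InputError("n_per_group must be >= 2")
    from .spectral import power_at_frequencies

    spectral_cfg = spectral_cfg or SpectralConfig()
    subjects = []
    band_rows = []
    perhz_rows = []
    for gi, (genotype, cfg) in enumerate([(Genotype.WT, wt_cfg),
                                          (Genotype.AS, as_cfg)]):
        for si in range(n_per_group):
            sub_seed = int(np.random.SeedSequence([seed, gi, si])
                           .generate_state(1)[0] % (2**31))
            rng = np.random.default_rng([sub_seed, 11])
            cfg_i = _subject_cfg(cfg, rng)
            sid = f"{genotype.value}{si:02d}"
            meta = SubjectMeta(subject_id=sid, genotype=genotype, cycle=cycle)
            rec, truth = generate_recording(cfg_i, sub_seed, meta=meta)
            subjects.append((rec, truth))
            mch = measure_channel or rec.channel_names[0]
            for ch in rec.channel_names:
                ps = compute_psd(rec.signals[ch], rec.fs, spectral_cfg, channel=ch)
                bp = integrate_band_power(ps)
                band_rows.append({"subject_id": sid, "genotype": genotype.value,
                                  "channel": ch, "cycle": cycle.value, **bp})
                if ch == mch:
                    hz = power_at_frequencies(ps)
                    for k, v in enumerate(hz):
                        perhz_rows.append({"value": float(v),
                                           "genotype": genotype.value,
                                           "frequency": k, "subject_id": sid})
    return Cohort(subjects=subjects,
                  band_table=pd.DataFrame(band_rows),
                  per_hz_table=pd.DataFrame(perhz_rows))


def cohort_per_hz_table(cohort: Cohort) -> pd.DataFrame:
    """Long-format per-Hz table (value, genotype, frequency) for the ANOVA."""
    return cohort.per_hz_table[["value", "genotype", "frequency"]].copy()
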