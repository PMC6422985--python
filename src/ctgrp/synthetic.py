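"""Synthetic cardiotocography (CTG) generator.

Produces labeled fetal heart-rate records with the qualitative structure a
CTG pipeline must handle: a baseline in the normal 110-160 bpm range,
short-term (beat-to-beat) and long-term variability, Gaussian-shaped
acceleration bumps and deceleration dips, zero-valued transducer
dropouts, isolated spiky artifacts, and 0.25 bpm acquisition
quantization. The pathological (hypoxia) preset encodes the clinical
picture of fetal distress — reduced and slowed variability, fewer
accelerations, recurrent contraction-coupled decelerations — and
attaches an umbilical-artery pH below the 7.15 decision threshold. This
is a statistical stand-in for real intrapartum data, not a
physiologically validated simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .records import NORMAL, PATHOLOGICAL, FHRRecord, derive_seed

__all__ = [
    "SynthConfig",
    "normal_preset",
    "pathological_preset",
    "generate_fhr",
    "generate_cohort",
]


@dataclass
class SynthConfig:
    """Parameters of one synthetic FHR record.

    Rates are events per hour; ``baseline_bpm=None`` draws the baseline
    uniformly from [110, 160] bpm. Variability has two components, each
    with an amplitude (standard deviation, bpm) and a correlation time
    (seconds): ``stv_bpm``/``stv_corr_s`` for the beat-to-beat
    (short-term) part and ``ltv_bpm``/``ltv_corr_s`` for the slow
    (long-term) oscillation. Decelerations have configurable depth and
    duration ranges and either a ``sporadic`` (Poisson) or ``recurrent``
    (contraction-coupled) timing pattern. ``quant_bpm`` is the
    acquisition quantization step. Hypoxia suppresses beat-to-beat
    autonomic modulation, so the pathological preset both shrinks the
    variability amplitudes and lengthens their correlation times — the
    trace becomes smooth and low-complexity, not merely smaller.
    """

    duration_s: float = 960.0
    fs: float = 4.0
    baseline_bpm: Optional[float] = None
    stv_bpm: float = 7.0
    stv_corr_s: float = 0.15
    ltv_bpm: float = 5.0
    ltv_corr_s: float = 2.0
    accel_rate: float = 15.0
    decel_rate: float = 1.0
    decel_depth_bpm: Tuple[float, float] = (10.0, 40.0)
    decel_dur_s: Tuple[float, float] = (20.0, 90.0)
    decel_pattern: str = "sporadic"   # sporadic (Poisson) | recurrent (contraction-coupled)
    dropout_rate: float = 4.0
    spike_rate: float = 12.0
    quant_bpm: float = 0.25
    class_label: str = NORMAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("stv_bpm", "stv_corr_s", "ltv_bpm", "ltv_corr_s",
                     "accel_rate", "decel_rate", "dropout_rate", "spike_rate",
                     "quant_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decel_pattern not in ("sporadic", "recurrent"):
            raise ValueError(f"unknown decel_pattern {self.decel_pattern!r}")
        if self.class_label not in (NORMAL, PATHOLOGICAL):
            raise ValueError(f"unknown class_label {self.class_label!r}")


def normal_preset(**overrides) -> SynthConfig:
    """Default configuration of a healthy (normal) fetus."""
    return SynthConfig(class_label=NORMAL, **overrides)


def pathological_preset(**overrides) -> SynthConfig:
    """Hypoxia preset, relative to :func:`normal_preset`.

    Encodes the intrapartum hypoxia picture: overall variability halved
    (both short- and long-term amplitude), beat-to-beat modulation
    suppressed (20x longer short-term correlation time, giving a smooth
    low-complexity trace whose slew often drops below the 0.25 bpm
    acquisition quantum), slow baseline wander (15 s long-term
    correlation), accelerations x1/4, and recurrent late-type
    decelerations — frequent (one per ~3 min, tracking contractions),
    gradual and long (60-120 s) but shallow (8-16 bpm). Any explicit
    override wins.
    """
    base = SynthConfig()
    defaults = dict(
        stv_bpm=base.stv_bpm / 2,
        stv_corr_s=base.stv_corr_s * 20,
        ltv_bpm=base.ltv_bpm / 2,
        ltv_corr_s=base.ltv_corr_s * 7.5,
        accel_rate=base.accel_rate * 0.25,
        decel_rate=20.0,
        decel_depth_bpm=(8.0, 16.0),
        decel_dur_s=(60.0, 120.0),
        decel_pattern="recurrent",
        class_label=PATHOLOGICAL,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def _event_bumps(n: int, fs: float, rng: np.random.Generator, rate_per_h: float,
                 amp_range: tuple, dur_range_s: tuple, duration_s: float,
                 centers=None) -> np.ndarray:
    """Sum of Gaussian-shaped transient events (positive amplitudes).

    Event times are Poisson (``rate_per_h``) unless explicit ``centers``
    (seconds) are given.
    """
    out = np.zeros(n)
    if centers is None:
        count = rng.poisson(rate_per_h * duration_s / 3600.0)
        centers = [rng.uniform(0, duration_s) for _ in range(count)]
    t = np.arange(n) / fs
    for center in centers:
        amp = rng.uniform(*amp_range)
        dur = rng.uniform(*dur_range_s)
        sigma = dur / 4.0  # +-2 sigma spans the nominal event duration
        out += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return out


def _contraction_times(rng: np.random.Generator, duration_s: float,
                       presence_p: float = 0.9) -> list:
    """Quasi-regular contraction-coupled event times (late decelerations).

    One slot per uterine contraction (period drawn from 150-210 s, +-20 s
    jitter); each slot produces a deceleration with probability
    ``presence_p``, so virtually every window of a recurrent-deceleration
    trace contains events — the clinical meaning of "recurrent".
    """
    period = rng.uniform(150.0, 210.0)
    phase = rng.uniform(0, period)
    out = []
    c = phase
    while c < duration_s:
        if rng.random() < presence_p:
            out.append(c + rng.uniform(-20.0, 20.0))
        c += period
    return out


def generate_fhr(config: SynthConfig) -> FHRRecord:
    """Generate one synthetic FHR record.

    The clean signal is baseline + short- and long-term variability +
    acceleration bumps (+10-25 bpm, 15-60 s) - deceleration dips (depth
    and duration per config), clipped to [baseline-30, baseline+30] and to the
    physiological 50-200 bpm window so that artifact-free records pass
    preprocessing unchanged. Artifacts (zero dropouts, then spikes) are
    overwritten on top. Identical config (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    if n < 1:
        raise ValueError("duration too short for one sample")

    baseline = config.baseline_bpm
    if baseline is None:
        baseline = rng.uniform(110.0, 160.0)

    if config.class_label == NORMAL:
        ph = rng.uniform(7.20, 7.40)
    else:
        ph = rng.uniform(6.95, 7.10)

    # short-term (beat-to-beat) variability: smoothed white noise whose
    # correlation time sets the trace's complexity at the 4 Hz sample scale
    stv_noise = gaussian_filter1d(rng.standard_normal(n),
                                  sigma=max(config.stv_corr_s * config.fs, 1e-9),
                                  mode="reflect")
    sd = stv_noise.std()
    stv = stv_noise / sd * config.stv_bpm if sd > 0 else np.zeros(n)
    # long-term variability: slow oscillation, a few cycles per minute
    ltv_noise = gaussian_filter1d(rng.standard_normal(n),
                                  sigma=max(config.ltv_corr_s * config.fs, 1e-9),
                                  mode="reflect")
    sd = ltv_noise.std()
    ltv = ltv_noise / sd * config.ltv_bpm if sd > 0 else np.zeros(n)
    variability = stv + ltv

    accel = _event_bumps(n, config.fs, rng, config.accel_rate, (10.0, 25.0),
                         (15.0, 60.0), config.duration_s)
    decel_centers = None
    if config.decel_pattern == "recurrent":
        decel_centers = _contraction_times(rng, config.duration_s)
    decel = _event_bumps(n, config.fs, rng, config.decel_rate,
                         config.decel_depth_bpm, config.decel_dur_s,
                         config.duration_s, centers=decel_centers)

    signal = baseline + variability + accel - decel
    lo = max(50.0, baseline - 30.0)
    hi = min(200.0, baseline + 30.0)
    signal = np.clip(signal, lo, hi)

    # dropouts: zero runs, lengths 2-30 s (some exceed the 15 s removal rule)
    n_drop = rng.poisson(config.dropout_rate * config.duration_s / 3600.0)
    for _ in range(n_drop):
        length = int(round(rng.uniform(2.0, 30.0) * config.fs))
        start = rng.integers(0, max(n - length, 1))
        signal[start:start + length] = 0.0

    # spikes: isolated samples displaced beyond the 25 bpm stability rule,
    # some past the 50/200 bpm physiological limits
    n_spike = rng.poisson(config.spike_rate * config.duration_s / 3600.0)
    if n_spike > 0:
        pos = rng.choice(n, size=min(n_spike, n), replace=False)
        offs = rng.uniform(35.0, 90.0, size=pos.size) * rng.choice([-1.0, 1.0], size=pos.size)
        vals = np.clip(signal[pos] + offs, 5.0, 245.0)
        keep = signal[pos] > 0  # do not overwrite dropouts
        signal[pos[keep]] = vals[keep]

    # acquisition quantization (CTU-UHB stores FHR at 0.25 bpm resolution);
    # zeros stay zero, so dropout coding is preserved
    if config.quant_bpm > 0:
        signal = np.round(signal / config.quant_bpm) * config.quant_bpm

    record_id = f"syn-{config.class_label[:4]}-{config.seed:010d}"
    return FHRRecord(record_id=record_id, samples=signal, fs=config.fs,
                     ph=float(ph), label=config.class_label)


def generate_cohort(n_per_class: int, config_overrides: Optional[dict] = None,
                    seed: int = 0) -> list:
    """Generate a balanced cohort: ``n_per_class`` records of each class.

    Every record receives a distinct seed derived from ``seed``, so two
    cohorts built with the same master seed are identical. Records are
    ordered all-normal first, then all-pathological.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    overrides = dict(config_overrides or {})
    overrides.pop("class_label", None)
    overrides.pop("seed", None)
    records = []
    for preset, cls in ((normal_preset, NORMAL), (pathological_preset, PATHOLOGICAL)):
        for i in range(n_per_class):
            sub = derive_seed(seed, f"{cls}:{i}")
            cfg = preset(seed=sub, **overrides)
            rec = generate_fhr(cfg)
            rec.record_id = f"syn-{cls[:4]}-{i:04d}"
            records.append(rec)
    return records
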