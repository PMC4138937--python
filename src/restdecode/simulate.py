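"""Synthetic two-condition resting-state BOLD generator.

Each ROI's series is a band-limited oscillation (a sum of sinusoids
with frequencies inside 0.01-0.08 Hz and random phases) on top of
1/f-shaped ("pink") noise and white noise, plus a constant baseline.
In the eyes-closed condition the oscillation amplitude of designated
*effect* ROIs is multiplied by ``1 + effect_size``, emulating the
dominant direction reported for real data (eyes-closed carries the
larger low-frequency amplitude in sensorimotor regions).  Each subject
carries a lognormal amplitude factor shared between their two
recordings, so the paired design is informative: within-subject
differences are cleaner than between-subject ones.

The generator emits full-length recordings (``n_volumes`` time points);
discarding the initial equilibration volumes is the pipeline's job, not
the generator's.  Generation is a pure function of (config, template):
the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .template import RoiTemplate

EC, EO = "EC", "EO"
CONDITIONS = (EC, EO)


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition geometry and signal/noise model of a synthetic cohort.

    Attributes
    ----------
    n_subjects : int
        Paired subjects; each contributes one EC and one EO recording.
    tr : float
        Repetition time (sampling interval) in seconds.
    n_volumes, n_discard : int
        Emitted series length and the number of initial volumes the
        downstream pipeline will trim (the generator itself never trims;
        ``n_discard`` only fixes the DFT grid that oscillator
        frequencies snap to).
    effect_rois : tuple[int, ...] | None
        Template row indices whose low-frequency amplitude differs
        between conditions.  ``None`` means "the first 10 sensorimotor
        regions of the template" (resolved at generation time).
    effect_size : float
        Multiplier on oscillation amplitude in effect ROIs under EC:
        amplitude is scaled by ``1 + effect_size``.
    noise_sigma : float
        Standard deviation of the additive white noise, in signal units
        (oscillators have unit amplitude each).
    one_over_f_exponent, one_over_f_sigma : float
        Spectral exponent beta of the pink-noise component (amplitude
        shaped as f**(-beta/2)) and its standard deviation.
    n_oscillators : int
        Sinusoids summed per ROI.
    subject_amp_sd : float
        Sigma of the lognormal per-subject amplitude factor (shared
        across the subject's two recordings).
    snap_to_bins : bool
        Draw oscillator frequencies from the exact DFT bins of the
        trimmed series inside the low band (keeps all noise-free power
        inside 0.01-0.08 Hz; no rectangular-window leakage).
    baseline : float
        Constant offset added to every series (removed by detrending).
    """

    n_subjects: int = 24
    tr: float = 2.0
    n_volumes: int = 240
    n_discard: int = 10
    effect_rois: tuple[int, ...] | None = None
    effect_size: float = 1.0
    noise_sigma: float = 2.0
    one_over_f_exponent: float = 1.0
    one_over_f_sigma: float = 1.0
    n_oscillators: int = 5
    subject_amp_sd: float = 0.2
    freq_low: float = 0.01
    freq_high: float = 0.08
    snap_to_bins: bool = True
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= self.n_discard or self.n_discard < 0:
            raise ValueError("need n_volumes > n_discard >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sigma < 0 or self.one_over_f_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if not (0 < self.freq_low <= self.freq_high):
            raise ValueError("need 0 < freq_low <= freq_high")
        if self.effect_rois is not None:
            object.__setattr__(self, "effect_rois", tuple(int(i) for i in self.effect_rois))


@dataclass
class SubjectRecording:
    """One condition's multivariate time series for one subject.

    ``data`` is time x ROI, full length (not yet trimmed).
    """

    subject_id: str
    condition: str
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time x ROI matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")


def default_effect_rois(template: RoiTemplate, n: int = 10) -> tuple[int, ...]:
    """First ``n`` sensorimotor regions of the template (deterministic)."""
    idx = template.module_indices("sensorimotor")
    if len(idx) < n:
        idx = np.arange(min(n, len(template)))
    return tuple(int(i) for i in idx[:n])


def resolve_effect_rois(config: SimulationConfig, template: RoiTemplate) -> tuple[int, ...]:
    if config.effect_rois is None:
        return default_effect_rois(template)
    bad = [i for i in config.effect_rois if not 0 <= i < len(template)]
    if bad:
        raise ValueError(f"effect_rois outside template range: {bad}")
    return config.effect_rois


def _candidate_freqs(config: SimulationConfig) -> np.ndarray:
    """Frequencies the oscillators may take (DFT bins of the trimmed series)."""
    n_kept = config.n_volumes - config.n_discard
    f = np.fft.rfftfreq(n_kept, config.tr)
    # half-open [low, high), matching the low-band bin convention downstream
    inband = f[(f >= config.freq_low) & (f < config.freq_high)]
    if len(inband) == 0:
        raise ValueError("no DFT bin falls inside [freq_low, freq_high]")
    return inband


def _pink_noise(rng: np.random.Generator, n_rois: int, n_t: int,
                beta: float, sigma: float, tr: float) -> np.ndarray:
    """1/f-shaped noise: white spectrum reweighted by f**(-beta/2)."""
    if sigma == 0:
        return np.zeros((n_rois, n_t))
    white = rng.standard_normal((n_rois, n_t))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_t, tr)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    series = np.fft.irfft(spec * shape, n=n_t, axis=1)
    sd = series.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sigma * series / sd


def _subject_amp_factor(config: SimulationConfig, subject_seed: int) -> float:
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed), 7]))
    if config.subject_amp_sd == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, config.subject_amp_sd)))


def simulate_subject_timeseries(
    config: SimulationConfig,
    template: RoiTemplate,
    condition: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectRecording:
    """Generate one recording (time x ROI) for one subject/condition.

    The per-subject amplitude factor depends only on ``subject_seed``,
    so the EC and EO recordings of the same subject share it; oscillator
    frequencies, phases and noise are drawn independently per recording
    (two separate scans).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    effect = resolve_effect_rois(config, template)
    n_rois = len(template)
    n_t = config.n_volumes
    t = np.arange(n_t) * config.tr

    rng = np.random.default_rng(
        np.random.SeedSequence([int(subject_seed), CONDITIONS.index(condition)])
    )
    k = config.n_oscillators
    if config.snap_to_bins:
        cand = _candidate_freqs(config)
        freqs = rng.choice(cand, size=(n_rois, k), replace=True)
    else:
        freqs = rng.uniform(config.freq_low, config.freq_high, size=(n_rois, k))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_rois, k))
    osc = np.sin(2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None])
    osc = osc.sum(axis=1)  # (n_rois, n_t)

    amp = np.full(n_rois, _subject_amp_factor(config, subject_seed))
    if condition == EC and config.effect_size > 0 and len(effect):
        amp = amp.copy()
        amp[list(effect)] *= 1.0 + config.effect_size

    series = amp[:, None] * osc
    series += _pink_noise(rng, n_rois, n_t, config.one_over_f_exponent,
                          config.one_over_f_sigma, config.tr)
    if config.noise_sigma > 0:
        series += rng.normal(0.0, config.noise_sigma, size=(n_rois, n_t))
    series += config.baseline

    return SubjectRecording(
        subject_id=subject_id or f"sub-{subject_seed}",
        condition=condition,
        data=series.T,
        tr=config.tr,
    )


def subject_seeds(config: SimulationConfig) -> np.ndarray:
    """Deterministic per-subject seeds derived from ``config.seed``."""
    ss = np.random.SeedSequence(int(config.seed))
    state = ss.generate_state(config.n_subjects, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def simulate_cohort(config: SimulationConfig, template: RoiTemplate) -> list[SubjectRecording]:
    """Generate the full cohort: every subject under both conditions.

    Returns ``2 * n_subjects`` recordings ordered subject-major
    (sub-001 EC, sub-001 EO, sub-002 EC, ...).
    """
    seeds = subject_seeds(config)
    recordings: list[SubjectRecording] = []
    for i, s in enumerate(seeds):
        sid = f"sub-{i + 1:03d}"
        for cond in CONDITIONS:
            recordings.append(
                simulate_subject_timeseries(config, template, cond, int(s), subject_id=sid)
            )
    return recordings


def null_config(config: SimulationConfig, seed: int | None = None) -> SimulationConfig:
    """Copy of ``config`` with the condition effect switched off."""
    return replace(config, effect_size=0.0, seed=config.seed if seed is None else seed)
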