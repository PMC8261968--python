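"""Synthetic cohort generator.

The real multicentre child cohort is not publicly available, so every
downstream stage is exercised on generated data that carries the structure
the analysis assumes:

* signal level — intermittent child activity: short bursts of movement
  (Poisson bout arrivals, exponential durations) at step frequencies around
  2.5–3 Hz, superimposed on gravity, sampled at 30 Hz / ±6 g;
* epoch level — 3-s vector-magnitude series over a 7-day week with a
  quiet night window and configurable group shifts in the upper intensity
  range;
* cohort level — confounders (age, sex, country, household income, parental
  education) and outcomes generated from the standardized intensity spectrum
  with known effect vectors, confounder effects and noise, so that
  parameter-recovery tests have ground truth.

Generation is deterministic under a fixed seed at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .processing import EpochSeries
from .spectrum import SpectrumDefinition, default_bin_edges

__all__ = [
    "ActivityProfile",
    "CohortConfig",
    "generate_raw_signal",
    "generate_epoch_cohort",
    "generate_spectrum_cohort",
    "generate_confounders",
    "generate_outcomes",
    "noise_sd_for_r2",
    "generate_latent_rank_data",
]

_WAKE_DEFAULT = ("06:00", "23:00")


def _secs(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return int(h) * 3600 + int(m) * 60


@dataclass(frozen=True)
class ActivityProfile:
    """Bout-process description of a child's free-living activity.

    Activity arrives as bouts (homogeneous Poisson process within the wake
    window) with exponentially distributed durations and gamma-distributed
    intensities; between bouts the sensor sees low-level residual movement.
    ``step_frequency_hz`` is the dominant movement frequency used for raw
    signal synthesis — around 2.5–3 Hz for running children.
    """

    bout_rate_per_hour: float = 10.0
    bout_duration_s: float = 100.0        # mean of exponential
    bout_intensity_mg: float = 250.0      # mean of gamma
    bout_intensity_shape: float = 1.8     # gamma shape (fixed, mean varies)
    rest_mean_mg: float = 18.0            # gamma mean of between-bout epochs
    rest_shape: float = 1.5
    step_frequency_hz: float = 2.8
    sedentary_fraction: float = 0.72      # target share of wake time at rest
    wake_window: tuple = _WAKE_DEFAULT

    def __post_init__(self) -> None:
        if self.bout_rate_per_hour < 0:
            raise ValueError("bout_rate_per_hour must be non-negative")
        if self.bout_duration_s <= 0 or self.bout_intensity_mg <= 0:
            raise ValueError("bout duration and intensity must be positive")
        if not 2.0 <= self.step_frequency_hz <= 3.5:
            raise ValueError("step_frequency_hz must be within [2.0, 3.5]")
        if not 0.0 <= self.sedentary_fraction <= 1.0:
            raise ValueError("sedentary_fraction must be within [0, 1]")
        if self.sedentary_fraction + self.active_fraction > 1.0 + 1e-9:
            raise ValueError("sedentary + active fractions exceed 1")

    @property
    def active_fraction(self) -> float:
        """Expected share of wake time inside bouts."""
        return min(self.bout_rate_per_hour * self.bout_duration_s / 3600.0, 1.0)

    @property
    def wake_seconds(self) -> tuple:
        return _secs(self.wake_window[0]), _secs(self.wake_window[1])


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for a generated cohort.

    ``group_shift_mg`` maps group label -> additive shift of the mean bout
    intensity (mg), producing more time in the upper spectrum bins for
    shifted groups. ``beta_spectrum`` is the outcome effect per standardized
    spectrum bin; ``beta_confounders`` aligns with the dummy-coded confounder
    design the outcome generator is given.
    """

    n_subjects: int = 300
    n_days: int = 7
    profile: ActivityProfile = field(default_factory=ActivityProfile)
    groups: tuple = ("ITA", "HUN", "GER", "ESP", "SWE", "POL")
    group_shift_mg: dict = field(default_factory=dict)
    beta_spectrum: tuple = field(default_factory=lambda: (0.0,) * 22)
    beta_confounders: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    spectrum_definition: SpectrumDefinition = field(default_factory=default_bin_edges)
    #: between-subject lognormal sigmas of bout rate and intensity
    rate_sigma: float = 0.30
    intensity_sigma: float = 0.22

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if len(self.beta_spectrum) != self.spectrum_definition.n_bins:
            raise ValueError(
                f"beta_spectrum length {len(self.beta_spectrum)} != "
                f"{self.spectrum_definition.n_bins} spectrum bins"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.group_shift_mg) - set(self.groups)
        if unknown:
            raise ValueError(f"group_shift_mg for unknown groups: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# raw-signal synthesis

#: mean of |sin| over a cycle; relates sinusoid amplitude to rectified mean
_RECTIFIED_MEAN = 2.0 / np.pi
#: vector-magnitude factor for axis amplitudes (1, 0.2, 0.2) moving in phase
_AXIS_VM = float(np.sqrt(1.0 + 2 * 0.2**2))


def generate_raw_signal(
    profile: ActivityProfile,
    duration_days: float = 1.0,
    seed: int = 0,
    fs: float = 30.0,
    t0: str = "2013-09-02T00:00:00",
    subject_id: str = "sim",
    noise_sd_g: float = 0.003,
):
    """Synthesize a raw tri-axial recording at 30 Hz, ±6 g.

    Rest periods are the 1-g gravity component (vertical axis) plus small
    sensor noise. Active bouts superimpose a sinusoid at the profile's step
    frequency — full amplitude on the vertical axis, 20% on the other two —
    with amplitude chosen so that the epoch-mean filtered vector magnitude
    matches the bout's drawn intensity. Output is clipped to ±6 g.
    """
    from .processing import RawRecording  # local import to avoid cycle at typing time

    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_days * 86400 * fs))
    t = np.arange(n) / fs  # seconds since t0 (midnight)
    xyz = rng.normal(0.0, noise_sd_g, size=(n, 3))
    xyz[:, 0] += 1.0  # gravity on the vertical axis

    wake_lo, wake_hi = profile.wake_seconds
    wake_len = wake_hi - wake_lo
    n_days = int(np.ceil(duration_days))
    for day in range(n_days):
        day_off = day * 86400
        n_bouts = rng.poisson(profile.bout_rate_per_hour * wake_len / 3600.0)
        starts = day_off + wake_lo + rng.uniform(0, wake_len, size=n_bouts)
        durs = rng.exponential(profile.bout_duration_s, size=n_bouts)
        intens = rng.gamma(
            profile.bout_intensity_shape,
            profile.bout_intensity_mg / profile.bout_intensity_shape,
            size=n_bouts,
        )
        for s, d, inten in zip(starts, durs, intens):
            i0 = int(np.searchsorted(t, s))
            i1 = int(np.searchsorted(t, min(s + d, day_off + wake_hi)))
            if i1 <= i0 or i0 >= n:
                continue
            i1 = min(i1, n)
            amp_g = (inten / 1000.0) / (_RECTIFIED_MEAN * _AXIS_VM)
            wave = amp_g * np.sin(2 * np.pi * profile.step_frequency_hz * t[i0:i1])
            xyz[i0:i1, 0] += wave
            xyz[i0:i1, 1] += 0.2 * wave
            xyz[i0:i1, 2] += 0.2 * wave
    np.clip(xyz, -6.0, 6.0, out=xyz)
    return RawRecording(subject_id=subject_id, t0=np.datetime64(t0, "s"), fs=fs, xyz=xyz)


# ---------------------------------------------------------------------------
# epoch-level cohort

def _subject_params(config: CohortConfig, rng):
    """Per-subject bout rate / intensity with lognormal heterogeneity."""
    n = config.n_subjects
    groups = rng.choice(list(config.groups), size=n)
    rate = config.profile.bout_rate_per_hour * rng.lognormal(
        -config.rate_sigma**2 / 2, config.rate_sigma, size=n)
    shift = np.asarray([config.group_shift_mg.get(g, 0.0) for g in groups])
    inten = (config.profile.bout_intensity_mg + shift) * rng.lognormal(
        -config.intensity_sigma**2 / 2, config.intensity_sigma, size=n)
    return groups, rate, inten


def _simulate_subject_epochs(
    profile: ActivityProfile, rate: float, intensity: float, n_days: int,
    rng, epoch_s: int = 3,
) -> np.ndarray:
    """One subject's per-epoch vector magnitude over n_days (midnight-aligned)."""
    per_day = 86400 // epoch_s
    vm = np.zeros(n_days * per_day)
    wake_lo, wake_hi = profile.wake_seconds
    e_lo, e_hi = wake_lo // epoch_s, wake_hi // epoch_s
    n_wake = e_hi - e_lo
    for day in range(n_days):
        base = day * per_day + e_lo
        rest = rng.gamma(profile.rest_shape,
                         profile.rest_mean_mg / profile.rest_shape, size=n_wake)
        vm[base : base + n_wake] = rest
        n_bouts = rng.poisson(rate * (wake_hi - wake_lo) / 3600.0)
        if n_bouts == 0:
            continue
        starts = rng.uniform(0, wake_hi - wake_lo, size=n_bouts)
        durs = rng.exponential(profile.bout_duration_s, size=n_bouts)
        b_int = rng.gamma(profile.bout_intensity_shape,
                          intensity / profile.bout_intensity_shape, size=n_bouts)
        e_start = (starts // epoch_s).astype(int)
        e_len = np.maximum((durs // epoch_s).astype(int), 1)
        e_len = np.minimum(e_len, n_wake - e_start)
        total = int(e_len.sum())
        if total == 0:
            continue
        # flatten bout epochs: offsets within each bout via repeat/arange
        idx = np.repeat(e_start, e_len) + (
            np.arange(total) - np.repeat(np.cumsum(e_len) - e_len, e_len))
        jitter = rng.lognormal(-0.02, 0.2, size=total)
        np.maximum.at(vm, base + idx, np.repeat(b_int, e_len) * jitter)
    return vm


def generate_epoch_cohort(config: CohortConfig):
    """Generate per-subject 3-s epoch series plus a confounder table.

    Each subject gets ``n_days`` midnight-aligned days; epochs outside the
    wake window are zero (device off at night). Returns
    ``(list[EpochSeries], DataFrame)`` with the confounder table carrying
    subject_id, group/country, age, sex, income, education.
    """
    rng = np.random.default_rng(config.seed)
    groups, rates, intens = _subject_params(config, rng)
    conf = generate_confounders(config.n_subjects, rng, groups=groups)
    series = []
    for i in range(config.n_subjects):
        vm = _simulate_subject_epochs(config.profile, rates[i], intens[i],
                                      config.n_days, rng)
        series.append(EpochSeries(
            subject_id=conf["subject_id"].iloc[i],
            t0=np.datetime64("2013-09-02T00:00:00", "s"),
            vm_mg=vm,
        ))
    return series, conf


def generate_confounders(n: int, rng, groups=None) -> pd.DataFrame:
    """Confounder table: age 6–16 y, sex ~ Bernoulli(0.5), country (6 levels),
    5-level household income, 3-level parental education."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if groups is None:
        groups = rng.choice(["ITA", "HUN", "GER", "ESP", "SWE", "POL"], size=n)
    age = rng.uniform(6.0, 16.0, size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "country": groups,
        "age": age,
        "sex": rng.choice(["male", "female"], size=n),
        "income": rng.choice(["low", "low-mid", "mid", "mid-high", "high"],
                             p=[0.1, 0.2, 0.4, 0.2, 0.1], size=n),
        "education": rng.choice(["low", "medium", "high"],
                                p=[0.2, 0.5, 0.3], size=n),
        # height tracks age (~5.5 cm/y through childhood) plus variation
        "height": 110.0 + 5.5 * (age - 6.0) + rng.normal(0.0, 7.0, size=n),
    })


# ---------------------------------------------------------------------------
# fast spectrum-level cohort

def generate_spectrum_cohort(config: CohortConfig):
    """Draw subjects' intensity spectra directly (minutes/day per bin).

    Same bout/intensity mechanism as the epoch-level generator — per-subject
    Poisson bout epochs with gamma intensities on top of gamma rest epochs —
    but per-bin epoch counts are drawn multinomially from the implied bin
    probabilities instead of simulating every epoch, which makes
    1000-subject cohorts instant. Returns ``(DataFrame n×bins minutes/day,
    confounder DataFrame)``.
    """
    rng = np.random.default_rng(config.seed)
    groups, rates, intens = _subject_params(config, rng)
    conf = generate_confounders(config.n_subjects, rng, groups=groups)
    prof = config.profile
    edges = config.spectrum_definition.histogram_edges()
    wake_lo, wake_hi = prof.wake_seconds
    epochs_per_day = (wake_hi - wake_lo) // 3
    n_epochs = epochs_per_day * config.n_days

    rest_p = np.diff(stats.gamma.cdf(edges, prof.rest_shape,
                                     scale=prof.rest_mean_mg / prof.rest_shape))
    rest_p = np.clip(rest_p, 0, None)
    rest_p /= rest_p.sum()
    rows = np.empty((config.n_subjects, len(edges) - 1))
    for i in range(config.n_subjects):
        active = min(rates[i] * prof.bout_duration_s / 3600.0, 0.95)
        n_bout = rng.binomial(n_epochs, active)
        bout_p = np.diff(stats.gamma.cdf(
            edges, prof.bout_intensity_shape,
            scale=intens[i] / prof.bout_intensity_shape))
        bout_p = np.clip(bout_p, 0, None)
        bout_p /= bout_p.sum()
        counts = rng.multinomial(n_epochs - n_bout, rest_p) + rng.multinomial(n_bout, bout_p)
        rows[i] = counts * 3.0 / 60.0 / config.n_days
    table = pd.DataFrame(rows, index=conf["subject_id"],
                         columns=config.spectrum_definition.bin_labels())
    return table, conf


# ---------------------------------------------------------------------------
# outcomes with known ground truth

def generate_outcomes(
    spectrum_z: np.ndarray | pd.DataFrame,
    confounder_design: np.ndarray | pd.DataFrame | None,
    config: CohortConfig,
    rng=None,
):
    """Generate a response with known linear ground truth.

    ``y = spectrum_z · beta_spectrum + design · beta_confounders + ε`` with
    ``ε ~ N(0, noise_sd²)``. Returns ``(y, truth)`` where ``truth`` records
    the realized variance decomposition (signal, confounder, noise, and the
    true population R² implied by the realized signal variance).
    """
    Z = np.asarray(spectrum_z, dtype=float)
    beta = np.asarray(config.beta_spectrum, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != beta.size:
        raise ValueError(f"spectrum_z has {Z.shape[1] if Z.ndim == 2 else '?'} "
                         f"columns, beta_spectrum has {beta.size}")
    signal = Z @ beta
    if confounder_design is not None and len(config.beta_confounders):
        D = np.asarray(confounder_design, dtype=float)
        bc = np.asarray(config.beta_confounders, dtype=float)
        if D.shape[0] != Z.shape[0]:
            raise ValueError("spectrum and confounder design row counts differ")
        if D.shape[1] != bc.size:
            raise ValueError("beta_confounders length != design columns")
        conf_part = D @ bc
    else:
        conf_part = np.zeros(Z.shape[0])
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    eps = rng.normal(0.0, config.noise_sd, size=Z.shape[0])
    y = signal + conf_part + eps
    var_sig = float(np.var(signal + conf_part, ddof=1))
    truth = {
        "var_signal": float(np.var(signal, ddof=1)),
        "var_confounders": float(np.var(conf_part, ddof=1)),
        "var_noise": config.noise_sd**2,
        "true_r2": var_sig / (var_sig + config.noise_sd**2) if var_sig > 0 else 0.0,
    }
    return y, truth


def noise_sd_for_r2(spectrum_z: np.ndarray, beta_spectrum, target_r2: float) -> float:
    """Noise SD giving a target population R² for a pure-spectrum signal."""
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    signal = np.asarray(spectrum_z, float) @ np.asarray(beta_spectrum, float)
    v = float(np.var(signal, ddof=1))
    return float(np.sqrt(v * (1.0 - target_r2) / target_r2))


def generate_latent_rank_data(
    n: int,
    p: int = 22,
    n_latent: int = 2,
    noise_sd: float = 0.3,
    x_noise_sd: float = 0.05,
    seed: int = 0,
):
    """Predictors driven by a few orthogonal latent directions, response by all.

    Ground truth for complexity selection: the response needs exactly
    ``n_latent`` PLS components. The loadings are flat-magnitude sign
    patterns (uniform, alternating, ...) so every predictor has the same
    variance — per-column standardization then rescales uniformly and cannot
    collapse the staggered latent scales, which is what keeps a single
    covariance direction from capturing the whole signal.
    """
    rng = np.random.default_rng(seed)
    T, _ = np.linalg.qr(rng.normal(size=(n, n_latent)))
    T *= np.sqrt(n)  # unit-variance orthogonal latent scores
    patterns = [np.ones(p)]
    block = 1
    while len(patterns) < n_latent:
        patterns.append((-1.0) ** (np.arange(p) // block))
        block *= 2
    L = np.empty((p, n_latent))
    for k, v in enumerate(patterns):
        if k:
            v = v - L[:, :k] @ (L[:, :k].T @ v)  # orthogonalize
        L[:, k] = v / np.linalg.norm(v)
    scales = np.linspace(2.0, 1.0, n_latent)
    X = T @ (L * scales).T + rng.normal(0.0, x_noise_sd, size=(n, p))
    c = np.linspace(1.0, 0.8, n_latent) * (-1.0) ** np.arange(n_latent)
    y = T @ c + rng.normal(0.0, noise_sd, size=n)
    return X, y
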