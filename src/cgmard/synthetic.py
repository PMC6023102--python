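"""Synthetic CGM study generator.

Emulates a head-to-head in-patient CGM accuracy study: a cohort of subjects
(default 12) monitored for a week on a 5-min CGM grid, SMBG reference draws
at least hourly during the daytime plus one per night, and two designated
glucose-excursion days (2 and 5) on which rapid-absorption meals produce
exaggerated peaks followed by induced hypoglycemic dips.

The blood-glucose generator is descriptive (baseline + meal excursion bumps
+ smooth stochastic drift), not a physiological glucose–insulin model: the
accuracy metrics only care about realistic amplitude and rate-of-change
structure.  Each trace is rescaled so that its mean absolute rate of change
and mean glucose hit configurable targets (defaults 0.55 mg/dL/min and
150 mg/dL) — the two statistics that govern the delay-only MARD floor
through the quasi-steady approximation MARD ~ 100 * tau * E[|dBG/dt| / BG].

The CGM sensor model layers, on top of the diffusion-delayed IG signal,
multiplicative white measurement noise, a slow sensitivity drift
(biofouling), an extra first-day run-in deviation, and periodic one-point
recalibration whose accuracy is set by a reference-error model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dynamics import DelayModel, simulate_interstitial
from .exceptions import GeneratorError, InvalidInputError
from .metrics import GlucoseTrace, PairedDataset
from .reference_error import ReferenceErrorModel
from .wmard import ReferenceDistribution, estimate_density

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440.0


def _rng(seed: Union[np.random.Generator, int, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ProtocolConfig:
    """In-patient study protocol parameters."""

    n_subjects: int = 12
    n_days: int = 7
    sample_interval: float = 5.0  # minutes
    excursion_days: Tuple[int, ...] = (2, 5)  # 1-based study days
    day_start_hour: int = 6  # first daytime SMBG draw
    day_end_hour: int = 22  # last daytime SMBG draw (inclusive)
    roc_target: float = 0.55  # mean |dBG/dt| target, mg/dL/min
    mean_target: float = 150.0  # mean glucose target, mg/dL

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_days < 1:
            raise InvalidInputError("n_subjects and n_days must be >= 1")
        if self.sample_interval <= 0:
            raise InvalidInputError("sample_interval must be > 0")
        if any(d < 1 or d > self.n_days for d in self.excursion_days):
            raise InvalidInputError("excursion days must lie within [1, n_days]")
        if self.roc_target <= 0 or self.mean_target <= 0:
            raise InvalidInputError("targets must be positive")


@dataclass(frozen=True)
class SensorConfig:
    """CGM sensor error model parameters."""

    tau: float = 11.0  # BG->IG diffusion time constant, min
    noise_sd_percent: float = 5.0  # multiplicative white noise SD
    run_in_percent: float = 10.0  # extra relative under-read at insertion, decays over day 1
    drift_rate_percent_per_day: float = 1.0  # sensitivity loss per day (biofouling)
    calibration_interval_h: float = 12.0
    calibration_error: ReferenceErrorModel = field(
        default_factory=lambda: ReferenceErrorModel(err_ref=5.0)
    )

    def __post_init__(self):
        for name in ("tau", "noise_sd_percent", "run_in_percent",
                     "drift_rate_percent_per_day", "calibration_interval_h"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# BG trace generation
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray, t0: float, amp: float, rise: float, decay: float) -> np.ndarray:
    """Double-exponential absorption bump, peak normalized to ``amp``."""
    u = np.maximum(t - t0, 0.0)
    s = np.where(t > t0, np.exp(-u / decay) - np.exp(-u / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return amp * s / peak


def _raw_profile(cfg: ProtocolConfig, rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    dt = cfg.sample_interval
    n = len(t)
    baseline = rng.uniform(105.0, 130.0)
    # smooth stochastic drift (insulin/activity fluctuations), ~50 min correlation
    white = rng.normal(0.0, 1.0, n)
    drift = gaussian_filter1d(white, sigma=50.0 / dt, mode="reflect")
    sd = drift.std()
    drift = drift / sd * 24.0 if sd > 0 else drift
    y = baseline + drift

    for day in range(cfg.n_days):
        excursion = (day + 1) in cfg.excursion_days
        day0 = day * MINUTES_PER_DAY
        for meal_hour in (7.5, 12.5, 18.5):
            t_meal = day0 + meal_hour * 60.0 + rng.uniform(-30.0, 30.0)
            if excursion:
                # fast-absorbing high-carb meal with the insulin bolus
                # delayed: fast rise, long elevated tail
                y = y + _bump(t, t_meal, rng.uniform(230.0, 300.0), 15.0, 110.0)
                if meal_hour > 12.0:
                    # overdosed insulin: deep dip ~2.5 h after the meal,
                    # followed by a counterregulatory rebound
                    t_dip = t_meal + 160.0 + rng.uniform(-20.0, 20.0)
                    depth = rng.uniform(105.0, 135.0)
                    y = y - depth * np.exp(-0.5 * ((t - t_dip) / 90.0) ** 2)
                    y = y + _bump(t, t_dip + 70.0, 0.45 * depth, 25.0, 60.0)
            else:
                y = y + _bump(t, t_meal, rng.uniform(30.0, 60.0), 20.0, 70.0)
        if not excursion and rng.uniform() < 0.5:
            # occasional mild nocturnal hypoglycemia under basal insulin
            t_night = day0 + rng.uniform(120.0, 300.0)
            depth = rng.uniform(45.0, 75.0)
            y = y - depth * np.exp(-0.5 * ((t - t_night) / 70.0) ** 2)
            y = y + _bump(t, t_night + 60.0, 0.5 * depth, 30.0, 70.0)
    return y


def _mean_abs_roc(values: np.ndarray, dt: float) -> float:
    return float(np.mean(np.abs(np.diff(values))) / dt)


#: minimum time (min) an excursion day must spend below 70 mg/dL
_HYPO_DWELL_MIN = 45.0


def _carve_hypo(
    y: np.ndarray, t: np.ndarray, cfg: ProtocolConfig, rng: np.random.Generator
) -> np.ndarray:
    """Guarantee a hypoglycemic episode on each excursion day.

    If, after rescaling, an excursion day spends less than ~45 min below
    70 mg/dL, a smooth dip is carved at the day's minimum to restore the
    induced-hypoglycemia feature of the protocol.
    """
    y = y.copy()
    dt = t[1] - t[0] if len(t) > 1 else cfg.sample_interval
    for day in cfg.excursion_days:
        day0 = (day - 1) * MINUTES_PER_DAY
        mask = (t >= day0) & (t < day0 + MINUTES_PER_DAY)
        if not np.any(mask):
            continue
        dwell = float(np.sum(y[mask] < 70.0)) * dt
        if dwell >= _HYPO_DWELL_MIN:
            continue
        center = t[mask][np.argmin(y[mask])]
        target = rng.uniform(50.0, 58.0)
        y = y - (y[mask].min() - target) * np.exp(-0.5 * ((t - center) / 60.0) ** 2)
    return y


def generate_bg_trace(
    cfg: ProtocolConfig,
    subject_index: int = 0,
    seed: Union[np.random.Generator, int, None] = None,
) -> GlucoseTrace:
    """Generate one subject's truth BG trace on the protocol's 5-min grid.

    The composed profile is affinely rescaled so the realized mean glucose
    and mean absolute rate of change land within 10% of the configured
    targets (values clipped to [40, 450] mg/dL); a :class:`GeneratorError`
    is raised if the targets cannot be met.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=0 if seed is None else seed,
                                   spawn_key=(subject_index,))
        )
    dt = cfg.sample_interval
    n = int(round(cfg.n_days * MINUTES_PER_DAY / dt))
    t = dt * np.arange(n)
    y = _raw_profile(cfg, rng, t)

    for _ in range(4):
        roc = _mean_abs_roc(y, dt)
        if roc <= 0:
            raise GeneratorError("degenerate flat profile")
        scale = cfg.roc_target / roc
        y = cfg.mean_target + scale * (y - y.mean())
        y = _carve_hypo(y, t, cfg, rng)
        y = np.clip(y, 40.0, 450.0)
        roc_ok = abs(_mean_abs_roc(y, dt) - cfg.roc_target) <= 0.10 * cfg.roc_target
        mean_ok = abs(y.mean() - cfg.mean_target) <= 0.10 * cfg.mean_target
        if roc_ok and mean_ok:
            break
    else:
        raise GeneratorError(
            "could not reach the rate-of-change/mean targets within 10%"
        )
    return GlucoseTrace(values=y, sampling_interval=dt, start_time=0.0, label="BG")


def generate_cohort(
    cfg: ProtocolConfig, seed: Union[int, None] = None
) -> List[GlucoseTrace]:
    """Truth BG traces for all subjects (seeded per subject)."""
    return [
        generate_bg_trace(cfg, subject_index=i, seed=seed)
        for i in range(cfg.n_subjects)
    ]


# ---------------------------------------------------------------------------
# CGM sensor simulation
# ---------------------------------------------------------------------------


def simulate_cgm(
    bg: GlucoseTrace,
    cfg: SensorConfig,
    seed: Union[np.random.Generator, int, None] = None,
) -> GlucoseTrace:
    """Simulate the CGM output for a truth BG trace.

    Pipeline: diffusion-delayed IG -> time-varying sensitivity (run-in decay
    over day 1 plus linear biofouling drift) -> periodic one-point
    recalibration (the sensitivity estimate at each calibration instant
    carries the relative error of the configured calibration error model)
    -> multiplicative white display noise.
    """
    rng = _rng(seed)
    ig = simulate_interstitial(bg, DelayModel(tau=cfg.tau))
    t = bg.times - bg.start_time
    t_day = t / MINUTES_PER_DAY

    run_in = cfg.run_in_percent / 100.0 * np.maximum(0.0, 1.0 - t_day)
    sens = (1.0 - cfg.drift_rate_percent_per_day / 100.0 * t_day) * (1.0 - run_in)
    raw = ig.values * sens

    # one-point recalibration: estimated sensitivity = true * (1 + e_cal)
    cal_step = cfg.calibration_interval_h * 60.0
    if cal_step > 0 and cal_step <= t[-1]:
        cal_times = np.arange(0.0, t[-1] + 1e-9, cal_step)
    else:
        cal_times = np.array([0.0])
    cal_idx = np.clip(
        np.round(cal_times / bg.sampling_interval).astype(int), 0, len(t) - 1
    )
    e_cal = (
        rng.normal(0.0, cfg.calibration_error.relative_sd, size=len(cal_idx))
        if cfg.calibration_error.err_ref > 0
        else np.zeros(len(cal_idx))
    )
    seg = np.searchsorted(cal_times, t, side="right") - 1
    est_sens = sens[cal_idx] * (1.0 + e_cal)
    calibrated = raw / est_sens[seg] * np.where(seg >= 0, 1.0, 1.0)

    if cfg.noise_sd_percent > 0:
        noise = rng.normal(0.0, cfg.noise_sd_percent / 100.0, size=len(t))
        calibrated = calibrated * (1.0 + noise)
    return bg.with_values(np.clip(calibrated, 1.0, 600.0), label="CGM")


# ---------------------------------------------------------------------------
# Reference measurement schedule
# ---------------------------------------------------------------------------


def sample_reference_schedule(
    cfg: ProtocolConfig, seed: Union[np.random.Generator, int, None] = None
) -> np.ndarray:
    """SMBG draw times: hourly daytime draws (jittered +-10 min) plus one
    nocturnal draw per night.  Strictly increasing, minutes from run start."""
    rng = _rng(seed)
    times = []
    for day in range(cfg.n_days):
        day0 = day * MINUTES_PER_DAY
        for hour in range(cfg.day_start_hour, cfg.day_end_hour + 1):
            times.append(day0 + hour * 60.0 + rng.uniform(-10.0, 10.0))
        if day < cfg.n_days - 1:
            # night between this day and the next: 01:00-05:00
            times.append((day + 1) * MINUTES_PER_DAY + rng.uniform(60.0, 300.0))
        else:
            # final night stays inside the recording: 23:00-23:55
            times.append(day0 + rng.uniform(1380.0, 1435.0))
    out = np.sort(np.asarray(times))
    if np.any(np.diff(out) <= 0):  # pragma: no cover - spacing makes ties impossible
        out = np.unique(out)
    return out


# ---------------------------------------------------------------------------
# Scenario bundling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyScenario:
    """A generated study: configs plus per-subject truth BG and IG traces."""

    protocol: ProtocolConfig
    sensor: SensorConfig
    bg_traces: Tuple[GlucoseTrace, ...]
    ig_traces: Tuple[GlucoseTrace, ...]


def build_scenario(
    protocol: ProtocolConfig = ProtocolConfig(),
    sensor: SensorConfig = SensorConfig(),
    seed: Union[int, None] = None,
) -> StudyScenario:
    """Generate the cohort truth traces for a study scenario."""
    bg = generate_cohort(protocol, seed=seed)
    ig = tuple(simulate_interstitial(tr, DelayModel(tau=sensor.tau)) for tr in bg)
    return StudyScenario(protocol=protocol, sensor=sensor, bg_traces=tuple(bg), ig_traces=ig)


#: spacing (min) of the extra safety SMBG draws while a subject is hypoglycemic
_HYPO_MONITOR_INTERVAL = 15.0


def _safety_draw_times(bg: GlucoseTrace) -> np.ndarray:
    """Extra reference draws every ~15 min while BG is below 70 mg/dL.

    In-patient protocols with induced hypoglycemia mandate intensified
    reference monitoring during the episodes; these draws also guarantee the
    hypoglycemic region is represented in the paired data.
    """
    hypo = bg.values < 70.0
    if not np.any(hypo):
        return np.empty(0)
    step = max(1, int(round(_HYPO_MONITOR_INTERVAL / bg.sampling_interval)))
    idx = np.flatnonzero(hypo)
    keep = [idx[0]]
    for i in idx[1:]:
        if i - keep[-1] >= step:
            keep.append(i)
    return bg.times[np.asarray(keep)]


def simulate_study(
    protocol: ProtocolConfig = ProtocolConfig(),
    sensor: SensorConfig = SensorConfig(),
    seed: Union[int, None] = None,
) -> Tuple[StudyScenario, List[GlucoseTrace], List[PairedDataset]]:
    """Full study simulation: scenario, CGM traces and per-subject pairs.

    The reference schedule is the protocol's hourly-daytime/nocturnal SMBG
    plan plus intensified safety draws during hypoglycemic episodes.  The
    paired datasets hold the CGM reading nearest each draw against the true
    BG at the matched instant (reference error is injected downstream by the
    analysis routines, not baked into the data).
    """
    scenario = build_scenario(protocol, sensor, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(10_000,))
    )
    cgm_traces, paired = [], []
    for bg in scenario.bg_traces:
        cgm = simulate_cgm(bg, sensor, seed=rng)
        cgm_traces.append(cgm)
        sched = sample_reference_schedule(protocol, seed=rng)
        sched = np.unique(np.concatenate([sched, _safety_draw_times(bg)]))
        idx = np.clip(
            np.round((sched - cgm.start_time) / cgm.sampling_interval).astype(int),
            0,
            len(cgm) - 1,
        )
        # reference = true BG at the matched CGM sample instant, so that a
        # perfect error-free sensor yields exactly zero ARD at every pair
        paired.append(
            PairedDataset(times=sched, cgm_values=cgm.values[idx], ref_values=bg.values[idx])
        )
    return scenario, cgm_traces, paired


# ---------------------------------------------------------------------------
# Distribution-targeted subsampling
# ---------------------------------------------------------------------------


def _selection_probabilities(
    ref_values: np.ndarray,
    target: str,
    pref: ReferenceDistribution,
    bandwidth: float,
) -> np.ndarray:
    """Unnormalized selection probabilities target(r) / p_hat(r)."""
    p_hat = estimate_density(ref_values, bandwidth=bandwidth)
    den = p_hat(ref_values, grid_interpolated=True)
    if target == "lognormal":
        num = pref.pdf(ref_values)
    elif target == "uniform":
        num = np.ones_like(ref_values)  # flat over [min(r), max(r)]
    elif target == "empirical":
        num = den.copy()
    else:
        raise InvalidInputError(f"unknown target distribution {target!r}")
    probs = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return probs


def subsample_by_distribution(
    paired: PairedDataset,
    target: str,
    n: int,
    seed: Union[np.random.Generator, int, None] = None,
    pref: ReferenceDistribution = ReferenceDistribution(),
    bandwidth: float = 10.0,
) -> PairedDataset:
    """Importance-resample n pairs so the reference values approach a target
    distribution (``"lognormal"``: the standardized truncated log-normal;
    ``"uniform"``: flat over the observed range; ``"empirical"``: simple
    random subsampling).  Without replacement, exact output size n.
    """
    if not (1 <= n <= paired.n):
        raise InvalidInputError(f"n must be in [1, {paired.n}]")
    rng = _rng(seed)
    probs = _selection_probabilities(paired.ref_values, target, pref, bandwidth)
    positive = probs > 0
    if positive.sum() < n:
        raise InvalidInputError(
            f"only {int(positive.sum())} pairs have positive selection "
            f"probability under target {target!r}; cannot draw {n}"
        )
    # weighted sampling without replacement via exponential keys
    keys = np.full(paired.n, np.inf)
    keys[positive] = rng.exponential(size=int(positive.sum())) / probs[positive]
    idx = np.argpartition(keys, n - 1)[:n]
    return paired.subset(idx)


# ---------------------------------------------------------------------------
# Range-dependent-error cohort (WMARD experiments)
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def range_dependent_relative_sd(r: np.ndarray, hypo_factor: float = 2.0) -> np.ndarray:
    """Relative CGM error SD as a smooth function of the reference value.

    Euglycemic floor 5%, rising to ``hypo_factor`` times that below
    70 mg/dL and by an extra 3 percentage points deep in hyperglycemia —
    the qualitative range profile reported for real sensors.
    """
    r = np.asarray(r, dtype=float)
    base = 0.05
    return (
        base * (1.0 + (hypo_factor - 1.0) * _sigmoid((70.0 - r) / 15.0))
        + 0.03 * _sigmoid((r - 250.0) / 40.0)
    )


def generate_range_dependent_cohort(
    n: int = 3000,
    seed: Union[int, None] = None,
    hypo_factor: float = 2.0,
    pref: ReferenceDistribution = ReferenceDistribution(),
) -> PairedDataset:
    """Paired cohort whose ARD depends on the glycemic range.

    Reference values are a log-normal bulk (70%, the standardized target)
    topped up with 30% uniform draws over [45, 445] mg/dL so that every
    glycemic region is well populated and the coverage rules pass; CGM
    readings are the references perturbed by zero-mean Gaussian relative
    noise whose SD follows :func:`range_dependent_relative_sd`.
    """
    rng = _rng(seed)
    n_uniform = int(round(0.3 * n))
    ref = np.concatenate(
        [
            pref.rvs(n - n_uniform, rng=rng),
            rng.uniform(45.0, 445.0, size=n_uniform),
        ]
    )
    ref = np.clip(ref, 41.0, 449.0)
    rng.shuffle(ref)
    sd = range_dependent_relative_sd(ref, hypo_factor=hypo_factor)
    cgm = np.maximum(ref * (1.0 + sd * rng.normal(size=n)), 1.0)
    return PairedDataset(times=np.arange(n, dtype=float), cgm_values=cgm, ref_values=ref)
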