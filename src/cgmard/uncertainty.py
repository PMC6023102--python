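"""Monte Carlo uncertainty of MARD and the MARD reliability index (MRI).

A MARD from a clinical study is a noisy estimate: it depends on how many
paired reference points were taken (Nref) and how accurate the reference
device was (err_ref, the 95% CI half-width of its relative error).  Across
Monte Carlo replications the MARD at a design point (Nref, err_ref) is well
approximated by a Gaussian centred at MARD2 + dMARD with spread sigma_MARD,
where MARD2 is the idealized MARD (dense sampling, error-free reference):

    dMARD     = a * err_ref^2
    sigma_MARD = (b + c * err_ref) / sqrt(Nref)
    a = 0.01244 - 0.00037 * MARD2
    b = 51.6178 - 7.7553 * MARD2 + 0.3569 * MARD2^2
    c = 0.0037

(all quantities in percent; the a, b, c correlations were derived for MARD2
between 10% and 16%).  The MRI is the half-width of the symmetric interval
around MARD2 containing a fraction gamma of the MARD sampling distribution:

    gamma = 1/2 * [erf((MRI - dMARD)/(sqrt(2) sigma)) - erf((-MRI - dMARD)/(sqrt(2) sigma))].

The module also evaluates the MARD idealization ladder MARD0..MARDreal on a
synthetic study scenario, switching the individual degrading effects
(diffusion delay, finite sampling, reference error, reference distribution)
on one at a time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .exceptions import ConvergenceError, InvalidInputError
from .metrics import MardEstimate, PairedDataset, compute_ard_series, compute_mard, weighted_mard
from .reference_error import ReferenceErrorModel, inject_reference_error
from . import wmard as _wmard

logger = logging.getLogger(__name__)

#: MARD2 range (percent) over which the default a, b, c correlations hold.
VALIDITY_RANGE = (10.0, 16.0)


def _check_validity(mard2: float) -> None:
    if not (VALIDITY_RANGE[0] <= mard2 <= VALIDITY_RANGE[1]):
        warnings.warn(
            f"MARD2={mard2:g}% is outside the [{VALIDITY_RANGE[0]:g}, "
            f"{VALIDITY_RANGE[1]:g}]% range the surface coefficients were "
            "derived for; values might not be appropriate",
            stacklevel=3,
        )


@dataclass(frozen=True)
class SurfaceCoefficients:
    """Coefficients of the Gaussian MARD-uncertainty surface.

    ``delta`` and ``sigma`` evaluate the mean offset and spread of the MARD
    sampling distribution at a design point.  ``from_mard2`` builds the
    default, literature-derived coefficients; ``fit_surface_coefficients``
    refits them on synthetic data.
    """

    a: float
    b: float
    c: float
    mard2: float

    @classmethod
    def from_mard2(cls, mard2: float) -> "SurfaceCoefficients":
        _check_validity(mard2)
        return cls(
            a=0.01244 - 0.00037 * mard2,
            b=51.6178 - 7.7553 * mard2 + 0.3569 * mard2**2,
            c=0.0037,
            mard2=mard2,
        )

    def delta(self, err_ref: float) -> float:
        if err_ref < 0:
            raise InvalidInputError("err_ref must be >= 0")
        return self.a * err_ref**2

    def sigma(self, err_ref: float, n_ref: int) -> float:
        if err_ref < 0:
            raise InvalidInputError("err_ref must be >= 0")
        if n_ref < 1:
            raise InvalidInputError("n_ref must be >= 1")
        return (self.b + self.c * err_ref) / np.sqrt(n_ref)


def delta_mard(err_ref: float, mard2: float) -> float:
    """Mean MARD inflation (percent) caused by reference error err_ref."""
    return SurfaceCoefficients.from_mard2(mard2).delta(err_ref)


def sigma_mard(err_ref: float, n_ref: int, mard2: float) -> float:
    """SD (percent) of the MARD sampling distribution at (err_ref, n_ref)."""
    return SurfaceCoefficients.from_mard2(mard2).sigma(err_ref, n_ref)


@dataclass(frozen=True)
class MriResult:
    """MARD reliability index at a given study design point."""

    mri: float
    gamma: float
    n_ref: int
    err_ref: float
    mard2: float


def compute_mri(
    n_ref: int,
    err_ref: float,
    mard2: float,
    gamma: float = 0.95,
    coefficients: Optional[SurfaceCoefficients] = None,
) -> MriResult:
    """Solve the erf equation for the MRI by bracketing root finding.

    The MRI is the half-width of the symmetric interval around MARD2 that
    contains fraction ``gamma`` of the Gaussian N(dMARD, sigma^2) MARD
    sampling distribution.  For err_ref = 0 the offset vanishes and the MRI
    reduces to the Gaussian quantile 1.959964 * sigma (at gamma = 0.95).
    """
    if not (0.0 < gamma < 1.0):
        raise InvalidInputError("gamma must be in (0, 1)")
    coeff = coefficients if coefficients is not None else SurfaceCoefficients.from_mard2(mard2)
    delta = coeff.delta(err_ref)
    sigma = coeff.sigma(err_ref, n_ref)

    def covered(m: float) -> float:
        s = np.sqrt(2.0) * sigma
        return 0.5 * (erf((m - delta) / s) - erf((-m - delta) / s))

    def f(m: float) -> float:
        return covered(m) - gamma

    hi = delta + 10.0 * sigma  # coverage there exceeds any gamma <= 0.9999
    if f(hi) < 0:
        raise ConvergenceError(
            f"MRI bracket [0, {hi:g}] does not contain the root "
            f"(gamma={gamma}, delta={delta:g}, sigma={sigma:g})"
        )
    mri = float(brentq(f, 0.0, hi, xtol=1e-13, maxiter=200))
    # Newton polish to machine precision; d(coverage)/dM is the Gaussian
    # density summed at the two interval ends
    sqrt2pi = np.sqrt(2.0 * np.pi)
    for _ in range(3):
        deriv = (
            np.exp(-0.5 * ((mri - delta) / sigma) ** 2)
            + np.exp(-0.5 * ((mri + delta) / sigma) ** 2)
        ) / (sigma * sqrt2pi)
        if deriv <= 0:
            break
        mri -= f(mri) / deriv
    residual = covered(mri) - gamma
    if abs(residual) > 1e-9:
        raise ConvergenceError(f"MRI residual {residual:.3e} exceeds 1e-9")
    return MriResult(mri=mri, gamma=gamma, n_ref=n_ref, err_ref=err_ref, mard2=mard2)


def mri_surface(
    n_ref_grid: Sequence[int],
    err_ref_grid: Sequence[float],
    mard2: float,
    gamma: float = 0.95,
) -> pd.DataFrame:
    """MRI on an (n_ref, err_ref) design grid.

    Rows are indexed by ``n_ref`` and columns by ``err_ref``; each column is
    non-increasing in n_ref, each row non-decreasing in err_ref.
    """
    n_ref_grid = list(n_ref_grid)
    err_ref_grid = list(err_ref_grid)
    if not n_ref_grid or not err_ref_grid:
        raise InvalidInputError("grids must be non-empty")
    values = np.array(
        [
            [compute_mri(n, e, mard2, gamma=gamma).mri for e in err_ref_grid]
            for n in n_ref_grid
        ]
    )
    return pd.DataFrame(values, index=pd.Index(n_ref_grid, name="n_ref"),
                        columns=pd.Index(err_ref_grid, name="err_ref"))


def subsample_mard_ci(
    paired: PairedDataset,
    n_ref: int,
    reps: int = 1000,
    gamma: float = 0.95,
    seed: Union[np.random.Generator, int, None] = None,
    replace: bool = False,
) -> MardEstimate:
    """Empirical CI of MARD under random subsampling to n_ref pairs.

    Subsets are drawn without replacement by default (random dropping of
    paired points); ``replace=True`` switches to a bootstrap.  The point
    estimate is the full-data MARD; the CI bounds are the empirical
    (1-gamma)/2 and (1+gamma)/2 percentiles over the replicate MARDs.
    """
    if not (1 <= n_ref <= paired.n):
        raise InvalidInputError(f"n_ref must be in [1, {paired.n}]")
    if reps < 100:
        raise InvalidInputError("reps must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ards = compute_ard_series(paired)
    sub_means = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(paired.n, size=n_ref, replace=replace)
        sub_means[r] = ards[idx].mean()
    lo, hi = np.percentile(sub_means, [100 * (1 - gamma) / 2, 100 * (1 + gamma) / 2])
    full = float(ards.mean())
    return MardEstimate(
        mard=full,
        n=paired.n,
        ci_low=float(min(lo, full)),
        ci_high=float(max(hi, full)),
        gamma=gamma,
    )


@dataclass(frozen=True)
class McDistribution:
    """Summary of the Monte Carlo MARD sampling distribution."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    gamma: float
    n_ref: int
    err_ref: float
    reps: int
    samples: np.ndarray


def mc_mard_distribution(
    paired: PairedDataset,
    n_ref: int,
    err_ref: float,
    reps: int = 1000,
    gamma: float = 0.95,
    seed: Union[np.random.Generator, int, None] = None,
) -> McDistribution:
    """Distribution of MARD under joint subsampling and reference error.

    Each replicate subsamples the dataset to ``n_ref`` pairs without
    replacement, injects reference error ``err_ref`` and recomputes MARD.
    """
    if not (1 <= n_ref <= paired.n):
        raise InvalidInputError(f"n_ref must be in [1, {paired.n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = ReferenceErrorModel(err_ref=err_ref)
    cgm = paired.cgm_values
    ref = paired.ref_values
    samples = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(paired.n, size=n_ref, replace=False)
        ref_r = ref[idx]
        if err_ref > 0:
            ref_r = inject_reference_error(ref_r, model, rng)
        samples[r] = np.mean(100.0 * np.abs(cgm[idx] - ref_r) / ref_r)
    lo, hi = np.percentile(samples, [100 * (1 - gamma) / 2, 100 * (1 + gamma) / 2])
    return McDistribution(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if reps > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        gamma=gamma,
        n_ref=n_ref,
        err_ref=err_ref,
        reps=reps,
        samples=samples,
    )


def fit_surface_coefficients(
    paired: PairedDataset,
    n_ref_grid: Sequence[int],
    err_ref_grid: Sequence[float],
    reps: int = 400,
    mard2: Optional[float] = None,
    seed: Union[np.random.Generator, int, None] = None,
) -> SurfaceCoefficients:
    """Least-squares refit of a, b, c on a Monte Carlo design grid.

    The default coefficients encode the clinical dataset they were derived
    from; a synthetic cohort needs its own fit.  ``a`` is fitted from the
    mean offsets (mean - MARD2 against err_ref^2), ``b`` and ``c`` from the
    replicate SDs scaled by sqrt(n_ref) (sd*sqrt(n) against err_ref).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mard2 is None:
        mard2 = compute_mard(paired).mard
    offsets, e2 = [], []
    sd_scaled, e1 = [], []
    for n in n_ref_grid:
        for e in err_ref_grid:
            dist = mc_mard_distribution(paired, n_ref=n, err_ref=e, reps=reps, seed=rng)
            offsets.append(dist.mean - mard2)
            e2.append(e**2)
            sd_scaled.append(dist.sd * np.sqrt(n))
            e1.append(e)
    e2 = np.asarray(e2)
    offsets = np.asarray(offsets)
    denom = np.dot(e2, e2)
    a = float(np.dot(e2, offsets) / denom) if denom > 0 else 0.0
    design = np.column_stack([np.ones(len(e1)), np.asarray(e1)])
    (b, c), *_ = np.linalg.lstsq(design, np.asarray(sd_scaled), rcond=None)
    return SurfaceCoefficients(a=a, b=float(b), c=float(c), mard2=float(mard2))


# ---------------------------------------------------------------------------
# MARD idealization ladder
# ---------------------------------------------------------------------------

MARD_LEVELS = ("MARD0", "MARD1", "MARD2", "MARD3", "MARDreal")


def mard_ladder(
    scenario,
    err_ref: float = 5.0,
    reps: int = 500,
    seed: Union[np.random.Generator, int, None] = None,
    pref: Optional[_wmard.ReferenceDistribution] = None,
    bandwidth: float = 10.0,
) -> pd.DataFrame:
    """Estimate E[MARD] and SD[MARD] at each idealization level.

    Per Monte Carlo replicate a fresh CGM noise realization is simulated for
    every subject of the scenario, then:

    * MARD1 — dense sampling, CGM compared against the IG truth (diffusion
      delay removed);
    * MARD0 — MARD1 with the dense ARDs importance-weighted so the reference
      (BG) distribution matches the standardized target ``pref``;
    * MARD2 — dense sampling, CGM against the BG truth;
    * MARD3 — finite reference schedule (the protocol's SMBG draws),
      error-free reference;
    * MARDreal — finite schedule plus reference error ``err_ref``.

    Returns a DataFrame indexed by level with columns ``mean_mard`` and
    ``sd_mard`` (percent).
    """
    from .synthetic import sample_reference_schedule, simulate_cgm  # local: avoid cycle

    if not scenario.bg_traces:
        raise InvalidInputError("scenario has no truth traces")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pref = pref if pref is not None else _wmard.ReferenceDistribution()

    bg_all = np.concatenate([tr.values for tr in scenario.bg_traces])
    ig_all = np.concatenate([tr.values for tr in scenario.ig_traces])
    # weights for MARD0 depend only on the fixed truth BG values
    p_hat = _wmard.estimate_density(bg_all, bandwidth=bandwidth)
    w0 = _wmard.compute_weights(bg_all, pref, p_hat, grid_interpolated=True)

    ref_model = ReferenceErrorModel(err_ref=err_ref)
    out = {lvl: np.empty(reps) for lvl in MARD_LEVELS}
    for r in range(reps):
        cgm_traces = [
            simulate_cgm(bg, scenario.sensor, seed=rng)
            for bg in scenario.bg_traces
        ]
        cgm_all = np.concatenate([tr.values for tr in cgm_traces])
        ard_vs_ig = 100.0 * np.abs(cgm_all - ig_all) / ig_all
        ard_vs_bg = 100.0 * np.abs(cgm_all - bg_all) / bg_all
        out["MARD1"][r] = ard_vs_ig.mean()
        out["MARD0"][r] = weighted_mard(ard_vs_ig, w0)
        out["MARD2"][r] = ard_vs_bg.mean()

        sched_cgm, sched_ref = [], []
        for bg, cgm in zip(scenario.bg_traces, cgm_traces):
            t = sample_reference_schedule(scenario.protocol, seed=rng)
            idx = np.clip(
                np.round((t - cgm.start_time) / cgm.sampling_interval).astype(int),
                0,
                len(cgm) - 1,
            )
            # reference = true BG at the matched sample instant (no spurious
            # time-mismatch error; the schedule contributes sampling variance only)
            sched_cgm.append(cgm.values[idx])
            sched_ref.append(bg.values[idx])
        sched_cgm = np.concatenate(sched_cgm)
        sched_ref = np.concatenate(sched_ref)
        out["MARD3"][r] = np.mean(100.0 * np.abs(sched_cgm - sched_ref) / sched_ref)
        pert = inject_reference_error(sched_ref, ref_model, rng) if err_ref > 0 else sched_ref
        out["MARDreal"][r] = np.mean(100.0 * np.abs(sched_cgm - pert) / pert)

    rows = {
        lvl: (out[lvl].mean(), out[lvl].std(ddof=1) if reps > 1 else 0.0)
        for lvl in MARD_LEVELS
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_mard", "sd_mard"]
    ).rename_axis("level")
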