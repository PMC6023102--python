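"""Core accuracy metrics for continuous glucose monitoring (CGM).

The fundamental quantity is the absolute relative difference (ARD) between a
CGM reading and a paired reference blood-glucose (BG) measurement,

    ARD_k = 100 % * |y_CGM(t_k) - y_ref(t_k)| / y_ref(t_k),

and its arithmetic mean over all paired points, the MARD.  All glucose values
are in mg/dL and all times in minutes from the start of the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, InvalidInputError

logger = logging.getLogger(__name__)

GLUCOSE_MAX_MGDL = 600.0


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class GlucoseTrace:
    """Uniformly sampled glucose time series.

    Parameters
    ----------
    values : array-like
        Glucose concentrations in mg/dL; strictly positive, at most 600.
    sampling_interval : float
        Constant spacing of the samples in minutes (> 0).
    start_time : float
        Time of the first sample in minutes.
    label : str
        Role tag: ``"BG"`` (blood glucose truth), ``"IG"`` (interstitial),
        ``"CGM"`` (sensor output) or ``"SMBG-dense"``.
    """

    values: np.ndarray
    sampling_interval: float
    start_time: float = 0.0
    label: str = "BG"

    def __post_init__(self):
        arr = _as_float_array(self.values, "values")
        if arr.size == 0:
            raise InvalidInputError("trace must contain at least one sample")
        if np.any(arr <= 0) or np.any(arr > GLUCOSE_MAX_MGDL):
            raise InvalidInputError(
                "glucose values must be in (0, 600] mg/dL"
            )
        if not self.sampling_interval > 0:
            raise InvalidInputError("sampling_interval must be > 0")
        object.__setattr__(self, "values", arr)

    @property
    def times(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.start_time + self.sampling_interval * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values, label: Optional[str] = None) -> "GlucoseTrace":
        """Copy of this trace with new values (same time grid)."""
        return GlucoseTrace(
            values=values,
            sampling_interval=self.sampling_interval,
            start_time=self.start_time,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class PairedDataset:
    """Time-aligned (CGM, reference BG) measurement pairs.

    ``times`` must be strictly increasing and every reference value strictly
    positive (the ARD divides by it).
    """

    times: np.ndarray
    cgm_values: np.ndarray
    ref_values: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        cgm = _as_float_array(self.cgm_values, "cgm_values")
        ref = _as_float_array(self.ref_values, "ref_values")
        if not (len(times) == len(cgm) == len(ref)):
            raise InvalidInputError("times, cgm_values, ref_values must have equal length")
        if len(times) < 1:
            raise InvalidInputError("paired dataset must contain at least one pair")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        bad = np.flatnonzero(ref <= 0)
        if bad.size:
            raise InvalidInputError(
                f"reference values must be strictly positive; offending index {bad[0]}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cgm_values", cgm)
        object.__setattr__(self, "ref_values", ref)

    @property
    def n(self) -> int:
        return len(self.times)

    def __len__(self) -> int:
        return len(self.times)

    def subset(self, indices) -> "PairedDataset":
        """Sub-dataset at the given indices (re-sorted by time)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return PairedDataset(
            times=self.times[idx],
            cgm_values=self.cgm_values[idx],
            ref_values=self.ref_values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "cgm_mgdl": self.cgm_values,
                "ref_mgdl": self.ref_values,
            }
        )


@dataclass(frozen=True)
class MardEstimate:
    """A MARD value (percent) with its sample size and optional CI."""

    mard: float
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self):
        if self.mard < 0:
            raise InvalidInputError("MARD cannot be negative")
        if (self.ci_low is None) != (self.ci_high is None):
            raise InvalidInputError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not (self.ci_low <= self.mard + 1e-12 and self.mard <= self.ci_high + 1e-12):
                raise InvalidInputError("CI must bracket the point estimate")


@dataclass(frozen=True)
class RangeBinning:
    """Glycemic-range binning for range-resolved MARD.

    Bins are left-closed right-open ``[low, low+width)``; the final bin is
    closed at ``high`` so the full range is covered.
    """

    low: float = 40.0
    high: float = 420.0
    width: float = 20.0

    def __post_init__(self):
        if not (self.high > self.low and self.width > 0):
            raise InvalidInputError("need high > low and width > 0")
        n = (self.high - self.low) / self.width
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError("(high - low) must be divisible by width")

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.low, self.high + self.width / 2, self.width)

    @property
    def n_bins(self) -> int:
        return int(round((self.high - self.low) / self.width))

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for out-of-range values.

        The closing edge ``high`` belongs to the last bin.
        """
        values = np.asarray(values, dtype=float)
        idx = np.floor((values - self.low) / self.width).astype(int)
        idx[values == self.high] = self.n_bins - 1
        idx[(values < self.low) | (values > self.high)] = -1
        return idx


def compute_ard_series(paired: PairedDataset) -> np.ndarray:
    """Per-pair absolute relative difference, in percent."""
    return 100.0 * np.abs(paired.cgm_values - paired.ref_values) / paired.ref_values


def compute_mard(paired: PairedDataset, statistic: str = "mean") -> MardEstimate:
    """MARD of a paired dataset (no confidence interval attached).

    ``statistic="median"`` is available for comparison with studies that
    report the median ARD, but the mean is the default and the convention
    everywhere else in this package.
    """
    ards = compute_ard_series(paired)
    if statistic == "mean":
        value = float(np.mean(ards))
    elif statistic == "median":
        value = float(np.median(ards))
    else:
        raise InvalidInputError(f"unknown statistic {statistic!r}")
    return MardEstimate(mard=value, n=paired.n)


def weighted_mard(ards: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean of ARD values (percent); weights need not be normalized."""
    ards = np.asarray(ards, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ards.shape != weights.shape:
        raise InvalidInputError("ards and weights must have equal length")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise InvalidInputError("weights must be finite and non-negative")
    total = weights.sum()
    if total <= 0:
        raise InvalidInputError("sum of weights must be positive")
    return float(np.dot(weights, ards) / total)


def mard_by_range(
    paired: PairedDataset, bins: RangeBinning = RangeBinning()
) -> pd.DataFrame:
    """Mean ARD per glycemic-range bin of the reference value.

    Returns a DataFrame with columns ``bin_low``, ``bin_high``, ``mean_ard``
    (NaN marks an empty bin — deliberately not 0) and ``count``.  Pairs whose
    reference value falls outside ``[low, high]`` are excluded from the table;
    their count is stored in ``result.attrs["n_out_of_range"]``.
    """
    ards = compute_ard_series(paired)
    idx = bins.assign(paired.ref_values)
    in_range = idx >= 0
    counts = np.bincount(idx[in_range], minlength=bins.n_bins)
    sums = np.bincount(idx[in_range], weights=ards[in_range], minlength=bins.n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = bins.edges
    out = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "mean_ard": means,
            "count": counts,
        }
    )
    n_out = int(np.sum(~in_range))
    if n_out:
        logger.info("mard_by_range: %d pairs outside [%g, %g] mg/dL", n_out, bins.low, bins.high)
    out.attrs["n_out_of_range"] = n_out
    return out


def pair_measurements(
    cgm: GlucoseTrace,
    ref_times: Sequence[float],
    ref_values: Sequence[float],
    tolerance: float,
) -> PairedDataset:
    """Match reference points to the nearest-in-time CGM sample.

    A reference point farther than ``tolerance`` minutes from every CGM sample
    is dropped (and logged).  When a reference time is exactly midway between
    two CGM samples the earlier sample wins: the CGM lags BG, so the earlier
    sample never uses future information.
    """
    if tolerance < 0:
        raise InvalidInputError("tolerance must be >= 0")
    ref_times = _as_float_array(ref_times, "ref_times")
    ref_values = _as_float_array(ref_values, "ref_values")
    if len(ref_times) != len(ref_values):
        raise InvalidInputError("ref_times and ref_values must have equal length")
    order = np.argsort(ref_times, kind="stable")
    ref_times = ref_times[order]
    ref_values = ref_values[order]

    grid = cgm.times
    pos = np.searchsorted(grid, ref_times)
    lo = np.clip(pos - 1, 0, len(grid) - 1)
    hi = np.clip(pos, 0, len(grid) - 1)
    d_lo = np.abs(ref_times - grid[lo])
    d_hi = np.abs(ref_times - grid[hi])
    # tie -> earlier sample
    nearest = np.where(d_lo <= d_hi, lo, hi)
    dist = np.minimum(d_lo, d_hi)
    keep = dist <= tolerance

    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info(
            "pair_measurements: dropped %d reference points beyond tolerance %g min",
            n_dropped,
            tolerance,
        )
    if not np.any(keep):
        raise EmptyResultError("no reference point matched a CGM sample within tolerance")
    return PairedDataset(
        times=ref_times[keep],
        cgm_values=cgm.values[nearest[keep]],
        ref_values=ref_values[keep],
    )


def concatenate(datasets: Sequence[PairedDataset]) -> PairedDataset:
    """Concatenate paired datasets onto a common increasing time axis.

    Subject-relative times would collide across subjects, so each dataset is
    shifted to start after the previous one ends.  MARD is order-independent,
    making the shift harmless for every metric in this package.
    """
    if not datasets:
        raise InvalidInputError("need at least one dataset")
    times, cgm, ref = [], [], []
    offset = 0.0
    for ds in datasets:
        t = ds.times - ds.times[0] + offset
        times.append(t)
        cgm.append(ds.cgm_values)
        ref.append(ds.ref_values)
        offset = t[-1] + 1.0
    return PairedDataset(
        times=np.concatenate(times),
        cgm_values=np.concatenate(cgm),
        ref_values=np.concatenate(ref),
    )
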