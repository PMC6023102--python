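"""Monte Carlo experiments combining the synthetic generator with the metrics.

Currently: the WMARD distribution-invariance experiment — repeatedly
subsample one cohort to two very different reference-value distributions and
show that MARD shifts while WMARD stays put.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import CoverageError, InvalidInputError
from .metrics import PairedDataset, compute_ard_series
from .synthetic import _selection_probabilities
from .wmard import (
    DensityEstimate,
    ReferenceDistribution,
    validate_coverage,
)


@dataclass(frozen=True)
class InvarianceResult:
    """Mean MARD/WMARD under two subsampling designs, and their gaps."""

    mean_mard_lognormal: float
    mean_wmard_lognormal: float
    mean_mard_uniform: float
    mean_wmard_uniform: float
    reps: int
    n_subsample: int

    @property
    def delta_mard(self) -> float:
        """|mean MARD(log-normal design) - mean MARD(uniform design)|, pp."""
        return abs(self.mean_mard_lognormal - self.mean_mard_uniform)

    @property
    def delta_wmard(self) -> float:
        return abs(self.mean_wmard_lognormal - self.mean_wmard_uniform)


def distribution_invariance_experiment(
    paired: PairedDataset,
    reps: int = 5000,
    n_subsample: Union[int, None] = None,
    seed: Union[np.random.Generator, int, None] = None,
    pref: ReferenceDistribution = ReferenceDistribution(),
    bandwidth: float = 10.0,
) -> InvarianceResult:
    """Compare MARD vs WMARD across two subsampling designs.

    For each of ``reps`` replicates, half of the cohort (or ``n_subsample``
    pairs) is drawn without replacement twice: once with selection
    probabilities shaped towards the standardized log-normal reference
    distribution, once towards a flat (uniform-like) distribution.  MARD and
    WMARD are recomputed per subset; WMARD re-estimates the subset's own
    reference-value density (Gaussian KDE, fixed bandwidth) every time, as
    it would in a real study.

    The cohort must satisfy the coverage rules up front (subsets inherit
    coverage in all but pathological cases and are not re-checked in the
    replicate loop).
    """
    if n_subsample is None:
        n_subsample = paired.n // 2
    if not (2 <= n_subsample <= paired.n):
        raise InvalidInputError("n_subsample out of range")
    if not validate_coverage(paired.ref_values).passed:
        raise CoverageError("cohort fails coverage rules; WMARD would be unreliable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ards = compute_ard_series(paired)
    ref = paired.ref_values
    results = {}
    for target in ("lognormal", "uniform"):
        probs = _selection_probabilities(ref, target, pref, bandwidth)
        positive = probs > 0
        if positive.sum() < n_subsample:
            raise InvalidInputError(f"cohort too small for target {target!r}")
        mards = np.empty(reps)
        wmards = np.empty(reps)
        for r in range(reps):
            keys = np.full(paired.n, np.inf)
            keys[positive] = rng.exponential(size=int(positive.sum())) / probs[positive]
            idx = np.argpartition(keys, n_subsample - 1)[:n_subsample]
            r_sub = ref[idx]
            a_sub = ards[idx]
            mards[r] = a_sub.mean()
            p_hat = DensityEstimate(r_sub, bandwidth=bandwidth)
            w = pref.pdf(r_sub) / p_hat(r_sub, grid_interpolated=True)
            wmards[r] = np.dot(w, a_sub) / w.sum()
        results[target] = (mards.mean(), wmards.mean())

    return InvarianceResult(
        mean_mard_lognormal=float(results["lognormal"][0]),
        mean_wmard_lognormal=float(results["lognormal"][1]),
        mean_mard_uniform=float(results["uniform"][0]),
        mean_wmard_uniform=float(results["uniform"][1]),
        reps=reps,
        n_subsample=n_subsample,
    )
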