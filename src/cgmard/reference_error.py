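"""Stochastic error model for the reference BG measurement device.

Reference meters (SMBG strips, lab analyzers) are not error-free.  Their
accuracy is conventionally quoted as the 95% confidence half-width of the
relative measurement error, ``err_ref`` in percent.  The error is modelled
as uncorrelated, zero-mean, multiplicative Gaussian noise:

    y_perturbed = y_ref * (1 + e),   e ~ N(0, (err_ref / 100 / 1.96)^2).

A bias term is deliberately absent: when the same meter calibrates the CGM
and supplies the paired reference values, a shared bias cancels out of the
comparison and only the stochastic part moves the MARD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import InvalidInputError
from .metrics import PairedDataset, compute_ard_series

logger = logging.getLogger(__name__)

#: 97.5% standard-normal quantile used to convert a 95% CI half-width to a SD.
Z_95 = 1.96

CLIP_FLOOR_MGDL = 1.0


@dataclass(frozen=True)
class ReferenceErrorModel:
    """Gaussian relative error of the reference device.

    Parameters
    ----------
    err_ref : float
        95%-CI half-width of the relative error, percent (>= 0).
    seed : int, optional
        Default seed for draws when no generator is supplied.
    """

    err_ref: float
    seed: Optional[int] = None

    def __post_init__(self):
        if not np.isfinite(self.err_ref) or self.err_ref < 0:
            raise InvalidInputError("err_ref must be finite and >= 0")

    @property
    def relative_sd(self) -> float:
        """Standard deviation of the relative error (fraction, not percent)."""
        return self.err_ref / 100.0 / Z_95

    def rng(self, rng: Union[np.random.Generator, int, None] = None) -> np.random.Generator:
        if isinstance(rng, np.random.Generator):
            return rng
        if rng is None:
            rng = self.seed
        return np.random.default_rng(rng)


def inject_reference_error(
    ref_values: Sequence[float],
    model: ReferenceErrorModel,
    rng: Union[np.random.Generator, int, None] = None,
) -> np.ndarray:
    """Perturb reference values with the model's multiplicative noise.

    Draws below 1 mg/dL are clipped (with a logged warning): the perturbed
    value re-enters the ARD denominator and must stay positive.
    """
    ref = np.asarray(ref_values, dtype=float)
    if np.any(ref <= 0):
        raise InvalidInputError("reference values must be positive")
    if model.err_ref == 0:
        return ref.copy()
    gen = model.rng(rng)
    e = gen.normal(0.0, model.relative_sd, size=ref.shape)
    out = ref * (1.0 + e)
    n_clip = int(np.sum(out < CLIP_FLOOR_MGDL))
    if n_clip:
        logger.warning(
            "inject_reference_error: clipped %d perturbed values at %g mg/dL",
            n_clip,
            CLIP_FLOOR_MGDL,
        )
        out = np.maximum(out, CLIP_FLOOR_MGDL)
    return out


def perturbed_ard_series(
    paired: PairedDataset,
    model: ReferenceErrorModel,
    rng: Union[np.random.Generator, int, None] = None,
    errors: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """ARD series with reference error injected into the reference values.

    The same perturbed value appears in the numerator difference and in the
    denominator — the CGM readings are untouched.  ``errors`` fixes the
    relative error draws explicitly (deterministic analyses and tests).
    """
    if errors is not None:
        e = np.asarray(errors, dtype=float)
        if e.shape != paired.ref_values.shape:
            raise InvalidInputError("errors must match the number of pairs")
        perturbed = np.maximum(paired.ref_values * (1.0 + e), CLIP_FLOOR_MGDL)
    else:
        perturbed = inject_reference_error(paired.ref_values, model, rng)
    shadow = PairedDataset(
        times=paired.times, cgm_values=paired.cgm_values, ref_values=perturbed
    )
    return compute_ard_series(shadow)
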