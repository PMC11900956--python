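"""Empirical linear scaling of isotropic shieldings to chemical shifts.

Systematic error in computed shieldings is removed by ordinary least
squares of the shielding σ on the experimental shift δ_exp,

    σ = a·δ_exp + b,

after which computed shieldings are converted ("internally referenced")
to shifts by inverting the line: δ_calc = (σ − b)/a. For physically
sensible data the slope a is negative — shielding decreases as the shift
increases — and close to −1.

Fits are always per element: ¹H and ¹³C shielding/shift ranges differ by
an order of magnitude and are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
from scipy import stats

from .ensemble import AveragedShieldings
from .errors import InsufficientDataError, PositiveSlopeWarning, ValidationError
from .model import Nucleus


@dataclass
class ScalingFit:
    """Slope/intercept of σ = a·δ_exp + b for one element and fit scope.

    ``scope_id`` is the candidate id for per-candidate fits or ``"pooled"``
    for a dataset-wide fit.
    """

    element: str
    scope_id: str
    a: float
    b: float
    n: int

    def shift(self, sigma: float) -> float:
        """Scaled calculated shift δ_calc = (σ − b)/a."""
        return (sigma - self.b) / self.a

    def shielding(self, delta: float) -> float:
        """Forward line a·δ + b."""
        return self.a * delta + self.b


def fit_scaling(
    delta_exp,
    sigma,
    element: str,
    scope_id: str = "",
) -> ScalingFit:
    """Ordinary least squares of shieldings on experimental shifts.

    Parameters
    ----------
    delta_exp, sigma : aligned sequences of experimental shifts and
        (Boltzmann-averaged) shieldings, ppm. Missing entries must already
        be excluded.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 pairs, or all ``delta_exp`` identical.

    Warns
    -----
    PositiveSlopeWarning
        If the fitted slope is positive (physically suspect but not fatal).
    """
    x = np.asarray(list(delta_exp), dtype=float)
    y = np.asarray(list(sigma), dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} shifts vs {y.size} shieldings")
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 pairs to fit, got {x.size}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("all experimental shifts identical (zero variance)")
    result = stats.linregress(x, y)
    a, b = float(result.slope), float(result.intercept)
    if a == 0:
        raise ValidationError("degenerate fit: zero slope")
    if a > 0:
        warnings.warn(
            f"positive shielding-vs-shift slope a={a:.4g} for {element} "
            f"(scope {scope_id!r}); check input orientation",
            PositiveSlopeWarning,
            stacklevel=2,
        )
    return ScalingFit(element=element, scope_id=scope_id, a=a, b=b, n=int(x.size))


def apply_scaling(
    sigma: Union[AveragedShieldings, Mapping[Nucleus, float]],
    fit: ScalingFit,
) -> dict[Nucleus, float]:
    """Convert shieldings to scaled shifts δ_calc = (σ − b)/a.

    Accepts a plain nucleus→shielding mapping (all nuclei must match the
    fit's element) and includes nuclei whose experimental shift is missing
    — that is how unknown shifts get predicted.
    """
    mapping = sigma.sigma if isinstance(sigma, AveragedShieldings) else sigma
    out: dict[Nucleus, float] = {}
    for nucleus, value in mapping.items():
        if nucleus.element != fit.element:
            raise ValidationError(
                f"element mismatch: fit is for {fit.element}, got {nucleus!r}"
            )
        out[nucleus] = fit.shift(value)
    return out
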