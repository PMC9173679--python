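"""Quantile-matched sampling distributions.

Patient-level biomarker data behind published triage studies are rarely
public; what *is* printed are per-class quartile triplets.  The sampler here
is pinned to those anchors: its inverse CDF passes exactly through
(0.25, q1), (0.5, median), (0.75, q3), interpolates between them, and decays
exponentially beyond the outer quartiles.  No parametric family is fitted,
so the printed quartiles are reproduced by construction.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .models import QuartileAnchor, ValidationError

__all__ = ["QuantileMatchedDistribution", "fit_quartile_distribution"]

AnchorLike = Union[QuartileAnchor, tuple]


def _as_anchor(anchor: AnchorLike) -> QuartileAnchor:
    if isinstance(anchor, QuartileAnchor):
        return anchor
    return QuartileAnchor(*anchor)


class QuantileMatchedDistribution:
    """Sampleable distribution with exact quartiles at a printed anchor.

    Parameters
    ----------
    anchor
        (q1, median, q3) triplet; quartiles of the returned distribution.
    lower_scale, upper_scale
        Scales (in value units, or log units when ``log_scale``) of the
        exponential tails below q1 / above q3.  A zero scale pins the tail
        to the outer quartile.
    log_scale
        Interpolate and extrapolate in log space.  Requires q1 > 0.  Used
        for concentration anchors, whose spread is multiplicative; signed
        deltas stay on the linear scale.
    floor
        Optional hard lower bound applied after inversion (e.g. 0 for
        unsigned delta magnitudes).
    """

    def __init__(
        self,
        anchor: AnchorLike,
        lower_scale: float,
        upper_scale: float,
        *,
        log_scale: bool = False,
        floor: Optional[float] = None,
    ) -> None:
        anchor = _as_anchor(anchor)
        if lower_scale < 0 or upper_scale < 0:
            raise ValidationError("tail scales must be non-negative")
        if log_scale and anchor.q1 <= 0:
            raise ValidationError(
                f"log-scale interpolation requires q1 > 0, got q1={anchor.q1}"
            )
        self.anchor = anchor
        self.lower_scale = float(lower_scale)
        self.upper_scale = float(upper_scale)
        self.log_scale = bool(log_scale)
        self.floor = floor
        if log_scale:
            self._knots = np.log(np.array(anchor.as_tuple(), dtype=float))
        else:
            self._knots = np.array(anchor.as_tuple(), dtype=float)

    def ppf(self, u):
        """Inverse CDF, vectorised; exact at u = 0.25, 0.5, 0.75."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValidationError("quantile levels must lie in [0, 1]")
        k1, k2, k3 = self._knots
        x = np.interp(u, [0.25, 0.5, 0.75], [k1, k2, k3])
        with np.errstate(divide="ignore"):
            lo = u < 0.25
            if self.lower_scale > 0:
                x = np.where(lo, k1 + self.lower_scale * np.log(u / 0.25), x)
            else:
                x = np.where(lo, k1, x)
            hi = u > 0.75
            if self.upper_scale > 0:
                x = np.where(hi, k3 - self.upper_scale * np.log((1.0 - u) / 0.25), x)
            else:
                x = np.where(hi, k3, x)
        if self.log_scale:
            x = np.exp(x)
        if self.floor is not None:
            x = np.maximum(x, self.floor)
        return x if x.ndim else float(x)

    def rvs(self, size: int, rng: np.random.Generator):
        """Draw ``size`` samples by inverting uniforms from ``rng``."""
        u = rng.random(size)
        # keep the inverse finite at the open ends of the tails
        return self.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))


def fit_quartile_distribution(
    anchor: AnchorLike, tail_scale: float
) -> QuantileMatchedDistribution:
    """Quantile-matched generator for a printed [q1; median; q3] triplet.

    Piecewise-linear inverse CDF between the anchors with symmetric
    exponential tails beyond the outer quartiles, each of scale
    ``tail_scale`` x interquartile range.

    >>> d = fit_quartile_distribution((8, 16, 49), 1.0)
    >>> d.ppf(0.5)
    16.0
    """
    if tail_scale <= 0:
        raise ValidationError(f"tail_scale must be positive, got {tail_scale}")
    anchor = _as_anchor(anchor)
    scale = tail_scale * anchor.iqr
    return QuantileMatchedDistribution(anchor, scale, scale, log_scale=False)
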