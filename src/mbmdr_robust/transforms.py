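"""Pre-analysis trait transformations.

Five transformations can precede MB-MDR screening: identity (raw), natural
logarithm (log), standardization (stz), pooled average-tie ranks (rank), and
rank transformation to normality (rtn), i.e. mapping ranks to standard-normal
quantiles.  Standardization is affine and therefore leaves every two-group t
statistic unchanged; rank and rtn depend on the data only through its
ordering, so they are invariant under any strictly increasing pre-transform.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "TRANSFORM_TAGS",
    "DegenerateTraitError",
    "transform_log",
    "transform_standardize",
    "transform_rank",
    "transform_rank_to_normal",
    "apply_transform",
]

TRANSFORM_TAGS = ("raw", "log", "stz", "rank", "rtn")


class DegenerateTraitError(ValueError):
    """Raised when a transform is undefined for the input (e.g. constant trait)."""


def _as_trait(t) -> np.ndarray:
    x = np.asarray(t, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("trait must be a nonempty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("trait values must be finite")
    return x


def transform_log(t) -> np.ndarray:
    """Natural logarithm; non-positive inputs are shifted by -min + 1 first.

    The shift keeps the transform defined (and order-preserving) for traits
    that can be negative, such as Gaussian residuals.
    """
    x = _as_trait(t)
    lo = x.min()
    if lo <= 0.0:
        x = x - lo + 1.0
    return np.log(x)


def transform_standardize(t) -> np.ndarray:
    """Center by the overall mean and scale by the overall sample sd (ddof=1)."""
    x = _as_trait(t)
    if x.size < 2:
        raise DegenerateTraitError("standardization needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTraitError("constant trait cannot be standardized")
    return (x - x.mean()) / sd


def transform_rank(t) -> np.ndarray:
    """Pooled ranks 1..n in increasing order; ties get the average rank."""
    return rankdata(_as_trait(t), method="average")


def transform_rank_to_normal(t, position: str = "midpoint") -> np.ndarray:
    """Map average-tie ranks r to standard-normal quantiles.

    position="midpoint" uses the plotting position (r - 0.5)/n (symmetric,
    never reaches 0 or 1); position="vdw" uses the van der Waerden variant
    r/(n + 1).
    """
    r = transform_rank(t)
    n = r.size
    if position == "midpoint":
        q = (r - 0.5) / n
    elif position == "vdw":
        q = r / (n + 1.0)
    else:
        raise ValueError("position must be 'midpoint' or 'vdw'")
    return ndtri(q)


def apply_transform(tag: str, t) -> np.ndarray:
    """Dispatch on a transform tag from ``TRANSFORM_TAGS``."""
    if tag == "raw":
        return _as_trait(t)
    if tag == "log":
        return transform_log(t)
    if tag == "stz":
        return transform_standardize(t)
    if tag == "rank":
        return transform_rank(t)
    if tag == "rtn":
        return transform_rank_to_normal(t)
    raise ValueError(f"unknown transform tag {tag!r}; expected one of {TRANSFORM_TAGS}")
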