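"""Short- and medium-range pair potential functions.

A *potential* is a bounded function of inter-point distance, taking values
in ``[0, 1]``, that sets the shape of an interaction term in a pairwise
interaction Gibbs model.  Two scales are modeled:

* **short range** — maximal at distance zero and decaying with distance;
  parameterized by a single radius ``R``;
* **medium range** — a band ``(R_inner, R_outer)``; the potential is
  maximal inside/at the middle of the band and vanishes (or decays) away
  from it.

Normalization convention
------------------------
For the exponential family the interaction radius is the distance at which
the potential equals 1/2:

* short:   ``phi(d) = 2**(-d / R)``            (1 at d=0, 1/2 at d=R)
* medium:  ``psi(d) = 2**(-|d - m| / h)`` with ``m = (R_inner+R_outer)/2``
  and ``h = (R_outer-R_inner)/2``              (1 at the band midpoint,
  1/2 at both band edges)

Step potentials are plain indicators: ``1{d <= R}`` and
``1{R_inner <= d <= R_outer}``.

Fitted interaction coefficients scale inversely with the potential's
magnitude, so this half-at-radius convention matters when comparing
absolute coefficient values across potential families or radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("exponential", "step")

#: default interaction radii in microns: short 30, medium band (70, 150)
DEFAULT_SHORT_RADIUS = 30.0
DEFAULT_MEDIUM_RADII = (70.0, 150.0)


def _check_distances(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d


def short_values(d, radius, family: str = "exponential") -> np.ndarray:
    """Evaluate a short-range potential at distances ``d``.

    ``radius`` may be a scalar or an array broadcastable against ``d``
    (per-pair radii).
    """
    d = _check_distances(d)
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("short-range radius must be positive")
    if family == "exponential":
        return np.exp2(-d / radius)
    if family == "step":
        return np.where(d <= radius, 1.0, 0.0)
    raise ValueError(f"unknown potential family {family!r}; expected one of {FAMILIES}")


def medium_values(d, inner, outer, family: str = "exponential") -> np.ndarray:
    """Evaluate a medium-range band potential at distances ``d``.

    ``inner``/``outer`` may be scalars or arrays broadcastable against
    ``d``; ``outer > inner > 0`` is required.
    """
    d = _check_distances(d)
    inner = np.asarray(inner, dtype=float)
    outer = np.asarray(outer, dtype=float)
    if np.any(inner <= 0) or np.any(outer <= inner):
        raise ValueError("medium-range radii must satisfy 0 < inner < outer")
    if family == "exponential":
        mid = 0.5 * (inner + outer)
        half_width = 0.5 * (outer - inner)
        return np.exp2(-np.abs(d - mid) / half_width)
    if family == "step":
        return np.where((d >= inner) & (d <= outer), 1.0, 0.0)
    raise ValueError(f"unknown potential family {family!r}; expected one of {FAMILIES}")


@dataclass(frozen=True)
class PotentialSpec:
    """A pair potential: scale, functional family and radius/radii.

    ``radii`` is a single radius for ``scale="short"`` and an
    ``(inner, outer)`` pair for ``scale="medium"``.
    """

    scale: str
    family: str = "exponential"
    radii: object = None

    def __post_init__(self):
        if self.scale not in ("short", "medium"):
            raise ValueError("scale must be 'short' or 'medium'")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        radii = self.radii
        if radii is None:
            radii = (
                DEFAULT_SHORT_RADIUS
                if self.scale == "short"
                else DEFAULT_MEDIUM_RADII
            )
        if self.scale == "short":
            radii = float(radii)
            if radii <= 0:
                raise ValueError("short-range radius must be positive")
        else:
            inner, outer = (float(r) for r in radii)
            if inner <= 0 or outer <= inner:
                raise ValueError("medium-range radii must satisfy 0 < inner < outer")
            radii = (inner, outer)
        object.__setattr__(self, "radii", radii)

    def evaluate(self, d) -> np.ndarray:
        """Evaluate the potential at distance(s) ``d`` (microns)."""
        if self.scale == "short":
            return short_values(d, self.radii, self.family)
        inner, outer = self.radii
        return medium_values(d, inner, outer, self.family)

    __call__ = evaluate


def short_potential(radius: float = DEFAULT_SHORT_RADIUS,
                    family: str = "exponential") -> PotentialSpec:
    return PotentialSpec(scale="short", family=family, radii=radius)


def medium_potential(radii=DEFAULT_MEDIUM_RADII,
                     family: str = "exponential") -> PotentialSpec:
    return PotentialSpec(scale="medium", family=family, radii=tuple(radii))


def eval_short(spec: PotentialSpec, d) -> np.ndarray:
    """Evaluate a short-range :class:`PotentialSpec` at distance(s) ``d``."""
    if spec.scale != "short":
        raise ValueError("eval_short requires a short-scale PotentialSpec")
    return spec.evaluate(d)


def eval_medium(spec: PotentialSpec, d) -> np.ndarray:
    """Evaluate a medium-range :class:`PotentialSpec` at distance(s) ``d``."""
    if spec.scale != "medium":
        raise ValueError("eval_medium requires a medium-scale PotentialSpec")
    return spec.evaluate(d)
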