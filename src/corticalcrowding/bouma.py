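"""Visual-field geometry of letter crowding.

Peripheral letter recognition is limited by *crowding*: a letter is only
recognizable if its neighbors are farther away than the local crowding
distance.  The radial crowding distance grows linearly with eccentricity
(the Bouma law),

    s_r(phi) = b * (phi + phi0),

with ``b`` the observer's Bouma factor and ``phi0`` a small offset (deg)
that keeps the law affine near the fovea.  Crowding zones are radially
elongated: the tangential crowding distance is ``s_t = s_r / a`` with
``a ~ 2``.  Packing letters at exactly threshold spacing everywhere gives a
local letter density of ``1 / (s_r * s_t)`` letters per deg² and, integrated
over a disk of radius ``phi_max``, a total uncrowded-letter count

    lambda = (2*pi*a / b**2) * [ln(1 + phi_max/phi0) - 1/(1 + phi0/phi_max)].

``lambda`` is the single psychophysical summary that this package relates to
cortical map surface area.  The closed form is guarded by an independent
numerical quadrature of the density (``uncrowded_letter_count_numeric``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "BoumaLawParams",
    "VisualFieldSpec",
    "radial_crowding_distance",
    "tangential_crowding_distance",
    "letter_density",
    "uncrowded_letter_count",
    "uncrowded_letter_count_numeric",
    "lambda_sensitivity",
    "letter_layout",
    "DEFAULT_PHI0",
    "DEFAULT_A",
    "DEFAULT_PHI_MAX",
]

#: Default eccentricity offset of the Bouma law, deg.
DEFAULT_PHI0 = 0.24
#: Default radial-to-tangential crowding-distance ratio.
DEFAULT_A = 2.0
#: Default maximum eccentricity of the analyzed visual field, deg.
DEFAULT_PHI_MAX = 10.0


@dataclass(frozen=True)
class BoumaLawParams:
    """Parameters of the crowding model.

    Parameters
    ----------
    b : float
        Bouma factor (unitless slope of crowding distance vs eccentricity).
    phi0 : float
        Eccentricity offset, deg.  Must be > 0 for the letter count to be
        finite (the density otherwise diverges logarithmically at the fovea).
    a : float
        Radial-to-tangential crowding-distance ratio (unitless, >= typically 2).
    """

    b: float
    phi0: float = DEFAULT_PHI0
    a: float = DEFAULT_A

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"Bouma factor b must be > 0, got {self.b}")
        if self.phi0 < 0:
            raise ValueError(f"phi0 must be >= 0, got {self.phi0}")
        if not self.a > 0:
            raise ValueError(f"ratio a must be > 0, got {self.a}")

    def with_b(self, b: float) -> "BoumaLawParams":
        return replace(self, b=b)


@dataclass(frozen=True)
class VisualFieldSpec:
    """Circular visual field of radius ``phi_max`` deg."""

    phi_max: float = DEFAULT_PHI_MAX

    def __post_init__(self) -> None:
        if not self.phi_max > 0:
            raise ValueError(f"phi_max must be > 0, got {self.phi_max}")


def _check_phi(phi):
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("eccentricity phi must be >= 0")
    return phi if phi.ndim else float(phi)


def radial_crowding_distance(params: BoumaLawParams, phi):
    """Radial crowding distance ``b * (phi + phi0)`` in deg at eccentricity ``phi``."""
    phi = _check_phi(phi)
    return params.b * (phi + params.phi0)


def tangential_crowding_distance(params: BoumaLawParams, phi):
    """Tangential crowding distance, ``radial / a``, in deg."""
    return radial_crowding_distance(params, phi) / params.a


def letter_density(params: BoumaLawParams, phi):
    """Letters per deg² when packed at threshold spacing: ``1 / (s_r * s_t)``.

    Equals ``a / (b**2 * (phi + phi0)**2)``; strictly decreasing in ``phi``.
    """
    phi = _check_phi(phi)
    if np.any(np.asarray(phi) + params.phi0 <= 0):
        raise ValueError(
            "letter density is singular at phi + phi0 = 0; need phi + phi0 > 0"
        )
    return params.a / (params.b ** 2 * (phi + params.phi0) ** 2)


def _log_bracket(phi0: float, phi_max: float) -> float:
    """The geometry factor ln(1 + phi_max/phi0) - 1/(1 + phi0/phi_max)."""
    return math.log1p(phi_max / phi0) - 1.0 / (1.0 + phi0 / phi_max)


def uncrowded_letter_count(
    params: BoumaLawParams, field: VisualFieldSpec = VisualFieldSpec()
) -> float:
    """Closed-form count of letters fitting in the uncrowded visual field.

    Integrates ``letter_density`` in polar coordinates over the disk of
    radius ``phi_max`` (the angular integral contributes an exact factor
    2*pi; the radial integral of ``phi/(phi+phi0)**2`` is
    ``ln(phi+phi0) + phi0/(phi+phi0)``), giving

        lambda = (2*pi*a / b**2) * [ln(1 + phi_max/phi0) - 1/(1 + phi0/phi_max)]

    Returns a real number; round to the nearest integer when reporting a
    letter count.

    Raises
    ------
    ValueError
        If ``phi0 == 0``: the integral diverges logarithmically at the
        fovea, so the count is infinite.
    """
    if params.phi0 == 0:
        raise ValueError(
            "uncrowded letter count diverges logarithmically for phi0 = 0; "
            "a positive foveal offset phi0 is required"
        )
    pref = 2.0 * math.pi * params.a / params.b ** 2
    return pref * _log_bracket(params.phi0, field.phi_max)


def uncrowded_letter_count_numeric(
    params: BoumaLawParams,
    field: VisualFieldSpec = VisualFieldSpec(),
    inner_radius: float = 0.0,
    rel_tol: float = 1e-10,
) -> float:
    """Quadrature oracle for :func:`uncrowded_letter_count`.

    Numerically integrates ``2*pi*phi*density(phi)`` from ``inner_radius`` to
    ``phi_max`` with ``scipy.integrate.quad``.  The angular integral is exact
    (the density is isotropic in polar angle), so only the radial dimension
    is quadrature.  Serves as the independent check on the closed form.

    ``phi0 = 0`` is tolerated only with a strictly positive ``inner_radius``
    (the foveal singularity must be excluded explicitly).
    """
    if params.phi0 == 0 and inner_radius <= 0:
        raise ValueError(
            "with phi0 = 0 the integrand is singular at phi = 0; "
            "supply a positive inner_radius to exclude the fovea"
        )
    if inner_radius < 0 or inner_radius >= field.phi_max:
        raise ValueError("inner_radius must lie in [0, phi_max)")

    def integrand(phi: float) -> float:
        return 2.0 * math.pi * phi * letter_density(params, phi)

    value, abserr = integrate.quad(
        integrand, inner_radius, field.phi_max, epsrel=rel_tol, epsabs=0.0, limit=200
    )
    if value > 0 and abserr / value > max(1e-6, 10 * rel_tol):
        raise RuntimeError(
            f"quadrature did not converge: value={value:.6g}, "
            f"estimated error={abserr:.2g}"
        )
    return value


def lambda_sensitivity(
    params: BoumaLawParams,
    field: VisualFieldSpec = VisualFieldSpec(),
    phi0_values: Sequence[float] = (),
    a_values: Sequence[float] = (),
    phi_max_values: Sequence[float] = (),
) -> pd.DataFrame:
    """Sensitivity of the letter count to the assumed field constants.

    For each alternative value of ``phi0``, ``a`` or ``phi_max`` (at fixed
    Bouma factor), reports the multiplier applied to lambda and the implied
    multiplier on the cortical crowding distance ``c`` from a conservation
    fit with areas held fixed (``k`` scales with lambda, and ``c = k**-0.5``,
    so the ``c`` multiplier is the inverse square root of the lambda
    multiplier).

    Returns a DataFrame with columns
    ``parameter, baseline, value, lambda_multiplier, c_multiplier``.
    """
    lam0 = uncrowded_letter_count(params, field)
    rows = []

    def add(name: str, baseline: float, value: float, lam_new: float) -> None:
        mult = lam_new / lam0
        rows.append(
            {
                "parameter": name,
                "baseline": baseline,
                "value": value,
                "lambda_multiplier": mult,
                "c_multiplier": mult ** -0.5,
            }
        )

    for phi0 in phi0_values:
        lam = uncrowded_letter_count(replace(params, phi0=phi0), field)
        add("phi0", params.phi0, phi0, lam)
    for a in a_values:
        lam = uncrowded_letter_count(replace(params, a=a), field)
        add("a", params.a, a, lam)
    for phi_max in phi_max_values:
        lam = uncrowded_letter_count(params, VisualFieldSpec(phi_max))
        add("phi_max", field.phi_max, phi_max, lam)
    return pd.DataFrame(
        rows, columns=["parameter", "baseline", "value", "lambda_multiplier", "c_multiplier"]
    )


def letter_layout(
    params: BoumaLawParams,
    field: VisualFieldSpec = VisualFieldSpec(),
    theta_min: float = 0.0,
    theta_max: float = 2.0 * math.pi,
    phi_min: float = 0.0,
    phi_max: float | None = None,
) -> np.ndarray:
    """Discrete letter positions packed at threshold spacing in a sector.

    Visualization aid: places letters on concentric rings starting at the
    inner sector edge.  Consecutive ring radii differ by the radial crowding
    distance evaluated midway between them (for the linear Bouma law the
    implicit midpoint step has a closed form); within a ring, letters are
    spaced by the local tangential crowding distance, flooring the per-ring
    count.  Over the full field the total count approximates the continuous
    letter count lambda, up to discretization.

    Returns an ``(n, 2)`` array of ``(eccentricity deg, polar angle rad)``.
    """
    if phi_max is None:
        phi_max = field.phi_max
    if not (0 <= phi_min <= phi_max <= field.phi_max):
        raise ValueError("sector eccentricity interval must lie within the field")
    width = theta_max - theta_min
    if width <= 0 or phi_min == phi_max:
        return np.empty((0, 2))
    width = min(width, 2.0 * math.pi)

    b, phi0 = params.b, params.phi0
    positions: list[tuple[float, float]] = []
    phi = phi_min
    while phi <= phi_max:
        if phi > 0:
            st = tangential_crowding_distance(params, phi)
            n_letters = int(math.floor(width * phi / st))
            if n_letters > 0:
                thetas = theta_min + (np.arange(n_letters) + 0.5) * (width / n_letters)
                positions.extend((phi, float(t)) for t in thetas)
        # implicit midpoint step: phi' - phi = b*((phi + phi')/2 + phi0)
        phi = (phi * (1 + b / 2) + b * phi0) / (1 - b / 2) if b < 2 else phi + \
            radial_crowding_distance(params, phi)
        if phi == phi_min:  # degenerate (b == 0 cannot happen; guard stalls)
            break
    return np.array(positions) if positions else np.empty((0, 2))
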