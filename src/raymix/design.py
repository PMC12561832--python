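"""Experimental design: geometric dilution series and fixed-ratio mixture rays.

A concentration-response experiment spans the window between a maximum-effect
concentration ``C_H`` (inhibition >= ~98%) and a minimum-effect concentration
``C_L`` (inhibition <= ~1%) with geometrically spaced points, so the design is
uniform on the log-concentration axis where the sigmoid lives.

Binary mixtures are laid out as fixed-ratio *rays*: along a ray the mass
fractions ``(p_A, p_B)`` of the two components are constant and only the total
concentration varies.  The direct equipartition ray design (EquRay) places
``n`` rays so that ray ``k`` combines ``k`` toxic units of component A with
``n + 1 - k`` toxic units of component B, one toxic unit being that
component's own EC50.  An additional ray at a fixed environmental mass ratio
(e.g. As:Pb = 1:10) can be added alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

__all__ = [
    "DilutionSeries",
    "MixtureRay",
    "dilution_factor",
    "concentration_series",
    "equray_rays",
    "fixed_ratio_ray",
    "design_frame",
]


@dataclass(frozen=True)
class DilutionSeries:
    """A geometric concentration ladder from ``c_high`` down to ``c_low``.

    Concentrations are in µg/L throughout the package; ``factor`` is the
    constant consecutive ratio ``F = (c_low/c_high)^(1/(n_points-1))``.
    """

    c_high: float
    c_low: float
    n_points: int
    factor: float
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != self.n_points:
            raise InvalidDesignError("concentration count does not match n_points")
        if not np.isclose(c[0], self.c_high, rtol=1e-9) or not np.isclose(
            c[-1], self.c_low, rtol=1e-9
        ):
            raise InvalidDesignError("series endpoints must equal c_high and c_low")


@dataclass(frozen=True)
class MixtureRay:
    """A fixed-ratio binary mixture.

    ``fractions`` are the mass-concentration fractions ``(p_A, p_B)`` of the
    two components; they sum to 1 and stay constant along the ray.
    ``basis`` records how the ratio was derived: from EC50 multiples
    (EquRay) or from a stated environmental concentration ratio.
    """

    ray_id: str
    component_ids: tuple[str, str]
    fractions: tuple[float, float]
    basis: Literal["ec50_multiples", "fixed_ratio"]
    basis_detail: tuple[float, float] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        p_a, p_b = self.fractions
        if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
            raise InvalidDesignError("mixture fractions must lie strictly in (0, 1)")
        if abs(p_a + p_b - 1.0) > 1e-12:
            raise InvalidDesignError("mixture fractions must sum to 1")

    @property
    def p_a(self) -> float:
        return self.fractions[0]

    @property
    def p_b(self) -> float:
        return self.fractions[1]

    def partial_concentrations(self, total: float) -> tuple[float, float]:
        """Split a total concentration into the two component concentrations."""
        return total * self.fractions[0], total * self.fractions[1]


def dilution_factor(c_high: float, c_low: float, n_points: int) -> float:
    """Constant dilution factor of a geometric series.

    ``F = (c_low / c_high) ** (1 / (n_points - 1))``, so that compounding F
    over ``n_points - 1`` steps maps ``c_high`` onto ``c_low``.
    """
    if not (0.0 < c_low <= c_high):
        raise InvalidDesignError(
            f"need 0 < c_low <= c_high, got c_low={c_low!r}, c_high={c_high!r}"
        )
    if n_points < 2:
        raise InvalidDesignError(f"need at least 2 points, got {n_points}")
    return float((c_low / c_high) ** (1.0 / (n_points - 1)))


def concentration_series(c_high: float, c_low: float, n_points: int) -> DilutionSeries:
    """Geometric ladder ``C_k = C_H * F**(k-1)`` for ``k = 1..n_points``.

    Descending order; ``C_1 = c_high`` and ``C_n = c_low`` exactly (the last
    point is pinned to ``c_low`` to suppress accumulated rounding).
    """
    if n_points < 3:
        raise InvalidDesignError(f"a dilution series needs >= 3 points, got {n_points}")
    f = dilution_factor(c_high, c_low, n_points)
    conc = c_high * f ** np.arange(n_points, dtype=float)
    conc[0] = c_high
    conc[-1] = c_low
    return DilutionSeries(
        c_high=float(c_high),
        c_low=float(c_low),
        n_points=int(n_points),
        factor=f,
        concentrations=tuple(float(x) for x in conc),
    )


def equray_rays(
    ec50_a: float,
    ec50_b: float,
    n_rays: int = 5,
    component_ids: tuple[str, str] = ("A", "B"),
) -> list[MixtureRay]:
    """Equipartition rays between two single-compound EC50s.

    Ray ``k`` (k = 1..n_rays) mixes ``k`` toxic units of A with
    ``n_rays + 1 - k`` toxic units of B (one toxic unit = that component's
    EC50 in mass concentration), giving mass fraction

        p_A(k) = k*EC50_A / (k*EC50_A + (n_rays + 1 - k)*EC50_B)

    Rays come back ordered by increasing ``p_A`` and labelled R1..Rn.  The
    fractions are invariant to rescaling both EC50s by a common factor, so
    the concentration unit used for the EC50s cannot leak into the design.
    """
    if ec50_a <= 0 or ec50_b <= 0:
        raise InvalidDesignError("EC50s must be positive to build EquRay rays")
    if n_rays < 1:
        raise InvalidDesignError("need at least one ray")
    rays = []
    for k in range(1, n_rays + 1):
        units_a, units_b = float(k), float(n_rays + 1 - k)
        p_a = k * ec50_a / (k * ec50_a + units_b * ec50_b)
        rays.append(
            MixtureRay(
                ray_id=f"R{k}",
                component_ids=component_ids,
                fractions=(float(p_a), float(1.0 - p_a)),
                basis="ec50_multiples",
                basis_detail=(units_a, units_b),
            )
        )
    return rays


def fixed_ratio_ray(
    ratio_a: float,
    ratio_b: float,
    ray_id: str = "Rf",
    component_ids: tuple[str, str] = ("A", "B"),
) -> MixtureRay:
    """Ray at a stated mass-concentration ratio, e.g. 1:10 for As:Pb."""
    if ratio_a <= 0 or ratio_b <= 0:
        raise InvalidDesignError(
            "both ratio terms must be positive; a zero term is a single compound, "
            "not a mixture ray"
        )
    p_a = ratio_a / (ratio_a + ratio_b)
    return MixtureRay(
        ray_id=ray_id,
        component_ids=component_ids,
        fractions=(float(p_a), float(1.0 - p_a)),
        basis="fixed_ratio",
        basis_detail=(float(ratio_a), float(ratio_b)),
    )


def design_frame(
    rays: Sequence[MixtureRay], series: DilutionSeries
) -> pd.DataFrame:
    """Tabulate a full ray design as a flat table.

    Columns: ray_id, point_index, total_conc_ugL, conc_A_ugL, conc_B_ugL, p_A.
    """
    rows = []
    for ray in rays:
        for i, total in enumerate(series.concentrations, start=1):
            ca, cb = ray.partial_concentrations(total)
            rows.append(
                {
                    "ray_id": ray.ray_id,
                    "point_index": i,
                    "total_conc_ugL": total,
                    "conc_A_ugL": ca,
                    "conc_B_ugL": cb,
                    "p_A": ray.p_a,
                }
            )
    return pd.DataFrame(rows)
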