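"""Mixture reference models (CA, IA) and interaction classification.

Concentration Addition (CA, Loewe additivity) treats the components as
dilutions of one another: the total concentration producing effect x is the
fraction-weighted harmonic combination of the single-compound ECx values,

    EC_x,mix = [ sum_i p_i / EC_x,i ]^-1 .

Independent Action (IA, Bliss independence) treats the components as acting
on independent targets, so at a total concentration c the predicted effect
is the probabilistic union of the component effects at their partial
concentrations,

    E(c) = 1 - prod_i (1 - f_i(p_i * c)) .

Observed mixture points are compared against each reference model through
their observation-based confidence intervals (OCIs): a prediction inside
the OCI is consistent with the reference (additive); observed effect above
the prediction band is stronger-than-predicted toxicity (synergism), below
it antagonism.  Equivalently, on the effect axis: prediction below OCI_lo
-> synergistic, prediction above OCI_hi -> antagonistic.  A configuration
switch flips the orientation for users who read the rule on the
concentration axis instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .design import MixtureRay
from .effects import EffectTable
from .fitting import ConfidenceBands, FittedCRC, ecx

__all__ = [
    "LABELS",
    "PointAssessment",
    "MixturePrediction",
    "RaySummary",
    "InteractionAssessment",
    "ca_ecx",
    "ca_effect",
    "ia_effect",
    "mixture_prediction",
    "classify_points",
    "summarize_ray",
    "assess_ray",
]

LABELS = ("additive", "synergistic", "antagonistic")
Label = Literal["additive", "synergistic", "antagonistic"]
Reference = Literal["CA", "IA"]

# effect window in which a sigmoid discriminates between hypotheses
DEFAULT_EFFECT_WINDOW = (0.2, 0.8)
# low / medium / high total-concentration band edges, µg/L
DEFAULT_REGION_EDGES = (1e3, 2e4)
_X_EPS = 1e-9


def ca_ecx(ray: MixtureRay, crcs: Sequence[FittedCRC], x: float) -> float:
    """CA-predicted total concentration (µg/L) giving effect ``x``."""
    if not (0.0 < x < 1.0):
        raise ValueError(f"effect level must be in (0, 1), got {x}")
    denom = sum(p / ecx(crc, x) for p, crc in zip(ray.fractions, crcs))
    return float(1.0 / denom)


def ca_effect(
    ray: MixtureRay,
    crcs: Sequence[FittedCRC],
    total_conc: float,
    xtol: float = 1e-10,
) -> float:
    """CA curve read on the effect axis, by bisection on the effect level.

    ``ca_ecx`` is strictly increasing in x (each component ECx is), so the
    root is unique.  Concentrations outside the representable effect range
    clamp to the window edges (effects within 1e-9 of 0 or 1).
    """
    if total_conc <= 0:
        raise ValueError("total concentration must be positive")
    lo, hi = _X_EPS, 1.0 - _X_EPS
    if total_conc <= ca_ecx(ray, crcs, lo):
        return lo
    if total_conc >= ca_ecx(ray, crcs, hi):
        return hi
    return float(
        optimize.brentq(
            lambda x: np.log(ca_ecx(ray, crcs, x)) - np.log(total_conc),
            lo,
            hi,
            xtol=xtol,
        )
    )


def ia_effect(
    ray: MixtureRay, crcs: Sequence[FittedCRC], total_conc: float
) -> float:
    """IA-predicted effect at a total concentration (µg/L)."""
    if total_conc <= 0:
        raise ValueError("total concentration must be positive")
    survive = 1.0
    for p, crc in zip(ray.fractions, crcs):
        survive *= 1.0 - crc.effect_at(p * total_conc)
    return float(1.0 - survive)


@dataclass
class MixturePrediction:
    """Reference-model prediction curves for one mixture ray."""

    ray: MixtureRay
    component_crcs: tuple[FittedCRC, FittedCRC]
    effect_grid: np.ndarray
    ca_conc: np.ndarray  # CA: EC_x,mix (µg/L) per effect-grid point
    conc_grid: np.ndarray
    ia_curve: np.ndarray  # IA: effect per conc-grid point

    def ca_effect_at(self, total_conc: float) -> float:
        return ca_effect(self.ray, self.component_crcs, total_conc)

    def ia_effect_at(self, total_conc: float) -> float:
        return ia_effect(self.ray, self.component_crcs, total_conc)


def mixture_prediction(
    ray: MixtureRay,
    crcs: Sequence[FittedCRC],
    conc_grid: np.ndarray | None = None,
    effect_grid: np.ndarray | None = None,
) -> MixturePrediction:
    """Tabulate CA and IA curves for a ray from its component fits."""
    crcs = tuple(crcs)
    if effect_grid is None:
        effect_grid = np.linspace(0.01, 0.99, 99)
    ca_conc = np.array([ca_ecx(ray, crcs, x) for x in effect_grid])
    if conc_grid is None:
        conc_grid = np.logspace(
            np.log10(ca_conc.min()), np.log10(ca_conc.max()), 200
        )
    ia_curve = np.array([ia_effect(ray, crcs, c) for c in conc_grid])
    return MixturePrediction(
        ray=ray,
        component_crcs=crcs,
        effect_grid=np.asarray(effect_grid),
        ca_conc=ca_conc,
        conc_grid=np.asarray(conc_grid),
        ia_curve=ia_curve,
    )


@dataclass(frozen=True)
class PointAssessment:
    """Interaction verdict at one tested total concentration."""

    total_conc: float
    observed_mean: float
    oci_low: float
    oci_high: float
    predicted: float
    label: Label


def classify_points(
    table: EffectTable,
    bands: ConfidenceBands,
    prediction: MixturePrediction,
    reference: Reference,
    orientation: Literal["effect_axis", "concentration_axis"] = "effect_axis",
) -> list[PointAssessment]:
    """Label each tested concentration against one reference model.

    At a tested total concentration c the reference prediction E_ref(c)
    (CA read on the effect axis by numerical inversion; IA directly) is
    compared with the 95% OCI of the observed mean effect:

    - inside the interval            -> additive
    - below it (observed stronger)   -> synergistic
    - above it (observed weaker)     -> antagonistic

    ``orientation="concentration_axis"`` swaps the synergistic and
    antagonistic assignments, for reading the rule on the dose axis.
    Points without an OCI (single replicate) are skipped with a warning.
    """
    oci_by_conc = {
        float(c): (float(lo), float(hi))
        for c, lo, hi in zip(bands.oci_conc, bands.oci_low, bands.oci_high)
    }
    points: list[PointAssessment] = []
    for c, mean in zip(table.conc, table.mean_effect):
        key = float(c)
        if key not in oci_by_conc:
            warnings.warn(f"no OCI at concentration {c:g} µg/L: point skipped")
            continue
        lo, hi = oci_by_conc[key]
        if reference == "CA":
            pred = prediction.ca_effect_at(key)
        elif reference == "IA":
            pred = prediction.ia_effect_at(key)
        else:
            raise ValueError(f"unknown reference model {reference!r}")
        if lo <= pred <= hi:
            label: Label = "additive"
        elif pred < lo:
            label = "synergistic"
        else:
            label = "antagonistic"
        if orientation == "concentration_axis" and label != "additive":
            label = "antagonistic" if label == "synergistic" else "synergistic"
        points.append(
            PointAssessment(
                total_conc=key,
                observed_mean=float(mean),
                oci_low=lo,
                oci_high=hi,
                predicted=float(pred),
                label=label,
            )
        )
    return points


@dataclass
class RaySummary:
    """Ray-level interaction label plus a per-concentration-region summary."""

    label: Label
    region_labels: dict[str, Label | None]
    n_points_in_window: int


def _majority(labels: Sequence[Label]) -> Label:
    """Majority label; any tie for the top count is resolved as additive."""
    counts = {lab: 0 for lab in LABELS}
    for lab in labels:
        counts[lab] += 1
    top = max(counts.values())
    winners = [lab for lab, n in counts.items() if n == top]
    return winners[0] if len(winners) == 1 else "additive"


def summarize_ray(
    points: Sequence[PointAssessment],
    effects: Sequence[float] | None = None,
    effect_window: tuple[float, float] = DEFAULT_EFFECT_WINDOW,
    region_edges: tuple[float, float] = DEFAULT_REGION_EDGES,
) -> RaySummary:
    """Aggregate point labels into a ray verdict and a region breakdown.

    The ray label is the majority label among points whose (fitted, if
    supplied, else observed) effect lies in the discriminating window
    [0.2, 0.8]; ties resolve conservatively to additive.  If no point falls
    in the window, all points vote, with a warning.  Regions are the fixed
    low (< region_edges[0]), medium, and high (> region_edges[1]) total-
    concentration bands in µg/L.
    """
    if not points:
        raise ValueError("cannot summarize a ray with no labeled points")
    if effects is None:
        effects = [p.observed_mean for p in points]
    if len(effects) != len(points):
        raise ValueError("effects and points must align")

    lo_w, hi_w = effect_window
    in_window = [p for p, e in zip(points, effects) if lo_w <= e <= hi_w]
    if in_window:
        ray_label = _majority([p.label for p in in_window])
    else:
        warnings.warn(
            "no points in the discriminating effect window: ray label uses all points"
        )
        ray_label = _majority([p.label for p in points])

    low_edge, high_edge = region_edges
    if not low_edge < high_edge:
        raise ValueError("region band edges must be strictly increasing")
    regions: dict[str, list[Label]] = {"low": [], "medium": [], "high": []}
    for p in points:
        if p.total_conc < low_edge:
            regions["low"].append(p.label)
        elif p.total_conc <= high_edge:
            regions["medium"].append(p.label)
        else:
            regions["high"].append(p.label)
    region_labels = {
        name: (_majority(labs) if labs else None) for name, labs in regions.items()
    }
    return RaySummary(
        label=ray_label,
        region_labels=region_labels,
        n_points_in_window=len(in_window),
    )


@dataclass
class InteractionAssessment:
    """Full CA + IA assessment of one mixture ray."""

    ray: MixtureRay
    prediction: MixturePrediction
    points: dict[Reference, list[PointAssessment]] = field(default_factory=dict)
    summaries: dict[Reference, RaySummary] = field(default_factory=dict)


def assess_ray(
    table: EffectTable,
    bands: ConfidenceBands,
    ray: MixtureRay,
    crcs: Sequence[FittedCRC],
    mixture_fit: FittedCRC | None = None,
    orientation: Literal["effect_axis", "concentration_axis"] = "effect_axis",
    effect_window: tuple[float, float] = DEFAULT_EFFECT_WINDOW,
    region_edges: tuple[float, float] = DEFAULT_REGION_EDGES,
) -> InteractionAssessment:
    """Classify one ray against both reference models and summarise.

    When the ray's own fitted CRC is available its fitted effects locate
    the discriminating window; otherwise observed means are used.
    """
    prediction = mixture_prediction(ray, crcs)
    assessment = InteractionAssessment(ray=ray, prediction=prediction)
    for reference in ("CA", "IA"):
        pts = classify_points(table, bands, prediction, reference, orientation)
        effects = None
        if mixture_fit is not None and pts:
            effects = [mixture_fit.effect_at(p.total_conc) for p in pts]
        assessment.points[reference] = pts
        assessment.summaries[reference] = summarize_ray(
            pts, effects=effects, effect_window=effect_window, region_edges=region_edges
        )
    return assessment
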