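"""Synthetic plate-data generator.

Emulates the algal growth-inhibition assay the analysis expects: a 12-point
geometric concentration ladder per treatment, 3 replicates per point, blank
controls, and a 96 h OD680 endpoint.  The instrument model is

    control OD    ~ Normal(control_od, sigma_od), truncated at 0
    treatment OD  = control_od * (1 - E_true(c)) + background + Normal(0, sigma_od)

i.e. measurement noise lives on the absorbance scale (the measured
quantity), not the effect scale; an effect-scale noise option exists for
quick tests.  ``background`` models un-subtracted blank absorbance, so both
blank-subtraction conventions are testable.

Mixture truths come from the reference models themselves: ``CA_truth``
inverts the Loewe/CA combination of the component curves, ``IA_truth``
composes them by Bliss independence.  A dose-modification factor ``kappa``
rescales the effective total concentration (E_true evaluated at
``kappa * c``) before either truth: kappa > 1 makes the mixture stronger
than the reference predicts (synergism), kappa < 1 weaker (antagonism).
``dose_modifier`` mode is the CA truth with kappa applied; it is a test
harness device, not a toxicological mechanism.

Defaults mirror the study design this generator stands in for: 12 points x
3 replicates, control OD 0.70, sigma_od 0.02 — the noise level that puts
fit RMSEs in the low-0.02 range typical of this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .design import DilutionSeries, MixtureRay, concentration_series
from .effects import PLATE_COLUMNS, PlateReading
from .errors import ConfigurationError
from .fitting import FittedCRC
from .interaction import ca_effect, ia_effect

__all__ = [
    "NoiseModel",
    "SimulationScenario",
    "simulate_single",
    "simulate_ray",
    "simulate_scenario",
    "write_fixture",
    "mixture_truth_effect",
]

InteractionMode = Literal["CA_truth", "IA_truth", "dose_modifier"]

DEFAULT_CONTROL_OD = 0.70
DEFAULT_SIGMA_OD = 0.02
DEFAULT_REPLICATES = 3
DEFAULT_N_CONTROLS = 3


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level noise: OD-scale by default, effect-scale optionally."""

    sigma_od: float = DEFAULT_SIGMA_OD
    sigma_effect: float = 0.0
    control_od: float = DEFAULT_CONTROL_OD
    background_od: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_od < 0 or self.sigma_effect < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.control_od <= 0:
            raise ConfigurationError("control OD must be positive")
        if self.background_od < 0:
            raise ConfigurationError("background OD must be >= 0")


@dataclass
class SimulationScenario:
    """A full study: single-compound truths, design, rays, noise, seed.

    ``truths`` maps component id -> its true concentration-response curve.
    ``designs`` maps series id (component or ray) -> (c_high, c_low) window;
    all series share ``n_points`` and ``replicates``.
    """

    truths: dict[str, FittedCRC]
    designs: dict[str, tuple[float, float]]
    rays: list[MixtureRay] = field(default_factory=list)
    n_points: int = 12
    replicates: int = DEFAULT_REPLICATES
    noise: NoiseModel = field(default_factory=NoiseModel)
    interaction_mode: InteractionMode = "CA_truth"
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if self.n_points < 3:
            raise ConfigurationError("need at least three concentration points")
        for ray in self.rays:
            for comp in ray.component_ids:
                if comp not in self.truths:
                    raise ConfigurationError(
                        f"ray {ray.ray_id!r} references unknown component {comp!r}"
                    )
            if ray.ray_id not in self.designs:
                raise ConfigurationError(f"no design window for ray {ray.ray_id!r}")

    def series_for(self, series_id: str) -> DilutionSeries:
        c_high, c_low = self.designs[series_id]
        return concentration_series(c_high, c_low, self.n_points)


def mixture_truth_effect(
    ray: MixtureRay,
    truths: Sequence[FittedCRC],
    total_conc: float,
    mode: InteractionMode = "CA_truth",
    kappa: float = 1.0,
) -> float:
    """True mixture effect at a total concentration under a generative mode."""
    c_eff = kappa * total_conc
    if mode in ("CA_truth", "dose_modifier"):
        return ca_effect(ray, truths, c_eff)
    if mode == "IA_truth":
        return ia_effect(ray, truths, c_eff)
    raise ConfigurationError(f"unknown interaction mode {mode!r}")


def _noisy_readings(
    series_id: str,
    ray_id: str,
    conc_a: np.ndarray,
    conc_b: np.ndarray,
    e_true: np.ndarray,
    replicates: int,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> list[PlateReading]:
    readings = []
    for ca, cb, e in zip(conc_a, conc_b, e_true):
        for rep in range(1, replicates + 1):
            e_rep = e
            if noise.sigma_effect > 0:
                e_rep = e_rep + rng.normal(0.0, noise.sigma_effect)
            od = noise.control_od * (1.0 - e_rep) + noise.background_od
            if noise.sigma_od > 0:
                od += rng.normal(0.0, noise.sigma_od)
            readings.append(
                PlateReading(
                    treatment_id=series_id,
                    ray_id=ray_id,
                    conc_a=float(ca),
                    conc_b=float(cb),
                    replicate=rep,
                    od680=max(0.0, float(od)),
                    is_control=False,
                )
            )
    return readings


def _control_readings(
    n_controls: int, noise: NoiseModel, rng: np.random.Generator
) -> list[PlateReading]:
    readings = []
    for rep in range(1, n_controls + 1):
        od = noise.control_od + noise.background_od
        if noise.sigma_od > 0:
            od += rng.normal(0.0, noise.sigma_od)
        readings.append(
            PlateReading(
                treatment_id="control",
                ray_id="single",
                conc_a=0.0,
                conc_b=0.0,
                replicate=rep,
                od680=max(0.0, float(od)),
                is_control=True,
            )
        )
    return readings


def simulate_single(
    component_id: str,
    truth: FittedCRC,
    series: DilutionSeries,
    replicates: int = DEFAULT_REPLICATES,
    noise: NoiseModel | None = None,
    n_controls: int = DEFAULT_N_CONTROLS,
    rng: np.random.Generator | int | None = None,
    include_controls: bool = True,
    column: Literal["A", "B"] = "A",
) -> list[PlateReading]:
    """Simulate a single-compound treatment series plus blank controls.

    ``column`` selects which concentration column of the plate CSV the
    compound occupies (the other stays zero).  With ``sigma_od =
    sigma_effect = 0`` and zero background the recovered effects equal the
    truth exactly.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng)
    noise = noise or NoiseModel()
    conc = np.asarray(series.concentrations)
    e_true = np.array([truth.effect_at(c) for c in conc])
    zeros = np.zeros_like(conc)
    conc_a, conc_b = (conc, zeros) if column == "A" else (zeros, conc)
    readings = []
    if include_controls:
        readings += _control_readings(n_controls, noise, rng)
    readings += _noisy_readings(
        component_id, "single", conc_a, conc_b, e_true, replicates, noise, rng
    )
    return readings


def simulate_ray(
    ray: MixtureRay,
    truths: Sequence[FittedCRC],
    series: DilutionSeries,
    mode: InteractionMode = "CA_truth",
    kappa: float = 1.0,
    replicates: int = DEFAULT_REPLICATES,
    noise: NoiseModel | None = None,
    n_controls: int = DEFAULT_N_CONTROLS,
    rng: np.random.Generator | int | None = None,
    include_controls: bool = True,
) -> list[PlateReading]:
    """Simulate one mixture ray: totals from the series, split by the ray.

    ``truths`` are the component concentration-response curves, ordered as
    ``ray.component_ids``.
    """
    if kappa <= 0:
        raise ConfigurationError("kappa must be positive")
    rng = np.random.default_rng(rng)
    noise = noise or NoiseModel()
    totals = np.asarray(series.concentrations)
    conc_a = totals * ray.p_a
    conc_b = totals * ray.p_b
    e_true = np.array(
        [mixture_truth_effect(ray, truths, c, mode=mode, kappa=kappa) for c in totals]
    )
    readings = []
    if include_controls:
        readings += _control_readings(n_controls, noise, rng)
    readings += _noisy_readings(
        ray.ray_id, ray.ray_id, conc_a, conc_b, e_true, replicates, noise, rng
    )
    return readings


def simulate_scenario(scenario: SimulationScenario) -> list[PlateReading]:
    """Simulate a full study (all singles, all rays, one shared control set).

    One control block is generated for the whole run, matching a design in
    which every series is read against the same blank controls.  The PCG64
    generator seeded by ``scenario.seed`` makes output reproducible across
    platforms.
    """
    rng = np.random.default_rng(scenario.seed)
    noise = scenario.noise
    readings = _control_readings(DEFAULT_N_CONTROLS, noise, rng)
    for idx, (comp_id, truth) in enumerate(scenario.truths.items()):
        if comp_id not in scenario.designs:
            continue
        readings += simulate_single(
            comp_id,
            truth,
            scenario.series_for(comp_id),
            replicates=scenario.replicates,
            noise=noise,
            rng=rng,
            include_controls=False,
            column="A" if idx == 0 else "B",
        )
    for ray in scenario.rays:
        truths = [scenario.truths[c] for c in ray.component_ids]
        readings += simulate_ray(
            ray,
            truths,
            scenario.series_for(ray.ray_id),
            mode=scenario.interaction_mode,
            kappa=scenario.kappa,
            replicates=scenario.replicates,
            noise=noise,
            rng=rng,
            include_controls=False,
        )
    return readings


def write_fixture(readings: Iterable[PlateReading], path: str | Path) -> Path:
    """Write readings in the plate CSV dialect (round-trips with read_plate)."""
    path = Path(path)
    rows = [
        {
            "treatment_id": r.treatment_id,
            "ray_id": r.ray_id,
            "conc_A_ugL": repr(r.conc_a),
            "conc_B_ugL": repr(r.conc_b),
            "replicate": r.replicate,
            "od680": repr(r.od680),
            "is_control": int(r.is_control),
        }
        for r in readings
    ]
    df = pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
    df.to_csv(path, index=False)
    return path
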