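"""End-to-end pipeline: design/ingest -> effects -> fits -> CA/IA -> reports.

The run configuration (YAML) points either at a plate CSV to ingest or at a
simulation scenario to generate, plus the analysis knobs: which sigmoids to
fit, the confidence level, the NOEC procedure, the classification
orientation and the concentration-region band edges.  One call to
:func:`run_pipeline` produces

* ``fits.csv``      — per-series fitted parameters, goodness of fit, EC50,
  NOEC and LOEC, with single-compound rows in the mirrored µg/L convention
  and mixture rows in the verbatim g/L convention of published tables;
* ``assessment.json`` — per-ray CA/IA point labels, ray verdicts and
  low/medium/high region summaries;
* ``run_log.json``  — versions, seed, resolved configuration and the
  parameter convention used for every fit, so any number in the reports is
  reproducible from this file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import MixtureRay, equray_rays, fixed_ratio_ray
from .effects import EffectTable, build_effect_table, read_plate
from .errors import ComputationError, ConfigurationError
from .fitting import (
    MODELS,
    ConfidenceBands,
    FittedCRC,
    confidence_bands,
    ecx,
    fit_crc,
    noec_loec,
    select_best,
)
from .interaction import (
    DEFAULT_EFFECT_WINDOW,
    DEFAULT_REGION_EDGES,
    InteractionAssessment,
    assess_ray,
)
from .simulate import (
    NoiseModel,
    SimulationScenario,
    simulate_scenario,
    write_fixture,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "load_run_config",
    "scenario_from_dict",
    "run_pipeline",
    "report_tables",
    "LABEL_VOCABULARY",
]

# published-table vocabulary for the interaction labels
LABEL_VOCABULARY = {
    "additive": "Additivity",
    "synergistic": "Synergism",
    "antagonistic": "Antagonism",
}


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_run_config`` for the YAML)."""

    output_dir: Path
    input_path: Path | None = None
    scenario: SimulationScenario | None = None
    models: tuple[str, ...] = MODELS
    confidence_level: float = 0.95
    noec_method: Literal["dunnett", "threshold"] = "dunnett"
    orientation: Literal["effect_axis", "concentration_axis"] = "effect_axis"
    region_edges: tuple[float, float] = DEFAULT_REGION_EDGES
    effect_window: tuple[float, float] = DEFAULT_EFFECT_WINDOW
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigurationError(
                "exactly one of input_path and scenario must be given"
            )
        if not (0.0 < self.confidence_level < 1.0):
            raise ConfigurationError(
                f"confidence level must be in (0, 1), got {self.confidence_level}"
            )
        if not self.region_edges[0] < self.region_edges[1]:
            raise ConfigurationError("region band edges must be strictly increasing")
        if not 0.0 <= self.effect_window[0] < self.effect_window[1] <= 1.0:
            raise ConfigurationError("effect window must be an interval within [0, 1]")
        bad = [m for m in self.models if m not in MODELS]
        if bad or not self.models:
            raise ConfigurationError(f"models must be a nonempty subset of {MODELS}")
        if self.noec_method not in ("dunnett", "threshold"):
            raise ConfigurationError(f"unknown NOEC method {self.noec_method!r}")
        if self.orientation not in ("effect_axis", "concentration_axis"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")


def _truth_from_dict(d: dict[str, Any]) -> FittedCRC:
    return FittedCRC(
        model=d.get("model", "Logit"),
        alpha=float(d["alpha"]),
        beta=float(d["beta"]),
        conc_scale=d.get("conc_scale", "ugL"),
        alpha_sign=int(d.get("alpha_sign", 1)),
    )


def _auto_window(
    truth_ecx, e_low: float = 0.01, e_high: float = 0.98
) -> tuple[float, float]:
    """Design window [C_H, C_L] bracketing the minimum/maximum effect levels."""
    return truth_ecx(e_high), truth_ecx(e_low)


def scenario_from_dict(d: dict[str, Any]) -> SimulationScenario:
    """Build a :class:`SimulationScenario` from a parsed YAML mapping.

    Component and ray design windows default to the concentrations at which
    the (CA-combined, for rays) truth reaches 1% and 98% inhibition — the
    same minimum/maximum-effect criterion a range-finding experiment uses.
    """
    try:
        comp_specs: dict[str, dict] = d["components"]
    except KeyError as exc:
        raise ConfigurationError("scenario must define 'components'") from exc
    if len(comp_specs) != 2:
        raise ConfigurationError("exactly two components are supported")
    truths = {cid: _truth_from_dict(spec) for cid, spec in comp_specs.items()}
    comp_ids = tuple(comp_specs)

    designs: dict[str, tuple[float, float]] = {}
    for cid, spec in comp_specs.items():
        if "window" in spec:
            c_high, c_low = (float(v) for v in spec["window"])
        else:
            c_high, c_low = _auto_window(lambda x, c=cid: ecx(truths[c], x))
        designs[cid] = (c_high, c_low)

    rays: list[MixtureRay] = []
    ray_cfg = d.get("rays", {}) or {}
    n_equ = ray_cfg.get("equray", 0)
    if n_equ:
        ec50s = [ecx(truths[c], 0.5) for c in comp_ids]
        rays += equray_rays(ec50s[0], ec50s[1], n_rays=int(n_equ), component_ids=comp_ids)
    for spec in ray_cfg.get("fixed", []) or []:
        ra, rb = (float(v) for v in spec["ratio"])
        rays.append(
            fixed_ratio_ray(ra, rb, ray_id=spec.get("id", "Rf"), component_ids=comp_ids)
        )

    mode = d.get("interaction_mode", "CA_truth")
    kappa = float(d.get("kappa", 1.0))
    windows = ray_cfg.get("windows", {}) or {}
    for ray in rays:
        if ray.ray_id in windows:
            c_high, c_low = (float(v) for v in windows[ray.ray_id])
        else:
            from .interaction import ca_ecx

            truth_pair = [truths[c] for c in ray.component_ids]
            c_high, c_low = _auto_window(lambda x: ca_ecx(ray, truth_pair, x))
        designs[ray.ray_id] = (c_high, c_low)

    noise_cfg = d.get("noise", {}) or {}
    noise = NoiseModel(
        sigma_od=float(noise_cfg.get("sigma_od", NoiseModel.sigma_od)),
        sigma_effect=float(noise_cfg.get("sigma_effect", 0.0)),
        control_od=float(noise_cfg.get("control_od", NoiseModel.control_od)),
        background_od=float(noise_cfg.get("background_od", 0.0)),
    )
    return SimulationScenario(
        truths=truths,
        designs=designs,
        rays=rays,
        n_points=int(d.get("n_points", 12)),
        replicates=int(d.get("replicates", 3)),
        noise=noise,
        interaction_mode=mode,
        kappa=kappa,
        seed=int(d.get("seed", 0)),
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Top-level keys: ``input`` (plate CSV path) *or* ``scenario`` (inline
    simulation scenario mapping); optional ``models``, ``confidence_level``,
    ``noec_method``, ``orientation``, ``region_edges``, ``effect_window``,
    ``output_dir``, ``seed``, ``log_level``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = None
    if "scenario" in raw:
        scen_dict = dict(raw["scenario"])
        if "seed" in raw and "seed" not in scen_dict:
            scen_dict["seed"] = raw["seed"]
        scenario = scenario_from_dict(scen_dict)
    cfg = RunConfig(
        output_dir=Path(raw.get("output_dir", "raymix_out")),
        input_path=Path(raw["input"]) if "input" in raw else None,
        scenario=scenario,
        models=tuple(raw.get("models", MODELS)),
        confidence_level=float(raw.get("confidence_level", 0.95)),
        noec_method=raw.get("noec_method", "dunnett"),
        orientation=raw.get("orientation", "effect_axis"),
        region_edges=tuple(float(v) for v in raw.get("region_edges", DEFAULT_REGION_EDGES)),
        effect_window=tuple(
            float(v) for v in raw.get("effect_window", DEFAULT_EFFECT_WINDOW)
        ),
        seed=int(raw["seed"]) if "seed" in raw else None,
        log_level=str(raw.get("log_level", "INFO")),
    )
    cfg.validate()
    return cfg


@dataclass
class SeriesResult:
    """Everything computed for one treatment series."""

    series_id: str
    kind: Literal["single", "mixture"]
    table: EffectTable
    fits: list[FittedCRC]
    best: FittedCRC
    bands: ConfidenceBands
    ec50_ugl: float
    noec_ugl: float
    loec_ugl: float


@dataclass
class RunResult:
    """Output bundle of one pipeline run."""

    series: dict[str, SeriesResult]
    assessments: dict[str, InteractionAssessment]
    component_order: tuple[str, str]
    report_paths: dict[str, Path] = field(default_factory=dict)


def _classify_series(table: EffectTable) -> str:
    a = np.any(table.conc_a > 0)
    b = np.any(table.conc_b > 0)
    return "mixture" if (a and b) else "single"


def _ray_from_table(table: EffectTable, component_ids: tuple[str, str]) -> MixtureRay:
    """Recover the fixed mixture ratio of an ingested mixture series."""
    fracs = table.conc_a / table.conc
    p_a = float(fracs.mean())
    if np.ptp(fracs) > 1e-6:
        raise ComputationError(
            f"series {table.series_id!r} is not a fixed-ratio ray "
            f"(component-A fraction varies by {np.ptp(fracs):.3g})"
        )
    return MixtureRay(
        ray_id=table.series_id,
        component_ids=component_ids,
        fractions=(p_a, 1.0 - p_a),
        basis="fixed_ratio",
        basis_detail=(p_a, 1.0 - p_a),
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute design/ingest -> fit -> predict -> classify -> report.

    Deterministic (byte-identical reports) for a fixed configuration and
    seed.  Raises with the failing stage named.
    """
    config.validate()
    config.output_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: acquire readings -----------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        if config.seed is not None:
            scenario = SimulationScenario(
                truths=scenario.truths,
                designs=scenario.designs,
                rays=scenario.rays,
                n_points=scenario.n_points,
                replicates=scenario.replicates,
                noise=scenario.noise,
                interaction_mode=scenario.interaction_mode,
                kappa=scenario.kappa,
                seed=config.seed,
            )
        readings = simulate_scenario(scenario)
        write_fixture(readings, config.output_dir / "simulated_plate.csv")
    else:
        readings = read_plate(config.input_path)

    # --- stage: effects ---------------------------------------------------
    tables = build_effect_table(readings)

    # --- stage: fit -------------------------------------------------------
    series_results: dict[str, SeriesResult] = {}
    singles_a, singles_b = [], []
    for sid, table in sorted(tables.items()):
        kind = _classify_series(table)
        fits = []
        errors = []
        for model in config.models:
            try:
                fits.append(fit_crc(table, model))
            except ComputationError as exc:
                errors.append(f"{model}: {exc}")
        if not fits:
            raise ComputationError(
                f"fit stage failed for series {sid!r}: " + "; ".join(errors)
            )
        best = select_best(fits)
        bands = confidence_bands(best, table, level=config.confidence_level)
        noec, loec = noec_loec(table, method=config.noec_method)
        series_results[sid] = SeriesResult(
            series_id=sid,
            kind=kind,
            table=table,
            fits=fits,
            best=best,
            bands=bands,
            ec50_ugl=ecx(best, 0.5),
            noec_ugl=noec,
            loec_ugl=loec,
        )
        if kind == "single":
            (singles_a if np.any(table.conc_a > 0) else singles_b).append(sid)

    # --- stage: predict + classify ---------------------------------------
    assessments: dict[str, InteractionAssessment] = {}
    mixtures = [s for s in series_results.values() if s.kind == "mixture"]
    component_order: tuple[str, str] = ("A", "B")
    if mixtures:
        if len(singles_a) != 1 or len(singles_b) != 1:
            raise ComputationError(
                "classify stage needs exactly one single-compound series per "
                f"component; found A={singles_a}, B={singles_b}"
            )
        component_order = (singles_a[0], singles_b[0])
        crc_pair = (
            series_results[singles_a[0]].best,
            series_results[singles_b[0]].best,
        )
        for res in mixtures:
            ray = _ray_from_table(res.table, component_order)
            assessments[res.series_id] = assess_ray(
                res.table,
                res.bands,
                ray,
                crc_pair,
                mixture_fit=res.best,
                orientation=config.orientation,
                effect_window=config.effect_window,
                region_edges=config.region_edges,
            )

    result = RunResult(
        series=series_results,
        assessments=assessments,
        component_order=component_order,
    )
    result.report_paths = report_tables(result, config)
    return result


def _round(v: float, ndigits: int) -> float | None:
    if v is None or not np.isfinite(v):
        return None
    return round(float(v), ndigits)


def report_tables(result: RunResult, config: RunConfig) -> dict[str, Path]:
    """Write fits.csv, assessment.json and run_log.json to the output dir.

    Parameter rounding follows the published-table style: four decimals for
    location, slope, R2 and RMSE, two for EC50/NOEC/LOEC in µg/L.  Single-
    compound rows are expressed in the mirrored µg/L convention, mixture
    rows verbatim in g/L, and each row records its convention explicitly.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    conventions: dict[str, dict[str, str]] = {}
    for sid, res in sorted(result.series.items()):
        if res.kind == "single":
            crc = res.best.with_conc_scale("ugL")
            alpha_out, convention = -crc.alpha_verbatim, "mirrored_ugL"
        else:
            crc = res.best.with_conc_scale("gL")
            alpha_out, convention = crc.alpha_verbatim, "verbatim_gL"
        conventions[sid] = {"model": res.best.model, "parameter_convention": convention}
        rows.append(
            {
                "id": sid,
                "kind": res.kind,
                "function": res.best.model,
                "alpha": _round(alpha_out, 4),
                "beta": _round(crc.beta, 4),
                "r2": _round(res.best.r2_adj, 4),
                "rmse": _round(res.best.rmse, 4),
                "ec50_ugL": _round(res.ec50_ugl, 2),
                "noec_ugL": _round(res.noec_ugl, 2),
                "loec_ugL": _round(res.loec_ugl, 2),
                "convention": convention,
            }
        )
    fits_path = out / "fits.csv"
    pd.DataFrame(rows).to_csv(fits_path, index=False)

    assessment: list[dict[str, Any]] = []
    for sid, a in sorted(result.assessments.items()):
        entry: dict[str, Any] = {
            "ray_id": sid,
            "p_A": round(a.ray.p_a, 6),
            "ec50_mix_ugL": _round(result.series[sid].ec50_ugl, 2),
            "labels": {
                ref: LABEL_VOCABULARY[s.label] for ref, s in a.summaries.items()
            },
            "regions": {
                ref: {
                    band: (LABEL_VOCABULARY[lab] if lab else None)
                    for band, lab in s.region_labels.items()
                }
                for ref, s in a.summaries.items()
            },
            "points": {
                ref: [
                    {
                        "total_conc_ugL": _round(p.total_conc, 4),
                        "observed_mean": _round(p.observed_mean, 4),
                        "oci_low": _round(p.oci_low, 4),
                        "oci_high": _round(p.oci_high, 4),
                        "predicted": _round(p.predicted, 4),
                        "label": LABEL_VOCABULARY[p.label],
                    }
                    for p in pts
                ]
                for ref, pts in a.points.items()
            },
        }
        assessment.append(entry)
    assess_path = out / "assessment.json"
    with open(assess_path, "w", encoding="utf-8") as fh:
        json.dump(assessment, fh, indent=2, sort_keys=True)
        fh.write("\n")

    log = {
        "raymix_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed
        if config.seed is not None
        else (config.scenario.seed if config.scenario else None),
        "config": {
            "models": list(config.models),
            "confidence_level": config.confidence_level,
            "noec_method": config.noec_method,
            "orientation": config.orientation,
            "region_edges_ugL": list(config.region_edges),
            "effect_window": list(config.effect_window),
            "input": str(config.input_path) if config.input_path else "scenario",
        },
        "fit_conventions": conventions,
        "component_order": list(result.component_order),
    }
    log_path = out / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"fits": fits_path, "assessment": assess_path, "run_log": log_path}
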