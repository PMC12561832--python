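"""Plate readings and growth-inhibition effects.

The raw observable is optical density at 680 nm (OD680), the chlorophyll-a
absorption peak, measured after the 96 h exposure.  Growth inhibition at a
treatment is

    E = (I0 - Ii) / I0

where ``I0`` is the mean OD680 of the blank controls and ``Ii`` the OD680
of the treatment.  Effects are deliberately *not* clipped to [0, 1]: noise
or growth stimulation can push E slightly negative, and truncating before
curve fitting would bias the fit.  A negative mean effect triggers a
warning instead.

Input CSV dialect (UTF-8, "." decimal):

    treatment_id,ray_id,conc_A_ugL,conc_B_ugL,replicate,od680,is_control
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AmbiguityError, FormatError, InvalidControlError

__all__ = [
    "PLATE_COLUMNS",
    "PlateReading",
    "EffectTable",
    "read_plate",
    "inhibition",
    "build_effect_table",
]

PLATE_COLUMNS = (
    "treatment_id",
    "ray_id",
    "conc_A_ugL",
    "conc_B_ugL",
    "replicate",
    "od680",
    "is_control",
)

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no", ""}


@dataclass(frozen=True)
class PlateReading:
    """One well: a single OD680 measurement of one replicate."""

    treatment_id: str
    ray_id: str
    conc_a: float
    conc_b: float
    replicate: int
    od680: float
    is_control: bool

    @property
    def total_conc(self) -> float:
        return self.conc_a + self.conc_b


@dataclass
class EffectTable:
    """Per-concentration inhibition effects for one treatment series.

    Concentrations ascend; ``effects[j]`` holds the replicate-level effects
    at ``conc[j]``, all computed against the pooled control mean of the same
    run.  ``sem`` is NaN wherever only a single replicate exists.
    """

    series_id: str
    conc: np.ndarray
    conc_a: np.ndarray
    conc_b: np.ndarray
    effects: list[np.ndarray]
    mean_effect: np.ndarray
    sem: np.ndarray
    n_reps: np.ndarray
    control_effects: np.ndarray
    control_mean_od: float

    def __len__(self) -> int:
        return len(self.conc)


def read_plate(path: str | Path) -> list[PlateReading]:
    """Read and validate a plate CSV.

    Raises :class:`FormatError` (with offending line numbers) for missing
    columns, unparseable fields, negative OD, or a file with no control rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    readings: list[PlateReading] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            conc_a = float(row["conc_A_ugL"])
            conc_b = float(row["conc_B_ugL"])
            replicate = int(row["replicate"])
            od = float(row["od680"])
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
            continue
        flag = str(row["is_control"]).strip().lower()
        if flag in _TRUTHY:
            is_control = True
        elif flag in _FALSY:
            is_control = False
        else:
            problems.append(f"line {line}: unrecognised is_control value {flag!r}")
            continue
        if od < 0:
            problems.append(f"line {line}: negative od680 ({od})")
            continue
        if is_control and (conc_a != 0 or conc_b != 0):
            problems.append(f"line {line}: control row with nonzero concentration")
            continue
        readings.append(
            PlateReading(
                treatment_id=str(row["treatment_id"]),
                ray_id=str(row["ray_id"]),
                conc_a=conc_a,
                conc_b=conc_b,
                replicate=replicate,
                od680=od,
                is_control=is_control,
            )
        )
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))
    if not any(r.is_control for r in readings):
        raise FormatError(f"{path}: no control rows (is_control truthy) found")
    return readings


def inhibition(control_mean: float, treatment_mean: float) -> float:
    """Growth inhibition ``E = (I0 - Ii) / I0``.

    Negative values (growth stimulation relative to control) are returned
    as-is with a warning; clipping is left to presentation layers.
    """
    if control_mean <= 0:
        raise InvalidControlError(
            f"control mean OD must be positive, got {control_mean!r}"
        )
    e = (control_mean - treatment_mean) / control_mean
    if e < 0:
        warnings.warn(
            f"negative inhibition {e:.4f}: treatment OD exceeds control mean",
            stacklevel=2,
        )
    return float(e)


def _series_key(reading: PlateReading) -> str:
    if reading.ray_id and reading.ray_id != "single":
        return reading.ray_id
    return reading.treatment_id


def build_effect_table(
    readings: Iterable[PlateReading],
) -> dict[str, EffectTable]:
    """Convert raw readings to per-series effect tables.

    All treatment effects use the pooled control mean ``I0`` of the supplied
    readings.  Returns one :class:`EffectTable` per treatment series, keyed
    by ray id (or by treatment id for single-compound series).
    """
    readings = list(readings)
    controls = [r for r in readings if r.is_control]
    if not controls:
        raise InvalidControlError("at least one control replicate is required")
    control_ods = np.array([r.od680 for r in controls], dtype=float)
    i0 = float(control_ods.mean())
    if i0 <= 0:
        raise InvalidControlError(f"pooled control mean OD is non-positive ({i0})")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        control_effects = np.array([inhibition(i0, od) for od in control_ods])

    # series -> conc -> {replicate: effect}
    grouped: dict[str, dict[tuple[float, float], dict[int, float]]] = {}
    for r in readings:
        if r.is_control:
            continue
        key = _series_key(r)
        conc_key = (r.conc_a, r.conc_b)
        reps = grouped.setdefault(key, {}).setdefault(conc_key, {})
        if r.replicate in reps:
            raise AmbiguityError(
                f"series {key!r}: duplicate replicate {r.replicate} at "
                f"concentration {conc_key}"
            )
        reps[r.replicate] = (i0 - r.od680) / i0

    tables: dict[str, EffectTable] = {}
    for key, by_conc in grouped.items():
        conc_keys = sorted(by_conc, key=lambda ab: ab[0] + ab[1])
        totals = np.array([a + b for a, b in conc_keys])
        conc_a = np.array([a for a, _ in conc_keys])
        conc_b = np.array([b for _, b in conc_keys])
        effects = [
            np.array([by_conc[ck][rep] for rep in sorted(by_conc[ck])])
            for ck in conc_keys
        ]
        n_reps = np.array([len(e) for e in effects])
        mean_effect = np.array([e.mean() for e in effects])
        sem = np.array(
            [e.std(ddof=1) / np.sqrt(len(e)) if len(e) > 1 else np.nan for e in effects]
        )
        if np.any(mean_effect < 0):
            warnings.warn(
                f"series {key!r}: negative mean inhibition at some concentrations "
                "(growth stimulation or noise)",
                stacklevel=2,
            )
        tables[key] = EffectTable(
            series_id=key,
            conc=totals,
            conc_a=conc_a,
            conc_b=conc_b,
            effects=effects,
            mean_effect=mean_effect,
            sem=sem,
            n_reps=n_reps,
            control_effects=control_effects,
            control_mean_od=i0,
        )
    return tables
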