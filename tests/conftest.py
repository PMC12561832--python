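"""Shared fixtures: published-style curves and hand-built effect tables."""

from __future__ import annotations

import numpy as np
import pytest

from raymix.effects import EffectTable
from raymix.fitting import FittedCRC


@pytest.fixture
def as_published() -> FittedCRC:
    """As(V) Logit curve in the mirrored single-compound convention (µg/L)."""
    return FittedCRC("Logit", alpha=6.4033, beta=2.4878, conc_scale="ugL", alpha_sign=-1)


@pytest.fixture
def pb_published() -> FittedCRC:
    """Pb(II) Logit curve in the mirrored single-compound convention (µg/L)."""
    return FittedCRC("Logit", alpha=8.5098, beta=1.9786, conc_scale="ugL", alpha_sign=-1)


def crc_with_ec50(ec50_ugl: float, beta: float = 2.5, model: str = "Logit") -> FittedCRC:
    """Verbatim-convention curve with a prescribed EC50 (µg/L)."""
    import math

    if model == "Logit":
        mid = 0.0  # logit(0.5)
    else:
        mid = math.log(math.log(2.0))  # cloglog(0.5)
    alpha = mid - beta * math.log10(ec50_ugl)
    return FittedCRC(model, alpha=alpha, beta=beta, conc_scale="ugL", alpha_sign=1)


def make_table(
    conc,
    effects,
    series_id: str = "S",
    control_effects=None,
    conc_a=None,
    conc_b=None,
) -> EffectTable:
    """Build an EffectTable directly from a replicate-effect matrix.

    ``effects`` is a sequence of per-concentration replicate arrays (ragged
    allowed).
    """
    conc = np.asarray(conc, dtype=float)
    eff = [np.atleast_1d(np.asarray(e, dtype=float)) for e in effects]
    order = np.argsort(conc)
    conc = conc[order]
    eff = [eff[i] for i in order]
    n_reps = np.array([len(e) for e in eff])
    mean = np.array([e.mean() for e in eff])
    sem = np.array(
        [e.std(ddof=1) / np.sqrt(len(e)) if len(e) > 1 else np.nan for e in eff]
    )
    if control_effects is None:
        control_effects = np.zeros(3)
    return EffectTable(
        series_id=series_id,
        conc=conc,
        conc_a=np.asarray(conc_a, dtype=float)[order] if conc_a is not None else conc,
        conc_b=np.asarray(conc_b, dtype=float)[order]
        if conc_b is not None
        else np.zeros_like(conc),
        effects=eff,
        mean_effect=mean,
        sem=sem,
        n_reps=n_reps,
        control_effects=np.asarray(control_effects, dtype=float),
        control_mean_od=0.7,
    )
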