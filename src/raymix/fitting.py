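"""Concentration-response curve (CRC) fitting and derived toxicity indices.

Two 2-parameter sigmoids of inhibition vs log10 concentration are supported,
written here in their canonical ("verbatim") form

    Logit:    E = 1 / (1 + exp(-alpha - beta * x))
    Weibull:  E = 1 - exp(-exp(alpha + beta * x))

with ``x = log10(c)`` in a declared concentration unit (µg/L or g/L) and
``beta > 0`` so the effect rises with concentration.

Published parameter tables in this field are not always in the verbatim
form: single-compound tables are often reported in a *mirrored* convention
in which the half-effect concentration is ``10**(+alpha/beta)`` rather than
``10**(-alpha/beta)``.  :class:`FittedCRC` therefore carries both an
explicit ``conc_scale`` and an ``alpha_sign`` flag (+1 verbatim, -1
mirrored), so either published convention can be inverted exactly.

Fit quality is summarised by the adjusted coefficient

    R2_adj = 1 - [(n-1) * SS_res] / [(n-m) * SS_tot]

and ``RMSE = sqrt(SS_res / n)`` (note the divisor ``n``, not ``n - m``).
The sample size must be at least five observations per parameter, the usual
chemometric rule for CRC fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .effects import EffectTable
from .errors import (
    DegenerateDataError,
    FitFailureError,
    NoFitError,
)

__all__ = [
    "MODELS",
    "FittedCRC",
    "ConfidenceBands",
    "model_effect",
    "fit_crc",
    "goodness_of_fit",
    "select_best",
    "ecx",
    "confidence_bands",
    "noec_loec",
]

MODELS = ("Logit", "Weibull")
ModelName = Literal["Logit", "Weibull"]
ConcScale = Literal["ugL", "gL"]

# log10 of (µg/L per g/L); used to move parameters between scales
_LOG10_UG_PER_G = 6.0


def model_effect(
    model: ModelName, alpha: float, beta: float, log10_c: float | np.ndarray
) -> float | np.ndarray:
    """Verbatim sigmoid value at ``x = log10(c)``.

    Total on its domain: any finite inputs give an effect in (0, 1).
    """
    x = np.asarray(log10_c, dtype=float)
    eta = alpha + beta * x
    if model == "Logit":
        out = 1.0 / (1.0 + np.exp(-eta))
    elif model == "Weibull":
        out = 1.0 - np.exp(-np.exp(eta))
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return float(out) if np.isscalar(log10_c) else out


@dataclass(frozen=True)
class FittedCRC:
    """A fitted (or published) 2-parameter sigmoid.

    ``alpha_sign`` selects the parameter convention: +1 means ``alpha`` is
    the verbatim location, -1 means the stored ``alpha`` is the mirrored
    (published single-compound) value whose verbatim location is ``-alpha``.
    ``conc_scale`` is the unit in which log10(c) was taken when fitting.
    """

    model: ModelName
    alpha: float
    beta: float
    conc_scale: ConcScale = "ugL"
    alpha_sign: int = 1
    param_covariance: np.ndarray | None = None
    r2_adj: float = math.nan
    r2: float = math.nan
    rmse: float = math.nan
    n_obs: int = 0
    n_params: int = 2

    @property
    def alpha_verbatim(self) -> float:
        return self.alpha_sign * self.alpha

    def _to_scale_log10(self, conc_ugl: float | np.ndarray) -> np.ndarray:
        c = np.asarray(conc_ugl, dtype=float)
        x = np.log10(c)
        if self.conc_scale == "gL":
            x = x - _LOG10_UG_PER_G
        return x

    def effect_at(self, conc_ugl: float | np.ndarray) -> float | np.ndarray:
        """Predicted inhibition at a concentration given in µg/L."""
        x = self._to_scale_log10(conc_ugl)
        out = model_effect(self.model, self.alpha_verbatim, self.beta, x)
        return float(out) if np.isscalar(conc_ugl) else np.asarray(out)

    def with_conc_scale(self, scale: ConcScale) -> "FittedCRC":
        """Re-express the same curve with log10(c) taken in another unit.

        Shifting the unit by a factor u multiplies concentrations, so
        ``alpha_verbatim`` changes by ``beta * log10(u)`` while the curve as
        a function of concentration is unchanged.
        """
        if scale == self.conc_scale:
            return self
        shift = _LOG10_UG_PER_G if scale == "gL" else -_LOG10_UG_PER_G
        new_verbatim = self.alpha_verbatim + self.beta * shift
        return replace(self, alpha=self.alpha_sign * new_verbatim, conc_scale=scale)


def _link(model: ModelName, e: np.ndarray) -> np.ndarray:
    """Linearising transform: logit for Logit, cloglog for Weibull."""
    if model == "Logit":
        return np.log(e / (1.0 - e))
    return np.log(-np.log(1.0 - e))


def _inverse_link(model: ModelName, x: float) -> float:
    if model == "Logit":
        return math.log(x / (1.0 - x))
    return math.log(-math.log(1.0 - x))


def goodness_of_fit(
    observed: Sequence[float], fitted: Sequence[float], n_params: int
) -> tuple[float, float]:
    """Adjusted R-squared and RMSE of a fit.

    ``R2_adj = 1 - [(n-1)*SS_res] / [(n-m)*SS_tot]``;
    ``RMSE = sqrt(SS_res / n)``.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and fitted must have the same length")
    n, m = len(y), int(n_params)
    if n <= m:
        raise ValueError(f"need more observations ({n}) than parameters ({m})")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError(
            "observed effects have zero variance; R-squared undefined"
        )
    r2_adj = 1.0 - ((n - 1) * ss_res) / ((n - m) * ss_tot)
    rmse = math.sqrt(ss_res / n)
    return r2_adj, rmse


def _plain_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _starting_values(model: ModelName, x: np.ndarray, e: np.ndarray) -> list[np.ndarray]:
    """Multi-start seeds: linearised-transform regression plus a coarse grid."""
    starts: list[np.ndarray] = []
    clipped = np.clip(e, 1e-4, 1.0 - 1e-4)
    z = _link(model, clipped)
    try:
        beta0, alpha0 = np.polyfit(x, z, 1)
        if np.isfinite(alpha0) and np.isfinite(beta0) and beta0 > 0:
            starts.append(np.array([alpha0, beta0]))
    except np.linalg.LinAlgError:  # pragma: no cover - polyfit rarely fails
        pass
    mid = _inverse_link(model, 0.5)
    x_mid = float(np.median(x))
    for beta in (0.5, 1.0, 2.0, 4.0, 8.0):
        starts.append(np.array([mid - beta * x_mid, beta]))
    return starts


def fit_crc(
    table: EffectTable,
    model: ModelName,
    conc_scale: ConcScale = "ugL",
    min_points: int = 10,
) -> FittedCRC:
    """Nonlinear least-squares fit of a sigmoid to per-concentration means.

    Minimises the sum of squared deviations between observed mean effects
    and the model, from several starting points (a linearised-transform
    regression seed plus a coarse slope grid); the best converged solution
    wins.  Requires at least ``min_points`` distinct concentrations (five
    per parameter).  The parameter covariance is the Gauss-Newton estimate
    ``sigma^2 * (J'J)^-1`` from the Jacobian at the optimum.
    """
    conc = np.asarray(table.conc, dtype=float)
    e = np.asarray(table.mean_effect, dtype=float)
    if len(np.unique(conc)) < min_points:
        raise DegenerateDataError(
            f"need >= {min_points} distinct concentrations, got {len(np.unique(conc))}"
        )
    if np.allclose(e, e[0]):
        raise DegenerateDataError("effects carry no concentration signal (all equal)")
    x = np.log10(conc)
    if conc_scale == "gL":
        x = x - _LOG10_UG_PER_G

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model_effect(model, theta[0], theta[1], x) - e

    best = None
    for theta0 in _starting_values(model, x, e):
        try:
            res = optimize.least_squares(
                residuals,
                theta0,
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy raises only on bad input
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise FitFailureError(f"{model} fit did not converge from any start")

    alpha_hat, beta_hat = best.x
    yhat = model_effect(model, alpha_hat, beta_hat, x)
    r2_adj, rmse = goodness_of_fit(e, yhat, 2)
    n, m = len(e), 2
    ss_res = float(np.sum((e - yhat) ** 2))
    cov: np.ndarray | None = None
    if n > m:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * ss_res / (n - m)
        except np.linalg.LinAlgError:
            warnings.warn("singular Jacobian: parameter covariance unavailable")
            cov = None
    return FittedCRC(
        model=model,
        alpha=float(alpha_hat),
        beta=float(beta_hat),
        conc_scale=conc_scale,
        alpha_sign=1,
        param_covariance=cov,
        r2_adj=r2_adj,
        r2=_plain_r2(e, yhat),
        rmse=rmse,
        n_obs=n,
        n_params=m,
    )


def select_best(fits: Sequence[FittedCRC], r2_tie_tol: float = 1e-6) -> FittedCRC:
    """Best curve: largest adjusted R2, ties by smaller RMSE, then Logit first."""
    fits = list(fits)
    if not fits:
        raise NoFitError("no successful fits to choose from")
    best = fits[0]
    for crc in fits[1:]:
        if crc.r2_adj > best.r2_adj + r2_tie_tol:
            best = crc
        elif abs(crc.r2_adj - best.r2_adj) <= r2_tie_tol:
            if crc.rmse < best.rmse - 1e-15:
                best = crc
            elif abs(crc.rmse - best.rmse) <= 1e-15 and MODELS.index(
                crc.model
            ) < MODELS.index(best.model):
                best = crc
    return best


def ecx(crc: FittedCRC, x: float) -> float:
    """Effect concentration ECx in µg/L, by closed-form curve inversion.

    Logit: ``c = 10**((logit(x) - alpha_v) / beta)``;
    Weibull: ``c = 10**((ln(-ln(1-x)) - alpha_v) / beta)``, with ``alpha_v``
    the verbatim location on the fit's own concentration scale, converted to
    µg/L on return.  Round-trips with :meth:`FittedCRC.effect_at` to 1e-9.
    """
    if not (0.0 < x < 1.0):
        raise ValueError(f"effect level must be in (0, 1), got {x}")
    log10_c = (_inverse_link(crc.model, x) - crc.alpha_verbatim) / crc.beta
    if crc.conc_scale == "gL":
        log10_c += _LOG10_UG_PER_G
    return float(10.0**log10_c)


@dataclass
class ConfidenceBands:
    """Function-based (FCI) and observation-based (OCI) confidence bands.

    The FCI is a pointwise delta-method band around the fitted curve on a
    log-spaced concentration grid; the OCI is a per-concentration t-interval
    on the replicate mean, defined only at tested concentrations with >= 2
    replicates.
    """

    level: float
    grid_conc: np.ndarray
    fitted: np.ndarray
    fci_low: np.ndarray
    fci_high: np.ndarray
    oci_conc: np.ndarray
    oci_mean: np.ndarray
    oci_low: np.ndarray
    oci_high: np.ndarray


def _effect_gradient(
    crc: FittedCRC, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """d(effect)/d(alpha_v, beta) at log10-concentrations ``x`` (fit scale)."""
    eta = crc.alpha_verbatim + crc.beta * x
    if crc.model == "Logit":
        e = 1.0 / (1.0 + np.exp(-eta))
        d_eta = e * (1.0 - e)
    else:
        e = 1.0 - np.exp(-np.exp(eta))
        d_eta = np.exp(eta) * (1.0 - e)
    return d_eta, d_eta * x


def confidence_bands(
    crc: FittedCRC,
    table: EffectTable,
    level: float = 0.95,
    n_grid: int = 200,
) -> ConfidenceBands:
    """95% (by default) FCI around the fitted curve and OCIs at tested points.

    FCI: delta method on (alpha, beta) with a t quantile on n - m degrees of
    freedom.  OCI: ``mean +/- t_{reps-1} * SE`` of the replicate mean.  If
    the parameter covariance is unavailable the FCI collapses onto the
    fitted curve with a warning; the fit itself is retained.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    conc = np.asarray(table.conc, dtype=float)
    grid = np.logspace(np.log10(conc.min()), np.log10(conc.max()), n_grid)
    x = crc._to_scale_log10(grid)
    fitted = np.asarray(model_effect(crc.model, crc.alpha_verbatim, crc.beta, x))

    if crc.param_covariance is None or not np.all(np.isfinite(crc.param_covariance)):
        warnings.warn("no finite parameter covariance: FCI has zero width")
        half = np.zeros_like(fitted)
    else:
        g_a, g_b = _effect_gradient(crc, x)
        grad = np.stack([g_a, g_b], axis=1)
        var = np.einsum("ij,jk,ik->i", grad, crc.param_covariance, grad)
        var = np.clip(var, 0.0, None)
        df = max(crc.n_obs - crc.n_params, 1)
        tq = stats.t.ppf(0.5 + level / 2.0, df)
        half = tq * np.sqrt(var)

    oci_mask = table.n_reps >= 2
    oci_conc = conc[oci_mask]
    oci_mean = table.mean_effect[oci_mask]
    oci_half = np.array(
        [
            stats.t.ppf(0.5 + level / 2.0, n - 1) * s
            for n, s in zip(table.n_reps[oci_mask], table.sem[oci_mask])
        ]
    )
    return ConfidenceBands(
        level=level,
        grid_conc=grid,
        fitted=fitted,
        fci_low=fitted - half,
        fci_high=fitted + half,
        oci_conc=oci_conc,
        oci_mean=oci_mean,
        oci_low=oci_mean - oci_half,
        oci_high=oci_mean + oci_half,
    )


def noec_loec(
    table: EffectTable,
    method: Literal["dunnett", "threshold"] = "dunnett",
    alpha: float = 0.05,
    threshold: float = 0.01,
    rng: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """No-/lowest-observed-effect concentrations (NOEC, LOEC) in µg/L.

    ``dunnett`` (default): one-sided many-to-one comparison of replicate
    effects against the control replicates at significance ``alpha``; the
    LOEC is the lowest concentration whose mean is significantly above
    control, the NOEC the next concentration down.

    ``threshold``: the LOEC is the lowest concentration with mean effect
    above ``threshold`` (default 1% inhibition, matching the usual
    minimum-effect design criterion).

    Sentinels: if no concentration shows an effect the NOEC is the highest
    tested concentration and the LOEC is NaN; if every concentration shows
    an effect the NOEC is NaN (below the tested range) and the LOEC is the
    lowest tested concentration.
    """
    conc = np.asarray(table.conc, dtype=float)
    order = np.argsort(conc)
    conc = conc[order]

    if method == "threshold":
        significant = np.asarray(table.mean_effect)[order] > threshold
    elif method == "dunnett":
        if np.any(table.n_reps < 2):
            raise DegenerateDataError(
                "dunnett NOEC needs >= 2 replicates at every concentration"
            )
        samples = [table.effects[i] for i in order]
        # fixed rng: the multivariate-t quantile is evaluated by randomized
        # quadrature and must not wobble between identical runs
        res = stats.dunnett(
            *samples, control=table.control_effects, alternative="greater", rng=rng
        )
        significant = res.pvalue < alpha
    else:
        raise ValueError(f"unknown NOEC method {method!r}")

    if not significant.any():
        return float(conc[-1]), math.nan
    first = int(np.argmax(significant))
    loec = float(conc[first])
    noec = float(conc[first - 1]) if first > 0 else math.nan
    return noec, loec
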