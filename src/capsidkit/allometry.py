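"""Allometric scaling models G(T) = a_G * T^b_G and D(T) = a_D * T^b_D.

Genome length (kbp) and capsid diameter (nm) of tailed phages follow power
laws in the icosahedral architecture index T.  Two conserved structural
facts fix the theoretical exponents: dsDNA is packed at a constant density
(so G scales with capsid volume, G ~ D^3) and the exposed surface per major
capsid protein is constant (so T scales with capsid surface, T ~ D^2),
giving G ~ T^(3/2) and D ~ T^(1/2).

The empirical fit averages observations per distinct T first (so heavily
re-sampled architectures such as T = 7 do not dominate), takes base-10 logs
of both axes and runs ordinary least squares.  The fitted object carries the
residual statistics needed for confidence/prediction intervals at any T; a
fit can also be instantiated directly from published parameter values, in
which case it predicts means but cannot produce intervals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

#: exponents implied by constant packing density and constant per-MCP surface
THEORETICAL_EXPONENTS = {"genome_kbp": 1.5, "diameter_nm": 0.5}

VARIABLES = ("genome_kbp", "diameter_nm")


class ModelCapabilityError(ValueError):
    """Raised when an evaluation-only fit is asked for residual-based output."""


@dataclass(frozen=True)
class AllometricFit:
    """A fitted (or published-parameter) log10-log10 allometric model.

    ``log10_a`` and ``b`` are intercept and slope of log10(y) on log10(T);
    ``residual_sd`` (log10 units), ``mean_log10_t``, ``sxx`` and ``df``
    support interval prediction and are ``None`` for evaluation-only fits.
    """

    variable: str
    log10_a: float
    b: float
    se_log10_a: float | None = None
    se_b: float | None = None
    n: int | None = None
    r_squared: float | None = None
    residual_sd: float | None = None
    mean_log10_t: float | None = None
    sxx: float | None = None
    df: int | None = None
    t_values: tuple[float, ...] | None = None
    log10_t: tuple[float, ...] | None = None
    log10_y: tuple[float, ...] | None = None

    @property
    def has_residual_stats(self) -> bool:
        return None not in (self.residual_sd, self.mean_log10_t, self.sxx, self.df, self.n)

    @property
    def exponent_cv(self) -> float | None:
        """Coefficient of variation of the exponent, se_b / b."""
        if self.se_b is None:
            return None
        return self.se_b / self.b


def fit_allometric(pairs: Sequence[tuple[float, float]], variable: str) -> AllometricFit:
    """Fit the power law to ``(t, value)`` observations.

    Observations sharing a T value are arithmetically averaged in linear
    space first; both axes are then logged (base 10) and fitted by ordinary
    least squares.  Requires at least 3 distinct T values and positive data.
    """
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}")
    groups: dict[float, list[float]] = {}
    for t, y in pairs:
        if t <= 0 or y <= 0:
            raise ValueError("t and values must be positive for a log-log fit")
        groups.setdefault(round(float(t), 9), []).append(float(y))
    if len(groups) < 3:
        raise ValueError("need at least 3 distinct T values to fit")
    ts = np.array(sorted(groups))
    means = np.array([np.mean(groups[t]) for t in ts])
    x = np.log10(ts)
    y = np.log10(means)
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    n = len(ts)
    xbar = float(x.mean())
    sxx = float(((x - xbar) ** 2).sum())
    resid_sd = float(math.sqrt(res.ssr / (n - 2))) if n > 2 else 0.0
    r_squared = float(res.rsquared) if res.centered_tss > 0 else 0.0
    return AllometricFit(
        variable=variable,
        log10_a=float(res.params[0]),
        b=float(res.params[1]),
        se_log10_a=float(res.bse[0]),
        se_b=float(res.bse[1]),
        n=n,
        r_squared=r_squared,
        residual_sd=resid_sd,
        mean_log10_t=xbar,
        sxx=sxx,
        df=n - 2,
        t_values=tuple(float(t) for t in ts),
        log10_t=tuple(float(v) for v in x),
        log10_y=tuple(float(v) for v in y),
    )


def from_printed_params(
    log10_a: float,
    b: float,
    variable: str,
    se_log10_a: float | None = None,
    se_b: float | None = None,
) -> AllometricFit:
    """Evaluation-only fit from published parameter values (no intervals)."""
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}")
    if not (math.isfinite(log10_a) and math.isfinite(b)):
        raise ValueError("parameters must be finite")
    return AllometricFit(variable=variable, log10_a=float(log10_a), b=float(b),
                         se_log10_a=se_log10_a, se_b=se_b)


def predict_mean(fit: AllometricFit, t: float) -> float:
    """Model mean ``10^log10_a * t^b`` in the fit's units (kbp or nm)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return 10.0 ** fit.log10_a * t ** fit.b


def inverse_t(fit: AllometricFit, value: float) -> float:
    """Continuous architecture index implied by a genome length or diameter."""
    if value <= 0:
        raise ValueError("value must be positive")
    return (value / 10.0 ** fit.log10_a) ** (1.0 / fit.b)


@dataclass(frozen=True)
class IntervalPrediction:
    t: float
    mean: float
    lower: float
    upper: float
    level: float
    kind: str  # mean_response | new_observation


def predict_interval(
    fit: AllometricFit,
    t: float,
    level: float = 0.95,
    kind: str = "mean_response",
) -> IntervalPrediction:
    """Back-transformed regression interval at T = t.

    The standard linear-regression half-width on the log10 scale is
    ``t_quantile * s * sqrt([1 +] 1/n + (x0 - xbar)^2 / Sxx)`` (the leading 1
    only for ``new_observation``); exponentiating gives an interval that is
    asymmetric around the mean on the linear scale.
    """
    if kind not in ("mean_response", "new_observation"):
        raise ValueError("kind must be 'mean_response' or 'new_observation'")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not fit.has_residual_stats:
        raise ModelCapabilityError(
            "this fit carries no residual statistics (printed-parameter fits cannot produce intervals)"
        )
    if t <= 0:
        raise ValueError("t must be positive")
    x0 = math.log10(t)
    yhat = fit.log10_a + fit.b * x0
    extra = 1.0 if kind == "new_observation" else 0.0
    tq = stats.t.ppf(0.5 + level / 2.0, fit.df)
    half = tq * fit.residual_sd * math.sqrt(extra + 1.0 / fit.n + (x0 - fit.mean_log10_t) ** 2 / fit.sxx)
    return IntervalPrediction(
        t=float(t),
        mean=10.0 ** yhat,
        lower=10.0 ** (yhat - half),
        upper=10.0 ** (yhat + half),
        level=level,
        kind=kind,
    )


@dataclass(frozen=True)
class ResidualDiagnostics:
    t_values: tuple[float, ...]
    residuals: tuple[float, ...]  # log10 units
    standardized: tuple[float, ...]
    leverage: tuple[float, ...]
    normality_p: float | None
    heteroscedastic: bool
    max_standardized_index: int


def residual_diagnostics(fit: AllometricFit) -> ResidualDiagnostics:
    """Standardised residuals, leverages, a normality p-value, and a
    heteroscedasticity flag (|residual| correlated with the fitted value)."""
    if not fit.has_residual_stats or fit.log10_t is None:
        raise ModelCapabilityError("residual diagnostics require a freshly fitted model")
    x = np.asarray(fit.log10_t)
    y = np.asarray(fit.log10_y)
    fitted = fit.log10_a + fit.b * x
    resid = y - fitted
    lev = 1.0 / fit.n + (x - fit.mean_log10_t) ** 2 / fit.sxx
    s = fit.residual_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(s > 0, resid / (s * np.sqrt(np.clip(1.0 - lev, 1e-12, None))), 0.0)
    normality_p: float | None = None
    if fit.n >= 3 and np.ptp(resid) > 0:
        normality_p = float(stats.shapiro(resid)[1])
    hetero = False
    if fit.n >= 4 and np.ptp(np.abs(resid)) > 0 and np.ptp(fitted) > 0:
        rho, p = stats.spearmanr(np.abs(resid), fitted)
        hetero = bool(p < 0.05 and abs(rho) > 0.5)
    return ResidualDiagnostics(
        t_values=fit.t_values,
        residuals=tuple(float(v) for v in resid),
        standardized=tuple(float(v) for v in std),
        leverage=tuple(float(v) for v in lev),
        normality_p=normality_p,
        heteroscedastic=hetero,
        max_standardized_index=int(np.argmax(np.abs(std))),
    )


# ---------------------------------------------------------------------------
# serialization and the packaged published parameters


def fit_to_json(fit: AllometricFit, path=None) -> str:
    doc = {k: v for k, v in fit.__dict__.items()}
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def fit_from_json(source) -> AllometricFit:
    if isinstance(source, (str, Path)) and Path(source).exists():
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    for key in ("t_values", "log10_t", "log10_y"):
        if doc.get(key) is not None:
            doc[key] = tuple(doc[key])
    return AllometricFit(**doc)


def printed_fit(variable: str) -> AllometricFit:
    """The published genome (kbp) or diameter (nm) model parameters,
    shipped with the package: log10 a_G = 0.37, b_G = 1.47;
    log10 a_D = 1.38, b_D = 0.52 (with their standard errors)."""
    text = resources.files("capsidkit.data").joinpath("printed_params.json").read_text()
    doc = json.loads(text)
    if variable not in doc:
        raise ValueError(f"no printed parameters for variable {variable!r}")
    p = doc[variable]
    return from_printed_params(
        p["log10_a"], p["b"], variable, se_log10_a=p.get("se_log10_a"), se_b=p.get("se_b")
    )
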