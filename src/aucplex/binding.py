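"""Binding isotherms and cooperative (Hill) model fitting.

Builds fraction-bound isotherms from titration data — either integrals of
DNA-signal sedimentation-coefficient distributions (free vs complex-shifted
windows) or gel-shift densitometry tables — and fits the Hill model

    theta([L]) = [L]^n / (K_D^n + [L]^n)

by nonlinear least squares, comparing it against the non-cooperative (n = 1)
model with least-squares AIC and Akaike weights.  K_D here is the
half-saturation concentration (units M); writing the denominator constant as
K_D + [L]^n instead (a form sometimes printed, with the constant in units
M^n) is available via ``literal_kd=True``.  Parameter uncertainties come
from a residual-resampling bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .sv import SedimentationDistribution, integrate_distribution

__all__ = [
    "BindingIsotherm", "HillFitResult", "ModelComparison", "BootstrapResult",
    "FREE_DNA_WINDOW", "BOUND_DNA_WINDOW",
    "hill_theta", "isotherm_from_titration", "emsa_isotherm",
    "fit_hill", "compare_models", "bootstrap_ci",
]

#: Default c(s) integration windows (S) for labeled-DNA titrations:
#: unbound duplex and the complex-shifted region.
FREE_DNA_WINDOW = (2.0, 3.5)
BOUND_DNA_WINDOW = (3.5, 12.0)


# ---------------------------------------------------------------------------
# Isotherm containers and construction
# ---------------------------------------------------------------------------

@dataclass
class BindingIsotherm:
    """Fraction of DNA bound vs total titrant concentration.

    Concentrations are strictly positive and sorted ascending; theta outside
    [0, 1] by small amounts (noise) is soft-clipped with a warning.
    """

    concentrations: np.ndarray       # M
    theta: np.ndarray                # fraction bound
    sd: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if conc.shape != theta.shape or conc.ndim != 1:
            raise ValueError("concentrations and theta must be 1-D and equal length")
        if np.any(conc <= 0):
            raise ValueError("titrant concentrations must be strictly positive")
        order = np.argsort(conc)
        conc, theta = conc[order], theta[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("duplicate titrant concentrations; average them first")
        if np.any(theta < -1e-9) or np.any(theta > 1 + 1e-9):
            warnings.warn("theta outside [0, 1]; soft-clipping")
        theta = np.clip(theta, 0.0, 1.0)
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)[order]
        self.concentrations, self.theta, self.sd = conc, theta, sd

    def __len__(self) -> int:
        return self.concentrations.size


def isotherm_from_titration(distributions: Mapping[float, SedimentationDistribution],
                            free_range: tuple[float, float] = FREE_DNA_WINDOW,
                            bound_range: tuple[float, float] = BOUND_DNA_WINDOW
                            ) -> BindingIsotherm:
    """Fraction bound per titration point from DNA-signal c(s) integrals.

    theta = bound / (bound + free), integrating each distribution over the
    complex-shifted and free-DNA windows (defaults 3.5-12 S and 2-3.5 S).
    """
    if free_range[1] > bound_range[0] and bound_range[1] > free_range[0] \
            and not np.isclose(free_range[1], bound_range[0]) \
            and not np.isclose(bound_range[1], free_range[0]):
        if max(free_range[0], bound_range[0]) < min(free_range[1], bound_range[1]):
            raise ValueError("free and bound integration ranges overlap")
    concs, thetas = [], []
    for conc, dist in sorted(distributions.items()):
        free = integrate_distribution(dist, *free_range)
        bound = integrate_distribution(dist, *bound_range)
        if free + bound <= 0:
            raise ValueError(
                f"titration point at {conc:g} M: both free and bound integrals are zero")
        concs.append(conc)
        thetas.append(bound / (free + bound))
    return BindingIsotherm(np.array(concs), np.array(thetas))


def emsa_isotherm(table: pd.DataFrame | str) -> BindingIsotherm:
    """Validated isotherm from a gel-shift densitometry table.

    Expects columns ``conc_M`` and ``theta`` (fraction bound per lane);
    duplicate-concentration lanes are averaged with the SD recorded.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table, comment="#")
    missing = {"conc_M", "theta"} - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table lacks columns: {sorted(missing)}")
    if len(table) < 4:
        raise ValueError("need at least 4 lanes")
    theta = table["theta"].to_numpy(dtype=float)
    if np.any(theta < -0.01) or np.any(theta > 1.01):
        raise ValueError("bound fractions outside [0, 1] by more than 1%")
    grouped = table.groupby("conc_M")["theta"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    return BindingIsotherm(mean.index.to_numpy(dtype=float),
                           mean.to_numpy(dtype=float),
                           sd.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Hill model
# ---------------------------------------------------------------------------

def hill_theta(L, K_D: float, n: float, literal_kd: bool = False):
    """Hill isotherm theta = [L]^n / (K_D^n + [L]^n).

    With ``literal_kd=True`` the denominator constant is used as-is
    (K_D + [L]^n, constant in units M^n).  Evaluated in logistic form,
    theta = expit(n ln[L] - ln(constant)), which is overflow-safe for the
    extreme (K, n) excursions a nonlinear optimizer may probe.
    """
    from scipy.special import expit
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    if literal_kd:
        out = expit(n * logL - np.log(K_D))
    else:
        out = expit(n * (logL - np.log(K_D)))
    return np.where(L > 0, out, 0.0) if out.ndim else (out if L > 0 else 0.0)


@dataclass
class HillFitResult:
    """Fitted Hill parameters with least-squares AIC."""

    K_D: float
    n: float
    sd_K: float | None
    sd_n: float | None
    residual_ss: float
    aic: float
    n_points: int
    fixed_n: float | None = None
    literal_kd: bool = False

    def predict(self, L):
        return hill_theta(L, self.K_D, self.n, self.literal_kd)


def _aic_ls(ss: float, n_obs: int, k_params: int) -> float:
    """Least-squares AIC = N ln(SS/N) + 2k, k counting the variance parameter."""
    ss = max(ss, 1e-300)
    return n_obs * np.log(ss / n_obs) + 2.0 * k_params


def fit_hill(iso: BindingIsotherm, fix_n: float | None = None,
             literal_kd: bool = False) -> HillFitResult:
    """Fit the Hill model by multi-start nonlinear least squares.

    Starts span a log-spaced K grid across the titration range (half-decade
    steps), with n started at 1 and 2; the best converged minimum wins.
    ``fix_n`` pins the Hill coefficient (``fix_n=1`` is the non-cooperative
    rectangular-hyperbola model).
    """
    L, y = iso.concentrations, iso.theta
    if len(iso) < 4:
        raise ValueError("need at least 4 titration points")
    inside = np.sum((y > 0.1) & (y < 0.9))
    if inside < 2:
        warnings.warn("few points in the transition region (0.1 < theta < 0.9); "
                      "fit may be poorly constrained")

    def residuals(params):
        if fix_n is None:
            logK, logn = params
            return hill_theta(L, np.exp(logK), np.exp(logn), literal_kd) - y
        (logK,) = params
        return hill_theta(L, np.exp(logK), fix_n, literal_kd) - y

    k_starts = np.geomspace(L[0], L[-1], 8)
    n_starts = (1.0, 2.0) if fix_n is None else (fix_n,)
    best = None
    for K0 in k_starts:
        for n0 in n_starts:
            x0 = [np.log(K0)] if fix_n is not None else [np.log(K0), np.log(n0)]
            try:
                sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Hill fit failed to converge from any start")
    if fix_n is None:
        K_D, n = np.exp(best.x)
        k_params = 3  # K, n, variance
    else:
        K_D, n = float(np.exp(best.x[0])), float(fix_n)
        k_params = 2  # K, variance
    ss = float(2.0 * best.cost)
    return HillFitResult(float(K_D), float(n), None, None, ss,
                         _aic_ls(ss, len(iso), k_params), len(iso),
                         fixed_n=fix_n, literal_kd=literal_kd)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Per-model AIC and Akaike weights (percent, summing to 100)."""

    aic: dict[str, float]
    weights_percent: dict[str, float]
    fits: dict[str, HillFitResult] = field(default_factory=dict)

    @property
    def best_model(self) -> str:
        return max(self.weights_percent, key=self.weights_percent.get)


def akaike_weights(aic: Mapping[str, float]) -> dict[str, float]:
    """Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2), in percent."""
    vals = np.array(list(aic.values()), dtype=float)
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    w = 100.0 * w / w.sum()
    return dict(zip(aic.keys(), w))


def compare_models(iso: BindingIsotherm, literal_kd: bool = False) -> ModelComparison:
    """Hill (free n) vs non-cooperative (n = 1) by AIC and Akaike weights."""
    fits = {
        "hill": fit_hill(iso, fix_n=None, literal_kd=literal_kd),
        "noncooperative": fit_hill(iso, fix_n=1.0, literal_kd=literal_kd),
    }
    if fits["hill"].n_points != fits["noncooperative"].n_points:
        raise ValueError("models fitted to different numbers of points")
    aic = {name: fit.aic for name, fit in fits.items()}
    return ModelComparison(aic, akaike_weights(aic), fits)


# ---------------------------------------------------------------------------
# Bootstrap uncertainties
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Residual-resampling bootstrap distribution of Hill parameters."""

    sd_K: float
    sd_n: float
    ci_K: tuple[float, float]        # 2.5/97.5 percentiles
    ci_n: tuple[float, float]
    replicates_K: np.ndarray
    replicates_n: np.ndarray
    seed: int


def _se_log_params(sol, n_obs: int) -> np.ndarray:
    """Linearization SEs of the log-parameters from the least-squares Jacobian."""
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def bootstrap_ci(fit: HillFitResult, iso: BindingIsotherm, n_reps: int = 500,
                 seed: int = 0, ci_level: float = 95.0) -> BootstrapResult:
    """Studentized residual-resampling bootstrap for K_D and n.

    Residuals of the given fit — inflated by sqrt(N/(N-p)) to undo the
    variance absorbed by the fitted parameters — are resampled with
    replacement onto the fitted curve and refitted from the best-fit
    parameters.  Intervals are bootstrap-t on the log-parameters (each
    replicate is studentized by its own linearization SE), which keeps
    near-nominal coverage at the small point counts typical of titrations;
    SDs are of the raw replicate parameter draws.  Errors if more than 20%
    of replicates fail.
    """
    if n_reps < 100:
        raise ValueError("need n_reps >= 100")
    rng = np.random.default_rng(seed)
    L, y = iso.concentrations, iso.theta
    n_params = 1 if fit.fixed_n is not None else 2
    x0 = ([np.log(fit.K_D)] if fit.fixed_n is not None
          else [np.log(fit.K_D), np.log(fit.n)])

    def residuals_for(target):
        def residuals(params):
            if fit.fixed_n is None:
                return hill_theta(L, np.exp(params[0]), np.exp(params[1]),
                                  fit.literal_kd) - target
            return hill_theta(L, np.exp(params[0]), fit.fixed_n,
                              fit.literal_kd) - target
        return residuals

    sol0 = least_squares(residuals_for(y), x0, method="lm", max_nfev=2000)
    se0 = _se_log_params(sol0, len(iso))
    yhat = fit.predict(L)
    resid = (y - yhat) * np.sqrt(len(iso) / max(len(iso) - n_params, 1))
    if not np.any(np.abs(resid) > 1e-12):
        warnings.warn("zero residuals; bootstrap SDs are zero")
    Ks, ns, tK, tn = [], [], [], []
    failures = 0
    for _ in range(n_reps):
        y_rep = np.clip(yhat + rng.choice(resid, size=resid.size, replace=True),
                        0.0, 1.0)
        try:
            sol = least_squares(residuals_for(y_rep), sol0.x, method="lm",
                                max_nfev=1000)
            if not np.all(np.isfinite(sol.x)):
                raise RuntimeError
        except Exception:
            failures += 1
            continue
        se = _se_log_params(sol, len(iso))
        Ks.append(np.exp(sol.x[0]))
        tK.append((sol.x[0] - sol0.x[0]) / max(se[0], 1e-12))
        if fit.fixed_n is None:
            ns.append(np.exp(sol.x[1]))
            tn.append((sol.x[1] - sol0.x[1]) / max(se[1], 1e-12))
        else:
            ns.append(fit.fixed_n)
    if failures > 0.2 * n_reps:
        raise RuntimeError(f"bootstrap failed in {failures}/{n_reps} replicates")
    Ks, ns = np.asarray(Ks), np.asarray(ns)
    alpha = (100.0 - ci_level) / 2.0

    def t_interval(center, se, tstats):
        q_lo, q_hi = np.percentile(tstats, [alpha, 100.0 - alpha])
        return (float(np.exp(center - q_hi * se)), float(np.exp(center - q_lo * se)))

    ci_K = t_interval(sol0.x[0], max(se0[0], 0.0), tK)
    if fit.fixed_n is None:
        ci_n = t_interval(sol0.x[1], max(se0[1], 0.0), tn)
        sd_n = float(ns.std(ddof=1))
    else:
        ci_n = (float(fit.fixed_n), float(fit.fixed_n))
        sd_n = 0.0
    return BootstrapResult(
        sd_K=float(Ks.std(ddof=1)), sd_n=sd_n, ci_K=ci_K, ci_n=ci_n,
        replicates_K=Ks, replicates_n=ns, seed=seed)
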