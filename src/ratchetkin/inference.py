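"""Model fitting and discrimination on force-velocity datasets.

A dataset is a table of (signed force, [dNTP], mean velocity, SEM) records.
Per-force Michaelis-Menten fits give V_max(F) and K_M(F); the global fit
adjusts one of the three coupling models simultaneously to every record,
weighted by 1/SEM^2, with rates parameterized in log space (positivity)
and multi-start initialization (the a/b and r/s amplitude split is weakly
identified when the force dependence is shallow).  Uncertainties come both
from the fit covariance and from seeded case-resampling bootstrap.  Model
discrimination reports weighted RSS and AIC for all three models plus the
two signature tests the data themselves expose: the force dependence (or
flatness) of 1/V_max and of K_M/V_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .kinetics import (
    KBT_22C,
    InvalidParameterError,
    MMCoefficients,
    Model1Rates,
    Model2Rates,
    RatchetRates,
    rates_from_coefficients,
    rupture_force,
    translocation_landscape,
    velocity_model1,
    velocity_model2,
    velocity_model3,
)

__all__ = [
    "MMFitResult",
    "FitReport",
    "ModelRanking",
    "SlopeTest",
    "IdentifiabilityError",
    "validate_dataset",
    "fit_mm_at_force",
    "global_fit",
    "model_predictions",
    "discriminate_models",
]


class IdentifiabilityError(ValueError):
    """Too few force/dNTP levels to constrain the requested fit."""


@dataclass
class MMFitResult:
    """Michaelis-Menten parameters at one force."""

    force: float
    V_max: float
    K_M: float
    se_V_max: float
    se_K_M: float
    converged: bool = True


@dataclass
class SlopeTest:
    """Weighted-regression slope of a log quantity vs force.

    ``ci`` is the bootstrap percentile interval; ``significant`` is True
    when the interval excludes zero (a genuine force dependence).
    """

    slope: float
    ci: tuple
    significant: bool


@dataclass
class FitReport:
    """Result of a global force-velocity fit for one model."""

    model: int
    params: dict
    rss: float                      # weighted residual sum of squares
    aic: float
    n_obs: int
    n_params: int
    coefficients: MMCoefficients | None = None
    derived: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    bootstrap_ci: dict = field(default_factory=dict)
    n_starts_converged: int = 0

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": self.params,
            "rss": self.rss,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "derived": self.derived,
            "se": self.se,
            "bootstrap_ci": self.bootstrap_ci,
        }
        return out


@dataclass
class ModelRanking:
    """Three-model comparison: AIC ranking plus signature slope tests."""

    reports: dict
    ranking: list
    inv_vmax_slope: SlopeTest | None = None
    km_over_vmax_slope: SlopeTest | None = None

    @property
    def best_model(self) -> int:
        return self.ranking[0]


# ---------------------------------------------------------------------------


def validate_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    """Check the force-velocity table invariants for global fitting."""
    required = {"force_pN", "dntp_uM", "velocity_nt_s", "sem_nt_s"}
    missing = required - set(dataset.columns)
    if missing:
        raise InvalidParameterError(f"dataset missing columns {missing}")
    if dataset["dntp_uM"].nunique() < 2 or dataset["force_pN"].nunique() < 3:
        raise IdentifiabilityError(
            "need >= 2 dNTP levels and >= 3 forces for global fitting")
    return dataset


def _weights(sem: np.ndarray) -> np.ndarray:
    """1/SEM weights; degenerate (zero/non-finite) SEMs get unit weight."""
    sem = np.asarray(sem, dtype=float)
    ok = np.isfinite(sem) & (sem > 0)
    if not ok.any():
        return np.ones_like(sem)
    w = np.empty_like(sem)
    w[ok] = 1.0 / sem[ok]
    w[~ok] = 1.0 / sem[ok].min()
    return w


def fit_mm_at_force(dataset: pd.DataFrame, force: float | None = None,
                    tol: float = 0.1) -> MMFitResult:
    """Weighted Michaelis-Menten fit v = V_max*C/(K_M + C) at one force.

    ``dataset`` may be pre-restricted, or pass ``force`` to select records
    within ``tol`` pN.  Requires >= 3 dNTP levels.
    """
    df = dataset
    if force is not None:
        df = df[np.abs(df["force_pN"] - force) <= tol]
    if df["dntp_uM"].nunique() < 3:
        raise IdentifiabilityError("need >= 3 dNTP levels at this force")
    C = df["dntp_uM"].to_numpy(float)
    v = df["velocity_nt_s"].to_numpy(float)
    w = _weights(df["sem_nt_s"].to_numpy(float))
    F = float(df["force_pN"].mean())
    mm = lambda c, vmax, km: vmax * c / (km + c)
    p0 = [max(v.max(), 1e-3), max(np.median(C), 1.0)]
    try:
        popt, pcov = curve_fit(mm, C, v, p0=p0, sigma=1.0 / w,
                               absolute_sigma=True, maxfev=20000,
                               bounds=([0, 0], [np.inf, np.inf]))
        se = np.sqrt(np.diag(pcov))
        return MMFitResult(force=F, V_max=float(popt[0]), K_M=float(popt[1]),
                           se_V_max=float(se[0]), se_K_M=float(se[1]))
    except RuntimeError:
        return MMFitResult(force=F, V_max=float(v.max()),
                           K_M=float(np.median(C)), se_V_max=np.nan,
                           se_K_M=np.nan, converged=False)


# ---------------------------------------------------------------------------
# Global fits

_N_M3, _N_M1, _N_M2 = 6, 5, 6


def _model_velocity(model: int, theta: np.ndarray, F, C, kBT: float):
    if model == 3:
        a, b, r, s = np.exp(theta[:4])
        coeffs = MMCoefficients(a=a, b=b, r=r, s_coef=s,
                                d_b=theta[4], d_s=theta[5])
        return velocity_model3(F, C, coeffs, kBT)
    if model == 1:
        kcat, kon0, koff0 = np.exp(theta[:3])
        rates = Model1Rates(k_on0=kon0, k_off0=koff0, k_cat=kcat,
                            d_on=theta[3], d_off=theta[4])
        return velocity_model1(F, C, rates, kBT)
    if model == 2:
        kon, koff, kcat, kmcat, kppi0 = np.exp(theta[:5])
        rates = Model2Rates(k_on=kon, k_off=koff, k_cat=kcat, k_mcat=kmcat,
                            k_ppi0=kppi0, d_ppi=theta[5])
        return velocity_model2(F, C, rates, kBT)
    raise InvalidParameterError(f"unknown model {model}")


def _theta_bounds(model: int):
    if model == 3:
        return ([-30] * 4 + [0.0, 0.0], [10] * 4 + [2.0, 2.0])
    if model == 1:
        return ([-30] * 3 + [0.0, 0.0], [15] * 3 + [2.0, 2.0])
    return ([-30] * 5 + [0.0], [20] * 5 + [2.0])


def _heuristic_theta(model: int, df: pd.DataFrame) -> np.ndarray:
    """Data-driven starting point for the multi-start optimizer."""
    v_max = df["velocity_nt_s"].max()
    # crude K_M/V_max scale from the lowest-dNTP records
    low = df[df["dntp_uM"] == df["dntp_uM"].min()]
    inv_slope = float(np.median((1.0 / np.maximum(low["velocity_nt_s"], 1e-6)
                                 - 1.0 / v_max) * low["dntp_uM"]))
    inv_slope = max(inv_slope, 1e-3)
    if model == 3:
        return np.array([np.log(0.7 / v_max), np.log(0.3 / v_max),
                         np.log(0.6 * inv_slope), np.log(0.4 * inv_slope),
                         0.3, 0.4])
    if model == 1:
        return np.array([np.log(v_max), np.log(1.0 / inv_slope),
                         np.log(1e-3), 0.3, 0.1])
    return np.array([np.log(1.0 / inv_slope), np.log(1e-2),
                     np.log(v_max * 1.1), np.log(1.0), np.log(1e4), 0.3])


def _fit_once(model: int, theta0, F, C, v, w, kBT):
    lo, hi = _theta_bounds(model)
    theta0 = np.clip(theta0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
    res = least_squares(
        lambda th: w * (_model_velocity(model, th, F, C, kBT) - v),
        theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    return res


def _multi_start(model, F, C, v, w, kBT, n_starts, rng):
    base = _heuristic_theta(model, pd.DataFrame(
        {"force_pN": F, "dntp_uM": C, "velocity_nt_s": v}))
    best, n_ok = None, 0
    for k in range(max(n_starts, 1)):
        theta0 = base.copy()
        if k > 0:
            npar = base.size
            jitter = rng.normal(0.0, 0.7, size=npar)
            theta0 = base + jitter
            # distances jittered uniformly instead of lognormally
            nd = 2 if model != 2 else 1
            theta0[-nd:] = rng.uniform(0.0, 1.0, size=nd)
        try:
            res = _fit_once(model, theta0, F, C, v, w, kBT)
        except Exception:
            continue
        if res.success or res.cost < np.inf:
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError(f"model {model} fit failed from all starts")
    return best, n_ok


def _report_from_theta(model, theta, rss, n_obs, kBT) -> FitReport:
    n_params = {1: _N_M1, 2: _N_M2, 3: _N_M3}[model]
    aic = rss + 2 * n_params
    report = FitReport(model=model, params={}, rss=float(rss),
                       aic=float(aic), n_obs=n_obs, n_params=n_params)
    if model == 3:
        a, b, r, s = np.exp(theta[:4])
        coeffs = MMCoefficients(a=a, b=b, r=r, s_coef=s,
                                d_b=float(theta[4]), d_s=float(theta[5]))
        report.coefficients = coeffs
        report.params = {"a": a, "b": b, "r": r, "s_coef": s,
                         "d_b": float(theta[4]), "d_s": float(theta[5])}
        if coeffs.d_s >= coeffs.d_b:
            rates = rates_from_coefficients(coeffs)
            land = translocation_landscape(rates, 0.0, kBT)
            report.derived = {
                "k_cat": rates.k_cat, "k_T0": rates.k_T0,
                "k_mT0": rates.k_mT0, "k_on": rates.k_on,
                "d_T": rates.d_T, "d_mT": rates.d_mT,
                "delta": rates.delta, "K_delta0": land.K_delta,
                "dG_trans_kBT": land.dG_trans,
            }
    elif model == 1:
        kcat, kon0, koff0 = np.exp(theta[:3])
        report.params = {"k_cat": kcat, "k_on0": kon0, "k_off0": koff0,
                         "d_on": float(theta[3]), "d_off": float(theta[4])}
    else:
        kon, koff, kcat, kmcat, kppi0 = np.exp(theta[:5])
        report.params = {"k_on": kon, "k_off": koff, "k_cat": kcat,
                         "k_mcat": kmcat, "k_ppi0": kppi0,
                         "d_ppi": float(theta[5])}
    return report


def global_fit(dataset: pd.DataFrame, model: int = 3,
               n_bootstrap: int = 200, seed=None, n_starts: int = 10,
               kBT: float = KBT_22C) -> FitReport:
    """Simultaneous weighted fit of one model to all (F, [dNTP]) records.

    Multi-start trust-region least squares on log-rate parameters; the
    weighted RSS is chi^2 when SEMs are exact.  Bootstrap confidence
    intervals (2.5/97.5 percentiles) use case resampling of records with a
    fixed seed; set ``n_bootstrap=0`` to skip.
    """
    df = validate_dataset(dataset)
    rng = np.random.default_rng(seed)
    F = df["force_pN"].to_numpy(float)
    C = df["dntp_uM"].to_numpy(float)
    v = df["velocity_nt_s"].to_numpy(float)
    w = _weights(df["sem_nt_s"].to_numpy(float))

    best, n_ok = _multi_start(model, F, C, v, w, kBT, n_starts, rng)
    rss = 2 * best.cost  # least_squares cost = 0.5 * sum(res^2)
    report = _report_from_theta(model, best.x, rss, F.size, kBT)
    report.n_starts_converged = n_ok

    # covariance-based standard errors on the internal parameters
    try:
        J = best.jac
        dof = max(F.size - best.x.size, 1)
        cov = np.linalg.pinv(J.T @ J) * rss / dof
        se_theta = np.sqrt(np.abs(np.diag(cov)))
        names = list(report.params)
        # delta method: log-rates carry relative SE
        se = {}
        for i, name in enumerate(names):
            val = report.params[name]
            se[name] = (abs(val) * se_theta[i]
                        if i < len(names) - _n_distances(model)
                        else se_theta[i])
        report.se = se
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass

    if n_bootstrap > 0:
        samples = {k: [] for k in report.params}
        n = F.size
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                res_b = _fit_once(model, best.x, F[idx], C[idx], v[idx],
                                  w[idx], kBT)
            except Exception:
                continue
            rep_b = _report_from_theta(model, res_b.x, 2 * res_b.cost, n, kBT)
            for k, val in rep_b.params.items():
                samples[k].append(val)
        report.bootstrap_ci = {
            k: (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5)))
            for k, s in samples.items() if len(s) >= 20
        }
    return report


def _n_distances(model: int) -> int:
    return 1 if model == 2 else 2


# ---------------------------------------------------------------------------


def model_predictions(coeffs: MMCoefficients, forces,
                      dNTPs=(2, 5, 10, 50, 100, 200, 500),
                      v_detach: float = 7.0,
                      kBT: float = KBT_22C) -> dict:
    """Best-fit prediction curves on the requested grids.

    Returns 1/V_max(F), K_M(F), K_M/V_max(F) and the rupture force versus
    [dNTP] (None where the zero-load velocity never exceeds the detachment
    criterion).
    """
    F = np.asarray(forces, dtype=float)
    inv_vmax = coeffs.a + coeffs.b * np.exp(-F * coeffs.d_b / kBT)
    km_over_vmax = coeffs.r + coeffs.s_coef * np.exp(-F * coeffs.d_s / kBT)
    return {
        "force_pN": F,
        "inv_vmax_s": inv_vmax,
        "km_uM": km_over_vmax / inv_vmax,
        "km_over_vmax_s_uM": km_over_vmax,
        "dntp_uM": np.asarray(dNTPs, dtype=float),
        "rupture_force_pN": [rupture_force(coeffs, c, v_detach, kBT)
                             for c in dNTPs],
    }


def _slope_from_mm(dataset: pd.DataFrame, which: str) -> float:
    fits = []
    for F, df_f in dataset.groupby("force_pN"):
        if df_f["dntp_uM"].nunique() < 3:
            continue
        fits.append(fit_mm_at_force(df_f))
    if len(fits) < 3:
        raise IdentifiabilityError("need >= 3 forces with >= 3 dNTP levels")
    F = np.array([f.force for f in fits])
    if which == "inv_vmax":
        y = np.log(1.0 / np.array([f.V_max for f in fits]))
    else:
        y = np.log(np.array([f.K_M / f.V_max for f in fits]))
    A = np.vstack([F, np.ones_like(F)]).T
    slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(slope)


def _signature_slope(dataset: pd.DataFrame, which: str, n_bootstrap: int,
                     rng) -> SlopeTest:
    """Bootstrap slope of log(1/V_max) or log(K_M/V_max) vs force.

    The bootstrap is parametric — velocities redrawn as N(v, sem) — since
    the table holds one averaged record per condition.
    """
    slope = _slope_from_mm(dataset, which)
    sem = dataset["sem_nt_s"].to_numpy(float)
    v = dataset["velocity_nt_s"].to_numpy(float)
    sem_eff = np.where(np.isfinite(sem) & (sem > 0), sem, 0.02 * v)
    slopes = []
    for _ in range(n_bootstrap):
        df_b = dataset.copy()
        df_b["velocity_nt_s"] = np.maximum(rng.normal(v, sem_eff), 1e-6)
        try:
            slopes.append(_slope_from_mm(df_b, which))
        except (IdentifiabilityError, RuntimeError):
            continue
    if len(slopes) < 20:
        return SlopeTest(slope=slope, ci=(-np.inf, np.inf), significant=False)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return SlopeTest(slope=slope, ci=(float(lo), float(hi)),
                     significant=not (lo <= 0.0 <= hi))


def discriminate_models(dataset: pd.DataFrame, seed=None, n_starts: int = 8,
                        n_bootstrap: int = 200,
                        kBT: float = KBT_22C) -> ModelRanking:
    """Fit Models 1-3, rank by AIC and run the signature slope tests.

    A force-flat 1/V_max is the fingerprint of the binding power stroke; a
    force-flat K_M/V_max is the fingerprint of the PPi-release power stroke
    (when the reverse catalytic step is much slower than PPi release); the
    Brownian ratchet allows both to depend on load.
    """
    df = validate_dataset(dataset)
    rng = np.random.default_rng(seed)
    reports = {}
    for model in (1, 2, 3):
        reports[model] = global_fit(df, model=model, n_bootstrap=0,
                                    seed=rng, n_starts=n_starts, kBT=kBT)
    ranking = sorted(reports, key=lambda m: reports[m].aic)
    inv_vmax = km_over = None
    try:
        inv_vmax = _signature_slope(df, "inv_vmax", n_bootstrap, rng)
        km_over = _signature_slope(df, "km_over_vmax", n_bootstrap, rng)
    except IdentifiabilityError:
        pass
    return ModelRanking(reports=reports, ranking=ranking,
                        inv_vmax_slope=inv_vmax, km_over_vmax_slope=km_over)
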