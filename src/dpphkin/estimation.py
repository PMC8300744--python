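"""Rate-constant and stoichiometry estimation from DPPH* decay traces.

The measurement chain is: absorbance at 515 nm -> Beer-Lambert conversion
to [DPPH*] in M -> nonlinear least-squares fit of the kinetic scheme
(:mod:`dpphkin.kinetics`) -> rate constants k1 (and k2 for the
side-reaction model), the fitted initial antioxidant concentration
``aoh0_fit``, and the stoichiometric factor

    n = aoh0_fit / aoh_known,

the ratio of the antioxidant concentration the fit demands to the
concentration actually pipetted into the cuvette.  n counts how many DPPH*
radicals one antioxidant molecule quenches.

The fitting surface is the scikit-learn style :class:`DPPHKineticsEstimator`;
the module-level functions (`fit_kinetics`, `scan_integer_n`,
`select_model`, `fit_extract`, ...) are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .kinetics import (
    ConcentrationTrace,
    InitialState,
    RateParameters,
    TimeGrid,
    simulate_decay,
)

__all__ = [
    "AbsorbanceTrace",
    "AssayContext",
    "FitConfig",
    "FitResult",
    "ModelSelection",
    "RateConcentrationRegression",
    "ScanResult",
    "ExtractFit",
    "DPPHKineticsEstimator",
    "FitFailureError",
    "absorbance_to_concentration",
    "compute_r_squared",
    "fit_kinetics",
    "stoichiometric_factor_fitted",
    "stoichiometric_factor_graphical",
    "aggregate_n",
    "scan_integer_n",
    "select_model",
    "inverse_rate_regression",
    "fit_extract",
    "round_half_up",
]

#: default molar absorptivity of DPPH* in methanol at 515 nm, M^-1 cm^-1
DEFAULT_EPSILON = 10_870.0

#: additive floor used to fit k2 on a log scale while allowing k2 = 0
K2_LOG_FLOOR = 1e-3

#: practical significance floor for k2 in model selection, M^-1 s^-1
#: (below the smallest side-reaction rate constant seen in practice)
K2_SELECTION_FLOOR = 0.5


class FitFailureError(RuntimeError):
    """All optimizer starts failed to converge."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AbsorbanceTrace:
    """Raw 515 nm absorbance (AU) vs time (s) plus optical constants."""

    times: np.ndarray
    absorbance: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    path_length: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if t.shape != a.shape:
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.epsilon > 0 and self.path_length > 0):
            raise ValueError("epsilon and path_length must be positive")


@dataclass(frozen=True)
class AssayContext:
    """Nominal cuvette composition: initial DPPH* and antioxidant, in M."""

    dpph0_nominal: float
    aoh_known: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.dpph0_nominal > 0:
            raise ValueError("dpph0_nominal must be positive")
        if not self.aoh_known > 0:
            raise ValueError("aoh_known must be positive")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings shared by all fitting entry points.

    Bounds are in M^-1 s^-1 (rates) and as a multiple of the nominal
    antioxidant concentration (aoh0).  ``fix_dpph0=True`` pins the initial
    DPPH* concentration to the nominal value; otherwise it is read off the
    first data point, which absorbs mixing dead-time.
    """

    k1_bounds: tuple = (1.0, 1e8)
    k2_bounds: tuple = (0.0, 1e6)
    aoh0_max_factor: float = 20.0
    n_starts: int = 5
    seed: int = 0
    fix_dpph0: bool = True
    ftol: float = 1e-12
    xtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.k1_bounds[0] < 0 or self.k2_bounds[0] < 0:
            raise ValueError("lower bounds must be non-negative")
        if self.n_starts < 1:
            raise ValueError("need at least one optimizer start")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one kinetic fit."""

    model: str  # "simple" | "side"
    k1: float
    k2: Optional[float]
    aoh0_fit: float
    r_squared: float
    ssr: float
    residuals: np.ndarray
    n_fit: float
    n_points: int
    n_params: int
    success: bool = True
    message: str = ""


@dataclass(frozen=True)
class ModelSelection:
    """Nested-model comparison between the simple and side-reaction fits."""

    chosen: str
    f_statistic: float
    p_value: float
    r_squared_simple: float
    r_squared_side: float
    fit_simple: FitResult = field(repr=False, default=None)
    fit_side: FitResult = field(repr=False, default=None)


@dataclass(frozen=True)
class RateConcentrationRegression:
    """OLS of 1/k1 on antioxidant concentration (slope s/M^-1... per M)."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ScanResult:
    """Integer stoichiometry scan: best n and the per-candidate R^2 profile."""

    best_n: int
    r_squared_profile: dict
    fits: dict = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class ExtractFit:
    """Side-model fit of an extract trace, referenced to its phenol content.

    ``n_prime`` is the apparent stoichiometric factor: fitted effective
    antioxidant concentration over the Folin-Ciocalteu gallic-acid
    equivalent (GAE) concentration.
    """

    fit: FitResult
    aoh_folin: float
    n_prime: float


# ---------------------------------------------------------------------------
# elementary operations


def absorbance_to_concentration(trace: AbsorbanceTrace) -> ConcentrationTrace:
    """Beer-Lambert conversion A = eps*l*c, DPPH channel only.

    Negative absorbance points (baseline noise) are clipped to zero with a
    warning.
    """
    a = trace.absorbance
    if np.any(a < 0):
        warnings.warn("negative absorbance clipped to 0", stacklevel=2)
        a = np.clip(a, 0.0, None)
    c = a / (trace.epsilon * trace.path_length)
    z = np.zeros_like(c)
    return ConcentrationTrace(times=trace.times, dpph=c, aoh=z, ao=z, p2=z)


def compute_r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSR/SStot about the observed mean.

    Worse-than-mean predictions give negative values, which are reported
    as-is.  A constant observed series leaves R^2 undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length series with >= 2 points")
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("R^2 undefined: observed series is constant")
    ssr = float(np.sum((obs - pred) ** 2))
    return 1.0 - ssr / sstot


def stoichiometric_factor_fitted(aoh0_fit: float, aoh_known: float) -> float:
    """n = fitted initial antioxidant concentration / known concentration."""
    if not (aoh0_fit > 0 and aoh_known > 0):
        raise ValueError("concentrations must be positive")
    return aoh0_fit / aoh_known


def stoichiometric_factor_graphical(
    conc_trace: ConcentrationTrace,
    ctx: AssayContext,
    plateau_fraction: float = 0.01,
) -> float:
    """n from the trace directly: DPPH* loss over the known concentration.

    Emits a warning when the trace has not plateaued, judged by the final
    slope still exceeding ``plateau_fraction`` of the initial slope.
    """
    d = np.asarray(conc_trace.dpph, dtype=float)
    t = np.asarray(conc_trace.times, dtype=float)
    loss = d[0] - d[-1]
    slope0 = abs((d[1] - d[0]) / (t[1] - t[0]))
    slope_end = abs((d[-1] - d[-2]) / (t[-1] - t[-2]))
    if slope0 > 0 and slope_end > plateau_fraction * slope0:
        warnings.warn(
            "trace has not reached its plateau; graphical n underestimates",
            stacklevel=2,
        )
    return loss / ctx.aoh_known


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.05 -> 2.1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_n(per_concentration_n: Sequence[tuple]) -> float:
    """Panel-level n: mean of n_i at the two lowest antioxidant concentrations.

    Only the low-concentration end of a panel has DPPH* in sufficient excess
    for n to reflect stoichiometry rather than radical limitation, so the
    aggregate uses the two lowest concentrations only, rounded half-up to
    one decimal.
    """
    if len(per_concentration_n) < 2:
        raise ValueError("need n at >= 2 concentrations")
    lowest = sorted(per_concentration_n, key=lambda p: p[0])[:2]
    mean = sum(Decimal(str(n)) for _, n in lowest) / 2
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def inverse_rate_regression(pairs: Sequence[tuple]) -> RateConcentrationRegression:
    """OLS of 1/k1 on antioxidant concentration across a panel.

    The reciprocal of the observed rate constant grows linearly with the
    antioxidant concentration; the regression slope/intercept summarise
    that trend.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 (concentration, k1) pairs")
    conc = np.array([p[0] for p in pairs], dtype=float)
    k1 = np.array([p[1] for p in pairs], dtype=float)
    if np.any(k1 <= 0):
        raise ValueError("all k1 must be positive")
    res = stats.linregress(conc, 1.0 / k1)
    return RateConcentrationRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# the estimator


class DPPHKineticsEstimator(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the DPPH* kinetic scheme to a decay trace.

    Fits simulated [DPPH*](t) to an observed concentration trace.  Free
    parameters are (k1, aoh0) for ``model="simple"``, (k1, k2, aoh0) for
    ``model="side"``; ``model="auto"`` fits both and keeps the side model
    only when the nested F-test is significant and the fitted k2 exceeds
    its practical floor.  All parameters are optimised on a log10 scale
    within bounds, from ``n_starts`` Latin-hypercube starting points plus
    one heuristic start derived from the initial slope of the data.

    Parameters
    ----------
    model : {"simple", "side", "auto"}
        Reaction scheme to fit.
    dpph0 : float
        Nominal initial DPPH* concentration, M.
    aoh_known : float
        Nominal antioxidant concentration in the cuvette, M.  Scales the
        aoh0 search box and the reported stoichiometric factor.
    aoh0_fixed : float or None
        When set, aoh0 is pinned to this value (used by the integer-n
        scan) and only the rate constants are free.
    fix_dpph0 : bool
        Pin the simulated initial DPPH* to ``dpph0`` (default); otherwise
        start from the first observed point.
    k1_bounds, k2_bounds : tuple
        Search bounds, M^-1 s^-1.
    aoh0_max_factor : float
        Upper aoh0 bound as a multiple of ``aoh_known``.
    n_starts : int
        Number of optimizer starts.
    seed : int
        Seed for the Latin-hypercube start grid.
    alpha : float
        Significance level for the nested F-test under ``model="auto"``.

    Attributes
    ----------
    k1_ : float
        Fitted main rate constant, M^-1 s^-1.
    k2_ : float or None
        Fitted side-reaction rate constant (None for the simple model).
    aoh0_ : float
        Fitted initial antioxidant concentration, M.
    n_fit_ : float
        Stoichiometric factor aoh0_ / aoh_known.
    r_squared_, ssr_, residuals_ : goodness of fit on the training trace.
    model_ : str
        The scheme actually fitted ("simple" or "side").
    selection_ : ModelSelection
        Present only after ``model="auto"``.
    result_ : FitResult
        Frozen record of the fit.
    """

    def __init__(
        self,
        model: str = "simple",
        dpph0: float = 100e-6,
        aoh_known: float = 10e-6,
        aoh0_fixed: Optional[float] = None,
        fix_dpph0: bool = True,
        k1_bounds: tuple = (1.0, 1e8),
        k2_bounds: tuple = (0.0, 1e6),
        aoh0_max_factor: float = 20.0,
        n_starts: int = 5,
        seed: int = 0,
        alpha: float = 0.05,
        ftol: float = 1e-12,
        xtol: float = 1e-12,
    ):
        self.model = model
        self.dpph0 = dpph0
        self.aoh_known = aoh_known
        self.aoh0_fixed = aoh0_fixed
        self.fix_dpph0 = fix_dpph0
        self.k1_bounds = k1_bounds
        self.k2_bounds = k2_bounds
        self.aoh0_max_factor = aoh0_max_factor
        self.n_starts = n_starts
        self.seed = seed
        self.alpha = alpha
        self.ftol = ftol
        self.xtol = xtol

    # -- internal helpers ---------------------------------------------------

    @staticmethod
    def _as_times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a 1-column array of times")
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D times or a column vector")
        return t

    def _simulate(self, theta, kind, t, dpph0):
        """[DPPH*](t) for packed log10 parameters theta."""
        if kind == "simple":
            k1 = 10.0 ** theta[0]
            k2 = 0.0
            aoh0 = self.aoh0_fixed if self.aoh0_fixed is not None else 10.0 ** theta[-1]
        else:
            k1 = 10.0 ** theta[0]
            k2 = max(10.0 ** theta[1] - K2_LOG_FLOOR, 0.0)
            aoh0 = self.aoh0_fixed if self.aoh0_fixed is not None else 10.0 ** theta[-1]
        params = RateParameters(k1=k1, k2=k2, include_side=(kind == "side"))
        trace = simulate_decay(
            params, InitialState(dpph0=dpph0, aoh0=aoh0), TimeGrid(t)
        )
        return trace.dpph, (k1, k2, aoh0)

    def _bounds_and_starts(self, kind, y):
        """Log10 parameter box and the multi-start matrix."""
        lo_k1, hi_k1 = np.log10(max(self.k1_bounds[0], 1e-12)), np.log10(self.k1_bounds[1])
        lo_k2 = np.log10(K2_LOG_FLOOR)
        hi_k2 = np.log10(self.k2_bounds[1] + K2_LOG_FLOOR)
        lo_a = np.log10(self.aoh_known * 1e-3)
        hi_a = np.log10(self.aoh_known * self.aoh0_max_factor)

        fit_aoh0 = self.aoh0_fixed is None
        if kind == "simple":
            lo = [lo_k1] + ([lo_a] if fit_aoh0 else [])
            hi = [hi_k1] + ([hi_a] if fit_aoh0 else [])
        else:
            lo = [lo_k1, lo_k2] + ([lo_a] if fit_aoh0 else [])
            hi = [hi_k1, hi_k2] + ([hi_a] if fit_aoh0 else [])
        lo, hi = np.array(lo), np.array(hi)

        # heuristic start: initial slope ~ k1 * aoh_known * dpph0
        dpph0 = y[0] if not self.fix_dpph0 else self.dpph0
        aoh_guess = max((y[0] - y[-1]) / 2.0, self.aoh_known * 0.1)
        k1_guess = 1e3
        starts = [np.clip(
            np.array(
                [np.log10(k1_guess)]
                + ([np.log10(10.0 + K2_LOG_FLOOR)] if kind == "side" else [])
                + ([np.log10(aoh_guess)] if fit_aoh0 else [])
            ),
            lo, hi,
        )]
        if self.n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(lo), seed=self.seed)
            unit = sampler.random(self.n_starts - 1)
            for row in unit:
                starts.append(lo + row * (hi - lo))
        return (lo, hi), starts, dpph0

    def _fit_one_model(self, kind, t, y):
        (lo, hi), starts, dpph0 = self._bounds_and_starts(kind, y)

        def residuals(theta):
            pred, _ = self._simulate(theta, kind, t, dpph0)
            return pred - y

        best = None
        for x0 in starts:
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi),
                    ftol=self.ftol, xtol=self.xtol, gtol=1e-12,
                )
            except Exception:  # noqa: BLE001 - a diverged start is not fatal
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError(
                f"{kind} model: no optimizer start converged on this trace"
            )

        pred, (k1, k2, aoh0) = self._simulate(best.x, kind, t, dpph0)
        resid = y - pred
        ssr = float(np.sum(resid**2))
        try:
            r2 = compute_r_squared(y, pred)
        except ValueError:
            raise FitFailureError("degenerate trace: observed series is constant")
        if np.isclose(np.log10(k1), np.log10(self.k1_bounds[0]), atol=1e-6) or \
           np.isclose(np.log10(max(k1, 1e-300)), np.log10(self.k1_bounds[1]), atol=1e-6):
            warnings.warn("k1 pinned at a search bound", stacklevel=3)
        n_params = len(lo)
        return FitResult(
            model=kind,
            k1=k1,
            k2=(k2 if kind == "side" else None),
            aoh0_fit=aoh0,
            r_squared=r2,
            ssr=ssr,
            residuals=resid,
            n_fit=aoh0 / self.aoh_known,
            n_points=len(y),
            n_params=n_params,
            success=True,
            message=str(best.message),
        )

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        """Fit the scheme to times ``X`` (s) and observed [DPPH*] ``y`` (M)."""
        t = self._as_times(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y must have equal length")
        if t.size < 10:
            raise ValueError("need >= 10 time points to fit the scheme")

        if self.model == "auto":
            fit_s = self._fit_one_model("simple", t, y)
            fit_x = self._fit_one_model("side", t, y)
            sel = select_model(fit_s, fit_x, alpha=self.alpha)
            self.selection_ = sel
            res = fit_x if sel.chosen == "side" else fit_s
        elif self.model in ("simple", "side"):
            res = self._fit_one_model(self.model, t, y)
        else:
            raise ValueError(f"unknown model kind {self.model!r}")

        self.result_ = res
        self.model_ = res.model
        self.k1_ = res.k1
        self.k2_ = res.k2
        self.aoh0_ = res.aoh0_fit
        self.n_fit_ = res.n_fit
        self.r_squared_ = res.r_squared
        self.ssr_ = res.ssr
        self.residuals_ = res.residuals
        self.dpph0_used_ = self.dpph0 if self.fix_dpph0 else float(y[0])
        return self

    def predict(self, X):
        """Simulated [DPPH*] (M) at times ``X`` under the fitted parameters."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted yet")
        t = self._as_times(X)
        params = RateParameters(
            k1=self.k1_,
            k2=self.k2_ or 0.0,
            include_side=(self.model_ == "side"),
        )
        trace = simulate_decay(
            params,
            InitialState(dpph0=self.dpph0_used_, aoh0=self.aoh0_),
            TimeGrid(t),
        )
        return trace.dpph


# ---------------------------------------------------------------------------
# functional wrappers


def _estimator_from_config(ctx: AssayContext, model: str, cfg: FitConfig,
                           aoh0_fixed: Optional[float] = None) -> DPPHKineticsEstimator:
    return DPPHKineticsEstimator(
        model=model,
        dpph0=ctx.dpph0_nominal,
        aoh_known=ctx.aoh_known,
        aoh0_fixed=aoh0_fixed,
        fix_dpph0=cfg.fix_dpph0,
        k1_bounds=cfg.k1_bounds,
        k2_bounds=cfg.k2_bounds,
        aoh0_max_factor=cfg.aoh0_max_factor,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        ftol=cfg.ftol,
        xtol=cfg.xtol,
    )


def fit_kinetics(
    conc_trace: ConcentrationTrace,
    ctx: AssayContext,
    model: str = "simple",
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Fit the chosen scheme to a DPPH* concentration trace."""
    est = _estimator_from_config(ctx, model, cfg)
    est.fit(conc_trace.times, conc_trace.dpph)
    return est.result_


def select_model(
    fit_simple: FitResult,
    fit_side: FitResult,
    alpha: float = 0.05,
    k2_floor: float = K2_SELECTION_FLOOR,
) -> ModelSelection:
    """Choose between the nested schemes by an extra-sum-of-squares F-test.

    The side model (one extra parameter, k2) is kept only when the SSR
    reduction is statistically significant at ``alpha`` AND the fitted k2
    exceeds a practical floor; otherwise the simple scheme wins by
    parsimony.
    """
    n = fit_side.n_points
    df_extra = fit_side.n_params - fit_simple.n_params
    df_resid = n - fit_side.n_params
    if fit_simple.ssr > fit_side.ssr:
        f_stat = ((fit_simple.ssr - fit_side.ssr) / max(df_extra, 1)) / max(
            fit_side.ssr / df_resid, 1e-300
        )
    else:
        f_stat = 0.0
    p_value = float(stats.f.sf(f_stat, max(df_extra, 1), df_resid))
    k2_hat = fit_side.k2 or 0.0
    chosen = "side" if (p_value < alpha and k2_hat > k2_floor) else "simple"
    return ModelSelection(
        chosen=chosen,
        f_statistic=float(f_stat),
        p_value=p_value,
        r_squared_simple=fit_simple.r_squared,
        r_squared_side=fit_side.r_squared,
        fit_simple=fit_simple,
        fit_side=fit_side,
    )


def scan_integer_n(
    conc_trace: ConcentrationTrace,
    ctx: AssayContext,
    n_candidates: Sequence[int] = (1, 2, 3, 4, 5),
    cfg: FitConfig = FitConfig(),
) -> ScanResult:
    """Profile the integer stoichiometric factor under the side model.

    For each candidate n the initial antioxidant concentration is pinned at
    n * aoh_known and only (k1, k2) are refitted; the n with the highest
    R^2 wins.  Ties break toward the smaller n with a warning.
    """
    if len(n_candidates) == 0:
        raise ValueError("n_candidates must be non-empty")
    profile: dict = {}
    fits: dict = {}
    for n in sorted(n_candidates):
        est = _estimator_from_config(
            ctx, "side", cfg, aoh0_fixed=n * ctx.aoh_known
        )
        est.fit(conc_trace.times, conc_trace.dpph)
        profile[int(n)] = est.r_squared_
        fits[int(n)] = est.result_
    best_r2 = max(profile.values())
    winners = [n for n, r2 in profile.items() if r2 == best_r2]
    if len(winners) > 1:
        warnings.warn(f"R^2 tie among n={winners}; choosing the smallest",
                      stacklevel=2)
    return ScanResult(best_n=min(winners), r_squared_profile=profile, fits=fits)


def fit_extract(
    conc_trace: ConcentrationTrace,
    aoh_folin: float,
    cfg: FitConfig = FitConfig(),
    dpph0: float = 100e-6,
    label: str = "extract",
) -> ExtractFit:
    """Side-model fit of an extract treated as one effective antioxidant.

    ``aoh_folin`` is the total-phenol concentration in M GAE; the apparent
    stoichiometric factor n' references the fitted effective concentration
    to it.  Warns when the extract is too concentrated for the assay
    (above a quarter of the DPPH* concentration).
    """
    if not aoh_folin > 0:
        raise ValueError("aoh_folin must be positive")
    if aoh_folin > dpph0 / 4.0:
        warnings.warn(
            "extract phenol content exceeds 1/4 of the DPPH* concentration; "
            "dilute for a radical-excess assay",
            stacklevel=2,
        )
    ctx = AssayContext(dpph0_nominal=dpph0, aoh_known=aoh_folin, label=label)
    res = fit_kinetics(conc_trace, ctx, model="side", cfg=cfg)
    return ExtractFit(fit=res, aoh_folin=aoh_folin, n_prime=res.aoh0_fit / aoh_folin)
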