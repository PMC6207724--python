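"""Conformational-selection drug-binding kinetics.

The allosteric inhibitor binds only the closed conformation of SHP2:

    open  <-- k_open --  closed            (conformational exchange)
    open  -- k_close --> closed
    closed + L  -- k_on -->  closed.L      (bimolecular association)
    closed.L    -- k_off --> closed + L

``k_close`` is the open->closed rate, ``k_open`` the closed->open rate, so
``K_open_close = k_open / k_close = p_open / p_closed`` for the ligand-free
protein.  Because only the closed fraction is binding competent, the
apparent (observed) dissociation constant is diluted relative to the
intrinsic one:

    K_D_obs = (K_open_close + 1) * k_off / k_on.

Stopped-flow relaxation traces under pseudo-first-order conditions are
biexponential; the two observed rates are the non-zero eigenvalues of the
linearised three-state scheme (``eigen_rates``).  In the limit where
binding is much faster than exchange, the fast phase is approximately
linear in ligand with observed slope ``k_on / (K_open_close + 1)``
(``pseudo_fast_rate``) and the slow phase follows a hyperbola whose
plateau is ``k_close`` (``pseudo_slow_rate``); those two approximations
are the field's standard route from measured rates to the microscopic
constants and are implemented alongside the exact eigenvalues, which serve
as their oracle.

Units: concentrations in uM, time in seconds, rates in s^-1 or uM^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .errors import (
    DataInconsistencyError,
    FitError,
    InsufficientDataError,
    SolverError,
    UnidentifiableError,
)

#: Default per-species fluorescence coefficients (arbitrary units per uM).
#: Tryptophan emission is partially quenched on closing and further on
#: drug binding; the actual values are free parameters of the forward model.
DEFAULT_FLUOROPHORE_WEIGHTS = {"open": 1.0, "closed": 0.85, "complex": 0.45}

#: Ligand excess over protein above which pseudo-first-order analysis is valid.
PSEUDO_FIRST_ORDER_RATIO = 10.0


@dataclass(frozen=True)
class ConfSelScheme:
    """Microscopic rate constants of the conformational-selection scheme.

    ``ses`` optionally carries standard errors keyed by field name.
    """

    k_open: float   # closed -> open, s^-1
    k_close: float  # open -> closed, s^-1
    k_on: float     # intrinsic association to the closed state, uM^-1 s^-1
    k_off: float    # dissociation from the complex, s^-1
    ses: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("k_open", "k_close", "k_on", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def K_open_close(self) -> float:
        return self.k_open / self.k_close

    @property
    def p_open(self) -> float:
        return self.K_open_close / (1.0 + self.K_open_close)

    @property
    def p_closed(self) -> float:
        return 1.0 / (1.0 + self.K_open_close)

    @property
    def K_D(self) -> float:
        """Intrinsic dissociation constant of the closed state, uM."""
        return self.k_off / self.k_on

    @property
    def K_D_obs(self) -> float:
        """Apparent dissociation constant diluted by the open fraction, uM."""
        return (self.K_open_close + 1.0) * self.K_D


@dataclass
class Trace:
    """One stopped-flow fluorescence trace."""

    time: np.ndarray    # seconds, strictly increasing
    signal: np.ndarray  # arbitrary fluorescence units
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 20:
            raise ValueError("a trace needs at least 20 points")
        if self.time.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if self.time[0] < 0:
            raise ValueError("time must start at >= 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class ExpFit:
    """Result of a 1- or 2-exponential fit, rates sorted descending."""

    n_phases: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    drift: float | None
    cov: np.ndarray | None
    ssr: float
    aic: float
    n_points: int

    @property
    def residual_sd(self) -> float:
        n_par = 1 + 2 * self.n_phases + (1 if self.drift is not None else 0)
        dof = max(self.n_points - n_par, 1)
        return math.sqrt(self.ssr / dof)

    @property
    def rate_ses(self) -> np.ndarray:
        """Standard errors of the rates, from the fit covariance."""
        if self.cov is None:
            return np.full(self.n_phases, np.nan)
        # parameter layout: offset, (a_i, k_i) pairs, [drift]
        idx = [2 + 2 * i for i in range(self.n_phases)]
        return np.sqrt(np.diag(self.cov)[idx])

    def model(self, t: np.ndarray) -> np.ndarray:
        y = np.full_like(np.asarray(t, dtype=float), self.offset)
        for a, k in zip(self.amplitudes, self.rates):
            y = y + a * np.exp(-k * np.asarray(t, dtype=float))
        if self.drift is not None:
            y = y + self.drift * np.asarray(t, dtype=float)
        return y


@dataclass
class RateVsConc:
    """Observed relaxation rates versus ligand concentration."""

    ligand_conc: np.ndarray
    k_fast: np.ndarray
    k_fast_se: np.ndarray | None = None
    k_slow: np.ndarray | None = None
    k_slow_se: np.ndarray | None = None
    protein_conc: float | None = None

    def __post_init__(self):
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.k_fast = np.asarray(self.k_fast, dtype=float)
        if np.any(self.ligand_conc <= 0):
            raise ValueError("ligand concentrations must be positive")
        for name in ("k_fast_se", "k_slow", "k_slow_se"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def pseudo_first_order(self) -> bool:
        if self.protein_conc is None:
            return True
        return bool(
            np.all(self.ligand_conc >= PSEUDO_FIRST_ORDER_RATIO * self.protein_conc)
        )


# ---------------------------------------------------------------------------
# Forward model: mass-action ODE of the three-state scheme
# ---------------------------------------------------------------------------

def equilibrium_species(scheme: ConfSelScheme, protein_0: float, ligand_0: float):
    """Analytic equilibrium of open/closed/complex/free ligand, in uM.

    The binding-competent pool behaves as a single site with affinity
    ``K_D_obs``; the bound complex follows the standard quadratic solution,
    and the free protein splits between open and closed by ``K_open_close``.
    """
    kd_obs = scheme.K_D_obs
    s = protein_0 + ligand_0 + kd_obs
    complex_eq = 0.5 * (s - math.sqrt(s * s - 4.0 * protein_0 * ligand_0))
    free_protein = protein_0 - complex_eq
    closed = free_protein * scheme.p_closed
    opened = free_protein * scheme.p_open
    return {
        "open": opened,
        "closed": closed,
        "complex": complex_eq,
        "ligand": ligand_0 - complex_eq,
    }


def simulate_scheme(
    scheme: ConfSelScheme,
    protein_0: float,
    ligand_0: float,
    fluorophore_weights: dict | None = None,
    t_grid: np.ndarray | None = None,
    initial_species: dict | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    return_species: bool = False,
):
    """Integrate the full nonlinear binding scheme and report a trace.

    The protein starts at its ligand-free open/closed equilibrium (unless
    ``initial_species`` overrides it, e.g. for dilution experiments) and is
    mixed with ligand at t = 0.  Ligand depletion is modelled explicitly.
    The signal is the weighted sum of species concentrations.
    """
    if protein_0 < 0 or ligand_0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    weights = dict(DEFAULT_FLUOROPHORE_WEIGHTS)
    if fluorophore_weights:
        weights.update(fluorophore_weights)
    if t_grid is None:
        slowest = min(scheme.k_open, scheme.k_close, scheme.k_off)
        t_grid = np.linspace(0.0, 5.0 / slowest, 500)
    t_grid = np.asarray(t_grid, dtype=float)

    if initial_species is None:
        y0 = [scheme.p_open * protein_0, scheme.p_closed * protein_0, 0.0, ligand_0]
    else:
        y0 = [
            initial_species.get("open", 0.0),
            initial_species.get("closed", 0.0),
            initial_species.get("complex", 0.0),
            initial_species.get("ligand", 0.0),
        ]
    protein_tot = y0[0] + y0[1] + y0[2]
    ligand_tot = y0[2] + y0[3]

    def rhs(_t, y):
        o, c, cl, l = y
        bind = scheme.k_on * c * l
        unbind = scheme.k_off * cl
        do = -scheme.k_close * o + scheme.k_open * c
        dc = scheme.k_close * o - scheme.k_open * c - bind + unbind
        dcl = bind - unbind
        dl = -bind + unbind
        return [do, dc, dcl, dl]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    o, c, cl, l = sol.y
    scale = max(protein_tot, 1e-30)
    if np.max(np.abs(o + c + cl - protein_tot)) > 1e-9 * scale:
        raise SolverError("protein conservation violated beyond 1e-9 relative")
    lscale = max(ligand_tot, 1e-30)
    if ligand_tot > 0 and np.max(np.abs(cl + l - ligand_tot)) > 1e-9 * lscale:
        raise SolverError("ligand conservation violated beyond 1e-9 relative")
    signal = weights["open"] * o + weights["closed"] * c + weights["complex"] * cl
    trace = Trace(
        time=t_grid,
        signal=signal,
        meta={
            "protein_uM": protein_tot,
            "ligand_uM": ligand_tot,
            "weights": weights,
        },
    )
    if return_species:
        return trace, {"open": o, "closed": c, "complex": cl, "ligand": l}
    return trace


# ---------------------------------------------------------------------------
# Relaxation rates of the linearised (pseudo-first-order) scheme
# ---------------------------------------------------------------------------

def eigen_rates(scheme: ConfSelScheme, ligand: float):
    """Exact relaxation rates at constant (pseudo-first-order) ligand.

    The 3x3 rate matrix over (open, closed, complex) has one zero eigenvalue
    (conservation); the magnitudes of the other two satisfy

        sum     = k_open + k_close + k_on*L + k_off
        product = k_close * k_on*L + (k_close + k_open) * k_off

    and are returned as ``(lambda_fast, lambda_slow)`` from the closed-form
    quadratic.
    """
    if ligand < 0:
        raise ValueError("ligand concentration must be non-negative")
    kl = scheme.k_on * ligand
    s = scheme.k_open + scheme.k_close + kl + scheme.k_off
    p = scheme.k_close * kl + (scheme.k_close + scheme.k_open) * scheme.k_off
    disc = max(s * s - 4.0 * p, 0.0)
    root = math.sqrt(disc)
    lam_fast = 0.5 * (s + root)
    lam_slow = 0.5 * (s - root)
    return lam_fast, lam_slow


def pseudo_fast_rate(scheme: ConfSelScheme, ligand) -> np.ndarray:
    """Fast-phase approximation: ``k_on/(K_open_close + 1) * L + k_off``."""
    ligand = np.asarray(ligand, dtype=float)
    return scheme.k_on / (scheme.K_open_close + 1.0) * ligand + scheme.k_off


def pseudo_slow_rate(scheme: ConfSelScheme, ligand) -> np.ndarray:
    """Slow-phase approximation: hyperbola in L with plateau ``k_close``.

        k_slow(L) = (k_close * L + C * k_off) / (C + L),
        C = (k_close + k_open) / k_on.
    """
    ligand = np.asarray(ligand, dtype=float)
    c = (scheme.k_close + scheme.k_open) / scheme.k_on
    return (scheme.k_close * ligand + c * scheme.k_off) / (c + ligand)


# ---------------------------------------------------------------------------
# Exponential trace fitting
# ---------------------------------------------------------------------------

def _exp_model(n_phases: int, allow_drift: bool) -> Callable:
    if n_phases == 1:
        if allow_drift:
            return lambda t, c, a1, k1, m: c + a1 * np.exp(-k1 * t) + m * t
        return lambda t, c, a1, k1: c + a1 * np.exp(-k1 * t)
    if allow_drift:
        return (
            lambda t, c, a1, k1, a2, k2, m: c
            + a1 * np.exp(-k1 * t)
            + a2 * np.exp(-k2 * t)
            + m * t
        )
    return lambda t, c, a1, k1, a2, k2: c + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def fit_exponentials(
    trace: Trace,
    n_phases: int = 2,
    allow_drift: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> ExpFit:
    """Least-squares multi-exponential fit with multi-start initialisation.

    Rate starting values are log-spaced across the decades bracketed by the
    trace's sampling interval and total span; the best of all converged
    starts (by SSR) is returned with its covariance and AIC.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.time, trace.signal
    n_par = 1 + 2 * n_phases + (1 if allow_drift else 0)
    if t.size < 5 * n_par:
        raise InsufficientDataError(
            f"need >= {5 * n_par} points for a {n_phases}-phase fit, got {t.size}"
        )
    model = _exp_model(n_phases, allow_drift)
    span = t[-1] - t[0]
    dt = np.min(np.diff(t))
    k_lo, k_hi = 0.5 / span, 0.5 / dt
    k_seeds = np.geomspace(k_lo, k_hi, n_starts)
    amp = y[0] - y[-1]
    if amp == 0.0:
        amp = max(np.ptp(y), 1e-12)
    offset0 = y[-1]
    lower = [-np.inf] + [-np.inf, 1e-8] * n_phases + ([-np.inf] if allow_drift else [])
    upper = [np.inf] * n_par

    best = None
    rng = np.random.default_rng(seed)
    for ks in k_seeds:
        if n_phases == 1:
            p0 = [offset0, amp, ks]
        else:
            p0 = [offset0, 0.7 * amp, ks, 0.3 * amp, ks / (8.0 * (1 + rng.random()))]
        if allow_drift:
            p0.append(0.0)
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError(f"{n_phases}-phase exponential fit did not converge")
    popt, pcov, ssr = best
    offset = popt[0]
    amps = np.array([popt[1 + 2 * i] for i in range(n_phases)])
    rates = np.array([popt[2 + 2 * i] for i in range(n_phases)])
    drift = popt[-1] if allow_drift else None
    order = np.argsort(rates)[::-1]
    amps, rates = amps[order], rates[order]
    # reorder covariance to match the sorted phases
    perm = [0]
    for i in order:
        perm.extend([1 + 2 * i, 2 + 2 * i])
    if allow_drift:
        perm.append(n_par - 1)
    pcov = pcov[np.ix_(perm, perm)]
    n = t.size
    aic = n * math.log(max(ssr, 1e-300) / n) + 2 * n_par
    return ExpFit(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        offset=float(offset),
        drift=None if drift is None else float(drift),
        cov=pcov,
        ssr=ssr,
        aic=aic,
        n_points=n,
    )


def select_phase_count(
    trace: Trace, allow_drift: bool = False, seed: int = 0
) -> int:
    """Choose 1 vs 2 exponential phases.

    Two phases are selected when AIC favours them *and* the extra phase is
    physically resolvable: the two rates differ by at least threefold, or
    the smaller phase amplitude exceeds three times the residual noise.
    """
    fit1 = fit_exponentials(trace, 1, allow_drift=allow_drift, seed=seed)
    try:
        fit2 = fit_exponentials(trace, 2, allow_drift=allow_drift, seed=seed)
    except (FitError, InsufficientDataError):
        return 1
    if fit2.aic >= fit1.aic:
        return 1
    if fit2.rates[1] <= 0 or fit2.rates[0] / fit2.rates[1] < 1.0 + 1e-3:
        return 1
    ratio_ok = fit2.rates[0] / fit2.rates[1] >= 3.0
    amp_ok = np.min(np.abs(fit2.amplitudes)) > 3.0 * fit2.residual_sd
    return 2 if (ratio_ok or amp_ok) else 1


# ---------------------------------------------------------------------------
# Microscopic rate constants from rate-versus-concentration data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastPhaseFit:
    k_on: float          # true (intrinsic) on-rate, uM^-1 s^-1
    k_on_se: float
    k_off: float         # intercept, s^-1
    k_off_se: float
    slope_obs: float     # observed slope before the population correction
    slope_obs_se: float


@dataclass(frozen=True)
class SlowPhaseFit:
    k_close: float
    k_close_se: float
    k_open: float
    k_open_se: float


def _weighted_line(x: np.ndarray, y: np.ndarray, se: np.ndarray | None):
    """Weighted least-squares line fit; returns slope, intercept and SEs."""
    if se is not None and np.all(se > 0):
        w = 1.0 / se**2
        scale_by_chi2 = False
    else:
        w = np.ones_like(x)
        scale_by_chi2 = True
    sw = np.sum(w)
    sx = np.sum(w * x)
    sxx = np.sum(w * x * x)
    sy = np.sum(w * y)
    sxy = np.sum(w * x * y)
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    var_slope = sw / det
    var_intercept = sxx / det
    if scale_by_chi2:
        resid = y - slope * x - intercept
        dof = max(x.size - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        var_slope *= s2
        var_intercept *= s2
    return slope, intercept, math.sqrt(var_slope), math.sqrt(var_intercept)


def fit_fast_phase(
    data: RateVsConc,
    k_open_close: float,
    k_open_close_se: float = 0.0,
) -> FastPhaseFit:
    """Extract the true on-rate and off-rate from the fast phase.

    The fast-phase rates are linear in ligand with observed slope
    ``k_on / (K_open_close + 1)``; the true ``k_on`` is recovered by
    multiplying the slope by ``(K_open_close + 1)`` and the intercept is
    ``k_off``.  Weighted by inverse variance when SEs are available.
    """
    if data.ligand_conc.size < 3:
        raise InsufficientDataError("fast-phase fit needs >= 3 concentrations")
    slope, intercept, slope_se, intercept_se = _weighted_line(
        data.ligand_conc, data.k_fast, data.k_fast_se
    )
    if slope <= 0:
        raise DataInconsistencyError(
            f"fast-phase rates decrease with ligand (slope {slope:.4g})"
        )
    factor = k_open_close + 1.0
    k_on = slope * factor
    # first-order propagation including the equilibrium-constant uncertainty
    k_on_se = math.hypot(slope_se * factor, slope * k_open_close_se)
    return FastPhaseFit(
        k_on=k_on,
        k_on_se=k_on_se,
        k_off=float(intercept),
        k_off_se=float(intercept_se),
        slope_obs=float(slope),
        slope_obs_se=float(slope_se),
    )


def fit_slow_phase(data: RateVsConc, k_on: float, k_off: float) -> SlowPhaseFit:
    """Fit the slow-phase hyperbola for the closing (and opening) rate.

    With ``k_on`` and ``k_off`` fixed from the fast phase, the slow-phase
    rates follow a hyperbola whose plateau is ``k_close`` and whose
    half-saturation constant is ``(k_close + k_open)/k_on``.
    """
    if data.k_slow is None:
        raise InsufficientDataError("no slow-phase rates supplied")
    x = data.ligand_conc
    y = np.asarray(data.k_slow, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("slow-phase fit needs >= 4 concentrations")
    rel_range = (np.max(y) - np.min(y)) / max(np.max(y), 1e-30)
    if rel_range < 0.01:
        raise UnidentifiableError(
            "slow-phase rates show no curvature; closing rate unidentifiable"
        )

    def model(conc, k_close, k_open):
        c = (k_close + k_open) / k_on
        return (k_close * conc + c * k_off) / (c + conc)

    sigma = data.k_slow_se if (
        data.k_slow_se is not None and np.all(data.k_slow_se > 0)
    ) else None
    kc0 = float(np.max(y))
    best = None
    # the SSR surface can trap a single start; seed k_open across decades
    for ko0 in (1e-3 * kc0, 1e-2 * kc0, 0.1 * kc0, 0.5 * kc0, 2.0 * kc0):
        try:
            popt, pcov = curve_fit(
                model,
                x,
                y,
                p0=[kc0, ko0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=([1e-10, 1e-10], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError("slow-phase hyperbola fit failed to converge")
    popt, pcov, _ = best
    ses = np.sqrt(np.diag(pcov))
    return SlowPhaseFit(
        k_close=float(popt[0]),
        k_close_se=float(ses[0]),
        k_open=float(popt[1]),
        k_open_se=float(ses[1]),
    )


def fit_dissociation(
    trace: Trace, allow_drift: bool = False, seed: int = 0
):
    """Off-rate from a dilution-chase trace by single-exponential fit.

    Rebinding after dilution is neglected (valid when the post-dilution
    ligand concentration is well below ``K_D_obs``); the simulator can be
    used to quantify the resulting bias in other regimes.

    Returns ``(k_off, k_off_se)``.
    """
    fit = fit_exponentials(trace, 1, allow_drift=allow_drift, seed=seed)
    return float(fit.rates[0]), float(fit.rate_ses[0])


# ---------------------------------------------------------------------------
# Apparent affinity with uncertainty propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApparentKd:
    value: float      # uM
    se_delta: float   # first-order (delta-method) propagation
    se_mc: float      # seeded Monte-Carlo resampling


def apparent_kd_from(
    k_on: float,
    k_off: float,
    k_open_close: float,
    k_on_se: float = 0.0,
    k_off_se: float = 0.0,
    k_open_close_se: float = 0.0,
    n_mc: int = 20000,
    seed: int = 0,
) -> ApparentKd:
    """Apparent dissociation constant ``(K_open_close + 1) * k_off / k_on``.

    Uncertainty is propagated both to first order and by Monte-Carlo
    resampling of the inputs (Gaussian, truncated at zero), as a cross-check.
    """
    if k_on <= 0 or k_off <= 0 or k_open_close < 0:
        raise ValueError("rates must be positive and K_open_close non-negative")
    value = (k_open_close + 1.0) * k_off / k_on
    g_on = -value / k_on
    g_off = value / k_off
    g_k = k_off / k_on
    se_delta = math.sqrt(
        (g_on * k_on_se) ** 2 + (g_off * k_off_se) ** 2 + (g_k * k_open_close_se) ** 2
    )
    rng = np.random.default_rng(seed)
    draws_on = np.abs(rng.normal(k_on, k_on_se, n_mc))
    draws_off = np.abs(rng.normal(k_off, k_off_se, n_mc))
    draws_k = np.abs(rng.normal(k_open_close, k_open_close_se, n_mc))
    samples = (draws_k + 1.0) * draws_off / np.maximum(draws_on, 1e-30)
    se_mc = float(np.std(samples, ddof=1))
    return ApparentKd(value=float(value), se_delta=se_delta, se_mc=se_mc)


def apparent_kd(scheme: ConfSelScheme, n_mc: int = 20000, seed: int = 0) -> ApparentKd:
    """Apparent affinity of a scheme, using its stored standard errors."""
    k = scheme.K_open_close
    se = scheme.ses
    k_se = 0.0
    if "k_open" in se or "k_close" in se:
        k_se = k * math.hypot(
            se.get("k_open", 0.0) / scheme.k_open,
            se.get("k_close", 0.0) / scheme.k_close,
        )
    return apparent_kd_from(
        scheme.k_on,
        scheme.k_off,
        k,
        k_on_se=se.get("k_on", 0.0),
        k_off_se=se.get("k_off", 0.0),
        k_open_close_se=k_se,
        n_mc=n_mc,
        seed=seed,
    )


def average_traces(traces: Sequence[Trace]) -> Trace:
    """Average replicate traces on their common time grid."""
    if not traces:
        raise InsufficientDataError("no traces to average")
    t0 = traces[0].time
    for tr in traces[1:]:
        if tr.time.size != t0.size or not np.allclose(tr.time, t0):
            raise ValueError("replicate traces must share one time grid")
    signal = np.mean([tr.signal for tr in traces], axis=0)
    meta = dict(traces[0].meta)
    meta["n_averaged"] = len(traces)
    return Trace(time=t0.copy(), signal=signal, meta=meta)
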