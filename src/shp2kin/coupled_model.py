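"""Steady-state coupling of open/close exchange, catalysis and drug binding.

Full-length SHP2 partitions between a catalytically silent closed state and
an open state carrying the active phosphatase engine:

    closed  <-- k_close --  open
    closed  -- k_open  -->  open
    open + S <-> ES <-> ESS        (two-site sequential engine, turnover
                                    kcat1 from ES and kcat2 from ESS)
    closed + D <-> closed.D        (allosteric inhibitor sequesters the
                                    closed conformer, intrinsic K_D)

The observed per-enzyme turnover is the steady state of this linear scheme
(substrate and drug held constant).  Because the closed state exchanges
only with free open enzyme, the steady-state flux balance pins
``[closed]/[open] = k_close/k_open`` regardless of how slow the exchange
is; substrate occupancy of the open manifold therefore *depletes* the total
closed fraction, and the suppression of activity relative to the free
engine is bounded above by ``1/p_open``, approached at low occupancy.

Two independent solvers are provided — a direct linear (null-space) solve
and ODE relaxation — and must agree; the ODE route doubles as a check that
the algebraic steady state is the long-time limit of the kinetics.

Units: concentrations in uM, time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .binding_kinetics import ConfSelScheme
from .enzyme_kinetics import TwoSiteParams, two_site_rate
from .errors import SolverError

#: Default association rate of substrate to either site, uM^-1 s^-1.
#: The engine's rate law treats substrate binding as a rapid equilibrium,
#: so the default keeps association far faster than turnover
#: (k_off = k_on * K_D >> kcat); lower it to probe binding-limited regimes,
#: where the effective Michaelis constant (k_off + kcat)/k_on exceeds K_D.
DEFAULT_SUBSTRATE_ON_RATE = 1000.0


def default_engine() -> TwoSiteParams:
    """Illustrative fully-open engine (PTP-domain-like) parameters.

    Chosen so the engine turns over at ~261 s^-1 at 500 uM substrate with a
    clear partial-substrate-inhibition signature.  This fixture is
    synthetic — it stands in for engine constants that are not published in
    a reusable form and is not a measured set.
    """
    return TwoSiteParams(kcat1=370.0, kcat2=185.0, kd1=110.0, kd2=800.0)


@dataclass(frozen=True)
class CoupledConfig:
    """Configuration of the coupled exchange-plus-catalysis scheme.

    ``k_open_close`` is the canonical equilibrium constant
    ``k_open / k_close = p_open / p_closed`` (direction: open over closed);
    its reciprocal ``K_close_open`` is exposed as a property for interfaces
    quoted in the opposite direction.
    """

    engine: TwoSiteParams
    k_open_close: float
    k_close: float = 5.8          # open -> closed at 35 C, s^-1
    drug: ConfSelScheme | None = None
    enzyme_uM: float = 0.01
    s_on1: float = DEFAULT_SUBSTRATE_ON_RATE
    s_on2: float = DEFAULT_SUBSTRATE_ON_RATE
    temperature: str = "35C"

    def __post_init__(self):
        if self.k_open_close <= 0 or self.k_close <= 0:
            raise ValueError("k_open_close and k_close must be positive")
        if self.enzyme_uM < 0 or self.s_on1 <= 0 or self.s_on2 <= 0:
            raise ValueError("concentrations/on-rates must be positive")

    @property
    def k_open(self) -> float:
        return self.k_open_close * self.k_close

    @property
    def K_close_open(self) -> float:
        return 1.0 / self.k_open_close

    @property
    def p_open(self) -> float:
        return self.k_open_close / (1.0 + self.k_open_close)

    @classmethod
    def from_close_open(cls, engine: TwoSiteParams, k_close_open: float, **kw):
        """Construct from the closed-over-open equilibrium constant."""
        return cls(engine=engine, k_open_close=1.0 / k_close_open, **kw)


@dataclass(frozen=True)
class ActivityPrediction:
    """Steady-state turnover and species fractions at one condition."""

    substrate: float
    drug: float
    k_obs: float                   # per-enzyme turnover, s^-1
    fractions: dict = field(default_factory=dict)

    @property
    def p_open_manifold(self) -> float:
        """Fraction of enzyme in the open (substrate-accessible) manifold."""
        return (
            self.fractions.get("open", 0.0)
            + self.fractions.get("ES", 0.0)
            + self.fractions.get("ESS", 0.0)
        )


# state order: closed, closed.D, open, ES, ESS
_STATES = ("closed", "closed_drug", "open", "ES", "ESS")


def _rate_matrix(config: CoupledConfig, substrate: float, drug_free: float):
    """First-order rate matrix M with d(x)/dt = M x over the five states."""
    eng = config.engine
    koff1 = config.s_on1 * eng.kd1
    koff2 = config.s_on2 * eng.kd2
    if config.drug is not None:
        d_on = config.drug.k_on * drug_free
        d_off = config.drug.k_off
    else:
        # no drug arm: the closed.D state only drains, keeping the system
        # non-singular while its steady-state population is exactly zero
        d_on, d_off = 0.0, 1.0
    b1 = config.s_on1 * substrate
    b2 = config.s_on2 * substrate
    m = np.zeros((5, 5))
    # closed
    m[0, 0] = -(config.k_open + d_on)
    m[0, 1] = d_off
    m[0, 2] = config.k_close
    # closed.D
    m[1, 0] = d_on
    m[1, 1] = -d_off
    # open  (catalysis from ES returns enzyme here with product release)
    m[2, 0] = config.k_open
    m[2, 2] = -(config.k_close + b1)
    m[2, 3] = koff1 + eng.kcat1
    # ES    (catalysis from ESS regenerates ES)
    m[3, 2] = b1
    m[3, 3] = -(koff1 + eng.kcat1 + b2)
    m[3, 4] = koff2 + eng.kcat2
    # ESS
    m[4, 3] = b2
    m[4, 4] = -(koff2 + eng.kcat2)
    return m


def _solve_algebraic(m: np.ndarray) -> np.ndarray:
    a = m.copy()
    a[-1, :] = 1.0
    b = np.zeros(m.shape[0])
    b[-1] = 1.0
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise SolverError(f"singular steady-state system: {exc}") from exc
    if np.any(x < -1e-9):
        raise SolverError("negative steady-state population")
    return np.clip(x, 0.0, None)


def _solve_relaxation(m: np.ndarray, config: CoupledConfig) -> np.ndarray:
    x0 = np.zeros(m.shape[0])
    x0[0] = config.k_close / (config.k_open + config.k_close)
    x0[2] = 1.0 - x0[0]
    t_end = 100.0 / min(config.k_open, config.k_close)
    for _ in range(4):
        sol = solve_ivp(
            lambda _t, x: m @ x,
            (0.0, t_end),
            x0,
            method="Radau",
            rtol=1e-8,
            atol=1e-14,
            jac=lambda _t, _x: m,
        )
        if not sol.success:
            raise SolverError(f"steady-state relaxation failed: {sol.message}")
        x0 = sol.y[:, -1]
        if np.max(np.abs(m @ x0)) < 1e-8:
            break
        t_end *= 10.0
    total = x0.sum()
    return np.clip(x0 / total, 0.0, None)


def steady_state_activity(
    config: CoupledConfig,
    substrate: float,
    drug_free: float = 0.0,
    method: str = "algebraic",
) -> ActivityPrediction:
    """Per-enzyme turnover at steady state for a fixed substrate (uM).

    ``method`` is ``"algebraic"`` (direct linear solve, default) or
    ``"ode"`` (relaxation of the kinetic equations); the two must agree and
    the second serves as an independent route in tests.
    """
    if substrate < 0 or drug_free < 0:
        raise ValueError("substrate and drug must be non-negative")
    m = _rate_matrix(config, substrate, drug_free)
    if method == "algebraic":
        x = _solve_algebraic(m)
    elif method == "ode":
        x = _solve_relaxation(m, config)
    else:
        raise ValueError("method must be 'algebraic' or 'ode'")
    if abs(x.sum() - 1.0) > 1e-9:
        raise SolverError("species fractions do not sum to 1")
    fractions = {name: float(v) for name, v in zip(_STATES, x)}
    k_obs = config.engine.kcat1 * fractions["ES"] + config.engine.kcat2 * fractions["ESS"]
    return ActivityPrediction(
        substrate=float(substrate),
        drug=float(drug_free),
        k_obs=float(k_obs),
        fractions=fractions,
    )


def simulate_fulllength_curves(
    config_a: CoupledConfig,
    config_b: CoupledConfig,
    substrate_grid,
) -> dict:
    """Predicted activity curves for two landscapes plus the free engine.

    Returns per-substrate predicted ``k_obs`` for both configurations, the
    fully open engine rate, and the fold-suppression of each protein
    relative to the engine.
    """
    grid = np.asarray(substrate_grid, dtype=float)
    k_a = np.array([steady_state_activity(config_a, s).k_obs for s in grid])
    k_b = np.array([steady_state_activity(config_b, s).k_obs for s in grid])
    # reference: the same kinetic engine held fully open, so suppression
    # isolates the conformational equilibrium from binding-speed effects
    open_cfg = CoupledConfig(
        engine=config_a.engine,
        k_open_close=1e9,
        k_close=config_a.k_close,
        s_on1=config_a.s_on1,
        s_on2=config_a.s_on2,
    )
    engine = np.array([steady_state_activity(open_cfg, s).k_obs for s in grid])
    with np.errstate(divide="ignore", invalid="ignore"):
        supp_a = np.where(k_a > 0, engine / k_a, np.inf)
        supp_b = np.where(k_b > 0, engine / k_b, np.inf)
    return {
        "substrate": grid,
        "k_obs_a": k_a,
        "k_obs_b": k_b,
        "engine": engine,
        "suppression_a": supp_a,
        "suppression_b": supp_b,
    }


# ---------------------------------------------------------------------------
# Inhibition
# ---------------------------------------------------------------------------

def _activity_at_total_dose(
    config: CoupledConfig, substrate: float, dose_total: float
) -> ActivityPrediction:
    """Steady state at a total drug dose, accounting for free-drug depletion."""
    if config.drug is None:
        raise ValueError("config has no drug binding arm")
    if dose_total == 0.0:
        return steady_state_activity(config, substrate, 0.0)
    e_tot = config.enzyme_uM

    def bound(d_free: float) -> float:
        pred = steady_state_activity(config, substrate, d_free)
        return e_tot * pred.fractions["closed_drug"]

    if e_tot <= 0:
        d_free = dose_total
    else:
        def gap(d_free: float) -> float:
            return d_free + bound(d_free) - dose_total

        d_free = brentq(gap, 0.0, dose_total, xtol=1e-14, rtol=1e-12)
    pred = steady_state_activity(config, substrate, d_free)
    return ActivityPrediction(
        substrate=pred.substrate,
        drug=dose_total,
        k_obs=pred.k_obs,
        fractions=pred.fractions,
    )


@dataclass(frozen=True)
class InhibitionCurve:
    doses: np.ndarray
    activity: np.ndarray
    basal: float
    ic50: float

    @property
    def pct_inhibition(self) -> np.ndarray:
        return 100.0 * (1.0 - self.activity / self.basal)


def inhibition_curve(
    config: CoupledConfig,
    dose_grid,
    substrate: float,
) -> InhibitionCurve:
    """Activity versus total drug dose, with the half-inhibition point.

    Drug binding is resolved inside the coupled steady state (closed-state
    sequestration), free drug is corrected for the bound fraction whenever
    the enzyme concentration is non-negligible, and the IC50 is found by
    bisection on the dose axis.
    """
    doses = np.asarray(dose_grid, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    basal = steady_state_activity(config, substrate, 0.0).k_obs
    activity = np.array(
        [_activity_at_total_dose(config, substrate, d).k_obs for d in doses]
    )
    ic50 = half_inhibition_dose(config, substrate, basal=basal)
    return InhibitionCurve(doses=doses, activity=activity, basal=basal, ic50=ic50)


def half_inhibition_dose(
    config: CoupledConfig, substrate: float, basal: float | None = None
) -> float:
    """Dose at which the steady-state activity halves, by bisection."""
    if basal is None:
        basal = steady_state_activity(config, substrate, 0.0).k_obs
    if basal <= 0:
        raise SolverError("basal activity is zero; IC50 undefined")
    target = 0.5 * basal

    def gap(dose: float) -> float:
        return _activity_at_total_dose(config, substrate, dose).k_obs - target

    hi = max(config.drug.K_D_obs, 1e-3) if config.drug else 1.0
    while gap(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise SolverError("activity never falls to half its basal value")
    return float(brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-10))


def activator_shift(
    k_open_close: float, activator: float, k_a_open: float
) -> float:
    """Thermodynamic linkage of an open-state-binding activator.

    A ligand (e.g. a bisphosphorylated activating peptide) that binds only
    the open conformation with affinity ``k_a_open`` multiplies the
    open/close equilibrium constant by ``1 + [activator]/K_A``.
    """
    if k_open_close <= 0 or k_a_open <= 0:
        raise ValueError("equilibrium and affinity constants must be positive")
    if activator < 0:
        raise ValueError("activator concentration must be non-negative")
    return k_open_close * (1.0 + activator / k_a_open)
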