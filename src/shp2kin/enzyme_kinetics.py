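"""Steady-state enzymology: partial substrate inhibition and dose-response.

The fully open phosphatase engine does not follow simple Michaelis-Menten
behaviour: at high substrate the observed turnover drops from a maximum and
levels off at a second, lower rate.  The simplest model reproducing this
*partial* substrate inhibition is a two-site sequential (Adair-Pauling)
binding scheme in which both the singly (ES) and doubly (ESS) occupied
enzyme turn over, with distinct rates:

    k_obs(S) = (kcat1 * S/KD1 + kcat2 * S^2/(KD1*KD2))
               / (1 + S/KD1 + S^2/(KD1*KD2))

``KD1`` and ``KD2`` are macroscopic sequential dissociation constants (uM);
``kcat1 > kcat2`` produces the rise-peak-plateau signature, while
``KD2 -> inf`` recovers Michaelis-Menten with ``K_M = KD1``.

Inhibitor dose-response data are fitted with a four-parameter logistic
(Boltzmann) sigmoid in log10 concentration, and the module can invert a
monotone inhibition curve to find the drug concentration that restores a
target activity level — for activating mutants this is far above the IC50.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import FitError, InsufficientDataError

__all__ = [
    "TwoSiteParams",
    "RatePoint",
    "TwoSiteFit",
    "DoseResponseFit",
    "two_site_rate",
    "michaelis_menten_rate",
    "fit_two_site",
    "boltzmann_response",
    "boltzmann_ic50",
    "sequestration_activity",
    "restoration_concentration",
]


@dataclass(frozen=True)
class TwoSiteParams:
    """Parameters of the two-site sequential substrate model."""

    kcat1: float  # turnover of ES, s^-1
    kcat2: float  # turnover of ESS, s^-1
    kd1: float    # first sequential dissociation constant, uM
    kd2: float    # second sequential dissociation constant, uM

    def __post_init__(self):
        for name in ("kcat1", "kcat2", "kd1", "kd2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def partial_inhibition(self) -> bool:
        """True when the rate profile peaks then decays (kcat1 > kcat2)."""
        return self.kcat1 > self.kcat2


@dataclass(frozen=True)
class RatePoint:
    """One steady-state measurement: substrate (uM), rate and SD (s^-1)."""

    substrate: float
    k_obs: float
    sd: float = 0.0

    def __post_init__(self):
        if self.substrate < 0:
            raise ValueError("substrate must be >= 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TwoSiteFit:
    """Fit result: parameters, SEs, and which nested model was preferred."""

    params: TwoSiteParams
    ses: dict
    model: str           # "two-site" or "michaelis-menten"
    aic_two_site: float
    aic_mm: float
    cov: np.ndarray | None = None


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of % inhibition versus dose."""

    ic50: float          # uM
    hill: float
    floor: float         # % inhibition at zero dose
    ceiling: float       # % inhibition at saturating dose
    ses: dict = field(default_factory=dict)
    cov: np.ndarray | None = None

    def response(self, dose) -> np.ndarray:
        """Percent inhibition at the given dose(s), uM."""
        return boltzmann_response(dose, self.ic50, self.hill, self.floor, self.ceiling)


def two_site_rate(substrate, params: TwoSiteParams):
    """Observed turnover (s^-1) of the two-site sequential model."""
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate must be >= 0")
    x1 = s / params.kd1
    x2 = s * s / (params.kd1 * params.kd2)
    out = (params.kcat1 * x1 + params.kcat2 * x2) / (1.0 + x1 + x2)
    return float(out) if np.isscalar(substrate) else out


def michaelis_menten_rate(substrate, kcat: float, km: float):
    s = np.asarray(substrate, dtype=float)
    out = kcat * s / (km + s)
    return float(out) if np.isscalar(substrate) else out


def _aic(ssr: float, n: int, n_par: int) -> float:
    return n * math.log(max(ssr, 1e-300) / n) + 2 * n_par


def fit_two_site(data: Sequence[RatePoint]) -> TwoSiteFit:
    """Weighted NLS fit of the two-site model, with a nested-model check.

    Fits both the full four-parameter model and the Michaelis-Menten special
    case and reports whichever AIC prefers.  Data that never descend from
    their maximum carry no information about the second site; a warning is
    issued and the reduced model returned.
    """
    pts = sorted(data, key=lambda p: p.substrate)
    if len(pts) < 6:
        raise InsufficientDataError("two-site fit needs >= 6 substrate levels")
    s = np.array([p.substrate for p in pts])
    y = np.array([p.k_obs for p in pts])
    sd = np.array([p.sd for p in pts])
    sigma = sd if np.all(sd > 0) else None

    # initial guesses: peak rate, final rate, half-max substrate, 10*max(S)
    kcat1_0 = float(np.max(y))
    kcat2_0 = max(float(y[-1]), 1e-6)
    half = 0.5 * kcat1_0
    above = s[y >= half]
    kd1_0 = float(above[0]) if above.size else float(np.median(s[s > 0]))
    kd1_0 = max(kd1_0, 1e-6)
    kd2_0 = 10.0 * float(np.max(s))

    descent = float(np.max(y) - y[-1]) > 0.02 * float(np.max(y)) and (
        int(np.argmax(y)) < len(y) - 1
    )
    if not descent:
        warnings.warn(
            "rate profile is monotone (no descent); second substrate site is "
            "unconstrained, returning the Michaelis-Menten reduced model",
            stacklevel=2,
        )

    def full(sub, kcat1, kcat2, kd1, kd2):
        return two_site_rate(sub, TwoSiteParams(kcat1, kcat2, kd1, kd2))

    def mm(sub, kcat, km):
        return michaelis_menten_rate(sub, kcat, km)

    fit_full = None
    if descent:
        try:
            popt, pcov = curve_fit(
                full,
                s,
                y,
                p0=[kcat1_0, kcat2_0, kd1_0, kd2_0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=(1e-12, np.inf),
                maxfev=40000,
            )
            ssr = float(np.sum((full(s, *popt) - y) ** 2))
            fit_full = (popt, pcov, _aic(ssr, s.size, 4))
        except (RuntimeError, ValueError):
            fit_full = None

    try:
        popt_mm, pcov_mm = curve_fit(
            mm,
            s,
            y,
            p0=[kcat1_0, kd1_0],
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=(1e-12, np.inf),
            maxfev=40000,
        )
        ssr_mm = float(np.sum((mm(s, *popt_mm) - y) ** 2))
        aic_mm = _aic(ssr_mm, s.size, 2)
    except (RuntimeError, ValueError) as exc:
        if fit_full is None:
            raise FitError(f"both substrate models failed to fit: {exc}") from exc
        popt_mm, pcov_mm, aic_mm = None, None, math.inf

    if fit_full is not None and fit_full[2] < aic_mm:
        popt, pcov, aic_full = fit_full
        ses = np.sqrt(np.diag(pcov))
        return TwoSiteFit(
            params=TwoSiteParams(*popt),
            ses={k: float(v) for k, v in zip(("kcat1", "kcat2", "kd1", "kd2"), ses)},
            model="two-site",
            aic_two_site=aic_full,
            aic_mm=aic_mm,
            cov=pcov,
        )
    # reduced model: report as TwoSiteParams with an effectively absent
    # second site (kd2 far above any tested substrate, kcat2 = kcat1)
    ses_mm = np.sqrt(np.diag(pcov_mm))
    kd2_eff = 1e6 * float(np.max(s))
    return TwoSiteFit(
        params=TwoSiteParams(popt_mm[0], popt_mm[0], popt_mm[1], kd2_eff),
        ses={"kcat1": float(ses_mm[0]), "kd1": float(ses_mm[1])},
        model="michaelis-menten",
        aic_two_site=fit_full[2] if fit_full is not None else math.inf,
        aic_mm=aic_mm,
        cov=pcov_mm,
    )


# ---------------------------------------------------------------------------
# Dose-response (IC50)
# ---------------------------------------------------------------------------

def boltzmann_response(dose, ic50: float, hill: float, floor: float, ceiling: float):
    """Four-parameter logistic in log10 dose.

    Response rises from ``floor`` to ``ceiling`` with midpoint at ``ic50``;
    at ``dose == ic50`` the response is the mean of the asymptotes.
    """
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        logd = np.log10(np.maximum(d, 1e-300))
    out = floor + (ceiling - floor) / (
        1.0 + 10.0 ** (hill * (math.log10(ic50) - logd))
    )
    out = np.where(d <= 0, floor, out)
    return float(out) if np.isscalar(dose) else out


def boltzmann_ic50(
    dose,
    response,
    sd=None,
    fix_asymptotes: bool = False,
) -> DoseResponseFit:
    """Fit a sigmoidal dose-response curve and return the IC50 in uM.

    ``fix_asymptotes=True`` constrains the asymptotes to 0 and 100 %
    (two-parameter fit); by default all four parameters are free.
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if d.size < 5:
        raise InsufficientDataError("dose-response fit needs >= 5 doses")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    sigma = np.asarray(sd, dtype=float) if sd is not None else None
    if sigma is not None and not np.all(sigma > 0):
        sigma = None

    mid_guess = float(np.sqrt(d.min() * d.max()))
    crossing = d[y >= 0.5 * (y.min() + y.max())]
    if crossing.size:
        mid_guess = float(crossing[np.argmin(crossing)])

    try:
        if fix_asymptotes:
            def model(dd, ic50, hill):
                return boltzmann_response(dd, ic50, hill, 0.0, 100.0)

            popt, pcov = curve_fit(
                model,
                d,
                y,
                p0=[mid_guess, 1.0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=([1e-12, 1e-3], [np.inf, 100.0]),
                maxfev=40000,
            )
            ic50, hill = popt
            floor, ceiling = 0.0, 100.0
            names = ("ic50", "hill")
        else:
            def model(dd, ic50, hill, floor, ceiling):
                return boltzmann_response(dd, ic50, hill, floor, ceiling)

            popt, pcov = curve_fit(
                model,
                d,
                y,
                p0=[mid_guess, 1.0, float(y.min()), float(y.max())],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=(
                    [1e-12, 1e-3, -np.inf, -np.inf],
                    [np.inf, 100.0, np.inf, np.inf],
                ),
                maxfev=40000,
            )
            ic50, hill, floor, ceiling = popt
            names = ("ic50", "hill", "floor", "ceiling")
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"dose-response fit failed: {exc}") from exc
    if ceiling <= floor:
        raise FitError(
            f"fitted dose-response is not sigmoidal (ceiling {ceiling:.3g} <= "
            f"floor {floor:.3g})"
        )
    ses = {k: float(v) for k, v in zip(names, np.sqrt(np.diag(pcov)))}
    return DoseResponseFit(
        ic50=float(ic50),
        hill=float(hill),
        floor=float(floor),
        ceiling=float(ceiling),
        ses=ses,
        cov=pcov,
    )


# ---------------------------------------------------------------------------
# Activity restoration
# ---------------------------------------------------------------------------

def sequestration_activity(basal: float, kd_obs: float) -> Callable:
    """Activity versus dose under pure closed-state sequestration.

    When the drug simply removes active enzyme with apparent affinity
    ``kd_obs``, the residual activity is ``basal / (1 + D / kd_obs)``.
    """
    if basal <= 0 or kd_obs <= 0:
        raise ValueError("basal activity and kd_obs must be positive")
    return lambda dose: basal / (1.0 + np.asarray(dose, dtype=float) / kd_obs)


def restoration_concentration(
    basal_activity: float,
    target_activity: float,
    inhibition_model,
    dose_max: float = 1e9,
) -> float:
    """Drug concentration at which activity falls to ``target_activity``.

    ``inhibition_model`` may be a callable ``activity(dose)`` (monotone
    decreasing), a :class:`DoseResponseFit` (interpreted as % inhibition of
    the basal activity), or a float apparent K_D (pure sequestration).
    Returns ``math.inf`` when the target lies below the model's floor.
    """
    if target_activity > basal_activity:
        raise ValueError(
            f"target activity {target_activity} exceeds basal {basal_activity}"
        )
    if target_activity == basal_activity:
        return 0.0
    if isinstance(inhibition_model, DoseResponseFit):
        fitres = inhibition_model

        def activity(dose):
            return basal_activity * (1.0 - float(fitres.response(dose)) / 100.0)

    elif isinstance(inhibition_model, (int, float)):
        activity = sequestration_activity(basal_activity, float(inhibition_model))
    else:
        activity = inhibition_model

    def objective(dose):
        return float(activity(dose)) - target_activity

    lo = 0.0
    hi = 1.0
    while objective(hi) > 0:
        hi *= 10.0
        if hi > dose_max:
            return math.inf
    return float(brentq(objective, lo, hi, xtol=1e-12, rtol=1e-12))
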