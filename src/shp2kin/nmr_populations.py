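"""Two-state population estimation from amide chemical shifts.

SHP2 exchanges between a closed, auto-inhibited conformation and an open,
active one.  For residues in fast exchange, the observed ``[1H-15N]`` cross
peak lies on the straight line connecting the pure-state peak positions, at
the population-weighted average.  Given a query spectrum plus reference
spectra for the fully open state (the isolated PTP domain) and the fully
closed state (the drug-inhibited complex), each residue's peak is projected
onto the open-to-closed axis to obtain a per-residue fraction closed, the
residues are filtered for two-state behaviour, and a single global fraction
closed is estimated by maximum likelihood with Hessian-based uncertainties.

All chemical shifts are in ppm.  The 15N axis is down-weighted by a factor
of 0.15 (``N_SHIFT_WEIGHT``) so that proton and nitrogen displacements
contribute on a comparable scale.

Projection convention
---------------------
With displacement vectors measured from the *open* reference,

    A = delta(query) - delta(open),   B = delta(closed) - delta(open),

the projection ``F = |A| cos(theta) / |B|`` is the fraction *closed*: it is
0 at the open reference, 1 at the closed reference, and collinear residues
satisfy ``theta ~ 0``.  The alternative convention with both vectors
measured from the closed reference (``A = query - closed``,
``B = closed - open``) yields ``F = -(fraction open)`` for on-axis peaks
and ``theta ~ 180 deg``; it is available via ``convention="literature"`` but
is inconsistent with the per-residue retention window ``0 <= F <= 1``, so
the open-referenced convention is the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BoundaryError,
    DegenerateAxisError,
    EmptySelectionError,
    InsufficientDataError,
    KeyMismatchError,
)

logger = logging.getLogger(__name__)

#: Down-weighting of the 15N chemical-shift axis relative to 1H.
N_SHIFT_WEIGHT = 0.15

#: Retention threshold on the open-to-closed axis length, ppm (weighted).
MIN_B_PPM = 0.03

#: Collinearity tolerance for the two-state filter, degrees.
ANGLE_TOL_DEG = 10.0

ATOM_GROUPS = ("backbone-NH", "sidechain-NHe")

CONVENTIONS = ("closed", "literature")

#: Filter exclusion reasons, in the fixed order in which they are checked.
EXCLUSION_REASONS = ("excluded", "min_b", "angle", "f_range")


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross peak: residue, atom group and (1H, 15N) ppm."""

    residue_id: int
    delta_h: float
    delta_n: float
    atom_group: str = "backbone-NH"

    def __post_init__(self):
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError("chemical shifts must be finite")
        if self.atom_group not in ATOM_GROUPS:
            raise ValueError(
                f"atom_group must be one of {ATOM_GROUPS}, got {self.atom_group!r}"
            )

    @property
    def key(self):
        return (self.residue_id, self.atom_group)


class PeakSet:
    """A labelled spectrum: peaks keyed by (residue_id, atom_group)."""

    def __init__(self, label: str, peaks: Iterable[Peak] = ()):
        self.label = label
        self.peaks: dict = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak):
        if peak.key in self.peaks:
            raise ValueError(f"duplicate peak key {peak.key} in {self.label!r}")
        self.peaks[peak.key] = peak

    def get(self, key):
        return self.peaks.get(key)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks.values())

    def __contains__(self, key):
        return key in self.peaks

    def keys(self):
        return self.peaks.keys()

    def to_records(self):
        return [
            {
                "residue_id": p.residue_id,
                "atom_group": p.atom_group,
                "delta_h_ppm": p.delta_h,
                "delta_n_ppm": p.delta_n,
            }
            for p in sorted(self, key=lambda q: q.key)
        ]


@dataclass(frozen=True)
class ResidueProjection:
    """Projection geometry of one residue onto the open-to-closed axis.

    ``vec_a`` and ``vec_b`` live in the weighted (1H, 0.15*15N) ppm plane.
    ``f`` is the raw projection under the chosen convention; ``f_closed``
    always reads as fraction closed regardless of convention.
    """

    residue_id: int
    atom_group: str
    vec_a: np.ndarray
    vec_b: np.ndarray
    theta_deg: float
    f: float
    b_norm: float
    convention: str = "closed"
    passed_filters: bool | None = None
    exclusion_reason: str | None = None

    @property
    def f_closed(self) -> float:
        # Under the literature convention an on-axis peak at fraction closed p
        # projects to F = -(1 - p), so fraction closed reads as 1 + F.
        return self.f if self.convention == "closed" else 1.0 + self.f

    @property
    def a_norm(self) -> float:
        return float(np.linalg.norm(self.vec_a))

    @property
    def collinearity_deviation_deg(self) -> float:
        """Angular deviation from the collinear (two-state) geometry."""
        return self.theta_deg if self.convention == "closed" else 180.0 - self.theta_deg


@dataclass(frozen=True)
class PopulationEstimate:
    """Maximum-likelihood global fraction closed with Hessian variances."""

    f_hat: float
    sigma_hat: float
    var_f: float
    var_sigma: float
    n_residues: int
    log_likelihood: float

    @property
    def se_f(self) -> float:
        return math.sqrt(self.var_f)

    @property
    def se_sigma(self) -> float:
        return math.sqrt(self.var_sigma)

    @property
    def f_hat_clipped(self) -> float:
        """Reported fraction closed, clipped to [0, 1]."""
        return min(1.0, max(0.0, self.f_hat))


@dataclass(frozen=True)
class ExclusionList:
    """Residues dropped a priori (e.g. within 15 A of the drug pocket)."""

    residue_ids: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_iterable(cls, ids: Iterable[int]) -> "ExclusionList":
        return cls(frozenset(int(i) for i in ids))

    def __contains__(self, residue_id: int) -> bool:
        return residue_id in self.residue_ids

    def __len__(self):
        return len(self.residue_ids)


# ---------------------------------------------------------------------------
# Chemical shift perturbation
# ---------------------------------------------------------------------------

def csp(peak_a: Peak, peak_b: Peak, n_weight: float = N_SHIFT_WEIGHT) -> float:
    """Combined 1H/15N chemical-shift perturbation between two peaks, ppm.

    ``sqrt(d_H^2 + (w * d_N)^2)`` with the nitrogen axis down-weighted by
    ``n_weight``.  Both peaks must refer to the same residue and atom group.
    """
    if peak_a.key != peak_b.key:
        raise KeyMismatchError(
            f"cannot compare peaks with keys {peak_a.key} and {peak_b.key}"
        )
    dh = peak_a.delta_h - peak_b.delta_h
    dn = n_weight * (peak_a.delta_n - peak_b.delta_n)
    return math.hypot(dh, dn)


# ---------------------------------------------------------------------------
# Projection onto the open-to-closed axis
# ---------------------------------------------------------------------------

def _weighted_displacement(to: Peak, frm: Peak, n_weight: float) -> np.ndarray:
    return np.array(
        [to.delta_h - frm.delta_h, n_weight * (to.delta_n - frm.delta_n)]
    )


def project_residue(
    query: Peak,
    open_ref: Peak,
    closed_ref: Peak,
    n_weight: float = N_SHIFT_WEIGHT,
    convention: str = "closed",
) -> ResidueProjection:
    """Project one residue's query peak onto the open-to-closed axis.

    Returns the displacement vectors, the angle between them and the scalar
    projection ``F``.  Under the default ``"closed"`` convention ``F`` is the
    fraction closed (0 at the open reference, 1 at the closed reference).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if not (query.key == open_ref.key == closed_ref.key):
        raise KeyMismatchError(
            "query/open/closed peaks must share (residue_id, atom_group): "
            f"{query.key}, {open_ref.key}, {closed_ref.key}"
        )
    vec_b = _weighted_displacement(closed_ref, open_ref, n_weight)
    b_norm = float(np.linalg.norm(vec_b))
    if b_norm == 0.0:
        raise DegenerateAxisError(
            f"open and closed references coincide for residue {query.residue_id}"
        )
    if convention == "closed":
        vec_a = _weighted_displacement(query, open_ref, n_weight)
    else:
        vec_a = _weighted_displacement(query, closed_ref, n_weight)
    a_norm = float(np.linalg.norm(vec_a))
    if a_norm == 0.0:
        # Query coincides with the reference the vectors are measured from:
        # the projection sits exactly at that endpoint, and the angle takes
        # the collinear limit of the respective convention.
        theta = 0.0 if convention == "closed" else 180.0
        f_val = 0.0
    else:
        cos_t = float(np.dot(vec_a, vec_b) / (a_norm * b_norm))
        cos_t = max(-1.0, min(1.0, cos_t))
        theta = math.degrees(math.acos(cos_t))
        f_val = a_norm * cos_t / b_norm
    return ResidueProjection(
        residue_id=query.residue_id,
        atom_group=query.atom_group,
        vec_a=vec_a,
        vec_b=vec_b,
        theta_deg=theta,
        f=f_val,
        b_norm=b_norm,
        convention=convention,
    )


def project_peaksets(
    query: PeakSet,
    open_ref: PeakSet,
    closed_ref: PeakSet,
    n_weight: float = N_SHIFT_WEIGHT,
    convention: str = "closed",
) -> list:
    """Project every residue present in all three spectra.

    Peak matching is by exact (residue_id, atom_group) key; residues missing
    from any spectrum are dropped with a logged count.
    """
    shared = sorted(
        set(query.keys()) & set(open_ref.keys()) & set(closed_ref.keys())
    )
    n_dropped = len(query) - len(shared)
    if n_dropped:
        logger.info(
            "%d of %d query peaks lack a match in both references and were dropped",
            n_dropped,
            len(query),
        )
    out = []
    for key in shared:
        try:
            out.append(
                project_residue(
                    query.get(key),
                    open_ref.get(key),
                    closed_ref.get(key),
                    n_weight=n_weight,
                    convention=convention,
                )
            )
        except DegenerateAxisError:
            logger.warning("degenerate axis for residue %s; skipped", key)
    return out


# ---------------------------------------------------------------------------
# Residue filters
# ---------------------------------------------------------------------------

def filter_residues(
    projections: Sequence[ResidueProjection],
    exclusions: ExclusionList | None = None,
    angle_tol_deg: float = ANGLE_TOL_DEG,
    min_b_ppm: float = MIN_B_PPM,
):
    """Apply the two-state retention filters to a set of projections.

    A residue is kept when it is not on the a-priori exclusion list, its
    axis length satisfies ``|B| >= min_b_ppm``, its displacement is
    collinear with the axis within ``angle_tol_deg``, and its projected
    fraction lies in ``[0, 1]``.  Checks run in that fixed order and every
    dropped residue records exactly one (the first failing) reason.

    Returns ``(retained, annotated)`` where ``annotated`` carries every
    input projection with ``passed_filters`` and ``exclusion_reason`` set.
    Raises :class:`EmptySelectionError` if nothing survives.
    """
    if angle_tol_deg <= 0 or min_b_ppm <= 0:
        raise ValueError("filter thresholds must be positive")
    exclusions = exclusions or ExclusionList()
    annotated = []
    retained = []
    for proj in projections:
        reason = None
        if proj.residue_id in exclusions:
            reason = "excluded"
        elif proj.b_norm < min_b_ppm:
            reason = "min_b"
        elif proj.collinearity_deviation_deg > angle_tol_deg:
            reason = "angle"
        elif not (0.0 <= proj.f_closed <= 1.0):
            reason = "f_range"
        tagged = replace(proj, passed_filters=reason is None, exclusion_reason=reason)
        annotated.append(tagged)
        if reason is None:
            retained.append(tagged)
    if not retained:
        raise EmptySelectionError("no residues passed the two-state filters")
    return retained, annotated


# ---------------------------------------------------------------------------
# Maximum-likelihood population estimate
# ---------------------------------------------------------------------------

def log_likelihood(
    projections: Sequence[ResidueProjection], f: float, sigma: float
) -> float:
    """Gaussian log likelihood of a global fraction closed ``f``.

    Each retained residue contributes a residual ``|B| * f - |A| cos(theta)``
    assumed normal with standard deviation ``sigma`` (ppm).
    """
    b = np.array([p.b_norm for p in projections])
    y = np.array([p.f_closed * p.b_norm for p in projections])
    resid = b * f - y
    return float(
        np.sum(-0.5 * np.log(2.0 * np.pi * sigma**2) - resid**2 / (2.0 * sigma**2))
    )


def estimate_population(
    projections: Sequence[ResidueProjection],
) -> PopulationEstimate:
    """Maximum-likelihood global fraction closed from retained residues.

    The likelihood is maximised in closed form:

        F_hat     = sum(|B|_i |A|_i cos(theta_i)) / sum(|B|_i^2)
        sigma_hat = sqrt(mean((|B|_i F_hat - |A|_i cos(theta_i))^2))

    Variances come from the negative inverse of the observed-information
    (Hessian) matrix at the optimum; the cross term vanishes there, so
    ``var(F) = sigma^2 / sum(|B|^2)`` and ``var(sigma) = sigma^2 / (2 n)``.
    The estimate is reported unclipped; a warning is logged if it falls
    outside [0, 1].
    """
    n = len(projections)
    if n < 2:
        raise InsufficientDataError(
            f"population estimation needs >= 2 residues, got {n}"
        )
    b = np.array([p.b_norm for p in projections])
    y = np.array([p.f_closed * p.b_norm for p in projections])
    sxx = float(np.sum(b**2))
    f_hat = float(np.sum(b * y) / sxx)
    resid = b * f_hat - y
    sigma2 = float(np.mean(resid**2))
    sigma_hat = math.sqrt(sigma2)
    # Off-diagonal of the observed information is proportional to
    # sum(resid * |B|), which is exactly zero at the optimum.
    cross = float(np.sum(resid * b))
    if sigma2 > 0 and abs(cross) > 1e-8 * math.sqrt(sxx * np.sum(resid**2)):
        logger.warning("information-matrix cross term unexpectedly large: %g", cross)
    if sigma2 > 0.0:
        var_f = sigma2 / sxx
        var_sigma = sigma2 / (2.0 * n)
        ll = log_likelihood(projections, f_hat, sigma_hat)
    else:
        # Noise-free data: the likelihood is unbounded and the estimate exact.
        var_f = 0.0
        var_sigma = 0.0
        ll = math.inf
    if not (0.0 <= f_hat <= 1.0):
        logger.warning("global fraction closed %.4f outside [0, 1]", f_hat)
    return PopulationEstimate(
        f_hat=f_hat,
        sigma_hat=sigma_hat,
        var_f=var_f,
        var_sigma=var_sigma,
        n_residues=n,
        log_likelihood=ll,
    )


def equilibrium_from_population(f_closed: float) -> float:
    """Open/close equilibrium constant ``K = p_open/p_closed`` from f_closed."""
    if not 0.0 < f_closed < 1.0:
        raise BoundaryError(
            f"fraction closed must lie strictly in (0, 1), got {f_closed}"
        )
    return (1.0 - f_closed) / f_closed


def equilibrium_se(f_closed: float, se_f: float) -> float:
    """First-order standard error of ``(1 - f)/f`` given the SE of ``f``."""
    if not 0.0 < f_closed < 1.0:
        raise BoundaryError(
            f"fraction closed must lie strictly in (0, 1), got {f_closed}"
        )
    return se_f / f_closed**2


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------

def analyze_peaksets(
    query: PeakSet,
    open_ref: PeakSet,
    closed_ref: PeakSet,
    exclusions: ExclusionList | None = None,
    angle_tol_deg: float = ANGLE_TOL_DEG,
    min_b_ppm: float = MIN_B_PPM,
    n_weight: float = N_SHIFT_WEIGHT,
    convention: str = "closed",
):
    """Full population analysis: project, filter, estimate.

    Returns ``(estimate, annotated_projections)``.
    """
    projections = project_peaksets(
        query, open_ref, closed_ref, n_weight=n_weight, convention=convention
    )
    retained, annotated = filter_residues(
        projections,
        exclusions=exclusions,
        angle_tol_deg=angle_tol_deg,
        min_b_ppm=min_b_ppm,
    )
    estimate = estimate_population(retained)
    return estimate, annotated
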