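"""Chemical-shift projection analysis and population MLE."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shp2kin as sk
from shp2kin import nmr_populations as nmr
from shp2kin.errors import (
    BoundaryError,
    DegenerateAxisError,
    EmptySelectionError,
    InsufficientDataError,
    KeyMismatchError,
)


def peak(rid, dh, dn):
    return sk.Peak(residue_id=rid, delta_h=dh, delta_n=dn)


class TestCsp:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((8.0, 120.0), (8.0, 120.0), 0.0),            # identical peaks
            ((8.0, 121.0), (8.0, 120.0), 0.15),           # pure 15N displacement
            ((8.03, 120.2), (8.0, 120.0), 0.0424264),     # sqrt(0.0009 + 0.0009)
        ],
    )
    def test_weighted_shift_difference(self, a, b, expected):
        assert sk.csp(peak(5, *a), peak(5, *b)) == pytest.approx(expected, abs=1e-6)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(KeyMismatchError):
            sk.csp(peak(5, 8.0, 120.0), peak(6, 8.0, 120.0))


class TestProjection:
    OPEN = peak(7, 8.00, 120.0)
    CLOSED = peak(7, 8.20, 121.0)

    def test_query_at_closed_reference(self):
        proj = sk.project_residue(self.CLOSED, self.OPEN, self.CLOSED)
        assert proj.f == pytest.approx(1.0, abs=1e-12)
        assert proj.theta_deg == pytest.approx(0.0, abs=1e-6)

    def test_query_at_open_reference(self):
        proj = sk.project_residue(self.OPEN, self.OPEN, self.CLOSED)
        assert proj.f == pytest.approx(0.0, abs=1e-12)

    def test_on_axis_three_quarters(self):
        # query at open + 0.75 * (closed - open): A = 0.75 B exactly
        proj = sk.project_residue(peak(7, 8.15, 120.75), self.OPEN, self.CLOSED)
        assert proj.f == pytest.approx(0.75, abs=1e-12)
        assert proj.theta_deg == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(DegenerateAxisError):
            sk.project_residue(self.CLOSED, self.OPEN, self.OPEN)

    def test_literature_convention_measures_fraction_open(self):
        # under the literature vector definitions an on-axis query at
        # fraction closed p projects to F = -(1 - p)
        proj = sk.project_residue(
            peak(7, 8.15, 120.75), self.OPEN, self.CLOSED, convention="literature"
        )
        assert proj.f == pytest.approx(-0.25, abs=1e-12)
        assert proj.f_closed == pytest.approx(0.75, abs=1e-12)
        assert proj.collinearity_deviation_deg == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=60, derandomize=True)
    @given(
        p=st.floats(0.0, 1.0),
        dh=st.floats(-0.4, 0.4),
        dn=st.floats(-2.5, 2.5),
        conv=st.sampled_from(["closed", "literature"]),
    )
    def test_linearity_along_axis(self, p, dh, dn, conv):
        """On-axis queries project to exactly their mixing fraction."""
        if math.hypot(dh, 0.15 * dn) < 1e-4:
            return
        open_ref = peak(3, 8.5, 118.0)
        closed_ref = peak(3, 8.5 + dh, 118.0 + dn)
        query = peak(3, 8.5 + p * dh, 118.0 + p * dn)
        proj = sk.project_residue(query, open_ref, closed_ref, convention=conv)
        assert proj.f_closed == pytest.approx(p, abs=1e-7)

    @settings(max_examples=40, derandomize=True)
    @given(scale=st.floats(0.05, 20.0))
    def test_scale_invariance(self, scale):
        """Scaling both displacement vectors leaves F and theta unchanged."""
        open_ref = peak(3, 8.5, 118.0)
        closed_small = peak(3, 8.5 + 0.02, 118.0 + 0.3)
        closed_big = peak(3, 8.5 + 0.02 * scale, 118.0 + 0.3 * scale)
        q_small = peak(3, 8.5 + 0.012 + 0.001, 118.0 + 0.18)
        q_big = peak(
            3, 8.5 + (0.012 + 0.001) * scale, 118.0 + 0.18 * scale
        )
        p1 = sk.project_residue(q_small, open_ref, closed_small)
        p2 = sk.project_residue(q_big, open_ref, closed_big)
        assert p1.f == pytest.approx(p2.f, rel=1e-9)
        assert p1.theta_deg == pytest.approx(p2.theta_deg, abs=1e-7)


def _axis_projection(rid, f, b_norm=0.2, theta_deg=0.0):
    """Build a projection with controlled geometry for filter tests."""
    vec_b = np.array([b_norm, 0.0])
    a_par = f * b_norm
    vec_a = np.array(
        [a_par, a_par * math.tan(math.radians(theta_deg))]
    )
    theta = math.degrees(
        math.acos(
            float(np.dot(vec_a, vec_b) / (np.linalg.norm(vec_a) * b_norm))
        )
    ) if np.linalg.norm(vec_a) > 0 else 0.0
    f_proj = float(np.dot(vec_a, vec_b) / b_norm**2)
    return nmr.ResidueProjection(
        residue_id=rid,
        atom_group="backbone-NH",
        vec_a=vec_a,
        vec_b=vec_b,
        theta_deg=theta,
        f=f_proj,
        b_norm=b_norm,
    )


class TestFilters:
    def test_each_violation_gets_its_reason(self):
        projs = [
            _axis_projection(1, 0.4),                      # clean
            _axis_projection(2, 0.4, b_norm=0.02),         # short axis
            _axis_projection(3, 0.4, theta_deg=12.0),      # off-axis by 12 deg
            _axis_projection(4, 1.05),                     # beyond closed
            _axis_projection(5, 0.4),                      # on exclusion list
        ]
        excl = sk.ExclusionList.from_iterable([5])
        retained, annotated = sk.filter_residues(projs, exclusions=excl)
        assert [p.residue_id for p in retained] == [1]
        reasons = {p.residue_id: p.exclusion_reason for p in annotated}
        assert reasons == {1: None, 2: "min_b", 3: "angle", 4: "f_range", 5: "excluded"}

    def test_reason_priority_is_fixed(self):
        # a residue that violates everything reports the first-checked reason
        bad = _axis_projection(9, 1.4, b_norm=0.01, theta_deg=20.0)
        _, annotated = sk.filter_residues(
            [bad, _axis_projection(1, 0.5)],
            exclusions=sk.ExclusionList.from_iterable([9]),
        )
        assert annotated[0].exclusion_reason == "excluded"

    def test_order_independence_of_retained_set(self):
        projs = [
            _axis_projection(i, f, b, t)
            for i, (f, b, t) in enumerate(
                [(0.3, 0.2, 0.0), (0.9, 0.02, 0.0), (0.5, 0.3, 15.0),
                 (1.2, 0.2, 0.0), (0.7, 0.1, 3.0)],
                start=1,
            )
        ]
        retained_fwd, _ = sk.filter_residues(projs)
        shuffled = projs[:]
        random.Random(0).shuffle(shuffled)
        retained_shuf, _ = sk.filter_residues(shuffled)
        assert {p.residue_id for p in retained_fwd} == {
            p.residue_id for p in retained_shuf
        }

    def test_all_excluded_raises(self):
        with pytest.raises(EmptySelectionError):
            sk.filter_residues([_axis_projection(1, 0.4, b_norm=0.001)])


class TestPopulationMLE:
    def test_noiseless_recovery_is_exact(self):
        projs = [
            _axis_projection(i, 0.3, b_norm=b)
            for i, b in enumerate([0.05, 0.1, 0.2, 0.4], start=1)
        ]
        est = sk.estimate_population(projs)
        assert est.f_hat == pytest.approx(0.3, abs=1e-12)
        assert est.sigma_hat == pytest.approx(0.0, abs=1e-10)
        assert est.var_f == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_matches_grid_maximisation(self, rng):
        """Closed-form MLE equals brute-force maximisation of the likelihood."""
        for _ in range(5):
            n = 12
            b = np.exp(rng.uniform(np.log(0.05), np.log(0.5), n))
            y = b * 0.62 + rng.normal(0.0, 0.01, n)
            projs = [
                _axis_projection(i + 1, y[i] / b[i], b_norm=b[i]) for i in range(n)
            ]
            est = sk.estimate_population(projs)

            # independent oracle: dense grid + local refinement on the
            # analytic log likelihood written from scratch
            def loglik(f, s):
                r = b * f - y
                return np.sum(-0.5 * np.log(2 * np.pi * s**2) - r**2 / (2 * s**2))

            fs = np.linspace(est.f_hat - 0.2, est.f_hat + 0.2, 801)
            ss = np.linspace(max(est.sigma_hat * 0.2, 1e-5), est.sigma_hat * 3, 801)
            grid = np.array([[loglik(f, s) for s in ss] for f in fs])
            i, j = np.unravel_index(np.argmax(grid), grid.shape)
            from scipy.optimize import minimize

            res = minimize(
                lambda p: -loglik(p[0], p[1]),
                [fs[i], ss[j]],
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14},
            )
            assert est.f_hat == pytest.approx(res.x[0], abs=1e-6)
            assert est.sigma_hat == pytest.approx(res.x[1], abs=1e-6)

    def test_hessian_variances_match_observed_information(self, rng):
        n = 20
        b = np.exp(rng.uniform(np.log(0.05), np.log(0.5), n))
        y = b * 0.4 + rng.normal(0.0, 0.008, n)
        projs = [_axis_projection(i + 1, y[i] / b[i], b_norm=b[i]) for i in range(n)]
        est = sk.estimate_population(projs)
        # numerical Hessian of the log likelihood at the optimum
        eps = 1e-6

        def ll(f, s):
            return nmr.log_likelihood(projs, f, s)

        f0, s0 = est.f_hat, est.sigma_hat
        d2f = (ll(f0 + eps, s0) - 2 * ll(f0, s0) + ll(f0 - eps, s0)) / eps**2
        d2s = (ll(f0, s0 + eps) - 2 * ll(f0, s0) + ll(f0, s0 - eps)) / eps**2
        dfs = (
            ll(f0 + eps, s0 + eps)
            - ll(f0 + eps, s0 - eps)
            - ll(f0 - eps, s0 + eps)
            + ll(f0 - eps, s0 - eps)
        ) / (4 * eps**2)
        assert est.var_f == pytest.approx(-1.0 / d2f, rel=1e-3)
        assert est.var_sigma == pytest.approx(-1.0 / d2s, rel=1e-3)
        # cross term of the information matrix vanishes at the optimum
        assert abs(dfs) < 1e-3 * abs(d2f)

    def test_too_few_residues_rejected(self):
        with pytest.raises(InsufficientDataError):
            sk.estimate_population([_axis_projection(1, 0.5)])


class TestEquilibrium:
    @pytest.mark.parametrize(
        "f_closed, expected",
        [
            (0.5, 1.0),
            (0.896, 0.116071),   # 10.4% open, WT landscape
            (0.042, 22.809524),  # 95.8% open, E76K landscape
        ],
    )
    def test_open_close_equilibrium_constant(self, f_closed, expected):
        assert sk.equilibrium_from_population(f_closed) == pytest.approx(
            expected, rel=1e-4
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_rejected(self, bad):
        with pytest.raises(BoundaryError):
            sk.equilibrium_from_population(bad)


class TestEndToEnd:
    def test_matched_projection_drops_unshared_residues(self):
        open_set = sk.PeakSet("open", [peak(1, 8.0, 120.0), peak(2, 8.5, 115.0)])
        closed_set = sk.PeakSet("closed", [peak(1, 8.2, 121.0), peak(2, 8.6, 116.0)])
        query = sk.PeakSet("q", [peak(1, 8.1, 120.5), peak(3, 9.0, 125.0)])
        projs = sk.project_peaksets(query, open_set, closed_set)
        assert [p.residue_id for p in projs] == [1]

    def test_duplicate_peak_keys_rejected(self):
        with pytest.raises(ValueError):
            sk.PeakSet("dup", [peak(1, 8.0, 120.0), peak(1, 8.1, 121.0)])
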