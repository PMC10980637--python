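"""Design construction, likelihood correctness, fitting and profile CIs."""

import numpy as np
import pytest
from scipy.special import expit, logit

import wintercjs as w
from conftest import all_patterns, history_prob_bruteforce


def _const_spec(**kw):
    return w.ParameterSpec(phi1=(), phi2=(), p=(), fixed_p_years=(), **kw)


def _single_bird(pattern, axis_years=(2014, 2015)):
    """One individual entering the first winter of a small axis."""
    reg = w.WinteringRegion.from_label("RES")
    h = w.EncounterHistory("x", axis_years[0], axis_years[0],
                           np.asarray(pattern, dtype=np.int8), reg)
    return w.Dataset([h], w.OccasionAxis(tuple(axis_years)))


class TestDesign:
    def test_parameter_counts_match_published_structures(self, default_dataset):
        """Free-parameter counts for the main candidate structures."""
        ds, _, _ = default_dataset
        cases = [
            (dict(phi1=("age2", "dis"), phi2=("age2",),
                  p=("ct", "age3", "dis")), 12),
            (dict(phi1=("age2", "region"), phi2=("age2",),
                  p=("ct", "age3", "dis")), 14),
            (dict(phi1=("age2", "dis", "fly"), phi2=("age2",),
                  p=("ct", "age3", "dis")), 13),
            (dict(phi1=("age2", "region"), phi2=("age2", "fly"),
                  p=("ct", "age3", "dis")), 16),
            (dict(phi1=("age2",), phi2=("age2",),
                  p=("ct", "age3", "dis")), 10),
        ]
        for kw, expected in cases:
            assert w.build_design(w.ParameterSpec(**kw), ds).K == expected

    def test_constant_model_has_three_parameters(self, default_dataset):
        ds, _, _ = default_dataset
        design = w.build_design(_const_spec(), ds)
        assert design.K == 3
        assert (design.k1, design.k2, design.kp) == (1, 1, 1)

    def test_formula_parser_roundtrip(self):
        spec = w.ParameterSpec.parse(
            "phi1 ~ 2age + dis; phi2 ~ 2age; p ~ ct + 3age + dis; "
            "fix p[2008:2013]=0"
        )
        assert spec.phi1 == ("age2", "dis")
        assert spec.phi2 == ("age2",)
        assert spec.p == ("ct", "age3", "dis")
        assert spec.fixed_p_years == tuple(range(2008, 2014))
        assert w.ParameterSpec.parse(spec.label).phi1 == spec.phi1

    def test_fixed_years_excluded_from_parameters(self, default_dataset):
        """p ~ t has free levels only for the unfixed years."""
        ds, _, _ = default_dataset
        spec = w.ParameterSpec(phi1=("age2",), phi2=("age2",), p=("t",))
        design = w.build_design(spec, ds)
        # 13 nominal years, 2008-2013 structurally zero -> 7 free levels
        assert design.kp == 7
        assert (design.p_idx >= 0).sum() < design.valid.sum()

    def test_rank_deficiency_reported_with_aliased_columns(self, default_dataset):
        # the region interaction spans distance: adding dis is fully aliased
        ds, _, _ = default_dataset
        spec = w.ParameterSpec(phi1=("region", "dis"), phi2=("age2",),
                               p=("ct", "age3", "dis"))
        with pytest.raises(w.IdentifiabilityError, match="dis"):
            w.build_design(spec, ds)


class TestLikelihood:
    def test_closed_form_single_interval(self):
        """Entry + one occasion: seen = phi*p; unseen = 1 - phi*p."""
        phi, p = 0.5, 0.8
        theta = np.array([logit(phi), logit(p)])
        seen = w.build_design(_const_spec(), _single_bird([1]))
        assert w.neg2_log_likelihood(theta, seen) == pytest.approx(
            -2 * np.log(phi * p), rel=1e-12
        )
        unseen = w.build_design(_const_spec(), _single_bird([0]))
        assert w.neg2_log_likelihood(theta, unseen) == pytest.approx(
            -2 * np.log(phi * (1 - p) + (1 - phi)), rel=1e-12
        )

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_enumeration_oracle_and_normalisation(self, T):
        """Against brute-force path enumeration; probabilities sum to 1."""
        rng = np.random.default_rng(42 + T)
        for _ in range(5):
            phi = tuple(rng.uniform(0.2, 0.95, T))
            p = tuple(rng.uniform(0.1, 0.9, T))
            total = 0.0
            for pattern in all_patterns(T):
                ds = _single_bird(pattern, tuple(range(2014, 2014 + T + 1)))
                spec = w.ParameterSpec(phi1=("t",), phi2=("t",), p=("t",),
                                       fixed_p_years=())
                design = w.build_design(spec, ds)
                # map design cells onto the year-indexed truth
                theta = np.zeros(design.K)
                cells = design.phi_cells
                eta = []
                for _, row in cells.iterrows():
                    # t is the interval-start year; interval 0 starts 2014
                    k = int(row["t"]) - 2014
                    eta.append(logit(phi[k]))
                for _, row in design.p_cells.iterrows():
                    k = int(row["t"]) - 2015
                    eta.append(logit(p[k]))
                # solve X theta = eta for the block-diagonal design
                X = np.zeros((design.K, design.K))
                X[: len(cells), : design.k1 + design.k2] = design.X_phi
                X[len(cells):, design.k1 + design.k2:] = design.X_p
                theta = np.linalg.solve(X, np.array(eta))
                op = w.neg2_log_likelihood(theta, design)
                prob = np.exp(-op / 2.0)
                expected = history_prob_bruteforce(tuple(pattern), phi, p)
                assert prob == pytest.approx(expected, abs=1e-12)
                total += prob
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_marray_and_individual_likelihood_agree(self, default_dataset):
        """Dual route: multinomial m-array likelihood on time-structured
        models equals the individual-history likelihood."""
        ds, _, _ = default_dataset
        spec = w.ParameterSpec(phi1=("t",), phi2=("t",), p=("t",))
        design = w.build_design(spec, ds)
        rng = np.random.default_rng(5)
        theta = rng.uniform(-1, 1, design.K)
        phi_cells, p_cells = design.probabilities(theta)
        phi1 = {}
        phi2 = {}
        for i, row in design.phi_cells.iterrows():
            year = int(row["t"]) + 1  # interval start year -> end year
            if row["block"] == "phi1":
                phi1[year] = phi_cells[i]
            else:
                phi2[year] = phi_cells[i]
        p_by_year = {y: 0.0 for y in ds.axis.breeding_years}
        for i, row in design.p_cells.iterrows():
            p_by_year[int(row["t"])] = p_cells[i]
        ma = w.build_marray(ds)
        v1 = w.neg2_log_likelihood(theta, design)
        v2 = w.marray_neg2_log_likelihood(ma, phi1, phi2, p_by_year)
        assert v1 == pytest.approx(v2, abs=1e-8)

    def test_invariance_under_permutation(self, default_dataset, m100_spec):
        ds, _, _ = default_dataset
        design = w.build_design(m100_spec, ds)
        rng = np.random.default_rng(9)
        theta = rng.uniform(-1, 1, design.K)
        v = w.neg2_log_likelihood(theta, design)
        perm = [ds.histories[k] for k in rng.permutation(len(ds))]
        design2 = w.build_design(m100_spec, w.Dataset(perm, ds.axis))
        assert w.neg2_log_likelihood(theta, design2) == pytest.approx(v, rel=1e-12)

    def test_analytic_gradient_matches_finite_differences(
        self, default_dataset, m100_spec
    ):
        ds, _, _ = default_dataset
        design = w.build_design(m100_spec, ds)
        rng = np.random.default_rng(17)
        theta = rng.uniform(-1, 1, design.K)
        _, grad = w.neg2_log_likelihood(theta, design, gradient=True)
        eps = 1e-5
        for i in range(design.K):
            e = np.zeros(design.K)
            e[i] = eps
            num = (
                w.neg2_log_likelihood(theta + e, design)
                - w.neg2_log_likelihood(theta - e, design)
            ) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_nonfinite_theta_rejected(self, default_dataset, m100_spec):
        ds, _, _ = default_dataset
        design = w.build_design(m100_spec, ds)
        bad = np.zeros(design.K)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            w.neg2_log_likelihood(bad, design)


class TestFit:
    def test_survival_mle_is_return_fraction_when_p_is_one(self):
        """With one interval and certain detection, the MLE is the observed
        return fraction exactly."""
        reg = w.WinteringRegion.from_label("RES")
        hs = [
            w.EncounterHistory(f"i{k}", 2014, 2014,
                               np.array([1 if k < 7 else 0], dtype=np.int8),
                               reg)
            for k in range(10)
        ]
        ds = w.Dataset(hs, w.OccasionAxis((2014, 2015)))
        # detection certain: fix p via a huge offset is not expressible, so
        # fit phi and p jointly; with a single interval phi*p and the split
        # are confounded -- instead check the product against the fraction
        fm = w.fit(_const_spec(), ds, seed=0, n_starts=3)
        est = fm.real_estimates()
        phi = est[est.block == "phi1"]["estimate"].iloc[0]
        p = est[est.block == "p"]["estimate"].iloc[0]
        assert phi * p == pytest.approx(0.7, abs=1e-4)

    def test_recovers_generating_parameters(self, m100_spec):
        """Moderate-n check that the MLEs sit near the generating values."""
        cfg = w.default_config(seed=21).scaled(1500)
        ds, _, truth = w.simulate(cfg)
        fm = w.fit(m100_spec, ds, seed=21, n_starts=3)
        assert fm.converged
        est = fm.real_estimates()
        rep = {"LD": "EAF LD", "SD": "EAF SD", "RES": "RES"}
        for _, row in est[est.block == "phi1"].iterrows():
            tv = truth["phi1"][(row["age2"], rep[row["dis"]])]
            assert row["estimate"] == pytest.approx(tv, abs=0.12)
        for _, row in est[est.block == "phi2"].iterrows():
            assert row["estimate"] == pytest.approx(
                truth["phi2"][row["age2"]], abs=0.06
            )

    def test_all_seen_hits_boundary_with_flag(self):
        reg = w.WinteringRegion.from_label("RES")
        hs = [
            w.EncounterHistory(f"i{k}", 2014, 2014,
                               np.ones(3, dtype=np.int8), reg)
            for k in range(20)
        ]
        ds = w.Dataset(hs, w.OccasionAxis(tuple(range(2014, 2018))))
        fm = w.fit(_const_spec(), ds, seed=0, n_starts=2)
        est = fm.real_estimates()
        assert (est["estimate"] > 0.999).all()
        assert est["boundary"].all()
        assert fm.boundary

    def test_nested_models_never_increase_deviance(self, default_dataset):
        ds, _, _ = default_dataset
        chain = [
            w.ParameterSpec(phi1=("age2",), phi2=("age2",),
                            p=("ct", "age3", "dis")),
            w.ParameterSpec(phi1=("age2", "dis"), phi2=("age2",),
                            p=("ct", "age3", "dis")),
            w.ParameterSpec(phi1=("age2", "region"), phi2=("age2",),
                            p=("ct", "age3", "dis")),
        ]
        devs = [w.fit(s, ds, seed=2, n_starts=3).deviance for s in chain]
        assert devs[0] >= devs[1] - 1e-6
        assert devs[1] >= devs[2] - 1e-6


class TestProfileCI:
    def test_degenerate_at_level_zero(self, default_dataset, m100_spec):
        ds, _, _ = default_dataset
        fm = w.fit(m100_spec, ds, seed=1, n_starts=2)
        ci = w.profile_ci(fm, 0, level=0.0)
        assert ci.lower == ci.upper == ci.estimate
        assert ci.flag == "degenerate"

    def test_interval_contains_mle(self, default_dataset, m100_spec):
        ds, _, _ = default_dataset
        fm = w.fit(m100_spec, ds, seed=1, n_starts=2)
        ci = w.profile_ci(fm, {"block": "phi2", "age2": "ad"})
        assert ci.lower < ci.estimate < ci.upper

    def test_boundary_estimate_gives_one_sided_interval(self):
        reg = w.WinteringRegion.from_label("RES")
        hs = [
            w.EncounterHistory(f"i{k}", 2014, 2014,
                               np.ones(3, dtype=np.int8), reg)
            for k in range(20)
        ]
        ds = w.Dataset(hs, w.OccasionAxis(tuple(range(2014, 2018))))
        fm = w.fit(_const_spec(), ds, seed=0, n_starts=2)
        ci = w.profile_ci(fm, 0)
        assert ci.upper == 1.0
        assert "boundary_upper" in ci.flag

    def test_matches_wald_interval_at_large_n(self, m100_spec):
        """Near-quadratic likelihood: profile and Wald widths agree to 1%."""
        from statsmodels.tools.numdiff import approx_hess1

        cfg = w.default_config(seed=7).scaled(8000)
        ds, _, _ = w.simulate(cfg)
        fm = w.fit(m100_spec, ds, seed=7, n_starts=2)
        d = fm.design
        i = int(d.phi_cells[d.phi_cells.block == "phi2"].index[0])
        x = np.zeros(d.K)
        x[: d.k1 + d.k2] = d.X_phi[i]
        H = approx_hess1(fm.theta,
                         lambda th: 0.5 * w.neg2_log_likelihood(th, d))
        cov = np.linalg.inv(H)
        se_eta = float(np.sqrt(x @ cov @ x))
        eta = float(x @ fm.theta)
        z = 1.959963984540054
        wald = expit(eta - z * se_eta), expit(eta + z * se_eta)
        ci = w.profile_ci(fm, i)
        assert (ci.upper - ci.lower) == pytest.approx(
            wald[1] - wald[0], rel=0.01
        )
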