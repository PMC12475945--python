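"""Resampling extrapolation machinery: targets, draws, tallies, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import firearmcost as fc
from firearmcost.errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyPoolError,
)
from firearmcost.national_simulation import (
    MINIMAL_STRATIFIERS,
    prepare_mc_inputs,
)


def _zero_targets(states=("N01",), years=(2016,)):
    return pd.DataFrame(
        [{"state": s, "year": y, "ip_target": 0} for s in states for y in years]
    )


class TestEdTarget:
    @pytest.mark.parametrize(
        "ip,ed,sip,expected",
        [
            (500, 8, 5, 800),
            (0, 8, 5, 0),
            (100, 161, 100, 161),
            (1, 5, 2, 3),  # 2.5 rounds half-up to 3
            (1, 3, 2, 2),  # 1.5 rounds half-up to 2
        ],
    )
    def test_half_up_product(self, ip, ed, sip, expected):
        assert fc.compute_ed_target(ip, ed, sip) == expected

    def test_zero_sample_inpatient(self):
        with pytest.raises(DegenerateInputError):
            fc.compute_ed_target(10, 5, 0)


class TestResampleVisits:
    def _pool(self, n, cost=100.0):
        return pd.DataFrame(
            {
                "visit_id": [f"v{i}" for i in range(n)],
                "visit_type": "inpatient",
                "cost_base": cost if np.isscalar(cost) else cost,
            }
        )

    def test_zero_draws(self):
        out = fc.resample_visits(self._pool(3), 0, np.random.default_rng(0))
        assert out.empty

    def test_single_record_pool(self):
        out = fc.resample_visits(self._pool(1, 42.0), 5, np.random.default_rng(0))
        assert len(out) == 5
        assert (out["cost_base"] == 42.0).all()
        assert out["resampled"].all()
        assert out["visit_id"].nunique() == 5  # fresh ids

    def test_empty_pool_raises(self):
        with pytest.raises(EmptyPoolError):
            fc.resample_visits(self._pool(0), 3, np.random.default_rng(0),
                               year=2016, visit_type="inpatient")

    def test_sample_mean_near_pool_mean(self):
        # CLT: mean of 10 000 with-replacement draws lies within
        # 4 sd/sqrt(n) of the pool mean with probability > 0.999
        rng = np.random.default_rng(3)
        pool = self._pool(500, cost=np.random.default_rng(1).lognormal(10, 1, 500))
        out = fc.resample_visits(pool, 10_000, rng)
        sd = pool["cost_base"].std(ddof=0)
        assert abs(out["cost_base"].mean() - pool["cost_base"].mean()) < 4 * sd / 100


class TestBuildNationalSample:
    def test_zero_targets_identity(self, analytic_sample):
        year = 2016
        spec = fc.SimulationSpec(n_simulations=1)
        out = fc.build_national_sample(
            year, analytic_sample, _zero_targets(), spec, np.random.default_rng(0)
        )
        base = analytic_sample[analytic_sample["year"] == year]
        assert len(out) == len(base)
        assert not out["resampled"].any()
        assert out["cost_base"].sum() == pytest.approx(base["cost_base"].sum())

    def test_inpatient_count_identity(self, analytic_sample):
        year = 2017
        targets = pd.DataFrame(
            [
                {"state": "N01", "year": year, "ip_target": 3},
                {"state": "N02", "year": year, "ip_target": 4},
            ]
        )
        spec = fc.SimulationSpec(n_simulations=1)
        out = fc.build_national_sample(
            year, analytic_sample, targets, spec, np.random.default_rng(1)
        )
        base = analytic_sample[analytic_sample["year"] == year]
        n_ip_base = (base["visit_type"] == "inpatient").sum()
        n_ip_out = (out["visit_type"] == "inpatient").sum()
        assert n_ip_out == n_ip_base + 7  # additivity of per-state targets
        resampled_ip = out[(out["resampled"]) & (out["visit_type"] == "inpatient")]
        assert sorted(resampled_ip["source_state"].value_counts().to_dict().items()) == [
            ("N01", 3), ("N02", 4)
        ]

    def test_ed_draws_follow_rounded_ratio(self, analytic_sample):
        year = 2018
        base = analytic_sample[analytic_sample["year"] == year]
        n_ed = int((base["visit_type"] == "ed_only").sum())
        n_ip = int((base["visit_type"] == "inpatient").sum())
        targets = pd.DataFrame([{"state": "N01", "year": year, "ip_target": 50}])
        out = fc.build_national_sample(
            year, analytic_sample, targets, fc.SimulationSpec(1), np.random.default_rng(2)
        )
        expected_ed = fc.compute_ed_target(50, n_ed, n_ip)
        got_ed = int(((out["resampled"]) & (out["visit_type"] == "ed_only")).sum())
        assert got_ed == expected_ed


class TestSummarizeSample:
    def test_single_record(self):
        sample = pd.DataFrame(
            {
                "visit_type": ["inpatient"],
                "cost_base": [100.0],
                "payer": ["Medicaid"],
            }
        )
        res = fc.summarize_sample(sample, stratifiers=("overall", "payer"))
        assert res.cells.set_index(["stratifier", "level", "visit_type"]).loc[
            ("overall", "all", "overall"), "total_cost"
        ] == 100.0
        key = res.cells.set_index(["stratifier", "level", "visit_type"])
        assert key.loc[("payer", "Medicaid", "inpatient"), "total_cost"] == 100.0
        assert key.loc[("payer", "Medicaid", "ed_only"), "total_cost"] == 0.0

    def test_partition_identity_with_missing(self, analytic_sample):
        res = fc.summarize_sample(
            prepare_mc_inputs(analytic_sample),
            stratifiers=("overall", "zip_income_quartile"),
        )
        cells = res.cells.set_index(["stratifier", "level", "visit_type"])
        overall = cells.loc[("overall", "all", "overall"), "total_cost"]
        strat = cells.xs("zip_income_quartile", level="stratifier").xs(
            "overall", level="visit_type"
        )
        assert strat["total_cost"].sum() == pytest.approx(overall, rel=1e-9)
        assert strat.loc["missing", "n_visits"] > 0  # missing level is tracked

    def test_empty_sample_all_cells_zero(self, analytic_sample):
        empty = prepare_mc_inputs(analytic_sample).iloc[0:0]
        res = fc.summarize_sample(empty, stratifiers=("overall", "payer", "medicaid_quartile"))
        assert (res.cells["total_cost"] == 0).all()
        assert (res.cells["n_visits"] == 0).all()

    def test_unknown_stratifier(self, analytic_sample):
        with pytest.raises(ConfigurationError):
            fc.summarize_sample(analytic_sample, stratifiers=("bogus_column",))

    def test_quartile_cells_partition_sample(self, analytic_sample):
        res = fc.summarize_sample(
            prepare_mc_inputs(analytic_sample),
            stratifiers=("overall", "medicaid_quartile"),
        )
        cells = res.cells.set_index(["stratifier", "level", "visit_type"])
        q = cells.xs("medicaid_quartile", level="stratifier").xs("overall", level="visit_type")
        assert q["n_visits"].sum() == len(analytic_sample)
        assert q.loc["missing", "n_visits"] == 0


class TestRunMonteCarlo:
    def test_single_sim_zero_targets_equals_sample_summary(self, analytic_sample):
        targets = _zero_targets(years=tuple(sorted(analytic_sample["year"].unique())))
        spec = fc.SimulationSpec(n_simulations=1, master_seed=5)
        run = fc.run_monte_carlo(analytic_sample, targets, spec,
                                 stratifiers=MINIMAL_STRATIFIERS)
        expected = fc.summarize_sample(
            prepare_mc_inputs(analytic_sample), MINIMAL_STRATIFIERS
        )
        pd.testing.assert_frame_equal(run.results[0].cells, expected.cells)

    def test_same_seed_reproduces_results(self, analytic_sample, small_dataset):
        spec = fc.SimulationSpec(n_simulations=3, master_seed=9)
        run_a = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                   stratifiers=MINIMAL_STRATIFIERS)
        run_b = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                   stratifiers=MINIMAL_STRATIFIERS)
        for a, b in zip(run_a.results, run_b.results):
            pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_count_conservation(self, analytic_sample, small_dataset):
        spec = fc.SimulationSpec(n_simulations=4, master_seed=2)
        run = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                 stratifiers=MINIMAL_STRATIFIERS)
        n_ip_sample = int((analytic_sample["visit_type"] == "inpatient").sum())
        n_ed_sample = int((analytic_sample["visit_type"] == "ed_only").sum())
        t_ip = int(run.ed_targets["ip_target"].sum())
        t_ed = int(run.ed_targets["ed_target"].sum())
        for res in run.results:
            assert res.counts["inpatient"] == n_ip_sample + t_ip
            assert res.counts["ed_only"] == n_ed_sample + t_ed

    def test_expectation_oracle_small(self, analytic_sample, small_dataset):
        # closed-form mean of a with-replacement sum: T x pool mean
        spec = fc.SimulationSpec(n_simulations=200, master_seed=17)
        run = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                 stratifiers=("overall",))
        year = 2016
        pool = analytic_sample[
            (analytic_sample["year"] == year)
            & (analytic_sample["visit_type"] == "inpatient")
        ]["cost_base"]
        t_ip = int(small_dataset.targets.loc[small_dataset.targets["year"] == year,
                                             "ip_target"].sum())
        totals = np.array([
            res.resampled_by_year.loc[
                (res.resampled_by_year["year"] == year)
                & (res.resampled_by_year["visit_type"] == "inpatient"),
                "total_cost",
            ].sum()
            for res in run.results
        ])
        oracle_mean = t_ip * pool.mean()
        analytic_se = np.sqrt(t_ip * pool.var(ddof=0))
        assert abs(totals.mean() - oracle_mean) < 4 * analytic_se
        # variance oracle at the same scale
        assert abs(totals.std(ddof=1) - analytic_se) < 0.25 * analytic_se

    def test_batch_means_stabilize(self, analytic_sample, small_dataset):
        # across-simulation means over disjoint batches shrink ~ 1/sqrt(batch)
        spec = fc.SimulationSpec(n_simulations=120, master_seed=23)
        run = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                 stratifiers=("overall",))
        totals = np.array([
            res.cells.query("visit_type == 'overall'")["total_cost"].iloc[0]
            for res in run.results
        ])

        def batch_sd(size):
            means = totals[: (len(totals) // size) * size].reshape(-1, size).mean(axis=1)
            return means.std(ddof=1)

        assert batch_sd(30) < batch_sd(5)

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            fc.SimulationSpec(n_simulations=0).validate()
        with pytest.raises(ConfigurationError):
            fc.SimulationSpec(rounding_rule="banker").validate()

    def test_result_csv_round_trip(self, analytic_sample, small_dataset, tmp_path):
        spec = fc.SimulationSpec(n_simulations=2, master_seed=1)
        run = fc.run_monte_carlo(analytic_sample, small_dataset.targets, spec,
                                 stratifiers=MINIMAL_STRATIFIERS)
        run.write(tmp_path)
        loaded = fc.MonteCarloRun.read_results(tmp_path)
        assert len(loaded) == 2
        pd.testing.assert_frame_equal(
            loaded[0].cells, run.results[0].cells, check_dtype=False
        )
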