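"""Monte Carlo engine: sampling, propagation, exceedance and sensitivity."""

import numpy as np
import pandas as pd
import pytest

import pterisk as pk
from pterisk.core_io import DistributionSpec, Medium, Population
from pterisk.mc_engine import (
    ParameterDraws,
    exceedance_probability,
    pooled_exceedance,
    run_mc,
    sample_parameters,
    sensitivity,
    site_seed,
)


def _point_specs(values: dict) -> dict:
    return {k: DistributionSpec(kind="point", params={"value": v}) for k, v in values.items()}


_CHILD_SOIL = {
    "r_ing": 200.0, "r_inh": 7.5, "ef": 350.0, "ed": 6.0,
    "bw": 15.0, "sa": 2800.0, "af": 0.2, "abs": 0.001, "pef": 1.36e9,
}


class TestSampleParameters:
    def test_point_specs_constant_vectors(self):
        draws = sample_parameters(_point_specs(_CHILD_SOIL), 100, seed=1)
        for name, v in draws.draws.items():
            assert np.all(v == _CHILD_SOIL[name])

    def test_identical_seed_identical_draws(self, refs):
        specs = refs.exposure_specs("child", "soil")
        a = sample_parameters(specs, 5000, seed=9)
        b = sample_parameters(specs, 5000, seed=9)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_truncated_draws_respect_bounds(self, refs):
        specs = refs.exposure_specs("child", "soil")
        draws = sample_parameters(specs, 10_000, seed=3)
        for v in draws.draws.values():
            assert (v > 0).all()

    def test_n_iter_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_parameters(_point_specs(_CHILD_SOIL), 0, seed=1)


class TestRunMC:
    def test_point_draws_reproduce_deterministic_result_exactly(self, soil_table, refs, refs_point):
        c = soil_table.values.iloc[0]
        det = pk.assess_site(c, refs, "child", "soil")
        specs = refs_point.exposure_specs("child", "soil")
        draws = sample_parameters(specs, 50, seed=0)
        mc = run_mc(c, draws, refs)
        assert np.all(mc.nri_samples == mc.nri_samples[0])
        assert mc.nri_samples[0] == pytest.approx(det.nri_total, rel=1e-12)
        assert mc.cri_samples[0] == pytest.approx(det.cri_total, rel=1e-12)
        assert mc.summary.loc["nri", "sd"] == 0.0

    def test_zero_concentrations_zero_samples(self, refs):
        c = pd.Series(0.0, index=list(pk.ELEMENTS))
        draws = sample_parameters(_point_specs(_CHILD_SOIL), 20, seed=0)
        mc = run_mc(c, draws, refs)
        assert np.all(mc.nri_samples == 0)
        assert mc.p_exceed_nri == 0.0 and mc.p_exceed_cri == 0.0

    def test_seeded_run_bit_identical(self, soil_table, refs):
        a = pk.run_mc_table(soil_table, refs, "child", n_iter=500, seed=17)
        b = pk.run_mc_table(soil_table, refs, "child", n_iter=500, seed=17)
        for site in soil_table.sites:
            np.testing.assert_array_equal(a[site].nri_samples, b[site].nri_samples)
            np.testing.assert_array_equal(a[site].cri_samples, b[site].cri_samples)

    def test_per_site_seeds_independent_of_order(self, soil_table, refs):
        full = pk.run_mc_table(soil_table, refs, "child", n_iter=200, seed=5)
        sub = soil_table.subset_elements(soil_table.elements)
        sub.values = sub.values.iloc[::-1]
        reversed_run = pk.run_mc_table(sub, refs, "child", n_iter=200, seed=5)
        site = soil_table.sites[0]
        np.testing.assert_array_equal(full[site].nri_samples, reversed_run[site].nri_samples)

    def test_mc_mean_converges_with_ef_only_varied(self, soil_table, refs, refs_point):
        # EF uniform, everything else point: MC mean of the (EF-linear) risk
        # must approach the deterministic value at mean EF within 3 SE
        c = soil_table.values.iloc[0]
        specs = dict(refs_point.exposure_specs("child", "soil"))
        specs["ef"] = DistributionSpec(kind="uniform", params={"low": 300.0, "high": 365.0})
        draws = sample_parameters(specs, 10_000, seed=21)
        mc = run_mc(c, draws, refs)
        det = pk.assess_site(
            c,
            refs,
            "child",
            "soil",
            params=pk.ExposureParams(
                r_ing=200.0, ef=332.5, ed=6.0, bw=15.0, sa=2800.0, af=0.2,
                abs_frac=0.001, r_inh=7.5, pef=1.36e9,
            ),
        )
        se = mc.summary.loc["nri", "sd"] / np.sqrt(10_000)
        assert abs(mc.summary.loc["nri", "mean"] - det.nri_total) < 3 * se

    def test_percentiles_monotone_and_mean_within_range(self, soil_table, refs):
        mc = pk.run_mc_table(soil_table, refs, "child", n_iter=1000, seed=2)[soil_table.sites[0]]
        s = mc.summary.loc["nri"]
        assert s["p5"] <= s["p50"] <= s["p95"]
        assert mc.nri_samples.min() <= s["mean"] <= mc.nri_samples.max()


class TestExceedance:
    @pytest.mark.parametrize(
        "samples, threshold, expected",
        [
            ([0.1, 0.2], 1.0, 0.0),
            ([2.0, 3.0], 1.0, 1.0),
            ([0.5, 1.5, 2.5, 0.9], 1.0, 0.5),
            ([1.0, 1.0], 1.0, 0.0),  # strict inequality
        ],
    )
    def test_counting_oracle(self, samples, threshold, expected):
        assert exceedance_probability(samples, threshold) == expected

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            exceedance_probability([], 1.0)

    def test_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 1000)
        ps = [exceedance_probability(x, t) for t in np.linspace(0.1, 10, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pooled_exceedance_matches_manual_count(self, soil_table, refs):
        results = pk.run_mc_table(soil_table, refs, "child", n_iter=300, seed=4)
        pooled = pooled_exceedance(results)
        allnri = np.concatenate([r.nri_samples for r in results.values()])
        assert pooled["p_exceed_nri"] == pytest.approx(np.mean(allnri > 1.0))


class TestSensitivity:
    def _draws(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        draws = {k: np.full(n, v) for k, v in _CHILD_SOIL.items()}
        draws["bw"] = rng.normal(15, 2.3, n).clip(min=1.0)
        return ParameterDraws(
            population=Population.child, medium=Medium.soil, n_iter=n, seed=seed, draws=draws
        )

    def test_output_copy_of_one_parameter_gets_full_share(self):
        d = self._draws()
        s = sensitivity(d, d.draws["bw"].copy())
        assert s["bw"] == pytest.approx(100.0)
        assert all(s[p] == 0.0 for p in s.index if p != "bw")

    def test_inverse_of_bw_gets_minus_100(self):
        d = self._draws()
        s = sensitivity(d, 1.0 / d.draws["bw"])
        assert s["bw"] == pytest.approx(-100.0)

    def test_invariant_to_monotone_rescaling_of_output(self, refs):
        specs = refs.exposure_specs("child", "soil")
        d = sample_parameters(specs, 2000, seed=6)
        out = d.draws["r_ing"] / d.draws["bw"]
        s1 = sensitivity(d, out)
        s2 = sensitivity(d, np.log(out) * 7.0 + 3.0)
        pd.testing.assert_series_equal(s1, s2)

    def test_all_constant_parameters_error(self):
        n = 100
        draws = {k: np.full(n, v) for k, v in _CHILD_SOIL.items()}
        d = ParameterDraws(
            population=Population.child, medium=Medium.soil, n_iter=n, seed=0, draws=draws
        )
        with pytest.raises(ValueError, match="constant"):
            sensitivity(d, np.arange(n, dtype=float))

    def test_default_child_soil_run_bw_negative(self, soil_table, refs):
        specs = refs.exposure_specs("child", "soil")
        draws = sample_parameters(specs, 4000, seed=8)
        mc = run_mc(soil_table.values.iloc[0], draws, refs)
        s = sensitivity(draws, mc.nri_samples)
        assert s["bw"] < 0
        assert abs(s).sum() == pytest.approx(100.0)


def test_site_seed_stable_and_in_range():
    s1 = site_seed(42, "S001", "child")
    s2 = site_seed(42, "S001", "child")
    s3 = site_seed(42, "S002", "child")
    assert s1 == s2 != s3
    assert 0 <= s1 < 2**31
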