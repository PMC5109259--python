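"""Distribution sampling, truncation, correlation induction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rpra.params import (
    CorrelationSpec,
    ParameterSpec,
    SampleMatrix,
    fit_summary_to_spec,
    induce_correlations,
    read_parameter_table,
    sample_parameter,
    sample_parameters,
)
from rpra.synthetic import ConcentrationSummary


class TestSampleParameter:
    def test_point_family_returns_constant(self):
        spec = ParameterSpec("EF", family="point", mean=350)
        assert np.array_equal(sample_parameter(spec, 5, seed=0), np.full(5, 350.0))

    def test_lognormal_recovers_arithmetic_moments(self):
        # moment identities: mu_log = ln(m^2/sqrt(m^2+s^2)), s2_log = ln(1+s^2/m^2)
        spec = ParameterSpec("BW", family="lognormal", mean=60, sd=10)
        x = sample_parameter(spec, 100_000, seed=7)
        assert x.mean() == pytest.approx(60, abs=0.2)
        assert x.std(ddof=1) == pytest.approx(10, abs=0.3)

    def test_triangular_mean_matches_closed_form(self):
        # mean of triangular(a, c, b) is (a + b + c)/3
        spec = ParameterSpec(
            "T", family="triangular", mean=1.0, minimum=0.0, maximum=2.0, mode=1.0
        )
        x = sample_parameter(spec, 100_000, seed=3)
        assert x.mean() == pytest.approx(1.0, abs=0.01)
        assert x.min() >= 0 and x.max() <= 2

    def test_truncation_keeps_all_draws_inside_bounds(self):
        spec = ParameterSpec("C", family="lognormal", mean=2.25, sd=1.13,
                             minimum=1.02, maximum=4.01)
        x = sample_parameter(spec, 50_000, seed=11)
        assert x.min() >= 1.02 and x.max() <= 4.01

    def test_zero_sd_lognormal_is_constant(self):
        spec = ParameterSpec("K", family="lognormal", mean=5.0, sd=0.0)
        assert np.array_equal(sample_parameter(spec, 10, seed=1), np.full(10, 5.0))

    def test_infeasible_truncation_raises_with_name(self):
        spec = ParameterSpec("tight", family="lognormal", mean=100.0, sd=1.0,
                             minimum=99.999, maximum=100.0)
        with pytest.raises(ValueError, match="tight"):
            sample_parameter(spec, 1000, seed=0)

    def test_reproducible_and_name_keyed_streams(self):
        spec = ParameterSpec("BW", family="lognormal", mean=60, sd=10)
        a = sample_parameter(spec, 1000, seed=5)
        b = sample_parameter(spec, 1000, seed=5)
        assert np.array_equal(a, b)
        other = sample_parameter(
            ParameterSpec("SA", family="lognormal", mean=60, sd=10), 1000, seed=5
        )
        assert not np.array_equal(a, other)

    def test_adding_a_parameter_does_not_perturb_others(self):
        s1 = [ParameterSpec("A", family="lognormal", mean=10, sd=2)]
        s2 = s1 + [ParameterSpec("B", family="lognormal", mean=3, sd=1)]
        m1 = sample_parameters(s1, 500, seed=9)
        m2 = sample_parameters(s2, 500, seed=9)
        assert np.array_equal(m1["A"], m2["A"])


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="weibull", mean=1.0),
            dict(family="lognormal", mean=-1.0, sd=1.0),
            dict(family="lognormal", mean=5.0, sd=-0.1),
            dict(family="lognormal", mean=5.0, sd=1.0, minimum=6.0, maximum=10.0),
            dict(family="triangular", mean=1.0),
            dict(family="triangular", mean=1.0, minimum=0.0, maximum=2.0, mode=5.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ParameterSpec("bad", **kwargs)

    def test_triangular_mode_defaults_to_clipped_mean(self):
        spec = ParameterSpec("T", family="triangular", mean=9.0, minimum=0.0, maximum=2.0)
        assert spec.triangular_mode == 2.0


class TestInduceCorrelations:
    def _uniform_matrix(self, n=10_000, seed=2):
        rng = np.random.default_rng(seed)
        return SampleMatrix(
            pd.DataFrame({"u": rng.uniform(size=n), "v": rng.uniform(size=n)}), seed
        )

    def test_empty_spec_is_identity(self):
        m = self._uniform_matrix()
        out = induce_correlations(m, CorrelationSpec())
        assert out.data.equals(m.data)

    def test_hits_positive_target(self):
        m = self._uniform_matrix()
        out = induce_correlations(m, CorrelationSpec.from_pairs([("u", "v", 0.9)]))
        rho = stats.spearmanr(out["u"], out["v"]).statistic
        assert 0.85 <= rho <= 0.95

    def test_hits_negative_target_and_preserves_marginals(self):
        m = self._uniform_matrix()
        out = induce_correlations(m, CorrelationSpec.from_pairs([("u", "v", -0.5)]))
        rho = stats.spearmanr(out["u"], out["v"]).statistic
        assert -0.55 <= rho <= -0.45
        for col in ("u", "v"):
            assert np.array_equal(np.sort(out[col]), np.sort(m[col]))

    def test_non_psd_structure_raises(self):
        rng = np.random.default_rng(0)
        m = SampleMatrix(
            pd.DataFrame(rng.uniform(size=(100, 3)), columns=["a", "b", "c"]), 0
        )
        bad = CorrelationSpec.from_pairs(
            [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", -0.9)]
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            induce_correlations(m, bad)

    def test_unknown_parameter_raises(self):
        m = self._uniform_matrix(n=100)
        with pytest.raises(KeyError, match="missing"):
            induce_correlations(m, CorrelationSpec.from_pairs([("u", "missing", 0.5)]))

    @given(rho=st.floats(min_value=-0.95, max_value=0.95))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_marginals_always_preserved(self, rho):
        m = self._uniform_matrix(n=2000, seed=4)
        out = induce_correlations(m, CorrelationSpec.from_pairs([("u", "v", rho)]))
        for col in ("u", "v"):
            assert np.array_equal(np.sort(out[col]), np.sort(m[col]))


class TestFitSummaryToSpec:
    def test_carries_all_four_statistics(self):
        summ = ConcentrationSummary("RVS", "As", 72.3, 26.8, 34.7, 106.3, "mg/kg", 7)
        spec = fit_summary_to_spec(summ)
        assert spec.family == "lognormal"
        assert (spec.mean, spec.sd, spec.minimum, spec.maximum) == (72.3, 26.8, 34.7, 106.3)

    def test_zero_sd_summary_samples_to_constant(self):
        summ = ConcentrationSummary("RVS", "Cr", 70.0, 0.0, 70.0, 70.0, "mg/kg", 7)
        x = sample_parameter(fit_summary_to_spec(summ), 100, seed=0)
        assert np.array_equal(x, np.full(100, 70.0))

    def test_truncated_water_summary_draws_inside_range(self):
        summ = ConcentrationSummary(
            "surface_water", "Cd", 0.10, 0.07, 0.03, 0.25, "ug/L", 10
        )
        x = sample_parameter(fit_summary_to_spec(summ), 100_000, seed=1)
        assert x.min() >= 0.03 and x.max() <= 0.25

    def test_nonpositive_mean_rejected(self):
        class Summ:
            mean, sd, minimum, maximum = 0.0, 1.0, 0.0, 2.0

        with pytest.raises(ValueError, match="nonpositive|lognormal"):
            fit_summary_to_spec(Summ())


def test_read_parameter_table_roundtrip(tmp_path):
    path = tmp_path / "params.csv"
    path.write_text(
        "name,family,mean,sd,min,max,mode,units\n"
        "BW,lognormal,60,10,40,100,,kg\n"
        "EF,point,350,,,,,d/yr\n"
        "T,triangular,1.4,,0.25,3.0,1.0,h\n"
    )
    specs = {s.name: s for s in read_parameter_table(path)}
    assert specs["BW"].sd == 10 and specs["BW"].maximum == 100
    assert specs["EF"].family == "point"
    assert specs["T"].triangular_mode == 1.0


def test_duplicate_parameter_names_rejected():
    specs = [ParameterSpec("A", family="point", mean=1)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        sample_parameters(specs, 10, seed=0)
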