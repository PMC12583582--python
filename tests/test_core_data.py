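"""Domain types, registry lookups, survey I/O and descriptive statistics."""

import math

import numpy as np
import pytest

from soilrisk import core_data
from soilrisk.core_data import (IsotopeMeasurement, PAHProfile, ParameterRegistry,
                                SchemaError, SoilSample, UnknownAnalyteError,
                                ValidationError, compute_descriptive_stats,
                                read_survey, write_survey)


class TestTypes:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError, match="Cd"):
            SoilSample("S1", {"Cd": -0.1})

    def test_undeclared_element_rejected(self):
        with pytest.raises(ValidationError, match="Hg"):
            SoilSample("S1", {"Hg": 1.0})

    def test_nd_is_distinct_from_zero(self):
        p = PAHProfile("S1", {"Ant": 0.0, "BaP": None})
        assert p.detected() == {"Ant": 0.0}
        assert p.concentrations("zero") == {"Ant": 0.0, "BaP": 0.0}
        assert p.concentrations("exclude") == {"Ant": 0.0}
        assert p.concentrations("half-lod", {"BaP": 0.4}) == {"Ant": 0.0, "BaP": 0.2}

    def test_half_lod_requires_lod(self):
        with pytest.raises(ValueError, match="LOD"):
            PAHProfile("S1", {"BaP": None}).concentrations("half-lod")

    def test_isotope_ratio_must_be_positive(self):
        with pytest.raises(ValidationError):
            IsotopeMeasurement("S1", {"r206_207": -1.2})

    def test_isotope_consistency_warning(self):
        # 206/207 differs by >0.5% from 206/204 ÷ 207/204 = 18.7/15.6 = 1.19872
        m = IsotopeMeasurement("S1", {"r206_204": 18.7, "r207_204": 15.6,
                                      "r206_207": 1.2100})
        warnings = m.consistency_warnings()
        assert len(warnings) == 1 and "r206_207" in warnings[0]
        consistent = IsotopeMeasurement("S1", {"r206_204": 18.7, "r207_204": 15.6,
                                               "r206_207": 18.7 / 15.6})
        assert consistent.consistency_warnings() == []


class TestRegistry:
    def test_lookup_total_over_declared_set(self, registry):
        for el in ("Zn", "Cu", "Ni", "Pb", "Cr", "Cd", "As"):
            assert registry.ucc_for(el) > 0
            assert registry.tr_for(el) > 0

    def test_unknown_analyte_is_hard_error(self, registry):
        with pytest.raises(UnknownAnalyteError):
            registry.ucc_for("Hg")
        with pytest.raises(UnknownAnalyteError):
            registry.tef_for("Chr", "study")

    def test_benchmark_invariants(self, registry):
        for cmp_ in registry.nc:
            assert registry.mpc_for(cmp_) >= registry.nc_for(cmp_)
        for cmp_ in registry.erl_erm:
            erl, erm = registry.erl_erm_for(cmp_)
            assert erm >= erl

    def test_yaml_override(self, tmp_path):
        p = tmp_path / "refs.yaml"
        p.write_text("ucc:\n  Zn: 50\ntr:\n  Zn: 2\n")
        reg = ParameterRegistry.from_yaml(p)
        assert reg.ucc_for("Zn") == 50
        assert reg.tr_for("Zn") == 2
        assert reg.ucc_for("Cu") == 29  # untouched default


class TestIO:
    def test_pte_round_trip_preserves_values(self, tmp_path):
        samples = [SoilSample(f"S{i}", {"Zn": 100.123456789 + i, "Cd": 0.21},
                              ph=8.1, ec=500.0) for i in range(3)]
        path = tmp_path / "pte.csv"
        write_survey(samples, path)
        back, issues = read_survey(path, "pte")
        assert issues == []
        assert len(back) == 3
        for a, b in zip(samples, back):
            assert a.pte == b.pte and a.ph == b.ph and a.ec == b.ec

    def test_negative_value_names_row_and_column(self, tmp_path):
        path = tmp_path / "pte.csv"
        path.write_text("sample_id,Zn,Cd\nS1,100,0.2\nS2,90,-0.3\n")
        with pytest.raises(ValidationError, match="S2.*Cd"):
            read_survey(path, "pte")
        records, issues = read_survey(path, "pte", strict=False)
        assert len(records) == 1 and "S2" in issues[0]

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,Zn\nS1,100\n")
        with pytest.raises(SchemaError, match="sample_id"):
            read_survey(path, "pte")

    def test_isotope_inconsistency_reported(self, tmp_path):
        path = tmp_path / "iso.csv"
        path.write_text("sample_id,r206_204,r207_204,r206_207,Pb\n"
                        "S1,18.7,15.6,1.21,30\n")
        records, issues = read_survey(path, "isotope")
        assert len(records) == 1
        assert any("r206_207" in w for w in issues)

    def test_pah_nd_round_trip(self, tmp_path):
        profiles = [PAHProfile("S1", {"Ant": 10.5, "BaP": None})]
        path = tmp_path / "pah.csv"
        write_survey(profiles, path)
        back, _ = read_survey(path, "pah")
        assert back[0].pah == {"Ant": 10.5, "BaP": None}


class TestDescriptiveStats:
    def test_survey_zn_cv(self):
        # mean 125.55 and sd 40.77 give the tabulated cv of 0.32
        assert round(40.77 / 125.55, 2) == 0.32
        stats = compute_descriptive_stats([100.0, 120.0, 156.65])
        assert stats.cv == pytest.approx(stats.sd / stats.mean)

    def test_constant_vector_flags_shape_stats(self):
        stats = compute_descriptive_stats([5.0, 5.0, 5.0])
        assert stats.mean == 5 and stats.sd == 0 and stats.cv == 0
        assert not stats.shape_defined
        assert stats.skewness is None and stats.kurtosis is None

    def test_moments_against_direct_summation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        n = len(x)
        mean = x.sum() / n
        sd = math.sqrt(((x - mean) ** 2).sum() / (n - 1))
        m2 = ((x - mean) ** 2).sum() / n
        m3 = ((x - mean) ** 3).sum() / n
        m4 = ((x - mean) ** 4).sum() / n
        g1 = m3 / m2 ** 1.5
        skew = math.sqrt(n * (n - 1)) / (n - 2) * g1  # adjusted Fisher–Pearson
        g2 = m4 / m2 ** 2 - 3.0
        kurt = ((n - 1) / ((n - 2) * (n - 3))) * ((n + 1) * g2 + 6)
        stats = compute_descriptive_stats(x)
        assert stats.mean == pytest.approx(mean)
        assert stats.sd == pytest.approx(sd)
        assert stats.cv == pytest.approx(sd / mean)
        assert stats.skewness == pytest.approx(skew)
        assert stats.kurtosis == pytest.approx(kurt)

    def test_min_mean_max_ordering(self):
        stats = compute_descriptive_stats([3.0, 9.0, 1.0, 4.0])
        assert stats.min <= stats.mean <= stats.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_descriptive_stats([])


def test_module_declares_ratio_keys():
    assert set(core_data.RATIO_KEYS) >= {"r206_207", "r208_207"}
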