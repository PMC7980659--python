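"""Published predictor evaluation, the generic linear engine, units."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skinperm as sp
from skinperm.errors import (
    DescriptorMismatchError,
    MissingDescriptorError,
    UnitError,
)


class TestPublishedPredictors:
    @pytest.mark.parametrize(
        "log_kow,mw,expected",
        [
            (0.0, 1e-12, -2.80),   # intercept (MW term vanishes)
            (1.0, 100.0, -2.70),
            (2.0, 1e-12, -1.48),
        ],
    )
    def test_dermwin_values(self, log_kow, mw, expected):
        p = sp.predict_dermwin(sp.PartitionDescriptors(log_kow=log_kow, mw=mw))
        assert p.value == pytest.approx(expected, abs=1e-9)
        assert p.unit == "cm/h"

    @pytest.mark.parametrize(
        "fields,expected",
        [
            (dict(E=0, S=0, A=0, B=0, V=1e-12), -5.328),  # intercept
            (dict(E=0, S=0, A=0, B=0, V=1.0), -3.531),
            (dict(E=0, S=0, A=0, B=1.0, V=1e-12), -7.756),
        ],
    )
    def test_zhang_values(self, fields, expected):
        p = sp.predict_zhang(sp.SoluteDescriptors(**fields))
        assert p.value == pytest.approx(expected, abs=1e-9)
        assert p.unit == "cm/s"

    @pytest.mark.parametrize(
        "log_kow,log_kaw,expected",
        [(0.0, 0.0, -5.41), (1.0, 1.0, -4.81), (-1.0, -1.0, -6.01)],
    )
    def test_ppm_values(self, log_kow, log_kaw, expected):
        p = sp.predict_ppm(
            sp.PartitionDescriptors(log_kow=log_kow, log_kaw=log_kaw)
        )
        assert p.value == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "u1,u2,expected",
        [(0.0, 0.0, -5.35), (1.0, 0.0, -4.77), (0.0, 1.0, -8.86)],
    )
    def test_gcgc_values(self, u1, u2, expected):
        p = sp.predict_gcgc(sp.RetentionParameters(u1, u2))
        assert p.value == pytest.approx(expected, abs=1e-9)

    def test_ppm_propagates_input_provenance(self):
        d = sp.PartitionDescriptors(
            log_kow=sp.ProvenancedValue(1.0, "ASM"),
            log_kaw=sp.ProvenancedValue(-2.0, "experimental"),
        )
        p = sp.predict_ppm(d)
        assert p.provenance == {"log_kow": "ASM", "log_kaw": "experimental"}

    def test_missing_descriptor_errors_name_the_descriptor(self):
        with pytest.raises(MissingDescriptorError, match="mw"):
            sp.predict_dermwin(sp.PartitionDescriptors(log_kow=1.0))
        with pytest.raises(MissingDescriptorError, match="log_kaw"):
            sp.predict_ppm(sp.PartitionDescriptors(log_kow=1.0))
        with pytest.raises(MissingDescriptorError, match="B"):
            sp.predict_zhang(sp.SoluteDescriptors(E=0, S=0, A=0, V=1.0))


class TestRegistryEquivalence:
    def test_dedicated_ops_match_registry_bitwise(self, rng):
        """1000 random descriptor draws: wrappers == generic evaluation exactly."""
        reg = sp.load_registry()
        for _ in range(1000):
            kow, kaw, mw = rng.normal(0, 3), rng.normal(0, 3), abs(rng.normal(200, 80)) + 1
            e, s, a, b, v = rng.normal(0, 1, 5)
            v = abs(v) + 0.1
            u1, u2 = rng.normal(4, 1), rng.normal(0.5, 0.2)
            pd_ = sp.PartitionDescriptors(log_kow=kow, log_kaw=kaw, mw=mw)
            assert sp.predict_ppm(pd_).value == sp.predict_linear(
                reg["ppm_eq5"], {"log_kow": kow, "log_kaw": kaw}
            )
            assert sp.predict_dermwin(pd_).value == sp.predict_linear(
                reg["dermwin_eq1"], {"log_kow": kow, "mw": mw}
            )
            sd = sp.SoluteDescriptors(E=e, S=s, A=a, B=b, V=v)
            assert sp.predict_zhang(sd).value == sp.predict_linear(
                reg["zhang_eq2"],
                {"E": e, "S": s, "A": a, "B": b, "V": v, "Jplus": 0.0, "Jminus": 0.0},
            )
            assert sp.predict_gcgc(sp.RetentionParameters(u1, u2)).value == (
                sp.predict_linear(reg["gcgc_eq7"], {"u1": u1, "u2": u2})
            )

    def test_registry_ships_all_published_entries(self):
        reg = sp.load_registry()
        assert set(reg) == {
            "dermwin_eq1", "zhang_eq2", "ppm_eq5", "ppm_eq6", "gcgc_eq7", "gcgc_eq8",
        }
        assert reg["ppm_eq6"].intercept == -5.46
        assert sp.predict_linear(
            reg["ppm_eq6"], {"log_kow": 1.0, "log_kaw": 1.0}
        ) == pytest.approx(-4.86, abs=1e-9)

    def test_identity_coefficient_passthrough(self):
        m = sp.LFERCoefficients("identity", 0.0, {"x": 1.0})
        for c in (-3.7, 0.0, 12.25):
            assert sp.predict_linear(m, {"x": c}) == c

    def test_key_mismatch_lists_missing(self):
        m = sp.get_model("ppm_eq5")
        with pytest.raises(DescriptorMismatchError) as exc:
            sp.predict_linear(m, {"log_kow": 1.0})
        assert exc.value.missing == ["log_kaw"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        x1=st.floats(-10, 10), x2=st.floats(-10, 10),
        y1=st.floats(-10, 10), y2=st.floats(-10, 10),
    )
    def test_superposition_about_intercept(self, a, b, x1, x2, y1, y2):
        """predict_linear is affine: response to a*x + b*y decomposes."""
        m = sp.LFERCoefficients("toy", -2.0, {"p": 0.7, "q": -1.3})
        mixed = sp.predict_linear(m, {"p": a * x1 + b * y1, "q": a * x2 + b * y2})
        fx = sp.predict_linear(m, {"p": x1, "q": x2}) - m.intercept
        fy = sp.predict_linear(m, {"p": y1, "q": y2}) - m.intercept
        assert mixed == pytest.approx(m.intercept + a * fx + b * fy, abs=1e-8)


class TestZhangNeutralReduction:
    def test_absent_ionic_descriptors_equal_explicit_zero(self, rng):
        for _ in range(20):
            e, s, a, b = rng.normal(0, 1, 4)
            v = abs(rng.normal(1, 0.5)) + 0.1
            without = sp.predict_zhang(sp.SoluteDescriptors(E=e, S=s, A=a, B=b, V=v))
            with_zero = sp.predict_zhang(
                sp.SoluteDescriptors(E=e, S=s, A=a, B=b, V=v, Jplus=0.0, Jminus=0.0)
            )
            assert without.value == with_zero.value


class TestUnits:
    def test_identity_conversion(self):
        assert sp.convert_logkp_unit(-5.328, "cm/s", "cm/s") == -5.328

    def test_seconds_to_hours_adds_log_3600(self):
        assert sp.convert_logkp_unit(0.0, "cm/s", "cm/h") == pytest.approx(
            math.log10(3600), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(v=st.floats(-12, 4))
    def test_round_trip(self, v):
        back = sp.convert_logkp_unit(
            sp.convert_logkp_unit(v, "cm/s", "cm/h"), "cm/h", "cm/s"
        )
        assert back == pytest.approx(v, abs=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            sp.convert_logkp_unit(1.0, "cm/s", "m/s")

    def test_prediction_in_unit_helper(self):
        p = sp.predict_ppm(sp.PartitionDescriptors(log_kow=0.0, log_kaw=0.0))
        q = p.in_unit("cm/h")
        assert q.value == pytest.approx(-5.41 + math.log10(3600), abs=1e-12)
        assert q.unit == "cm/h"
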