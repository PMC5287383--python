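"""Internal-standard normalization, replicate aggregation, Dixon's Q."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglyco.chem import Peak
from nglyco.errors import InsufficientData, MissingInternalStandard
from nglyco.quantify import (
    AbundanceMatrix,
    InternalStandardRef,
    aggregate_group,
    dixon_outlier_test,
    group_summaries,
    locate_internal_standard,
    normalize_intensities,
    screen_outliers,
)


def _peaks(*pairs, mode="positive"):
    return [Peak(mz=m, intensity=i, mode=mode) for m, i in pairs]


def _matrix(values_by_group: dict[str, list[float]], species="(Hex)5(HexNAc)2 [M+Na]+"):
    rows, groups = {}, {}
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            sid = f"{group[0]}{i + 1}"
            rows[sid] = {species: v}
            groups[sid] = group
    data = pd.DataFrame.from_dict(rows, orient="index")
    return AbundanceMatrix(data=data, groups=pd.Series(groups))


class TestInternalStandard:
    def test_only_in_window_peak_found(self):
        peak = locate_internal_standard(_peaks((1157.30, 500.0), (1257.42, 900.0)), "positive")
        assert peak.mz == 1157.30

    def test_most_intense_in_window_wins(self):
        peak = locate_internal_standard(_peaks((1157.20, 100.0), (1157.31, 400.0)), "positive")
        assert peak.mz == 1157.31

    def test_missing_standard_raises(self):
        with pytest.raises(MissingInternalStandard):
            locate_internal_standard(_peaks((1257.42, 900.0)), "positive")

    def test_negative_mode_reference(self):
        peak = locate_internal_standard(_peaks((1133.20, 50.0), mode="negative"), "negative")
        assert peak.mz == 1133.20
        assert InternalStandardRef().mz_for("negative") == 1133.25


class TestNormalization:
    def test_examples(self):
        is_peak = Peak(mz=1157.25, intensity=900.0, mode="positive")
        out = normalize_intensities(_peaks((1157.25, 900.0), (1257.42, 450.0), (1300.0, 0.0)), is_peak)
        assert [p.intensity for p in out] == [100.0, 50.0, 0.0]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying all raw intensities by k leaves corrected values unchanged."""
        raw = [(1157.25, 800.0), (1257.42, 240.0), (1500.0, 60.0)]
        base = normalize_intensities(_peaks(*raw), Peak(1157.25, 800.0, "positive"))
        scaled = normalize_intensities(
            _peaks(*((m, i * scale) for m, i in raw)), Peak(1157.25, 800.0 * scale, "positive")
        )
        for a, b in zip(base, scaled):
            assert a.intensity == pytest.approx(b.intensity, rel=1e-12)

    def test_zero_standard_rejected(self):
        with pytest.raises(MissingInternalStandard):
            normalize_intensities(_peaks((1257.0, 1.0)), Peak(1157.25, 0.0, "positive"))


class TestAggregation:
    def test_single_nonzero_triple_matches_printed_cell(self):
        """One replicate at 22.95 with two zeros reproduces the table cell
        mean 7.65, SD 13.25 under the zeros-included convention."""
        m = _matrix({"control": [22.95, 0.0, 0.0]})
        s = aggregate_group(m, m.species[0], "control")
        assert s.detectable
        assert s.mean == pytest.approx(7.65, abs=1e-9)
        assert s.sd == pytest.approx(13.25, abs=5e-3)

    def test_all_zero_is_undetectable(self):
        s = aggregate_group(_matrix({"control": [0.0, 0.0, 0.0]}), "(Hex)5(HexNAc)2 [M+Na]+", "control")
        assert not s.detectable and s.mean == 0.0 and s.sd == 0.0

    def test_constant_replicates(self):
        s = aggregate_group(_matrix({"model": [5.0, 5.0, 5.0]}), "(Hex)5(HexNAc)2 [M+Na]+", "model")
        assert s.mean == 5.0 and s.sd == 0.0

    @given(values=st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_conservation(self, values):
        """n * mean equals the replicate sum exactly."""
        m = _matrix({"treated": values})
        s = aggregate_group(m, m.species[0], "treated")
        assert s.n * s.mean == pytest.approx(sum(values), rel=1e-12, abs=1e-9)

    def test_group_summaries_shape(self):
        m = _matrix({"control": [1.0, 2.0], "model": [0.0, 0.0], "treated": [3.0, 4.0]})
        summ = group_summaries(m)
        assert summ.loc[m.species[0], "model_detectable"] == False  # noqa: E712
        assert summ.loc[m.species[0], "control_n"] == 2


class TestDixon:
    def test_flags_clear_outlier(self):
        res = dixon_outlier_test([1.0, 1.1, 5.0], alpha=0.05)
        assert res.flagged and res.suspect == 2
        assert res.q == pytest.approx(3.9 / 4.0)
        assert res.critical == 0.970

    def test_no_flag_for_even_spread(self):
        res = dixon_outlier_test([1.0, 2.0, 3.0], alpha=0.05)
        assert not res.flagged and res.q == pytest.approx(0.5)

    def test_constant_sample_is_no_test(self):
        res = dixon_outlier_test([4.2, 4.2, 4.2])
        assert not res.flagged and res.reason == "zero range"

    def test_too_small_sample_raises(self):
        with pytest.raises(InsufficientData):
            dixon_outlier_test([1.0, 2.0])

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, a, b):
        """The Q decision is unchanged by positive affine transforms."""
        values = [1.4, 2.0, 2.2, 9.0]
        base = dixon_outlier_test(values)
        moved = dixon_outlier_test([a * v + b for v in values])
        assert base.flagged == moved.flagged and base.suspect == moved.suspect
        assert base.q == pytest.approx(moved.q, rel=1e-9)

    def test_matrix_screen_reports_and_excludes(self):
        m = _matrix({"control": [1.0, 1.1, 9.0], "model": [2.0, 2.1, 2.2], "treated": [3.0, 3.0, 3.0]})
        report, screened = screen_outliers(m, exclude=True)
        assert len(report) == 1
        assert report.iloc[0]["group"] == "control"
        assert screened.data.loc["c3", m.species[0]] == pytest.approx(1.05)
        # report-only leaves the matrix untouched
        report2, untouched = screen_outliers(m, exclude=False)
        assert untouched.data.equals(m.data)
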