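"""Dscore arithmetic, classification boundaries and aggregation conventions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppidrugg import reference
from ppidrugg.druggability import (
    DIFFICULT,
    DRUGGABLE,
    MODERATELY_DRUGGABLE,
    VERY_DRUGGABLE,
    UndefinedCorrelationError,
    aggregate_target,
    classify_halgren,
    classify_ppi,
    dscore,
    make_record,
    pearson_r2,
    percent_reduction,
    pic50,
    records_from_table,
)
from ppidrugg.pocket_descriptors import SiteDescriptors


class TestDscore:
    def test_zero_inputs(self):
        assert dscore(0, 0, 0) == 0.0

    @pytest.mark.parametrize(
        "n,e,p,expected4",
        [
            (54, 0.66, 0.28, 0.9960),  # HDM2 survey medians
            (27, 0.60, 1.01, 0.5212),  # XIAP survey medians
        ],
    )
    def test_reported_median_arithmetic(self, n, e, p, expected4):
        assert dscore(n, e, p) == pytest.approx(expected4, abs=5e-5)

    def test_domain_errors(self):
        for bad in ((-1, 0.5, 0.1), (10, 1.5, 0.1), (10, 0.5, -0.1)):
            with pytest.raises(ValueError):
                dscore(*bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=200),
        st.floats(min_value=0.0, max_value=0.99),
        st.floats(min_value=0.0, max_value=2.0),
    )
    def test_monotonicity(self, n, e, p):
        """Strictly increasing in n and e, strictly decreasing in p."""
        base = dscore(n, e, p)
        assert dscore(n + 1, e, p) > base
        assert dscore(n, e + 0.01, p) > base
        assert dscore(n, e, p + 0.01) < base


class TestClassification:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (1.20, VERY_DRUGGABLE),
            (1.0, VERY_DRUGGABLE),
            (0.9999999, DRUGGABLE),
            (0.75, DRUGGABLE),
            (0.7499999, MODERATELY_DRUGGABLE),
            (0.5, MODERATELY_DRUGGABLE),
            (0.4999999, DIFFICULT),
            (0.0, DIFFICULT),
            (None, DIFFICULT),  # ND
        ],
    )
    def test_ppi_boundaries(self, score, expected):
        assert classify_ppi(score) == expected

    @pytest.mark.parametrize(
        "score,expected",
        [(0.77, DIFFICULT), (0.7999999, DIFFICULT), (0.8, DRUGGABLE),
         (0.93, DRUGGABLE), (0.9999999, DRUGGABLE), (1.0, VERY_DRUGGABLE),
         (1.20, VERY_DRUGGABLE)],
    )
    def test_halgren_boundaries(self, score, expected):
        assert classify_halgren(score) == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
    def test_every_score_gets_exactly_one_class(self, score):
        assert classify_ppi(score) in (
            VERY_DRUGGABLE, DRUGGABLE, MODERATELY_DRUGGABLE, DIFFICULT
        )
        assert classify_halgren(score) in (VERY_DRUGGABLE, DRUGGABLE, DIFFICULT)


def _rec(i, value, form="ligand_bound", target="T"):
    if value is None:
        desc = SiteDescriptors.nd()
    else:
        n, e, p = value
        desc = SiteDescriptors(n=n, e=e, p=p, detected=True)
    return make_record(f"s{i}", target, form, desc)


class TestAggregation:
    def test_even_count_median_convention(self):
        # two dscores 0.4 and 0.6 -> median 0.5
        recs = [
            _rec(0, (4, 0.55, 0.4265)),   # dscore ~0.4
            _rec(1, (9, 0.55, 0.1565)),
        ]
        scores = [r.dscore for r in recs]
        summ = aggregate_target(recs)
        assert summ.overall["dscore"].median == pytest.approx(np.median(scores))
        assert summ.overall["dscore"].median == pytest.approx(
            (scores[0] + scores[1]) / 2
        )

    def test_half_integer_pocket_medians(self):
        """Even-count samples produce half-integer pocket-size medians
        (19.5, 32.5, 50.5 style)."""
        for pair, expected in (((19, 20), 19.5), ((32, 33), 32.5), ((50, 51), 50.5)):
            recs = [_rec(i, (n, 0.6, 0.2)) for i, n in enumerate(pair)]
            assert aggregate_target(recs).overall["n"].median == expected

    def test_single_record(self):
        summ = aggregate_target([_rec(0, (10, 0.5, 0.1))])
        s = summ.overall["dscore"]
        assert s.median == s.min == s.max
        assert s.sd is None

    def test_nd_counted_but_excluded_from_medians(self):
        recs = [_rec(0, (10, 0.5, 0.1)), _rec(1, None), _rec(2, None)]
        summ = aggregate_target(recs)
        assert summ.n_records == 3 and summ.n_detected == 1
        assert summ.overall["dscore"].count == 1

    def test_sample_sd(self):
        recs = [_rec(i, (n, 0.5, 0.0)) for i, n in enumerate((16, 25, 36))]
        vals = [r.dscore for r in recs]
        assert aggregate_target(recs).overall["dscore"].sd == pytest.approx(
            np.std(vals, ddof=1)
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_target([])


class TestPercentReduction:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [(1.09, 0.73, 33), (0.52, 0.31, 40), (0.72, 0.48, 33), (1.09, 0.87, 20),
         (1.0, 1.0, 0)],
    )
    def test_reported_cases(self, ref, other, expected):
        assert percent_reduction(ref, other) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.5)


class TestCorrelationAndActivity:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r2(x, [2 * v + 1 for v in x]).r2 == pytest.approx(1.0)
        out = pearson_r2(x, [-v for v in x])
        assert out.r == pytest.approx(-1.0) and out.r2 == pytest.approx(1.0)

    def test_against_covariance_formula(self):
        x = [0.2, 1.4, 2.9, 3.1, 4.8]
        y = [1.1, 0.4, 2.2, 3.9, 3.0]
        # direct textbook formula, computed independently
        mx, my = sum(x) / 5, sum(y) / 5
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        expected = cov / math.sqrt(vx * vy)
        assert pearson_r2(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_nd_imputed_as_zero_on_request(self):
        x = [1.0, 2.0, None, 4.0]
        out = pearson_r2(x, [1.0, 2.0, 0.0, 4.0], impute_nd_zero=True)
        assert out.r == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "ic50,expected", [(1e-9, 9.0), (1e-6, 6.0), (50e-9, 7.3010)]
    )
    def test_pic50(self, ic50, expected):
        assert pic50(ic50) == pytest.approx(expected, abs=1e-4)

    def test_pic50_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pic50(0.0)


class TestScoreOfReportedMedians:
    def test_formula_consistency_of_survey_rows(self):
        """Dscore at the reported component medians reproduces the reported
        median score to two decimals for the formula-consistent targets
        (Bcl-2 within 0.02; Bcl-xL and DCN1 are the documented
        median-of-scores vs score-of-medians exceptions)."""
        for target in reference.FORMULA_CONSISTENT_TARGETS:
            row = reference.TARGET_MEDIANS[target]
            assert round(dscore(row["n"], row["e"], row["p"]), 2) == pytest.approx(
                row["dscore"], abs=5e-3
            )
        row = reference.TARGET_MEDIANS["Bcl-2"]
        assert dscore(row["n"], row["e"], row["p"]) == pytest.approx(
            row["dscore"], abs=0.02
        )


def test_records_from_table_round_trip():
    table = pd.DataFrame(
        {
            "structure_id": ["a", "b"],
            "target": ["T", "T"],
            "form": ["apo", "ligand_bound"],
            "detected": [True, False],
            "n": [25, np.nan],
            "e": [0.6, np.nan],
            "p": [0.3, np.nan],
        }
    )
    recs = records_from_table(table)
    assert recs[0].dscore == pytest.approx(dscore(25, 0.6, 0.3))
    assert recs[1].dscore is None and recs[1].ppi_class == DIFFICULT
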