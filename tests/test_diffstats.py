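"""Log-ratio heuristic, CV gate, significance stand-in, range statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxetools import (
    ExpressionDataset,
    InternalSignificance,
    cv_plus,
    heuristic_log2_ratio,
    max_ed_range,
    replicate_concordance,
    summarize_all,
    summarize_gene,
)
from gxetools.diffstats import GeneDifferentialSummary, LogRatio
from tests.conftest import make_dataset

TIMES = (0.0, 6.0, 12.0, 24.0)


class TestHeuristicLogRatio:
    @pytest.mark.parametrize(
        "num, den, value, substituted",
        [
            (8.0, 2.0, 2.0, False),  # plain log2 on the well-expressed branch
            (0.5, 10.0, -5.0, True),  # absent vs high: capped at the limit
            (10.0, 0.5, 5.0, True),
            (3.0, 0.5, 0.0, True),  # absent vs modest: uninformative
            (0.5, 3.0, 0.0, True),
            (0.2, 0.7, 0.0, True),  # both essentially absent
            (0.5, 5.0, 0.0, True),  # compared entry exactly 5: strict bound
            (1.0, 1.0, 0.0, False),  # boundary of the analytic branch
        ],
    )
    def test_branches(self, num, den, value, substituted):
        lr = heuristic_log2_ratio(num, den)
        assert lr.value == pytest.approx(value)
        assert lr.heuristic_substituted is substituted

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        b=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        """Swapping numerator and denominator negates the score on both the
        analytic and the capped branch."""
        fwd, rev = heuristic_log2_ratio(a, b), heuristic_log2_ratio(b, a)
        assert fwd.value == pytest.approx(-rev.value, abs=1e-12)
        assert fwd.heuristic_substituted == rev.heuristic_substituted


class TestSummaries:
    def test_flat_gene_all_zero(self):
        ds = make_dataset({"g": {(g, t): 8.0 for g in ("G1", "G2") for t in TIMES}})
        s = summarize_gene(ds, "g")
        assert all(s.gd[t].value == 0 for t in TIMES)
        assert all(lr.value == 0 for lr in s.ed.values())
        # ED at the control time is exactly 0 by definition
        assert s.ed[("G1", 0.0)] == LogRatio(0.0, False)

    def test_ed_and_gd_orientation(self):
        # reference rises 4 -> 16 at 6 hr; alternate identical
        cells = {(g, t): 4.0 for g in ("G1", "G2") for t in TIMES}
        cells.update({("G1", 6.0): 16.0, ("G2", 6.0): 16.0})
        s = summarize_gene(make_dataset({"g": cells}), "g")
        assert s.ed[("G1", 6.0)].value == pytest.approx(2.0)  # later over control
        assert s.gd[6.0].value == pytest.approx(0.0)

    def test_scaling_leaves_ratios_unchanged(self):
        cells = {("G1", t): v for t, v in zip(TIMES, (4.0, 16.0, 8.0, 4.0))}
        cells.update({("G2", t): 6.0 for t in TIMES})
        ds = make_dataset({"g": cells})
        scaled = ExpressionDataset(
            ds.data.assign(fpkm=ds.data["fpkm"] * 7.0), "G1", "G2", TIMES
        )
        a, b = summarize_gene(ds, "g"), summarize_gene(scaled, "g")
        for t in TIMES:
            assert a.gd[t].value == pytest.approx(b.gd[t].value)
        for k in a.ed:
            assert a.ed[k].value == pytest.approx(b.ed[k].value)

    def test_missing_gene_errors(self):
        ds = make_dataset({"g": {(g, t): 5.0 for g in ("G1", "G2") for t in TIMES}})
        with pytest.raises(Exception, match="not in dataset"):
            summarize_gene(ds, "nope")


def _summary_with_cvs(values):
    keys = [(g, t) for g in ("G1", "G2") for t in TIMES]
    return GeneDifferentialSummary(
        "g", ("G1", "G2"), TIMES, cv=dict(zip(keys, values))
    )


class TestCvGate:
    def test_all_low(self):
        assert cv_plus(_summary_with_cvs([0.1] * 8)) is True

    def test_two_failing_cells(self):
        assert cv_plus(_summary_with_cvs([0.9, 0.9] + [0.1] * 6)) is False

    def test_boundary_is_strict(self):
        # 0.4 itself fails; 7 passing cells suffice
        assert cv_plus(_summary_with_cvs([0.41] + [0.39] * 7)) is True
        assert cv_plus(_summary_with_cvs([0.4, 0.4] + [0.39] * 6)) is False

    def test_undefined_cells_fail_with_warning(self):
        vals = [float("nan"), float("nan")] + [0.1] * 6
        with pytest.warns(UserWarning, match="undefined CV"):
            assert cv_plus(_summary_with_cvs(vals)) is False


class TestMaxEdRange:
    def _summary(self, entries):
        s = GeneDifferentialSummary("g", ("G1", "G2"), TIMES)
        s.ed = {("G1", 0.0): LogRatio(0.0), ("G2", 0.0): LogRatio(0.0)}
        for i, lr in enumerate(entries):
            s.ed[("G1", TIMES[1 + i % 3])] = lr
        return s

    def test_plain_maximum(self):
        s = self._summary([LogRatio(1.2), LogRatio(-3.0), LogRatio(0.5)])
        assert max_ed_range(s) == pytest.approx(3.0)

    def test_capped_values_ignored(self):
        s = self._summary([LogRatio(5.0, True), LogRatio(1.0)])
        assert max_ed_range(s) == pytest.approx(1.0)

    def test_all_capped_is_undefined(self):
        s = self._summary([LogRatio(5.0, True), LogRatio(0.0, True)])
        assert np.isnan(max_ed_range(s))


class TestInternalSignificance:
    def test_identical_replicates_not_significant(self):
        ds = make_dataset({"g": {(g, t): 8.0 for g in ("G1", "G2") for t in TIMES}})
        sig = InternalSignificance(ds)
        assert sig.gd_q("g", 6.0) == pytest.approx(1.0)
        assert sig.ed_q("g", "G1", 6.0) == pytest.approx(1.0)

    def test_null_false_positive_rate(self):
        """Same-distribution sides: after BH, almost no gene reaches q<0.05."""
        rng = np.random.default_rng(5)
        cells = {}
        for i in range(400):
            base = rng.uniform(5, 50)
            cells[f"g{i}"] = {
                (g, t): base for g in ("G1", "G2") for t in TIMES
            }
        ds = make_dataset(cells, noise=0.1, seed=6)
        sig = InternalSignificance(ds)
        frac = (sig.gd_q_.to_numpy() < 0.05).mean()
        assert frac <= 0.05

    def test_planted_effect_detected(self):
        """An 8-fold genotypic difference at low noise is essentially always
        significant."""
        cells = {}
        for i in range(200):
            cells[f"g{i}"] = {("G1", t): 80.0 for t in TIMES}
            cells[f"g{i}"].update({("G2", t): 10.0 for t in TIMES})
        ds = make_dataset(cells, noise=0.05, seed=7)
        sig = InternalSignificance(ds)
        assert (sig.gd_q_.to_numpy() < 0.05).mean() >= 0.99

    def test_q_not_below_p(self):
        """BH q-values are a monotone transform of p and never smaller."""
        rng = np.random.default_rng(8)
        cells = {
            f"g{i}": {
                (g, t): rng.uniform(2, 100)
                for g in ("G1", "G2")
                for t in TIMES
            }
            for i in range(100)
        }
        ds = make_dataset(cells, noise=0.2, seed=9)
        sig = InternalSignificance(ds)
        # recompute raw p for one contrast and compare ordering with q
        q = sig.gd_q_[6.0].to_numpy()
        order = np.argsort(q)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_too_few_replicates_rejected(self):
        ds = make_dataset(
            {"g": {(g, t): 8.0 for g in ("G1", "G2") for t in TIMES}}, reps=1
        )
        with pytest.raises(Exception, match="replicates"):
            InternalSignificance(ds)


class TestReplicateConcordance:
    def test_self_comparison_is_one(self):
        ds = make_dataset(
            {f"g{i}": {(g, t): 20.0 for g in ("G1", "G2") for t in TIMES}
             for i in range(10)}
        )
        assert replicate_concordance(ds, "G1", 0.0, 0, 0) == 1.0

    def test_same_distribution_high_concordance(self):
        rng = np.random.default_rng(1)
        cells = {
            f"g{i}": {(g, t): rng.uniform(5, 200) for g in ("G1", "G2") for t in TIMES}
            for i in range(300)
        }
        ds = make_dataset(cells, noise=0.1, seed=2)
        assert replicate_concordance(ds, "G1", 6.0, 0, 1) >= 0.95

    def test_disjoint_expression_low_concordance(self):
        cells = {f"g{i}": {(g, t): 100.0 for g in ("G1", "G2") for t in TIMES}
                 for i in range(50)}
        ds = make_dataset(cells)
        # overwrite replicate 1 of the probed cell with FPKM 1
        m = (
            (ds.data["genotype"] == "G1")
            & (ds.data["time_hr"] == 6.0)
            & (ds.data["replicate"] == 1)
        )
        ds.data.loc[m, "fpkm"] = 1.0
        assert replicate_concordance(ds, "G1", 6.0, 0, 1) <= 0.05

    def test_unknown_replicate(self):
        ds = make_dataset({"g": {(g, t): 5.0 for g in ("G1", "G2") for t in TIMES}})
        with pytest.raises(Exception, match="unknown replicate"):
            replicate_concordance(ds, "G1", 0.0, 0, 99)
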