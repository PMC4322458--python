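"""Rule-cascade classification: examples, oracle equivalence, accounting."""

import numpy as np
import pandas as pd
import pytest

from gxetools import (
    CategoryCounts,
    CategoryLabel,
    ClassifierThresholds,
    GeneCategoryClassifier,
    classify_gene,
    derived_percentages,
)
from gxetools.classify import CATEGORY_ORDER
from gxetools.diffstats import GeneDifferentialSummary, LogRatio

TIMES = (0.0, 6.0, 12.0, 24.0)
GENOS = ("G1", "G2")


def build_summary(
    means=20.0,
    cvs=0.1,
    gd=(0.0, 0.0, 0.0, 0.0),
    ed_g1=(0.0, 0.0, 0.0),
    ed_g2=(0.0, 0.0, 0.0),
    sgd_q=(1.0, 1.0, 1.0, 1.0),
    sed_q_g1=(1.0, 1.0, 1.0),
    sed_q_g2=(1.0, 1.0, 1.0),
    gd_sub=(False,) * 4,
):
    if np.isscalar(means):
        means = {(g, t): means for g in GENOS for t in TIMES}
    if np.isscalar(cvs):
        cvs = {(g, t): cvs for g in GENOS for t in TIMES}
    ed = {(g, 0.0): LogRatio(0.0) for g in GENOS}
    for g, vals in zip(GENOS, (ed_g1, ed_g2)):
        for t, v in zip(TIMES[1:], vals):
            ed[(g, t)] = v if isinstance(v, LogRatio) else LogRatio(float(v))
    sed_q = {}
    for g, vals in zip(GENOS, (sed_q_g1, sed_q_g2)):
        for t, v in zip(TIMES[1:], vals):
            sed_q[(g, t)] = float(v)
    return GeneDifferentialSummary(
        gene_id="g",
        genotypes=GENOS,
        time_points=TIMES,
        mean_fpkm=means,
        cv=cvs,
        gd={t: LogRatio(float(v), s) for t, v, s in zip(TIMES, gd, gd_sub)},
        ed=ed,
        sgd_q={t: float(q) for t, q in zip(TIMES, sgd_q)},
        sed_q=sed_q,
    )


class TestCascadeExamples:
    def test_untested(self):
        s = build_summary(means=0.8)
        assert classify_gene(s, True) is CategoryLabel.UNTESTED

    def test_low_expression(self):
        s = build_summary(means=1.8)
        assert classify_gene(s, True) is CategoryLabel.LOW_EXPRESSION

    def test_gxe_fold_rule(self):
        # significant GD of 3.3 at 12 hr against 1.1 elsewhere: 3.3 > 2.8*1.1
        s = build_summary(
            gd=(1.1, 1.1, 3.3, 1.1), sgd_q=(1.0, 1.0, 0.01, 1.0)
        )
        assert classify_gene(s, True) is CategoryLabel.GXE
        # without the CV gate the same gene is not a GxE call
        assert classify_gene(s, False) is not CategoryLabel.GXE

    def test_gxe_zero_gd_denominator(self):
        # the compared GD being 0 qualifies whenever the SGD is nonzero
        s = build_summary(gd=(0.0, 3.0, 3.0, 3.0), sgd_q=(1.0, 0.01, 0.01, 0.01))
        assert classify_gene(s, True) is CategoryLabel.GXE

    def test_g_plus_e(self):
        s = build_summary(
            gd=(3.0, 3.0, 3.0, 3.0),
            sgd_q=(0.01,) * 4,
            ed_g1=(3.0, 3.0, 3.0),
            ed_g2=(3.0, 3.0, 3.0),
            sed_q_g1=(0.01, 1.0, 1.0),
            sed_q_g2=(0.01, 1.0, 1.0),
        )
        assert classify_gene(s, True) is CategoryLabel.G_PLUS_E

    def test_e_only(self):
        s = build_summary(
            ed_g1=(1.5, 1.5, 1.5),
            ed_g2=(1.5, 1.5, 1.5),
            sed_q_g1=(0.01, 0.01, 1.0),
            sed_q_g2=(0.01, 1.0, 1.0),
        )
        assert classify_gene(s, True) is CategoryLabel.E_ONLY

    def test_g_only(self):
        s = build_summary(gd=(2.0, 2.0, 2.0, 2.0), sgd_q=(0.01,) * 4)
        assert classify_gene(s, True) is CategoryLabel.G_ONLY

    def test_constant(self):
        s = build_summary()
        assert classify_gene(s, True) is CategoryLabel.CONSTANT

    def test_ambiguous_variants(self):
        big = build_summary(ed_g1=(3.0, 0.0, 0.0))
        # CV gate failed, big ED, no strong SGD
        assert classify_gene(big, False) is CategoryLabel.E_AMBIGUOUS
        strong = build_summary(
            ed_g1=(3.0, 0.0, 0.0), gd=(3.0,) * 4, sgd_q=(1e-5, 1.0, 1.0, 1.0)
        )
        assert classify_gene(strong, False) is CategoryLabel.G_PLUS_E_AMBIGUOUS
        none = build_summary()
        assert classify_gene(none, False) is CategoryLabel.AMBIGUOUS

    def test_capped_scores_participate(self):
        # a capped +5 ED counts for the |ED| > 2 ambiguity rules
        s = build_summary(ed_g1=(LogRatio(5.0, True), 0.0, 0.0))
        assert classify_gene(s, False) is CategoryLabel.E_AMBIGUOUS


# ---------------------------------------------------------------------------
# independent predicate-table oracle
# ---------------------------------------------------------------------------


def oracle_classify(s: GeneDifferentialSummary, cv_ok: bool) -> CategoryLabel:
    """Independently coded evaluator: every rule's condition is computed
    standalone into a table, then the first true row is selected."""
    th = ClassifierThresholds()
    means = list(s.mean_fpkm.values())
    gd = [s.gd[t].value for t in s.time_points]
    sgd = [s.sgd_q[t] < th.sgd_q for t in s.time_points]
    sed_counts = []
    for g in s.genotypes:
        sed_counts.append(
            sum(s.sed_q[(g, t)] < th.sed_q for t in s.time_points[1:])
        )
    nz = [x for x in gd if abs(x) > 1e-9]
    same_sign = all(x > 0 for x in nz) or all(x < 0 for x in nz)
    any_big_ed = any(abs(lr.value) > th.big_ed for lr in s.ed.values())
    ratio_hit = False
    for i, t in enumerate(s.time_points):
        if not sgd[i]:
            continue
        for j in range(len(gd)):
            if j != i and abs(gd[i]) > th.gxe_fold * abs(gd[j]):
                ratio_hit = True
    predicates = {
        CategoryLabel.UNTESTED: max(means) <= th.untested_mean_fpkm,
        CategoryLabel.LOW_EXPRESSION: (
            max(means) < th.low_expr_max_fpkm
            and sum(means) / len(means) < th.low_expr_grand_mean
        ),
        CategoryLabel.GXE: cv_ok and ratio_hit,
        CategoryLabel.G_PLUS_E: (
            cv_ok and sum(sgd) >= 3 and min(sed_counts) >= 1 and same_sign
        ),
        CategoryLabel.E_ONLY: cv_ok and sum(sgd) <= 1 and min(sed_counts) >= 1,
        CategoryLabel.G_ONLY: (
            cv_ok and min(sed_counts) == 0 and sum(sgd) >= 3 and same_sign
        ),
        CategoryLabel.CONSTANT: (
            cv_ok and min(sed_counts) == 0 and sum(sgd) <= 1 and not any_big_ed
        ),
        CategoryLabel.G_PLUS_E_AMBIGUOUS: (
            any_big_ed and any(s.sgd_q[t] < th.ge_ambig_q for t in s.time_points)
        ),
        CategoryLabel.E_AMBIGUOUS: any_big_ed,
        CategoryLabel.AMBIGUOUS: True,
    }
    for label in CATEGORY_ORDER:
        if predicates[label]:
            return label
    raise AssertionError("unreachable")


def random_summary(rng) -> tuple:
    """A randomized summary stressing every branch of the cascade."""
    means = {
        (g, t): float(rng.choice([0.5, 1.5, 3.0, 10.0, 100.0]))
        for g in GENOS
        for t in TIMES
    }
    q_choices = [1.0, 0.3, 0.04, 0.0005]

    def ratio():
        if rng.random() < 0.2:
            return LogRatio(float(rng.choice([-5.0, 0.0, 5.0])), True)
        return LogRatio(float(rng.normal(0, 2.5)))

    s = GeneDifferentialSummary(
        gene_id="g",
        genotypes=GENOS,
        time_points=TIMES,
        mean_fpkm=means,
        cv={(g, t): 0.1 for g in GENOS for t in TIMES},
        gd={t: ratio() for t in TIMES},
        ed={
            **{(g, 0.0): LogRatio(0.0) for g in GENOS},
            **{(g, t): ratio() for g in GENOS for t in TIMES[1:]},
        },
        sgd_q={t: float(rng.choice(q_choices)) for t in TIMES},
        sed_q={
            (g, t): float(rng.choice(q_choices)) for g in GENOS for t in TIMES[1:]
        },
    )
    return s, bool(rng.random() < 0.7)


def test_cascade_matches_predicate_oracle():
    """The ordered IF/ELSE-IF implementation agrees gene-for-gene with a
    standalone predicate-table evaluation over randomized summaries."""
    rng = np.random.default_rng(123)
    for _ in range(3000):
        s, cv_ok = random_summary(rng)
        assert classify_gene(s, cv_ok) is oracle_classify(s, cv_ok)


def test_untested_gate_is_monotone():
    """Raising the Untested FPKM gate can only move genes into Untested."""
    rng = np.random.default_rng(7)
    lo = ClassifierThresholds()
    hi = ClassifierThresholds(untested_mean_fpkm=5.0)
    for _ in range(300):
        s, cv_ok = random_summary(rng)
        a, b = classify_gene(s, cv_ok, lo), classify_gene(s, cv_ok, hi)
        if a is CategoryLabel.UNTESTED:
            assert b is CategoryLabel.UNTESTED
        if a is not b:
            assert b is CategoryLabel.UNTESTED


class TestClassifierEstimator:
    def test_partition_and_determinism(self, fitted_noiseless):
        dataset, truth, clf = fitted_noiseless
        assert clf.counts_.total == len(dataset)
        again = GeneCategoryClassifier().fit(dataset)
        assert (again.labels_ == clf.labels_).all()

    def test_planted_recovery_noiseless(self, fitted_noiseless):
        dataset, truth, clf = fitted_noiseless
        planted = truth.as_frame(dataset.genotypes).set_index("gene_id")["category"]
        called = clf.labels_.map(lambda c: c.value)
        assert (called == planted).all()

    def test_counts_match_truth_frequencies(self, fitted_noiseless):
        dataset, truth, clf = fitted_noiseless
        planted = truth.as_frame(dataset.genotypes)["category"].value_counts()
        for cat, n in planted.items():
            assert clf.counts_[cat] == n

    def test_sklearn_params_roundtrip(self):
        clf = GeneCategoryClassifier(gxe_fold=3.0)
        params = clf.get_params()
        assert params["gxe_fold"] == 3.0
        clone = GeneCategoryClassifier(**params)
        assert clone.get_params() == params


class TestDerivedPercentages:
    def test_only_constant(self):
        counts = CategoryCounts({c.value: 0 for c in CATEGORY_ORDER})
        counts["Constant"] = 10
        d = derived_percentages(counts)
        assert d["pct_constant"] == pytest.approx(100.0)
        # no genotypically different genes: shares undefined, not errors
        assert np.isnan(d["pct_env_among_genotypic"])

    def test_missing_category_rejected(self):
        with pytest.raises(Exception, match="missing category"):
            derived_percentages({"Constant": 10})

    def test_study_scale_counts(self, table2_counts):
        d = derived_percentages(table2_counts)
        assert d["classifiable"] == 22255
        assert d["genotypically_different"] == 2138
        assert round(d["pct_constant"]) == 33
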