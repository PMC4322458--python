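"""Ten-category genotypic/environmental response classification.

Each gene is assigned exactly one of ten categories by an ordered rule
cascade (first matching rule wins):

1.  ``Untested`` — no cell (genotype x time) has a mean FPKM above 1.
2.  ``Low-expression`` — expressed, but every cell mean < 4 and the grand
    mean < 2: too low to classify.
3.  ``GxE`` — replicate quality passes (CV gate) and at least one
    significant genotypic difference is more than 2.8-fold the genotypic
    difference at another time-point: genotype conditions the environmental
    response.
4.  ``G+E`` — CV gate, >=3 significant GDs, a significant environmental
    response in both genotypes, and all GDs share one sign: a constant
    genotypic offset plus a shared time-course response.
5.  ``E-only`` — CV gate, <=1 significant GD, significant environmental
    response in both genotypes.
6.  ``G-only`` — CV gate, no environmental response for at least one
    genotype, >=3 significant GDs, same sign: a pure genotypic offset.
7.  ``Constant`` — CV gate, no environmental response for at least one
    genotype, <=1 significant GD, and no |ED| above 2 log2 units.
8.  ``G+E-ambiguous`` — some |ED| > 2 and a strongly significant GD
    (q < 0.001): clearly both responses, but too erratic to separate
    GxE from G+E.
9.  ``E-ambiguous`` — some |ED| > 2: clearly environmentally responsive.
10. ``Ambiguous`` — everything else (replicates too erratic to classify).

Rules 8-10 deliberately do not require the CV gate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset
from .diffstats import (
    ZERO_GD,
    GeneDifferentialSummary,
    InternalSignificance,
    cv_plus,
    max_ed_range,
    summarize_all,
)
from .errors import ValidationError


class CategoryLabel(str, Enum):
    """The ten mutually exclusive classification outcomes."""

    UNTESTED = "Untested"
    LOW_EXPRESSION = "Low-expression"
    GXE = "GxE"
    G_PLUS_E = "G+E"
    E_ONLY = "E-only"
    G_ONLY = "G-only"
    CONSTANT = "Constant"
    G_PLUS_E_AMBIGUOUS = "G+E-ambiguous"
    E_AMBIGUOUS = "E-ambiguous"
    AMBIGUOUS = "Ambiguous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: cascade order (also the canonical reporting order)
CATEGORY_ORDER = [
    CategoryLabel.UNTESTED,
    CategoryLabel.LOW_EXPRESSION,
    CategoryLabel.GXE,
    CategoryLabel.G_PLUS_E,
    CategoryLabel.E_ONLY,
    CategoryLabel.G_ONLY,
    CategoryLabel.CONSTANT,
    CategoryLabel.G_PLUS_E_AMBIGUOUS,
    CategoryLabel.E_AMBIGUOUS,
    CategoryLabel.AMBIGUOUS,
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """All tunable cut-offs of the rule cascade, with their field defaults."""

    untested_mean_fpkm: float = 1.0
    low_expr_max_fpkm: float = 4.0
    low_expr_grand_mean: float = 2.0
    cv_limit: float = 0.4
    cv_cells_required: int = 7
    sgd_q: float = 0.05
    sed_q: float = 0.05
    gxe_fold: float = 2.8
    ge_ambig_q: float = 0.001
    big_ed: float = 2.0

    def __post_init__(self):
        for name in ("untested_mean_fpkm", "low_expr_max_fpkm",
                     "low_expr_grand_mean", "cv_limit", "gxe_fold", "big_ed"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("sgd_q", "sed_q", "ge_ambig_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1)")


def classify_gene(
    summary: GeneDifferentialSummary,
    cv_ok: bool,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> CategoryLabel:
    """Apply the rule cascade to one gene; first matching rule wins."""
    th = thresholds
    means = np.array(list(summary.mean_fpkm.values()), dtype=float)
    # 1. Untested
    if not (means > th.untested_mean_fpkm).any():
        return CategoryLabel.UNTESTED
    # 2. Low-expression
    if means.max() < th.low_expr_max_fpkm and means.mean() < th.low_expr_grand_mean:
        return CategoryLabel.LOW_EXPRESSION

    times = list(summary.time_points)
    gd_abs = {t: abs(summary.gd[t].value) for t in times}
    sgd_times = [t for t in times if summary.sgd_q[t] < th.sgd_q]
    n_sgd = len(sgd_times)
    n_sed = {
        g: sum(
            1
            for (gg, t), q in summary.sed_q.items()
            if gg == g and q < th.sed_q
        )
        for g in summary.genotypes
    }
    both_sed = all(n >= 1 for n in n_sed.values())
    some_genotype_no_sed = any(n == 0 for n in n_sed.values())
    signs = {np.sign(summary.gd[t].value) for t in times if gd_abs[t] > ZERO_GD}
    ss_plus = len(signs) <= 1
    big_ed = any(abs(lr.value) > th.big_ed for lr in summary.ed.values())
    strong_sgd = any(summary.sgd_q[t] < th.ge_ambig_q for t in times)

    # 3. GxE: a significant GD >2.8-fold the GD at another time-point
    # (a zero GD at the other time-point qualifies whenever the SGD is
    # nonzero, since |gd| > 2.8 * 0 then holds)
    gxe = any(
        gd_abs[t] > th.gxe_fold * gd_abs[u]
        for t in sgd_times
        for u in times
        if u != t
    )
    if cv_ok and gxe:
        return CategoryLabel.GXE
    # 4. G+E
    if cv_ok and n_sgd >= 3 and both_sed and ss_plus:
        return CategoryLabel.G_PLUS_E
    # 5. E-only
    if cv_ok and n_sgd <= 1 and both_sed:
        return CategoryLabel.E_ONLY
    # 6. G-only
    if cv_ok and some_genotype_no_sed and n_sgd >= 3 and ss_plus:
        return CategoryLabel.G_ONLY
    # 7. Constant
    if cv_ok and some_genotype_no_sed and n_sgd <= 1 and not big_ed:
        return CategoryLabel.CONSTANT
    # 8-9. ambiguous variants with a clear environmental response
    if big_ed and strong_sgd:
        return CategoryLabel.G_PLUS_E_AMBIGUOUS
    if big_ed:
        return CategoryLabel.E_AMBIGUOUS
    return CategoryLabel.AMBIGUOUS


class CategoryCounts(dict):
    """Mapping CategoryLabel value -> count, with a grand total."""

    @property
    def total(self) -> int:
        return int(sum(self.values()))

    @classmethod
    def from_labels(cls, labels) -> "CategoryCounts":
        counts = cls({c.value: 0 for c in CATEGORY_ORDER})
        for lab in labels:
            key = lab.value if isinstance(lab, CategoryLabel) else str(lab)
            counts[key] = counts.get(key, 0) + 1
        return counts


class GeneCategoryClassifier(BaseEstimator):
    """Rule-cascade classifier for two-genotype FPKM time-courses.

    A scikit-learn-style estimator: ``fit`` computes per-gene differential
    summaries and labels for an :class:`ExpressionDataset`; fitted results
    live in trailing-underscore attributes.  The cascade is deterministic
    (no learning), so ``predict`` on a new dataset simply applies the same
    thresholds.

    Parameters mirror :class:`ClassifierThresholds`; ``significance`` is
    either ``"internal"`` (Welch/BH stand-in) or a provider object with
    ``gd_q``/``ed_q`` methods.

    Attributes
    ----------
    summaries_ : dict of gene_id -> GeneDifferentialSummary
    labels_ : pandas.Series of CategoryLabel, indexed by gene_id
    counts_ : CategoryCounts
    label_table_ : pandas.DataFrame
        Per-gene label plus the key intermediates (max |ED|, SGD/SED counts,
        CV gate).
    """

    def __init__(
        self,
        untested_mean_fpkm: float = 1.0,
        low_expr_max_fpkm: float = 4.0,
        low_expr_grand_mean: float = 2.0,
        cv_limit: float = 0.4,
        cv_cells_required: int = 7,
        sgd_q: float = 0.05,
        sed_q: float = 0.05,
        gxe_fold: float = 2.8,
        ge_ambig_q: float = 0.001,
        big_ed: float = 2.0,
        significance="internal",
    ):
        self.untested_mean_fpkm = untested_mean_fpkm
        self.low_expr_max_fpkm = low_expr_max_fpkm
        self.low_expr_grand_mean = low_expr_grand_mean
        self.cv_limit = cv_limit
        self.cv_cells_required = cv_cells_required
        self.sgd_q = sgd_q
        self.sed_q = sed_q
        self.gxe_fold = gxe_fold
        self.ge_ambig_q = ge_ambig_q
        self.big_ed = big_ed
        self.significance = significance

    @property
    def thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(
            untested_mean_fpkm=self.untested_mean_fpkm,
            low_expr_max_fpkm=self.low_expr_max_fpkm,
            low_expr_grand_mean=self.low_expr_grand_mean,
            cv_limit=self.cv_limit,
            cv_cells_required=self.cv_cells_required,
            sgd_q=self.sgd_q,
            sed_q=self.sed_q,
            gxe_fold=self.gxe_fold,
            ge_ambig_q=self.ge_ambig_q,
            big_ed=self.big_ed,
        )

    def fit(self, X: ExpressionDataset, y=None) -> "GeneCategoryClassifier":
        if not isinstance(X, ExpressionDataset):
            raise ValidationError("X must be an ExpressionDataset")
        th = self.thresholds  # validates parameters
        provider = (
            InternalSignificance(X, expression_gate=th.untested_mean_fpkm)
            if self.significance == "internal"
            else self.significance
        )
        self.summaries_ = summarize_all(X, provider)
        rows = []
        labels = {}
        for gene, summ in self.summaries_.items():
            cv_ok = cv_plus(summ, th.cv_limit, th.cv_cells_required)
            label = classify_gene(summ, cv_ok, th)
            labels[gene] = label
            n_sed = {
                g: sum(
                    1
                    for (gg, t), q in summ.sed_q.items()
                    if gg == g and q < th.sed_q
                )
                for g in summ.genotypes
            }
            rows.append(
                {
                    "gene_id": gene,
                    "category": label.value,
                    "cv_ok": cv_ok,
                    "max_abs_ed": max_ed_range(summ),
                    "n_sgd": sum(
                        1 for t in summ.time_points if summ.sgd_q[t] < th.sgd_q
                    ),
                    "n_sed_reference": n_sed[summ.genotypes[0]],
                    "n_sed_alternate": n_sed[summ.genotypes[1]],
                }
            )
        self.labels_ = pd.Series(labels, name="category")
        self.counts_ = CategoryCounts.from_labels(labels.values())
        self.label_table_ = pd.DataFrame(rows).set_index("gene_id")
        return self

    def predict(self, X: ExpressionDataset) -> pd.Series:
        """Classify a dataset; returns per-gene CategoryLabel Series."""
        return type(self)(**self.get_params()).fit(X).labels_

    def fit_predict(self, X: ExpressionDataset, y=None) -> pd.Series:
        return self.fit(X).labels_


def classify_all(
    dataset: ExpressionDataset,
    significance="internal",
    thresholds: ClassifierThresholds | None = None,
):
    """Label every gene; returns (CategoryCounts, per-gene label table)."""
    th = thresholds or ClassifierThresholds()
    clf = GeneCategoryClassifier(significance=significance, **asdict(th))
    clf.fit(dataset)
    return clf.counts_, clf.label_table_


def derived_percentages(counts) -> dict:
    """Summary statistics derived from the ten category counts.

    ``classifiable`` excludes Untested, Low-expression and Ambiguous genes;
    percentage shares are over classifiable genes, except the
    environmental-response shares, which are over genotypically different
    genes (G-only + GxE + G+E + G+E-ambiguous).  Zero denominators yield
    NaN rather than raising.
    """
    need = {c.value for c in CATEGORY_ORDER}
    missing = need - set(counts)
    if missing:
        raise ValidationError(f"missing category counts: {sorted(missing)}")

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    c = {k: int(v) for k, v in counts.items()}
    total = sum(c.values())
    classifiable = (
        total - c["Untested"] - c["Low-expression"] - c["Ambiguous"]
    )
    n_e_type = c["E-only"] + c["E-ambiguous"]
    genotypic = c["G-only"] + c["GxE"] + c["G+E"] + c["G+E-ambiguous"]
    env_among_genotypic = c["GxE"] + c["G+E"] + c["G+E-ambiguous"]
    out = {
        "total": total,
        "classifiable": classifiable,
        "n_E_type": n_e_type,
        "genotypically_different": genotypic,
        "pct_constant": pct(c["Constant"], classifiable),
        "pct_E": pct(n_e_type, classifiable),
        "pct_GxE": pct(c["GxE"], classifiable),
        "pct_env_among_genotypic": pct(env_among_genotypic, genotypic),
        "pct_gonly_vs_constant": pct(
            c["G-only"], c["G-only"] + c["Constant"]
        ),
        "pct_gxe_of_genotypic": pct(c["GxE"], genotypic),
    }
    out["pct_constant_or_E"] = out["pct_constant"] + out["pct_E"]
    return out
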