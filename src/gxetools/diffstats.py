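"""Per-gene differential statistics: GD/ED log-ratios, CVs, significance.

Two kinds of per-gene quantity feed the category classifier:

* **GD** (genotypic difference): log2 ratio of the two genotypes' replicate-
  mean FPKM at one time-point, reference over alternate.
* **ED** (environmental difference): log2 ratio of a time-point's replicate-
  mean FPKM to the 0 hr control within one genotype; ED at the control is 0
  by definition.

Both ratios pass through a degenerate-expression heuristic: when one side of
a comparison is essentially absent (FPKM < 1), the log-ratio is replaced by a
capped score of +5, -5 or 0 depending on the magnitude of the other side.
Capped scores participate in classification but are excluded from range
statistics.

Significance of GDs and EDs (SGD / SED flags) comes from a pluggable
provider: either q-values ingested from an external differential test
(Cuffdiff-style), or an internal stand-in (Welch's t on log2(FPKM+1)
replicates with Benjamini-Hochberg correction per contrast family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset
from .errors import ValidationError

#: tolerance below which a GD is treated as exactly zero (sign undefined)
ZERO_GD = 1e-9


@dataclass(frozen=True)
class LogRatio:
    """A log2 FPKM ratio, possibly replaced by a capped heuristic score."""

    value: float
    heuristic_substituted: bool = False


def heuristic_log2_ratio(numerator_fpkm: float, denominator_fpkm: float) -> LogRatio:
    """log2(numerator/denominator) with the low-expression heuristic.

    If both means are >= 1 FPKM the plain log2 ratio is returned.  If the
    denominator is < 1 and the numerator > 5 the ratio is capped at +5 (an
    upper limit on the dynamic range); symmetrically -5 when the numerator is
    < 1 against a denominator > 5; and 0 when one side is < 1 but the other
    does not exceed 5 (the comparison is uninformative).  Boundary values
    are treated strictly as written, so a compared entry of exactly 5
    against a side < 1 scores 0.
    """
    a, b = float(numerator_fpkm), float(denominator_fpkm)
    if a < 0 or b < 0:
        raise ValidationError("FPKM means must be non-negative")
    if a >= 1.0 and b >= 1.0:
        return LogRatio(float(np.log2(a / b)), False)
    if b < 1.0 and a > 5.0:
        return LogRatio(5.0, True)
    if a < 1.0 and b > 5.0:
        return LogRatio(-5.0, True)
    return LogRatio(0.0, True)


def heuristic_log2_ratio_arrays(num: np.ndarray, den: np.ndarray):
    """Vectorised :func:`heuristic_log2_ratio`; returns (values, substituted)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    plain = (num >= 1.0) & (den >= 1.0)
    plus = (den < 1.0) & (num > 5.0)
    minus = (num < 1.0) & (den > 5.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log2(num / den)
    values = np.select([plain, plus, minus], [logr, 5.0, -5.0], default=0.0)
    return values, ~plain


@dataclass
class GeneDifferentialSummary:
    """Everything the rule cascade needs to know about one gene."""

    gene_id: str
    genotypes: tuple  # (reference, alternate)
    time_points: tuple
    mean_fpkm: dict = field(default_factory=dict)  # (genotype, time) -> float
    cv: dict = field(default_factory=dict)  # (genotype, time) -> float (nan = undefined)
    gd: dict = field(default_factory=dict)  # time -> LogRatio (reference/alternate)
    ed: dict = field(default_factory=dict)  # (genotype, time) -> LogRatio (t over control)
    sgd_q: dict = field(default_factory=dict)  # time -> q
    sed_q: dict = field(default_factory=dict)  # (genotype, time) -> q, non-control only


# ---------------------------------------------------------------------------
# significance providers
# ---------------------------------------------------------------------------


class TableSignificance:
    """q-values ingested from an external differential test.

    ``mapping`` is keyed as produced by :func:`gxetools.io.read_qvalue_table`:
    ``(gene_id, ("GD", time))`` and ``(gene_id, ("ED", genotype, time))``.
    Missing contrasts default to q = 1 (never significant) unless
    ``strict=True``.
    """

    def __init__(self, mapping: dict, strict: bool = False):
        self.mapping = dict(mapping)
        self.strict = strict

    def _get(self, key):
        if key in self.mapping:
            return float(self.mapping[key])
        if self.strict:
            raise KeyError(f"no q-value for contrast {key}")
        return 1.0

    def gd_q(self, gene_id, time_hr) -> float:
        return self._get((gene_id, ("GD", float(time_hr))))

    def ed_q(self, gene_id, genotype, time_hr) -> float:
        return self._get((gene_id, ("ED", genotype, float(time_hr))))


def _welch_p(m1, v1, n1, m2, v2, n2):
    """Two-sided Welch p-values from per-side means/variances (arrays).

    A variance floor of (0.01*mean + 0.01)^2 is added to each side so that
    degenerate zero-variance replicate sets (exact synthetic data) yield a
    finite statistic; identical means still give t = 0, p = 1.
    """
    f1 = (0.01 * np.abs(m1) + 0.01) ** 2
    f2 = (0.01 * np.abs(m2) + 0.01) ** 2
    v1 = v1 + f1
    v2 = v2 + f2
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * sps.t.sf(np.abs(t), df)


class InternalSignificance:
    """Welch-t + Benjamini-Hochberg stand-in differential test.

    Replicate FPKMs are log2(FPKM+1) transformed; each GD contrast compares
    the two genotypes at one time-point and each ED contrast compares a
    time-point against the control within one genotype.  BH correction is
    applied within contrast families (all GD contrasts together; ED contrasts
    per genotype), restricted to genes passing the expression gate (some
    replicate-mean FPKM > ``expression_gate``); gated-out genes get q = 1.
    """

    def __init__(self, dataset: ExpressionDataset, expression_gate: float = 1.0):
        self.expression_gate = expression_gate
        self._fit(dataset)

    def _fit(self, ds: ExpressionDataset) -> None:
        ref, alt = ds.genotypes
        t0 = ds.control_time
        # per-cell replicate stats on log2(FPKM+1), aligned on gene index
        cells = {}
        genes = None
        for g in ds.genotypes:
            for t in ds.time_points:
                mat = ds.log2_replicate_matrix(g, t)
                n = mat.notna().sum(axis=1)
                if (n < 2).any():
                    bad = n.index[n < 2][0]
                    raise ValidationError(
                        f"<2 replicates for gene {bad!r} in cell ({g}, {t}); "
                        "supply external q-values instead"
                    )
                cells[(g, t)] = (
                    mat.mean(axis=1).to_numpy(),
                    mat.var(axis=1, ddof=1).to_numpy(),
                    n.to_numpy(),
                )
                if genes is None:
                    genes = mat.index
                elif not genes.equals(mat.index):
                    raise ValidationError("inconsistent gene sets across cells")
        self.genes_ = genes
        means = ds.cell_means().reindex(genes)
        gated = (means.max(axis=1) > self.expression_gate).to_numpy()
        self.gated_ = pd.Series(gated, index=genes)

        def contrast_p(key1, key2):
            m1, v1, n1 = cells[key1]
            m2, v2, n2 = cells[key2]
            return _welch_p(m1, v1, n1, m2, v2, n2)

        # GD family: both genotypes at each time-point
        gd_p = {t: contrast_p((ref, t), (alt, t)) for t in ds.time_points}
        self.gd_q_ = self._bh_family(gd_p, genes, gated)
        # ED families: one per genotype, non-control time-points vs control
        self.ed_q_ = {}
        for g in ds.genotypes:
            ed_p = {
                t: contrast_p((g, t), (g, t0)) for t in ds.time_points if t != t0
            }
            self.ed_q_[g] = self._bh_family(ed_p, genes, gated)

    @staticmethod
    def _bh_family(pvals: dict, genes, gated: np.ndarray) -> pd.DataFrame:
        times = sorted(pvals)
        p = np.column_stack([pvals[t] for t in times])
        q = np.ones_like(p)
        if gated.any():
            flat = p[gated].ravel()
            q[gated] = multipletests(flat, method="fdr_bh")[1].reshape(
                gated.sum(), len(times)
            )
        return pd.DataFrame(q, index=genes, columns=times)

    def gd_q(self, gene_id, time_hr) -> float:
        return float(self.gd_q_.at[gene_id, float(time_hr)])

    def ed_q(self, gene_id, genotype, time_hr) -> float:
        return float(self.ed_q_[genotype].at[gene_id, float(time_hr)])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_all(
    dataset: ExpressionDataset, significance=None
) -> dict:
    """Build a :class:`GeneDifferentialSummary` for every gene.

    ``significance`` is any provider with ``gd_q``/``ed_q`` methods; by
    default the internal Welch/BH test is fitted on the dataset.
    """
    if significance is None:
        significance = InternalSignificance(dataset)
    ref, alt = dataset.genotypes
    t0 = dataset.control_time
    means = dataset.cell_means()
    cvs = dataset.cell_cvs().reindex(means.index)

    gd_vals, gd_sub = {}, {}
    for t in dataset.time_points:
        v, s = heuristic_log2_ratio_arrays(
            means[(ref, t)].to_numpy(), means[(alt, t)].to_numpy()
        )
        gd_vals[t], gd_sub[t] = v, s
    ed_vals, ed_sub = {}, {}
    for g in dataset.genotypes:
        for t in dataset.time_points:
            if t == t0:
                continue
            v, s = heuristic_log2_ratio_arrays(
                means[(g, t)].to_numpy(), means[(g, t0)].to_numpy()
            )
            ed_vals[(g, t)], ed_sub[(g, t)] = v, s

    out = {}
    for i, gene in enumerate(means.index):
        ed = {(g, t0): LogRatio(0.0, False) for g in dataset.genotypes}
        for key in ed_vals:
            ed[key] = LogRatio(float(ed_vals[key][i]), bool(ed_sub[key][i]))
        out[gene] = GeneDifferentialSummary(
            gene_id=gene,
            genotypes=(ref, alt),
            time_points=dataset.time_points,
            mean_fpkm={
                (g, t): float(means.at[gene, (g, t)])
                for g in dataset.genotypes
                for t in dataset.time_points
            },
            cv={
                (g, t): float(cvs.at[gene, (g, t)])
                for g in dataset.genotypes
                for t in dataset.time_points
            },
            gd={
                t: LogRatio(float(gd_vals[t][i]), bool(gd_sub[t][i]))
                for t in dataset.time_points
            },
            ed=ed,
            sgd_q={t: significance.gd_q(gene, t) for t in dataset.time_points},
            sed_q={
                (g, t): significance.ed_q(gene, g, t)
                for g in dataset.genotypes
                for t in dataset.time_points
                if t != t0
            },
        )
    return out


def summarize_gene(
    dataset: ExpressionDataset, gene_id, significance=None
) -> GeneDifferentialSummary:
    """Per-gene convenience wrapper over :func:`summarize_all`."""
    if gene_id not in set(dataset.data["gene_id"]):
        raise ValidationError(f"gene {gene_id!r} not in dataset")
    sub = dataset.subset([gene_id])
    if significance is None:
        # a one-gene BH family is meaningless; fit on the full dataset
        significance = InternalSignificance(dataset)
    return summarize_all(sub, significance)[gene_id]


def cv_plus(
    summary: GeneDifferentialSummary,
    cv_limit: float = 0.4,
    cells_required: int = 7,
) -> bool:
    """Replicate-quality gate: CV < ``cv_limit`` in >= 7 of the 8 cells.

    Undefined CVs (mean 0 or <2 replicates) count as failing cells; more
    than one undefined cell triggers a warning since the gate can then fail
    for lack of information rather than noise.
    """
    values = np.array(list(summary.cv.values()), dtype=float)
    undefined = np.isnan(values)
    if undefined.sum() > 1:
        warnings.warn(
            f"{summary.gene_id}: {int(undefined.sum())} cells with undefined CV",
            stacklevel=2,
        )
    passing = int((values[~undefined] < cv_limit).sum())
    return passing >= cells_required


def max_ed_range(summary: GeneDifferentialSummary) -> float:
    """Largest |ED| over genotypes and non-control time-points.

    Heuristic-capped EDs are excluded; NaN marks a gene whose every ED was
    capped (undefined range, not zero).
    """
    t0 = summary.time_points[0]
    vals = [
        abs(lr.value)
        for (g, t), lr in summary.ed.items()
        if t != t0 and not lr.heuristic_substituted
    ]
    return max(vals) if vals else float("nan")


def replicate_concordance(
    dataset: ExpressionDataset,
    genotype,
    time_hr,
    rep_a,
    rep_b,
    q_values: dict | None = None,
    fold_log2: float = 1.0,
    expression_gate: float = 1.0,
) -> float:
    """Fraction of expression-gated genes with no significant replicate difference.

    With ``q_values`` (gene -> q from an external test between the two
    replicate libraries) a gene is discordant when q < 0.05.  Without it, a
    generic stand-in is used: discordant when the heuristic log2 ratio of
    the two replicate values exceeds ``fold_log2`` in magnitude.
    """
    sub = dataset.data[
        (dataset.data["genotype"] == genotype)
        & (dataset.data["time_hr"] == float(time_hr))
    ]
    reps = set(sub["replicate"].unique())
    for r in (rep_a, rep_b):
        if r not in reps:
            raise ValidationError(f"unknown replicate {r!r} in cell")
    piv = sub.pivot_table(
        index="gene_id", columns="replicate", values="fpkm", aggfunc="first"
    )
    a = piv[rep_a].to_numpy(dtype=float)
    b = piv[rep_b].to_numpy(dtype=float)
    gated = (a + b) / 2.0 > expression_gate
    if not gated.any():
        return float("nan")
    if q_values is not None:
        q = np.array([q_values.get(g, 1.0) for g in piv.index], dtype=float)
        concordant = q[gated] >= 0.05
    else:
        vals, _ = heuristic_log2_ratio_arrays(a[gated], b[gated])
        concordant = np.abs(vals) <= fold_log2
    return float(concordant.mean())
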