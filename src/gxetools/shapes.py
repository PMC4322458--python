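"""Water-deficit response-curve shapes by template matching.

A gene's environmental response over the time-course (its ED vector, control
entry fixed at 0) is normalised by its maximum absolute ED and compared to
nine explicit shape models: Up-early, Up-linear, Up-late, their Down
mirrors, Peak, Trough and Constant.  The profile is assigned the template
with the lowest sum of squared differences (SSD).  Only the shape matters,
never the absolute expression level.

The Constant model applies only where a flat profile is admissible (the
per-genotype profiles of GxE genes); environmentally responsive E genes are
fitted against the eight non-constant models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import ValidationError

#: fixed template (and tie-break) order
SHAPE_ORDER = [
    "Up-early",
    "Up-linear",
    "Up-late",
    "Down-early",
    "Down-linear",
    "Down-late",
    "Peak",
    "Trough",
    "Constant",
]

#: profiles treated as up- vs down-regulated for direction grouping
UP_SHAPES = {"Up-early", "Up-linear", "Up-late"}
DOWN_SHAPES = {"Down-early", "Down-linear", "Down-late"}

DEGENERATE_EPS = 1e-9


def default_templates(time_points_hr) -> dict:
    """Normalised template vectors over the given time grid.

    Up-early saturates after the first interval; Up-linear rises in
    proportion to elapsed time; Up-late moves only at the final time-point;
    Down shapes are the negations; Peak rises then returns to baseline by
    the final time-point (Trough its negation); Constant is flat zero.
    """
    t = np.asarray(time_points_hr, dtype=float)
    if len(t) < 3:
        raise ValidationError("need at least 3 time-points for shape templates")
    n = len(t)
    up_early = np.ones(n)
    up_early[0] = 0.0
    up_linear = (t - t[0]) / (t[-1] - t[0])
    up_late = np.zeros(n)
    up_late[-1] = 1.0
    peak = np.ones(n)
    peak[0] = peak[-1] = 0.0
    return {
        "Up-early": up_early,
        "Up-linear": up_linear,
        "Up-late": up_late,
        "Down-early": -up_early,
        "Down-linear": -up_linear,
        "Down-late": -up_late,
        "Peak": peak,
        "Trough": -peak,
        "Constant": np.zeros(n),
    }


@dataclass(frozen=True)
class ShapeAssignment:
    """Best-fitting template for one gene/genotype profile."""

    gene_id: str
    genotype: str | None
    label: str
    ssd: float


def normalize_profile(ed_vector) -> np.ndarray:
    """Divide an ED vector by its maximum |ED|.

    The control (first) entry must be 0.  A vector with max |ED| below a
    small epsilon is degenerate: the zero vector is returned unchanged and
    is classified Constant where that model is admissible.
    """
    v = np.asarray(ed_vector, dtype=float)
    if abs(v[0]) > DEGENERATE_EPS:
        raise ValidationError("control entry of an ED vector must be 0")
    m = np.max(np.abs(v))
    if m < DEGENERATE_EPS:
        return np.zeros_like(v)
    return v / m


def fit_profile(
    normalized,
    candidate_set: str = "nine",
    templates: dict | None = None,
    gene_id: str = "",
    genotype: str | None = None,
) -> ShapeAssignment:
    """Assign the template with minimum SSD to a normalised profile.

    ``candidate_set`` is ``"eight"`` (no Constant; for E genes, which by
    definition respond) or ``"nine"`` (for the per-genotype profiles of GxE
    genes).  Ties break by fixed template order.
    """
    v = np.asarray(normalized, dtype=float)
    if candidate_set not in ("eight", "nine"):
        raise ValidationError("candidate_set must be 'eight' or 'nine'")
    labels = SHAPE_ORDER if candidate_set == "nine" else SHAPE_ORDER[:-1]
    if candidate_set == "eight" and np.max(np.abs(v)) < DEGENERATE_EPS:
        raise ValidationError(
            "degenerate (flat) profile cannot be fitted without the Constant model"
        )
    tpl = templates or default_templates_for_length(len(v))
    best_label, best_ssd = None, np.inf
    for lab in labels:
        ssd = float(np.sum((v - np.asarray(tpl[lab], dtype=float)) ** 2))
        if ssd < best_ssd:
            best_label, best_ssd = lab, ssd
    return ShapeAssignment(gene_id, genotype, best_label, best_ssd)


def default_templates_for_length(n: int) -> dict:
    # fall back to an index grid when only the vector length is known
    return default_templates(np.arange(n, dtype=float))


class ProfileShapeClassifier(BaseEstimator):
    """Minimum-SSD template matcher as a scikit-learn-style estimator.

    ``fit`` freezes the template set on a time grid; ``predict`` assigns a
    shape label to each row of a matrix of ED vectors (genes x time-points,
    control column first).

    Parameters
    ----------
    candidate_set : "eight" | "nine"
        Whether the Constant model is admissible.
    templates : dict or None
        Label -> vector overrides; defaults to :func:`default_templates`.
    """

    def __init__(self, candidate_set: str = "nine", templates: dict | None = None):
        self.candidate_set = candidate_set
        self.templates = templates

    def fit(self, X, y=None, time_points_hr=None) -> "ProfileShapeClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grid = (
            np.asarray(time_points_hr, dtype=float)
            if time_points_hr is not None
            else np.arange(X.shape[1], dtype=float)
        )
        self.templates_ = (
            dict(self.templates) if self.templates else default_templates(grid)
        )
        labels = SHAPE_ORDER if self.candidate_set == "nine" else SHAPE_ORDER[:-1]
        self.template_matrix_ = np.vstack(
            [np.asarray(self.templates_[lab], dtype=float) for lab in labels]
        )
        self.labels_in_order_ = labels
        return self

    def predict(self, X) -> np.ndarray:
        """Shape label per row (rows are raw or normalised ED vectors)."""
        return self.transform(X)["shape"].to_numpy()

    def transform(self, X) -> pd.DataFrame:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.vstack([normalize_profile(row) for row in X])
        if self.candidate_set == "eight":
            flat = np.max(np.abs(norms), axis=1) < DEGENERATE_EPS
            if flat.any():
                raise ValidationError(
                    "degenerate (flat) profile cannot be fitted without the "
                    "Constant model"
                )
        # SSD of every profile against every template, vectorised
        diff = norms[:, None, :] - self.template_matrix_[None, :, :]
        ssd = np.sum(diff**2, axis=2)
        idx = np.argmin(ssd, axis=1)  # argmin takes the first minimum: tie order
        return pd.DataFrame(
            {
                "shape": [self.labels_in_order_[i] for i in idx],
                "ssd": ssd[np.arange(len(idx)), idx],
            }
        )


# ---------------------------------------------------------------------------
# distributions and the GxE joint-profile analysis
# ---------------------------------------------------------------------------


def shape_distribution(assignments, gene_subset=None) -> pd.DataFrame:
    """Label frequencies (and counts) over a gene subset.

    ``assignments`` is an iterable of :class:`ShapeAssignment` (or a
    DataFrame with gene_id/shape columns).
    """
    if isinstance(assignments, pd.DataFrame):
        df = assignments
    else:
        df = pd.DataFrame(
            [{"gene_id": a.gene_id, "shape": a.label} for a in assignments]
        )
    if gene_subset is not None:
        df = df[df["gene_id"].isin(set(gene_subset))]
    if df.empty:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = df["shape"].value_counts()
    out = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    return out.reindex([s for s in SHAPE_ORDER if s in out.index])


@dataclass
class JointProfileTable:
    """Observed vs marginal-expectation joint shape table for GxE genes."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    n: int
    chi2: float
    dof: int
    p_value: float
    p_monte_carlo: float | None = None


def joint_profile_analysis(
    reference_labels,
    alternate_labels,
    monte_carlo: int = 0,
    seed: int = 0,
) -> JointProfileTable:
    """Cross-tabulate per-genotype shapes of GxE genes against independence.

    The expectation is the outer product of the observed marginal
    frequencies; the Pearson chi-squared statistic is computed over cells
    with positive expectation, with (r-1)(c-1) degrees of freedom over
    non-empty margins.  ``monte_carlo`` > 0 adds a permutation p-value for
    sparse tables (shuffling one genotype's labels).
    """
    ref = pd.Series(list(reference_labels))
    alt = pd.Series(list(alternate_labels))
    if len(ref) != len(alt):
        raise ValidationError("per-genotype label lists differ in length")
    n = len(ref)
    if n == 0:
        raise ValidationError("no GxE genes to analyse")
    order = [s for s in SHAPE_ORDER]
    observed = (
        pd.crosstab(ref, alt)
        .reindex(index=order, columns=order, fill_value=0)
        .astype(int)
    )
    row = observed.sum(axis=1).to_numpy(dtype=float)
    col = observed.sum(axis=0).to_numpy(dtype=float)
    expected = pd.DataFrame(
        np.outer(row, col) / n, index=observed.index, columns=observed.columns
    )
    mask = expected.to_numpy() > 0
    chi2 = float(
        np.sum(
            (observed.to_numpy()[mask] - expected.to_numpy()[mask]) ** 2
            / expected.to_numpy()[mask]
        )
    )
    r = int((row > 0).sum())
    c = int((col > 0).sum())
    dof = max((r - 1) * (c - 1), 1)
    p = float(sps.chi2.sf(chi2, dof)) if chi2 > 0 else 1.0
    p_mc = None
    if monte_carlo:
        rng = np.random.default_rng(seed)
        alt_arr = alt.to_numpy()
        count = 0
        for _ in range(monte_carlo):
            perm = rng.permutation(alt_arr)
            tab = pd.crosstab(ref, pd.Series(perm))
            rr = tab.sum(axis=1).to_numpy(dtype=float)
            cc = tab.sum(axis=0).to_numpy(dtype=float)
            exp = np.outer(rr, cc) / n
            m = exp > 0
            stat = np.sum((tab.to_numpy()[m] - exp[m]) ** 2 / exp[m])
            if stat >= chi2:
                count += 1
        p_mc = (count + 1) / (monte_carlo + 1)
    return JointProfileTable(observed, expected, n, chi2, dof, p, p_mc)


def same_profile_genotypic_bias(
    gd_table: pd.DataFrame,
    shared_shape: pd.Series,
) -> pd.DataFrame:
    """Distribution of the genotypic difference per time-point for GxE genes
    sharing one profile in both genotypes.

    ``gd_table`` holds the per-gene, per-time signed difference on the
    displayed orientation log2(FPKM_alternate / FPKM_reference) — the
    negation of GD — with heuristic-capped values already set to NaN.
    ``shared_shape`` gives each gene's common shape label.  Rows are
    (group, time) with group in All / Up / Down; columns are median,
    quartiles and whiskers (1.5 IQR fences clipped to the data).
    """
    groups = {"All": gd_table.index}
    groups["Up"] = shared_shape.index[shared_shape.isin(UP_SHAPES)]
    groups["Down"] = shared_shape.index[shared_shape.isin(DOWN_SHAPES)]
    rows = []
    for name, idx in groups.items():
        sub = gd_table.loc[gd_table.index.intersection(idx)]
        for t in gd_table.columns:
            vals = sub[t].dropna().to_numpy()
            if len(vals) == 0:
                rows.append(
                    dict(group=name, time_hr=t, n=0, median=np.nan,
                         q1=np.nan, q3=np.nan, lo=np.nan, hi=np.nan)
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append(
                dict(group=name, time_hr=t, n=len(vals), median=med,
                     q1=q1, q3=q3, lo=lo, hi=hi)
            )
    return pd.DataFrame(rows)
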