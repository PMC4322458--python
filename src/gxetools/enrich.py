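"""Categorical enrichment of gene subsets and pipeline summary reporting.

Subsets of interest (genes inside QTL intervals, an aquaporin family list,
any arbitrary list) are compared to the genome-wide category distribution
with a Pearson chi-squared goodness-of-fit test.  Because subsets can be
small, category labels are first merged into coarser display groups
(E-type, G+E-type, G-only, Constant, Low-expression, Ambiguous; Untested
genes are dropped entirely), and a fixed-seed Monte-Carlo p-value is added
whenever any expected cell falls below 5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .classify import CategoryLabel, derived_percentages
from .errors import ValidationError

#: display-group merge used for subset comparisons
DEFAULT_MERGE = {
    CategoryLabel.E_ONLY.value: "E-type",
    CategoryLabel.E_AMBIGUOUS.value: "E-type",
    CategoryLabel.GXE.value: "G+E-type",
    CategoryLabel.G_PLUS_E.value: "G+E-type",
    CategoryLabel.G_PLUS_E_AMBIGUOUS.value: "G+E-type",
    CategoryLabel.G_ONLY.value: "G-only",
    CategoryLabel.CONSTANT.value: "Constant",
    CategoryLabel.LOW_EXPRESSION.value: "Low-expression",
    CategoryLabel.AMBIGUOUS.value: "Ambiguous",
    # Untested is excluded, not merged
}

GROUP_ORDER = ["Constant", "E-type", "G-only", "G+E-type", "Low-expression", "Ambiguous"]


@dataclass
class MergedCategoryScheme:
    """Mapping of the ten category labels onto display groups."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_MERGE))

    def __post_init__(self):
        for c in CategoryLabel:
            if c is CategoryLabel.UNTESTED:
                continue
            if c.value not in self.mapping:
                raise ValidationError(f"merge scheme misses category {c.value!r}")

    def group(self, label) -> str | None:
        key = label.value if isinstance(label, CategoryLabel) else str(label)
        if key == CategoryLabel.UNTESTED.value:
            return None
        return self.mapping[key]

    @property
    def groups(self) -> list:
        seen = [g for g in GROUP_ORDER if g in self.mapping.values()]
        extra = [g for g in self.mapping.values() if g not in seen]
        return seen + sorted(set(extra))


@dataclass
class EnrichmentResult:
    """Subset-vs-background categorical comparison."""

    subset_name: str
    observed: pd.Series
    expected: pd.Series
    chi2: float
    dof: int
    p_value: float
    method: str
    p_monte_carlo: float | None = None


def genes_in_intervals(locations, intervals) -> set:
    """Gene ids whose span overlaps any interval by >= 1 base.

    Both inputs are in the internal 0-based half-open convention, so an
    interval ending where a gene starts does not overlap it.
    """
    trees = {}
    for iv in intervals:
        trees.setdefault(iv.chromosome, IntervalTree()).addi(iv.start, iv.end)
    loc_chroms = {loc.chromosome for loc in locations}
    unmatched = sorted(loc_chroms.symmetric_difference(trees))
    if trees and unmatched:
        warnings.warn(
            f"chromosome names present on one side only: {unmatched}",
            stacklevel=2,
        )
    hits = set()
    for loc in locations:
        tree = trees.get(loc.chromosome)
        if tree is not None and tree.overlap(loc.start, loc.end):
            hits.add(loc.gene_id)
    return hits


def _merged_counts(labels: pd.Series, scheme: MergedCategoryScheme) -> pd.Series:
    groups = labels.map(scheme.group)
    counts = groups.value_counts()
    return counts.reindex(scheme.groups, fill_value=0).astype(int)


def subset_enrichment(
    labels: pd.Series,
    subset,
    scheme: MergedCategoryScheme | None = None,
    subset_name: str = "subset",
    monte_carlo_draws: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Chi-squared comparison of a subset's merged category distribution to
    the background of all labelled, non-Untested genes.

    The asymptotic Pearson statistic is always reported; a fixed-seed
    Monte-Carlo p-value (sampling subsets of the same size from the
    background without replacement) is added when any expected cell is < 5,
    and then becomes the headline p-value.
    """
    scheme = scheme or MergedCategoryScheme()
    labels = labels.map(lambda v: v.value if isinstance(v, CategoryLabel) else str(v))
    background = labels[labels != CategoryLabel.UNTESTED.value]
    sub_labels = background.loc[background.index.intersection(pd.Index(set(subset)))]
    if sub_labels.empty:
        raise ValidationError("subset is empty after removing Untested genes")
    bg_counts = _merged_counts(background, scheme)
    obs = _merged_counts(sub_labels, scheme)
    n = int(obs.sum())
    expected = bg_counts / bg_counts.sum() * n
    mask = expected > 0
    chi2 = float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    dof = int(mask.sum()) - 1
    p_asym = float(sps.chi2.sf(chi2, dof)) if chi2 > 0 else 1.0
    p_mc = None
    method = "asymptotic"
    if (expected[mask] < 5).any() and monte_carlo_draws > 0:
        null = monte_carlo_null_chi2(
            bg_counts.to_numpy(), n, monte_carlo_draws, seed
        )
        p_mc = float((np.sum(null >= chi2 - 1e-12) + 1) / (len(null) + 1))
        method = "monte-carlo"
    return EnrichmentResult(
        subset_name, obs, expected, chi2, dof, p_asym, method, p_mc
    )


def monte_carlo_null_chi2(
    bg_counts: np.ndarray, subset_size: int, draws: int, seed: int
) -> np.ndarray:
    """Null chi-squared statistics for random subsets of the background.

    Subsets are drawn without replacement (multivariate hypergeometric),
    matching the sampling model of picking ``subset_size`` genes at random
    from the labelled background.
    """
    rng = np.random.default_rng(seed)
    bg = np.asarray(bg_counts, dtype=int)
    expected = bg / bg.sum() * subset_size
    sims = rng.multivariate_hypergeometric(bg, subset_size, size=draws)
    mask = expected > 0
    return np.sum(
        (sims[:, mask] - expected[mask]) ** 2 / expected[mask], axis=1
    )


def gxe_candidates_in_intervals(
    label_table: pd.DataFrame,
    locations,
    intervals,
    shape_pairs: pd.DataFrame | None = None,
    max_abs_gd: pd.Series | None = None,
) -> pd.DataFrame:
    """GxE-labelled genes overlapping any interval, ranked by max |GD|.

    ``label_table`` is the classifier's per-gene table (category column);
    ``shape_pairs`` optionally carries per-genotype shape labels; ties in
    the ranking metric break by gene id, so the output is deterministic.
    """
    gxe = set(
        label_table.index[label_table["category"] == CategoryLabel.GXE.value]
    )
    by_gene = {}
    trees = {}
    for iv in intervals:
        name = iv.name or f"{iv.chromosome}:{iv.start}-{iv.end}"
        trees.setdefault(iv.chromosome, IntervalTree()).addi(
            iv.start, iv.end, name
        )
    for loc in locations:
        if loc.gene_id not in gxe:
            continue
        tree = trees.get(loc.chromosome)
        if tree is None:
            continue
        hits = tree.overlap(loc.start, loc.end)
        if hits:
            by_gene[loc.gene_id] = sorted(h.data for h in hits)
    rows = []
    for gene, names in by_gene.items():
        row = {"gene_id": gene, "intervals": ";".join(names)}
        if max_abs_gd is not None and gene in max_abs_gd.index:
            row["max_abs_gd"] = float(max_abs_gd.loc[gene])
        else:
            row["max_abs_gd"] = float("nan")
        if shape_pairs is not None and gene in shape_pairs.index:
            row["shape_reference"] = shape_pairs.loc[gene, "shape_reference"]
            row["shape_alternate"] = shape_pairs.loc[gene, "shape_alternate"]
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=["gene_id", "intervals", "max_abs_gd",
                       "shape_reference", "shape_alternate"]
    )
    if df.empty:
        return df
    return df.sort_values(
        ["max_abs_gd", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def summary_report(
    counts,
    shape_distributions: dict | None = None,
    enrichment_results: list | None = None,
) -> dict:
    """Assemble the machine-readable run report.

    Contains the ten category counts, the derived percentage statistics,
    any shape distributions and enrichment comparisons.  The same dict is
    rendered to text by :func:`render_report`; regenerating from identical
    inputs yields byte-identical output.
    """
    report = {
        "category_counts": {k: int(v) for k, v in counts.items()},
        "derived": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in derived_percentages(counts).items()
        },
        "shape_distributions": {},
        "enrichment": [],
    }
    for name, dist in (shape_distributions or {}).items():
        report["shape_distributions"][name] = {
            shape: {
                "count": int(dist.loc[shape, "count"]),
                "fraction": float(dist.loc[shape, "fraction"]),
            }
            for shape in dist.index
        }
    for res in enrichment_results or []:
        report["enrichment"].append(
            {
                "subset": res.subset_name,
                "n": int(res.observed.sum()),
                "observed": {k: int(v) for k, v in res.observed.items()},
                "expected": {k: float(v) for k, v in res.expected.items()},
                "chi2": res.chi2,
                "dof": res.dof,
                "p_value": res.p_value,
                "p_monte_carlo": res.p_monte_carlo,
                "method": res.method,
            }
        )
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of :func:`summary_report` output."""
    lines = ["Expression category counts", "=" * 26]
    for cat, n in report["category_counts"].items():
        lines.append(f"{cat:<16s}{n:>10d}")
    lines.append(f"{'Total':<16s}{sum(report['category_counts'].values()):>10d}")
    lines.append("")
    lines.append("Derived statistics")
    lines.append("=" * 18)
    for k, v in report["derived"].items():
        if v is None:
            lines.append(f"{k:<28s}   undefined")
        elif isinstance(v, float):
            lines.append(f"{k:<28s}{v:>10.2f}")
        else:
            lines.append(f"{k:<28s}{v:>10d}")
    for name, dist in report["shape_distributions"].items():
        lines.append("")
        lines.append(f"Shape distribution: {name}")
        lines.append("-" * (20 + len(name)))
        for shape, d in dist.items():
            lines.append(f"{shape:<12s}{d['count']:>8d}{d['fraction']:>10.3f}")
    for res in report["enrichment"]:
        lines.append("")
        lines.append(f"Enrichment: {res['subset']} (n={res['n']})")
        lines.append("-" * (14 + len(res["subset"])))
        for grp in res["observed"]:
            lines.append(
                f"{grp:<16s}obs {res['observed'][grp]:>6d}   "
                f"exp {res['expected'][grp]:>9.2f}"
            )
        p = res["p_monte_carlo"] if res["p_monte_carlo"] is not None else res["p_value"]
        lines.append(
            f"chi2={res['chi2']:.3f} dof={res['dof']} p={p:.3g} ({res['method']})"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(render_report(report))
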