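"""Synthetic replicate FPKM time-courses with planted, known truth.

Emulates a two-genotype, four-time-point, three-replicate RNA-seq abundance
design: each gene gets a planted response category (constant, genotypic,
environmental, interaction, or one of the ambiguous/low-expression classes)
and, where applicable, a planted response-curve shape per genotype.  Effects
are planted on a log2 scale on top of a uniform log2 baseline; replicate
noise is multiplicative lognormal with a controllable coefficient of
variation (CV), since FPKM is non-negative and the classifier's replicate
quality gate operates on raw-FPKM CVs.

Planting rules per category (A = ``effect_size_log2``):

* ``Constant`` — no offset, no time-course effect.
* ``E-only`` — one shared non-constant shape of amplitude A in both
  genotypes, no genotypic offset.
* ``G-only`` — one genotype elevated by A at every time-point, flat
  profiles.
* ``G+E`` — genotypic offset A plus a shared shape of amplitude A.
* ``GxE`` — either a shape in one genotype against a flat profile in the
  other, or two different shapes of amplitude A (so the genotypic
  difference changes across time-points beyond the 2.8-fold rule at the
  noiseless limit).
* ``Untested`` — every replicate drawn uniform on [0, 1] (no cell mean
  above the FPKM > 1 testing gate).
* ``Low-expression`` — flat expression between 1.2 and 1.8 FPKM.
* ``Ambiguous`` — constant expression, but one replicate scaled 3x in two
  cells, pushing the sample CV there to sqrt(3)*2/5 = 0.69, which fails the
  7-of-8 CV gate regardless of the noise level (this keeps the noiseless
  limit exact, which a noise-multiplier scheme would not).
* ``E-ambiguous`` / ``G+E-ambiguous`` — as E-only / G+E plus the same
  two-cell replicate scaling, so the CV gate fails but the large
  environmental response (and, for G+E-ambiguous, the strongly significant
  genotypic difference) remains visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CategoryLabel
from .dataset import ExpressionDataset
from .errors import ConfigError
from .shapes import SHAPE_ORDER, default_templates

#: default planted category mixture (fractions sum to 1)
DEFAULT_PROPORTIONS = {
    CategoryLabel.CONSTANT: 0.22,
    CategoryLabel.E_ONLY: 0.22,
    CategoryLabel.E_AMBIGUOUS: 0.05,
    CategoryLabel.G_ONLY: 0.08,
    CategoryLabel.GXE: 0.12,
    CategoryLabel.G_PLUS_E: 0.08,
    CategoryLabel.G_PLUS_E_AMBIGUOUS: 0.05,
    CategoryLabel.UNTESTED: 0.08,
    CategoryLabel.LOW_EXPRESSION: 0.07,
    CategoryLabel.AMBIGUOUS: 0.03,
}

NON_CONSTANT_SHAPES = SHAPE_ORDER[:-1]

#: deterministic scale factor applied to one replicate in two cells for the
#: ambiguous classes; sample CV of (m, m, 3m) is sqrt(3)*2/5 ~= 0.69 >= 0.4
AMBIGUOUS_REP_SCALE = 3.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design."""

    n_genes: int = 1000
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    replicate_count: int = 3
    baseline_log2_fpkm_range: tuple = (2.0, 8.0)
    effect_size_log2: float = 3.0
    noise_cv: float = 0.1
    time_points_hr: tuple = (0.0, 6.0, 12.0, 24.0)
    genotypes: tuple = ("G1", "G2")  # first is the GD reference
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        props = {CategoryLabel(k): float(v) for k, v in self.category_proportions.items()}
        if any(v < 0 for v in props.values()):
            raise ConfigError("category proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("category proportions must sum to 1")
        self.category_proportions = props
        if self.replicate_count < 2:
            raise ConfigError("need >=2 replicates per cell (CV undefined otherwise)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        t = tuple(float(x) for x in self.time_points_hr)
        if list(t) != sorted(set(t)) or len(t) < 3:
            raise ConfigError("time_points_hr must be strictly increasing (>=3 points)")
        self.time_points_hr = t
        lo, hi = self.baseline_log2_fpkm_range
        if not lo < hi:
            raise ConfigError("baseline_log2_fpkm_range must be a proper interval")


@dataclass
class GeneTruth:
    """Planted parameters of one synthetic gene."""

    gene_id: str
    category: CategoryLabel
    shape_per_genotype: dict
    baseline_log2: float
    genotype_offset_log2: float  # reference minus alternate, log2 units
    environment_amplitude_log2: float


@dataclass
class TruthTable:
    records: list

    def __post_init__(self):
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate gene ids in truth table")

    def as_frame(self, genotypes) -> pd.DataFrame:
        ref, alt = genotypes
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "category": [r.category.value for r in self.records],
                "shape_reference": [r.shape_per_genotype[ref] for r in self.records],
                "shape_alternate": [r.shape_per_genotype[alt] for r in self.records],
                "baseline_log2": [r.baseline_log2 for r in self.records],
                "genotype_offset_log2": [r.genotype_offset_log2 for r in self.records],
                "environment_amplitude_log2": [
                    r.environment_amplitude_log2 for r in self.records
                ],
            }
        )

    def by_gene(self) -> dict:
        return {r.gene_id: r for r in self.records}


def _lognormal_factors(rng, cv, size):
    """Mean-1 multiplicative lognormal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size=size))


def generate_dataset(config: SimulationConfig):
    """Draw a synthetic dataset; returns (ExpressionDataset, TruthTable).

    Pure function of ``config.seed``: two runs with the same config are
    bitwise identical.
    """
    rng = np.random.default_rng(config.seed)
    ref, alt = config.genotypes
    times = config.time_points_hr
    t1 = times[1]  # cell scaled for the ambiguous classes
    n_rep = config.replicate_count
    A = config.effect_size_log2
    lo, hi = config.baseline_log2_fpkm_range
    templates = default_templates(times)

    cats = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in cats])
    assigned = rng.choice(len(cats), size=config.n_genes, p=probs)

    width = len(str(config.n_genes))
    rows = []
    records = []
    for i, ci in enumerate(assigned):
        cat = cats[ci]
        gene = f"gene{i:0{width}d}"
        shapes = {ref: "Constant", alt: "Constant"}
        offset = 0.0
        amplitude = 0.0
        baseline = np.nan
        profile = {ref: np.zeros(len(times)), alt: np.zeros(len(times))}
        scaled_cells = []

        if cat is CategoryLabel.UNTESTED:
            for g in (ref, alt):
                for t in times:
                    for r in range(n_rep):
                        rows.append((gene, g, t, r, rng.uniform(0.0, 1.0)))
            records.append(GeneTruth(gene, cat, shapes, baseline, 0.0, 0.0))
            continue

        if cat is CategoryLabel.LOW_EXPRESSION:
            baseline = float(np.log2(rng.uniform(1.2, 1.8)))
        else:
            drop = 0.0  # largest downward log2 excursion to keep means >= 2^lo
            if cat in (CategoryLabel.E_ONLY, CategoryLabel.E_AMBIGUOUS,
                       CategoryLabel.G_PLUS_E, CategoryLabel.G_PLUS_E_AMBIGUOUS):
                shape = NON_CONSTANT_SHAPES[rng.integers(len(NON_CONSTANT_SHAPES))]
                shapes = {ref: shape, alt: shape}
                amplitude = A
                profile = {g: A * templates[shape] for g in (ref, alt)}
                drop = max(drop, -min(profile[ref].min(), 0.0))
                if cat in (CategoryLabel.G_PLUS_E, CategoryLabel.G_PLUS_E_AMBIGUOUS):
                    offset = A if rng.random() < 0.5 else -A
            elif cat is CategoryLabel.G_ONLY:
                offset = A if rng.random() < 0.5 else -A
            elif cat is CategoryLabel.GXE:
                if rng.random() < 0.5:
                    # shape in one genotype, flat in the other
                    shape = NON_CONSTANT_SHAPES[rng.integers(len(NON_CONSTANT_SHAPES))]
                    responder = ref if rng.random() < 0.5 else alt
                    shapes[responder] = shape
                    profile[responder] = A * templates[shape]
                else:
                    s_ref, s_alt = rng.choice(
                        len(NON_CONSTANT_SHAPES), size=2, replace=False
                    )
                    shapes = {
                        ref: NON_CONSTANT_SHAPES[s_ref],
                        alt: NON_CONSTANT_SHAPES[s_alt],
                    }
                    profile = {
                        ref: A * templates[shapes[ref]],
                        alt: A * templates[shapes[alt]],
                    }
                amplitude = A
                drop = max(
                    -min(profile[ref].min(), 0.0), -min(profile[alt].min(), 0.0)
                )
            # the offset elevates one genotype above the baseline, so only
            # environmental drops push means below the baseline floor
            baseline = float(rng.uniform(min(lo + drop, hi - 1e-6), hi))

        if cat in (CategoryLabel.AMBIGUOUS, CategoryLabel.E_AMBIGUOUS,
                   CategoryLabel.G_PLUS_E_AMBIGUOUS):
            scaled_cells = [(ref, t1), (alt, t1)]

        for g in (ref, alt):
            geno_shift = offset if (g == ref and offset > 0) else (
                -offset if (g == alt and offset < 0) else 0.0
            )
            for j, t in enumerate(times):
                mean_fpkm = 2.0 ** (baseline + geno_shift + profile[g][j])
                values = mean_fpkm * _lognormal_factors(rng, config.noise_cv, n_rep)
                if (g, t) in scaled_cells:
                    values = values.copy()
                    values[0] *= AMBIGUOUS_REP_SCALE
                for r in range(n_rep):
                    rows.append((gene, g, t, r, float(values[r])))
        records.append(GeneTruth(gene, cat, shapes, baseline, offset, amplitude))

    data = pd.DataFrame(
        rows, columns=["gene_id", "genotype", "time_hr", "replicate", "fpkm"]
    )
    dataset = ExpressionDataset(data, ref, alt, times)
    return dataset, TruthTable(records)


def write_fixture(dataset: ExpressionDataset, truth: TruthTable, directory) -> dict:
    """Write the FPKM long table and the truth side-table; return a manifest.

    Values are written with 9 significant digits, so a read-back round-trips
    within 1e-6 relative tolerance.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fpkm_path = directory / "fpkm.tsv"
    truth_path = directory / "truth.tsv"
    dataset.data.to_csv(fpkm_path, sep="\t", index=False, float_format="%.9g")
    truth_df = truth.as_frame(dataset.genotypes)
    truth_df.to_csv(truth_path, sep="\t", index=False, float_format="%.9g")
    return {
        str(fpkm_path): len(dataset.data),
        str(truth_path): len(truth_df),
    }
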