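"""End-to-end orchestration: simulate/ingest -> classify -> shapes -> enrich -> report.

A run is driven by one declarative YAML config.  Exactly one of the
``simulation`` block and the ``inputs`` block must supply expression data;
all classifier thresholds and shape templates are config-overridable and
echoed into the run manifest, so a run is reproducible from the manifest
alone.  For a fixed seed the whole pipeline is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CategoryLabel,
    ClassifierThresholds,
    GeneCategoryClassifier,
)
from .dataset import ExpressionDataset
from .diffstats import TableSignificance
from .enrich import (
    MergedCategoryScheme,
    genes_in_intervals,
    gxe_candidates_in_intervals,
    subset_enrichment,
    summary_report,
    write_report,
)
from .errors import ConfigError
from .io import (
    read_fpkm_table,
    read_gene_list,
    read_gene_locations,
    read_intervals,
    read_qvalue_table,
)
from .shapes import ProfileShapeClassifier, joint_profile_analysis
from .simulate import SimulationConfig, TruthTable, generate_dataset, write_fixture

log = logging.getLogger("gxetools")

_KNOWN_KEYS = {
    "seed", "output_dir", "log_level", "simulation", "inputs",
    "thresholds", "templates",
}
_INPUT_KEYS = {
    "fpkm", "dialect", "reference", "qvalues", "intervals",
    "gene_locations", "gene_lists",
}


@dataclass
class PipelineConfig:
    """Validated, normalised pipeline configuration."""

    output_dir: Path
    seed: int
    simulation: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    templates: dict | None = None
    log_level: str = "INFO"
    seed_was_drawn: bool = False

    def as_manifest_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "seed_was_drawn": self.seed_was_drawn,
            "output_dir": str(self.output_dir),
            "thresholds": asdict(self.thresholds),
            "templates": (
                {k: list(map(float, v)) for k, v in self.templates.items()}
                if self.templates
                else None
            ),
            "log_level": self.log_level,
        }
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim["category_proportions"] = {
                k.value: v for k, v in sim["category_proportions"].items()
            }
            out["simulation"] = sim
        else:
            out["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        return out


def validate_config(source, strict: bool = True) -> PipelineConfig:
    """Load and normalise a config document (path, YAML string, or dict)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        msg = f"unknown config key(s): {sorted(unknown)}"
        if strict:
            raise ConfigError(msg)
        warnings.warn(msg, stacklevel=2)
        for k in unknown:
            raw.pop(k)

    has_sim = "simulation" in raw and raw["simulation"] is not None
    has_inputs = bool(raw.get("inputs"))
    if has_sim == has_inputs:
        raise ConfigError(
            "exactly one of 'simulation' and 'inputs' must supply expression data"
        )

    seed_was_drawn = "seed" not in raw or raw["seed"] is None
    seed = (
        int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        if seed_was_drawn
        else int(raw["seed"])
    )

    sim = None
    inputs = {}
    if has_sim:
        sim_raw = dict(raw["simulation"])
        sim_raw.setdefault("seed", seed)
        try:
            sim = SimulationConfig(**sim_raw)
        except TypeError as exc:
            raise ConfigError(f"invalid simulation block: {exc}")
    else:
        inputs = dict(raw["inputs"])
        unknown_in = set(inputs) - _INPUT_KEYS
        if unknown_in:
            raise ConfigError(f"unknown inputs key(s): {sorted(unknown_in)}")
        if "fpkm" not in inputs:
            raise ConfigError("inputs block requires an 'fpkm' path")

    try:
        thresholds = ClassifierThresholds(**(raw.get("thresholds") or {}))
    except TypeError as exc:
        raise ConfigError(f"invalid thresholds block: {exc}")

    templates = raw.get("templates")
    if templates is not None:
        templates = {str(k): np.asarray(v, dtype=float) for k, v in templates.items()}

    return PipelineConfig(
        output_dir=Path(raw.get("output_dir", "gxetools_out")),
        seed=seed,
        simulation=sim,
        inputs=inputs,
        thresholds=thresholds,
        templates=templates,
        log_level=str(raw.get("log_level", "INFO")),
        seed_was_drawn=seed_was_drawn,
    )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def ed_vectors(summaries, genes, genotype=None) -> pd.DataFrame:
    """Per-gene ED vectors (genes x time-points).

    With ``genotype=None`` the two genotypes' EDs are averaged (the pooled
    profile used for E genes, which by definition respond alike); otherwise
    the single genotype's profile is returned (used per-genotype for GxE
    genes).  Heuristic-capped EDs participate at their capped scores.
    """
    rows = {}
    for gene in genes:
        s = summaries[gene]
        vec = []
        for t in s.time_points:
            if genotype is None:
                vec.append(
                    np.mean([s.ed[(g, t)].value for g in s.genotypes])
                )
            else:
                vec.append(s.ed[(genotype, t)].value)
        rows[gene] = vec
    if not rows:
        return pd.DataFrame(columns=list(summaries and next(iter(summaries.values())).time_points or []))
    first = next(iter(summaries.values()))
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(first.time_points))


def displayed_genotypic_difference(summaries, genes) -> pd.DataFrame:
    """Signed per-time log2(FPKM_alternate / FPKM_reference), the negation
    of GD, with heuristic-capped values masked to NaN (range statistics
    ignore capped scores)."""
    rows = {}
    for gene in genes:
        s = summaries[gene]
        rows[gene] = [
            -s.gd[t].value if not s.gd[t].heuristic_substituted else np.nan
            for t in s.time_points
        ]
    first = next(iter(summaries.values()))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(first.time_points)
    )


def _sha256_of(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.as_manifest_dict(),
        "config_hash": _sha256_of(config.as_manifest_dict()),
        "stages": {},
    }

    # -- stage 1: simulate or ingest ------------------------------------
    truth: TruthTable | None = None
    significance = "internal"
    if config.simulation is not None:
        dataset, truth = generate_dataset(config.simulation)
        files = write_fixture(dataset, truth, out)
        manifest["stages"]["simulate"] = sorted(files)
        log.info("simulated %d genes", len(dataset))
    else:
        dataset = read_fpkm_table(
            config.inputs["fpkm"],
            dialect=config.inputs.get("dialect", "long"),
            reference=config.inputs.get("reference"),
        )
        manifest["stages"]["ingest"] = [str(config.inputs["fpkm"])]
        if "qvalues" in config.inputs:
            significance = TableSignificance(
                read_qvalue_table(config.inputs["qvalues"])
            )
        log.info("ingested %d genes", len(dataset))

    # -- stage 2: summarize + classify ----------------------------------
    clf = GeneCategoryClassifier(
        significance=significance, **asdict(config.thresholds)
    )
    clf.fit(dataset)
    label_path = out / "labels.tsv"
    clf.label_table_.to_csv(label_path, sep="\t")
    manifest["stages"]["classify"] = [str(label_path)]
    log.info("classified %d genes: %s", len(clf.labels_), dict(clf.counts_))

    # -- stage 3: shapes -------------------------------------------------
    shape_files = []
    shape_distributions = {}
    ref, alt = dataset.genotypes
    e_genes = [
        g
        for g, lab in clf.labels_.items()
        if lab in (CategoryLabel.E_ONLY, CategoryLabel.E_AMBIGUOUS)
    ]
    gxe_genes = [g for g, lab in clf.labels_.items() if lab is CategoryLabel.GXE]
    joint = None
    shape_pairs = None
    if e_genes:
        mat = ed_vectors(clf.summaries_, e_genes)
        fitter = ProfileShapeClassifier(
            candidate_set="eight", templates=config.templates
        )
        fitter.fit(mat.to_numpy(), time_points_hr=dataset.time_points)
        fit = fitter.transform(mat.to_numpy())
        fit.index = mat.index
        fit.insert(0, "gene_id", mat.index)
        path = out / "shapes_E.tsv"
        fit.to_csv(path, sep="\t", index=False)
        shape_files.append(str(path))
        from .shapes import shape_distribution

        shape_distributions["E-type"] = shape_distribution(
            fit.rename(columns={"shape": "shape"})
        )
    if gxe_genes:
        fitter = ProfileShapeClassifier(
            candidate_set="nine", templates=config.templates
        )
        per_geno = {}
        for g in dataset.genotypes:
            mat = ed_vectors(clf.summaries_, gxe_genes, genotype=g)
            fitter.fit(mat.to_numpy(), time_points_hr=dataset.time_points)
            fit = fitter.transform(mat.to_numpy())
            fit.index = mat.index
            per_geno[g] = fit
        shape_pairs = pd.DataFrame(
            {
                "shape_reference": per_geno[ref]["shape"],
                "shape_alternate": per_geno[alt]["shape"],
            }
        )
        path = out / "shapes_GxE.tsv"
        shape_pairs.to_csv(path, sep="\t")
        shape_files.append(str(path))
        joint = joint_profile_analysis(
            shape_pairs["shape_reference"], shape_pairs["shape_alternate"]
        )
        jpath = out / "joint_profiles.tsv"
        joint.observed.to_csv(jpath, sep="\t")
        shape_files.append(str(jpath))
    manifest["stages"]["shapes"] = shape_files

    # -- stage 4: enrichment ---------------------------------------------
    enrich_files = []
    enrichment_results = []
    locations = intervals = None
    if config.inputs.get("gene_locations"):
        locations = read_gene_locations(config.inputs["gene_locations"])
    if config.inputs.get("intervals"):
        intervals = read_intervals(config.inputs["intervals"])
    scheme = MergedCategoryScheme()
    if locations and intervals:
        in_qtl = genes_in_intervals(locations, intervals)
        if in_qtl:
            enrichment_results.append(
                subset_enrichment(
                    clf.labels_, in_qtl, scheme, "QTL-intervals",
                    seed=config.seed,
                )
            )
        max_gd = pd.Series(
            {
                g: max(abs(clf.summaries_[g].gd[t].value)
                       for t in dataset.time_points)
                for g in gxe_genes
            },
            dtype=float,
        )
        cand = gxe_candidates_in_intervals(
            clf.label_table_, locations, intervals,
            shape_pairs=shape_pairs, max_abs_gd=max_gd,
        )
        cpath = out / "gxe_candidates.tsv"
        cand.to_csv(cpath, sep="\t", index=False)
        enrich_files.append(str(cpath))
    for name, path in (config.inputs.get("gene_lists") or {}).items():
        gene_list = read_gene_list(path)
        enrichment_results.append(
            subset_enrichment(
                clf.labels_, gene_list, scheme, name, seed=config.seed
            )
        )
    manifest["stages"]["enrich"] = enrich_files

    # -- stage 5: report --------------------------------------------------
    report = summary_report(clf.counts_, shape_distributions, enrichment_results)
    if joint is not None:
        report["joint_profile"] = {
            "n": joint.n,
            "chi2": joint.chi2,
            "dof": joint.dof,
            "p_value": joint.p_value,
        }
    json_path = out / "report.json"
    text_path = out / "report.txt"
    write_report(report, json_path, text_path)
    manifest["stages"]["report"] = [str(json_path), str(text_path)]

    manifest["content_hash"] = _sha256_of(report)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
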