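"""Readers and writers for the tabular, interval and list formats.

All genomic coordinates are normalised to one internal convention:
0-based, half-open (the BED convention); the GFF3 reader converts from
1-based inclusive at the boundary.  Readers reject malformed rows rather
than silently coercing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import CATEGORY_ORDER, CategoryCounts
from .dataset import ExpressionDataset
from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chromosome: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneLocation:
    """Gene span in the internal 0-based half-open convention."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid span for gene {self.gene_id}: {self.start}-{self.end}"
            )

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end, self.gene_id)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["gene_id", "genotype", "time_hr", "replicate", "fpkm"]


def read_fpkm_table(
    path,
    dialect: str = "long",
    reference: str | None = None,
) -> ExpressionDataset:
    """Read replicate FPKM values into an :class:`ExpressionDataset`.

    ``dialect="long"`` expects columns ``gene_id, genotype, time_hr,
    replicate, fpkm``; ``dialect="cuffdiff-tracking"`` expects the
    read-group tracking layout ``tracking_id, condition, replicate, FPKM``
    with ``condition`` encoded as ``<genotype>_<time_hr>``.  Unknown extra
    columns are ignored.  The reference genotype (GD numerator) defaults to
    the first seen.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        df = df[_LONG_COLUMNS].copy()
    elif dialect == "cuffdiff-tracking":
        raw = pd.read_csv(path, sep="\t")
        need = ["tracking_id", "condition", "replicate", "FPKM"]
        missing = [c for c in need if c not in raw.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        geno, time = zip(*(_split_condition(c, path) for c in raw["condition"]))
        df = pd.DataFrame(
            {
                "gene_id": raw["tracking_id"],
                "genotype": geno,
                "time_hr": time,
                "replicate": raw["replicate"],
                "fpkm": raw["FPKM"],
            }
        )
    else:
        raise FormatError(f"unknown FPKM dialect {dialect!r}")

    try:
        df["time_hr"] = df["time_hr"].astype(float)
        df["fpkm"] = df["fpkm"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric time_hr or fpkm value ({exc})")
    neg = df.index[df["fpkm"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative FPKM at row {neg[0] + 2}")
    genotypes = list(pd.unique(df["genotype"]))
    if len(genotypes) != 2:
        raise ValidationError(
            f"{path}: expected exactly two genotypes, found {genotypes}"
        )
    ref = reference if reference is not None else genotypes[0]
    if ref not in genotypes:
        raise ValidationError(f"reference genotype {ref!r} not in {genotypes}")
    alt = next(g for g in genotypes if g != ref)
    return ExpressionDataset(df.reset_index(drop=True), ref, alt)


def _split_condition(label: str, path) -> tuple:
    try:
        geno, t = str(label).rsplit("_", 1)
        return geno, float(t)
    except ValueError:
        raise FormatError(
            f"{path}: condition label {label!r} not of the form <genotype>_<time_hr>"
        )


def read_qvalue_table(path, control_time: float = 0.0) -> dict:
    """Parse a Cuffdiff ``gene_exp.diff``-style table of q-values.

    Sample labels must be ``<genotype>_<time_hr>``.  A same-genotype pair
    maps to the ED contrast at the non-control time; a same-time pair of
    the two genotypes maps to the GD contrast at that time.  Returns a
    mapping ``(gene_id, ("GD", time))`` / ``(gene_id, ("ED", genotype,
    time))`` -> q-value, consumable by
    :class:`gxetools.diffstats.TableSignificance`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    need = ["gene_id", "sample_1", "sample_2", "q_value"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = {}
    for i, row in df.iterrows():
        q = float(row["q_value"])
        if not 0.0 <= q <= 1.0:
            raise ValidationError(f"{path}: q-value {q} outside [0,1] at row {i + 2}")
        g1, t1 = _split_condition(row["sample_1"], path)
        g2, t2 = _split_condition(row["sample_2"], path)
        if g1 == g2:
            if t1 == t2:
                raise FormatError(
                    f"{path}: row {i + 2} compares a sample with itself"
                )
            tt = t2 if t1 == control_time else t1 if t2 == control_time else max(t1, t2)
            key = (row["gene_id"], ("ED", g1, float(tt)))
        elif t1 == t2:
            key = (row["gene_id"], ("GD", float(t1)))
        else:
            raise FormatError(
                f"{path}: row {i + 2} compares different genotypes at different "
                "times; accepted labels pair one genotype across times (ED) or "
                "the two genotypes at one time (GD)"
            )
        out[key] = q
    return out


# ---------------------------------------------------------------------------
# intervals and gene locations
# ---------------------------------------------------------------------------


def read_intervals(path) -> list:
    """Read a BED3+ file into 0-based half-open :class:`GenomicInterval`."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer BED coordinates")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            try:
                out.append(GenomicInterval(parts[0], start, end, name))
            except ValidationError as exc:
                raise FormatError(f"{path}:{ln}: {exc}")
    return out


def _gff3_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gene_locations(path, fmt: str | None = None) -> list:
    """Read gene spans from GFF3 (1-based inclusive) or a simple TSV.

    The TSV layout is ``gene_id, chromosome, start, end[, strand]`` already
    in the internal 0-based half-open convention.  GFF3 ``gene`` features
    are converted (start-1, end); the gene id comes from the ``ID``
    attribute (a ``gene:`` prefix is stripped).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    out = []
    if fmt == "gff3":
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
                if parts[2] != "gene":
                    continue
                gene_id = _gff3_attr(parts[8], "ID")
                if gene_id is None:
                    raise FormatError(f"{path}:{ln}: gene feature without ID")
                if gene_id.startswith("gene:"):
                    gene_id = gene_id[5:]
                try:
                    start, end = int(parts[3]) - 1, int(parts[4])
                except ValueError:
                    raise FormatError(f"{path}:{ln}: non-integer coordinates")
                try:
                    out.append(
                        GeneLocation(gene_id, parts[0], start, end, parts[6] or None)
                    )
                except ValidationError as exc:
                    raise FormatError(f"{path}:{ln}: {exc}")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = ["gene_id", "chromosome", "start", "end"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for i, row in df.iterrows():
            try:
                out.append(
                    GeneLocation(
                        str(row["gene_id"]),
                        str(row["chromosome"]),
                        int(row["start"]),
                        int(row["end"]),
                        str(row["strand"]) if "strand" in df.columns else None,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: row {i + 2}: {exc}")
    else:
        raise FormatError(f"unknown gene-location format {fmt!r}")
    return out


def read_gene_list(path) -> list:
    """One gene id per line (blank lines and # comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def read_category_counts(path) -> CategoryCounts:
    """Two-column ``category <tab> count`` table -> :class:`CategoryCounts`."""
    path = Path(path)
    valid = {c.value for c in CATEGORY_ORDER}
    counts = CategoryCounts()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("category"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'category<TAB>count'")
            label, value = parts[0].strip(), parts[1].strip()
            if label not in valid:
                raise ValidationError(
                    f"{path}:{ln}: unknown category {label!r}; valid labels: "
                    f"{sorted(valid)}"
                )
            if label in counts:
                raise FormatError(f"{path}:{ln}: duplicate category {label!r}")
            try:
                n = int(value)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer count {value!r}")
            if n < 0:
                raise ValidationError(f"{path}:{ln}: negative count")
            counts[label] = n
    return counts
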