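"""File dialects and run configuration.

The pipeline exchanges four plain-text formats:

* **mutation TSV** -- one row per somatic variant with fixed columns
  ``chrom, pos, ref, alt, gene, func_class`` followed by two depth columns
  per sample (``<sample>_ref``, ``<sample>_alt``).  Positions are 1-based
  (VCF convention).
* **VCF subset** -- variants with a per-sample ``AD`` FORMAT field; the
  reader yields records equivalent to the TSV reader's.
* **segment TSV** -- SEG/BED-like copy-number segments with columns
  ``sample, chrom, start, end, n_snps, logr, baf``.  Coordinates are
  0-based half-open (BED convention); ``baf`` is the mirrored B-allele
  frequency in [0, 0.5] (empty when no heterozygous SNPs informed it).
* **Newick** -- trees, parseable by standard readers (dendropy backed).

Readers reject invariant violations (with the offending line number)
rather than silently coercing them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ConfigError",
    "FUNC_CLASSES",
    "MutationRecord",
    "SampleManifest",
    "SegmentRecord",
    "PipelineConfig",
    "read_mutation_table",
    "write_mutation_table",
    "read_vcf_subset",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_newick",
    "write_newick",
    "read_config",
]

FUNC_CLASSES = ("synonymous", "nonsynonymous", "splice", "indel", "other")

SAMPLE_TYPES = ("primary_region", "recurrence", "normal")


class FormatError(ValueError):
    """A file violated its dialect or an invariant of its record type."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class MutationRecord:
    """One somatic variant with per-sample read evidence.

    ``depths`` maps sample id to ``(ref_depth, alt_depth)``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: str = "other"
    depths: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise FormatError(f"unknown func_class {self.func_class!r}")
        for sample, (rd, ad) in self.depths.items():
            if rd < 0 or ad < 0:
                raise FormatError(
                    f"negative depth for sample {sample} at {self.chrom}:{self.pos}"
                )

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1 or self.func_class == "indel"


class SampleManifest:
    """Maps samples to tumors, regions and sample types.

    Exactly one sample must be the matched normal; every non-normal sample
    belongs to a tumor.  Backed by a DataFrame with columns
    ``sample_id, tumor_id, region_id, sample_type, collection_time_order``.
    """

    COLUMNS = ("sample_id", "tumor_id", "region_id", "sample_type", "collection_time_order")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["collection_time_order"] = frame["collection_time_order"].astype(int)
        bad = set(frame["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise FormatError(f"unknown sample_type values: {sorted(bad)}")
        if frame["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in manifest")
        normals = frame[frame["sample_type"] == "normal"]
        if len(normals) != 1:
            raise FormatError(f"manifest must contain exactly one normal sample, found {len(normals)}")
        nonnormal = frame[frame["sample_type"] != "normal"]
        if (nonnormal["tumor_id"].astype(str).str.len() == 0).any():
            raise FormatError("every non-normal sample must map to a tumor_id")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, rows: Iterable[Sequence]) -> "SampleManifest":
        return cls(pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))

    @classmethod
    def read(cls, path) -> "SampleManifest":
        return cls(pd.read_csv(path, sep="\t", dtype=str).assign(
            collection_time_order=lambda df: df["collection_time_order"].astype(int)))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def normal_sample(self) -> str:
        return str(self.frame.loc[self.frame["sample_type"] == "normal", "sample_id"].iloc[0])

    @property
    def tumor_samples_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.frame.iterrows():
            if row["sample_type"] == "normal":
                continue
            out.setdefault(str(row["tumor_id"]), []).append(str(row["sample_id"]))
        return out

    def samples_of(self, tumor_id: str) -> list[str]:
        try:
            return self.tumor_samples_map[tumor_id]
        except KeyError:
            raise KeyError(f"unknown tumor_id {tumor_id!r}") from None

    @property
    def primary_tumors(self) -> list[str]:
        seen: list[str] = []
        for _, row in self.frame.iterrows():
            if row["sample_type"] == "primary_region" and row["tumor_id"] not in seen:
                seen.append(str(row["tumor_id"]))
        return seen

    @property
    def recurrence_tumors(self) -> list[str]:
        seen: list[str] = []
        for _, row in self.frame.iterrows():
            if row["sample_type"] == "recurrence" and row["tumor_id"] not in seen:
                seen.append(str(row["tumor_id"]))
        return seen

    @property
    def tumor_samples(self) -> list[str]:
        """All non-normal samples, in manifest order."""
        return [s for s in self.samples if s != self.normal_sample]


@dataclass
class SegmentRecord:
    """One copy-number segment of one sample (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    logr: float
    baf: float  # NaN when missing

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"segment start must be < end ({self.chrom}:{self.start}-{self.end})"
            )
        if self.n_snps < 0:
            raise FormatError("n_snps must be >= 0")
        if not math.isnan(self.baf) and not 0.0 <= self.baf <= 0.5:
            raise FormatError(f"mirrored BAF must lie in [0, 0.5], got {self.baf}")


MUTATION_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "func_class")


def read_mutation_table(path, manifest: SampleManifest) -> list[MutationRecord]:
    """Parse the mutation TSV dialect; errors name the offending line."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MUTATION_FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    depth_cols = []
    for sample in manifest.samples:
        rc, ac = f"{sample}_ref", f"{sample}_alt"
        if rc not in df.columns or ac not in df.columns:
            raise FormatError(f"{path}: missing depth columns for sample {sample!r}")
        depth_cols.append((sample, rc, ac))
    records = []
    for i, r in enumerate(df.to_dict("records")):
        line_no = i + 2  # header on line 1
        try:
            depths = {}
            for sample, rc, ac in depth_cols:
                depths[sample] = (_parse_nonneg_int(r[rc], "ref depth"),
                                  _parse_nonneg_int(r[ac], "alt depth"))
            records.append(MutationRecord(
                chrom=r["chrom"], pos=_parse_nonneg_int(r["pos"], "pos"),
                ref=r["ref"], alt=r["alt"], gene=r["gene"],
                func_class=r["func_class"], depths=depths))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from None
    return records


def _parse_nonneg_int(text: str, what: str) -> int:
    try:
        value = int(str(text).strip())
    except ValueError:
        raise FormatError(f"non-integer {what}: {text!r}") from None
    if value < 0:
        raise FormatError(f"negative {what}: {value}")
    return value


def write_mutation_table(records: Sequence[MutationRecord], manifest: SampleManifest, path) -> None:
    rows = []
    for rec in records:
        row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
               "gene": rec.gene, "func_class": rec.func_class}
        for sample in manifest.samples:
            rd, ad = rec.depths.get(sample, (0, 0))
            row[f"{sample}_ref"] = rd
            row[f"{sample}_alt"] = ad
        rows.append(row)
    cols = list(MUTATION_FIXED_COLUMNS) + [
        f"{s}_{k}" for s in manifest.samples for k in ("ref", "alt")]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_vcf_subset(path, manifest: SampleManifest) -> list[MutationRecord]:
    """Read a VCF with per-sample AD; multi-allelic sites split per alt.

    Gene and functional class are taken from the INFO keys ``GENE`` and
    ``FCLASS`` when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_order = list(vcf.samples)
    missing = set(manifest.samples) - set(sample_order)
    if missing:
        raise FormatError(f"{path}: VCF lacks manifest samples {sorted(missing)}")
    records = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: variant {variant.CHROM}:{variant.POS} has no AD field")
        gene = variant.INFO.get("GENE") or ""
        fclass = variant.INFO.get("FCLASS") or "other"
        for alt_index, alt in enumerate(variant.ALT):
            depths = {}
            for si, sample in enumerate(sample_order):
                if sample not in manifest.samples:
                    continue
                rd = int(ad[si][0])
                adp = int(ad[si][1 + alt_index])
                depths[sample] = (max(rd, 0), max(adp, 0))
            records.append(MutationRecord(
                chrom=variant.CHROM, pos=int(variant.POS), ref=variant.REF,
                alt=str(alt), gene=str(gene), func_class=str(fclass), depths=depths))
    return records


def write_vcf(records: Sequence[MutationRecord], manifest: SampleManifest, path) -> None:
    """Emit records as an uncompressed VCF with per-sample AD (pysam backed)."""
    import pysam

    header = pysam.VariantHeader()
    chroms = []
    for rec in records:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom},length=300000000>")
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for sample in manifest.samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            v = out.new_record(contig=rec.chrom, start=rec.pos - 1,
                               alleles=(rec.ref, rec.alt))
            if rec.gene:
                v.info["GENE"] = rec.gene
            v.info["FCLASS"] = rec.func_class
            for sample in manifest.samples:
                rd, ad = rec.depths.get(sample, (0, 0))
                v.samples[sample]["AD"] = (rd, ad)
            out.write(v)


SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "n_snps", "logr", "baf")


def read_segments(path) -> pd.DataFrame:
    """Read the segment TSV; rejects overlapping segments within a sample."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.loc[:, list(SEGMENT_COLUMNS)].copy()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            SegmentRecord(sample=str(row.sample), chrom=str(row.chrom),
                          start=int(row.start), end=int(row.end),
                          n_snps=int(row.n_snps), logr=float(row.logr),
                          baf=float(row.baf) if pd.notna(row.baf) else float("nan"))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from None
    _check_segment_overlap(df, str(path))
    return df


def _check_segment_overlap(df: pd.DataFrame, origin: str) -> None:
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        intervals = sorted(zip(grp["start"], grp["end"]))
        for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise FormatError(
                    f"{origin}: overlapping segments for sample {sample} on {chrom} "
                    f"({s1}-{e1} vs {s2}-...)")


def write_segments(df: pd.DataFrame, path) -> None:
    df.loc[:, list(SEGMENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree, path) -> None:
    """Write a tree (dendropy Tree, Newick string, or object with to_newick())."""
    if hasattr(tree, "to_newick"):
        text = tree.to_newick()
    elif isinstance(tree, dendropy.Tree):
        text = tree.as_string(schema="newick")
    else:
        text = str(tree)
    if not text.rstrip().endswith(";"):
        text = text.rstrip() + ";"
    # validate by round-tripping through a standard parser
    dendropy.Tree.get(data=text, schema="newick")
    Path(path).write_text(text.rstrip() + "\n")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with defaults.

    Presence calling: a call is *present* when ``alt_depth >= min_alt`` and
    VAF ``>= min_vaf``; *covered-absent* when total depth ``>= min_cov_absent``
    and ``alt_depth <= max_alt_absent``; otherwise coverage is too low to
    claim anything.  ``heatmap_min_cov`` is the display filter (strict ``>``).
    """

    min_alt: int = 3
    min_vaf: float = 0.05
    min_cov_absent: int = 10
    max_alt_absent: int = 1
    heatmap_min_cov: int = 10
    distance_metric: str = "jaccard"
    linkage: str = "average"
    t_met: float = 0.5
    t_denovo: float = 0.2
    margin: float = 0.2
    k_private: int = 3
    rho_min: float = 0.05
    rho_max: float = 1.0
    rho_step: float = 0.01
    n_max: int = 4
    psi_options: tuple = (2.0,)
    logr_floor: float = -8.0

    def __post_init__(self) -> None:
        if not 0 < self.rho_min <= self.rho_max <= 1.0:
            raise ConfigError("require 0 < rho_min <= rho_max <= 1")
        if self.rho_step <= 0:
            raise ConfigError("rho_step must be positive")
        for name in ("min_vaf", "t_met", "t_denovo", "margin"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.distance_metric not in ("jaccard", "hamming"):
            raise ConfigError(f"unknown distance_metric {self.distance_metric!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "psi_options" in kwargs:
            kwargs["psi_options"] = tuple(kwargs["psi_options"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["psi_options"] = list(out["psi_options"])
        return out


def read_config(path=None) -> PipelineConfig:
    """Load a flat YAML config; missing file or empty mapping means defaults.

    Unknown keys are rejected so typos never silently fall back to defaults.
    """
    import logging

    if path is None:
        cfg = PipelineConfig()
    else:
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        cfg = PipelineConfig.from_mapping(data)
    logging.getLogger(__name__).info("resolved configuration: %s", cfg.to_dict())
    return cfg
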