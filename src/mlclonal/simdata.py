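"""Synthetic multifocal-patient generator.

Two entry points:

* :func:`simulate_patient` draws a random patient from a configurable
  clonal architecture (independent *multicentric* tumors, *metastatic*
  tumors sharing a founding clone, or a mix), then simulates per-sample
  read counts for every mutation and noisy logR/BAF segment profiles for
  every configured copy-number event.  Truth (clone tree, purities,
  segment states) rides along, so every downstream stage can be scored.

* :func:`generate_case_fixture` emits a deterministic 12-sample patient
  (three multicentric primaries sampled in three regions each, two
  recurrences seeded by the first primary, one matched normal) whose call
  matrix reproduces, by construction, a fixed reference count structure:
  per-tumor SNV/indel burdens, region-common cores, cross-tumor unique
  and overlap counts, recurrence sharing, a transition fraction, an
  HCC-A-private marker mutation (AXIN1) covered-absent in the
  recurrences, reciprocal recurrence-private mutations covered-absent in
  the seeding primary, and allele-specific copy-number truth including a
  14q copy-neutral LOH event.  Read counts for the fixture are clamped so
  the intended present / covered-absent status of every cell survives
  sampling noise; the general simulator never clamps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ascnv import expected_baf, expected_logr
from .io_formats import (
    ConfigError,
    MutationRecord,
    SampleManifest,
    write_mutation_table,
    write_newick,
    write_segments,
)

__all__ = [
    "SimConfig",
    "CloneTree",
    "SimulatedPatient",
    "simulate_reads",
    "simulate_segments",
    "simulate_patient",
    "generate_case_fixture",
    "FIXTURE_SEED",
]

FIXTURE_SEED = 1729

_CHROMS = [f"chr{i}" for i in range(1, 23)]

_TRANSITIONS = (("C", "T"), ("T", "C"))
_TRANSVERSIONS = (("C", "A"), ("C", "G"), ("T", "A"), ("T", "G"))


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_patient`."""

    seed: int = 0
    n_tumors: int = 3
    architecture: str = "multicentric"  # multicentric | metastatic | mixed
    regions_per_tumor: int = 3
    trunk_muts: int = 100
    branch_muts: int = 30
    private_muts: int = 15
    ti_fraction: float = 0.52
    purity: float | Mapping[str, float] = 0.7
    mean_depth: int = 100
    seq_error: float = 0.001
    cnv_events: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    indel_fraction: float = 0.08
    branch_ccf: float = 0.7
    private_ccf: float = 0.4

    def validate(self) -> None:
        if self.architecture not in ("multicentric", "metastatic", "mixed"):
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.n_tumors < 1 or self.regions_per_tumor < 1:
            raise ConfigError("need at least one tumor and one region")
        if self.mean_depth < 1:
            raise ConfigError("mean_depth must be >= 1")
        for name in ("ti_fraction", "seq_error", "indel_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for rho in self._purities().values():
            if not 0 < rho <= 1:
                raise ConfigError(f"purity must lie in (0, 1], got {rho}")
        if not 0 < self.private_ccf <= self.branch_ccf <= 1:
            raise ConfigError("require 0 < private_ccf <= branch_ccf <= 1")

    def _purities(self) -> dict[str, float]:
        samples = [f"T{t + 1}R{r + 1}" for t in range(self.n_tumors)
                   for r in range(self.regions_per_tumor)]
        if isinstance(self.purity, Mapping):
            return {s: float(self.purity.get(s, 0.7)) for s in samples}
        return {s: float(self.purity) for s in samples}


class CloneTree:
    """Clone genealogy: nodes with parent links, per-edge mutations/CNVs,
    and per-sample clone mixture weights.

    The root is the germline; the edge above each clone carries the
    mutations (and CNV events) acquired by that clone.  ``weights`` gives,
    per sample, the fraction of the sample's *tumor* compartment made of
    cells whose most derived clone is each node (non-negative, summing to
    1); a clone's cancer-cell fraction is the weight of its subtree.
    """

    def __init__(self) -> None:
        self.parent: dict[str, str | None] = {"germline": None}
        self.edge_mutations: dict[str, list[str]] = {}
        self.edge_cnvs: dict[str, list[tuple]] = {}
        self.weights: dict[str, dict[str, float]] = {}

    def add_clone(self, name: str, parent: str, mutations: Sequence[str] = (),
                  cnvs: Sequence[tuple] = ()) -> None:
        if name in self.parent:
            raise ValueError(f"duplicate clone {name!r}")
        if parent not in self.parent:
            raise ValueError(f"unknown parent {parent!r}")
        self.parent[name] = parent
        self.edge_mutations[name] = list(mutations)
        self.edge_cnvs[name] = list(cnvs)

    def set_weights(self, sample: str, weights: Mapping[str, float]) -> None:
        total = sum(weights.values())
        if any(w < 0 for w in weights.values()) or abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"invalid mixture weights for sample {sample}: {dict(weights)}")
        self.weights[sample] = dict(weights)

    @property
    def clones(self) -> list[str]:
        return [c for c in self.parent if c != "germline"]

    def path(self, clone: str) -> list[str]:
        out = []
        node: str | None = clone
        while node is not None and node != "germline":
            out.append(node)
            node = self.parent[node]
        return out[::-1]

    def subtree(self, clone: str) -> list[str]:
        out = [clone]
        for child, par in self.parent.items():
            if par == clone:
                out.extend(self.subtree(child))
        return out

    def ccf(self, sample: str, clone: str) -> float:
        """Cancer-cell fraction of ``clone`` in ``sample``'s tumor compartment."""
        w = self.weights.get(sample, {})
        return sum(w.get(c, 0.0) for c in self.subtree(clone))

    def mutation_ccf(self, sample: str) -> dict[str, float]:
        """CCF of every mutation in a sample (mutations ride their clone)."""
        out: dict[str, float] = {}
        for clone, muts in self.edge_mutations.items():
            c = self.ccf(sample, clone)
            for m in muts:
                out[m] = c
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for clone in self.clones:
            path = self.path(clone)
            if len(path) != len(set(path)):
                raise ValueError("cycle in clone tree")
            muts = self.edge_mutations.get(clone, [])
            dup = seen & set(muts)
            if dup:
                raise ValueError(f"mutations on multiple edges: {sorted(dup)[:5]}")
            seen |= set(muts)

    def to_newick(self) -> str:
        children: dict[str, list[str]] = {}
        for clone, par in self.parent.items():
            if par is not None:
                children.setdefault(par, []).append(clone)

        def render(node: str) -> str:
            kids = sorted(children.get(node, []))
            if not kids:
                return node
            inner = ",".join(f"{render(k)}:{len(self.edge_mutations.get(k, []))}"
                             for k in kids)
            return f"({inner}){node}"

        return render("germline") + ";"


@dataclass
class SimulatedPatient:
    """Truth plus observed data for one synthetic patient."""

    tree: CloneTree
    purity: dict[str, float]
    records: list[MutationRecord]
    segments: pd.DataFrame
    truth_segments: dict[str, list[dict]]
    manifest: SampleManifest

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mutation_table(self.records, self.manifest, outdir / "mutations.tsv")
        write_segments(self.segments, outdir / "segments.tsv")
        self.manifest.write(outdir / "manifest.tsv")
        truth = {
            "purity": self.purity,
            "edge_mutations": {c: m for c, m in self.tree.edge_mutations.items()},
            "segments": self.truth_segments,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        write_newick(self.tree, outdir / "clone_tree.nwk")


def simulate_reads(true_genotype_fraction: float, rho: float, depth_mean: int,
                   error: float, seed) -> tuple[int, int]:
    """Draw (ref_count, alt_count) for one site of one sample.

    Depth is Poisson around ``depth_mean``; the alt count is binomial with
    success probability ``q + error * (1 - q)`` where
    ``q = rho * true_genotype_fraction`` is the mixture-weighted fraction
    of mutated alleles (``true_genotype_fraction`` = CCF x mutated copies
    / total copies; 1/2 for a clonal het SNV in a diploid region).
    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if not 0 <= true_genotype_fraction <= 1:
        raise ValueError("true_genotype_fraction must lie in [0, 1]")
    if not 0 <= rho <= 1 or not 0 <= error <= 1:
        raise ValueError("rho and error must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = int(rng.poisson(depth_mean))
    q = rho * true_genotype_fraction
    p = q + error * (1.0 - q)
    alt = int(rng.binomial(depth, p)) if depth > 0 else 0
    return depth - alt, alt


def simulate_segments(true_states: Sequence[tuple[int, int]], rho: float,
                      noise_sd: float, n_snps: int, seed,
                      psi: float = 2.0) -> pd.DataFrame:
    """Forward-simulate a noisy segment table from true allele states.

    Each (nA, nB) state yields the forward-model logR and mirrored BAF
    plus Gaussian noise of sd ``noise_sd / sqrt(n_snps)``; BAF stays
    mirrored to [0, 0.5].  Segments are laid out on successive synthetic
    10 Mb intervals.
    """
    for n_a, n_b in true_states:
        if n_b < 0 or n_a < n_b:
            raise ValueError(f"require nA >= nB >= 0, got ({n_a}, {n_b})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = noise_sd / math.sqrt(max(n_snps, 1))
    rows = []
    for i, (n_a, n_b) in enumerate(true_states):
        chrom = _CHROMS[i % len(_CHROMS)]
        offset = (i // len(_CHROMS)) * 10_000_000
        logr = expected_logr(n_a, n_b, rho, psi) + rng.normal(0.0, sd)
        baf = expected_baf(n_a, n_b, rho)
        if math.isfinite(baf):
            baf = abs(baf + rng.normal(0.0, sd))
            baf = min(baf, 1.0 - baf)
        rows.append({"chrom": chrom, "start": offset, "end": offset + 10_000_000,
                     "n_snps": n_snps, "logr": logr, "baf": baf})
    return pd.DataFrame(rows)


def _draw_substitution(rng: np.random.Generator, ti_fraction: float) -> tuple[str, str]:
    if rng.random() < ti_fraction:
        return _TRANSITIONS[rng.integers(2)]
    return _TRANSVERSIONS[rng.integers(4)]


def simulate_patient(config: SimConfig) -> SimulatedPatient:
    """Simulate one multifocal patient under the configured architecture."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_r = config.n_tumors, config.regions_per_tumor

    tumors = [f"T{t + 1}" for t in range(n_t)]
    manifest_rows = []
    for t, tumor in enumerate(tumors):
        for r in range(n_r):
            manifest_rows.append((f"{tumor}R{r + 1}", tumor, f"R{r + 1}",
                                  "primary_region", 0))
    manifest_rows.append(("NORMAL", "", "", "normal", 0))
    manifest = SampleManifest.from_records(manifest_rows)
    purities = config._purities()

    tree = CloneTree()
    counter = [0]

    def new_mutations(n: int) -> list[str]:
        ids = [f"m{counter[0] + i:05d}" for i in range(n)]
        counter[0] += n
        return ids

    shared_trunk: str | None = None
    if config.architecture in ("metastatic", "mixed"):
        shared_trunk = "trunk"
        tree.add_clone(shared_trunk, "germline", new_mutations(config.trunk_muts),
                       config.cnv_events.get("trunk", ()))
    for t, tumor in enumerate(tumors):
        shares = (config.architecture == "metastatic"
                  or (config.architecture == "mixed" and t < 2))
        if shares:
            founder = f"{tumor}_branch"
            tree.add_clone(founder, shared_trunk, new_mutations(config.branch_muts),
                           config.cnv_events.get(tumor, ()))
        else:
            founder = f"{tumor}_founder"
            tree.add_clone(founder, "germline", new_mutations(config.trunk_muts),
                           config.cnv_events.get(tumor, ()))
        branch = None
        if n_r >= 2:
            branch = f"{tumor}_sub"
            tree.add_clone(branch, founder, new_mutations(config.branch_muts))
        for r in range(n_r):
            sample = f"{tumor}R{r + 1}"
            parent = founder if r == 0 or branch is None else branch
            private = f"{tumor}_private{r + 1}"
            tree.add_clone(private, parent, new_mutations(config.private_muts))
            weights = {private: config.private_ccf}
            if parent == branch:
                weights[branch] = config.branch_ccf - config.private_ccf
                weights[founder] = 1.0 - config.branch_ccf
            else:
                weights[founder] = 1.0 - config.private_ccf
            tree.set_weights(sample, weights)
    tree.validate()

    # mutation attributes
    n_muts = counter[0]
    attrs = []
    for i in range(n_muts):
        chrom = _CHROMS[i % len(_CHROMS)]
        pos = 1_000_000 + 37_000 * (i // len(_CHROMS))
        if rng.random() < config.indel_fraction:
            ref, alt, fclass = "CA", "C", "indel"
        else:
            ref, alt = _draw_substitution(rng, config.ti_fraction)
            fclass = "nonsynonymous" if rng.random() < 0.3 else "synonymous"
        attrs.append((chrom, pos, ref, alt, fclass))

    samples = manifest.samples
    records = []
    ccf_by_sample = {s: tree.mutation_ccf(s) for s in samples if s != "NORMAL"}
    for i in range(n_muts):
        mid = f"m{i:05d}"
        chrom, pos, ref, alt, fclass = attrs[i]
        depths = {}
        for s in samples:
            if s == "NORMAL":
                f, rho = 0.0, 0.0
            else:
                f = ccf_by_sample[s].get(mid, 0.0) / 2.0  # clonal het, diploid
                rho = purities[s]
            depths[s] = simulate_reads(f, rho, config.mean_depth,
                                       config.seq_error, rng)
        records.append(MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                      gene=f"GENE{i:04d}", func_class=fclass,
                                      depths=depths))

    # re-key clone-tree edges by the observable (chrom,pos,ref,alt) ids so
    # truth and observed tables join directly
    id_map = {f"m{i:05d}": records[i].mutation_id for i in range(n_muts)}
    for clone in list(tree.edge_mutations):
        tree.edge_mutations[clone] = [id_map[m] for m in tree.edge_mutations[clone]]

    segments, truth_segments = _simulate_patient_segments(
        config, tree, manifest, purities, rng)
    purity_out = {s: (0.0 if s == "NORMAL" else purities[s]) for s in samples}
    return SimulatedPatient(tree=tree, purity=purity_out, records=records,
                            segments=segments, truth_segments=truth_segments,
                            manifest=manifest)


def _simulate_patient_segments(config, tree, manifest, purities, rng):
    """Per-sample segment tables: configured events plus diploid background."""
    event_chroms: dict[str, list[tuple]] = {}
    for events in config.cnv_events.values():
        for ev in events:
            event_chroms.setdefault(str(ev[0]), []).append(ev)
    rows, truth = [], {}
    for sample in manifest.samples:
        rho = 0.0 if sample == "NORMAL" else purities[sample]
        carried: list[tuple] = []
        if sample != "NORMAL":
            for clone in tree.clones:  # clonal events only (CCF >= 0.5)
                if tree.ccf(sample, clone) >= 0.5:
                    carried.extend(tree.edge_cnvs.get(clone, ()))
        truth[sample] = [{"chrom": str(c), "start": int(s), "end": int(e),
                          "nA": int(a), "nB": int(b)} for c, s, e, a, b in carried]
        carried_map = {(str(c), int(s), int(e)): (int(a), int(b))
                       for c, s, e, a, b in carried}
        for chrom in _CHROMS:
            intervals = ([(str(c), int(s), int(e)) for c, s, e, _, _ in
                          event_chroms.get(chrom, [])]
                         or [(chrom, 0, 100_000_000)])
            for iv in sorted(set(intervals), key=lambda x: x[1]):
                n_a, n_b = carried_map.get(iv, (1, 1))
                n_snps = 50
                sd = 0.1 / math.sqrt(n_snps)
                if rho == 0.0:  # pure normal: diploid signal
                    logr, baf = 0.0, 0.5
                else:
                    logr = expected_logr(n_a, n_b, rho, 2.0)
                    baf = expected_baf(n_a, n_b, rho)
                logr += rng.normal(0.0, sd)
                if math.isfinite(baf):
                    baf = abs(baf + rng.normal(0.0, sd))
                    baf = min(baf, 1.0 - baf)
                rows.append({"sample": sample, "chrom": iv[0], "start": iv[1],
                             "end": iv[2], "n_snps": n_snps, "logr": logr,
                             "baf": baf})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# deterministic case fixture
# ---------------------------------------------------------------------------

_A = ["HCC-A1", "HCC-A2", "HCC-A3"]
_B = ["HCC-B1", "HCC-B2", "HCC-B3"]
_C = ["ICC-C1", "ICC-C2", "ICC-C3"]
_IM = ["IM1", "IM2"]
_ALL = _A + _B + _C + _IM

# name, count, samples present, n_indel, n_transition (among SNVs),
# n_nonsynonymous (among SNVs).  The counts are chosen so that every
# aggregate the fixture promises (per-tumor unions, region-common cores,
# cross-tumor unique/overlap counts, recurrence sharing and totals,
# non-synonymous and transition fractions) comes out exactly.
_FIXTURE_SUBCATS = [
    ("A_only_common", 16, _A, 0, 7, 6),
    ("A_only_a1", 20, [_A[0]], 0, 9, 6),
    ("A_only_a2", 16, [_A[1]], 0, 8, 5),
    ("A_only_a23", 30, [_A[1], _A[2]], 19, 6, 3),
    ("A_IM_common", 199, _A + _IM, 8, 99, 63),
    ("A_IM_a3", 16, [_A[2]] + _IM, 0, 8, 6),
    ("A_IM_a2", 4, [_A[1]] + _IM, 0, 2, 1),
    ("A_IM_im1", 13, _A + ["IM1"], 0, 7, 4),
    ("A_IM_im2", 13, _A + ["IM2"], 0, 7, 3),
    ("AB_IM", 34, _A + _B + _IM, 0, 18, 12),
    ("AC_IM", 36, _A + _C + _IM, 6, 18, 10),
    ("ABC_IM", 1, _ALL, 0, 1, 1),
    ("B_only_common", 101, _B, 10, 55, 30),
    ("B_only_b1", 16, [_B[0]], 0, 7, 4),
    ("B_only_b2", 14, [_B[1]], 0, 6, 3),
    ("B_only_b3", 14, [_B[2]], 0, 6, 3),
    ("BC_c1", 5, _B + [_C[0]], 3, 2, 1),
    ("BC_c2", 5, _B + [_C[1]], 3, 1, 1),
    ("BC_c3", 5, _B + [_C[2]], 2, 1, 0),
    ("BC_IM_c1", 8, _B + [_C[0]] + _IM, 3, 3, 2),
    ("BC_IM_c2", 6, _B + [_C[1]] + _IM, 2, 3, 2),
    ("BC_IM_c3", 7, _B + [_C[2]] + _IM, 2, 2, 1),
    ("C_only_common", 7, _C, 0, 5, 2),
    ("C_only_c1", 5, [_C[0]], 2, 2, 1),
    ("C_only_c2", 5, [_C[1]], 2, 2, 1),
    ("C_only_c3", 4, [_C[2]], 1, 2, 1),
    ("IM_both", 16, _IM, 0, 8, 0),
    ("IM1_only", 4, ["IM1"], 1, 1, 2),
    ("IM2_only", 10, ["IM2"], 5, 2, 2),
]

# marker mutations: subcategory -> (gene, chrom, pos); attached to the
# first SNV of the subcategory (all are non-synonymous by the quotas).
_FIXTURE_MARKERS = {
    "A_only_common": ("AXIN1", "chr16", 347_500),
    "A_IM_common": ("FAT4", "chr4", 126_237_554),
    "B_only_common": ("FAT4", "chr4", 126_320_821),
    "C_only_c1": ("NRAS", "chr1", 115_258_744),
}

_FIXTURE_PURITY = {s: 0.75 for s in _A + _IM}
_FIXTURE_PURITY.update({s: 0.50 for s in _B})
_FIXTURE_PURITY.update({s: 0.35 for s in _C})
_FIXTURE_PURITY["NORMAL"] = 0.0

# shared segment grid: (chrom, start, end, n_snps)
_FIXTURE_SEGMENTS = [
    ("chr1", 0, 120_000_000, 120), ("chr1", 125_000_000, 248_000_000, 120),
    ("chr2", 0, 240_000_000, 200), ("chr3", 0, 198_000_000, 160),
    ("chr5", 0, 48_000_000, 50), ("chr5", 50_000_000, 180_000_000, 130),
    ("chr7", 50_000_000, 62_000_000, 40),
    ("chr8", 0, 45_000_000, 45), ("chr8", 47_000_000, 146_000_000, 95),
    ("chr10", 0, 40_000_000, 40), ("chr10", 42_000_000, 135_000_000, 90),
    ("chr11", 60_000_000, 63_000_000, 25),
    ("chr13", 30_000_000, 42_000_000, 40),
    ("chr14", 20_000_000, 107_000_000, 85),
    ("chr16", 45_000_000, 90_000_000, 45),
    ("chr19", 0, 26_000_000, 30), ("chr19", 28_000_000, 59_000_000, 35),
    ("chr20", 25_000_000, 64_000_000, 40),
    ("chr21", 10_000_000, 22_000_000, 35),
    ("chr22", 20_000_000, 35_000_000, 30),
]

# non-diploid truth states per sample group, keyed by (chrom, start)
_A_GAINS = {("chr1", 125_000_000): (2, 1), ("chr5", 0): (2, 1),
            ("chr5", 50_000_000): (2, 1), ("chr8", 0): (1, 0),
            ("chr8", 47_000_000): (2, 1), ("chr10", 0): (2, 1),
            ("chr10", 42_000_000): (2, 1), ("chr14", 20_000_000): (2, 0),
            ("chr19", 0): (2, 1), ("chr19", 28_000_000): (2, 1),
            ("chr20", 25_000_000): (2, 1)}
_FIXTURE_CNV_TRUTH: dict[str, dict[tuple, tuple]] = {}
for _s in _A:
    _FIXTURE_CNV_TRUTH[_s] = dict(_A_GAINS)
_FIXTURE_CNV_TRUTH["HCC-A1"][("chr16", 45_000_000)] = (1, 0)
for _s in _IM:
    _FIXTURE_CNV_TRUTH[_s] = dict(_A_GAINS)
    _FIXTURE_CNV_TRUTH[_s][("chr11", 60_000_000)] = (1, 0)
for _s in _B:
    _FIXTURE_CNV_TRUTH[_s] = {("chr1", 125_000_000): (2, 1),
                              ("chr22", 20_000_000): (1, 0)}
for _s in _C:
    _FIXTURE_CNV_TRUTH[_s] = {("chr7", 50_000_000): (2, 1),
                              ("chr13", 30_000_000): (1, 0),
                              ("chr21", 10_000_000): (3, 1)}
_FIXTURE_CNV_TRUTH["NORMAL"] = {}

_FIXTURE_DEPTH_MEAN = 100
_FIXTURE_DEPTH_FLOOR = 12
_FIXTURE_SEQ_ERROR = 0.001
_FIXTURE_SEG_NOISE = 0.1  # sd per SNP; per segment sd = this / sqrt(n_snps)


def _fixture_manifest() -> SampleManifest:
    rows = []
    for tumor, regions in (("HCC-A", _A), ("HCC-B", _B), ("ICC", _C)):
        for i, s in enumerate(regions):
            rows.append((s, tumor, f"R{i + 1}", "primary_region", 0))
    rows.append(("IM1", "IM1", "R1", "recurrence", 1))
    rows.append(("IM2", "IM2", "R1", "recurrence", 1))
    rows.append(("NORMAL", "", "", "normal", 0))
    return SampleManifest.from_records(rows)


def _fixture_cell(rng: np.random.Generator, rho: float,
                  present: bool) -> tuple[int, int]:
    """One (ref, alt) draw with the intended call status guaranteed."""
    depth = max(_FIXTURE_DEPTH_FLOOR, int(rng.poisson(_FIXTURE_DEPTH_MEAN)))
    if present:
        alt = int(rng.binomial(depth, rho / 2.0))
        alt = min(depth, max(alt, max(3, math.ceil(0.05 * depth))))
    else:
        alt = min(int(rng.binomial(depth, _FIXTURE_SEQ_ERROR)), 1)
    return depth - alt, alt


def generate_case_fixture() -> SimulatedPatient:
    """Deterministic 12-sample multifocal patient (fixed internal seed)."""
    rng = np.random.default_rng(FIXTURE_SEED)
    manifest = _fixture_manifest()
    samples = manifest.samples

    tree = CloneTree()
    records: list[MutationRecord] = []
    chrom_counter = [0]

    def next_position() -> tuple[str, int]:
        i = chrom_counter[0]
        chrom_counter[0] += 1
        return _CHROMS[i % len(_CHROMS)], 1_000_000 + 37_000 * (i // len(_CHROMS))

    for name, count, present_in, n_indel, n_ti, n_nonsyn in _FIXTURE_SUBCATS:
        present = set(present_in)
        ids = []
        marker = _FIXTURE_MARKERS.get(name)
        for j in range(count):
            if j < n_indel:
                ref, alt = ("CA", "C") if j % 2 == 0 else ("C", "CT")
                fclass = "indel"
            else:
                k = j - n_indel  # SNV index within subcategory
                if k < n_ti:
                    ref, alt = _TRANSITIONS[k % 2]
                else:
                    ref, alt = _TRANSVERSIONS[(k - n_ti) % 4]
                fclass = "nonsynonymous" if k < n_nonsyn else "synonymous"
            if marker is not None and j == n_indel:  # first SNV carries the marker
                gene, chrom, pos = marker
            else:
                gene = f"GENE{len(records):04d}"
                chrom, pos = next_position()
            depths = {}
            for s in samples:
                depths[s] = _fixture_cell(rng, _FIXTURE_PURITY[s], s in present)
            rec = MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 gene=gene, func_class=fclass, depths=depths)
            records.append(rec)
            ids.append(rec.mutation_id)
        tree.add_clone(name, "germline", ids)
        for s in manifest.tumor_samples:
            tree.weights.setdefault(s, {})[name] = 1.0 if s in present else 0.0
    tree.validate()

    seg_rows = []
    truth_segments: dict[str, list[dict]] = {}
    for s in samples:
        rho = _FIXTURE_PURITY[s]
        truth_segments[s] = []
        for chrom, start, end, n_snps in _FIXTURE_SEGMENTS:
            n_a, n_b = _FIXTURE_CNV_TRUTH[s].get((chrom, start), (1, 1))
            truth_segments[s].append({"chrom": chrom, "start": start, "end": end,
                                      "nA": n_a, "nB": n_b})
            sd = _FIXTURE_SEG_NOISE / math.sqrt(n_snps)
            if rho == 0.0:  # pure normal: diploid signal regardless of state
                logr, baf = 0.0, 0.5
            else:
                logr = expected_logr(n_a, n_b, rho)
                baf = expected_baf(n_a, n_b, rho)
            logr += rng.normal(0.0, sd)
            baf = abs(baf + rng.normal(0.0, sd))
            baf = min(baf, 1.0 - baf)
            seg_rows.append({"sample": s, "chrom": chrom, "start": start,
                             "end": end, "n_snps": n_snps, "logr": logr,
                             "baf": baf})

    return SimulatedPatient(tree=tree, purity=dict(_FIXTURE_PURITY),
                            records=records, segments=pd.DataFrame(seg_rows),
                            truth_segments=truth_segments, manifest=manifest)
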