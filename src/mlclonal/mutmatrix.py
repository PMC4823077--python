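"""The mutations x samples evidence matrix.

Presence is called per cell from read depths alone: a mutation is
*present* in a sample when it has enough supporting reads at a credible
allele fraction, *covered-absent* when the site was sequenced deeply
enough that seeing (almost) no alternate reads is positive evidence of
absence, and *low-coverage* otherwise.  The covered-absent state matters:
arguing that two tumor lineages are siblings requires showing that each
lineage's private mutations are absent *with coverage* in the other, not
merely unobserved.

VAF at zero depth is missing (NaN), never 0 -- a zero would fabricate
exactly the covered-absence evidence the depth cannot support.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MutationRecord, PipelineConfig, SampleManifest

__all__ = [
    "PRESENT",
    "ABSENT_COVERED",
    "ABSENT_LOW_COVERAGE",
    "SampleCallMatrix",
    "call_presence",
    "build_matrix",
    "heatmap_filter",
    "substitution_spectrum",
]

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT_COVERED = "absent_covered"
ABSENT_LOW_COVERAGE = "absent_low_coverage"

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def call_presence(ref_depth: int, alt_depth: int,
                  config: PipelineConfig | None = None) -> str:
    """Classify one cell's evidence as present / covered-absent / low-coverage."""
    config = config or PipelineConfig()
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    depth = ref_depth + alt_depth
    vaf = alt_depth / depth if depth > 0 else 0.0
    if alt_depth >= config.min_alt and vaf >= config.min_vaf:
        return PRESENT
    if depth >= config.min_cov_absent and alt_depth <= config.max_alt_absent:
        return ABSENT_COVERED
    return ABSENT_LOW_COVERAGE


class SampleCallMatrix:
    """Evidence matrix over distinct (chrom, pos, ref, alt) rows.

    Attributes
    ----------
    meta : DataFrame indexed by mutation id with columns chrom, pos, ref,
        alt, gene, func_class, is_indel.
    ref_depth, alt_depth : int DataFrames (mutations x samples).
    vaf : float DataFrame, NaN where total depth is 0.
    status : str DataFrame of presence calls.
    suspect_germline : mutation ids called present in the matched normal;
        they stay in the matrix but are excluded from somatic present-sets.
    """

    def __init__(self, meta: pd.DataFrame, ref_depth: pd.DataFrame,
                 alt_depth: pd.DataFrame, manifest: SampleManifest,
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.manifest = manifest
        self.meta = meta
        self.ref_depth = ref_depth
        self.alt_depth = alt_depth
        depth = ref_depth + alt_depth
        self.depth = depth
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = alt_depth / depth
        self.vaf = vaf.where(depth > 0)
        self.status = self._call_statuses()
        normal = manifest.normal_sample
        suspects = list(self.status.index[self.status[normal] == PRESENT])
        if suspects:
            logger.warning("%d records present in normal %s flagged suspect-germline "
                           "and excluded from somatic sets", len(suspects), normal)
        self.suspect_germline = suspects

    def _call_statuses(self) -> pd.DataFrame:
        cfg = self.config
        depth = self.depth
        alt = self.alt_depth
        vaf = alt.where(depth > 0, 0).div(depth.where(depth > 0, 1))
        present = (alt >= cfg.min_alt) & (vaf >= cfg.min_vaf)
        covered = (depth >= cfg.min_cov_absent) & (alt <= cfg.max_alt_absent)
        out = pd.DataFrame(ABSENT_LOW_COVERAGE, index=alt.index, columns=alt.columns)
        out = out.mask(~present & covered, ABSENT_COVERED)
        out = out.mask(present, PRESENT)
        return out

    @property
    def samples(self) -> list[str]:
        return list(self.status.columns)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.meta.index)

    def present_set(self, samples: str | Iterable[str]) -> set[str]:
        """Somatic mutations present in any of the given samples."""
        if isinstance(samples, str):
            samples = [samples]
        mask = (self.status.loc[:, list(samples)] == PRESENT).any(axis=1)
        ids = set(self.status.index[mask]) - set(self.suspect_germline)
        return ids

    def covered(self, sample: str) -> pd.Series:
        """Boolean mask of rows with interpretable coverage in ``sample``."""
        return self.status[sample] != ABSENT_LOW_COVERAGE

    def subset(self, mutation_ids: Sequence[str]) -> "SampleCallMatrix":
        ids = list(mutation_ids)
        return SampleCallMatrix(self.meta.loc[ids], self.ref_depth.loc[ids],
                                self.alt_depth.loc[ids], self.manifest, self.config)


def build_matrix(records: Sequence[MutationRecord], manifest: SampleManifest,
                 config: PipelineConfig | None = None) -> SampleCallMatrix:
    """Assemble the call matrix; duplicate (chrom, pos, ref, alt) rows error."""
    ids = [rec.mutation_id for rec in records]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate mutation rows: {sorted(set(dupes))[:5]}")
    samples = manifest.samples
    meta = pd.DataFrame(
        {"chrom": [r.chrom for r in records], "pos": [r.pos for r in records],
         "ref": [r.ref for r in records], "alt": [r.alt for r in records],
         "gene": [r.gene for r in records],
         "func_class": [r.func_class for r in records],
         "is_indel": [r.is_indel for r in records]},
        index=pd.Index(ids, name="mutation_id"))
    ref_depth = pd.DataFrame(
        [[r.depths.get(s, (0, 0))[0] for s in samples] for r in records],
        index=meta.index, columns=samples, dtype=int)
    alt_depth = pd.DataFrame(
        [[r.depths.get(s, (0, 0))[1] for s in samples] for r in records],
        index=meta.index, columns=samples, dtype=int)
    return SampleCallMatrix(meta, ref_depth, alt_depth, manifest, config)


def heatmap_filter(matrix: SampleCallMatrix, min_cov: int | None = None,
                   func_class: str = "nonsynonymous") -> SampleCallMatrix:
    """Display filter: keep rows of the given class covered deeply everywhere.

    Coverage "above" the threshold is read strictly (depth > min_cov in
    every sample).  Idempotent; returns a row-subset of the input.
    """
    if min_cov is None:
        min_cov = matrix.config.heatmap_min_cov
    class_ok = matrix.meta["func_class"] == func_class
    cov_ok = (matrix.depth > min_cov).all(axis=1)
    keep = matrix.meta.index[class_ok & cov_ok]
    return matrix.subset(list(keep))


def _six_class(ref: str, alt: str) -> str | None:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref in ("A", "G"):  # collapse to pyrimidine-reference convention
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def substitution_spectrum(matrix: SampleCallMatrix,
                          samples: str | Iterable[str]) -> dict:
    """Six-class substitution fractions and transition fraction.

    ``samples`` may be one sample or a set of samples, in which case the
    spectrum is computed over the union of their present SNVs.  Indels are
    excluded; transitions are the C>T and T>C classes (equivalently A<->G
    and C<->T on either strand).
    """
    ids = matrix.present_set(samples)
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    n = 0
    for mid in ids:
        row = matrix.meta.loc[mid]
        if row["is_indel"]:
            continue
        cls = _six_class(row["ref"], row["alt"])
        if cls is None:
            continue
        counts[cls] += 1
        n += 1
    if n == 0:
        raise ValueError("no present SNVs; spectrum undefined")
    fractions = {cls: counts[cls] / n for cls in SPECTRUM_CLASSES}
    return {"fractions": fractions, "n_snv": n,
            "ti_fraction": fractions["C>T"] + fractions["T>C"]}
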