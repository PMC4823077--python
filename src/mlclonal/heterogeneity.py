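"""Set-based intertumor and intratumor heterogeneity statistics.

All statistics are over sets of somatic mutation ids derived from the
call matrix: a tumor's *union* pools the present calls of its sampled
regions, its *common* core is the intersection over regions, and

    heterogeneity = 1 - |common| / |union|

is the fraction of the tumor's mutation burden that multiregion sampling
reveals to be spatially restricted.  Uniqueness and overlap statistics
between tumors use the same union sets, with SNVs and indels pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io_formats import SampleManifest
from .mutmatrix import SampleCallMatrix

__all__ = [
    "VennPartition",
    "tumor_union",
    "venn_partition",
    "unique_fraction",
    "jaccard",
    "intratumor_stats",
    "recurrence_concordance",
    "recurrence_shared_fraction",
    "heterogeneity_report",
]


def tumor_union(matrix: SampleCallMatrix, manifest: SampleManifest,
                tumor_id: str) -> set[str]:
    """Union of present calls over the tumor's regions (or its single sample)."""
    samples = manifest.samples_of(tumor_id)
    return matrix.present_set(samples)


@dataclass
class VennPartition:
    """Exclusive-region counts for k named sets (2^k - 1 regions)."""

    names: tuple[str, ...]
    regions: dict[frozenset, int]  # membership pattern -> count
    totals: dict[str, int]

    def exclusive(self, name: str) -> int:
        """Elements in ``name`` and no other set."""
        return self.regions.get(frozenset([name]), 0)

    def count(self, *names: str) -> int:
        """Elements in exactly the given sets."""
        return self.regions.get(frozenset(names), 0)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def venn_partition(sets: Mapping[str, set]) -> VennPartition:
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = tuple(sets)
    regions: dict[frozenset, int] = {}
    universe = set().union(*sets.values())
    for element in universe:
        pattern = frozenset(n for n in names if element in sets[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    totals = {n: len(sets[n]) for n in names}
    return VennPartition(names=names, regions=regions, totals=totals)


def unique_fraction(target_set: set, other_sets: Iterable[set]) -> float:
    """Fraction of the target set found in none of the other sets."""
    if not target_set:
        raise ValueError("target set is empty")
    others = set().union(*other_sets) if other_sets else set()
    return len(target_set - others) / len(target_set)


def jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def intratumor_stats(matrix: SampleCallMatrix, manifest: SampleManifest,
                     tumor_id: str) -> tuple[float, float]:
    """(common_fraction, heterogeneity) over the tumor's sampled regions.

    The denominator is the tumor union; a mutation counts as common only
    when called present in every region (strict definition).  Single-region
    tumors return (1.0, 0.0) by convention, with a warning.
    """
    samples = manifest.samples_of(tumor_id)
    union = matrix.present_set(samples)
    if len(samples) < 2:
        warnings.warn(f"tumor {tumor_id} has a single region; "
                      "intratumor stats are trivial", stacklevel=2)
        return 1.0, 0.0
    common = set.intersection(*(matrix.present_set(s) for s in samples))
    if not union:
        return 1.0, 0.0
    common_fraction = len(common & union) / len(union)
    return common_fraction, 1.0 - common_fraction


def recurrence_concordance(recurrence_sets: Sequence[set], primary_set: set) -> float:
    """Fraction of the pooled recurrence alterations found in the primary."""
    union = set().union(*recurrence_sets) if recurrence_sets else set()
    if not union:
        raise ValueError("recurrence union is empty")
    return len(union & primary_set) / len(union)


def recurrence_shared_fraction(recurrence_sets: Sequence[set]) -> float:
    """Fraction of the pooled recurrence alterations shared by all recurrences."""
    union = set().union(*recurrence_sets) if recurrence_sets else set()
    if not union:
        raise ValueError("recurrence union is empty")
    shared = set.intersection(*(set(s) for s in recurrence_sets))
    return len(shared) / len(union)


def heterogeneity_report(matrix: SampleCallMatrix, manifest: SampleManifest) -> dict:
    """All set statistics of the case in one JSON-ready structure."""
    primaries = manifest.primary_tumors
    recurrences = manifest.recurrence_tumors
    unions = {t: tumor_union(matrix, manifest, t)
              for t in primaries + recurrences}
    indel_ids = set(matrix.meta.index[matrix.meta["is_indel"]])

    per_tumor = {}
    for t in primaries + recurrences:
        u = unions[t]
        common_fraction, het = intratumor_stats(matrix, manifest, t)
        entry = {
            "n_total": len(u),
            "n_snv": len(u - indel_ids),
            "n_indel": len(u & indel_ids),
            "common_fraction": common_fraction,
            "heterogeneity": het,
        }
        if t in primaries and u:
            others = [unions[o] for o in primaries if o != t]
            entry["unique_fraction"] = unique_fraction(u, others)
            entry["n_unique"] = len(u - set().union(*others)) if others else len(u)
        per_tumor[t] = entry

    pairs = {}
    for a, b in combinations(primaries + recurrences, 2):
        pairs[f"{a}|{b}"] = {
            "overlap": len(unions[a] & unions[b]),
            "jaccard": jaccard(unions[a], unions[b]),
        }

    report = {"per_tumor": per_tumor, "pairwise": pairs}
    if primaries:
        report["venn_primaries"] = {
            "|".join(sorted(k)): v
            for k, v in venn_partition({t: unions[t] for t in primaries}).regions.items()
        } if len(primaries) >= 2 else {}

    if recurrences:
        rec_sets = [unions[r] for r in recurrences]
        rec_union = set().union(*rec_sets)
        recurrence = {
            "union_size": len(rec_union),
            "shared_fraction": recurrence_shared_fraction(rec_sets)
            if len(recurrences) >= 2 else 1.0,
            "concordance_union": {
                p: recurrence_concordance(rec_sets, unions[p]) for p in primaries},
            "concordance_per_recurrence": {
                r: {p: recurrence_concordance([unions[r]], unions[p])
                    for p in primaries}
                for r in recurrences},
        }
        report["recurrence"] = recurrence
    return report
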