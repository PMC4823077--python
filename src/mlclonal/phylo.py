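"""Sample phylogeny and recurrence-origin classification.

Three views of the same binary presence matrix:

* **hierarchical clustering** of samples on mutation-profile distances
  (Jaccard by default, average linkage), the exploratory view;
* a **shared-mutation parsimony tree**: mutations are grouped by the set
  of samples supporting them (their *split*), compatible splits are
  accepted greedily by support count into a laminar clade family (a
  perfect phylogeny when the matrix is conflict free), and each
  incompatible minority split is mapped to the accepted clade requiring
  the fewest character flips.  Branch lengths carry the number of
  mutations mapped to the branch;
* an **origin classifier** for recurrent tumors: a recurrence whose
  mutation profile is concordant with one primary far beyond the others
  is called an intrahepatic metastasis seeded by that primary; near-zero
  concordance with every primary means de novo origin.  The seeded
  relationship is refined with covered-absence evidence: reciprocal
  private mutations (each lineage carrying mutations the other lacks at
  good coverage) imply sibling clones diverged from a common founding
  clone, while a one-sided private set implies linear descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import squareform

from . import heterogeneity
from .io_formats import PipelineConfig, SampleManifest
from .mutmatrix import ABSENT_LOW_COVERAGE, ABSENT_COVERED, PRESENT, SampleCallMatrix

__all__ = [
    "PhyloTree",
    "OriginCall",
    "ClusterResult",
    "binary_distance",
    "hierarchical_cluster",
    "build_parsimony_tree",
    "classify_origin",
]


def binary_distance(matrix: SampleCallMatrix, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise sample distances on presence profiles.

    Rows with low coverage in either sample of a pair are excluded from
    both numerator and denominator, so missing data never masquerades as
    absence.  ``jaccard``: 1 - |both present| / |either present|;
    ``hamming``: fraction of covered rows with discordant calls.
    """
    samples = matrix.manifest.tumor_samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    status = matrix.status.loc[:, samples]
    present = status == PRESENT
    covered = status != ABSENT_LOW_COVERAGE
    for s in samples:
        if not covered[s].any():
            raise ValueError(f"sample {s} has no covered rows")
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            both_cov = covered[a] & covered[b]
            pa, pb = present[a] & both_cov, present[b] & both_cov
            if metric == "jaccard":
                either = (pa | pb).sum()
                d = 1.0 - (pa & pb).sum() / either if either else 0.0
            elif metric == "hamming":
                n = both_cov.sum()
                d = (pa ^ pb).sum() / n if n else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            dist.loc[a, b] = dist.loc[b, a] = float(d)
    return dist


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    newick: str


def hierarchical_cluster(distances: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of a symmetric distance matrix.

    Samples are ordered lexicographically before linkage so that ties in
    merge distances break deterministically by sample id.  The dendrogram
    is serialised as Newick with branch lengths equal to height differences.
    """
    labels = sorted(distances.index)
    d = distances.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(d, d.T) or np.diag(d).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    z = scipy_linkage(squareform(d, checks=False), method=method)
    root = to_tree(z)

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        parts = ",".join(
            f"{newick(c)}:{max(node.dist - c.dist, 0.0):.6g}"
            for c in (node.left, node.right))
        return f"({parts})"

    return ClusterResult(labels=labels, linkage=z, newick=newick(root) + ";")


@dataclass
class PhyloTree:
    """Sample tree with per-branch mutation assignments.

    ``clades`` maps each clade (frozenset of sample ids) to the list of
    mutation ids on the branch leading to it; the clade of all leaves is
    the trunk.  The family is laminar, so parenthood is containment.
    """

    leaves: tuple[str, ...]
    clades: dict[frozenset, list[str]]
    conflicts: dict[str, int] = field(default_factory=dict)  # mutation -> flip cost

    def branch_counts(self) -> dict[frozenset, int]:
        return {clade: len(muts) for clade, muts in self.clades.items()}

    def has_clade(self, samples) -> bool:
        return frozenset(samples) in self.clades

    def children(self, clade: frozenset) -> list[frozenset]:
        out = []
        for other in self.clades:
            if other < clade and not any(
                    other < mid < clade for mid in self.clades):
                out.append(other)
        return sorted(out, key=lambda c: sorted(c))

    def to_newick(self) -> str:
        root = frozenset(self.leaves)

        def render(clade: frozenset) -> str:
            kids = self.children(clade)
            covered = set().union(*kids) if kids else set()
            singles = [frozenset([s]) for s in sorted(clade - covered)]
            parts = []
            for child in list(kids) + singles:
                count = len(self.clades.get(child, []))
                if len(child) == 1:
                    parts.append(f"{next(iter(child))}:{count}")
                else:
                    parts.append(f"{render(child)}:{count}")
            return "(" + ",".join(parts) + ")"

        return render(root) + ";"


def _compatible(s: frozenset, family: list[frozenset]) -> bool:
    return all(s <= t or t <= s or not (s & t) for t in family)


def build_parsimony_tree(matrix: SampleCallMatrix,
                         manifest: SampleManifest) -> PhyloTree:
    """Greedy perfect-phylogeny construction from the presence matrix.

    Low-coverage cells are treated as missing and do not define splits.
    On a conflict-free matrix this recovers the generating topology with
    every mutation on its true branch; incompatible minority splits are
    assigned to the accepted clade minimising presence/absence flips
    (ties: smaller clade, then lexicographic).
    """
    leaves = tuple(manifest.tumor_samples)
    status = matrix.status.loc[:, list(leaves)]
    support: dict[frozenset, list[str]] = {}
    for mid in matrix.mutation_ids:
        if mid in matrix.suspect_germline:
            continue
        row = status.loc[mid]
        s = frozenset(row.index[row == PRESENT])
        if s:
            support.setdefault(s, []).append(mid)

    root = frozenset(leaves)
    if list(support) == [root]:
        warnings.warn("all samples share all mutations; star tree", stacklevel=2)

    ordered = sorted(support, key=lambda s: (-len(support[s]), sorted(s)))
    family = [root] + [frozenset([leaf]) for leaf in leaves]
    clades: dict[frozenset, list[str]] = {c: [] for c in family}
    conflicts: dict[str, int] = {}
    deferred: list[frozenset] = []
    for s in ordered:
        if s in clades:
            clades[s].extend(support[s])
        elif _compatible(s, family):
            family.append(s)
            clades[s] = list(support[s])
        else:
            deferred.append(s)
    for s in deferred:
        best = min(family, key=lambda t: (len(s ^ t), len(t), sorted(t)))
        clades[best].extend(support[s])
        for mid in support[s]:
            conflicts[mid] = len(s ^ best)
    return PhyloTree(leaves=leaves, clades=clades, conflicts=conflicts)


@dataclass
class OriginCall:
    """Origin and relationship classification for one recurrent tumor."""

    recurrence_id: str
    best_primary: str | None
    concordance: dict[str, float]
    origin: str  # intrahepatic_metastasis | de_novo | ambiguous
    relationship: str  # sibling | linear_descendant | ambiguous
    evidence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"recurrence_id": self.recurrence_id,
                "best_primary": self.best_primary,
                "concordance": self.concordance,
                "origin": self.origin,
                "relationship": self.relationship,
                "evidence": self.evidence}


def _covered_absent_in_all(matrix: SampleCallMatrix, mutation_ids, samples) -> list[str]:
    status = matrix.status
    out = []
    for mid in sorted(mutation_ids):
        if all(status.loc[mid, s] == ABSENT_COVERED for s in samples):
            out.append(mid)
    return out


def classify_origin(matrix: SampleCallMatrix, manifest: SampleManifest,
                    config: PipelineConfig | None = None,
                    cnv_discordance: dict | None = None) -> list[OriginCall]:
    """Classify each recurrent tumor against the primaries.

    Origin: intrahepatic metastasis when the best primary concordance
    reaches ``t_met`` and exceeds the runner-up by ``margin``; de novo
    when every concordance is below ``t_denovo``; otherwise ambiguous.
    Relationship to the seeding primary rests on reciprocal private
    mutations that are covered-absent on the other side (at least
    ``k_private`` each for siblings; a one-sided empty set under coverage
    means linear descent).  ``cnv_discordance`` (recurrence id -> list of
    discordant segments from :func:`mlclonal.ascnv.compare_profiles`)
    is attached as supporting evidence.
    """
    config = config or PipelineConfig()
    primaries = manifest.primary_tumors
    recurrences = manifest.recurrence_tumors
    if not primaries or not recurrences:
        raise ValueError("need at least one primary and one recurrence")
    unions = {t: heterogeneity.tumor_union(matrix, manifest, t)
              for t in primaries + recurrences}
    all_primary = set().union(*(unions[p] for p in primaries))
    calls = []
    for rec in recurrences:
        rec_set = unions[rec]
        conc = {p: heterogeneity.recurrence_concordance([rec_set], unions[p])
                for p in primaries}
        ranked = sorted(conc, key=lambda p: (-conc[p], p))
        best = ranked[0]
        runner_up = conc[ranked[1]] if len(ranked) > 1 else 0.0
        if conc[best] >= config.t_met and conc[best] - runner_up >= config.margin:
            origin = "intrahepatic_metastasis"
        elif conc[best] < config.t_denovo:
            origin = "de_novo"
        else:
            origin = "ambiguous"

        # private mutations, each side relative to all other tumors
        other_tumors = [t for t in primaries if t != best]
        primary_private = unions[best] - set().union(
            set(), *(unions[t] for t in other_tumors + recurrences))
        rec_private = rec_set - all_primary
        rec_samples = [s for r in recurrences for s in manifest.samples_of(r)]
        primary_absent = _covered_absent_in_all(matrix, primary_private, rec_samples)
        rec_absent = _covered_absent_in_all(matrix, rec_private,
                                            manifest.samples_of(best))
        k = config.k_private
        if not primary_private and not rec_private:
            relationship = "ambiguous"
            warnings.warn(f"{rec}: no private candidates on either side; "
                          "relationship ambiguous", stacklevel=2)
        elif len(primary_absent) >= k and len(rec_absent) >= k:
            relationship = "sibling"
        elif bool(primary_absent) != bool(rec_absent):
            relationship = "linear_descendant"
        else:
            relationship = "ambiguous"

        evidence = {
            "primary_private_covered_absent": primary_absent,
            "recurrence_private_covered_absent": rec_absent,
            "discordant_cnv": (cnv_discordance or {}).get(rec, []),
        }
        calls.append(OriginCall(recurrence_id=rec, best_primary=best,
                                concordance=conc, origin=origin,
                                relationship=relationship, evidence=evidence))
    return calls
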