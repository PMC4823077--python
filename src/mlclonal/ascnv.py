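"""Allele-specific copy number (ASCN) and normal-contamination estimation.

A tumor sample is a mixture of tumor cells (fraction rho, the purity) and
admixed normal cells (contamination 1 - rho).  For a segment carrying
``nA`` copies of the major and ``nB`` copies of the minor parental allele
(``nA >= nB >= 0``) in the tumor cells, the expected mirrored B-allele
frequency of heterozygous germline SNPs and the expected log2 coverage
ratio are

    BAF  = (1 - rho + rho * nB) / (2 * (1 - rho) + rho * (nA + nB))
    logR = log2( (2 * (1 - rho) + rho * (nA + nB)) / psi )

with ``psi`` the ploidy normalisation (2 for a near-diploid genome).  The
fit inverts this forward model by an ASCAT-style grid search: for each
candidate purity, every segment is assigned the integer allele state that
minimises its squared (logR, BAF) residual, and the purity minimising the
``n_snps``-weighted total residual wins.  Ties go to the lowest purity.

A genome whose segments are all allele-balanced carries no purity
information (the (1,1) state fits any purity exactly); such fits are
returned with ``identifiable=False``.  A subtler degeneracy maps state
(nA, nB) at purity rho onto (2*nA - 1, 2*nB - 1) at purity rho/2 whenever
all states map to valid integers; any unbalanced segment with ``nB = 0``
blocks it, so LOH segments anchor the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PipelineConfig

__all__ = [
    "ASCNProfile",
    "expected_baf",
    "expected_logr",
    "fit_purity_ascn",
    "detect_cn_loh",
    "compare_profiles",
]


def _check_state(n_a: int, n_b: int) -> None:
    if n_b < 0 or n_a < n_b:
        raise ValueError(f"require nA >= nB >= 0, got ({n_a}, {n_b})")


def expected_baf(n_a: int, n_b: int, rho: float) -> float:
    """Expected mirrored BAF of het SNPs on a (nA, nB) segment at purity rho.

    Returns NaN for the homozygous-deletion corner case (rho = 1 and
    nA = nB = 0) where no allele is left to measure.
    """
    _check_state(n_a, n_b)
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    denom = 2.0 * (1.0 - rho) + rho * (n_a + n_b)
    if denom <= 0:
        return float("nan")
    return (1.0 - rho + rho * n_b) / denom


def expected_logr(n_a: int, n_b: int, rho: float, psi: float = 2.0,
                  floor: float = -8.0) -> float:
    """Expected log2 coverage ratio of a (nA, nB) segment at purity rho."""
    _check_state(n_a, n_b)
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    total = 2.0 * (1.0 - rho) + rho * (n_a + n_b)
    if total <= 0:
        return floor
    return max(math.log2(total / psi), floor)


def _segment_flag(n_a: int, n_b: int) -> str:
    total = n_a + n_b
    if total == 2 and n_b == 0:
        return "cn_loh"
    if total > 2:
        return "gain"
    if total < 2:
        return "loss"
    return "neutral"


@dataclass
class ASCNProfile:
    """Fitted allele-specific copy-number profile of one sample."""

    sample_id: str
    purity: float
    psi: float
    segments: pd.DataFrame  # chrom,start,end,n_snps,logr,baf,nA,nB,residual,flag
    identifiable: bool = True
    total_residual: float = 0.0
    rho_profile: pd.DataFrame = field(default=None, repr=False)

    @property
    def contamination(self) -> float:
        return 1.0 - self.purity


def fit_purity_ascn(segments: pd.DataFrame, config: PipelineConfig | None = None,
                    sample_id: str = "") -> ASCNProfile:
    """Grid-search purity and integer allele states for one sample.

    ``segments`` needs columns ``chrom, start, end, n_snps, logr, baf``
    (one sample's rows; ``baf`` may be NaN on some segments but at least
    one segment must carry a BAF).
    """
    config = config or PipelineConfig()
    seg = segments.reset_index(drop=True)
    if len(seg) == 0 or not np.isfinite(seg["baf"].to_numpy(dtype=float)).any():
        raise ValueError("need at least one segment with a BAF to fit purity")

    states = [(a, b) for a in range(config.n_max + 1) for b in range(a + 1)]
    n_steps = int(round((config.rho_max - config.rho_min) / config.rho_step))
    rho_grid = np.round(config.rho_min + config.rho_step * np.arange(n_steps + 1), 10)
    rho_grid = rho_grid[rho_grid <= config.rho_max + 1e-12]

    obs_logr = seg["logr"].to_numpy(dtype=float)
    obs_baf = seg["baf"].to_numpy(dtype=float)
    has_baf = np.isfinite(obs_baf)
    weights = np.maximum(seg["n_snps"].to_numpy(dtype=float), 1.0)

    best = None  # (total, rho, psi, state_idx, residuals)
    totals_by_rho: dict[float, float] = {}
    for psi in config.psi_options:
        for rho in rho_grid:
            exp_l = np.array([expected_logr(a, b, rho, psi, config.logr_floor)
                              for a, b in states])
            exp_b = np.array([expected_baf(a, b, rho) for a, b in states])
            # residual matrix: segments x states
            res = (obs_logr[:, None] - exp_l[None, :]) ** 2
            baf_term = (obs_baf[:, None] - exp_b[None, :]) ** 2
            baf_term = np.where(np.isfinite(baf_term), baf_term, np.inf)
            res = res + np.where(has_baf[:, None], baf_term, 0.0)
            state_idx = np.argmin(res, axis=1)
            seg_res = res[np.arange(len(seg)), state_idx]
            total = float(np.sum(weights * seg_res))
            key = float(rho)
            totals_by_rho[key] = min(total, totals_by_rho.get(key, np.inf))
            if best is None or total < best[0] - 1e-12:
                best = (total, float(rho), float(psi), state_idx, seg_res)

    total, rho_hat, psi_hat, state_idx, seg_res = best
    fitted = seg.copy()
    fitted["nA"] = [states[i][0] for i in state_idx]
    fitted["nB"] = [states[i][1] for i in state_idx]
    fitted["residual"] = seg_res
    fitted["flag"] = [_segment_flag(*states[i]) for i in state_idx]

    totals = np.array([totals_by_rho[float(r)] for r in rho_grid])
    flat = (totals.max() - totals.min()) <= 1e-9 + 0.01 * totals.min()
    profile = ASCNProfile(
        sample_id=sample_id, purity=rho_hat, psi=psi_hat, segments=fitted,
        identifiable=not flat, total_residual=total,
        rho_profile=pd.DataFrame({"rho": rho_grid, "total_residual": totals}))
    if flat:
        warnings.warn(
            f"purity is not identifiable for sample {sample_id or '<unnamed>'}: "
            "residual profile is flat (allele-balanced genome?)", stacklevel=2)
    return profile


def detect_cn_loh(profile: ASCNProfile) -> pd.DataFrame:
    """Segments with copy-neutral LOH, i.e. allele state (2, 0)."""
    seg = profile.segments
    return seg[seg["flag"] == "cn_loh"].reset_index(drop=True)


def compare_profiles(profile_a: ASCNProfile, profile_b: ASCNProfile) -> pd.DataFrame:
    """Per-interval concordance of two fitted profiles.

    Segment grids are intersected by coordinates; an overlapping interval is
    concordant when both samples carry the identical (nA, nB) state (states
    are already in the mirrored minor-allele convention, which aligns the
    allele labels).  The discordant rows feed the recurrence-origin
    classifier as copy-number evidence.
    """
    rows = []
    a_by_chrom: dict[str, list] = {}
    for _, r in profile_a.segments.iterrows():
        a_by_chrom.setdefault(str(r["chrom"]), []).append(r)
    for _, rb in profile_b.segments.iterrows():
        for ra in a_by_chrom.get(str(rb["chrom"]), []):
            start = max(int(ra["start"]), int(rb["start"]))
            end = min(int(ra["end"]), int(rb["end"]))
            if start >= end:
                continue
            state_a = (int(ra["nA"]), int(ra["nB"]))
            state_b = (int(rb["nA"]), int(rb["nB"]))
            rows.append({
                "chrom": str(rb["chrom"]), "start": start, "end": end,
                "nA_a": state_a[0], "nB_a": state_a[1],
                "nA_b": state_b[0], "nB_b": state_b[1],
                "concordant": state_a == state_b,
            })
    if not rows:
        warnings.warn("profiles cover disjoint genomes; empty comparison", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "start", "end", "nA_a", "nB_a",
                                     "nA_b", "nB_b", "concordant"])
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
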