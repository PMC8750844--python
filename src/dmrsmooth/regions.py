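"""Refinement of candidate regions and Bonferroni-corrected t-testing.

A candidate region is the set of CpG sites inside an equilibrium point's
positional confidence window. Biological refinement requires each region to
be a dense cluster: member sites are split at any inter-site gap above
0.3 kb (a DMR should contain at least one CpG per 300 bp), singleton and
sub-10-site clusters are dropped, and clusters sharing sites are merged so
no site is tested twice. Each surviving region is tested by a one-sample
two-sided t-test of the per-site methylation differences against zero, at a
per-test level of 0.05 divided by the number of tested regions (Bonferroni).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .equilibria import EquilibriumPoint

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRegion",
    "RegionRecord",
    "DMRCall",
    "DegenerateVarianceError",
    "build_candidates",
    "refine_regions",
    "test_region",
    "bonferroni_alpha",
    "call_dmrs",
]


class DegenerateVarianceError(ValueError):
    """All member-site differences identical: t statistic undefined."""


@dataclass
class CandidateRegion:
    """Member sites of one confidence window (indices into the site table)."""

    chrom: str
    lower_pos: int
    upper_pos: int
    site_indices: np.ndarray
    point: EquilibriumPoint | None = None

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)


@dataclass
class RegionRecord:
    """Output record for a tested region (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_diff: float
    t_stat: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region must satisfy start < end")
        if self.n_sites < 1:
            raise ValueError("region must contain at least one site")
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass
class DMRCall(RegionRecord):
    """RegionRecord plus the multiplicity context of its decision."""

    alpha_used: float = float("nan")
    n_tested: int = 0
    window_method: str = ""
    tested: bool = True
    site_indices: np.ndarray | None = None


def build_candidates(
    points: list[EquilibriumPoint], pos: np.ndarray, chrom: str
) -> list[CandidateRegion]:
    """Collect the sites inside each resolved confidence window."""
    out = []
    for pt in points:
        if pt.window is None:
            continue
        lo, hi = pt.window
        i0 = int(np.searchsorted(pos, lo, side="left"))
        i1 = int(np.searchsorted(pos, hi, side="right"))
        if i1 <= i0:
            continue
        out.append(
            CandidateRegion(chrom, int(lo), int(hi), np.arange(i0, i1), pt)
        )
    return out


def refine_regions(
    candidates: list[CandidateRegion],
    pos: np.ndarray,
    max_gap: int = 300,
    min_sites: int = 10,
) -> list[CandidateRegion]:
    """Apply the density/size refinement rules to candidate windows.

    Within each candidate, member sites are split into maximal clusters at
    every inter-site gap strictly greater than ``max_gap`` ("within 0.3 kb"
    read inclusively); clusters below ``min_sites`` — singletons being the
    fully-dispersed case — are discarded. Surviving clusters become regions
    bounded by their first and last site; regions from different equilibrium
    points that share at least one site are merged. Idempotent; output is
    sorted by genomic start.
    """
    clusters: list[tuple[int, int, CandidateRegion]] = []  # inclusive index spans
    for cand in candidates:
        idx = np.sort(cand.site_indices)
        if idx.size == 0:
            continue
        gaps = np.diff(pos[idx])
        breaks = np.flatnonzero(gaps > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            if e - s + 1 >= min_sites:
                clusters.append((int(idx[s]), int(idx[e]), cand))

    # merge clusters sharing >= 1 site (index intervals: overlap <=> sharing)
    clusters.sort()
    merged: list[tuple[int, int, CandidateRegion]] = []
    for lo, hi, cand in clusters:
        if merged and lo <= merged[-1][1]:
            plo, phi, pcand = merged[-1]
            merged[-1] = (plo, max(phi, hi), pcand)
        else:
            merged.append((lo, hi, cand))

    out = []
    for lo, hi, cand in merged:
        out.append(
            CandidateRegion(
                cand.chrom,
                int(pos[lo]),
                int(pos[hi]),
                np.arange(lo, hi + 1),
                cand.point,
            )
        )
    return out


def test_region(d_region: np.ndarray) -> tuple[float, float, float]:
    """One-sample two-sided t-test of the member-site differences vs zero.

    Returns (mean_diff, t, p) with t = mean / (sd/√n) on n−1 df.
    """
    d_region = np.asarray(d_region, dtype=float)
    n = d_region.shape[0]
    if n < 2:
        raise ValueError("t-test needs at least 2 sites (df = n - 1 > 0)")
    sd = float(np.std(d_region, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("zero standard deviation across sites")
    t, p = stats.ttest_1samp(d_region, 0.0)
    return float(np.mean(d_region)), float(t), float(p)


def bonferroni_alpha(n_tested: int, family_alpha: float = 0.05) -> float:
    """Per-test significance level family_alpha / #tested regions."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    return family_alpha / n_tested


def call_dmrs(
    refined: list[CandidateRegion],
    d: np.ndarray,
    family_alpha: float = 0.05,
) -> list[DMRCall]:
    """Test every refined region; significant ⇔ p < family_alpha/#tested.

    All regions are returned with their decisions (the DMR list is the
    significant subset). Regions with zero variance across sites are
    reported untested (p = NaN, not significant) rather than silently
    dropped.
    """
    if not refined:
        return []
    alpha = bonferroni_alpha(len(refined), family_alpha)
    calls: list[DMRCall] = []
    for reg in refined:
        dr = d[reg.site_indices]
        method = reg.point.window_method if reg.point is not None else ""
        try:
            mean_diff, t, p = test_region(dr)
            tested = True
        except DegenerateVarianceError:
            mean_diff, t, p, tested = float(np.mean(dr)), float("nan"), float("nan"), False
            logger.warning(
                "region %s:%d-%d has zero variance; reported untested",
                reg.chrom, reg.lower_pos, reg.upper_pos,
            )
        calls.append(
            DMRCall(
                chrom=reg.chrom,
                start=int(reg.lower_pos),
                end=int(reg.upper_pos),
                n_sites=int(reg.site_indices.size),
                mean_diff=mean_diff,
                t_stat=t,
                p_value=p,
                significant=bool(tested and p < alpha),
                alpha_used=alpha,
                n_tested=len(refined),
                window_method=method,
                tested=tested,
                site_indices=reg.site_indices,
            )
        )
    return calls
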