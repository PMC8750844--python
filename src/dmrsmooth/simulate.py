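"""Synthetic replicated bisulfite count data with known differential truth.

The generator emulates the structure the pipeline assumes: irregular CpG
spacing (geometric inter-site gaps, default mean 100 bp), a smooth baseline
methylation surface shared by both groups, localized difference bumps with a
raised-cosine taper (so the true difference curve is smooth), and per-site
counts drawn as total ~ Poisson(depth) and meth ~ Binomial(total, level) per
replicate. Poisson depth means zero-total sites occur naturally, exercising
the zero-total filter. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_io import SiteTable

logger = logging.getLogger(__name__)

__all__ = [
    "DMRSpec",
    "SimulationSpec",
    "TruthSet",
    "simulate_counts",
    "evaluate_calls",
    "write_simulated_dataset",
]


@dataclass(frozen=True)
class DMRSpec:
    """A planted difference bump: centre (bp), full width (bp), effect size."""

    center: float
    width: float
    effect: float


@dataclass
class SimulationSpec:
    """World description for one simulated two-group chromosome."""

    n_sites: int = 20_000
    mean_spacing: float = 100.0  # bp, geometric gap law
    baseline: float | Callable[[np.ndarray], np.ndarray] = 0.5
    dmrs: Sequence[DMRSpec] = field(default_factory=tuple)
    depth_mean: float = 30.0
    n_reps_a: int = 3
    n_reps_b: int = 3
    seed: int = 0
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class TruthSet:
    """Planted intervals and the exact per-site group levels."""

    intervals: list[tuple[int, int, float]]  # (start, end, effect), 1-based inclusive
    pos: np.ndarray
    level_a: np.ndarray
    level_b: np.ndarray

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("truth intervals must be non-overlapping")
        self.intervals = ivs


#: fraction of each bump's width occupied by the two cosine edge tapers
TAPER_FRACTION = 0.5


def _bump_profile(x: np.ndarray, dmrs: Sequence[DMRSpec]) -> np.ndarray:
    """Sum of flat-core bumps with raised-cosine edge tapers (Tukey windows).

    Inside |x−c| ≤ w/2 the effect is at full size over the central
    (1 − TAPER_FRACTION)·w core and rolls off smoothly to zero through a
    half-cosine over each remaining edge, so the true difference curve is
    smooth while the interior of a planted region carries the nominal
    effect.
    """
    e = np.zeros_like(x, dtype=float)
    for b in dmrs:
        rel = np.abs(x - b.center)
        half = b.width / 2.0
        taper = TAPER_FRACTION * half  # per-side taper length
        core = half - taper
        inside = rel <= half
        ramp = np.clip((rel[inside] - core) / max(taper, 1e-12), 0.0, 1.0)
        e[inside] += b.effect * 0.5 * (1.0 + np.cos(np.pi * ramp))
    return e


def simulate_counts(spec: SimulationSpec) -> tuple[SiteTable, TruthSet]:
    """Draw a replicated count table and its ground truth from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    gaps = rng.geometric(1.0 / spec.mean_spacing, size=spec.n_sites)
    pos = np.cumsum(gaps).astype(np.int64)

    x = pos.astype(float)
    base = spec.baseline(x) if callable(spec.baseline) else np.full(spec.n_sites, float(spec.baseline))
    if np.any((base < 0) | (base > 1)):
        raise ValueError("baseline level outside [0, 1]")
    effect = _bump_profile(x, spec.dmrs)
    level_a = np.clip(base + effect, 0.0, 1.0)
    level_b = base
    if spec.dmrs and np.allclose(level_a, level_b):
        raise ValueError("infeasible spec: planted effects entirely clipped away")

    def _draw(level: np.ndarray, n_reps: int) -> tuple[np.ndarray, np.ndarray]:
        total = rng.poisson(spec.depth_mean, size=(spec.n_sites, n_reps))
        meth = rng.binomial(total, level[:, None])
        return meth, total

    a_meth, a_total = _draw(level_a, spec.n_reps_a)
    b_meth, b_total = _draw(level_b, spec.n_reps_b)
    st = SiteTable(spec.chrom, pos, a_meth, a_total, b_meth, b_total)

    intervals = []
    for b in spec.dmrs:
        lo = int(np.ceil(b.center - b.width / 2.0))
        hi = int(np.floor(b.center + b.width / 2.0))
        intervals.append((lo, hi, b.effect))
    truth = TruthSet(intervals, pos, level_a, level_b)
    return st, truth


def evaluate_calls(
    calls: Sequence, truth: TruthSet, min_overlap: int = 1
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of significant calls.

    A truth interval is recovered when at least one significant call overlaps
    it by ``min_overlap`` bp; a call is false when it overlaps no truth
    interval. Empty denominators follow the 0/0 = 0 convention.
    """
    sig = [c for c in calls if getattr(c, "significant", False)]

    def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
        return min(a1, b1) - max(a0, b0) + 1

    recovered = 0
    for t0, t1, _ in truth.intervals:
        if any(_overlap(c.start, c.end, t0, t1) >= min_overlap for c in sig):
            recovered += 1
    false = sum(
        1
        for c in sig
        if not any(_overlap(c.start, c.end, t0, t1) >= min_overlap for t0, t1, _ in truth.intervals)
    )
    sensitivity = recovered / len(truth.intervals) if truth.intervals else 0.0
    fdp = false / len(sig) if sig else 0.0
    return sensitivity, fdp


def write_simulated_dataset(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Write Bismark-coverage replicates plus a truth BED; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st, truth = simulate_counts(spec)

    def _write_cov(path: Path, meth: np.ndarray, total: np.ndarray) -> None:
        lines = []
        for p, m, t in zip(st.pos, meth, total):
            pct = 100.0 * m / t if t > 0 else 0.0
            lines.append(f"{st.chrom}\t{p}\t{p}\t{pct:.6g}\t{m}\t{t - m}")
        path.write_text("\n".join(lines) + "\n")

    files: dict[str, list[str]] = {"group_a": [], "group_b": []}
    for r in range(spec.n_reps_a):
        f = outdir / f"groupA_rep{r + 1}.cov"
        _write_cov(f, st.a_meth[:, r], st.a_total[:, r])
        files["group_a"].append(str(f))
    for r in range(spec.n_reps_b):
        f = outdir / f"groupB_rep{r + 1}.cov"
        _write_cov(f, st.b_meth[:, r], st.b_total[:, r])
        files["group_b"].append(str(f))

    truth_bed = outdir / "truth.bed"
    with truth_bed.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for k, (s, e, eff) in enumerate(truth.intervals, start=1):
            fh.write(f"{st.chrom}\t{s - 1}\t{e}\tTRUE_DMR_{k}\t{int(1000 * abs(eff))}\t.\n")

    manifest = {
        "chrom": st.chrom,
        "n_sites": st.n_sites,
        "seed": spec.seed,
        "files": files,
        "truth_bed": str(truth_bed),
        "n_true_dmrs": len(truth.intervals),
    }
    (outdir / "simulation.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
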