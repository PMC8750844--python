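"""Derivative estimation and equilibrium-point detection on the difference curve.

The first derivative of the smoothed difference curve is estimated at every
analyzed site by a kernel-weighted local quadratic fit: minimising

    U(α) = Σ_i κ_h(x_i − x0) (y_i − α0 − α1(x_i−x0) − α2(x_i−x0)²)²

gives θ̂(x0) = α̂0 and θ̂̇(x0) = α̂1 (the quadratic term reduces boundary
bias relative to a local linear fit). A pointwise normal confidence interval
for α̂1, built from a heteroscedasticity-agnostic sandwich variance, drives
the two-sided test of H0: θ̇(x0) = 0. Equilibrium points (local extrema of
the smoothed curve) are coordinates where the derivative crosses zero or,
absent an observable sign change, where a run of CIs containing zero marks a
plateau. Around each equilibrium point the derivative CI (l, u) is inverted
into a positional confidence window by scanning ten sites to either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .curve import DifferenceCurve, KernelConfig, SegmentPlan, adaptive_bandwidths

logger = logging.getLogger(__name__)

__all__ = [
    "LocalQuadraticFit",
    "DerivativeCI",
    "DerivativeTrack",
    "EquilibriumPoint",
    "DegenerateFitError",
    "local_quadratic_fit",
    "derivative_ci",
    "derivative_track",
    "find_equilibrium_points",
    "invert_confidence_window",
]


class DegenerateFitError(ValueError):
    """Local design matrix is singular (fewer than 3 usable coordinates)."""


@dataclass
class LocalQuadraticFit:
    """Kernel-weighted quadratic fit at a single target coordinate."""

    x0: float
    alpha0: float
    alpha1: float
    alpha2: float
    se_alpha1: float
    n_eff: float  # kernel-weight mass ~ effective influence points
    h_used: float


@dataclass
class DerivativeCI:
    """Pointwise normal CI and two-sided p-value for H0: θ̇(x0) = 0."""

    l: float
    u: float
    p_value: float
    level: float = 0.95

    @property
    def contains_zero(self) -> bool:
        # degenerate se=0 intervals collapse to a point; treat (0,0) as
        # containing zero so the p/CI duality holds in the limit
        if self.l == self.u:
            return self.l == 0.0
        return self.l < 0.0 < self.u


@dataclass
class DerivativeTrack:
    """Per-analyzed-site derivative fits along a stitched chromosome track.

    ``site_index`` maps track rows back to indices of the full filtered site
    table; all other arrays are parallel to it.
    """

    site_index: np.ndarray
    pos: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    se_alpha1: np.ndarray
    ci_l: np.ndarray
    ci_u: np.ndarray
    p_value: np.ndarray
    level: float = 0.95

    @property
    def n(self) -> int:
        return int(self.pos.shape[0])

    @property
    def ci_zero(self) -> np.ndarray:
        degenerate = self.ci_l == self.ci_u
        return np.where(
            degenerate, self.ci_l == 0.0, (self.ci_l < 0.0) & (self.ci_u > 0.0)
        )


@dataclass
class EquilibriumPoint:
    """A zero of the estimated derivative with its positional window."""

    track_idx: int
    site_index: int
    pos: float
    kind: str  # "maximum" | "minimum"
    deriv: float
    ci: DerivativeCI
    window: tuple[float, float] | None = None
    window_method: str = "pending"  # inverted | mirrored | failed


# ---------------------------------------------------------------------------
# fitting

def _fit_batch(
    pos: np.ndarray,
    d: np.ndarray,
    x0: np.ndarray,
    cfg: KernelConfig,
):
    """Vectorised weighted quadratic fits at many coordinates.

    Covariates are centred and scaled by the per-point bandwidth for
    conditioning; coefficients are rescaled back afterwards. Weights are the
    unnormalised Gaussian exp(−u²/2) so Σw acts as an effective influence
    count (the κ_h 1/h factor cancels from the estimator and its variance).
    Returns (alpha[m,3], se_alpha1[m], n_eff[m], h[m]).
    """
    pos = np.asarray(pos, dtype=float)
    d = np.asarray(d, dtype=float)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.unique(pos).shape[0] < 3:
        raise DegenerateFitError("need at least 3 distinct coordinates")
    h = adaptive_bandwidths(pos, x0, cfg)
    t = (pos[None, :] - x0[:, None]) / h[:, None]  # scaled centred covariate
    w = np.exp(-0.5 * t * t)
    w2 = w * w

    # moment sums S_k = Σ w t^k (k=0..4), B_k = Σ w² t^k, T_k = Σ w t^k y
    tk = np.ones_like(t)
    S = np.empty((x0.shape[0], 5))
    B = np.empty((x0.shape[0], 5))
    T = np.empty((x0.shape[0], 3))
    for k in range(5):
        S[:, k] = (w * tk).sum(axis=1)
        B[:, k] = (w2 * tk).sum(axis=1)
        if k < 3:
            T[:, k] = (w * tk * d[None, :]).sum(axis=1)
        tk = tk * t

    idx = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4]])
    A = S[:, idx]  # (m, 3, 3) moment matrices
    Bm = B[:, idx]
    try:
        beta = np.linalg.solve(A, T[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("singular local design") from exc

    # explicit residuals: the quadratic-form shortcut cancels catastrophically
    # on (near-)exact fits and would report a spurious nonzero variance
    resid = d[None, :] - beta[:, 0:1] - beta[:, 1:2] * t - beta[:, 2:3] * (t * t)
    rss = (w * resid * resid).sum(axis=1)
    dof = np.maximum(S[:, 0] - 3.0, 1e-12)
    sigma2 = rss / dof

    Ainv = np.linalg.inv(A)
    cov_t = np.einsum("mij,mjk,mkl->mil", Ainv, Bm, Ainv)
    se_beta1 = np.sqrt(np.maximum(cov_t[:, 1, 1] * sigma2, 0.0))

    alpha = np.empty((x0.shape[0], 3))
    alpha[:, 0] = beta[:, 0]
    alpha[:, 1] = beta[:, 1] / h
    alpha[:, 2] = beta[:, 2] / (h * h)
    se_alpha1 = se_beta1 / h
    return alpha, se_alpha1, S[:, 0], h


def local_quadratic_fit(
    pos: np.ndarray, d: np.ndarray, x0: float, cfg: KernelConfig
) -> LocalQuadraticFit:
    """Fit the local quadratic at one coordinate; α̂1 estimates θ̇(x0)."""
    alpha, se1, n_eff, h = _fit_batch(pos, d, np.array([float(x0)]), cfg)
    return LocalQuadraticFit(
        x0=float(x0),
        alpha0=float(alpha[0, 0]),
        alpha1=float(alpha[0, 1]),
        alpha2=float(alpha[0, 2]),
        se_alpha1=float(se1[0]),
        n_eff=float(n_eff[0]),
        h_used=float(h[0]),
    )


def _ci_arrays(alpha1: np.ndarray, se: np.ndarray, level: float):
    z = stats.norm.ppf(0.5 + level / 2.0)
    safe_se = np.where(se > 0, se, np.inf)
    p = 2.0 * stats.norm.sf(np.abs(alpha1) / safe_se)
    p = np.where((se == 0) & (alpha1 != 0), 0.0, p)  # exact-fit limit
    return alpha1 - z * se, alpha1 + z * se, p


def derivative_ci(fit: LocalQuadraticFit, level: float = 0.95) -> DerivativeCI:
    """Normal CI (l, u) = α̂1 ∓ z·se and two-sided p for H0: θ̇(x0)=0.

    se = 0 is the exact-fit limit: p = 0 when α̂1 ≠ 0, p = 1 when α̂1 = 0,
    CI degenerate at α̂1.
    """
    l, u, p = _ci_arrays(
        np.array([fit.alpha1]), np.array([fit.se_alpha1]), level
    )
    return DerivativeCI(float(l[0]), float(u[0]), float(p[0]), level)


def derivative_track(
    curve: DifferenceCurve,
    cfg: KernelConfig,
    plan: SegmentPlan,
    level: float = 0.95,
) -> DerivativeTrack:
    """Local quadratic derivative fits at every analyzed site, stitched.

    Each site's fit uses only the sites of the segment whose contribution
    span contains it, reusing the adaptive bandwidth rule; trimmed margins
    are not evaluated.
    """
    lo, hi = plan.analyzed_range
    chunks: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for seg in plan.segments:
        c0, c1 = max(seg.contrib_start, lo), min(seg.contrib_end, hi)
        if c0 >= c1:
            continue
        alpha, se1, _, _ = _fit_batch(
            curve.pos[seg.start : seg.end],
            curve.d[seg.start : seg.end],
            curve.pos[c0:c1].astype(float),
            cfg,
        )
        chunks.append((c0, c1, alpha[:, 0], alpha[:, 1], alpha[:, 2], se1))
    if not chunks:
        empty = np.empty(0)
        return DerivativeTrack(
            np.empty(0, dtype=np.int64), empty, empty, empty, empty, empty,
            empty, empty, empty, level,
        )
    chunks.sort(key=lambda c: c[0])
    site_index = np.concatenate([np.arange(c0, c1) for c0, c1, *_ in chunks])
    a0 = np.concatenate([c[2] for c in chunks])
    a1 = np.concatenate([c[3] for c in chunks])
    a2 = np.concatenate([c[4] for c in chunks])
    se = np.concatenate([c[5] for c in chunks])
    ci_l, ci_u, p = _ci_arrays(a1, se, level)
    return DerivativeTrack(
        site_index=site_index,
        pos=curve.pos[site_index].astype(float),
        alpha0=a0,
        alpha1=a1,
        alpha2=a2,
        se_alpha1=se,
        ci_l=ci_l,
        ci_u=ci_u,
        p_value=p,
        level=level,
    )


# ---------------------------------------------------------------------------
# equilibrium points

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def find_equilibrium_points(track: DerivativeTrack) -> list[EquilibriumPoint]:
    """Locate equilibrium points of the derivative track.

    (a) at every sign change of α̂1 (+→− maximum, −→+ minimum) the point is
    chosen within the flanking run of CI-containing-zero sites as the site
    with minimal |α̂1| (its CI must contain zero); ties break to the largest
    p-value. (b) a maximal run of CI-containing-zero sites with no observed
    sign change yields at most one plateau point: the site with the largest
    p-value, its kind inferred from the flanking derivative signs (falling
    back to the local curvature α̂2 when the run touches the track ends).
    A run abutting a sign change is consumed by rule (a).
    """
    n = track.n
    if n == 0:
        return []
    a1 = track.alpha1
    ci_zero = track.ci_zero
    p = track.p_value

    # sign changes between consecutive analyzed sites (zeros belong to runs)
    cross = a1[:-1] * a1[1:] < 0.0
    cross_idx = np.flatnonzero(cross)  # change between i and i+1

    points: list[EquilibriumPoint] = []
    used_crossings: set[int] = set()
    for s, e in _runs(ci_zero):
        # crossing pair (i, i+1) touches the run when i or i+1 lies inside it
        touching = [int(i) for i in cross_idx if s - 1 <= i <= e - 1]
        members = np.arange(s, e)
        if touching:
            used_crossings.update(touching)
            first = touching[0]
            kind = "maximum" if a1[first] > 0 else "minimum"
            order = np.lexsort((-p[members], np.abs(a1[members])))
            pick = int(members[order[0]])
        else:
            pick = int(members[np.argmax(p[members])])
            left = a1[s - 1] if s > 0 else None
            right = a1[e] if e < n else None
            if left is not None and left != 0.0:
                kind = "maximum" if left > 0 else "minimum"
            elif right is not None and right != 0.0:
                kind = "maximum" if right < 0 else "minimum"
            else:
                kind = "maximum" if track.alpha2[pick] <= 0 else "minimum"
        points.append(
            EquilibriumPoint(
                track_idx=pick,
                site_index=int(track.site_index[pick]),
                pos=float(track.pos[pick]),
                kind=kind,
                deriv=float(a1[pick]),
                ci=DerivativeCI(
                    float(track.ci_l[pick]),
                    float(track.ci_u[pick]),
                    float(p[pick]),
                    track.level,
                ),
            )
        )
    points.sort(key=lambda pt: pt.track_idx)
    return points


def invert_confidence_window(
    pt: EquilibriumPoint, track: DerivativeTrack, scan: int = 10
) -> EquilibriumPoint:
    """Invert the derivative CI (l, u) into a positional confidence window.

    For a maximum, scanning rightward up to ``scan`` sites the upper
    coordinate is the first site with α̂1 ≤ l, and leftward the lower
    coordinate is the first with α̂1 ≥ u; minima use mirrored comparisons.
    If only one side resolves at k sites, the other is mirrored k sites
    opposite (dropping the point when the mirror leaves the track); if
    neither resolves the point is discarded from candidacy.
    """
    j = pt.track_idx
    a1 = track.alpha1
    n = track.n
    l, u = pt.ci.l, pt.ci.u
    if pt.kind == "maximum":
        up_hit = lambda v: v <= l
        lo_hit = lambda v: v >= u
    else:
        up_hit = lambda v: v >= u
        lo_hit = lambda v: v <= l

    k_up = k_lo = None
    for k in range(1, scan + 1):
        if k_up is None and j + k < n and up_hit(a1[j + k]):
            k_up = k
        if k_lo is None and j - k >= 0 and lo_hit(a1[j - k]):
            k_lo = k
        if k_up is not None and k_lo is not None:
            break

    method = "inverted"
    if k_up is None and k_lo is None:
        return replace(pt, window=None, window_method="failed")
    if k_up is None:
        k_up, method = k_lo, "mirrored"
    elif k_lo is None:
        k_lo, method = k_up, "mirrored"
    if j + k_up >= n or j - k_lo < 0:  # mirror fell off the analyzed track
        return replace(pt, window=None, window_method="failed")
    window = (float(track.pos[j - k_lo]), float(track.pos[j + k_up]))
    return replace(pt, window=window, window_method=method)
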