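"""Mutual-information non-local total-variation (MI-NLTV) denoiser.

The denoiser refines a reconstructed attenuation volume slice by slice.
For every pixel a *stationary* patch of side ``2a + 1`` is compared with
every *moving* patch in a square non-local search window.  All
stationary/moving pixel pairs feed one joint intensity histogram, from
which a statistical measure

    M = MI(I_A, I_B) / H(I_A)

is formed: the mutual information between the stationary patch and the
pooled search-set patches, normalized by the stationary-patch entropy.
Structured, low-entropy patches that repeat in their neighbourhood score
high M; featureless noisy patches score low.  The smoothing weight per
pixel is

    w_j = exp(-(V_j / tau)^rho * M_j),

so high-intensity, high-M pixels (edges, dense inserts) are preserved
(w -> 0) and homogeneous noisy regions are smoothed (w -> 1).  ``tau`` is
an upper intensity percentile of the whole volume.

The weighted total-variation objective R(V) = sum_j w_j * D(V_j) with the
backward-difference gradient magnitude D is minimized by steepest descent
with the gradient normalized to unit Euclidean norm and an adaptive step
``lambda = gamma * sqrt(sum_j V_j^2) * step_scale``; gamma shrinks by
``r_red`` whenever the objective rises.

A conventional NLTV baseline replaces M with a normalized non-local-means
(Gaussian patch-distance) similarity; everything else is shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .core import Volume

__all__ = [
    "DenoiseParams",
    "JointHistogram",
    "WeightMap",
    "DescentState",
    "entropy",
    "mutual_information",
    "statistical_measure",
    "build_joint_histogram",
    "compute_weight_map",
    "nlm_weight_map",
    "tv_objective",
    "tv_gradient",
    "denoise",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class DenoiseParams:
    """Hyper-parameters of the MI-NLTV denoiser.

    Defaults follow the reference configuration: 5x5 patches (``a = 2``),
    21x21 search window, spatial exponent ``rho = 10``, ``tau`` at the 90th
    intensity percentile, 128x128 joint histogram, 20 descent iterations,
    initial step scaling ``gamma0 = 1`` reduced by ``r_red = 0.8`` on
    objective increases.
    """

    a: int = 2
    search_radius: int = 10  # half-extent; 2*10+1 = 21
    rho: float = 10.0
    tau_percentile: float = 90.0
    bins: int = 128
    iterations: int = 20
    gamma0: float = 1.0
    r_red: float = 0.8
    eps: Optional[float] = None  # None -> 1e-8 * slice intensity range
    weight_mode: str = "mi"  # "mi" | "nlm"
    nlm_h: Optional[float] = None  # None -> 0.1 * slice intensity range
    recompute_weights_every: int = 0  # 0 = weights fixed from the input slice
    step_scale: Optional[float] = None  # None -> 0.5/sqrt(n_pixels)
    weight_composition: str = "product"  # "product" | "quotient"
    include_null_displacement: bool = False
    aggregate: str = "pooled"  # "pooled" | "per_patch"
    reject_on_increase: bool = False

    def __post_init__(self) -> None:
        if self.a < 1:
            raise ValueError("patch radius a must be >= 1")
        if self.search_radius < self.a:
            raise ValueError("search_radius must be >= patch radius a")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not (0 < self.tau_percentile < 100):
            raise ValueError("tau_percentile must lie in (0, 100)")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.r_red < 1):
            raise ValueError("r_red must lie in (0, 1)")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.weight_mode not in ("mi", "nlm"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.weight_composition not in ("product", "quotient"):
            raise ValueError(f"unknown weight_composition {self.weight_composition!r}")
        if self.aggregate not in ("pooled", "per_patch"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.recompute_weights_every < 0:
            raise ValueError("recompute_weights_every must be >= 0")


@dataclass
class JointHistogram:
    """Joint intensity histogram between stationary (rows) and moving
    (columns) patch pixels, with its marginals."""

    counts: np.ndarray
    marginal_a: np.ndarray = field(init=False)
    marginal_b: np.ndarray = field(init=False)
    n: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("joint histogram counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("joint histogram counts must be non-negative")
        self.marginal_a = self.counts.sum(axis=1)
        self.marginal_b = self.counts.sum(axis=0)
        self.n = float(self.counts.sum())
        if self.n <= 0:
            raise ValueError("joint histogram is empty")


@dataclass
class WeightMap:
    """Per-pixel smoothing weights ``values`` in (0, 1] and the underlying
    statistical measure ``measure`` in [0, 1]."""

    values: np.ndarray
    measure: np.ndarray


@dataclass
class DescentState:
    """Iteration state of the adaptive steepest descent for one slice."""

    t: int
    gamma: float
    lam: float
    r_history: List[float]
    accepted: List[bool]
    gamma_history: List[float] = field(default_factory=list)
    lambda_history: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# entropies and mutual information
# ---------------------------------------------------------------------------

def entropy(marginal: np.ndarray) -> float:
    """Shannon entropy in bits, ``H = -sum p log2 p`` with ``0 log 0 = 0``.

    The input is normalized internally, so raw counts are accepted.
    """
    m = np.asarray(marginal, dtype=np.float64)
    total = m.sum()
    if m.size == 0 or total <= 0:
        raise ValueError("cannot compute the entropy of an empty histogram")
    p = m / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def mutual_information(h: JointHistogram) -> float:
    """``MI = H(A) + H(B) - H(A, B)`` in bits, clipped at zero from below."""
    h_a = entropy(h.marginal_a)
    h_b = entropy(h.marginal_b)
    h_ab = entropy(h.counts.ravel())
    return max(0.0, h_a + h_b - h_ab)


def statistical_measure(h: JointHistogram) -> float:
    """``M = MI / H(A)`` clamped to [0, 1]; zero for a featureless
    (zero-entropy) stationary patch, which then falls to the smoothing
    state."""
    h_a = entropy(h.marginal_a)
    if h_a < 1e-12:
        return 0.0
    return float(np.clip(mutual_information(h) / h_a, 0.0, 1.0))


# ---------------------------------------------------------------------------
# joint histogram construction
# ---------------------------------------------------------------------------

def _bin_indices(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    """Linear intensity-to-bin mapping on [lo, hi] with the top edge
    included in the last bin; a flat range maps everything to bin 0."""
    if hi <= lo:
        return np.zeros(np.shape(values), dtype=np.int64)
    idx = np.floor((np.asarray(values) - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def build_joint_histogram(
    slice_2d: np.ndarray, center: Tuple[int, int], params: DenoiseParams
) -> JointHistogram:
    """Pooled joint histogram between the stationary patch at ``center``
    and every displaced (moving) patch in the search window.

    Intensities are binned with the slice-global min/max so the top of each
    histogram axis corresponds to the slice maximum.  The null displacement
    is excluded unless ``params.include_null_displacement``; the total pair
    count is then ``(2a+1)^2 * ((2s+1)^2 - 1)``.
    """
    a, s, bins = params.a, params.search_radius, params.bins
    sl = np.asarray(slice_2d, dtype=np.float64)
    lo, hi = float(sl.min()), float(sl.max())
    pad = a + s
    padded = np.pad(sl, pad, mode="reflect")
    binned = _bin_indices(padded, lo, hi, bins)
    r0, c0 = center[0] + pad, center[1] + pad
    stat = binned[r0 - a : r0 + a + 1, c0 - a : c0 + a + 1].ravel()
    counts = np.zeros((bins, bins), dtype=np.float64)
    for dr in range(-s, s + 1):
        for dc in range(-s, s + 1):
            if dr == 0 and dc == 0 and not params.include_null_displacement:
                continue
            mov = binned[
                r0 + dr - a : r0 + dr + a + 1, c0 + dc - a : c0 + dc + a + 1
            ].ravel()
            np.add.at(counts, (stat, mov), 1.0)
    return JointHistogram(counts=counts)


# ---------------------------------------------------------------------------
# fast measure maps (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mi_measure_map_kernel(binned, nr, nc, a, s, bins, include_null, out):
    """Per-pixel pooled-histogram statistical measure.

    ``binned`` is the reflect-padded, pre-binned slice; output is the
    (nr, nc) measure map.  The joint histogram is sparse (at most n pairs
    touch it), so only touched bins are visited and reset.
    """
    pad = a + s
    counts = np.zeros((bins, bins), dtype=np.float64)
    marg_a = np.zeros(bins, dtype=np.float64)
    marg_b = np.zeros(bins, dtype=np.float64)
    max_pairs = (2 * a + 1) * (2 * a + 1) * (2 * s + 1) * (2 * s + 1)
    touched_i = np.empty(max_pairs, dtype=np.int64)
    touched_j = np.empty(max_pairs, dtype=np.int64)
    patch = np.empty((2 * a + 1) * (2 * a + 1), dtype=np.int64)

    for r in range(nr):
        for c in range(nc):
            r0 = r + pad
            c0 = c + pad
            m = 0
            for pr in range(-a, a + 1):
                for pc in range(-a, a + 1):
                    patch[m] = binned[r0 + pr, c0 + pc]
                    m += 1
            n_t = 0
            n_pairs = 0.0
            for dr in range(-s, s + 1):
                for dc in range(-s, s + 1):
                    if dr == 0 and dc == 0 and not include_null:
                        continue
                    m = 0
                    for pr in range(-a, a + 1):
                        for pc in range(-a, a + 1):
                            bi = patch[m]
                            bj = binned[r0 + dr + pr, c0 + dc + pc]
                            m += 1
                            if counts[bi, bj] == 0.0:
                                touched_i[n_t] = bi
                                touched_j[n_t] = bj
                                n_t += 1
                            counts[bi, bj] += 1.0
                            marg_a[bi] += 1.0
                            marg_b[bj] += 1.0
                            n_pairs += 1.0
            # entropies over touched bins only; reset as we go
            h_a = 0.0
            h_b = 0.0
            h_ab = 0.0
            for t in range(n_t):
                v = counts[touched_i[t], touched_j[t]]
                if v > 0.0:
                    p = v / n_pairs
                    h_ab -= p * np.log2(p)
                    counts[touched_i[t], touched_j[t]] = 0.0
            for b in range(bins):
                if marg_a[b] > 0.0:
                    p = marg_a[b] / n_pairs
                    h_a -= p * np.log2(p)
                    marg_a[b] = 0.0
                if marg_b[b] > 0.0:
                    p = marg_b[b] / n_pairs
                    h_b -= p * np.log2(p)
                    marg_b[b] = 0.0
            if h_a < 1e-12:
                out[r, c] = 0.0
            else:
                mi = h_a + h_b - h_ab
                if mi < 0.0:
                    mi = 0.0
                mval = mi / h_a
                if mval > 1.0:
                    mval = 1.0
                out[r, c] = mval


@njit(cache=True)
def _nlm_measure_map_kernel(padded, nr, nc, a, s, h2_patch, include_null, out):
    """Non-local-means similarity map: mean over displacements of
    ``exp(-||patch_0 - patch_d||^2 / ((2a+1)^2 h^2))``."""
    pad = a + s
    np_patch = (2 * a + 1) * (2 * a + 1)
    patch = np.empty(np_patch, dtype=np.float64)
    for r in range(nr):
        for c in range(nc):
            r0 = r + pad
            c0 = c + pad
            m = 0
            for pr in range(-a, a + 1):
                for pc in range(-a, a + 1):
                    patch[m] = padded[r0 + pr, c0 + pc]
                    m += 1
            acc = 0.0
            n_d = 0
            for dr in range(-s, s + 1):
                for dc in range(-s, s + 1):
                    if dr == 0 and dc == 0 and not include_null:
                        continue
                    ssd = 0.0
                    m = 0
                    for pr in range(-a, a + 1):
                        for pc in range(-a, a + 1):
                            diff = patch[m] - padded[r0 + dr + pr, c0 + dc + pc]
                            ssd += diff * diff
                            m += 1
                    acc += np.exp(-ssd / h2_patch)
                    n_d += 1
            out[r, c] = acc / n_d


def _measure_map(slice_2d: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Statistical-measure map M_j for one slice (mi or nlm mode)."""
    sl = np.asarray(slice_2d, dtype=np.float64)
    nr, nc = sl.shape
    pad = params.a + params.search_radius
    padded = np.pad(sl, pad, mode="reflect")
    out = np.empty((nr, nc))
    if params.weight_mode == "mi":
        if params.aggregate == "per_patch":
            return _measure_map_per_patch(sl, params)
        lo, hi = float(sl.min()), float(sl.max())
        binned = _bin_indices(padded, lo, hi, params.bins)
        _mi_measure_map_kernel(
            binned, nr, nc, params.a, params.search_radius, params.bins,
            params.include_null_displacement, out,
        )
    else:
        rng = float(sl.max() - sl.min())
        h = params.nlm_h if params.nlm_h is not None else 0.1 * (rng if rng > 0 else 1.0)
        h2 = (2 * params.a + 1) ** 2 * h * h
        _nlm_measure_map_kernel(
            padded, nr, nc, params.a, params.search_radius, h2,
            params.include_null_displacement, out,
        )
    return out


def _measure_map_per_patch(sl: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Average of per-displacement MI/H(A) instead of one pooled histogram.

    Reference variant for experimentation; quadratically slower, intended
    for small slices only.
    """
    from dataclasses import replace

    nr, nc = sl.shape
    out = np.empty((nr, nc))
    a, s = params.a, params.search_radius
    pooled = replace(params, aggregate="pooled")
    lo, hi = float(sl.min()), float(sl.max())
    pad = a + s
    padded = np.pad(sl, pad, mode="reflect")
    binned = _bin_indices(padded, lo, hi, params.bins)
    for r in range(nr):
        for c in range(nc):
            r0, c0 = r + pad, c + pad
            stat = binned[r0 - a : r0 + a + 1, c0 - a : c0 + a + 1].ravel()
            vals = []
            for dr in range(-s, s + 1):
                for dc in range(-s, s + 1):
                    if dr == 0 and dc == 0 and not params.include_null_displacement:
                        continue
                    mov = binned[
                        r0 + dr - a : r0 + dr + a + 1, c0 + dc - a : c0 + dc + a + 1
                    ].ravel()
                    counts = np.zeros((params.bins, params.bins))
                    np.add.at(counts, (stat, mov), 1.0)
                    vals.append(statistical_measure(JointHistogram(counts)))
            out[r, c] = np.mean(vals)
    return out


def _compose_weights(
    slice_2d: np.ndarray, measure: np.ndarray, tau: float, params: DenoiseParams
) -> np.ndarray:
    """Combine the spatial factor (V/tau)^rho with the measure into w_j."""
    v = np.maximum(np.asarray(slice_2d, dtype=np.float64), 0.0)
    spatial = (v / tau) ** params.rho
    if params.weight_composition == "product":
        expo = spatial * measure
    else:  # quotient variant: divide by the measure instead
        expo = spatial / np.maximum(measure, 1e-6)
    return np.exp(-expo)


def compute_weight_map(
    slice_2d: np.ndarray, params: DenoiseParams, tau: Optional[float] = None
) -> WeightMap:
    """MI-based weight map ``w_j = exp(-(V_j/tau)^rho * M_j)`` for a slice.

    ``tau`` is normally the ``tau_percentile`` point of the whole volume's
    intensity distribution; when denoising a single slice it defaults to
    the slice's own percentile.  Raises if ``tau`` is not positive (e.g.
    an all-zero volume).
    """
    sl = np.asarray(slice_2d, dtype=np.float64)
    if tau is None:
        tau = float(np.percentile(sl, params.tau_percentile))
    if tau <= 0:
        raise ValueError("tau must be > 0; is the volume all zero?")
    from dataclasses import replace

    p = params if params.weight_mode == "mi" else replace(params, weight_mode="mi")
    measure = _measure_map(sl, p)
    return WeightMap(values=_compose_weights(sl, measure, tau, params), measure=measure)


def nlm_weight_map(
    slice_2d: np.ndarray, params: DenoiseParams, tau: Optional[float] = None
) -> WeightMap:
    """Conventional-NLTV baseline: the measure is a normalized Gaussian
    patch-distance similarity, composed with the same spatial factor."""
    sl = np.asarray(slice_2d, dtype=np.float64)
    if tau is None:
        tau = float(np.percentile(sl, params.tau_percentile))
    if tau <= 0:
        raise ValueError("tau must be > 0; is the volume all zero?")
    from dataclasses import replace

    p = params if params.weight_mode == "nlm" else replace(params, weight_mode="nlm")
    measure = _measure_map(sl, p)
    return WeightMap(values=_compose_weights(sl, measure, tau, params), measure=measure)


# ---------------------------------------------------------------------------
# weighted TV objective and its gradient
# ---------------------------------------------------------------------------

def _diffs(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Backward differences with reflective boundary (zero on first row/col)."""
    dr = np.zeros_like(v)
    dc = np.zeros_like(v)
    dr[1:, :] = v[1:, :] - v[:-1, :]
    dc[:, 1:] = v[:, 1:] - v[:, :-1]
    return dr, dc


def _eps_for(v: np.ndarray, params: DenoiseParams) -> float:
    if params.eps is not None:
        return params.eps
    rng = float(np.max(v) - np.min(v))
    return 1e-8 * (rng if rng > 0 else 1.0)


def tv_objective(v: np.ndarray, w: np.ndarray, eps: float) -> float:
    """``R = sum_j w_j sqrt(dr^2 + dc^2 + eps^2)`` with backward differences."""
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if v.shape != w.shape:
        raise ValueError("slice and weight map shapes differ")
    dr, dc = _diffs(v)
    return float(np.sum(w * np.sqrt(dr * dr + dc * dc + eps * eps)))


def tv_gradient(
    v: np.ndarray, w: np.ndarray, eps: float
) -> Tuple[np.ndarray, float]:
    """Analytic gradient of :func:`tv_objective` and its Euclidean norm.

    Three terms: the pixel's own smoothed-TV term plus the coupling through
    its right and lower neighbours' backward differences.
    """
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if v.shape != w.shape:
        raise ValueError("slice and weight map shapes differ")
    dr, dc = _diffs(v)
    d = np.sqrt(dr * dr + dc * dc + eps * eps)
    grad = w * (dr + dc) / d
    # coupling through the (r+1, c) term, where this pixel appears as -dr
    t = w * dr / d
    grad[:-1, :] -= t[1:, :]
    # coupling through the (r, c+1) term, where this pixel appears as -dc
    t = w * dc / d
    grad[:, :-1] -= t[:, 1:]
    norm = float(np.sqrt(np.sum(grad * grad)))
    return grad, norm


# ---------------------------------------------------------------------------
# descent
# ---------------------------------------------------------------------------

def _denoise_slice(
    sl: np.ndarray, params: DenoiseParams, tau: float
) -> Tuple[np.ndarray, DescentState, WeightMap]:
    eps = _eps_for(sl, params)
    step_scale = (
        params.step_scale if params.step_scale is not None else 0.5 / np.sqrt(sl.size)
    )
    weight_fn = compute_weight_map if params.weight_mode == "mi" else nlm_weight_map
    wm = weight_fn(sl, params, tau=tau)
    v = np.array(sl, dtype=np.float64)
    gamma = params.gamma0
    r_prev = tv_objective(v, wm.values, eps)
    state = DescentState(
        t=0, gamma=gamma, lam=0.0, r_history=[r_prev], accepted=[],
        gamma_history=[gamma], lambda_history=[],
    )
    for t in range(1, params.iterations + 1):
        if params.recompute_weights_every and t > 1 and (
            (t - 1) % params.recompute_weights_every == 0
        ):
            wm = weight_fn(v, params, tau=tau)
        grad, norm = tv_gradient(v, wm.values, eps)
        if norm < 1e-300:
            state.t = t
            break
        lam = gamma * np.sqrt(np.sum(v * v)) * step_scale
        v_new = v - lam * grad / norm
        r_new = tv_objective(v_new, wm.values, eps)
        increased = r_new > r_prev
        if increased:
            gamma *= params.r_red
        if increased and params.reject_on_increase:
            state.accepted.append(False)
            state.r_history.append(r_prev)
        else:
            v = v_new
            state.accepted.append(True)
            state.r_history.append(r_new)
            r_prev = r_new
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite values during descent at iteration {t}"
            )
        state.t = t
        state.gamma = gamma
        state.lam = lam
        state.gamma_history.append(gamma)
        state.lambda_history.append(lam)
    return v, state, wm


def denoise(
    vol: Volume, params: DenoiseParams | None = None
) -> Tuple[Volume, List[DescentState]]:
    """Denoise a mu-domain volume slice by slice.

    ``tau`` is computed once from the whole volume's intensity distribution
    (negative reconstruction values are clamped to zero for the spatial
    factor only).  Each axial slice runs an independent adaptive steepest
    descent; the per-slice :class:`DescentState` list carries the objective
    history for logging and diagnostics.
    """
    if params is None:
        params = DenoiseParams()
    if vol.unit != "mu_mm^-1":
        raise ValueError(
            f"denoising operates on mu_mm^-1 volumes, got {vol.unit}; "
            "convert before/after with recon.hu_to_mu/mu_to_hu"
        )
    tau = float(np.percentile(np.maximum(vol.data, 0.0), params.tau_percentile))
    if tau <= 0:
        raise ValueError("tau percentile of the volume is not positive")
    out = np.empty_like(vol.data, dtype=np.float64)
    states: List[DescentState] = []
    for iz in range(vol.data.shape[0]):
        try:
            out[iz], state, _ = _denoise_slice(vol.data[iz], params, tau)
        except FloatingPointError as exc:
            raise FloatingPointError(f"slice {iz}: {exc}") from exc
        states.append(state)
        log.debug(
            "denoise slice %d: R %0.6g -> %0.6g, gamma %.3g",
            iz, state.r_history[0], state.r_history[-1], state.gamma,
        )
    result = Volume(data=out, spacing=vol.spacing, origin=vol.origin, unit=vol.unit)
    return result, states
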