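"""The border-ownership cost functional and its analytic gradient.

The total cost of a BO map ``b`` given an image is a weighted sum of six
components, each evaluated on the angle/space-smoothed map ``c`` (and in
fact only on its square ``e = c**2``, which makes the functional blind to
the sign of b):

* edge alignment   (weight ``alpha_a``): rewards BO perpendicular to image
  edges, ``-(1/T) * sum(A**2 * e)`` where ``A`` is the oriented odd-filter
  edge response and ``T`` the number of map entries;
* saturation       (``alpha_r``): ``(1/T) * sum(e**2)`` — a quartic brake
  that keeps the quadratic edge-alignment reward from growing without
  bound;
* vacancy          (``alpha_v``): ``(1/T) * sum(eps_v/(A**2+eps_v) * e)``
  — penalizes ownership where the image has no edge (this is what makes
  illusory boundaries expensive, hence rare);
* opposition       (``alpha_n``): penalizes simultaneous ownership in
  near-opposite directions — an object lies on only one side of its
  boundary;
* continuity       (``alpha_c``): penalizes object edges that end without
  another edge originating from the ending point (an occluding edge
  counts as an origin);
* bending          (``alpha_e``): penalizes boundary turns, concave turns
  (away from the owned side) ``kappa_concave`` times more than convex
  ones.

All spatial filters can be evaluated at ``n_scales`` dyadic-like scales
(widths multiplied by ``mu**n``) and averaged, and the whole functional is
additionally relaxed by a scalar ``s`` that widens the BO smoothing, the
spatial filters and the soft-ramp via affine multipliers — the coarse-to
fine schedule of the optimizer.

``CostEngine`` precomputes every kernel and image-dependent field for a
fixed (image, params, s) and then evaluates cost and gradient cheaply;
the module-level functions expose the individual components for direct
use and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate, correlate1d
from scipy.signal import fftconvolve
from scipy.special import ndtr

from .bo_core import DirectionSet, smooth_bo

__all__ = [
    "ModelParams",
    "ScaleMultipliers",
    "edge_responses",
    "edge_alignment_cost",
    "saturation_cost",
    "vacancy_cost",
    "opposition_cost",
    "smoothed_ramp",
    "continuity_cost",
    "bending_cost",
    "multiscale",
    "total_cost",
    "total_gradient",
    "CostEngine",
]


@dataclass(frozen=True)
class ModelParams:
    """All functional weights and filter widths.

    Widths are in pixels (``sigma_sa`` in direction-index units); weights
    are dimensionless.  The shipped ``defaults.yaml`` carries the single
    frozen parameter set used for every experiment.
    """

    alpha_a: float = 25.0
    alpha_r: float = 1.0
    alpha_v: float = 0.25
    alpha_n: float = 4.0
    alpha_c: float = 5.0
    alpha_e: float = 0.5
    sigma_a: float = 1.0
    eps_v: float = 0.01
    sigma_n: float = 1.0
    sigma_sa: float = 0.5
    sigma_sx: float = 0.5
    sigma_rp: float = 0.03
    n_scales: int = 2
    mu: float = 1.4142135623730951
    lam_c: float = 3.0
    lobe_across: float = 0.8
    delta_c: float = 0.0
    kappa_concave: float = 3.0
    kappa_smax: float = 200.0
    L: int = 12

    def __post_init__(self) -> None:
        for name in ("sigma_a", "sigma_n", "sigma_sa", "sigma_sx", "sigma_rp",
                     "lam_c", "lobe_across", "eps_v", "mu", "kappa_smax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_a", "alpha_r", "alpha_v", "alpha_n", "alpha_c", "alpha_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mu <= 1:
            raise ValueError("mu must be > 1")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.kappa_concave <= 1:
            raise ValueError("kappa_concave must be > 1")
        DirectionSet(self.L)  # validates divisibility by 4


@dataclass(frozen=True)
class ScaleMultipliers:
    """Affine coefficients mapping the relaxation scale s to filter widths.

    BO-smoothing width is multiplied by ``sb0 + sbs*s``, all spatial filter
    widths by ``sx0 + sxs*s`` and the soft-ramp width by ``sr0 + srs*s``.
    """

    sb0: float = 1.0
    sbs: float = 2.0
    sx0: float = 1.0
    sxs: float = 1.0
    sr0: float = 1.0
    srs: float = 0.5

    def bo(self, s: float) -> float:
        return self.sb0 + self.sbs * s

    def spatial(self, s: float) -> float:
        return self.sx0 + self.sxs * s

    def ramp(self, s: float) -> float:
        return self.sr0 + self.srs * s


# ---------------------------------------------------------------------------
# kernels


def _edge_filter(l: int, L: int, sigma: float) -> np.ndarray:
    """Oriented odd edge filter: Gaussian times a dead-zoned sign of the
    coordinate along direction l.  Kernel indexed [dy, dx], truncated at
    radius ceil(3*sigma)."""
    r = int(np.ceil(3.0 * sigma))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    a = 2.0 * np.pi * l / L
    ux, uy = np.cos(a), -np.sin(a)  # array coords: row index grows downward
    x_along = dx * ux + dy * uy
    sgn = np.sign(x_along)
    sgn[np.abs(x_along) <= 0.001] = 0.0
    return sgn * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)


def _lobe_kernel(d: int, L: int, lam: float, across: float) -> np.ndarray:
    """One-sided grouping lobe along direction index d.

    A half-Gaussian of length scale ``lam`` along +u_d, width ``across``
    across it; pixels strictly behind the origin (and the origin itself)
    are excluded.  Normalized to unit sum, so lobe grouping of a field is
    a weighted average over the pixels ahead.
    """
    r = int(np.ceil(2.0 * lam)) + 1
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    a = 2.0 * np.pi * d / L
    ux, uy = np.cos(a), -np.sin(a)
    along = dx * ux + dy * uy
    perp = -dx * uy + dy * ux
    w = np.exp(-(along**2) / (2.0 * lam**2) - perp**2 / (2.0 * across**2))
    w[along < 0.4] = 0.0
    return w / w.sum()


def _gauss1d_analytic(sigma: float) -> np.ndarray:
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    return np.exp(-(x**2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)


def _batch_correlate(fields: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Channel-wise 2-D cross-correlation with zero padding.

    ``fields``: (B, H, W); ``kernels``: (B, kh, kw) with odd kh, kw.
    Implemented as FFT convolution with flipped kernels.
    """
    return fftconvolve(fields, kernels[:, ::-1, ::-1], mode="same", axes=(1, 2))


class _FFTCorr:
    """Batched zero-padded cross-correlation with a fixed kernel stack.

    Caches the kernel spectra for a given field shape, and can reuse a
    precomputed field spectrum so several kernel stacks share one forward
    transform.  Equivalent to :func:`_batch_correlate` to round-off.
    """

    def __init__(self, kernels: np.ndarray):
        self.kernels = kernels
        self.kh, self.kw = kernels.shape[1:]
        self._cache: dict = {}

    def _spec(self, shape):
        from scipy.fft import next_fast_len

        if shape not in self._cache:
            H, W = shape
            fh = next_fast_len(H + self.kh - 1)
            fw = next_fast_len(W + self.kw - 1)
            khat = np.fft.rfft2(self.kernels[:, ::-1, ::-1], s=(fh, fw))
            self._cache[shape] = (fh, fw, khat)
        return self._cache[shape]

    def field_fft(self, fields: np.ndarray):
        fh, fw, _ = self._spec(fields.shape[1:])
        return np.fft.rfft2(fields, s=(fh, fw))

    def apply_fft(self, fhat: np.ndarray, shape, idx=slice(None)) -> np.ndarray:
        H, W = shape
        fh, fw, khat = self._spec(shape)
        full = np.fft.irfft2(fhat * khat[idx], s=(fh, fw))
        ry, rx = (self.kh - 1) // 2, (self.kw - 1) // 2
        return np.ascontiguousarray(full[:, ry : ry + H, rx : rx + W])

    def apply(self, fields: np.ndarray) -> np.ndarray:
        return self.apply_fft(self.field_fft(fields), fields.shape[1:])


def _stack_kernels(kernels: list[np.ndarray], pad_to: int = 1) -> np.ndarray:
    """Zero-pad kernels to a common odd support and stack along axis 0."""
    kh = max(pad_to, *(k.shape[0] for k in kernels))
    kw = max(pad_to, *(k.shape[1] for k in kernels))
    out = np.zeros((len(kernels), kh, kw))
    for i, k in enumerate(kernels):
        oy, ox = (kh - k.shape[0]) // 2, (kw - k.shape[1]) // 2
        out[i, oy : oy + k.shape[0], ox : ox + k.shape[1]] = k
    return out


# ---------------------------------------------------------------------------
# public component functions


def edge_responses(image: np.ndarray, sigma_a: float, L: int = 12) -> np.ndarray:
    """Oriented edge-response tensor A[y, x, l].

    Cross-correlation of the image with the odd filter bank; replicate
    padding avoids a spurious edge at the canvas frame.  The filter is odd
    along u_l, so A[..., l] == -A[..., l + L/2].
    """
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    image = np.asarray(image, dtype=float)
    out = np.empty(image.shape + (L,))
    for l in range(L):
        out[..., l] = correlate(image, _edge_filter(l, L, sigma_a), mode="nearest")
    return out


def edge_alignment_cost(c: np.ndarray, A: np.ndarray) -> float:
    """Reward (negative cost) for squared BO coinciding with squared edge response."""
    if c.shape != A.shape:
        raise ValueError("BO map and edge responses must have identical shape")
    return float(-np.mean(A**2 * c**2))


def saturation_cost(c: np.ndarray) -> float:
    """Quartic penalty limiting the BO magnitude."""
    return float(np.mean(c**4))


def vacancy_cost(c: np.ndarray, A: np.ndarray, eps_v: float) -> float:
    """Penalty for ownership at sites with no image edge."""
    if c.shape != A.shape:
        raise ValueError("BO map and edge responses must have identical shape")
    return float(np.mean(eps_v / (A**2 + eps_v) * c**2))


def _opposition_weights(L: int) -> tuple[np.ndarray, float]:
    q = L // 4
    m = np.arange(-(q - 1), q)
    w = np.cos(2.0 * np.pi * m / L) ** 2
    return m, float(w.sum())


def opposition_cost(c: np.ndarray, sigma_n: float, scale_factor: float = 1.0) -> float:
    """Penalty for near-opposite ownership: squared BO is spatially blurred,
    then ownership at direction l is paired with directions l + L/2 + m for
    |m| < L/4, weighted by cos^2 of the deviation angle."""
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    L = c.shape[2]
    e = (c**2).transpose(2, 0, 1)
    k = _gauss1d_analytic(sigma_n * scale_factor)
    B = correlate1d(correlate1d(e, k, axis=1, mode="constant"), k, axis=2, mode="constant")
    ms, tn = _opposition_weights(L)
    total = 0.0
    for m in ms:
        w = np.cos(2.0 * np.pi * m / L) ** 2
        total += w * np.sum(B * np.roll(B, -(L // 2 + m), axis=0))
    return float(total / (c.size * tn))


def smoothed_ramp(x, sigma: float):
    """Gaussian-smoothed ramp: closed form x*Phi(x/sigma) + sigma*phi(x/sigma).

    Tends to r(x) = max(x, 0) far from zero and equals sigma/sqrt(2*pi) at
    x = 0; its derivative is Phi(x/sigma), so it is C^1 everywhere.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    z = x / sigma
    val = x * ndtr(z) + sigma * np.exp(-(z**2) / 2.0) / np.sqrt(2.0 * np.pi)
    return val if val.ndim else float(val)


class _LobeOps:
    """Lobe groupings and the continuity / bending terms at one spatial scale.

    Works in (L, H, W) layout.  For each direction l, the boundary tangent
    is t_l = u_{l - L/4} (the owned side then lies to the left of travel,
    so a left turn of the tangent is convex).  ``fw[l]`` groups squared BO
    of direction l over the lobe ahead along +t_l, ``bk[l]`` over the lobe
    behind; their products across direction pairs realize the logical-and
    of an incoming and an outgoing edge.
    """

    def __init__(self, L: int, lam: float, across: float, kappa_smax: float,
                 kappa_concave: float, pad_to: int = 1):
        self.L, self.q = L, L // 4
        self.kappa_smax = kappa_smax
        self.margin = int(np.ceil(lam)) + 1
        lobes = [_lobe_kernel(d, L, lam, across) for d in range(L)]
        t = [(l - self.q) % L for l in range(L)]
        self.corr_fwd = _FFTCorr(_stack_kernels(
            [lobes[t[l]] for l in range(L)]
            + [lobes[(t[l] + L // 2) % L] for l in range(L)], pad_to))
        # adjoint kernels: transpose of a correlation with lobe d is a
        # correlation with lobe d + L/2 (the spatially flipped lobe); the
        # first block backs d/d(bk), the second d/d(fw)
        self.corr_adj = _FFTCorr(_stack_kernels(
            [lobes[t[l]] for l in range(L)]
            + [lobes[(t[l] + L // 2) % L] for l in range(L)], pad_to
        ))
        # bending weights: signed direction turn delta = l_out - l_in mapped to
        # (-L/2, L/2]; w = (turn/pi)^2, concave (delta < 0) scaled by kappa
        wb = np.zeros((L, L))
        for li in range(L):
            for lo in range(L):
                d = (lo - li) % L
                if d > L // 2:
                    d -= L
                w = (2.0 * abs(d) / L) ** 2
                if d < 0 or d == L // 2:  # U-turn treated as concave
                    w *= kappa_concave
                wb[li, lo] = w
        self.wb = wb
        # allowed outgoing directions for the continuity origin search:
        # everything except the back cone (within 45 deg of the reverse of
        # the ending direction)
        half = L // 2
        self.half = half
        self.smax_offsets = [r for r in range(L)
                             if min((r - half) % L, (half - r) % L) > L // 12]
        ls = np.arange(L)
        self.idx_pq = (ls + self.q) % L
        self.idx_mq = (ls - self.q) % L
        self._smax_idx = np.array([(ls + r) % L for r in self.smax_offsets])
        self._z_src = np.array([(ls - r) % L for r in self.smax_offsets])
        # occluder channels considered for an ending in direction theta:
        # through-going edges whose OWNERSHIP faces the continuation region
        # (the occluding object must cover where the ending edge would
        # continue, i.e. u_c . u_theta > 0) -> channels within +-60 deg
        self._occ_offsets = [o for o in range(-(L // 4 - 1), L // 4)
                             ]  # cos(2 pi o / L) > 0
        ls = np.arange(L)
        self._occ_idx = np.array([(ls + o) % L for o in self._occ_offsets])

    def fw_bk(self, e: np.ndarray, ehat=None) -> tuple[np.ndarray, np.ndarray]:
        shape = e.shape[1:]
        if ehat is None:
            ehat = self.corr_fwd.field_fft(e)
        out = self.corr_fwd.apply_fft(np.concatenate([ehat, ehat], axis=0), shape)
        return out[: self.L], out[self.L :]

    def adjoint(self, dbk: np.ndarray, dfw: np.ndarray) -> np.ndarray:
        """de from accumulated lobe-field gradients:
        de_l = corr_{t(l)}(dbk_l) + corr_{t(l)+L/2}(dfw_l)."""
        out = self.corr_adj.apply(np.concatenate([dbk, dfw], axis=0))
        return out[: self.L] + out[self.L :]

    def _soft_max_stack(self, st):
        k = self.kappa_smax
        mx = st.max(axis=0)
        ex = np.exp(k * (st - mx))
        sex = ex.sum(axis=0)
        return mx + np.log(sex / st.shape[0]) / k, ex / sex

    def origin_search(self, fw: np.ndarray, bk: np.ndarray):
        """Soft-max origin strengths (E_left, E_right) per ending direction.

        Two kinds of origin can continue an ending edge:

        * a consistent continuation — an edge leaving along phi whose owned
          side matches the ending edge's.  An ending whose travel keeps the
          owned region on its LEFT continues through the channel with
          tangent +u_phi (``C_L[phi] = fw[phi + L/4]``); a right-handed
          ending uses the mirrored channel (``C_R[phi] = bk[phi - L/4]``).
          The back cone around the reversed ending direction is excluded;
        * an occluder — a through-going edge crossing the ending point
          (lobe mass on both sides along its own tangent: soft minimum of
          the channel's forward and backward groupings) whose ownership
          faces the continuation region, so the occluding object actually
          covers where the ending edge would continue.

        Returns (E_L, E_R, cache) with the softmax/softmin weights needed
        for the adjoint.  The ownership constraint on continuations rules
        out patchwork states whose walls are owned by different regions
        (head-on junctions no longer count as continuous); the ownership
        constraint on occluders keeps an object's own far-side boundary
        from excusing a dangling end it cannot possibly hide.
        """
        k = self.kappa_smax
        C_L = fw[self.idx_pq]
        C_R = bk[self.idx_mq]
        mn = np.minimum(fw, bk)
        e0 = np.exp(-k * (fw - mn))
        e1 = np.exp(-k * (bk - mn))
        W = mn - np.log((e0 + e1) / 2.0) / k
        wpart = W[self._occ_idx]
        E_L, sw_L = self._soft_max_stack(
            np.concatenate([C_L[self._smax_idx], wpart], axis=0))
        E_R, sw_R = self._soft_max_stack(
            np.concatenate([C_R[self._smax_idx], wpart], axis=0))
        wmin = np.stack([e0 / (e0 + e1), e1 / (e0 + e1)])
        return E_L, E_R, (sw_L, sw_R, wmin)

    def origin_adjoint(self, Q_L: np.ndarray, Q_R: np.ndarray, cache):
        """Pull dF/dE_L and dF/dE_R back to (dfw, dbk)."""
        sw_L, sw_R, wmin = cache
        n9 = len(self.smax_offsets)
        dC_L = np.zeros_like(Q_L)
        dC_R = np.zeros_like(Q_R)
        for i, r in enumerate(self.smax_offsets):
            dC_L += np.roll(Q_L * sw_L[i], r, axis=0)
            dC_R += np.roll(Q_R * sw_R[i], r, axis=0)
        dW = np.zeros_like(Q_L)
        for j, o in enumerate(self._occ_offsets):
            dW += np.roll(Q_L * sw_L[n9 + j] + Q_R * sw_R[n9 + j], o, axis=0)
        dfw = dC_L[self.idx_mq] + dW * wmin[0]
        dbk = dC_R[self.idx_pq] + dW * wmin[1]
        return dfw, dbk

    def interior_mask(self, shape) -> np.ndarray:
        """1 on sites farther than the lobe reach from the canvas border.

        Ending terms are only summed here: a boundary that runs into the
        canvas frame is cut by the field of view, not ending in the scene,
        so it is not flagged as discontinuous.
        """
        H, W = shape
        m = min(self.margin, max((min(H, W) - 2) // 2, 0))
        mask = np.zeros((H, W))
        mask[m : H - m, m : W - m] = 1.0
        return mask


def continuity_cost(c: np.ndarray, params: ModelParams, scale_factor: float = 1.0,
                    sigma_rp: float | None = None) -> float:
    """Continuity penalty: smoothed-ramp deficit between the strength of an
    edge ending at a site and the strongest edge originating from it.

    The no-ending baseline ``ramp(-E)`` is subtracted per term, so sites
    without an ending edge contribute exactly zero however much origin
    mass surrounds them — the term reacts only to endings whose
    continuation is missing.
    """
    L = c.shape[2]
    ops = _LobeOps(L, params.lam_c * scale_factor, params.lobe_across * scale_factor,
                   params.kappa_smax, params.kappa_concave)
    e = (c**2).transpose(2, 0, 1)
    fw, bk = ops.fw_bk(e)
    E_L, E_R, _ = ops.origin_search(fw, bk)
    sr = params.sigma_rp if sigma_rp is None else sigma_rp
    el = E_L[ops.idx_mq]
    er = E_R[ops.idx_pq]
    dz = params.delta_c
    mask = ops.interior_mask(c.shape[:2])
    total = np.sum(mask * (smoothed_ramp(bk - el - dz, sr) + smoothed_ramp(fw - er - dz, sr)
                           - smoothed_ramp(-el - dz, sr) - smoothed_ramp(-er - dz, sr)))
    return float(total / c.size)


def bending_cost(c: np.ndarray, params: ModelParams, scale_factor: float = 1.0) -> float:
    """Bending penalty: product of incoming and outgoing lobe groupings,
    weighted by squared turn angle, concave turns kappa_concave times more."""
    L = c.shape[2]
    ops = _LobeOps(L, params.lam_c * scale_factor, params.lobe_across * scale_factor,
                   params.kappa_smax, params.kappa_concave)
    e = (c**2).transpose(2, 0, 1)
    fw, bk = ops.fw_bk(e)
    M = np.tensordot(ops.wb, fw, axes=([1], [0]))
    return float(np.sum(bk * M) / c.size)


def multiscale(component_fn, n_scales: int, mu: float) -> float:
    """Average of a cost component over n_scales spatial scales mu**n."""
    return float(np.mean([component_fn(mu**n) for n in range(n_scales)]))


# ---------------------------------------------------------------------------
# the engine


class CostEngine:
    """Total cost and gradient for a fixed image, parameter set and scale s.

    Precomputes the oriented edge responses, vacancy weights and all
    kernels at each of the ``n_scales`` filter scales; ``cost`` and
    ``cost_and_grad`` then run in a few batched convolutions.  The
    gradient is fully analytic: every component is a smooth function of
    e = c**2 with c the smoothed map, so dF/db = S(2c * dF/de) with S the
    (self-adjoint) smoothing operator.
    """

    def __init__(self, image: np.ndarray, params: ModelParams, s: float = 0.0,
                 multipliers: ScaleMultipliers | None = None):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("image must be 2-D gray-scale")
        mult = multipliers or ScaleMultipliers()
        self.image = image
        self.params = params
        self.s = float(s)
        self.L = params.L
        self.q = params.L // 4
        self.shape = image.shape + (params.L,)
        self.T = image.size * params.L
        self.sigma_sx_eff = params.sigma_sx * mult.bo(s)
        self.sigma_rp_eff = params.sigma_rp * mult.ramp(s)
        m_x = mult.spatial(s)
        self._ms, self._tn = _opposition_weights(params.L)
        L = params.L
        ls = np.arange(L)
        self._opp_idx = np.array([(ls + L // 2 + m) % L for m in self._ms])
        self._opp_w = np.cos(2.0 * np.pi * self._ms / L) ** 2
        # pad all lobe kernels to the largest support so every scale shares
        # one padded FFT shape (the squared-map spectrum is computed once)
        facs = [params.mu**n * m_x for n in range(params.n_scales)]
        lam_max = params.lam_c * max(facs)
        pad_to = 2 * (int(np.ceil(2.0 * lam_max)) + 1) + 1
        self._scales = []
        for fac in facs:
            A = edge_responses(image, params.sigma_a * fac, params.L).transpose(2, 0, 1)
            a2 = A**2
            self._scales.append({
                "fac": fac,
                "a2": a2,
                "wv": params.eps_v / (a2 + params.eps_v),
                "kn": _gauss1d_analytic(params.sigma_n * fac),
                "ops": _LobeOps(params.L, params.lam_c * fac,
                                params.lobe_across * fac,
                                params.kappa_smax, params.kappa_concave,
                                pad_to=pad_to),
            })

    # -- plumbing -----------------------------------------------------------

    def smooth(self, b: np.ndarray) -> np.ndarray:
        return smooth_bo(b, self.params.sigma_sa, self.sigma_sx_eff)

    def _check(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if b.shape != self.shape:
            raise ValueError(f"BO map shape {b.shape} != expected {self.shape}")
        return b

    # -- evaluation ---------------------------------------------------------

    def _evaluate(self, b: np.ndarray, want_grad: bool):
        p = self.params
        L, q, T = self.L, self.q, self.T
        c = self.smooth(self._check(b))
        e = (c**2).transpose(2, 0, 1)
        de = np.zeros_like(e) if want_grad else None
        comps = {"align": 0.0, "saturation": 0.0, "vacancy": 0.0,
                 "opposition": 0.0, "continuity": 0.0, "bending": 0.0}

        # saturation has no spatial filter: identical at every scale
        comps["saturation"] = float(np.sum(e**2) / T)
        if want_grad:
            de += p.alpha_r * 2.0 * e / T

        nsc = p.n_scales
        ehat = self._scales[0]["ops"].corr_fwd.field_fft(e)
        for sc in self._scales:
            comps["align"] += float(-np.sum(sc["a2"] * e) / T) / nsc
            comps["vacancy"] += float(np.sum(sc["wv"] * e) / T) / nsc
            if want_grad:
                de += (p.alpha_v * sc["wv"] - p.alpha_a * sc["a2"]) / (nsc * T)

            # opposition
            kn = sc["kn"]
            B = correlate1d(correlate1d(e, kn, axis=1, mode="constant"),
                            kn, axis=2, mode="constant")
            fn = 0.0
            dB = np.zeros_like(B) if want_grad else None
            for w, oi in zip(self._opp_w, self._opp_idx):
                paired = B[oi]
                fn += w * np.sum(B * paired)
                if want_grad:
                    dB += 2.0 * w * paired
            comps["opposition"] += fn / (T * self._tn) / nsc
            if want_grad:
                dB *= p.alpha_n / (nsc * T * self._tn)
                de += correlate1d(correlate1d(dB, kn, axis=1, mode="constant"),
                                  kn, axis=2, mode="constant")

            # continuity + bending share the lobe groupings
            ops = sc["ops"]
            fw, bk = ops.fw_bk(e, ehat)
            E_L, E_R, cache = ops.origin_search(fw, bk)
            sr = self.sigma_rp_eff
            el = E_L[ops.idx_mq]   # E_L for the sense-+ ending of channel l
            er = E_R[ops.idx_pq]   # E_R for the sense-- ending of channel l
            dz = p.delta_c         # deficits below the dead zone count as continued
            d_plus = bk - el - dz
            d_minus = fw - er - dz
            mask = ops.interior_mask(e.shape[1:])
            comps["continuity"] += float(
                np.sum(mask * (smoothed_ramp(d_plus, sr) + smoothed_ramp(d_minus, sr)
                               - smoothed_ramp(-el - dz, sr)
                               - smoothed_ramp(-er - dz, sr))) / T
            ) / nsc
            M = np.tensordot(ops.wb, fw, axes=([1], [0]))
            comps["bending"] += float(np.sum(bk * M) / T) / nsc

            if want_grad:
                h_c = p.alpha_c / (nsc * T)
                p_plus = mask * h_c * ndtr(d_plus / sr)
                p_minus = mask * h_c * ndtr(d_minus / sr)
                # each theta backs exactly one (l, sense) term per handedness
                Q_L = (mask * h_c * ndtr((-el - dz) / sr) - p_plus)[ops.idx_pq]
                Q_R = (mask * h_c * ndtr((-er - dz) / sr) - p_minus)[ops.idx_mq]
                dfw_c, dbk_c = ops.origin_adjoint(Q_L, Q_R, cache)
                hE = p.alpha_e / (nsc * T)
                Nf = np.tensordot(ops.wb.T, bk, axes=([1], [0]))
                de += ops.adjoint(p_plus + hE * M + dbk_c,
                                  p_minus + hE * Nf + dfw_c)

        total = (p.alpha_a * comps["align"] + p.alpha_r * comps["saturation"]
                 + p.alpha_v * comps["vacancy"] + p.alpha_n * comps["opposition"]
                 + p.alpha_c * comps["continuity"] + p.alpha_e * comps["bending"])
        if not want_grad:
            return total, comps, None
        grad = self.smooth(2.0 * c * de.transpose(1, 2, 0))
        return total, comps, grad

    def cost(self, b: np.ndarray) -> float:
        return self._evaluate(b, want_grad=False)[0]

    def components(self, b: np.ndarray) -> dict:
        return self._evaluate(b, want_grad=False)[1]

    def cost_and_grad(self, b: np.ndarray) -> tuple[float, np.ndarray]:
        total, _, grad = self._evaluate(b, want_grad=True)
        return total, grad


def total_cost(b: np.ndarray, image: np.ndarray, params: ModelParams, s: float = 0.0,
               multipliers: ScaleMultipliers | None = None) -> float:
    """Weighted multi-scale total cost of a raw BO map at relaxation scale s."""
    return CostEngine(image, params, s, multipliers).cost(b)


def total_gradient(b: np.ndarray, image: np.ndarray, params: ModelParams,
                   s: float = 0.0,
                   multipliers: ScaleMultipliers | None = None) -> np.ndarray:
    """Analytic gradient of the total cost with respect to every b[y, x, l]."""
    return CostEngine(image, params, s, multipliers).cost_and_grad(b)[1]
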