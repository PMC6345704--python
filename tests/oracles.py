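"""Independent brute-force reference implementations used only by tests.

Everything here is written as direct nested-loop summation of the model
formulas, sharing no code with the package internals, so agreement is a
meaningful check of the optimized implementations.
"""

import numpy as np


def naive_angular_kernel(L, sigma_sa):
    js = np.arange(-(L // 2 - 1), L // 2 + 1)
    w = np.exp(-js.astype(float) ** 2 / (2 * sigma_sa**2))
    return js, w / w.sum()


def naive_spatial_kernel(sigma):
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return x.astype(int), k / k.sum()


def naive_smooth(b, sigma_sa, sigma_sx):
    """Direct summation of the angle-then-space smoothing."""
    H, W, L = b.shape
    js, wj = naive_angular_kernel(L, sigma_sa)
    ang = np.zeros_like(b)
    for y in range(H):
        for x in range(W):
            for l in range(L):
                ang[y, x, l] = sum(wj[i] * b[y, x, (l + js[i]) % L]
                                   for i in range(len(js)))
    offs, wk = naive_spatial_kernel(sigma_sx)
    out = np.zeros_like(b)
    for y in range(H):
        for x in range(W):
            acc = np.zeros(L)
            for i, dy in enumerate(offs):
                for j, dx in enumerate(offs):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W:
                        acc += wk[i] * wk[j] * ang[yy, xx]
            out[y, x] = acc
    return out


def naive_edge_filter(l, L, sigma):
    r = int(np.ceil(3.0 * sigma))
    a = 2 * np.pi * l / L
    ux, uy = np.cos(a), -np.sin(a)
    k = np.zeros((2 * r + 1, 2 * r + 1))
    for i, dy in enumerate(range(-r, r + 1)):
        for j, dx in enumerate(range(-r, r + 1)):
            x_al = dx * ux + dy * uy
            s = 0.0 if abs(x_al) <= 0.001 else (1.0 if x_al > 0 else -1.0)
            k[i, j] = s * np.exp(-(dx**2 + dy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    return k


def naive_edge_response_at(image, x, y, l, L, sigma):
    """Direct cross-correlation sum at one site with replicate padding."""
    H, W = image.shape
    r = int(np.ceil(3.0 * sigma))
    k = naive_edge_filter(l, L, sigma)
    acc = 0.0
    for i, dy in enumerate(range(-r, r + 1)):
        for j, dx in enumerate(range(-r, r + 1)):
            yy = min(max(y + dy, 0), H - 1)
            xx = min(max(x + dx, 0), W - 1)
            acc += k[i, j] * image[yy, xx]
    return acc


def naive_opposition(c, sigma_n):
    """Direct summation of the near-opposite-ownership penalty."""
    H, W, L = c.shape
    e = c**2
    r = int(np.ceil(3.0 * sigma_n))
    B = np.zeros_like(e)
    for y in range(H):
        for x in range(W):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W:
                        g = np.exp(-(dx**2 + dy**2) / (2 * sigma_n**2)) / (2 * np.pi * sigma_n**2)
                        B[y, x] += g * e[yy, xx]
    q = L // 4
    tn = sum(np.cos(2 * np.pi * m / L) ** 2 for m in range(-(q - 1), q))
    total = 0.0
    for y in range(H):
        for x in range(W):
            for l in range(L):
                for m in range(-(q - 1), q):
                    w = np.cos(2 * np.pi * m / L) ** 2
                    total += w * B[y, x, l] * B[y, x, (l + L // 2 + m) % L]
    return total / (c.size * tn)


def naive_smoothed_ramp(x, sigma):
    """Numerical convolution of the hard ramp with a Gaussian."""
    from scipy.integrate import quad

    g = lambda t: np.exp(-(t**2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
    lo = -15 * sigma
    if x <= lo:
        return 0.0
    val, _ = quad(lambda t: (x - t) * g(t), lo, x, limit=200)
    return val
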