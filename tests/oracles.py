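"""Independent brute-force oracles used by the test suite.

Everything here is a straight transliteration of the underlying formulas
with explicit Python loops and replicate padding — deliberately slow and
deliberately sharing no code with the package, so that agreement between
the two routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


def conv2d_replicate(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop cross-correlation with replicate padding."""
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    padded = np.pad(plane, ((ry, ry), (rx, rx)), mode="edge")
    h, w = plane.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(kernel * padded[i : i + kh, j : j + kw])
    return out


def gaussian_kernel2d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def _window(padded: np.ndarray, i: int, j: int, r: int) -> np.ndarray:
    return padded[i : i + 2 * r + 1, j : j + 2 * r + 1]


def box_mean_loop(plane: np.ndarray, r: int) -> np.ndarray:
    padded = np.pad(plane, r, mode="edge")
    h, w = plane.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = _window(padded, i, j, r).mean()
    return out


def window_std_loop(g: np.ndarray, r: int) -> np.ndarray:
    padded = np.pad(g, r, mode="edge")
    h, w = g.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = _window(padded, i, j, r).std()
    return out


def edge_aware_weight_loop(g: np.ndarray, zeta1: int, eps: float) -> np.ndarray:
    chi = window_std_loop(g, 1) * window_std_loop(g, zeta1)
    n = chi.size
    out = np.zeros_like(chi)
    flat = chi.ravel()
    for k, ck in enumerate(flat):
        out.ravel()[k] = np.sum((ck + eps) / (flat + eps)) / n
    return out


def gamma_k_loop(chi: np.ndarray) -> np.ndarray:
    mu = chi.mean()
    rng = mu - chi.min()
    if rng == 0:
        return np.full_like(chi, 0.5)
    eta = 4.0 / rng
    out = np.zeros_like(chi)
    for idx, c in np.ndenumerate(chi):
        out[idx] = 1.0 - 1.0 / (1.0 + np.exp(eta * (c - mu)))
    return out


def gdgif_loop(
    p: np.ndarray,
    g: np.ndarray,
    zeta1: int,
    eps: float,
    lam: float,
    reg_form: str = "divide",
) -> np.ndarray:
    """Per-window regularized least squares solved via explicit 2x2 normal
    equations, followed by coefficient averaging."""
    chi = window_std_loop(g, 1) * window_std_loop(g, zeta1)
    big_gamma = edge_aware_weight_loop(g, zeta1, eps)
    gamma = gamma_k_loop(chi)
    reg = lam / big_gamma if reg_form == "divide" else lam * big_gamma

    h, w = p.shape
    r = zeta1
    pp = np.pad(p, r, mode="edge")
    gp = np.pad(g, r, mode="edge")
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gw = _window(gp, i, j, r).ravel()
            pw = _window(pp, i, j, r).ravel()
            lhs = np.array([[np.mean(gw * gw) + reg[i, j], gw.mean()], [gw.mean(), 1.0]])
            rhs = np.array([np.mean(gw * pw) + reg[i, j] * gamma[i, j], pw.mean()])
            a[i, j], b[i, j] = np.linalg.solve(lhs, rhs)
    a_bar = box_mean_loop(a, r)
    b_bar = box_mean_loop(b, r)
    return a_bar * g + b_bar


# --- metric transliterations -------------------------------------------------


def _hist_entropy(vals: np.ndarray) -> float:
    counts = np.zeros(256)
    for v in vals.ravel():
        counts[v] += 1
    p = counts / counts.sum()
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))


def qmi_loop(x: np.ndarray, y: np.ndarray, f: np.ndarray) -> float:
    def q8(p):
        return np.clip(np.round(p * 255.0), 0, 255).astype(int)

    xq, yq, fq = q8(x), q8(y), q8(f)
    total = 0.0
    for src in (xq, yq):
        joint = np.zeros((256, 256))
        for s, t in zip(src.ravel(), fq.ravel()):
            joint[s, t] += 1
        pj = joint / joint.sum()
        ps = pj.sum(axis=1)
        pf = pj.sum(axis=0)
        mi = 0.0
        for s in range(256):
            for t in range(256):
                if pj[s, t] > 0:
                    mi += pj[s, t] * np.log2(pj[s, t] / (ps[s] * pf[t]))
        total += mi / (_hist_entropy(src) + _hist_entropy(fq))
    return 2.0 * total


def _ssim_window(a: np.ndarray, b: np.ndarray) -> float:
    c1, c2 = 0.01**2, 0.03**2
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cab = ((a - ma) * (b - mb)).mean()
    return ((2 * ma * mb + c1) * (2 * cab + c2)) / ((ma**2 + mb**2 + c1) * (va + vb + c2))


def qy_loop(x: np.ndarray, y: np.ndarray, f: np.ndarray, window: int = 7) -> float:
    r = window // 2
    xp = np.pad(x, r, mode="edge")
    yp = np.pad(y, r, mode="edge")
    fp = np.pad(f, r, mode="edge")
    h, w = x.shape
    vals = []
    for i in range(h):
        for j in range(w):
            wx = _window(xp, i, j, r)
            wy = _window(yp, i, j, r)
            wf = _window(fp, i, j, r)
            sx, sy = wx.var(), wy.var()
            sxy = _ssim_window(wx, wy)
            sxf = _ssim_window(wx, wf)
            syf = _ssim_window(wy, wf)
            if sxy >= 0.75:
                lam = sx / (sx + sy) if sx + sy > 0 else 0.5
                vals.append(lam * sxf + (1 - lam) * syf)
            else:
                vals.append(max(sxf, syf))
    return float(np.mean(vals))


_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def _sobel_loop(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = conv2d_replicate(p, _SOBEL_X)
    sy = conv2d_replicate(p, _SOBEL_X.T)
    g = np.sqrt(sx**2 + sy**2)
    alpha = np.zeros_like(p)
    for idx in np.ndindex(p.shape):
        if sx[idx] == 0:
            alpha[idx] = 0.0 if sy[idx] == 0 else np.sign(sy[idx]) * np.pi / 2
        else:
            alpha[idx] = np.arctan(sy[idx] / sx[idx])
    return g, alpha


def qabf_loop(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    gamma_g: float = 0.9994,
    k_g: float = -15.0,
    sigma_g: float = 0.5,
    gamma_a: float = 0.9879,
    k_a: float = -22.0,
    sigma_a: float = 0.8,
) -> float:
    gf, af = _sobel_loop(f)
    num = 0.0
    den = 0.0
    for gs, als in (_sobel_loop(a), _sobel_loop(b)):
        for idx in np.ndindex(f.shape):
            if gs[idx] == 0 or gf[idx] == 0:
                rel = 0.0
            elif gs[idx] > gf[idx]:
                rel = gf[idx] / gs[idx]
            else:
                rel = gs[idx] / gf[idx]
            ori = 1.0 - abs(als[idx] - af[idx]) / (np.pi / 2)
            qg = gamma_g / (1.0 + np.exp(k_g * (rel - sigma_g)))
            qa = gamma_a / (1.0 + np.exp(k_a * (ori - sigma_a)))
            num += qg * qa * gs[idx]
            den += gs[idx]
    return num / den
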