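"""Robust LOESS and tensor-voting curve completion.

These are the two smoothing primitives of the boundary pipeline: RLOESS
(local quadratic regression with tricube distance weights and bisquare
robustness reweighting) cleans each across-B-scan depth series, and a
stick-tensor voting pass turns sparse per-column anchors into a continuous
trace, or regularizes an already dense one.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["rloess", "rloess_batch", "tensor_vote_interpolate"]


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def rloess_batch(
    y: np.ndarray,
    span: float = 0.1,
    degree: int = 2,
    iterations: int = 5,
    min_points: int = 9,
) -> np.ndarray:
    """Robust LOESS smoothing of many equally sampled series at once.

    Parameters
    ----------
    y
        ``(n_series, n_x)`` array; NaN entries are treated as missing and
        are filled by the local fit.
    span
        Fraction of the series length used in each local fit (window size
        is at least ``max(min_points, degree + 2)`` points).
    degree
        Local polynomial degree (2 = the classical quadratic LOESS fit).
    iterations
        Bisquare robustness reweighting passes after the initial fit.
        Residual scale is ``6 * median(|r|)`` per series.

    Returns
    -------
    ``(n_series, n_x)`` array of smoothed values; a series with fewer than
    ``degree + 1`` valid points comes back all-NaN (the caller decides how
    to fill it, e.g. from neighbouring series).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return rloess_batch(y[None, :], span, degree, iterations, min_points)[0]
    n_series, n_x = y.shape
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = min(n_x, max(int(np.ceil(span * n_x)), min_points, degree + 2))

    valid = np.isfinite(y)
    y0 = np.where(valid, y, 0.0)
    robust = np.ones_like(y0)

    x = np.arange(n_x, dtype=float)
    # contiguous nearest-k windows on a uniform grid
    starts = np.clip(np.arange(n_x) - (k - 1) // 2, 0, n_x - k)
    offsets = np.arange(k)
    win = starts[:, None] + offsets[None, :]  # (n_x, k) data indices per eval point
    dx = x[win] - x[:, None]  # (n_x, k)
    h = np.maximum(np.abs(dx).max(axis=1, keepdims=True), 1.0)
    w_dist = _tricube(dx / h)  # (n_x, k)
    # design matrix per eval point: powers of dx
    design = dx[:, :, None] ** np.arange(degree + 1)[None, None, :]  # (n_x, k, d+1)

    enough = valid.sum(axis=1) >= degree + 1
    fitted = np.full_like(y0, np.nan)

    for it in range(iterations + 1):
        w = w_dist[None, :, :] * valid[:, win] * robust[:, win]  # (n_series, n_x, k)
        yw = y0[:, win]  # (n_series, n_x, k)
        # weighted normal equations, batched over (series, eval point)
        A = np.einsum("sek,eka,ekb->seab", w, design, design)
        b = np.einsum("sek,eka,sek->sea", w, design, yw)
        # regularize rank-deficient local systems (e.g. all weight on one point)
        A = A + 1e-10 * np.eye(degree + 1)[None, None, :, :]
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        fitted = beta[..., 0]  # value at the eval point (dx = 0)
        # a window needs at least degree+1 usable points for a local fit
        usable = (w > 1e-8).sum(axis=2)
        fitted[usable < degree + 1] = np.nan
        if it == iterations:
            break
        resid = np.where(valid, y0 - fitted, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN series
            med = np.nanmedian(np.abs(resid), axis=1, keepdims=True)
        med = np.where(np.isfinite(med), med, 0.0)
        # floor the bisquare scale at numerical-noise level: residuals of an
        # already-exact fit must not trigger random down-weighting, while
        # genuine outliers still land far outside the floored scale
        data_scale = np.maximum(np.abs(y0).max(axis=1, keepdims=True), 1.0)
        scale = np.maximum(6.0 * med, 1e-6 * data_scale)
        r_rel = np.where(np.isfinite(resid), np.abs(resid), 0.0) / scale
        robust = np.clip(1.0 - r_rel**2, 0.0, None) ** 2

    # fill eval points whose window was empty from neighbouring estimates
    holes = ~np.isfinite(fitted)
    if holes.any():
        for s in np.nonzero(holes.any(axis=1))[0]:
            good = np.isfinite(fitted[s])
            if good.sum() >= degree + 1:
                fitted[s, ~good] = np.interp(x[~good], x[good], fitted[s, good])
            else:
                fitted[s] = np.nan
    fitted[~enough] = np.nan
    return fitted


def rloess(y: np.ndarray, span: float = 0.1, degree: int = 2, iterations: int = 5) -> np.ndarray:
    """Robust LOESS smoothing of a single series (see :func:`rloess_batch`)."""
    return rloess_batch(np.asarray(y, dtype=float), span, degree, iterations)


def tensor_vote_interpolate(
    columns: np.ndarray,
    depths: np.ndarray,
    scale: float = 15.0,
    width: int | None = None,
) -> np.ndarray:
    """Complete a sparse set of (column, depth) anchors into a dense trace.

    Each anchor is treated as a stick token whose orientation is estimated
    from its neighbours by a Gaussian-weighted local line fit; the anchor
    then casts a vote ``depth + slope * (c - column)`` to every column ``c``
    with strength decaying as ``exp(-(c - column)^2 / (2 scale^2))``.  A
    column's depth is the strength-weighted mean of the votes it receives.
    Collinear anchors are therefore completed exactly by their line, a
    single anchor yields a constant trace, and anchors at a common depth
    yield that depth everywhere.
    """
    columns = np.asarray(columns, dtype=float).ravel()
    depths = np.asarray(depths, dtype=float).ravel()
    if columns.size == 0:
        raise ValueError("tensor voting needs at least one anchor point")
    if columns.shape != depths.shape:
        raise ValueError("columns and depths must have the same length")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if width is None:
        width = int(np.max(columns)) + 1

    # orientation (slope) per anchor from a Gaussian-weighted local line fit
    dcc = columns[:, None] - columns[None, :]
    w_nb = np.exp(-(dcc**2) / (2.0 * scale**2))
    sw = w_nb.sum(axis=1)
    mx = (w_nb * columns[None, :]).sum(axis=1) / sw
    my = (w_nb * depths[None, :]).sum(axis=1) / sw
    cov = (w_nb * (columns[None, :] - mx[:, None]) * (depths[None, :] - my[:, None])).sum(axis=1)
    var = (w_nb * (columns[None, :] - mx[:, None]) ** 2).sum(axis=1)
    slopes = np.where(var > 1e-12, cov / np.maximum(var, 1e-12), 0.0)

    targets = np.arange(width, dtype=float)
    dct = targets[None, :] - columns[:, None]  # (n_anchor, width)
    votes = depths[:, None] + slopes[:, None] * dct
    strength = np.exp(-(dct**2) / (2.0 * scale**2))
    trace = (strength * votes).sum(axis=0) / strength.sum(axis=0)
    return trace
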