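"""Nonlinear forward-backward (NL) filtering of FRET trajectories.

Edge-preserving denoising in the Chung-Kennedy family: at every frame a bank
of forward (trailing) and backward (leading) running-mean predictors at
geometrically growing window sizes is combined with data-driven weights
proportional to each predictor's recent mean squared prediction error raised
to a negative exponent. Plateaus average down while step edges stay sharp,
because predictors straddling an edge accrue large errors and lose almost
all weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NLFilterParams", "nl_filter"]


@dataclass
class NLFilterParams:
    """Predictor-bank configuration.

    exponent_p   : weight exponent (weights ~ MSE^-p)
    base_window  : smallest running-average window N_FA, frames
    window_factor: geometric factor f between successive window sizes
    n_scales     : number of window sizes N_FA * f^k, k = 0..n_scales-1
    comparison_window: M frames over which prediction errors are scored
    """

    exponent_p: float = 5.0
    base_window: int = 1
    window_factor: float = 2.0
    n_scales: int = 2
    comparison_window: int = 10

    def __post_init__(self) -> None:
        if self.exponent_p <= 0:
            raise ValueError("exponent_p must be > 0")
        if self.base_window < 1:
            raise ValueError("base_window must be >= 1")
        if self.window_factor < 1:
            raise ValueError("window_factor must be >= 1")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.comparison_window < 1:
            raise ValueError("comparison_window must be >= 1")

    @property
    def window_sizes(self) -> list[int]:
        return [
            max(1, int(round(self.base_window * self.window_factor**k)))
            for k in range(self.n_scales)
        ]


def _trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    """mean of x[t-w : t] (strictly past); NaN where unavailable."""
    n = len(x)
    out = np.full(n, np.nan)
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(w, n)
    out[t] = (c[t] - c[t - w]) / w
    return out


def _trailing_sum_sq(err: np.ndarray, m: int) -> np.ndarray:
    """sum of err[t-m+1 : t+1]^2 over the trailing M frames (including t);
    NaN where err has NaNs inside the window."""
    e2 = err * err
    n = len(err)
    out = np.full(n, np.nan)
    c = np.concatenate([[0.0], np.cumsum(np.nan_to_num(e2))])
    bad = np.concatenate([[0.0], np.cumsum(np.isnan(e2).astype(float))])
    t = np.arange(m - 1, n)
    ok = (bad[t + 1] - bad[t + 1 - m]) == 0
    vals = c[t + 1] - c[t + 1 - m]
    out[t[ok]] = vals[ok]
    return out


def nl_filter(series, params: NLFilterParams | None = None) -> np.ndarray:
    """Apply the NL forward-backward filter to a FRET sequence.

    At frame t the forward predictor of window w is the mean of the w
    preceding samples and the backward predictor the mean of the w following
    samples. Each predictor's weight is (sum of squared prediction errors
    over the trailing M frames for forward / leading M frames for backward)
    raised to -p, normalized to sum to 1; predictors with (numerically) zero
    error share the weight evenly. Edge frames where one direction is
    unavailable fall back to the available one; the output length equals the
    input length and is bounded by the input range (convex combination of
    running means).
    """
    params = params or NLFilterParams()
    x = np.asarray(series, dtype=float)
    n = len(x)
    max_w = max(params.window_sizes)
    if n <= 2 * max_w:
        raise ValueError(f"series too short for NL filter (need > {2 * max_w} frames)")
    m = params.comparison_window
    p = params.exponent_p

    preds = []
    errs = []
    for w in params.window_sizes:
        fwd = _trailing_mean(x, w)
        bwd = _trailing_mean(x[::-1], w)[::-1]
        # prediction errors of each predictor at every frame
        fe = x - fwd
        be = x - bwd
        # error scores: trailing window for forward, leading for backward
        fs = _trailing_sum_sq(fe, m)
        bs = _trailing_sum_sq(be[::-1], m)[::-1]
        preds.extend([fwd, bwd])
        errs.extend([fs, bs])
    P = np.vstack(preds)  # (2*n_scales, n)
    S = np.vstack(errs)

    scale = max(float(np.nanvar(x)), 1e-30)
    tiny = 1e-12 * scale * m  # numerically-zero error threshold
    avail = np.isfinite(P) & np.isfinite(S)

    S2 = np.where(avail, S, np.inf)
    zero = S2 <= tiny
    any_zero = zero.any(axis=0)
    # inverse-error weights; clip keeps the power finite (zero-error columns
    # take the exact-predictor branch below anyway)
    w = np.clip(S2, tiny, None) ** (-p)
    w[~avail] = 0.0
    wsum = w.sum(axis=0)
    Pz = np.where(avail, P, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out_w = (w * Pz).sum(axis=0) / wsum
        out_z = np.where(zero, Pz, 0.0).sum(axis=0) / np.maximum(zero.sum(axis=0), 1)
    out = np.where(any_zero, out_z, out_w)

    # frames with no scored predictor (deep edges): average any finite predictor
    none = ~avail.any(axis=0)
    if none.any():
        fin = np.isfinite(P)
        for t in np.flatnonzero(none):
            a = fin[:, t]
            out[t] = P[a, t].mean() if a.any() else x[t]
    return out
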