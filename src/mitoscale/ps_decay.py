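"""Contact-probability decay analysis for mitotic chromosomes.

This module computes the genome-wide average contact probability P(s) as a
function of genomic separation s, balances contact matrices by iterative
correction, takes the log-log derivative of P(s) with LOESS smoothing, and
estimates the three descriptive scales of a rod-shaped mitotic chromosome:

* loop size ``L`` -- the genomic distance at the *peak* of the smoothed
  derivative (average chromatin loop length),
* layer size ``D`` -- the distance at the *sharp drop* (minimum) of the
  derivative, the amount of DNA packed in one radial layer of loops,
* loops per layer ``n = D / L``.

P(s) is computed by dividing the observed number of interactions at each
log-spaced distance bin by the total possible number of locus pairs at those
separations, then normalizing by the total interaction count so curves from
different sequencing depths are directly comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.signal import fftconvolve
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .genome_io import ContactMatrix, PairList

__all__ = [
    "LogBinScheme",
    "PsCurve",
    "DerivCurve",
    "LoopLayerEstimate",
    "balance",
    "compute_ps",
    "derivative",
    "estimate_loop_size",
    "estimate_layer_size",
    "estimate_loop_layer",
    "loops_per_layer",
    "DEFAULT_SCHEME",
]


@dataclass(frozen=True)
class LogBinScheme:
    """Geometric distance bins: edges s_min * 10**(k / bins_per_decade)."""

    s_min: float = 1_000.0
    s_max: float = 100_000_000.0
    bins_per_decade: int = 8

    def __post_init__(self):
        if self.s_min <= 0 or self.s_max <= self.s_min:
            raise ValueError("require 0 < s_min < s_max")
        if self.bins_per_decade < 1:
            raise ValueError("bins_per_decade must be a positive integer")

    @property
    def edges(self) -> np.ndarray:
        n_dec = math.log10(self.s_max / self.s_min)
        k = math.ceil(round(self.bins_per_decade * n_dec, 9))
        return self.s_min * 10 ** (np.arange(k + 1) / self.bins_per_decade)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def index(self, s) -> np.ndarray:
        """Bin index of separations; -1 for out-of-range."""
        s = np.asarray(s, dtype=float)
        edges = self.edges
        k = np.searchsorted(edges, s, side="right") - 1
        k[(s < edges[0]) | (s >= edges[-1])] = -1
        return k


DEFAULT_SCHEME = LogBinScheme(1_000.0, 100_000_000.0, 8)


@dataclass
class PsCurve:
    """Log-binned contact probability versus genomic distance.

    ``p`` holds P_k = (O_k / N_k) / Z where O_k is the observed interaction
    weight in distance bin k, N_k the number of possible locus pairs at those
    separations, and Z the total observed interactions (depth normalization).
    ``s_eff`` is the possible-pair-weighted mean separation within each bin
    (falling back to the geometric midpoint), the natural abscissa for
    derivatives.  Bins with N_k = 0 are invalid (NaN).
    """

    s_lo: np.ndarray
    s_hi: np.ndarray
    obs: np.ndarray
    n_possible: np.ndarray
    s_eff: np.ndarray = None
    z: float = None
    scheme: LogBinScheme | None = None

    def __post_init__(self):
        self.s_lo = np.asarray(self.s_lo, dtype=float)
        self.s_hi = np.asarray(self.s_hi, dtype=float)
        self.obs = np.asarray(self.obs, dtype=float)
        self.n_possible = np.asarray(self.n_possible, dtype=float)
        if self.s_eff is None:
            self.s_eff = self.s_mid.copy()
        else:
            self.s_eff = np.asarray(self.s_eff, dtype=float)
        bad = ~np.isfinite(self.s_eff)
        self.s_eff[bad] = self.s_mid[bad]
        if self.z is None:
            self.z = float(self.obs.sum())
        if (self.obs[self.valid] < 0).any():
            raise ValueError("observed weights must be non-negative")

    @property
    def s_mid(self) -> np.ndarray:
        return np.sqrt(self.s_lo * self.s_hi)

    @property
    def valid(self) -> np.ndarray:
        return self.n_possible > 0

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(self.valid, self.obs / self.n_possible, np.nan)
            return raw / self.z if self.z > 0 else raw * np.nan

    @classmethod
    def from_values(cls, scheme: LogBinScheme, p_values, s_eff=None) -> "PsCurve":
        """Build a curve directly from P(s) values on a scheme (unit depth)."""
        edges = scheme.edges
        p_values = np.asarray(p_values, dtype=float)
        n = np.where(np.isfinite(p_values), 1.0, 0.0)
        return cls(edges[:-1], edges[1:], np.where(n > 0, p_values, 0.0), n,
                   s_eff=s_eff, z=1.0, scheme=scheme)

    @classmethod
    def from_table(cls, s_lo, s_hi, s_eff, p, obs) -> "PsCurve":
        """Reconstruct a curve from a table written by write_ps_table."""
        p = np.asarray(p, dtype=float)
        n = np.where(np.isfinite(p), 1.0, 0.0)
        return cls(s_lo, s_hi, np.where(n > 0, p, 0.0), n, s_eff=s_eff, z=1.0)


@dataclass
class DerivCurve:
    """Log-log slope of P(s): raw central differences and LOESS smoothing."""

    s: np.ndarray
    slope: np.ndarray
    smoothed: np.ndarray
    span: float

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)


# ---------------------------------------------------------------------------
# Iterative correction (ICE) balancing
# ---------------------------------------------------------------------------

def balance(m: ContactMatrix, n_masked_diagonals: int = 2, tol: float = 1e-5,
            max_iter: int = 200) -> ContactMatrix:
    """Iteratively correct a contact matrix so all bin marginals equalize.

    Each chromosome is balanced independently: counts are repeatedly divided
    by the product of their row/column marginal factors until the variance
    of the scaled nonzero marginals around 1 falls below ``tol``.  The first
    ``n_masked_diagonals`` diagonals (|i - j| < n) are excluded from the
    marginals and dropped from the balanced output, mirroring standard Hi-C
    practice of ignoring the first two diagonals to avoid re-ligation
    artifacts.  Bins with zero marginal are flagged invalid (NaN weight).
    Non-convergence returns a result with ``converged=False`` and a warning.
    """
    if n_masked_diagonals < 0:
        raise ValueError("n_masked_diagonals must be >= 0")
    counts, weights = {}, {}
    converged_all = True
    for chrom in m.binning.chrom_names:
        coo = m.counts[chrom].tocoo()
        keep = (coo.col - coo.row) >= n_masked_diagonals
        i, j, v = coo.row[keep], coo.col[keep], coo.data[keep].astype(float)
        n = coo.shape[0]

        def marginals(entry_vals):
            marg = np.bincount(i, weights=entry_vals, minlength=n).astype(float)
            marg += np.bincount(j, weights=entry_vals, minlength=n)
            diag = i == j
            if diag.any():
                marg -= np.bincount(i[diag], weights=entry_vals[diag], minlength=n)
            return marg

        w = np.ones(n)
        valid = marginals(v) > 0
        w[~valid] = 0.0
        converged = False
        for _ in range(max_iter):
            b = v * w[i] * w[j]
            marg = marginals(b)
            mean = marg[valid].mean() if valid.any() else 0.0
            if mean == 0:
                converged = True
                break
            s_fac = marg / mean
            var = np.mean((s_fac[valid] - 1.0) ** 2)
            if var < tol:
                converged = True
                break
            w[valid] /= s_fac[valid]
        if not converged:
            converged_all = False
        # scale weights so valid balanced marginals are ~1
        b = v * w[i] * w[j]
        marg = marginals(b)
        mean = marg[valid].mean() if valid.any() else 0.0
        if mean > 0:
            w[valid] /= math.sqrt(mean)
        w[~valid] = np.nan
        counts[chrom] = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
        weights[chrom] = w
    if not converged_all:
        warnings.warn("iterative correction did not converge within max_iter",
                      RuntimeWarning, stacklevel=2)
    return ContactMatrix(m.binning, counts, weights=weights,
                         n_masked_diagonals=n_masked_diagonals,
                         converged=converged_all, trans_pairs=m.trans_pairs)


# ---------------------------------------------------------------------------
# P(s)
# ---------------------------------------------------------------------------

def compute_ps(data, scheme: LogBinScheme | None = None,
               use_weights="auto", chroms=None) -> PsCurve:
    """Genome-wide average contact probability decay curve.

    In matrix mode, O_k sums (optionally balanced) counts whose bin
    separation ``s = (j - i) * bin_width`` falls in distance bin k, and N_k
    counts the matrix element pairs at those separations (restricted to
    valid bins when weights are applied); masked diagonals are excluded.
    In pair mode (a :class:`PairList`), O_k is a histogram of bp separations
    and N_k the bp-resolution count of possible pairs,
    ``sum_c sum_{s in bin} (len_c - s)``, evaluated in closed form.
    Chromosomes are pooled (O and N summed) before dividing, and the curve
    is normalized by the total interaction count Z.
    """
    scheme = scheme or DEFAULT_SCHEME
    if isinstance(data, PairList):
        return _compute_ps_pairs(data, scheme)
    return _compute_ps_matrix(data, scheme, use_weights, chroms)


def _compute_ps_matrix(m: ContactMatrix, scheme, use_weights, chroms) -> PsCurve:
    if use_weights == "auto":
        use_weights = m.balanced
    if use_weights and not m.balanced:
        raise ValueError("use_weights=True requires a balanced matrix")
    bw = m.binning.bin_width
    K = scheme.n_bins
    edges = scheme.edges
    O = np.zeros(K)
    N = np.zeros(K)
    S = np.zeros(K)
    any_in_range = False
    chrom_list = chroms or m.binning.chrom_names
    d_lo = max(m.n_masked_diagonals, 1)
    for chrom in chrom_list:
        n = m.binning.n_bins(chrom)
        coo = m.counts[chrom].tocoo()
        d = coo.col - coo.row
        s = d.astype(float) * bw
        k = scheme.index(s)
        sel = (d >= d_lo) & (k >= 0)
        if use_weights:
            w = m.weights[chrom]
            wv = np.where(np.isfinite(w), w, 0.0)
            vals = coo.data[sel] * wv[coo.row[sel]] * wv[coo.col[sel]]
            valid_bins = np.isfinite(w).astype(float)
        else:
            vals = coo.data[sel].astype(float)
            valid_bins = np.ones(n)
        if sel.any():
            O += np.bincount(k[sel], weights=vals, minlength=K)[:K]
        d_all = np.arange(d_lo, n)
        if len(d_all) == 0:
            continue
        s_all = d_all.astype(float) * bw
        k_all = scheme.index(s_all)
        inr = k_all >= 0
        if not inr.any():
            continue
        any_in_range = True
        if use_weights:
            conv = fftconvolve(valid_bins, valid_bins[::-1])
            pairs_d = np.rint(conv[n - 1 + d_all]).clip(min=0)
        else:
            pairs_d = (n - d_all).astype(float)
        N += np.bincount(k_all[inr], weights=pairs_d[inr], minlength=K)[:K]
        S += np.bincount(k_all[inr], weights=pairs_d[inr] * s_all[inr], minlength=K)[:K]
    if not any_in_range:
        warnings.warn("log-bin scheme lies outside the data's distance range",
                      RuntimeWarning, stacklevel=3)
    with np.errstate(invalid="ignore"):
        s_eff = np.where(N > 0, S / np.maximum(N, 1e-300), np.nan)
    return PsCurve(edges[:-1], edges[1:], O, N, s_eff=s_eff, scheme=scheme)


def _compute_ps_pairs(pairs: PairList, scheme) -> PsCurve:
    if pairs.chromsizes is None:
        raise ValueError("pair-level P(s) requires chromosome sizes on the PairList")
    K = scheme.n_bins
    edges = scheme.edges
    s = pairs.separations().astype(float)
    k = scheme.index(s)
    sel = (k >= 0) & (s > 0)
    O = np.bincount(k[sel], weights=np.ones(sel.sum()), minlength=K)[:K]
    N = np.zeros(K)
    S = np.zeros(K)
    for chrom, length in pairs.chromsizes.items():
        # closed-form sum over integer separations a <= s < b of (len - s)
        a = np.ceil(np.maximum(edges[:-1], 1.0)).astype(np.int64)
        b = np.ceil(np.minimum(edges[1:], length + 1.0)).astype(np.int64)
        b = np.maximum(b, a)
        cnt = (b - a).astype(float)
        sum_s = (b * (b - 1) - a * (a - 1)) / 2.0
        N += cnt * length - sum_s
        sum_s2 = ((b - 1) * b * (2 * b - 1) - (a - 1) * a * (2 * a - 1)) / 6.0
        S += sum_s * length - sum_s2
    with np.errstate(invalid="ignore"):
        s_eff = np.where(N > 0, S / np.maximum(N, 1e-300), np.nan)
    if not (N > 0).any():
        warnings.warn("log-bin scheme lies outside the data's distance range",
                      RuntimeWarning, stacklevel=3)
    return PsCurve(edges[:-1], edges[1:], O, N, s_eff=s_eff, scheme=scheme)


# ---------------------------------------------------------------------------
# Derivative
# ---------------------------------------------------------------------------

def derivative(p: PsCurve, loess_span: float = 0.3) -> DerivCurve:
    """Log-log slope of P(s) with LOESS smoothing.

    The raw slope is the central difference of log10 P versus log10 s over
    consecutive valid bins (exact for power laws); the smoothed slope is a
    locally weighted linear regression (tricube weights, degree 1) of the
    raw slope over log10 s with window fraction ``loess_span``.
    """
    ok = p.valid & np.isfinite(p.p) & (p.p > 0)
    if ok.sum() < 3:
        raise ValueError(f"derivative requires >= 3 valid P(s) bins, got {int(ok.sum())}")
    x = np.log10(p.s_eff[ok])
    y = np.log10(p.p[ok])
    slope = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    x_mid = x[1:-1]
    if not 0 < loess_span <= 1:
        raise ValueError("loess_span must be in (0, 1]")
    if len(slope) >= 4:
        smoothed = _lowess(slope, x_mid, frac=loess_span, it=0, return_sorted=False)
    else:
        smoothed = slope.copy()
    return DerivCurve(10 ** x_mid, slope, smoothed, loess_span)


# ---------------------------------------------------------------------------
# Loop / layer estimators
# ---------------------------------------------------------------------------

@dataclass
class LoopLayerEstimate:
    """Loop size L, layer size D (bp), and detection diagnostics."""

    loop_size: float | None = None
    layer_size: float | None = None
    peak_slope: float = np.nan
    drop_slope: float = np.nan
    loop_flat: bool = False
    loop_at_boundary: bool = False
    layer_at_boundary: bool = False

    @property
    def n_loops_per_layer(self) -> float:
        return loops_per_layer(self)


def _refine_extremum(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Parabolic sub-grid refinement of an interior extremum at index k."""
    if k == 0 or k == len(x) - 1:
        return x[k]
    x0, x1, x2 = x[k - 1], x[k], x[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    # fit on a local uniform-ish coordinate; use true x via quadratic through 3 pts
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return x1
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0 or not np.isfinite(a):
        return x1
    xv = -b / (2 * a)
    if not (min(x0, x2) <= xv <= max(x0, x2)) or not np.isfinite(xv):
        return x1
    return xv


def _window(d: DerivCurve, lo: float, hi: float):
    sel = np.flatnonzero((d.s >= lo) & (d.s <= hi) & np.isfinite(d.smoothed))
    if len(sel) == 0:
        raise ValueError(f"no valid derivative points in window [{lo:g}, {hi:g}] bp")
    return sel


def estimate_loop_size(d: DerivCurve, search_lo: float = 10_000.0,
                       search_hi: float = 1_000_000.0,
                       flat_eps: float = 0.02) -> LoopLayerEstimate:
    """Average loop size: s at the peak of the smoothed derivative.

    The argmax of the smoothed slope within [search_lo, search_hi] is
    refined with a 3-point parabola in log10 s; ties break toward smaller s.
    ``loop_flat`` is set when (max - median) of the windowed slope falls
    below ``flat_eps`` (a flattened peak makes the point estimate coarse, as
    when loop sizes are broadly dispersed).
    """
    sel = _window(d, search_lo, search_hi)
    y = d.smoothed[sel]
    x = np.log10(d.s[sel])
    k = int(np.argmax(y))  # first occurrence -> smaller s on ties
    at_boundary = k in (0, len(sel) - 1)
    kk = sel[k]
    if not at_boundary and kk not in (0, len(d.s) - 1):
        xv = _refine_extremum(np.log10(d.s), d.smoothed, kk)
    else:
        xv = x[k]
    flat = (np.max(y) - np.median(y)) < flat_eps
    return LoopLayerEstimate(loop_size=float(10 ** xv), peak_slope=float(y[k]),
                             loop_flat=bool(flat), loop_at_boundary=at_boundary)


def estimate_layer_size(d: DerivCurve, search_lo: float = 1_000_000.0,
                        search_hi: float = 100_000_000.0) -> LoopLayerEstimate:
    """Layer size: s at the sharp drop (minimum) of the smoothed derivative.

    The point of steepest log-log decay within [search_lo, search_hi] marks
    the inter-layer falloff.  A minimum at the window boundary is flagged
    unreliable (``layer_at_boundary``), as for a monotone single power law.
    """
    sel = _window(d, search_lo, search_hi)
    y = d.smoothed[sel]
    x = np.log10(d.s[sel])
    k = int(np.argmin(y))
    at_boundary = k in (0, len(sel) - 1)
    kk = sel[k]
    if not at_boundary and kk not in (0, len(d.s) - 1):
        xv = _refine_extremum(np.log10(d.s), d.smoothed, kk)
    else:
        xv = x[k]
    return LoopLayerEstimate(layer_size=float(10 ** xv), drop_slope=float(y[k]),
                             layer_at_boundary=at_boundary)


def estimate_loop_layer(d: DerivCurve, loop_window=(10_000.0, 1_000_000.0),
                        layer_window=(1_000_000.0, 100_000_000.0),
                        flat_eps: float = 0.02) -> LoopLayerEstimate:
    """Joint loop- and layer-size estimate from one derivative curve."""
    lo = estimate_loop_size(d, *loop_window, flat_eps=flat_eps)
    la = estimate_layer_size(d, *layer_window)
    return LoopLayerEstimate(
        loop_size=lo.loop_size, layer_size=la.layer_size,
        peak_slope=lo.peak_slope, drop_slope=la.drop_slope,
        loop_flat=lo.loop_flat, loop_at_boundary=lo.loop_at_boundary,
        layer_at_boundary=la.layer_at_boundary,
    )


def loops_per_layer(e: LoopLayerEstimate) -> float:
    """Number of loops per radial layer, n = D / L."""
    if e.loop_size is None or e.layer_size is None:
        raise ValueError("both loop_size and layer_size must be detected")
    if e.loop_size <= 0:
        raise ValueError("loop_size must be positive")
    return e.layer_size / e.loop_size
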