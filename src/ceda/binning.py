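"""Possibly-gapped histograms and contingency tables.

Every downstream computation in this package — conditional-entropy
associations, response-manifold localities — reads continuous features
through a data-driven categorization.  The device used here is the
*possibly-gapped histogram*: bins of unequal width chosen so that the
piecewise-linear interpolant of the empirical CDF through the bin edges
stays within a tolerance of the ECDF itself, with wide empty stretches of
the support recorded explicitly as *gaps*.

The construction is deterministic: (1) gap detection — a spacing between
consecutive distinct values is a gap when it exceeds
``max(gap_factor, log2(#distinct values)) x median spacing``; the log
floor matters because under a continuous density the largest of n
spacings is routinely ``~log2(n)`` times the median, so a fixed multiple
alone would flag routine sampling fluctuations as gaps; (2) within each
gap-free cluster, recursive maximum-deviation bisection of the ECDF
(Ramer–Douglas–Peucker) down to tolerance ``tol``, with consecutive
clusters bridged by a single bin edge at the gap midpoint; (3) a
refinement pass inserting additional edges until the ECDF approximation
error (measured on the observed support) is within ``tol`` everywhere.
Features with at most ``discrete_max`` distinct values short-circuit to
one bin per value (edges at midpoints), the natural categorization of an
effectively discrete measurement.  The bins tile the whole support, so
new values can always be assigned to a nearest bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GappedHistogram",
    "ContingencyTable",
    "build_gapped_histogram",
    "assign_bins",
    "contingency_table",
]


@dataclass(frozen=True)
class GappedHistogram:
    """Ordered bins over one continuous feature, with explicit empty gaps.

    Bins are half-open ``[e_i, e_{i+1})`` except the last, which is closed.
    Each gap is an open interval strictly inside the support that contains
    no training datum; a single bin edge sits inside every gap, so the bin
    layout remains a partition of ``[edges[0], edges[-1]]``.
    """

    feature_name: str
    edges: np.ndarray
    gaps: tuple[tuple[float, float], ...]
    counts: np.ndarray
    n_total: int

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "edges": [float(e) for e in self.edges],
            "gaps": [[float(a), float(b)] for a, b in self.gaps],
            "counts": [int(c) for c in self.counts],
            "n_total": int(self.n_total),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GappedHistogram":
        return cls(
            feature_name=d["feature_name"],
            edges=np.asarray(d["edges"], dtype=float),
            gaps=tuple((float(a), float(b)) for a, b in d["gaps"]),
            counts=np.asarray(d["counts"], dtype=int),
            n_total=int(d["n_total"]),
        )


@dataclass(frozen=True)
class ContingencyTable:
    """R x C count matrix framed by two categorized axes."""

    row_levels: tuple
    col_levels: tuple
    counts: np.ndarray
    n_total: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "n_total", int(self.counts.sum()))

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.col_levels, self.row_levels, self.counts.T)


def _validate_values(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values are not allowed")
    return x


def _ecdf(sorted_values: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Right-continuous ECDF: fraction of the sample <= each query point."""
    return np.searchsorted(sorted_values, at, side="right") / len(sorted_values)


def _ecdf_mid(sorted_values: np.ndarray, at: np.ndarray) -> np.ndarray:
    """ECDF with the jump-midpoint convention: at an atom the value is the
    midpoint of the jump, elsewhere it coincides with the ECDF.  This is
    the natural target for a continuous piecewise-linear approximant — a
    step of mass m can never be tracked closer than m/2 by any continuous
    function, while its midpoint can be hit exactly."""
    lo = np.searchsorted(sorted_values, at, side="left")
    hi = np.searchsorted(sorted_values, at, side="right")
    return (lo + hi) / (2.0 * len(sorted_values))


def _rdp_breakpoints(u: np.ndarray, f: np.ndarray, tol: float) -> list[int]:
    """Indices of a piecewise-linear approximation of (u, f) within tol.

    Classic recursive maximum-deviation bisection: keep the chord unless
    some interior point deviates vertically by more than ``tol``, in which
    case split at the worst offender.
    """
    keep = {0, len(u) - 1}
    stack = [(0, len(u) - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        interp = f[lo] + (f[hi] - f[lo]) * (u[lo + 1:hi] - u[lo]) / (u[hi] - u[lo])
        dev = np.abs(interp - f[lo + 1:hi])
        imax = int(np.argmax(dev))
        if dev[imax] > tol:
            mid = lo + 1 + imax
            keep.add(mid)
            stack.append((lo, mid))
            stack.append((mid, hi))
    return sorted(keep)


def build_gapped_histogram(
    values,
    tol: float = 0.02,
    gap_factor: float = 3.0,
    feature_name: str = "",
    method: str = "gapped",
    n_bins: int = 10,
    discrete_max: int = 12,
) -> GappedHistogram:
    """Categorize one continuous feature into a possibly-gapped histogram.

    Parameters
    ----------
    values
        At least two finite real observations.
    tol
        Maximum vertical deviation allowed between the piecewise-linear
        ECDF interpolant through the bin edges and the ECDF itself
        (a fraction of the sample).
    gap_factor
        A spacing between consecutive distinct values wider than
        ``max(gap_factor, log2(#distinct)) x (median positive spacing)``
        is declared a gap.
    method
        ``"gapped"`` (default), or the fallbacks ``"uniform"`` /
        ``"equal_frequency"`` with ``n_bins`` bins and no gap detection.
    discrete_max
        With at most this many distinct values the feature is treated as
        discrete: one bin per value, edges at midpoints.
    """
    x = _validate_values(values)
    if x.size < 2:
        raise ValueError("need at least 2 values to build a histogram")
    if not (0.0 < tol < 1.0):
        raise ValueError("tol must be in (0, 1)")
    if gap_factor <= 0:
        raise ValueError("gap_factor must be positive")

    xs = np.sort(x)
    uniq = np.unique(xs)
    if uniq.size == 1:
        v = float(uniq[0])
        half = max(0.5, abs(v) * 1e-9)
        edges = np.array([v - half, v + half])
        return GappedHistogram(feature_name, edges, (), np.array([x.size]), x.size)

    if method == "uniform":
        edges = np.linspace(uniq[0], uniq[-1], n_bins + 1)
    elif method == "equal_frequency":
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.unique(np.quantile(xs, qs))
    elif method == "gapped":
        edges = None
    else:
        raise ValueError(f"unknown binning method: {method!r}")

    gaps: list[tuple[float, float]] = []
    if method == "gapped":
        spacings = np.diff(uniq)
        med = float(np.median(spacings))
        width = max(gap_factor, np.log2(uniq.size)) * med
        gap_mask = spacings > width
        gaps = [(float(uniq[i]), float(uniq[i + 1])) for i in np.flatnonzero(gap_mask)]

        if uniq.size <= discrete_max:
            # effectively discrete: every observed value gets its own bin;
            # edges at both the values and the midpoints make the PL
            # interpolant hit each jump midpoint exactly
            mids = 0.5 * (uniq[:-1] + uniq[1:])
            edges = np.unique(np.concatenate([uniq, mids]))
        else:
            # per-cluster RDP segmentation, clusters bridged at gap midpoints
            clusters = np.split(uniq, np.flatnonzero(gap_mask) + 1)
            pieces: list[np.ndarray] = []
            for ci, cu in enumerate(clusters):
                bps = cu[_rdp_breakpoints(cu, _ecdf_mid(xs, cu), tol)] if cu.size >= 2 else cu
                left = bps[0] if ci == 0 else 0.5 * (clusters[ci - 1][-1] + cu[0])
                pieces.append(np.concatenate([[left], bps[1:-1]]))
            edges = np.concatenate(pieces + [[uniq[-1]]])

            # refinement: guarantee the ECDF approximation error <= tol
            f_all = _ecdf_mid(xs, uniq)
            for _ in range(uniq.size):
                interp = np.interp(uniq, edges, _ecdf_mid(xs, edges))
                dev = np.abs(interp - f_all)
                imax = int(np.argmax(dev))
                if dev[imax] <= tol + 1e-12:
                    break
                edges = np.sort(np.append(edges, uniq[imax]))

    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(xs, bins=edges)
    return GappedHistogram(feature_name, edges, tuple(gaps), counts, x.size)


def assign_bins(hist: GappedHistogram, values) -> np.ndarray:
    """Map values to bin indices; gap and out-of-support values go to the
    nearest bin by boundary distance (exact gap midpoints break ties toward
    the lower-indexed bin)."""
    v = _validate_values(values)
    edges = hist.edges
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, hist.n_bins - 1)
    for a, b in hist.gaps:
        in_gap = (v > a) & (v < b)
        if not np.any(in_gap):
            continue
        left_bin = int(np.clip(np.searchsorted(edges, a, side="right") - 1, 0, hist.n_bins - 1))
        right_bin = int(np.clip(np.searchsorted(edges, b, side="right") - 1, 0, hist.n_bins - 1))
        go_left = (v[in_gap] - a) <= (b - v[in_gap])
        idx[in_gap] = np.where(go_left, left_bin, right_bin)
    return idx


def contingency_table(row_bins, col_bins) -> ContingencyTable:
    """Cross two categorized vectors into a count table.

    Levels are the sorted distinct values observed on each axis.
    """
    r = np.asarray(row_bins)
    c = np.asarray(col_bins)
    if r.shape != c.shape or r.ndim != 1:
        raise ValueError("row and column categorizations must be 1-D and of equal length")
    if r.size == 0:
        raise ValueError("empty table")
    row_levels, ri = np.unique(r, return_inverse=True)
    col_levels, ci = np.unique(c, return_inverse=True)
    counts = np.zeros((row_levels.size, col_levels.size), dtype=int)
    np.add.at(counts, (ri, ci), 1)
    return ContingencyTable(tuple(row_levels.tolist()), tuple(col_levels.tolist()), counts)


def ecdf_approximation_error(hist: GappedHistogram, values) -> float:
    """Max vertical deviation, over the observed support, between the
    histogram's piecewise-linear ECDF interpolant and the empirical CDF of
    ``values`` (the training sample), with the jump-midpoint convention at
    atoms (see ``_ecdf_mid``)."""
    xs = np.sort(_validate_values(values))
    uniq = np.unique(xs)
    interp = np.interp(uniq, hist.edges, _ecdf_mid(xs, hist.edges))
    return float(np.max(np.abs(interp - _ecdf_mid(xs, uniq))))
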