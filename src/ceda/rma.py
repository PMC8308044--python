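"""Response Manifold Analytics: locality lattices, major/minor factors,
and locality-restricted multivariate prediction.

Multiple response features coupled with a few *major* covariates form a
low-complexity manifold (pitch movement against spin direction and spin
rate is the motivating physical example).  The major covariates' gapped
histograms frame a lattice of rectangular localities on that manifold;
within each locality the response region is simple, while *minor*
factors — covariates whose levels dominate only some localities — carry
the residual heterogeneity.  Prediction then proceeds global-to-local:
find the query's locality, take its k* nearest members in major-covariate
space, filter them by the observed minor level, and average their
response vectors.  Errors are reported both per response and as
covariance-rescaled (Mahalanobis-type) quadratic forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import _entropy_bits
from .binning import GappedHistogram, assign_bins, build_gapped_histogram

__all__ = [
    "Locality",
    "LocalityLattice",
    "RMAQuery",
    "RMAPrediction",
    "locality_lattice",
    "major_factor_score",
    "minor_factor_entropy",
    "minor_factor_profile",
    "rma_predict",
    "correlated_sse",
    "per_response_sse",
]


@dataclass(frozen=True)
class Locality:
    """One hypercube of the major-covariate bin lattice."""

    bin_index: tuple[int, ...]
    member_ids: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class LocalityLattice:
    major_names: tuple[str, ...]
    histograms: tuple[GappedHistogram, ...]
    localities: dict[tuple[int, ...], Locality]
    assignments: np.ndarray  # per training row: index into the bin lattice

    def locate(self, major_values) -> tuple[int, ...]:
        """Bin tuple of a covariate vector (nearest bins in gaps/outside)."""
        vals = np.asarray(major_values, dtype=float).ravel()
        return tuple(int(assign_bins(h, [v])[0]) for h, v in zip(self.histograms, vals))

    def __len__(self) -> int:
        return len(self.localities)


@dataclass(frozen=True)
class RMAQuery:
    major: dict[str, float]
    minor: object | None = None


@dataclass(frozen=True)
class RMAPrediction:
    response: np.ndarray
    locality: tuple[int, ...]
    neighbor_ids: np.ndarray
    minor_filtered: bool
    fallback: bool
    relocated: bool = False


def _capped_histogram(values, name: str, max_bins: int | None, **hist_kwargs) -> GappedHistogram:
    h = build_gapped_histogram(values, feature_name=name, **hist_kwargs)
    if max_bins is not None and h.n_bins > max_bins:
        h = build_gapped_histogram(
            values, feature_name=name, method="equal_frequency", n_bins=max_bins
        )
    return h


def locality_lattice(
    major_histograms: list[GappedHistogram] | dict[str, GappedHistogram] | None,
    table: pd.DataFrame,
    major_names: list[str] | None = None,
    max_bins: int | None = None,
    n_bins: int | None = None,
    **hist_kwargs,
) -> LocalityLattice:
    """Partition training rows into the occupied cross-products of the
    major covariates' bins; every row lands in exactly one locality.

    ``max_bins`` caps each major covariate's gapped histogram
    (equal-frequency fallback); ``n_bins`` instead forces exactly that
    many equal-frequency strips per major covariate, mirroring the strip
    construction on real manifolds where a handful of bins per major
    covariate frames the patch lattice.
    """
    if isinstance(major_histograms, dict):
        major_names = list(major_histograms)
        hists = [major_histograms[n] for n in major_names]
    elif major_histograms is None:
        if not major_names:
            raise ValueError("major_names required when histograms are not given")
        if n_bins is not None:
            hists = [
                build_gapped_histogram(
                    table[n].to_numpy(), feature_name=n, method="equal_frequency", n_bins=n_bins
                )
                for n in major_names
            ]
        else:
            hists = [
                _capped_histogram(table[n].to_numpy(), n, max_bins, **hist_kwargs)
                for n in major_names
            ]
    else:
        hists = list(major_histograms)
        if major_names is None:
            major_names = [h.feature_name for h in hists]
    codes = np.column_stack(
        [assign_bins(h, table[n].to_numpy()) for h, n in zip(hists, major_names)]
    )
    localities: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(codes):
        localities.setdefault(tuple(int(c) for c in row), []).append(i)
    locs = {
        key: Locality(key, np.asarray(ids, dtype=int)) for key, ids in sorted(localities.items())
    }
    return LocalityLattice(tuple(major_names), tuple(hists), locs, codes)


def _joint_response_codes(
    table: pd.DataFrame, response_cols: list[str], max_bins: int = 8
) -> np.ndarray:
    """Joint categorization of the response vector: product of per-response
    equal-frequency binnings with ``max_bins`` bins each — a fixed common
    resolution, so conditional-entropy ratios are comparable across
    candidate covariates."""
    per_col = []
    for col in response_cols:
        v = table[col].to_numpy(dtype=float)
        h = build_gapped_histogram(v, feature_name=col, method="equal_frequency", n_bins=max_bins)
        per_col.append(assign_bins(h, v))
    joint = per_col[0].astype(np.int64)
    for codes in per_col[1:]:
        joint = joint * (int(codes.max()) + 1) + codes
    return joint


def _categorize(
    table: pd.DataFrame, col: str, n_bins: int = 8, **hist_kwargs
) -> np.ndarray:
    """Categorize a covariate column for the factor diagnostics.

    Numeric columns get equal-frequency bins at a common resolution —
    the ECDF-approximation histogram can legitimately collapse a smooth
    covariate to one or two bins, which carries no conditioning power and
    would make candidate scores incomparable.  Categorical columns pass
    through unchanged.
    """
    v = table[col].to_numpy()
    if not np.issubdtype(v.dtype, np.number):
        return v
    h = build_gapped_histogram(
        v.astype(float), feature_name=col, method="equal_frequency", n_bins=n_bins
    )
    return assign_bins(h, v.astype(float))


def _entropy_mm(counts: np.ndarray) -> float:
    """Shannon entropy (bits) with the Miller–Madow small-sample bias
    correction (K-1)/(2N ln 2); the plug-in estimate is biased low exactly
    in the small conditioning cells the major-factor score works with."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    k = np.count_nonzero(counts)
    return _entropy_bits(counts) + (k - 1) / (2.0 * n * np.log(2.0))


def _conditional_entropy(y_codes: np.ndarray, given: np.ndarray) -> float:
    """H(y | given) in bits (Miller–Madow corrected): occupancy-weighted
    entropy over the levels of the conditioning variable."""
    total = len(y_codes)
    h = 0.0
    for lev in np.unique(given):
        mask = given == lev
        _, cnt = np.unique(y_codes[mask], return_counts=True)
        h += (mask.sum() / total) * _entropy_mm(cnt)
    return h


def major_factor_score(
    table: pd.DataFrame,
    candidate: str,
    response_cols: list[str],
    anchor: str | None = None,
    max_response_bins: int = 4,
    max_covariate_bins: int = 8,
    **hist_kwargs,
) -> float:
    """Strip-structure score of a candidate major covariate, in [0, 1].

    Within each bin of the anchor covariate (or the whole sample if no
    anchor), compare the entropy of the jointly binned responses with and
    without conditioning on the candidate's bins:

        score = 1 - mean_a [ H(responses | anchor bin a, candidate bins)
                             / H(responses | anchor bin a) ]

    weighted by anchor-bin occupancy.  A candidate whose bins mark
    clear-cut strips on the response manifold scores near 1; one whose
    points defuse over the manifold scores near 0.  A single-bin candidate
    scores exactly 0.

    The default resolutions (4 equal-frequency bins per response, 8 per
    covariate) keep the doubly-conditioned cells populated at the sample
    sizes this diagnostic is used with; entropies carry a Miller–Madow
    bias correction on top.  Raising the resolutions sharpens the score
    on large samples but biases it upward for irrelevant candidates on
    small ones.
    """
    y = _joint_response_codes(table, response_cols, max_response_bins, **hist_kwargs)
    cand = _categorize(table, candidate, max_covariate_bins, **hist_kwargs)
    if len(np.unique(cand)) < 2:
        return 0.0
    anchor_codes = (
        _categorize(table, anchor, max_covariate_bins, **hist_kwargs)
        if anchor is not None
        else np.zeros(len(y), int)
    )
    total = len(y)
    score_sum = 0.0
    weight_sum = 0.0
    for lev in np.unique(anchor_codes):
        mask = anchor_codes == lev
        w = mask.sum() / total
        _, cnt = np.unique(y[mask], return_counts=True)
        h_base = _entropy_mm(cnt)
        if h_base <= 0.0:
            ratio = 1.0
        else:
            ratio = min(_conditional_entropy(y[mask], cand[mask]) / h_base, 1.0)
        score_sum += w * (1.0 - ratio)
        weight_sum += w
    return float(np.clip(score_sum / weight_sum, 0.0, 1.0))


def minor_factor_entropy(levels_in_locality, levels_global=None) -> tuple[float, float]:
    """Shannon entropy (bits) of a candidate's level distribution within a
    locality, plus the normalized localization score 1 - H_local/H_global
    (0 = no localization, -> 1 = one level dominates the locality)."""
    loc = np.asarray(levels_in_locality)
    _, cnt = np.unique(loc, return_counts=True)
    h_loc = _entropy_bits(cnt)
    if levels_global is None:
        return h_loc, float("nan")
    _, gcnt = np.unique(np.asarray(levels_global), return_counts=True)
    h_glob = _entropy_bits(gcnt)
    score = 1.0 - h_loc / h_glob if h_glob > 0 else 0.0
    return h_loc, float(score)


def minor_factor_profile(
    lattice: LocalityLattice,
    table: pd.DataFrame,
    candidates: list[str],
    flag_threshold: float = 0.5,
    min_locality_count: int = 20,
    **hist_kwargs,
) -> pd.DataFrame:
    """Per-locality entropy profile of candidate minor factors.

    Returns one row per (locality, candidate) with the raw within-locality
    entropy and the normalized localization score; a candidate is flagged
    minor when its maximum score over localities with at least
    ``min_locality_count`` members exceeds ``flag_threshold`` (tiny
    localities give unstable entropy estimates and are profiled but not
    used for flagging).
    """
    levels = {c: _categorize(table, c, **hist_kwargs) for c in candidates}
    rows = []
    for key, loc in lattice.localities.items():
        for cand in candidates:
            h_loc, score = minor_factor_entropy(levels[cand][loc.member_ids], levels[cand])
            rows.append(
                {
                    "locality": key,
                    "n": loc.size,
                    "candidate": cand,
                    "entropy": h_loc,
                    "localization": score,
                }
            )
    prof = pd.DataFrame(rows)
    big = prof[prof["n"] >= min_locality_count]
    flags = big.groupby("candidate")["localization"].max() > flag_threshold
    prof["flagged_minor"] = prof["candidate"].map(flags).fillna(False)
    return prof


def rma_predict(
    query: RMAQuery | dict,
    lattice: LocalityLattice,
    table: pd.DataFrame,
    response_cols: list[str],
    minor_col: str | None = None,
    k_star: int = 20,
) -> RMAPrediction:
    """Locality-restricted, minor-filtered k*-nearest-neighbor prediction
    of a multivariate response.

    The query's locality is found by nearest-bin assignment of its major
    covariates; if that cell holds no training point, the locality of the
    nearest training point in major-covariate space is used (flagged).
    The prediction is the arithmetic mean of the responses of the k*
    nearest locality members, filtered to the query's minor level when
    possible (falling back, flagged, to the unfiltered neighbors if the
    filter empties the set).
    """
    if isinstance(query, dict):
        query = RMAQuery(major=dict(query))
    qvec = np.array([float(query.major[n]) for n in lattice.major_names])
    key = lattice.locate(qvec)
    relocated = False
    if key not in lattice.localities:
        xmaj = table.loc[:, list(lattice.major_names)].to_numpy(dtype=float)
        nearest = int(np.argmin(np.linalg.norm(xmaj - qvec, axis=1)))
        key = tuple(int(c) for c in lattice.assignments[nearest])
        relocated = True
    loc = lattice.localities[key]
    members = loc.member_ids
    xmaj = table.iloc[members][list(lattice.major_names)].to_numpy(dtype=float)
    order = np.argsort(np.linalg.norm(xmaj - qvec, axis=1), kind="stable")
    neighbors = members[order[: min(k_star, len(members))]]

    fallback = False
    used = neighbors
    minor_filtered = False
    if minor_col is not None and query.minor is not None:
        match = table.iloc[neighbors][minor_col].to_numpy() == query.minor
        if match.any():
            used = neighbors[match]
            minor_filtered = True
        else:
            fallback = True
    resp = table.iloc[used][list(response_cols)].to_numpy(dtype=float).mean(axis=0)
    return RMAPrediction(resp, key, used, minor_filtered, fallback, relocated)


def per_response_sse(errors: np.ndarray) -> np.ndarray:
    """Plain sum of squared errors per response coordinate."""
    e = np.atleast_2d(np.asarray(errors, dtype=float))
    return (e**2).sum(axis=0)


def _quadratic_form_sum(errors: np.ndarray, cov: np.ndarray) -> float:
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular response covariance; using pseudo-inverse", stacklevel=3)
        inv = np.linalg.pinv(cov)
    return float(np.einsum("ij,jk,ik->", errors, inv, errors))


def correlated_sse(
    errors,
    responses_train,
    covariance_scope: str = "overall",
    lattice: LocalityLattice | None = None,
    locality_keys: list[tuple[int, ...]] | None = None,
    min_locality_count: int = 10,
) -> float:
    """Covariance-rescaled sum of squared error vectors
    sum_i e_i' Sigma^-1 e_i.

    ``covariance_scope="overall"`` uses the sample covariance (divisor
    n-1) of all training responses; ``"per_locality"`` uses each error's
    locality-specific training covariance, falling back to the overall one
    for localities with fewer than ``min_locality_count`` members.
    """
    e = np.atleast_2d(np.asarray(errors, dtype=float))
    resp = np.atleast_2d(np.asarray(responses_train, dtype=float))
    overall = np.cov(resp, rowvar=False, ddof=1)
    overall = np.atleast_2d(overall)
    if covariance_scope == "overall":
        return _quadratic_form_sum(e, overall)
    if covariance_scope != "per_locality":
        raise ValueError("covariance_scope must be 'overall' or 'per_locality'")
    if lattice is None or locality_keys is None or len(locality_keys) != len(e):
        raise ValueError("per_locality scope needs a lattice and per-error locality keys")
    total = 0.0
    for key in sorted(set(locality_keys)):
        mask = np.array([k == key for k in locality_keys])
        loc = lattice.localities.get(key)
        if loc is not None and loc.size >= min_locality_count:
            cov = np.atleast_2d(np.cov(resp[loc.member_ids], rowvar=False, ddof=1))
        else:
            cov = overall
        total += _quadratic_form_sum(e[mask], cov)
    return float(total)
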