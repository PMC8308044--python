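"""Seeded synthetic data with the structure the toolkit assumes.

Two generators cover the two analysis settings:

* ``generate_clouds`` — labeled Gaussian point-clouds for the multiclass
  setting, including the *engulfed* construction (a small cloud placed
  inside a larger one) that produces the asymmetric mixing geometries the
  set-valued classifier is designed to expose: queries from the engulfed
  label see a mixture while most queries from the host label do not.

* ``generate_manifold`` — a noisy 2-D spiral response manifold in the
  plane, parameterized by an angle covariate (the spin-direction analog)
  with an amplitude modulator (the spin-rate analog), plus independent
  nuisance covariates, a planted categorical *minor* factor whose levels
  dominate declared localities (with response offsets applied there), and
  a uniform categorical nuisance that should never be flagged.

Both emit a ground-truth sidecar naming the planted major and minor
factors, and are bit-reproducible under a fixed seed.  The canonical
150-sample Iris table ships as a checksummed fixture so every worked
example runs without downloads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CloudSpec",
    "ManifoldSpec",
    "generate_clouds",
    "generate_complementary_clouds",
    "generate_manifold",
    "load_iris_fixture",
    "IRIS_SHA256",
]

IRIS_SHA256 = "9cc1c345c71bcc9b486b74cbf6063fa66f4bb5e0f603a4b3c3471ec2e5e8e355"


@dataclass(frozen=True)
class CloudSpec:
    """One labeled Gaussian point-cloud.

    When ``engulfed_by`` names another spec, ``mean`` is interpreted as an
    offset from that cloud's mean, creating the asymmetric-overlap
    geometry (the engulfed cloud lies inside the host's support).
    """

    label: str
    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...] | float
    size: int
    engulfed_by: str | None = None

    def covariance(self, dim: int) -> np.ndarray:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim == 0:
            c = float(c) * np.eye(dim)
        if not np.allclose(c, c.T):
            raise ValueError(f"covariance of {self.label!r} must be symmetric")
        if np.any(np.linalg.eigvalsh(c) < -1e-12):
            raise ValueError(f"covariance of {self.label!r} must be positive semidefinite")
        return c


def generate_clouds(specs: list[CloudSpec], seed: int | None = None) -> pd.DataFrame:
    """Sample the clouds into one labeled feature table (columns f1..fk +
    'label'); per-label sizes are exact and output is seed-reproducible."""
    if not specs:
        raise ValueError("need at least one cloud spec")
    by_label = {s.label: s for s in specs}
    rng = np.random.default_rng(seed)
    dim = len(np.atleast_1d(specs[0].mean))
    frames = []
    for s in specs:
        if s.size < 1:
            raise ValueError(f"cloud {s.label!r} must have size >= 1")
        mean = np.asarray(s.mean, dtype=float)
        if s.engulfed_by is not None:
            host = by_label[s.engulfed_by]
            mean = np.asarray(host.mean, dtype=float) + mean
        pts = rng.multivariate_normal(mean, s.covariance(dim), size=s.size)
        df = pd.DataFrame(pts, columns=[f"f{i+1}" for i in range(dim)])
        df["label"] = s.label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_complementary_clouds(
    n_per: int = 60, seed: int | None = None, spread: float = 0.3, separation: float = 8.0
) -> tuple[pd.DataFrame, dict]:
    """Four labels whose separability is split across two complementary
    feature-groups.

    In group G1 = (f1, f2), labels a and b occupy well-separated
    locations while c and d share one; in group G2 = (f3, f4), c and d
    separate while a sits on c's location and b on d's.  A chain that
    leads with G1 resolves a and b at the first stage and hands only the
    {c, d} ambiguity to G2; leading with G2 leaves every first-stage
    category mixed.  Returns (table, ground_truth) with the group
    memberships recorded in the sidecar.
    """
    rng = np.random.default_rng(seed)
    s = separation
    g1_means = {"a": (0.0, 0.0), "b": (s, 0.0), "c": (s / 2, s * 0.75), "d": (s / 2, s * 0.75)}
    g2_means = {"a": (0.0, 0.0), "b": (s, 0.0), "c": (0.0, 0.0), "d": (s, 0.0)}
    frames = []
    for lab in "abcd":
        pts = np.hstack(
            [
                rng.normal(g1_means[lab], spread, size=(n_per, 2)),
                rng.normal(g2_means[lab], spread, size=(n_per, 2)),
            ]
        )
        df = pd.DataFrame(pts, columns=["f1", "f2", "f3", "f4"])
        df["label"] = lab
        frames.append(df)
    truth = {
        "groups": {"G1": ["f1", "f2"], "G2": ["f3", "f4"]},
        "resolved_by_G1": ["a", "b"],
        "resolved_by_G2": ["c", "d"],
        "planted_order": ["G1", "G2"],
        "seed": seed,
    }
    return pd.concat(frames, ignore_index=True), truth


@dataclass(frozen=True)
class ManifoldSpec:
    """Spiral response manifold Y = A(theta, rho) * (cos theta, sin theta).

    theta (the angle, uniform on ``theta_range``) and the amplitude
    modulator rho (uniform on ``rho_range``) are the planted major
    covariates, with A(theta, rho) = (c0 + c1 * rho) * theta.  Gaussian
    noise of scale ``noise`` is added to both responses.  Each entry of
    ``minor_localities`` maps a (theta_cell, rho_cell) of the
    ``grid x grid`` covariate grid to (dominant minor level, response
    offset): inside such a cell the minor label equals the dominant level
    with probability ``dominance`` and the offset is added to the
    responses of points carrying that level; elsewhere minor levels are
    uniform and offset-free.
    """

    theta_range: tuple[float, float] = (0.6, 4.7)
    rho_range: tuple[float, float] = (0.0, 1.0)
    c0: float = 1.0
    c1: float = 1.5
    noise: float = 0.05
    grid: int = 3
    minor_levels: tuple[str, ...] = ("p1", "p2", "p3")
    minor_localities: dict = field(
        default_factory=lambda: {
            (0, 0): ("p1", (0.3, 0.3)),
            (1, 1): ("p2", (-0.3, 0.3)),
            (2, 2): ("p3", (0.3, -0.3)),
        }
    )
    dominance: float = 0.9
    n_nuisance: int = 1

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not (0 < self.dominance <= 1):
            raise ValueError("dominance must be in (0, 1]")


def _grid_cell(v: np.ndarray, lo: float, hi: float, grid: int) -> np.ndarray:
    return np.clip(((v - lo) / (hi - lo) * grid).astype(int), 0, grid - 1)


def generate_manifold(
    spec: ManifoldSpec | None = None, n: int = 1500, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sample the spiral manifold; returns (table, ground_truth).

    Columns: responses y1, y2; major covariates theta, rho; continuous
    nuisances nuisance1..; categorical minor factor 'minor'; categorical
    uniform nuisance 'nuisance_cat'.
    """
    spec = spec or ManifoldSpec()
    rng = np.random.default_rng(seed)
    theta = rng.uniform(*spec.theta_range, size=n)
    rho = rng.uniform(*spec.rho_range, size=n)
    amp = (spec.c0 + spec.c1 * rho) * theta
    y = amp[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])

    t_cell = _grid_cell(theta, *spec.theta_range, spec.grid)
    r_cell = _grid_cell(rho, *spec.rho_range, spec.grid)
    levels = np.asarray(spec.minor_levels, dtype=object)
    minor = levels[rng.integers(0, len(levels), size=n)]
    for (tc, rc), (dominant, offset) in spec.minor_localities.items():
        in_cell = (t_cell == tc) & (r_cell == rc)
        take = in_cell & (rng.random(n) < spec.dominance)
        minor[take] = dominant
        hit = in_cell & (minor == dominant)
        y[hit] += np.asarray(offset, dtype=float)
    y += rng.normal(0.0, spec.noise, size=y.shape)

    table = pd.DataFrame({"y1": y[:, 0], "y2": y[:, 1], "theta": theta, "rho": rho})
    for i in range(spec.n_nuisance):
        table[f"nuisance{i+1}"] = rng.normal(0.0, 1.0, size=n)
    table["minor"] = minor
    table["nuisance_cat"] = levels[rng.integers(0, len(levels), size=n)]

    ground_truth = {
        "responses": ["y1", "y2"],
        "major": ["theta", "rho"],
        "minor": "minor",
        "nuisance_continuous": [f"nuisance{i+1}" for i in range(spec.n_nuisance)],
        "nuisance_categorical": "nuisance_cat",
        "minor_localities": {
            f"{tc},{rc}": {"level": lev, "offset": list(off)}
            for (tc, rc), (lev, off) in spec.minor_localities.items()
        },
        "amplitude": {"c0": spec.c0, "c1": spec.c1},
        "noise": spec.noise,
        "n": n,
        "seed": seed,
    }
    return table, ground_truth


def load_iris_fixture() -> pd.DataFrame:
    """The canonical 150 x 4 Iris table with a 'species' column, verified
    against a pinned checksum."""
    ref = resources.files("ceda").joinpath("data/iris.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != IRIS_SHA256:
        raise RuntimeError(f"iris fixture checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))
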