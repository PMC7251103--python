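"""Fourier-series descriptors of star-shaped microchannel boundaries.

A closed channel boundary is parameterized by its radius as a function of
polar angle,

    r(theta) = A0/2 + sum_{n=1..N} A_n cos(n theta) + B_n sin(n theta),

which gives a compact 2N+1 coefficient representation of any boundary that
is single-valued in radius about its center (star-shaped).  The series is
periodic in 2*pi, so the reconstructed boundary closes without a seam.

This module evaluates, fits, reconstructs and randomly generates such
shapes; the random generator produces the perturbed-polygon family used to
train the inverse network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FourierShape",
    "PerturbationParams",
    "fourier_radius",
    "fit_fourier",
    "shape_boundary",
    "polygon_radius",
    "random_shape",
    "save_boundary",
    "save_coefficients",
    "load_coefficients",
]

TWO_PI = 2.0 * np.pi

#: default number of uniform theta samples for Fourier analysis; spectrally
#: accurate for smooth radius functions and cheap at this size
DEFAULT_FIT_SAMPLES = 2048


@dataclass(frozen=True)
class FourierShape:
    """Truncated Fourier series of a boundary's radius function.

    Parameters
    ----------
    a0 : float
        Constant term; the mean radius equals ``a0 / 2``.
    a, b : ndarray, shape (N,)
        Cosine and sine coefficients for harmonics ``n = 1..N`` (length
        units).  The total parameter count is ``2 N + 1``.

    Positivity of the reconstructed radius (the star-shape condition) is not
    enforced at construction: network predictions may violate it and are
    still returned, with a warning, so it is checked where it matters
    (boundary export, rasterization) via :meth:`min_radius`.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise ValueError(
                f"cosine/sine coefficient vectors must be 1-D with equal "
                f"length, got shapes {a.shape} and {b.shape}"
            )
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a0", float(self.a0))

    @property
    def n_coeffs(self) -> int:
        """Highest harmonic order N."""
        return self.a.size

    def radius(self, theta):
        return fourier_radius(self, theta)

    def min_radius(self, n_theta: int = 2048) -> float:
        """Minimum reconstructed radius on a dense uniform theta grid."""
        theta = np.linspace(0.0, TWO_PI, n_theta, endpoint=False)
        return float(self.radius(theta).min())

    def is_star_shaped(self, n_theta: int = 2048) -> bool:
        """True if the radius stays strictly positive (valid boundary)."""
        return self.min_radius(n_theta) > 0.0

    def to_vector(self) -> np.ndarray:
        """Pack as ``[A0, A1..AN, B1..BN]`` (the network's target layout)."""
        return np.concatenate([[self.a0], self.a, self.b])

    @classmethod
    def from_vector(cls, vec) -> "FourierShape":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size % 2 == 0:
            raise ValueError(f"coefficient vector length must be odd (2N+1), got {vec.size}")
        n = (vec.size - 1) // 2
        return cls(a0=vec[0], a=vec[1 : n + 1], b=vec[n + 1 :])


def fourier_radius(shape: FourierShape, theta):
    """Evaluate the radius series at ``theta`` (radians, scalar or array)."""
    theta = np.asarray(theta, dtype=float)
    n = np.arange(1, shape.n_coeffs + 1)
    ang = np.multiply.outer(theta, n)
    r = shape.a0 / 2.0 + np.cos(ang) @ shape.a + np.sin(ang) @ shape.b
    return r if r.ndim else float(r)


def fit_fourier(radius_fn, n_coeffs: int, n_samples: int = DEFAULT_FIT_SAMPLES) -> FourierShape:
    """Fit a truncated Fourier series to a positive radius function.

    Parameters
    ----------
    radius_fn : callable or array_like
        Either a vectorized function ``theta -> radius`` evaluated on a
        uniform grid of ``n_samples`` angles in ``[0, 2 pi)``, or the radius
        samples themselves (in which case ``n_samples`` is their length).
    n_coeffs : int
        Highest harmonic order N; the fit has ``2 N + 1`` parameters.
    n_samples : int
        Number of uniform samples M.  Must satisfy ``M >= 4 N + 2`` so the
        analysis integrals are well resolved past the Nyquist margin.

    The analysis integrals ``A_n = (1/pi) int r cos(n t) dt`` (and the sine
    analogue) are computed with the rectangle rule on the periodic grid,
    which for uniform sampling is exactly the DFT and spectrally accurate
    for smooth ``r``.
    """
    if callable(radius_fn):
        theta = np.linspace(0.0, TWO_PI, n_samples, endpoint=False)
        samples = np.asarray(radius_fn(theta), dtype=float)
    else:
        samples = np.asarray(radius_fn, dtype=float).ravel()
        n_samples = samples.size
    n_coeffs = int(n_coeffs)
    if n_coeffs < 1:
        raise ValueError("n_coeffs must be >= 1")
    if n_samples < 4 * n_coeffs + 2:
        raise ValueError(
            f"need at least 4*N+2 = {4 * n_coeffs + 2} samples for N={n_coeffs}, got {n_samples}"
        )
    if not np.all(samples > 0.0):
        raise ValueError("radius samples must be strictly positive")
    spec = np.fft.rfft(samples)
    a0 = 2.0 * spec[0].real / n_samples
    a = 2.0 * spec[1 : n_coeffs + 1].real / n_samples
    b = -2.0 * spec[1 : n_coeffs + 1].imag / n_samples
    return FourierShape(a0=a0, a=a, b=b)


def shape_boundary(shape: FourierShape, n_points: int, closed: bool = True) -> np.ndarray:
    """Reconstruct the boundary polyline ``(x, y) = r(theta) (cos, sin)``.

    Returns an ``(n_points + 1, 2)`` array when ``closed`` (first vertex
    repeated at the end), else ``(n_points, 2)``.  Raises if the
    reconstructed radius is non-positive anywhere on the vertex grid.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    theta = np.linspace(0.0, TWO_PI, n_points, endpoint=False)
    r = fourier_radius(shape, theta)
    if np.any(r <= 0.0):
        raise ValueError("reconstructed radius is non-positive; boundary is not star-shaped")
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if closed:
        xy = np.vstack([xy, xy[:1]])
    return xy


def polygon_radius(n_sides: int, circumradius: float, rotation: float, theta):
    """Exact radius function of a regular polygon centered at the origin.

    ``r(theta) = circumradius * cos(pi/n) / cos(((theta - rotation) mod
    2 pi / n) - pi / n)``; vertices sit in the ``rotation`` direction (and
    every ``2 pi / n`` thereafter), where ``r`` equals the circumradius; the
    minimum equals the inradius ``circumradius * cos(pi / n)``.
    """
    n_sides = int(n_sides)
    if n_sides < 3:
        raise ValueError("a polygon needs at least 3 sides")
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    theta = np.asarray(theta, dtype=float)
    sector = TWO_PI / n_sides
    local = np.mod(theta - rotation, sector) - sector / 2.0
    r = circumradius * np.cos(np.pi / n_sides) / np.cos(local)
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class PerturbationParams:
    """Settings for the random perturbed-polygon shape generator.

    The generator draws a regular polygon (uniform side count, inradius and
    rotation), fits its ``n_coeffs``-order Fourier series, and multiplies
    every coefficient (A0 included) by an independent uniform factor.  A
    draw is accepted only if the perturbed radius stays above ``min_radius``
    everywhere, so the channel always encloses the square design region
    (``min_radius`` defaults to that region's half-diagonal under the
    default simulation geometry: 151 px * 2 um * sqrt(2) / 2).
    """

    n_coeffs: int = 20
    side_range: tuple[int, int] = (3, 8)
    multiplier_range: tuple[float, float] = (0.75, 1.25)
    #: unperturbed polygon inradius, in multiples of min_radius
    inradius_range: tuple[float, float] = (1.1, 1.45)
    min_radius: float = 151 * 2e-6 * np.sqrt(2.0) / 2.0
    max_attempts: int = 1000
    fit_samples: int = DEFAULT_FIT_SAMPLES

    def replace(self, **kw) -> "PerturbationParams":
        return dataclasses.replace(self, **kw)


def random_shape(rng: np.random.Generator, params: PerturbationParams | None = None) -> FourierShape:
    """Draw one random perturbed-polygon shape (rejection-sampled valid).

    Deterministic for a given generator state.  Raises ``RuntimeError``
    after ``params.max_attempts`` consecutive rejections.
    """
    if params is None:
        params = PerturbationParams()
    lo, hi = params.side_range
    mlo, mhi = params.multiplier_range
    ilo, ihi = params.inradius_range
    check_theta = np.linspace(0.0, TWO_PI, params.fit_samples, endpoint=False)
    for _ in range(params.max_attempts):
        n_sides = int(rng.integers(lo, hi + 1))
        inradius = params.min_radius * rng.uniform(ilo, ihi)
        circumradius = inradius / np.cos(np.pi / n_sides)
        rotation = rng.uniform(0.0, TWO_PI)
        base = fit_fourier(
            lambda t: polygon_radius(n_sides, circumradius, rotation, t),
            params.n_coeffs,
            params.fit_samples,
        )
        mult = rng.uniform(mlo, mhi, size=2 * params.n_coeffs + 1)
        shape = FourierShape(
            a0=base.a0 * mult[0],
            a=base.a * mult[1 : params.n_coeffs + 1],
            b=base.b * mult[params.n_coeffs + 1 :],
        )
        if fourier_radius(shape, check_theta).min() >= params.min_radius:
            return shape
    raise RuntimeError(
        f"no valid shape found in {params.max_attempts} attempts; "
        "check perturbation/containment settings"
    )


def save_boundary(shape: FourierShape, path, n_points: int = 360) -> None:
    """Export the closed boundary polyline as CSV with ``x, y`` columns
    (length units), suitable for downstream mask or photomask conversion."""
    xy = shape_boundary(shape, n_points, closed=True)
    pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}).to_csv(path, index=False)


def save_coefficients(shape: FourierShape, path) -> None:
    """Write coefficients as CSV with columns ``index, A, B``.

    Row ``index 0`` carries A0 in the ``A`` column (``B`` empty); rows
    ``1..N`` carry ``A_n, B_n``.
    """
    idx = np.arange(shape.n_coeffs + 1)
    frame = pd.DataFrame(
        {
            "index": idx,
            "A": np.concatenate([[shape.a0], shape.a]),
            "B": np.concatenate([[np.nan], shape.b]),
        }
    )
    frame.to_csv(path, index=False)


def load_coefficients(path) -> FourierShape:
    frame = pd.read_csv(path)
    for col in ("index", "A", "B"):
        if col not in frame.columns:
            raise ValueError(f"coefficient CSV missing column {col!r}")
    frame = frame.sort_values("index").reset_index(drop=True)
    if frame.loc[0, "index"] != 0:
        raise ValueError("coefficient CSV must contain the index-0 row holding A0")
    a0 = float(frame.loc[0, "A"])
    a = frame["A"].to_numpy(dtype=float)[1:]
    b = frame["B"].to_numpy(dtype=float)[1:]
    return FourierShape(a0=a0, a=a, b=np.nan_to_num(b))
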