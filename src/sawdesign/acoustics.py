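"""Forward Huygens–Fresnel simulation of SAW-driven pressure fields.

A travelling surface acoustic wave (SAW) running under a shaped fluid
channel acts as a distributed transducer: every substrate point beneath the
fluid radiates a spherical wavelet into the liquid, while points behind the
channel walls are silenced by total internal reflection.  The time-averaged
pressure amplitude in the channel is the magnitude of the superposition of
all wavelets, which reduces to a 2-D convolution:

* boundary condition  BC(x) = omega * xi0 * exp(-alpha x) * exp(-i k x)
  at fluid pixels (x = in-row distance from the leading channel edge along
  the propagation direction), zero elsewhere;
* spherical wave function  SWF(R) = (R + 1)^-1 * exp(-i omega R / c_f),
  normalized to unity at the substrate/liquid interface (R = 0);
* complex field  P = SWF * BC  (discrete convolution), time-averaged
  amplitude 0.5 * |P|, masked to the fluid domain.

The analytic diffraction-spacing law for a flat wall whose normal makes an
angle ``theta`` with the propagation direction,

    lambda_theta = lambda_l sin(theta) / sin(theta - asin((c_f/c_s) sin theta)),

predicts the period of the pressure-minima lines that form parallel to the
wall and anchors the simulator's physics.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
import yaml

from .shapes import FourierShape

__all__ = [
    "SimConfig",
    "PressureField",
    "FieldSolver",
    "pattern_spacing",
    "wavenumber",
    "saw_boundary_condition",
    "spherical_wave_kernel",
    "rasterize_shape",
    "compute_pressure",
    "design_region",
    "binarize",
    "save_field",
    "load_field",
    "export_png",
]

#: densities used for the default fluid-loading attenuation estimate
RHO_FLUID = 1000.0  # kg/m^3, water
RHO_SUBSTRATE = 4650.0  # kg/m^3, lithium niobate


@dataclass(frozen=True)
class SimConfig:
    """Grid geometry and physical parameters of the SAW/fluid system.

    Defaults model a 128° Y-X lithium niobate device driven at a 40 um SAW
    wavelength under a water-filled channel, discretized at 2 um/pixel on a
    300 x 300 grid (600 x 600 um domain) with a centered 151 x 151 pixel
    design region.

    ``rolloff_unit`` selects the length unit in which the ``+1`` of the
    spherical-wave amplitude factor ``(R + 1)^-1`` is expressed: ``"pixel"``
    (default; rolloff scale = one grid cell) or ``"physical"`` (metres).
    The phase term always uses physical length.
    """

    grid_shape: tuple[int, int] = (300, 300)
    pixel_pitch: float = 2e-6  # m
    saw_wavelength: float = 40e-6  # m
    fluid_sound_speed: float = 1490.0  # m/s (c_f, water)
    substrate_sound_speed: float = 3990.0  # m/s (c_s, LiNbO3 SAW speed)
    displacement_amplitude: float = 1.0  # xi0, arbitrary units
    attenuation: float | None = None  # alpha, 1/m; None -> fluid-loading default
    design_region_size: int = 151  # pixels, odd
    rolloff_unit: str = "pixel"

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape must be positive")
        for name in ("pixel_pitch", "saw_wavelength", "fluid_sound_speed",
                     "substrate_sound_speed", "displacement_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.saw_wavelength < 4 * self.pixel_pitch:
            raise ValueError("saw_wavelength must be >= 4 pixel_pitch to resolve the wave")
        if self.design_region_size > min(rows, cols):
            raise ValueError("design_region_size exceeds the grid")
        if self.design_region_size % 2 == 0:
            raise ValueError("design_region_size must be odd (unique center pixel)")
        if self.rolloff_unit not in ("pixel", "physical"):
            raise ValueError("rolloff_unit must be 'pixel' or 'physical'")
        if self.attenuation is None:
            alpha = RHO_FLUID * self.fluid_sound_speed / (
                RHO_SUBSTRATE * self.substrate_sound_speed * self.saw_wavelength
            )
            object.__setattr__(self, "attenuation", alpha)
        elif self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")

    # --- derived quantities -------------------------------------------------
    @property
    def frequency(self) -> float:
        """Drive frequency f = c_s / lambda_SAW (Hz)."""
        return self.substrate_sound_speed / self.saw_wavelength

    @property
    def angular_frequency(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def saw_wavenumber(self) -> float:
        """Angular wavenumber of the SAW, k = 2 pi / lambda_SAW (rad/m)."""
        return 2.0 * np.pi / self.saw_wavelength

    @property
    def fluid_wavelength(self) -> float:
        """lambda_l = c_f / f (m)."""
        return self.fluid_sound_speed / self.frequency

    @property
    def design_half_diagonal(self) -> float:
        """Half-diagonal of the square design region (m); the minimum channel
        radius that guarantees the region lies inside the fluid."""
        return self.design_region_size * self.pixel_pitch * np.sqrt(2.0) / 2.0

    @property
    def grid_center(self) -> tuple[int, int]:
        """(row, col) pixel index of the design-region center."""
        rows, cols = self.grid_shape
        s = self.design_region_size
        return ((rows - s) // 2 + s // 2, (cols - s) // 2 + s // 2)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_stream) -> "SimConfig":
        d = yaml.safe_load(text_or_stream)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class PressureField:
    """Simulated field: complex precursor, time-averaged amplitude, mask."""

    complex_field: np.ndarray
    amplitude: np.ndarray
    channel_mask: np.ndarray
    config: SimConfig

    def __post_init__(self):
        if not (self.complex_field.shape == self.amplitude.shape == self.channel_mask.shape):
            raise ValueError("field rasters must share one shape")


def wavenumber(wavelength: float, angular: bool = False) -> float:
    """Spatial frequency of a wavelength: cycles/length, or rad/length if
    ``angular`` (e.g. a 0.14 a.u. wavelength -> 7.1 a.u.^-1 cycles)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return (2.0 * np.pi if angular else 1.0) / wavelength


def pattern_spacing(theta: float, lambda_l: float, c_f: float, c_s: float) -> float:
    """Diffractive pattern spacing lambda_theta next to a flat wall.

    ``theta`` in ``(0, pi/2]`` is the wall orientation relative to the SAW,
    measured between the propagation direction and the wall's normal (a wall
    parallel to the propagation direction has ``theta = pi/2``); the spacing
    is measured perpendicular to the wall, the direction the minima lines
    radiate.  Returns ``+inf`` when the refracted-angle argument degenerates
    (no diffractive spacing).
    """
    if not 0.0 < theta <= np.pi / 2.0:
        raise ValueError("theta must lie in (0, pi/2]")
    if lambda_l <= 0 or c_f <= 0 or c_s <= 0:
        raise ValueError("lambda_l, c_f and c_s must be positive")
    s = (c_f / c_s) * np.sin(theta)
    if s > 1.0:
        raise ValueError("(c_f/c_s) sin(theta) > 1: refraction angle undefined")
    denom = np.sin(theta - np.arcsin(s))
    if denom <= 0.0:
        return float("inf")
    return float(lambda_l * np.sin(theta) / denom)


def saw_boundary_condition(channel_mask: np.ndarray, config: SimConfig) -> np.ndarray:
    """Complex source raster BC = omega xi0 exp(-alpha x_d) exp(-i k x) on fluid.

    The travelling-wave phase ``exp(-i k x)`` uses the global coordinate
    ``x = column * pixel_pitch`` along the propagation direction (+x =
    increasing column): the SAW phase accumulates continuously along the
    substrate, so a wall that cuts rows at different columns leaves the
    phase front intact.  The decay distance ``x_d`` is measured per row
    from the leading (leftmost) fluid pixel, because the wave is attenuated
    only where fluid loads the substrate.  Non-fluid pixels are zero, since
    total internal reflection silences sources behind the channel walls.
    """
    mask = np.asarray(channel_mask, dtype=bool)
    if mask.shape != tuple(config.grid_shape):
        raise ValueError(f"mask shape {mask.shape} != config grid {config.grid_shape}")
    rows, cols = mask.shape
    bc = np.zeros(mask.shape, dtype=np.complex128)
    has_fluid = mask.any(axis=1)
    if not has_fluid.any():
        return bc
    first = np.argmax(mask, axis=1)  # leading fluid column per row
    col = np.arange(cols)
    x_global = col * config.pixel_pitch
    x_decay = (col[None, :] - first[:, None]) * config.pixel_pitch
    omega = config.angular_frequency
    k = config.saw_wavenumber
    amp = omega * config.displacement_amplitude
    vals = amp * np.exp(-config.attenuation * x_decay) * np.exp(-1j * k * x_global)[None, :]
    bc[mask & has_fluid[:, None]] = vals[mask & has_fluid[:, None]]
    return bc


def _swf_values(dr: np.ndarray, dc: np.ndarray, config: SimConfig) -> np.ndarray:
    """SWF at pixel offsets (dr, dc): (R_unit + 1)^-1 exp(-i omega R / c_f)."""
    r_pix = np.hypot(dr, dc)
    r_phys = r_pix * config.pixel_pitch
    r_unit = r_pix if config.rolloff_unit == "pixel" else r_phys
    phase = config.angular_frequency * r_phys / config.fluid_sound_speed
    return np.exp(-1j * phase) / (r_unit + 1.0)


def spherical_wave_kernel(config: SimConfig, support_radius: int) -> np.ndarray:
    """Square spherical-wave kernel of side ``2 * support_radius + 1``.

    For the convolution to cover every source–target pair the caller should
    request ``support_radius`` at least the grid diagonal in pixels.  The
    center value is exactly ``1 + 0j``.
    """
    s = int(support_radius)
    off = np.arange(-s, s + 1, dtype=float)
    return _swf_values(off[:, None], off[None, :], config)


class FieldSolver:
    """FFT convolution plan for one config; reusable across many masks.

    The spherical-wave kernel is laid out circularly at an FFT-friendly size
    ``L >= 2 * dim - 1`` per axis, so the circular convolution reproduces the
    exact linear convolution at every grid pixel, and its transform is
    computed once.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        rows, cols = config.grid_shape
        self._lr = sfft.next_fast_len(2 * rows - 1, real=False)
        self._lc = sfft.next_fast_len(2 * cols - 1, real=False)
        dr = np.arange(self._lr, dtype=float)
        dc = np.arange(self._lc, dtype=float)
        dr[dr > self._lr / 2] -= self._lr
        dc[dc > self._lc / 2] -= self._lc
        kernel = _swf_values(dr[:, None], dc[None, :], config)
        self._kernel_fft = sfft.fft2(kernel)

    def convolve(self, source: np.ndarray) -> np.ndarray:
        """Exact linear convolution of ``source`` with the SWF kernel,
        evaluated at the source grid's pixels."""
        rows, cols = self.config.grid_shape
        if source.shape != (rows, cols):
            raise ValueError(f"source shape {source.shape} != grid {(rows, cols)}")
        padded = np.zeros((self._lr, self._lc), dtype=np.complex128)
        padded[:rows, :cols] = source
        out = sfft.ifft2(sfft.fft2(padded) * self._kernel_fft)
        return out[:rows, :cols]


_RASTER_BASIS_CACHE: dict = {}


def _raster_basis(config: SimConfig, n_coeffs: int):
    """Cached per-pixel (rho, cos(n theta), sin(n theta)) for rasterization.

    Amortizes the trigonometry over the many rasterizations performed while
    generating a training corpus under one geometry.
    """
    key = (config.grid_shape, config.grid_center, config.pixel_pitch, n_coeffs)
    hit = _RASTER_BASIS_CACHE.get(key)
    if hit is not None:
        return hit
    rows, cols = config.grid_shape
    cy, cx = config.grid_center
    y = (cy - np.arange(rows)) * config.pixel_pitch
    x = (np.arange(cols) - cx) * config.pixel_pitch
    xx, yy = np.meshgrid(x, y)
    theta = np.arctan2(yy, xx).ravel()
    rho = np.hypot(xx, yy)
    ang = np.multiply.outer(theta, np.arange(1, n_coeffs + 1))
    basis = (rho, np.cos(ang), np.sin(ang))
    if len(_RASTER_BASIS_CACHE) >= 4:  # bound the memory held by cached grids
        _RASTER_BASIS_CACHE.pop(next(iter(_RASTER_BASIS_CACHE)))
    _RASTER_BASIS_CACHE[key] = basis
    return basis


def rasterize_shape(shape: FourierShape, config: SimConfig) -> np.ndarray:
    """Boolean fluid mask: pixel centers strictly inside the boundary.

    The shape is centered on the design-region center; +x is the SAW
    propagation direction (increasing column), row 0 is the top of the grid
    (+y = decreasing row).  Star-shaped boundaries admit the exact test
    ``|p - center| < r(theta_p)``.
    """
    rho, cos_b, sin_b = _raster_basis(config, shape.n_coeffs)
    r = shape.a0 / 2.0 + cos_b @ shape.a + sin_b @ shape.b
    return rho < r.reshape(rho.shape)


def compute_pressure(shape_or_mask, config: SimConfig, solver: FieldSolver | None = None) -> PressureField:
    """Simulate the time-averaged pressure-amplitude field in a channel.

    Accepts either a :class:`FourierShape` (rasterized on the config grid)
    or a boolean fluid mask.  ``solver`` may be passed to reuse a cached FFT
    plan when simulating many shapes under one config.
    """
    if isinstance(shape_or_mask, FourierShape):
        mask = rasterize_shape(shape_or_mask, config)
    else:
        mask = np.asarray(shape_or_mask, dtype=bool)
        if mask.shape != tuple(config.grid_shape):
            raise ValueError(f"mask shape {mask.shape} != config grid {config.grid_shape}")
    if not mask.any():
        raise ValueError("channel mask is empty: no fluid pixels")
    if solver is None:
        solver = FieldSolver(config)
    elif solver.config.grid_shape != config.grid_shape:
        raise ValueError("solver was built for a different grid")
    bc = saw_boundary_condition(mask, config)
    p = solver.convolve(bc)
    p[~mask] = 0.0
    amplitude = 0.5 * np.abs(p)
    amplitude[~mask] = 0.0
    return PressureField(complex_field=p, amplitude=amplitude, channel_mask=mask, config=config)


def design_region(field_or_raster, size: int | None = None) -> np.ndarray:
    """Centered square crop of the design region from a field or raster."""
    if isinstance(field_or_raster, PressureField):
        raster = field_or_raster.amplitude
        size = field_or_raster.config.design_region_size if size is None else size
    else:
        raster = np.asarray(field_or_raster)
        if size is None:
            raise ValueError("size is required when cropping a bare raster")
    rows, cols = raster.shape
    if size > rows or size > cols:
        raise ValueError(f"design region {size} exceeds raster {raster.shape}")
    r0 = (rows - size) // 2
    c0 = (cols - size) // 2
    return raster[r0 : r0 + size, c0 : c0 + size]


def binarize(amplitude_raster, threshold_fraction: float = 0.75) -> np.ndarray:
    """Threshold at a fraction of the raster maximum.

    True where value > threshold_fraction * max; pixels attaining the exact
    maximum are always true (so the result is never empty).
    """
    raster = np.asarray(amplitude_raster, dtype=float)
    if raster.size == 0:
        raise ValueError("cannot binarize an empty raster")
    if np.any(raster < 0):
        raise ValueError("amplitude raster must be non-negative")
    peak = raster.max()
    if peak == 0.0:
        raise ValueError("all-zero raster: binarization threshold undefined")
    out = raster > threshold_fraction * peak
    out |= raster == peak
    return out


# --- field I/O ---------------------------------------------------------------

def save_field(field: PressureField, path) -> None:
    """Write a field to HDF5 (amplitude, complex parts, mask, config YAML)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=field.amplitude, track_times=False)
        f.create_dataset("complex_real", data=field.complex_field.real, track_times=False)
        f.create_dataset("complex_imag", data=field.complex_field.imag, track_times=False)
        f.create_dataset("mask", data=field.channel_mask.astype(np.uint8), track_times=False)
        f.attrs["config_yaml"] = field.config.to_yaml()


def load_field(path) -> PressureField:
    import h5py

    with h5py.File(path, "r") as f:
        config = SimConfig.from_yaml(_io.StringIO(f.attrs["config_yaml"]))
        return PressureField(
            complex_field=f["complex_real"][...] + 1j * f["complex_imag"][...],
            amplitude=f["amplitude"][...],
            channel_mask=f["mask"][...].astype(bool),
            config=config,
        )


def export_png(amplitude_raster, path, bit_depth: int = 16) -> None:
    """Export a normalized amplitude raster as an 8- or 16-bit gray PNG."""
    from PIL import Image

    raster = np.asarray(amplitude_raster, dtype=float)
    peak = raster.max()
    norm = raster / peak if peak > 0 else raster
    if bit_depth == 8:
        img = Image.fromarray((norm * 255).round().astype(np.uint8))
    elif bit_depth == 16:
        img = Image.fromarray((norm * 65535).round().astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")
    img.save(path)
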