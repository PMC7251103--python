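"""Synthetic training corpus for the inverse network.

Each sample pairs the binarized design-region pressure field of a random
perturbed-polygon channel (flattened to one row of 0/1 values) with the
2N+1 Fourier coefficients of the shape that produced it.  Inputs are stored
as unsigned bytes (a 20,000 x 22,801 corpus is ~0.45 GB as bytes versus
~3.6 GB as float64) and cast to floats at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .acoustics import FieldSolver, SimConfig, binarize, compute_pressure, design_region
from .shapes import PerturbationParams, random_shape

__all__ = ["TrainingSet", "vectorize", "generate_dataset", "save_dataset", "load_dataset",
           "default_perturbation_params"]

SPLIT_NAMES = ("train", "val", "test")


def vectorize(design_region_raster: np.ndarray, expected_size: int | None = None) -> np.ndarray:
    """Flatten a square design-region raster row-major (index = row*w + col).

    Inverse operation is ``vec.reshape(w, w)``.
    """
    raster = np.asarray(design_region_raster)
    if raster.ndim != 2 or raster.shape[0] != raster.shape[1]:
        raise ValueError(f"design region must be square, got shape {raster.shape}")
    if expected_size is not None and raster.shape[0] != expected_size:
        raise ValueError(f"expected {expected_size}x{expected_size} raster, got {raster.shape}")
    return raster.ravel(order="C")


def default_perturbation_params(config: SimConfig, **overrides) -> PerturbationParams:
    """Perturbation settings tied to a config: the containment radius is the
    design region's half-diagonal, so every generated channel encloses it."""
    params = PerturbationParams(min_radius=config.design_half_diagonal)
    return params.replace(**overrides) if overrides else params


@dataclass
class TrainingSet:
    """Paired (binarized field vectors, coefficient targets) with splits.

    ``inputs`` is (n_samples, design_size^2) uint8 {0, 1}; ``targets`` is
    (n_samples, 2N+1) float64 ordered ``[A0, A1..AN, B1..BN]``.
    """

    inputs: np.ndarray
    targets: np.ndarray
    split_labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.inputs.shape[0] != self.targets.shape[0] or \
                self.inputs.shape[0] != self.split_labels.shape[0]:
            raise ValueError("inputs, targets and split_labels must align on samples")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return np.flatnonzero(self.split_labels == split)

    def split_counts(self) -> dict:
        return {s: int((self.split_labels == s).sum()) for s in SPLIT_NAMES}


def _assign_splits(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random 80/10/10 assignment: counts round(0.8n), round(0.1n), rest."""
    n_train = round(0.8 * n)
    n_val = round(0.1 * n)
    labels = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val))
    return labels[rng.permutation(n)]


def generate_dataset(
    n_samples: int = 20_000,
    rng_seed: int = 0,
    config: SimConfig | None = None,
    params: PerturbationParams | None = None,
    progress: bool = False,
) -> TrainingSet:
    """Simulate ``n_samples`` random channels and assemble the training set.

    For each sample: draw a perturbed-polygon shape, simulate its pressure
    field, crop the design region, binarize at 75% of the peak, and flatten.
    Deterministic for a given ``rng_seed``.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples so an 80/10/10 split exists")
    config = config or SimConfig()
    params = params or default_perturbation_params(config)
    rng = np.random.default_rng(rng_seed)
    solver = FieldSolver(config)
    d = config.design_region_size
    inputs = np.empty((n_samples, d * d), dtype=np.uint8)
    targets = np.empty((n_samples, 2 * params.n_coeffs + 1), dtype=np.float64)
    iterator = range(n_samples)
    if progress:
        iterator = _maybe_tqdm(iterator)
    for i in iterator:
        shape = random_shape(rng, params)
        fld = compute_pressure(shape, config, solver)
        region = design_region(fld)
        inputs[i] = vectorize(binarize(region), d).astype(np.uint8)
        targets[i] = shape.to_vector()
    split_labels = _assign_splits(n_samples, rng)
    provenance = {
        "seed": int(rng_seed),
        "n_samples": int(n_samples),
        "config_yaml": config.to_yaml(),
        "perturbation": {
            "n_coeffs": int(params.n_coeffs),
            "side_range": [int(v) for v in params.side_range],
            "multiplier_range": [float(v) for v in params.multiplier_range],
            "inradius_range": [float(v) for v in params.inradius_range],
            "min_radius": float(params.min_radius),
            "max_attempts": int(params.max_attempts),
            "fit_samples": int(params.fit_samples),
        },
        "package_version": _pkg_version,
    }
    return TrainingSet(inputs=inputs, targets=targets, split_labels=split_labels,
                       provenance=provenance)


def _maybe_tqdm(it):
    try:
        from tqdm import tqdm

        return tqdm(it)
    except ImportError:  # pragma: no cover
        return it


def save_dataset(data: TrainingSet, path) -> None:
    """Write to HDF5: groups /inputs, /targets, /splits, /provenance."""
    import h5py
    import yaml

    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=data.inputs, track_times=False)
        f.create_dataset("targets", data=data.targets, track_times=False)
        f.create_dataset(
            "splits", data=np.char.encode(data.split_labels.astype("U5")), track_times=False
        )
        prov = f.create_group("provenance")
        prov.attrs["yaml"] = yaml.safe_dump(data.provenance, sort_keys=True)


def load_dataset(path) -> TrainingSet:
    import h5py
    import yaml

    with h5py.File(path, "r") as f:
        return TrainingSet(
            inputs=f["inputs"][...],
            targets=f["targets"][...],
            split_labels=np.char.decode(f["splits"][...]).astype("U5"),
            provenance=yaml.safe_load(f["provenance"].attrs["yaml"]),
        )
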