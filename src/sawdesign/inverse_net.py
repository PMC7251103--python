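"""Inverse solver: fully connected network from field image to coefficients.

A feedforward regression network maps the vectorized, binarized design-region
pressure field (22,801 inputs for the default 151 x 151 region) to the 41
Fourier coefficients (N = 20) of the channel boundary that produces it.  The
architecture is 4 ReLU hidden layers with a linear output, trained with the
Adam optimizer against mean-squared error on z-scored coefficients; RMSE on
the normalized coefficient vector is tracked per epoch.

Targets are normalized per coefficient with training-split statistics
(stored with the model): without this the constant term A0 (order 1e-4 m)
dominates the loss over the high-order harmonics (orders of magnitude
smaller), and the network would ignore exactly the coefficients that carry
the shape detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.neural_network import MLPRegressor

from .acoustics import SimConfig, binarize
from .dataset import TrainingSet, vectorize
from .shapes import FourierShape

__all__ = [
    "NetworkSpec",
    "TrainingRun",
    "InverseNet",
    "build_network",
    "train",
    "predict_shape",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer layout of the inverse network.

    Defaults: 22,801 inputs (151 x 151 design region), 4 hidden ReLU layers
    tapering from the image-sized input to the coefficient-sized output, and
    41 linear outputs (2N+1 for N = 20).
    """

    input_width: int = 22_801
    hidden_widths: tuple[int, ...] = (2048, 1024, 512, 128)
    output_width: int = 41

    def __post_init__(self):
        if self.input_width <= 0 or self.output_width <= 0:
            raise ValueError("input/output widths must be positive")
        if len(self.hidden_widths) == 0 or any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))


@dataclass
class TrainingRun:
    """Optimization settings and per-epoch history of one training run."""

    epochs: int = 250
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    #: early stopping patience in epochs on validation RMSE; None = fixed run
    patience: int | None = None
    history: dict = field(default_factory=lambda: {"train_rmse": [], "val_rmse": []})


class InverseNet:
    """Trained (or trainable) inverse model plus its normalizer and config.

    ``target_mean``/``target_scale`` hold the per-coefficient z-score
    normalizer fitted on the training split; ``config`` records the
    simulation geometry the training data was generated under, so the model
    checkpoint is self-contained for downstream design.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.model = MLPRegressor(
            hidden_layer_sizes=spec.hidden_widths,
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            batch_size=64,
            shuffle=True,
            random_state=self.seed,
            max_iter=1,
        )
        self.target_mean: np.ndarray | None = None
        self.target_scale: np.ndarray | None = None
        #: per-pixel mean of the training inputs, subtracted before the first
        #: layer (zero-centers the sparse binary features)
        self.pixel_mean: np.ndarray | None = None
        self.config: SimConfig | None = None
        self.run: TrainingRun | None = None

    # --- normalizer ---------------------------------------------------------
    def fit_normalizer(self, targets: np.ndarray) -> None:
        self.target_mean = targets.mean(axis=0)
        scale = targets.std(axis=0)
        scale[scale < 1e-12] = 1.0  # constant coefficients pass through
        self.target_scale = scale

    def normalize(self, targets: np.ndarray) -> np.ndarray:
        return (targets - self.target_mean) / self.target_scale

    def denormalize(self, normalized: np.ndarray) -> np.ndarray:
        return normalized * self.target_scale + self.target_mean

    # --- parameters ---------------------------------------------------------
    @property
    def is_initialized(self) -> bool:
        return hasattr(self.model, "coefs_")

    def parameters(self) -> list[np.ndarray]:
        """Weight matrices and bias vectors, input layer first."""
        if not self.is_initialized:
            raise RuntimeError("network parameters do not exist before the first update")
        return [w.copy() for w in self.model.coefs_] + [b.copy() for b in self.model.intercepts_]

    def initialize(self, rows: int = 2) -> None:
        """Materialize initial weights without meaningful training.

        Runs one Adam update with a vanishingly small step on a zero batch,
        which triggers the seed-deterministic weight initialization while
        perturbing the weights by less than 1e-20.  Also installs an identity
        normalizer if none is fitted, so the untrained network can serve as a
        prediction baseline.
        """
        lr = self.model.learning_rate_init
        bs = self.model.batch_size
        x = np.zeros((rows, self.spec.input_width), dtype=np.float32)
        y = np.zeros((rows, self.spec.output_width), dtype=np.float32)
        self.model.set_params(learning_rate_init=1e-30, batch_size=rows)
        self.model.partial_fit(x, y)
        self.model.set_params(learning_rate_init=lr, batch_size=bs)
        if self.target_mean is None:
            self.target_mean = np.zeros(self.spec.output_width)
            self.target_scale = np.ones(self.spec.output_width)


def build_network(spec: NetworkSpec, seed: int = 0) -> InverseNet:
    """Create an inverse network with the given layout; the (Glorot) weight
    initialization performed on the first update is deterministic in ``seed``."""
    return InverseNet(spec, seed=seed)


def _rmse(model: MLPRegressor, x: np.ndarray, y_norm: np.ndarray) -> float:
    pred = model.predict(x)
    return float(np.sqrt(np.mean((pred - y_norm) ** 2)))


def train(
    net: InverseNet,
    data: TrainingSet,
    run: TrainingRun | None = None,
    config: SimConfig | None = None,
    history_subsample: int = 2048,
    verbose: bool = False,
) -> InverseNet:
    """Train on the dataset's train split, tracking train/val RMSE per epoch.

    One epoch = one shuffled minibatch pass over the training split
    (Adam updates).  The per-epoch training RMSE is evaluated on at most
    ``history_subsample`` training rows to keep bookkeeping cheap; the
    validation RMSE uses the full validation split.
    """
    run = run or TrainingRun()
    if data.inputs.shape[1] != net.spec.input_width:
        raise ValueError(
            f"dataset input width {data.inputs.shape[1]} != network input "
            f"width {net.spec.input_width}"
        )
    if data.targets.shape[1] != net.spec.output_width:
        raise ValueError(
            f"dataset target width {data.targets.shape[1]} != network output "
            f"width {net.spec.output_width}"
        )
    net.model.set_params(batch_size=run.batch_size, learning_rate_init=run.learning_rate)
    idx_train = data.indices("train")
    idx_val = data.indices("val")
    # float32 end to end: halves the memory traffic of the large first-layer
    # products, which dominate CPU training time
    x_train = data.inputs[idx_train].astype(np.float32)
    net.pixel_mean = x_train.mean(axis=0)
    x_train -= net.pixel_mean
    y_raw = data.targets[idx_train]
    net.fit_normalizer(y_raw)
    y_train = net.normalize(y_raw).astype(np.float32)
    x_val = data.inputs[idx_val].astype(np.float32) - net.pixel_mean
    y_val = net.normalize(data.targets[idx_val]).astype(np.float32)
    if config is not None:
        net.config = config
    elif net.config is None and "config_yaml" in data.provenance:
        net.config = SimConfig.from_yaml(data.provenance["config_yaml"])

    rng = np.random.default_rng(run.seed)
    sub = idx_train
    if idx_train.size > history_subsample:
        sub = rng.choice(idx_train.size, size=history_subsample, replace=False)
        x_hist, y_hist = x_train[sub], y_train[sub]
    else:
        x_hist, y_hist = x_train, y_train
    run.history = {"train_rmse": [], "val_rmse": []}
    best_val, best_epoch = np.inf, -1
    for epoch in range(run.epochs):
        net.model.partial_fit(x_train, y_train)
        tr = _rmse(net.model, x_hist, y_hist)
        va = _rmse(net.model, x_val, y_val) if x_val.size else float("nan")
        run.history["train_rmse"].append(tr)
        run.history["val_rmse"].append(va)
        if verbose:
            print(f"epoch {epoch + 1:4d}  train RMSE {tr:.4f}  val RMSE {va:.4f}")
        if run.patience is not None and x_val.size:
            if va < best_val - 1e-12:
                best_val, best_epoch = va, epoch
            elif epoch - best_epoch >= run.patience:
                break
    net.run = run
    return net


def predict_shape(net: InverseNet, target_mask_or_field: np.ndarray) -> FourierShape:
    """Predict the channel shape for a 151 x 151 design-region raster.

    Boolean rasters are used as-is; amplitude rasters are binarized at the
    standard 75% threshold first.  The returned shape is positivity-checked:
    a non-star-shaped prediction is still returned but carries a warning.
    """
    if net.target_mean is None:
        raise RuntimeError("network is untrained: no target normalizer")
    raster = np.asarray(target_mask_or_field)
    side = int(round(np.sqrt(net.spec.input_width)))
    if raster.ndim == 1 and raster.size == net.spec.input_width:
        vec = raster.astype(np.float64)
    else:
        if raster.ndim != 2 or raster.shape != (side, side):
            raise ValueError(f"expected a {side}x{side} raster, got shape {raster.shape}")
        if raster.dtype != bool:
            raster = binarize(raster)
        vec = vectorize(raster, side).astype(np.float64)
    if not vec.any():
        raise ValueError("empty target raster: at least one active pixel is required")
    vec = vec.astype(np.float32)
    if net.pixel_mean is not None:
        vec = vec - net.pixel_mean
    normalized = net.model.predict(vec[None, :])[0]
    shape = FourierShape.from_vector(net.denormalize(normalized))
    if not shape.is_star_shaped():
        import warnings

        warnings.warn(
            "predicted shape has non-positive radius somewhere; boundary is "
            "not star-shaped",
            RuntimeWarning,
            stacklevel=2,
        )
    return shape


def save_checkpoint(net: InverseNet, path) -> None:
    """Single-file joblib checkpoint plus a human-readable YAML sidecar."""
    import joblib

    payload = {
        "spec": asdict(net.spec),
        "seed": net.seed,
        "model": net.model,
        "target_mean": net.target_mean,
        "target_scale": net.target_scale,
        "pixel_mean": net.pixel_mean,
        "config_yaml": net.config.to_yaml() if net.config is not None else None,
        "run": _run_to_dict(net.run),
    }
    joblib.dump(payload, path)
    sidecar = {k: payload[k] for k in ("spec", "seed", "config_yaml", "run")}
    with open(str(path) + ".yaml", "w") as f:
        yaml.safe_dump(sidecar, f, sort_keys=True)


def _run_to_dict(run: TrainingRun | None):
    if run is None:
        return None
    d = asdict(run)
    d["history"] = {k: [float(v) for v in vals] for k, vals in run.history.items()}
    return d


def load_checkpoint(path) -> InverseNet:
    import joblib

    payload = joblib.load(path)
    spec = NetworkSpec(**{**payload["spec"],
                          "hidden_widths": tuple(payload["spec"]["hidden_widths"])})
    net = InverseNet(spec, seed=payload["seed"])
    net.model = payload["model"]
    net.target_mean = payload["target_mean"]
    net.target_scale = payload["target_scale"]
    net.pixel_mean = payload.get("pixel_mean")
    if payload["config_yaml"]:
        net.config = SimConfig.from_yaml(payload["config_yaml"])
    if payload["run"]:
        d = dict(payload["run"])
        history = d.pop("history")
        net.run = TrainingRun(**d)
        net.run.history = history
    return net
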