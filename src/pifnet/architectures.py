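"""The three model families compared in the benchmark.

* **Baseline** — a shallow VGG-style 3D CNN of convolutional, max-pooling
  and fully-connected stages only.  Variant A has 4 conv stages (filters
  doubling 8 -> 64), variant B has 5 conv stages (8 -> 128) with the fourth
  stage unpooled so the final conv+pool stage still sees a poolable latent.
* **PIF variant** (``A-PIF`` / ``B-PIF``) — identical to the baseline up to
  the last conv+pool stage, which is replaced by a single PIF layer whose
  grid patches the latent feature maps (default 2x2x2 patches with the
  overlapping parallel strain).
* **Patch-based baseline** — one *shared* sub-network (4 conv + 2
  fully-connected stages) applied independently to the 12 patches of a
  2x3x2 split of the *input* volume; the volume-level class scores are the
  mean of the per-patch scores.  This is the classical patch-trained CNN in
  which weights are shared across positions — the conceptual opposite of a
  PIF layer, which shares weights only within a latent patch.

All families map a single-channel volume to 2 class logits, so the training
harness treats them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv, Dense, Flatten, MaxPool, Network, ReLU, cross_entropy
from .patches import PatchGrid, make_patch_grid, split
from .pif import PIFLayer, PIFLayerConfig

__all__ = [
    "ModelHandle", "SequentialModel", "PatchwiseModel",
    "build_baseline", "build_pif_variant", "build_patchwise_baseline",
    "build_model", "describe", "save_checkpoint", "load_checkpoint",
    "VARIANTS",
]

VARIANTS = ("A", "B", "A-PIF", "B-PIF", "patch_based")

# per-variant conv stage plan: (filters, pooled?)
_CONV_PLANS = {
    "A": [(8, True), (16, True), (32, True), (64, True)],
    "B": [(8, True), (16, True), (32, True), (64, False), (128, True)],
}
_HIDDEN_UNITS = 32
_KERNEL = (3, 3, 3)
_POOL = (2, 2, 2)

# defaults of the PIF stage that replaces the last conv+pool
_PIF_DEFAULTS = dict(patch_counts=(2, 2, 2), convs_per_patch=2,
                     kernel_size=(2, 2, 2), use_overlap=True, bias=True)


class SequentialModel:
    """A plain layer chain with cross-entropy training hooks."""

    def __init__(self, network: Network) -> None:
        self.network = network

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(x)

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        logits, _, caches = self.network.forward(x, with_caches=True)
        loss, dlogits = cross_entropy(logits, labels)
        _, grads = self.network.backward(dlogits, caches)
        return loss, grads


class PatchwiseModel:
    """Shared sub-network over a 2x3x2 split of the (zero-padded) input."""

    def __init__(self, network: Network, grid: PatchGrid,
                 padded_shape: tuple[int, ...]) -> None:
        self.network = network
        self.grid = grid
        self.padded_shape = padded_shape

    def _patches(self, x: np.ndarray) -> list[np.ndarray]:
        spatial = x.shape[2:]
        pad = [(0, p - s) for s, p in zip(spatial, self.padded_shape)]
        xp = np.pad(x, [(0, 0), (0, 0)] + pad)
        return split(xp, self.grid)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits = [self.network.forward(p) for p in self._patches(x)]
        return np.mean(logits, axis=0)

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        runs = [self.network.forward(p, with_caches=True)
                for p in self._patches(x)]
        logits = np.mean([r[0] for r in runs], axis=0)
        loss, dlogits = cross_entropy(logits, labels)
        dshare = dlogits / len(runs)
        grads: dict[str, np.ndarray] = {}
        for _, _, caches in runs:  # shared weights: gradients accumulate
            _, g = self.network.backward(dshare, caches)
            for k, v in g.items():
                grads[k] = grads.get(k, 0) + v
        return loss, grads


@dataclass
class ModelHandle:
    """A built model plus the declarative spec it was built from."""

    spec: dict
    model: SequentialModel | PatchwiseModel
    seed: int

    @property
    def variant(self) -> str:
        return self.spec["variant"]

    @property
    def family(self) -> str:
        """One of ``baseline``, ``pif``, ``patch_based`` (drives augmentation)."""
        v = self.variant
        return ("pif" if v.endswith("-PIF")
                else "patch_based" if v == "patch_based" else "baseline")

    @property
    def network(self) -> Network:
        return self.model.network

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_logits(x)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.network, lr=lr)


def _conv_block(name_prefix, layers, in_ch, filters, pooled, rng, dtype):
    layers.append((f"conv{name_prefix}", Conv(in_ch, filters, _KERNEL,
                                              rng=rng, dtype=dtype)))
    layers.append((f"relu{name_prefix}", ReLU()))
    if pooled:
        layers.append((f"pool{name_prefix}", MaxPool(_POOL)))
    return filters


def _head(layers, in_features, rng, dtype):
    layers.append(("flatten", Flatten()))
    layers.append(("fc1", Dense(in_features, _HIDDEN_UNITS, rng=rng, dtype=dtype)))
    layers.append(("relu_fc1", ReLU()))
    layers.append(("output", Dense(_HIDDEN_UNITS, 2, rng=rng, dtype=dtype)))


def _shape_after(layers, in_shape):
    shape = in_shape
    for name, layer in layers:
        try:
            shape = layer.out_shape(shape)
        except ValueError as err:
            raise ValueError(f"stage '{name}': {err}") from err
    return shape


def _scaled(plan, width):
    return [(max(1, round(f * width)), pooled) for f, pooled in plan]


def build_baseline(variant: str, input_shape: tuple[int, int, int], *,
                   seed: int = 0, width: float = 1.0,
                   dtype=np.float32) -> ModelHandle:
    """Build baseline model A or B for single-channel volumes.

    ``width`` scales every conv stage's filter count (1.0 = the default
    8-to-64/128 doubling plan); fractional widths give proportionally
    lighter models for desk-scale experiments.
    """
    if variant not in _CONV_PLANS:
        raise ValueError(f"variant must be one of {tuple(_CONV_PLANS)}")
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i, (filters, pooled) in enumerate(_scaled(_CONV_PLANS[variant], width),
                                          start=1):
        in_ch = _conv_block(i, layers, in_ch, filters, pooled, rng, dtype)
    latent = _shape_after(layers, (1, *input_shape))
    _head(layers, int(np.prod(latent)), rng, dtype)
    net = Network(layers)
    _shape_after(layers, (1, *input_shape))  # validates the head too
    spec = {"variant": variant, "input_shape": list(input_shape),
            "width": width}
    return ModelHandle(spec=spec, model=SequentialModel(net), seed=seed)


def build_pif_variant(variant: str, input_shape: tuple[int, int, int], *,
                      pif: dict | None = None, seed: int = 0,
                      width: float = 1.0, dtype=np.float32) -> ModelHandle:
    """Baseline A/B with the final conv+pool stage replaced by a PIF layer.

    ``pif`` overrides the PIF stage defaults (``patch_counts``,
    ``convs_per_patch``, ``kernel_size``, ``filters_out``, ``use_overlap``,
    ``per_patch_pooling``, ``bias``).
    """
    base = variant.removesuffix("-PIF")
    if base not in _CONV_PLANS:
        raise ValueError(f"variant must be A or B (optionally with -PIF suffix)")
    opts = dict(_PIF_DEFAULTS)
    plan = _scaled(_CONV_PLANS[base], width)
    opts["filters_out"] = plan[-1][0]
    opts["per_patch_pooling"] = list(_POOL)
    if pif:
        opts.update(pif)

    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i, (filters, pooled) in enumerate(plan[:-1], start=1):
        in_ch = _conv_block(i, layers, in_ch, filters, pooled, rng, dtype)
    latent = _shape_after(layers, (1, *input_shape))
    try:
        grid = make_patch_grid(latent[1:], tuple(opts["patch_counts"]),
                               with_overlap=opts["use_overlap"])
    except ValueError as err:
        raise ValueError(
            f"PIF grid {tuple(opts['patch_counts'])} incompatible with the "
            f"latent shape {latent[1:]} at the replaced stage: {err}") from err
    config = PIFLayerConfig(
        grid=grid,
        convs_per_patch=int(opts["convs_per_patch"]),
        kernel_size=tuple(opts["kernel_size"]),
        filters_out=int(opts["filters_out"]),
        use_overlap=bool(opts["use_overlap"]),
        per_patch_pooling=(tuple(opts["per_patch_pooling"])
                           if opts["per_patch_pooling"] else None),
        bias=bool(opts["bias"]),
    )
    layers.append(("pif", PIFLayer(latent[0], config, rng=rng, dtype=dtype)))
    latent_out = _shape_after(layers, (1, *input_shape))
    _head(layers, int(np.prod(latent_out)), rng, dtype)
    net = Network(layers)
    _shape_after(layers, (1, *input_shape))
    spec = {"variant": f"{base}-PIF", "input_shape": list(input_shape),
            "width": width,
            "pif": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                    for k, v in opts.items()}}
    return ModelHandle(spec=spec, model=SequentialModel(net), seed=seed)


def build_patchwise_baseline(input_shape: tuple[int, int, int], *,
                             seed: int = 0, width: float = 1.0,
                             dtype=np.float32) -> ModelHandle:
    """Shared 4-conv / 2-FC sub-network over a 2x3x2 split of the input.

    Unlike latent PIF splitting, the input split tolerates arbitrary volume
    sizes: each dimension is zero-padded up to the next multiple of its
    patch count.
    """
    counts = (2, 3, 2)
    padded = tuple(-(-s // c) * c for s, c in zip(input_shape, counts))
    grid = make_patch_grid(padded, counts, with_overlap=False)
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i, (filters, pooled) in enumerate(
            _scaled([(8, True), (16, True), (32, False), (64, False)], width),
            start=1):
        in_ch = _conv_block(i, layers, in_ch, filters, pooled, rng, dtype)
    latent = _shape_after(layers, (1, *grid.patch_size))
    _head(layers, int(np.prod(latent)), rng, dtype)
    net = Network(layers)
    _shape_after(layers, (1, *grid.patch_size))
    spec = {"variant": "patch_based", "input_shape": list(input_shape),
            "width": width}
    model = PatchwiseModel(net, grid, padded)
    return ModelHandle(spec=spec, model=model, seed=seed)


def build_model(variant: str, input_shape: tuple[int, int, int], *,
                pif: dict | None = None, seed: int = 0, width: float = 1.0,
                dtype=np.float32) -> ModelHandle:
    """Dispatch on variant name (``A``, ``B``, ``A-PIF``, ``B-PIF``,
    ``patch_based``)."""
    if variant == "patch_based":
        return build_patchwise_baseline(input_shape, seed=seed, width=width,
                                        dtype=dtype)
    if variant.endswith("-PIF"):
        return build_pif_variant(variant, input_shape, pif=pif, seed=seed,
                                 width=width, dtype=dtype)
    return build_baseline(variant, input_shape, seed=seed, width=width,
                          dtype=dtype)


def build_from_spec(spec: dict, *, seed: int = 0, dtype=np.float32) -> ModelHandle:
    return build_model(spec["variant"], tuple(spec["input_shape"]),
                       pif=spec.get("pif"), seed=seed,
                       width=spec.get("width", 1.0), dtype=dtype)


def describe(handle: ModelHandle):
    """Stage-by-stage output shapes and parameter counts as a DataFrame."""
    import pandas as pd

    rows = []
    if isinstance(handle.model, PatchwiseModel):
        shape = (1, *handle.model.grid.patch_size)
        rows.append({"stage": "input_split",
                     "output_shape": f"12 patches of {handle.model.grid.patch_size}",
                     "params": 0})
    else:
        shape = (1, *handle.spec["input_shape"])
    for name, layer in handle.network:
        shape = layer.out_shape(shape)
        rows.append({"stage": name, "output_shape": str(tuple(shape)),
                     "params": layer.n_params})
    if isinstance(handle.model, PatchwiseModel):
        rows.append({"stage": "mean_over_patches", "output_shape": "(2,)",
                     "params": 0})
    df = pd.DataFrame(rows)
    df.attrs["total_params"] = int(handle.network.n_params)
    return df


def save_checkpoint(handle: ModelHandle, path) -> None:
    """Weights plus the spec needed to rebuild the model, in one ``.npz``."""
    import json

    arrays = {k.replace("/", "__"): v
              for k, v in handle.network.named_params().items()}
    arrays["__spec__"] = np.frombuffer(
        json.dumps({**handle.spec, "seed": handle.seed}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, dtype=np.float32) -> ModelHandle:
    import json

    with np.load(path) as npz:
        spec = json.loads(bytes(npz["__spec__"]).decode())
        values = {k.replace("__", "/"): npz[k] for k in npz.files
                  if k != "__spec__"}
    seed = spec.pop("seed", 0)
    handle = build_from_spec(spec, seed=seed, dtype=dtype)
    handle.network.set_params(values)
    return handle
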