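"""Patch individual filter (PIF) layers.

A PIF layer is a convolutional stage without global weight sharing: the
incoming feature maps are split into a regular grid of spatial patches, each
patch is processed by its own small stack of convolutions (weights shared
*within* the patch, never across patches), and the processed patches are
reassembled in the order they were split.  An optional parallel strain
processes the same maps cut at origins shifted by half a patch size; where
an overlap patch covers a voxel, the layer outputs the element-wise mean of
the two strains, which — under the chain rule — averages the gradients of
the overlapping and non-overlapping patches in the backward pass.

The strains are combined at the reassembled (pre-pooling) resolution and the
configured max pooling is applied once to the combined map.  Because pooling
windows never cross patch borders when patch sizes are multiples of the
window, this is identical to per-patch pooling for the main grid while
keeping the two strains spatially aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv, Layer, MaxPool, ReLU
from .patches import PatchGrid, reassemble, split

__all__ = ["PIFLayerConfig", "PIFLayer", "pif_forward", "parameter_count"]


@dataclass(frozen=True)
class PIFLayerConfig:
    """Hyperparameters of one PIF layer.

    Parameters
    ----------
    grid : PatchGrid
        The latent-space partition (built with overlap origins if
        ``use_overlap``).
    convs_per_patch : int
        Length of the per-patch convolution stack; each stage is a
        zero-padded "same" convolution followed by the network nonlinearity.
    kernel_size : tuple of int
        Per-stage kernel, at most the patch size in every dimension.
    filters_out : int
        Output channels of every per-patch stage.
    use_overlap : bool
        Whether the shifted parallel strain is active.
    per_patch_pooling : tuple of int or None
        Max-pooling window applied after reassembly (patch-aligned), or
        ``None`` for no pooling.
    bias : bool
        Whether per-patch convolutions carry biases.
    """

    grid: PatchGrid
    convs_per_patch: int = 2
    kernel_size: tuple[int, ...] = (2, 2, 2)
    filters_out: int = 64
    use_overlap: bool = True
    per_patch_pooling: tuple[int, ...] | None = (2, 2, 2)
    bias: bool = True

    def __post_init__(self):
        if self.convs_per_patch < 1:
            raise ValueError("convs_per_patch must be >= 1")
        if self.filters_out < 1:
            raise ValueError("filters_out must be >= 1")
        if len(self.kernel_size) != self.grid.ndim:
            raise ValueError("kernel dimensionality does not match the grid")
        if any(k > s for k, s in zip(self.kernel_size, self.grid.patch_size)):
            raise ValueError(
                f"kernel {self.kernel_size} exceeds patch size "
                f"{self.grid.patch_size}")
        if self.use_overlap and self.grid.n_overlap_patches == 0:
            raise ValueError(
                "use_overlap requested but the grid has no overlap origins")


def parameter_count(config: PIFLayerConfig, in_channels: int) -> int:
    """Trainable weights of a PIF layer, by direct enumeration of its stacks.

    One patch stack holds ``convs_per_patch`` stages; the first maps
    ``in_channels`` to ``filters_out`` channels, later stages keep
    ``filters_out``.  Every patch — main grid and, if enabled, overlap grid —
    carries its own stack.
    """
    k = int(np.prod(config.kernel_size))
    f = config.filters_out
    per_stack = in_channels * f * k + (f if config.bias else 0)
    for _ in range(config.convs_per_patch - 1):
        per_stack += f * f * k + (f if config.bias else 0)
    n_stacks = config.grid.n_patches
    if config.use_overlap:
        n_stacks += config.grid.n_overlap_patches
    return n_stacks * per_stack


def _origin_tag(origin: tuple[int, ...]) -> str:
    return "_".join(str(o) for o in origin)


class PIFLayer(Layer):
    """The PIF layer as a drop-in network stage.

    Parameter names encode strain, patch origin and stage, e.g.
    ``patch_0_8_0/conv1/W`` and ``overlap_4_4_4/conv0/b``, so checkpoints
    carry one named weight group per patch per strain.
    """

    def __init__(self, in_channels: int, config: PIFLayerConfig, *,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        # params is a property here; deliberately skip Layer.__init__
        self.in_channels = int(in_channels)
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)

        def make_stack() -> list[Conv]:
            stack = []
            c_in = self.in_channels
            for _ in range(config.convs_per_patch):
                stack.append(Conv(c_in, config.filters_out, config.kernel_size,
                                  bias=config.bias, rng=rng, dtype=dtype))
                c_in = config.filters_out
            return stack

        self.main_stacks = [make_stack() for _ in config.grid.origins]
        self.overlap_stacks = (
            [make_stack() for _ in config.grid.overlap_origins]
            if config.use_overlap else [])
        self.pool = (MaxPool(config.per_patch_pooling)
                     if config.per_patch_pooling is not None else None)
        self._relu = ReLU()

    # -- parameter namespace ---------------------------------------------
    def _stack_items(self):
        g = self.config.grid
        for origin, stack in zip(g.origins, self.main_stacks):
            yield f"patch_{_origin_tag(origin)}", stack
        for origin, stack in zip(g.overlap_origins, self.overlap_stacks):
            yield f"overlap_{_origin_tag(origin)}", stack

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, stack in self._stack_items():
            for i, conv in enumerate(stack):
                for k, v in conv.params.items():
                    out[f"{tag}/conv{i}/{k}"] = v
        return out

    def set_param(self, name: str, value: np.ndarray) -> None:
        tag, conv_i, k = name.split("/")
        for t, stack in self._stack_items():
            if t == tag:
                stack[int(conv_i.removeprefix("conv"))].set_param(k, value)
                return
        raise KeyError(name)

    # -- shapes -----------------------------------------------------------
    def out_shape(self, in_shape):
        c, *spatial = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if tuple(spatial) != self.config.grid.input_spatial_shape:
            raise ValueError(
                f"spatial input {tuple(spatial)} does not match PIF grid "
                f"{self.config.grid.input_spatial_shape}")
        shape = (self.config.filters_out, *spatial)
        if self.pool is not None:
            shape = self.pool.out_shape(shape)
        return shape

    # -- per-patch processing --------------------------------------------
    def _run_stack(self, stack: list[Conv], patch: np.ndarray):
        caches = []
        for conv in stack:
            patch, c_conv = conv.forward(patch)
            patch, c_relu = self._relu.forward(patch)
            caches.append((c_conv, c_relu))
        return patch, caches

    def _back_stack(self, stack, dy, caches, grads, tag):
        for i in range(len(stack) - 1, -1, -1):
            c_conv, c_relu = caches[i]
            dy, _ = self._relu.backward(dy, c_relu)
            dy, g = stack[i].backward(dy, c_conv)
            for k, v in g.items():
                grads[f"{tag}/conv{i}/{k}"] = v
        return dy

    def process_patch(self, patch: np.ndarray, patch_index: int, *,
                      overlap: bool = False) -> np.ndarray:
        """Apply one patch's convolution stack to a single patch.

        ``patch`` is ``(C, *patch_size)`` or batched ``(N, C, *patch_size)``;
        pooling is not applied here (it acts on the reassembled map).
        """
        stacks = self.overlap_stacks if overlap else self.main_stacks
        squeeze = patch.ndim == self.config.grid.ndim + 1
        x = patch[None] if squeeze else patch
        if x.shape[-self.config.grid.ndim:] != self.config.grid.patch_size:
            raise ValueError(
                f"patch spatial shape {x.shape[2:]} does not match grid "
                f"patch size {self.config.grid.patch_size}")
        out, _ = self._run_stack(stacks[patch_index], x)
        return out[0] if squeeze else out

    # -- forward / backward ----------------------------------------------
    def forward(self, x):
        self.out_shape(x.shape[1:])
        grid = self.config.grid
        patches = split(x, grid)
        outs, main_caches = [], []
        for stack, p in zip(self.main_stacks, patches):
            out, caches = self._run_stack(stack, p)
            outs.append(out)
            main_caches.append(caches)
        y_main = reassemble(outs, grid)

        ov_caches = []
        y = y_main
        if self.config.use_overlap:
            y = y_main.copy()
            lead = (slice(None), slice(None))
            for origin, stack in zip(grid.overlap_origins, self.overlap_stacks):
                region = lead + grid.patch_slices(origin)
                p = x[region].copy()
                out, caches = self._run_stack(stack, p)
                ov_caches.append(caches)
                y[region] = 0.5 * (y_main[region] + out)

        pool_cache = None
        if self.pool is not None:
            y_pre_pool = y
            y, pool_cache = self.pool.forward(y)
        else:
            y_pre_pool = y
        return y, (x.shape, main_caches, ov_caches, pool_cache, y_main, y_pre_pool)

    def backward(self, dy, cache):
        x_shape, main_caches, ov_caches, pool_cache, _, _ = cache
        grid = self.config.grid
        grads: dict[str, np.ndarray] = {}
        if self.pool is not None:
            dy, _ = self.pool.backward(dy, pool_cache)

        dx = np.zeros(x_shape, dtype=dy.dtype)
        lead = (slice(None), slice(None))
        d_main = dy
        if self.config.use_overlap:
            d_main = dy.copy()
            for origin, stack, caches in zip(
                    grid.overlap_origins, self.overlap_stacks, ov_caches):
                region = lead + grid.patch_slices(origin)
                d_ov = 0.5 * dy[region]
                d_main[region] = d_main[region] * 0.5
                tag = f"overlap_{_origin_tag(origin)}"
                dx[region] += self._back_stack(stack, d_ov, caches, grads, tag)

        d_patches = split(d_main, grid)
        in_grads = []
        for origin, stack, caches, dp in zip(
                grid.origins, self.main_stacks, main_caches, d_patches):
            tag = f"patch_{_origin_tag(origin)}"
            in_grads.append(self._back_stack(stack, dp, caches, grads, tag))
        dx += reassemble(in_grads, grid)
        return dx, grads

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


def pif_forward(maps: np.ndarray, layer: PIFLayer) -> np.ndarray:
    """Run a PIF layer on an unbatched ``(C, *spatial)`` feature-map stack."""
    out, _ = layer.forward(maps[None])
    return out[0]
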