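"""Layer-wise relevance propagation (LRP) with the alpha/beta rule.

LRP redistributes a network's output score (or the activation of any hidden
unit) backwards through the layers until every input voxel carries a share
of "relevance", yielding a heatmap at input resolution.  The alpha/beta
rule treats positive and negative contributions separately: for a linear
stage with contributions ``z_ij`` from input unit ``i`` to output unit
``j``,

    R_i = sum_j ( alpha * z_ij+ / sum_k z_kj+  -  beta * z_ij- / sum_k z_kj- ) R_j

with ``alpha = 1 + beta`` so that relevance is conserved layer by layer
(up to the numerical stabilizer).  The default ``beta = 4`` puts a strong
weight on inhibitory evidence, a setting that works well for structural
MRI classifiers in practice.

Conventions adopted where the rule itself is silent: max pooling routes
relevance winner-takes-all through the pooling switches; flatten is pure
re-indexing; ReLU passes relevance through unchanged; biases absorb their
share (they are not redistributed), keeping input heatmaps comparable
across models.  PIF layers split the relevance with the same grid
bookkeeping as the forward pass, propagate it through each patch's private
stack, reassemble, and average the overlap strain's relevance with the main
strain's wherever an overlap patch covers a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architectures import ModelHandle, SequentialModel
from .nn import Conv, Dense, Flatten, MaxPool, ReLU
from .patches import reassemble
from .pif import PIFLayer

__all__ = [
    "RelevanceMap", "ActivationRecord", "record_activations",
    "lrp_step", "lrp_through_pif", "heatmap", "locality_index",
    "write_heatmap_nifti", "save_montage",
]

_EPS = 1e-9


@dataclass
class RelevanceMap:
    """Per-unit relevance aligned with one layer's activation shape."""

    values: np.ndarray
    layer_id: str
    alpha: float
    beta: float

    def __post_init__(self):
        _check_rule(self.alpha, self.beta)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relevance values must be finite")


def _check_rule(alpha: float, beta: float) -> None:
    if abs(alpha - (1.0 + beta)) > 1e-12:
        raise ValueError(
            f"alpha/beta rule requires alpha = 1 + beta, got "
            f"alpha={alpha}, beta={beta}")


@dataclass
class ActivationRecord:
    """Cached forward pass: per-layer inputs and backward caches."""

    inputs: list       # inputs[i] feeds layer i; inputs[-1] is the output
    caches: list
    layer_names: list[str]

    def index(self, layer_id: str) -> int:
        return self.layer_names.index(layer_id)


def record_activations(model: ModelHandle | SequentialModel,
                       x: np.ndarray) -> ActivationRecord:
    """Run the forward pass once and keep everything LRP needs.

    ``x`` is a batched ``(N, C, *spatial)`` array.
    """
    net = model.network if isinstance(model, ModelHandle) else model.network
    _, inputs, caches = net.forward(x, with_caches=True)
    return ActivationRecord(inputs=inputs, caches=caches,
                            layer_names=[n for n, _ in net])


# -- per-layer alpha/beta redistribution ---------------------------------

def _ab_dense(layer: Dense, x, R, alpha, beta, eps):
    W = layer.params["W"].astype(np.float64)
    x = x.astype(np.float64)
    xp, xn = np.clip(x, 0, None), np.clip(x, None, 0)
    Wp, Wn = np.clip(W, 0, None), np.clip(W, None, 0)
    zp = xp @ Wp.T + xn @ Wn.T   # >= 0
    zn = xp @ Wn.T + xn @ Wp.T   # <= 0
    cp = alpha * R / (zp + eps)
    cn = beta * R / (zn - eps)
    return (xp * (cp @ Wp) + xn * (cp @ Wn)
            - xp * (cn @ Wn) - xn * (cn @ Wp))


def _ab_conv(layer: Conv, x, R, alpha, beta, eps):
    W = layer.params["W"].astype(np.float64)
    x = x.astype(np.float64)
    xp, xn = np.clip(x, 0, None), np.clip(x, None, 0)
    Wp, Wn = np.clip(W, 0, None), np.clip(W, None, 0)

    def fwd(w, a):
        cols = layer._im2col(a)
        out = cols @ w.reshape(layer.filters_out, -1).T
        return np.moveaxis(out, -1, 1).reshape(R.shape)

    zp = fwd(Wp, xp) + fwd(Wn, xn)
    zn = fwd(Wn, xp) + fwd(Wp, xn)
    cp = alpha * R / (zp + eps)
    cn = beta * R / (zn - eps)
    return (xp * layer.input_grad(cp, weights=Wp)
            + xn * layer.input_grad(cp, weights=Wn)
            - xp * layer.input_grad(cn, weights=Wn)
            - xn * layer.input_grad(cn, weights=Wp))


def _stack_lrp(stack, stage_caches, R, alpha, beta, eps):
    """Propagate relevance through one per-patch conv stack (ReLU pass-through)."""
    for conv, (c_conv, _c_relu) in zip(reversed(stack), reversed(stage_caches)):
        _, x = c_conv
        R = _ab_conv(conv, x, R, alpha, beta, eps)
    return R


def lrp_through_pif(layer: PIFLayer, cache, R, alpha, beta, eps=_EPS):
    """Relevance through a PIF layer.

    The relevance arriving at the layer output is (i) routed backwards
    through the pooling switches, (ii) split per main-grid patch and
    propagated through each patch's private stack, (iii) reassembled, and
    (iv) wherever an overlap patch covers a voxel, replaced by the mean of
    the main-strain and overlap-strain relevances.
    """
    x_shape, main_caches, ov_caches, pool_cache, _, _ = cache
    grid = layer.config.grid
    if layer.pool is not None:
        R, _ = layer.pool.backward(R, pool_cache)
    lead = (slice(None), slice(None))
    patch_rel = []
    for origin, stack, caches in zip(grid.origins, layer.main_stacks,
                                     main_caches):
        region = lead + grid.patch_slices(origin)
        patch_rel.append(_stack_lrp(stack, caches, R[region], alpha, beta, eps))
    R_in = reassemble(patch_rel, grid)
    if layer.config.use_overlap:
        for origin, stack, caches in zip(grid.overlap_origins,
                                         layer.overlap_stacks, ov_caches):
            region = lead + grid.patch_slices(origin)
            r_ov = _stack_lrp(stack, caches, R[region], alpha, beta, eps)
            R_in[region] = 0.5 * (R_in[region] + r_ov)
    return R_in


def lrp_step(model: ModelHandle | SequentialModel, layer_id: str,
             upstream: RelevanceMap, activations: ActivationRecord,
             *, eps: float = _EPS) -> RelevanceMap:
    """Backpropagate relevance through the single layer ``layer_id``.

    ``upstream.values`` must be aligned with that layer's *output*; the
    result is aligned with its input.  Requires the cached forward pass of
    the input in question.
    """
    if activations is None:
        raise ValueError("lrp_step requires cached forward activations")
    _check_rule(upstream.alpha, upstream.beta)
    net = model.network if isinstance(model, ModelHandle) else model.network
    idx = activations.index(layer_id)
    layer = dict(net.layers)[layer_id]
    x = activations.inputs[idx]
    cache = activations.caches[idx]
    R = upstream.values.astype(np.float64)
    alpha, beta = upstream.alpha, upstream.beta

    if isinstance(layer, Dense):
        R = _ab_dense(layer, x, R, alpha, beta, eps)
    elif isinstance(layer, Conv):
        R = _ab_conv(layer, x, R, alpha, beta, eps)
    elif isinstance(layer, PIFLayer):
        R = lrp_through_pif(layer, cache, R, alpha, beta, eps)
    elif isinstance(layer, MaxPool):
        R, _ = layer.backward(R, cache)     # winner-takes-all switches
    elif isinstance(layer, Flatten):
        R, _ = layer.backward(R, cache)     # pure re-indexing
    elif isinstance(layer, ReLU):
        pass                                # relevance passes through
    else:  # pragma: no cover - no other layer kinds exist
        raise TypeError(f"no LRP rule for layer type {type(layer).__name__}")
    prev = activations.layer_names[idx - 1] if idx > 0 else "input"
    return RelevanceMap(values=R, layer_id=prev, alpha=alpha, beta=beta)


def heatmap(model: ModelHandle, volume: np.ndarray,
            start: str | tuple = "output", *, beta: float = 4.0,
            eps: float = _EPS) -> np.ndarray:
    """Input-resolution LRP heatmap for one single-channel volume.

    ``start`` selects where relevance is initialized (all other units zero):

    * ``"output"`` — the logit of the predicted class;
    * ``("output", class_index)`` — a specific class logit;
    * ``(layer_id, filter_index)`` — one filter's activation map at a
      conv/ReLU stage;
    * ``(pif_layer_id, patch_index, filter_index)`` — one filter within one
      patch of a PIF layer's output.

    ``alpha`` is implied by the rule constraint ``alpha = 1 + beta``.
    """
    if not isinstance(model.model, SequentialModel):
        raise TypeError("heatmaps are defined for sequential (non-patchwise) models")
    alpha = 1.0 + beta
    x = np.asarray(volume, dtype=np.float64)[None, None]
    rec = record_activations(model, x)
    names = rec.layer_names

    if start == "output" or (isinstance(start, tuple) and start[0] == "output"):
        idx = len(names) - 1
        out = rec.inputs[-1].astype(np.float64)
        cls = (int(start[1]) if isinstance(start, tuple)
               else int(out[0].argmax()))
        if not 0 <= cls < out.shape[1]:
            raise IndexError(f"class index {cls} out of range")
        R = np.zeros_like(out)
        R[0, cls] = out[0, cls]
        start_layer = names[idx]
    else:
        layer_id = start[0]
        idx = rec.index(layer_id)
        act = rec.inputs[idx + 1].astype(np.float64)
        layer = dict((n, l) for n, l in
                     (model.network.layers))[layer_id]
        R = np.zeros_like(act)
        if isinstance(layer, PIFLayer) and len(start) == 3:
            _, patch_index, filt = start
            grid = layer.config.grid
            if not 0 <= patch_index < grid.n_patches:
                raise IndexError(f"patch index {patch_index} out of range")
            if not 0 <= filt < act.shape[1]:
                raise IndexError(f"filter index {filt} out of range")
            origin = grid.origins[patch_index]
            win = (layer.pool.window if layer.pool is not None
                   else (1,) * grid.ndim)
            region = tuple(slice(o // w, (o + s) // w) for o, s, w in
                           zip(origin, grid.patch_size, win))
            sel = (0, filt) + region
            R[sel] = act[sel]
        else:
            filt = int(start[1])
            if not 0 <= filt < act.shape[1]:
                raise IndexError(f"filter index {filt} out of range")
            R[0, filt] = act[0, filt]
        start_layer = layer_id

    rel = RelevanceMap(values=R, layer_id=start_layer, alpha=alpha, beta=beta)
    for i in range(rec.index(start_layer), -1, -1):
        rel = lrp_step(model, names[i], rel, rec, eps=eps)
    return rel.values[0, 0]


def locality_index(hm: np.ndarray,
                   cells_per_dim: tuple[int, ...] = (2, 2, 2),
                   mass: float = 0.9) -> float:
    """Fraction of grid cells needed to hold 90% of the absolute relevance.

    The heatmap is partitioned into ``cells_per_dim`` roughly equal boxes;
    the index is (number of largest-|relevance| cells whose running sum
    first reaches ``mass`` of the total) divided by the number of cells.
    Lower values mean a more localized heatmap; a map concentrated in a
    single cell of an 8-cell grid scores 1/8, a uniform map scores 1.
    """
    hm = np.abs(np.asarray(hm, dtype=np.float64))
    total = hm.sum()
    if total <= 0:
        raise ValueError("locality index undefined for an all-zero heatmap")
    blocks = [hm]
    for axis, cells in enumerate(cells_per_dim):
        blocks = [sub for b in blocks for sub in np.array_split(b, cells, axis=axis)]
    sums = np.sort(np.array([b.sum() for b in blocks]))[::-1]
    needed = int(np.searchsorted(np.cumsum(sums), mass * total) + 1)
    return needed / len(sums)


def write_heatmap_nifti(hm: np.ndarray, path) -> None:
    """Write a heatmap as a NIfTI volume on the input grid (identity affine)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(hm, dtype=np.float32), np.eye(4)), path)


def save_montage(hm: np.ndarray, path, *, n_slices: int = 8) -> None:
    """PNG montage of evenly spaced axial slices of a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hm = np.asarray(hm)
    idx = np.linspace(0, hm.shape[2] - 1, n_slices).astype(int)
    vmax = np.abs(hm).max() or 1.0
    fig, axes = plt.subplots(1, n_slices, figsize=(2 * n_slices, 2))
    for ax, k in zip(np.atleast_1d(axes), idx):
        ax.imshow(hm[:, :, k].T, cmap="seismic", vmin=-vmax, vmax=vmax,
                  origin="lower")
        ax.set_axis_off()
        ax.set_title(f"z={k}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
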