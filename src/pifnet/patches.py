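"""Patch bookkeeping for PIF layers.

A PIF (patch individual filter) layer splits a stack of latent feature maps
into a regular grid of non-overlapping spatial patches, processes each patch
with its own kernels, and reassembles the patches in the order they were
split.  A parallel "overlap" strain uses the same grid shifted by half a
patch size, dropping any shifted patch that would extend past the domain
boundary (those would require padding and sit at the least informative image
borders).

All indexing is 0-based with half-open patch extents
``[origin, origin + patch_size)``; arrays are channel-first, i.e. the spatial
axes are the trailing ``ndim`` axes, so the same routines serve single maps,
channel stacks and batched stacks alike.  Patch order is lexicographic in the
origin coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatchGrid", "make_patch_grid", "split", "reassemble"]


@dataclass(frozen=True)
class PatchGrid:
    """Partition of a spatial domain into equal non-overlapping patches.

    Parameters
    ----------
    input_spatial_shape : tuple of int
        Voxels per spatial dimension (2-D or 3-D).
    patch_size : tuple of int
        Extent of one patch per dimension; must divide the domain exactly.
    origins : tuple of tuple of int
        Start coordinate of every main-grid patch, lexicographically ordered.
    overlap_origins : tuple of tuple of int
        Origins shifted by half a patch size, keeping only shifts whose patch
        lies fully inside the domain.
    """

    input_spatial_shape: tuple[int, ...]
    patch_size: tuple[int, ...]
    origins: tuple[tuple[int, ...], ...] = field(repr=False)
    overlap_origins: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def ndim(self) -> int:
        return len(self.input_spatial_shape)

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    @property
    def n_overlap_patches(self) -> int:
        return len(self.overlap_origins)

    def patch_slices(self, origin: tuple[int, ...]) -> tuple[slice, ...]:
        """Half-open slices selecting the patch starting at ``origin``."""
        return tuple(slice(o, o + s) for o, s in zip(origin, self.patch_size))


def make_patch_grid(
    input_spatial_shape: tuple[int, ...],
    patch_counts: tuple[int, ...],
    *,
    with_overlap: bool = True,
) -> PatchGrid:
    """Build a :class:`PatchGrid` from patch counts per dimension.

    Parameters
    ----------
    input_spatial_shape : tuple of int
        Spatial shape of the maps to be split (2-D or 3-D).
    patch_counts : tuple of int
        Number of patches per dimension; each must divide the corresponding
        spatial extent exactly (boundary patches are never padded or
        truncated).
    with_overlap : bool
        Whether to derive the shifted overlap origins.  Requires an even
        patch size in every dimension, since the shift is half a patch.

    Raises
    ------
    ValueError
        If shapes do not divide exactly, or overlap is requested with an odd
        patch size.
    """
    shape = tuple(int(v) for v in input_spatial_shape)
    counts = tuple(int(c) for c in patch_counts)
    if len(shape) not in (2, 3):
        raise ValueError(f"expected 2 or 3 spatial dimensions, got {len(shape)}")
    if len(counts) != len(shape):
        raise ValueError(
            f"patch_counts has {len(counts)} entries for a {len(shape)}-D shape"
        )
    if any(v <= 0 for v in shape) or any(c <= 0 for c in counts):
        raise ValueError("spatial shape and patch counts must be positive")
    for axis, (extent, count) in enumerate(zip(shape, counts)):
        if extent % count != 0:
            raise ValueError(
                f"dimension {axis}: extent {extent} is not divisible by "
                f"patch count {count}"
            )
    patch_size = tuple(extent // count for extent, count in zip(shape, counts))

    origins = tuple(
        itertools.product(*(range(0, extent, size) for extent, size in zip(shape, patch_size)))
    )

    overlap_origins: tuple[tuple[int, ...], ...] = ()
    if with_overlap:
        if any(s % 2 != 0 for s in patch_size):
            raise ValueError(
                f"overlap origins need an even patch size; got {patch_size}"
            )
        half = tuple(s // 2 for s in patch_size)
        shifted = (tuple(o + h for o, h in zip(origin, half)) for origin in origins)
        overlap_origins = tuple(
            origin
            for origin in shifted
            if all(o + s <= extent for o, s, extent in zip(origin, patch_size, shape))
        )

    return PatchGrid(
        input_spatial_shape=shape,
        patch_size=patch_size,
        origins=origins,
        overlap_origins=overlap_origins,
    )


def _check_spatial(maps: np.ndarray, grid: PatchGrid) -> None:
    spatial = maps.shape[-grid.ndim:]
    if maps.ndim < grid.ndim or spatial != grid.input_spatial_shape:
        raise ValueError(
            f"spatial shape {spatial} does not match grid "
            f"{grid.input_spatial_shape}"
        )


def split(
    maps: np.ndarray, grid: PatchGrid, *, origins: tuple[tuple[int, ...], ...] | None = None
) -> list[np.ndarray]:
    """Cut ``maps`` into per-patch sub-stacks in origin order.

    The trailing ``grid.ndim`` axes of ``maps`` are spatial; any leading axes
    (channels, batch) are carried along unchanged.  Returned patches are
    copies.  Pass ``origins=grid.overlap_origins`` to cut the overlap strain.
    """
    _check_spatial(maps, grid)
    origins = grid.origins if origins is None else origins
    lead = (slice(None),) * (maps.ndim - grid.ndim)
    return [maps[lead + grid.patch_slices(origin)].copy() for origin in origins]


def reassemble(patch_list: list[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`split`: place patches back at their origins.

    Requires exactly one patch per main-grid origin, each with the grid's
    patch size on its trailing axes; split followed by reassemble is a
    bit-exact identity.
    """
    if len(patch_list) != grid.n_patches:
        raise ValueError(
            f"expected {grid.n_patches} patches, got {len(patch_list)}"
        )
    expected = grid.patch_size
    first = patch_list[0]
    for p in patch_list:
        if p.shape[-grid.ndim:] != expected:
            raise ValueError(
                f"patch spatial shape {p.shape[-grid.ndim:]} does not match "
                f"grid patch size {expected}"
            )
        if p.shape[: -grid.ndim] != first.shape[: -grid.ndim]:
            raise ValueError("patches disagree in their leading (channel) axes")
    out_shape = first.shape[: -grid.ndim] + grid.input_spatial_shape
    out = np.empty(out_shape, dtype=np.result_type(*(p.dtype for p in patch_list)))
    lead = (slice(None),) * (first.ndim - grid.ndim)
    for origin, patch in zip(grid.origins, patch_list):
        out[lead + grid.patch_slices(origin)] = patch
    return out
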