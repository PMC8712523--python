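"""Slow, obviously-correct reference implementations.

These exist so the fast im2col paths in :mod:`pifnet.nn` and
:mod:`pifnet.pif` can be checked against simple position-by-position index
arithmetic.  They share only the conventions (cross-correlation, "same" zero
padding, channel-first layout), not the code.
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv_oracle"]


def conv_oracle(maps: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force multi-channel cross-correlation with "same" zero padding.

    Parameters
    ----------
    maps : ndarray, shape ``(C, *spatial)``
        Input feature maps (2 or 3 spatial dimensions).
    kernel : ndarray, shape ``(F, C, *k)``
        One kernel per output filter.

    Returns
    -------
    ndarray, shape ``(F, *spatial)``
        ``out[f, pos] = sum_{c, off} maps[c, pos - center + off] * kernel[f, c, off]``
        with zero padding outside the domain, evaluated position by position.
    """
    maps = np.asarray(maps)
    kernel = np.asarray(kernel)
    nd = maps.ndim - 1
    if kernel.ndim != nd + 2:
        raise ValueError("kernel must be (filters, channels, *kernel_size)")
    if kernel.shape[1] != maps.shape[0]:
        raise ValueError("channel mismatch between kernel and input")
    spatial = maps.shape[1:]
    ksize = kernel.shape[2:]
    if any(k > s for k, s in zip(ksize, spatial)):
        raise ValueError(f"kernel {ksize} larger than input {spatial}")
    lo = tuple((k - 1) // 2 for k in ksize)
    hi = tuple(k // 2 for k in ksize)
    padded = np.pad(maps, ((0, 0),) + tuple(zip(lo, hi)))
    out = np.empty((kernel.shape[0],) + spatial, dtype=np.result_type(maps, kernel))
    for pos in np.ndindex(*spatial):
        window = padded[(slice(None),) + tuple(slice(p, p + k)
                                               for p, k in zip(pos, ksize))]
        out[(slice(None),) + pos] = np.tensordot(
            kernel, window,
            axes=(list(range(1, kernel.ndim)), list(range(window.ndim))))
    return out
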