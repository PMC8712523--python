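"""Synthetic registered-MRI-like 3D volumes.

Real structural MRI that has been spatially normalized to a template is
highly homogeneous: every scan shows the same anatomy at the same voxel
coordinates, differing in localized disease- or class-related signal,
subject-specific low-level texture, scanner noise and a small residual
registration error.  The generator emulates exactly these ingredients:

* a procedural anatomical *template* (smoothed ellipsoidal compartments)
  shared bit-identically by every subject in a dataset,
* class-discriminative signal confined to fixed spherical *signal sites*
  (class 1 receives an intensity offset ``d`` inside each site),
* subject-specific smooth *texture* with the same distribution in both
  classes,
* additive Gaussian noise, and
* optional integer translation *jitter* emulating residual misregistration.

The default volume shape 32x38x32 is a one-third-scale echo of the
96x114x96 grids typical of template-registered structural MRI.  It keeps a
full training run of a 3D CNN tractable on a single CPU while preserving
the aspect ratio.  Per-volume max-intensity normalization is applied last,
matching the preprocessing used at training time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SyntheticSpec", "Dataset", "generate", "template",
           "write_nifti", "read_nifti"]

def default_sites(shape: tuple[int, int, int], d: float = 0.2) -> tuple:
    """Two spherical class-signal sites at fixed fractional positions.

    Radius scales with the volume (min-extent / 8, at least 2 voxels); the
    default intensity offset ``d`` = 0.2 is twice the default noise sigma.
    """
    r = max(2.0, round(min(shape) / 8))
    return (
        (tuple(int(0.3 * s) for s in shape), r, d),
        (tuple(int(0.7 * s) for s in shape), r, d),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset (defaults are the study conditions).

    ``signal_sites`` entries are ``(center, radius, d)`` with ``d`` the
    class-1 intensity offset inside the sphere; the default ``d`` of 0.2
    equals twice the default noise standard deviation.  ``jitter`` is the
    maximum per-axis translation in voxels (uniform integer in
    ``[-jitter, jitter]``).  With ``delocalized`` the site centers are
    re-drawn per subject, destroying the spatially fixed signal that the
    PIF prior targets (a negative-control regime).
    """

    n_per_class: int = 50
    shape: tuple[int, int, int] = (32, 38, 32)
    signal_sites: tuple | None = None
    texture_scale: float = 0.05
    noise_sd: float = 0.1
    jitter: int = 0
    delocalized: bool = False
    normalize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"degenerate volume shape {self.shape}")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")
        if self.signal_sites is None:
            object.__setattr__(self, "signal_sites", default_sites(self.shape))
        for center, radius, d in self.signal_sites:
            if not np.isfinite(d):
                raise ValueError("signal delta must be finite")
            for c, r, s in zip(center, (radius,) * 3, self.shape):
                if c - r < 0 or c + r > s - 1:
                    raise ValueError(
                        f"signal site at {center} (radius {radius}) extends "
                        f"outside the volume {self.shape}")


@dataclass
class Dataset:
    """In-memory labelled volume collection (one image per subject here)."""

    volumes: np.ndarray          # (N, X, Y, Z) float32
    labels: np.ndarray           # (N,) int, binary
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.volumes.shape[0] != len(self.labels):
            raise ValueError("volumes and labels disagree in length")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(len(self.labels))]

    def __len__(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]


def template(shape: tuple[int, int, int], seed: int = 0) -> np.ndarray:
    """Procedural anatomical template: smoothed ellipsoidal compartments.

    Deterministic given ``(shape, seed)``; intensities roughly in [0, 1.3]
    with an outer "brain" ellipsoid, a darker central compartment and two
    brighter deep structures.
    """
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*(np.linspace(-1, 1, s) for s in shape), indexing="ij")

    def ellipsoid(center, radii):
        return sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0

    vol = np.zeros(shape, dtype=np.float64)
    vol[ellipsoid((0, 0, 0), (0.85, 0.9, 0.85))] = 1.0
    vol[ellipsoid((0, 0.1, 0), (0.28, 0.35, 0.22))] = 0.4
    for sign in (-1, 1):
        vol[ellipsoid((0.35 * sign, -0.25, 0.2), (0.18, 0.2, 0.18))] = 1.3
    vol += 0.02 * rng.standard_normal(shape)  # faint frozen anatomy detail
    return gaussian_filter(vol, sigma=1.5).astype(np.float32)


def _site_mask(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius ** 2


def _shift(vol: np.ndarray, offsets: tuple[int, ...]) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(vol)
    src, dst = [], []
    for off, s in zip(offsets, vol.shape):
        if off >= 0:
            src.append(slice(0, s - off))
            dst.append(slice(off, s))
        else:
            src.append(slice(-off, s))
            dst.append(slice(0, s + off))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw a labelled dataset; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    base = template(spec.shape, seed=spec.seed)
    n = 2 * spec.n_per_class
    labels = np.array([0] * spec.n_per_class + [1] * spec.n_per_class)
    labels = labels[rng.permutation(n)]

    volumes = np.empty((n, *spec.shape), dtype=np.float32)
    for i in range(n):
        sites = spec.signal_sites
        if spec.delocalized:
            sites = tuple(
                (tuple(int(rng.integers(int(np.ceil(r)), s - int(np.ceil(r))))
                       for s in spec.shape), r, d)
                for _, r, d in spec.signal_sites)
        anat = base.astype(np.float64).copy()
        if labels[i] == 1:
            for center, radius, d in sites:
                anat[_site_mask(spec.shape, center, radius)] += d
        if spec.texture_scale > 0:
            tex = gaussian_filter(rng.standard_normal(spec.shape), sigma=1.5)
            anat += spec.texture_scale * tex / tex.std()
        if spec.jitter > 0:
            offsets = tuple(int(rng.integers(-spec.jitter, spec.jitter + 1))
                            for _ in range(3))
            anat = _shift(anat, offsets)
        vol = anat + spec.noise_sd * rng.standard_normal(spec.shape)
        if spec.normalize:
            peak = vol.max()
            if peak <= 0:
                raise ValueError("volume has non-positive maximum; cannot normalize")
            vol = vol / peak
        volumes[i] = vol.astype(np.float32)

    return Dataset(volumes=volumes, labels=labels)


# -- NIfTI round trip -----------------------------------------------------

_LABELS_FILE = "labels.tsv"


def write_nifti(dataset: Dataset, directory: str | os.PathLike) -> None:
    """Write one ``.nii.gz`` per volume plus a ``labels.tsv`` sidecar.

    The affine is identity at 1 mm isotropic (the volumes are synthetic and
    live on an arbitrary registered grid).
    """
    import nibabel as nib
    import pandas as pd

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for sid, label, vol in zip(dataset.subject_ids, dataset.labels,
                               dataset.volumes):
        fname = f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                 os.path.join(directory, fname))
        rows.append({"subject_id": sid, "label": int(label), "filename": fname})
    pd.DataFrame(rows).to_csv(os.path.join(directory, _LABELS_FILE),
                              sep="\t", index=False)


def read_nifti(directory: str | os.PathLike) -> Dataset:
    """Read a dataset written by :func:`write_nifti` (or equivalent).

    Every ``.nii.gz``/``.nii`` file in the directory must appear in the
    labels table and all volumes must share one spatial shape — PIF models
    require spatially standardized inputs.
    """
    import nibabel as nib
    import pandas as pd

    directory = os.fspath(directory)
    table_path = os.path.join(directory, _LABELS_FILE)
    if not os.path.exists(table_path):
        raise FileNotFoundError(f"missing labels table {table_path}")
    table = pd.read_csv(table_path, sep="\t")
    listed = set(table["filename"])
    on_disk = {f for f in os.listdir(directory)
               if f.endswith((".nii", ".nii.gz"))}
    stray = sorted(on_disk - listed)
    if stray:
        raise ValueError(f"volume not present in labels table: {stray[0]}")
    missing = sorted(listed - on_disk)
    if missing:
        raise FileNotFoundError(f"volume listed but absent: {missing[0]}")

    volumes, labels, ids = [], [], []
    shape = None
    for row in table.itertuples():
        img = nib.load(os.path.join(directory, row.filename))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError(f"{row.filename}: expected a 3-D volume")
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"{row.filename}: shape {data.shape} differs from {shape}; "
                "all volumes must share one voxel grid")
        volumes.append(data)
        labels.append(int(row.label))
        ids.append(str(row.subject_id))
    return Dataset(volumes=np.stack(volumes), labels=np.array(labels),
                   subject_ids=ids)
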