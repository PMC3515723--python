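"""ROI signal extraction from rCBF volumes.

Turns a set of 3D volumes plus region masks into a per-scan signal table:
one leading-eigenvariate value per region per analysis unit, plus a
whole-brain covariate extracted with the same operator.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "RCBFVolume",
    "ROIMask",
    "Stack",
    "smooth_volume",
    "smooth_data",
    "stack_scans",
    "unstack",
    "extract_eigenvariate",
    "extract_global",
    "eigenvariate_table",
    "read_volume",
    "read_mask",
    "write_mask",
    "voxel_sizes",
]

#: unit-key columns identifying one analysis unit
UNIT_COLUMNS = ["participant", "session", "condition"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.35482


@dataclass(frozen=True)
class RCBFVolume:
    """One scan's 3D intensity grid plus its voxel→mm affine."""

    data: np.ndarray
    affine: np.ndarray
    scan_key: tuple = ()

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if np.linalg.matrix_rank(np.asarray(self.affine)) != 4:
            raise ValueError("affine must be invertible")


@dataclass(frozen=True)
class ROIMask:
    """Named boolean voxel set on a volume grid."""

    name: str
    data: np.ndarray
    affine: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        if not self.data.any():
            raise ValueError(f"mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class Stack:
    """4D stack of analysis units sharing one grid.

    ``data`` has shape (n_units, nx, ny, nz); ``units`` maps stack row →
    (participant, session, condition).
    """

    data: np.ndarray
    units: pd.DataFrame
    affine: np.ndarray

    def __post_init__(self):
        if len(self.units) != self.data.shape[0]:
            raise ValueError("unit table and data row count disagree")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the linear part)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def smooth_data(data: np.ndarray, affine: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Gaussian-smooth a 3D array, FWHM given in mm, per-axis sigma in voxels."""
    from scipy import ndimage

    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return np.array(data, copy=True)
    sigma_vox = fwhm_mm / (voxel_sizes(affine) * _FWHM_TO_SIGMA)
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma_vox)


def smooth_volume(volume: RCBFVolume, fwhm_mm: float) -> RCBFVolume:
    """Return a smoothed copy of ``volume``; ``fwhm_mm = 0`` is the identity."""
    return dataclasses.replace(
        volume, data=smooth_data(volume.data, volume.affine, fwhm_mm)
    )


def _combine_replicates(
    group: pd.DataFrame,
    volumes: Mapping,
    use_replicates: str,
) -> np.ndarray:
    rows = group.sort_values("replicate")
    arrays = [np.asarray(volumes[k].data, dtype=float) for k in rows["_key"]]
    if use_replicates == "first":
        return arrays[0]
    if use_replicates == "average":
        return np.mean(arrays, axis=0)
    raise ValueError(f"use_replicates must be 'average' or 'first', got {use_replicates!r}")


def stack_scans(
    manifest: pd.DataFrame,
    volumes: Mapping[tuple, RCBFVolume],
    group_by: str = "session_condition",
    use_replicates: str = "average",
) -> dict:
    """Group scans into 4D stacks of analysis units.

    ``manifest`` needs columns participant, session, condition, replicate.
    ``volumes`` maps (participant, session, condition, replicate) →
    :class:`RCBFVolume`. One analysis unit is a participant × session ×
    condition cell; its replicate scans are averaged voxelwise by default.

    ``group_by='session_condition'`` keys the result by (session, condition);
    ``group_by='session_combined'`` keys by session and concatenates the
    per-condition units of that session into one stack.
    """
    if group_by not in ("session_condition", "session_combined"):
        raise ValueError(f"unknown group_by {group_by!r}")

    manifest = manifest.copy()
    manifest["_key"] = list(
        zip(manifest["participant"], manifest["session"],
            manifest["condition"], manifest["replicate"])
    )
    missing = [k for k in manifest["_key"] if k not in volumes]
    if missing:
        raise KeyError(f"manifest references scans with no volume: {missing[:5]}")

    ref_affine = None
    ref_shape = None
    for k in manifest["_key"]:
        vol = volumes[k]
        if ref_affine is None:
            ref_affine, ref_shape = np.asarray(vol.affine), vol.data.shape
        elif vol.data.shape != ref_shape or not np.allclose(vol.affine, ref_affine):
            raise ValueError(f"scan {k} does not share the reference grid/affine")

    units = []
    for (p, s, c), grp in manifest.groupby(
        ["participant", "session", "condition"], sort=False
    ):
        units.append(((p, s, c), _combine_replicates(grp, volumes, use_replicates)))

    stacks: dict = {}
    cond_order = list(dict.fromkeys(manifest["condition"]))
    sess_order = list(dict.fromkeys(manifest["session"]))
    if group_by == "session_condition":
        keys = [(s, c) for s in sess_order for c in cond_order]
        selector = lambda u, key: (u[1], u[2]) == key  # noqa: E731
    else:
        keys = sess_order
        selector = lambda u, key: u[1] == key  # noqa: E731

    for key in keys:
        rows = [(u, a) for u, a in units if selector(u, key)]
        if not rows:
            continue
        # combined stacks keep condition-major order to mirror per-task stacking
        if group_by == "session_combined":
            rows.sort(key=lambda r: (cond_order.index(r[0][2]), r[0][0]))
        unit_df = pd.DataFrame([r[0] for r in rows], columns=UNIT_COLUMNS)
        data = np.stack([r[1] for r in rows])
        stacks[key] = Stack(data=data, units=unit_df, affine=ref_affine)
    return stacks


def unstack(stack: Stack) -> list[RCBFVolume]:
    """Inverse of stacking: one volume per analysis unit, bitwise-identical data."""
    return [
        RCBFVolume(data=stack.data[i], affine=stack.affine,
                   scan_key=tuple(stack.units.iloc[i]))
        for i in range(stack.n_units)
    ]


def _first_eigenvariate(X: np.ndarray) -> np.ndarray:
    """Leading left-singular direction of a units × voxels matrix.

    Columns are mean-centered across units; the result is scaled to unit
    population variance and sign-fixed so its correlation with the mask mean
    signal is non-negative.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a units × voxels matrix")
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 units, got {X.shape[0]}")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= np.finfo(float).eps * max(X.shape) * max(1.0, np.abs(X).max()):
        raise ValueError("masked data are constant across units; eigenvariate undefined")
    e = u[:, 0]
    mean_sig = X.mean(axis=1)
    align = float(e @ (mean_sig - mean_sig.mean()))
    if align < 0:
        e = -e
    elif align == 0:
        nz = np.flatnonzero(e)
        if nz.size and e[nz[0]] < 0:
            e = -e
    return e / e.std()


def extract_eigenvariate(stack: Stack, mask: ROIMask) -> np.ndarray:
    """First eigenvariate of the masked signal, one value per analysis unit."""
    if mask.data.shape != stack.data.shape[1:]:
        raise ValueError(
            f"mask {mask.name!r} grid {mask.data.shape} does not match "
            f"stack grid {stack.data.shape[1:]}"
        )
    return _first_eigenvariate(stack.data[:, mask.data])


def extract_global(stack: Stack, whole_brain_mask: ROIMask) -> np.ndarray:
    """Whole-brain covariate: same operator as ROI extraction, brain-wide mask."""
    return extract_eigenvariate(stack, whole_brain_mask)


def eigenvariate_table(
    stack: Stack,
    roi_masks: Sequence[ROIMask],
    whole_brain_mask: ROIMask,
) -> pd.DataFrame:
    """Per-unit signal table: unit keys, one column per ROI, plus ``global``."""
    out = stack.units.copy()
    for mask in roi_masks:
        out[mask.name] = extract_eigenvariate(stack, mask)
    out["global"] = extract_global(stack, whole_brain_mask)
    return out


def read_volume(path, scan_key: tuple = ()) -> RCBFVolume:
    img = nib.load(str(path))
    return RCBFVolume(
        data=np.asarray(img.get_fdata(), dtype=float),
        affine=np.asarray(img.affine),
        scan_key=scan_key,
    )


def read_mask(path, name: str) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(name=name, data=np.asarray(img.get_fdata()) > 0.5,
                   affine=np.asarray(img.affine))


def write_mask(mask: ROIMask, path) -> None:
    nib.Nifti1Image(mask.data.astype(np.uint8), np.asarray(mask.affine)).to_filename(
        str(path)
    )
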