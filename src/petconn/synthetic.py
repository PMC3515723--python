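"""Synthetic rCBF study generator with fully known ground truth.

Emits a complete desk-scale study — region masks, per-scan volumes, a scan
manifest, and a clinical score table — from a declarative config. Every
latent quantity injected into the volumes is recorded, so downstream
estimates can be checked against what was actually planted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .roi_signals import RCBFVolume, ROIMask, smooth_data, voxel_sizes, write_mask

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "GroundTruth",
    "CohortResult",
    "default_config",
    "default_regions",
    "default_session_corr",
    "generate_masks",
    "generate_cohort",
    "grid_coordinates_mm",
]

#: combined-condition inter-region correlation structure used as the default
#: generative truth for the three sessions (regions ordered as DEFAULT_REGION_ORDER)
DEFAULT_REGION_ORDER = ("MFC", "LNAcc", "RNAcc", "LHIP", "RHIP")

_DEFAULT_CORR = {
    "baseline": [
        [1.000, 0.339, -0.018, 0.344, 0.477],
        [0.339, 1.000, 0.262, 0.304, 0.092],
        [-0.018, 0.262, 1.000, -0.115, -0.277],
        [0.344, 0.304, -0.115, 1.000, 0.740],
        [0.477, 0.092, -0.277, 0.740, 1.000],
    ],
    "week1": [
        [1.000, 0.573, 0.023, 0.329, 0.056],
        [0.573, 1.000, 0.249, 0.383, 0.122],
        [0.023, 0.249, 1.000, -0.163, -0.400],
        [0.329, 0.383, -0.163, 1.000, 0.716],
        [0.056, 0.122, -0.400, 0.716, 1.000],
    ],
    "week6": [
        [1.000, 0.222, 0.104, 0.068, -0.126],
        [0.222, 1.000, 0.391, 0.443, 0.096],
        [0.104, 0.391, 1.000, -0.057, -0.553],
        [0.068, 0.443, -0.057, 1.000, 0.666],
        [-0.126, 0.096, -0.553, 0.666, 1.000],
    ],
}


@dataclass(frozen=True)
class RegionSpec:
    """Parametric region: a sphere or axis-aligned box in mm coordinates."""

    name: str
    center_mm: tuple
    extent_mm: float  # radius (sphere) or half-width (box)
    shape: str = "sphere"

    def __post_init__(self):
        if self.shape not in ("sphere", "box"):
            raise ValueError(f"region shape must be 'sphere' or 'box', got {self.shape!r}")
        if self.extent_mm < 0:
            raise ValueError("extent_mm must be >= 0")


def default_regions() -> list[RegionSpec]:
    """Five-region network: one 10-mm medial frontal sphere, bilateral
    accumbens and hippocampus spheres of plausible size."""
    return [
        RegionSpec("MFC", (-1.0, 47.0, -4.0), 10.0),
        RegionSpec("LNAcc", (-10.0, 10.0, -8.0), 6.0),
        RegionSpec("RNAcc", (10.0, 10.0, -8.0), 6.0),
        RegionSpec("LHIP", (-28.0, -20.0, -14.0), 8.0),
        RegionSpec("RHIP", (28.0, -20.0, -14.0), 8.0),
    ]


def default_session_corr() -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in _DEFAULT_CORR.items()}


def _default_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    # RAS grid positioned so MNI (0,0,0) sits at an interior voxel and the
    # default region set (frontal sphere up to y=57) stays inside
    origin_voxel = np.array([g // 2 for g in grid_shape], dtype=float)
    origin_voxel[1] = round(grid_shape[1] * 0.45)
    aff[:3, 3] = -voxel_size_mm * origin_voxel
    return aff


@dataclass
class SyntheticConfig:
    grid_shape: tuple = (48, 56, 48)
    voxel_size_mm: float = 2.0
    affine: np.ndarray | None = None
    regions: list[RegionSpec] = field(default_factory=default_regions)
    brain_center_mm: tuple = (0.0, 5.0, -5.0)
    brain_semiaxes_mm: tuple = (44.0, 54.0, 42.0)
    session_edge_corr: dict = field(default_factory=default_session_corr)
    global_sd: float = 1.0
    noise_sd: float = 0.5
    smooth_fwhm_mm: float = 0.0
    n_participants: int = 29
    sessions: tuple = ("baseline", "week1", "week6")
    conditions: tuple = ("rest", "SMC", "DEC")
    replicates_per_condition: int = 2
    response_edge: tuple = ("MFC", "LHIP")
    response_session: str = "week1"
    response_effect: float = 0.0
    response_intercept: float = 5.0
    response_noise_sd: float = 1.0
    bprs_baseline_mean: float = 12.0
    bprs_baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.affine is None:
            self.affine = _default_affine(self.grid_shape, self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        self.validate()

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def validate(self) -> None:
        k = len(self.regions)
        names = self.region_names
        if len(set(names)) != k:
            raise ValueError("region names must be unique")
        if set(self.session_edge_corr) != set(self.sessions):
            raise ValueError("session_edge_corr must have one matrix per session")
        for sess, mat in self.session_edge_corr.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (k, k):
                raise ValueError(f"correlation matrix for {sess!r} must be {k}x{k}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"correlation matrix for {sess!r} is not symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"correlation matrix for {sess!r} must have unit diagonal")
            try:
                np.linalg.cholesky(mat)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"correlation matrix for {sess!r} is not positive definite"
                ) from None
        for name in self.response_edge:
            if name not in names:
                raise ValueError(f"response_edge region {name!r} not in regions")
        if self.response_session not in self.sessions:
            raise ValueError(f"response_session {self.response_session!r} not in sessions")
        if self.global_sd < 0 or self.noise_sd < 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("standard deviations and smoothing FWHM must be >= 0")


@dataclass
class GroundTruth:
    """Everything that was actually injected, for downstream verification."""

    latent_signals: pd.DataFrame  # one row per scan: unit keys, region latents, global g
    true_edge_corr: dict
    true_response_slope: float
    per_participant_scores: pd.DataFrame
    edge_products: pd.Series  # per-participant mean planted edge signal product


@dataclass
class CohortResult:
    volumes: dict  # (participant, session, condition, replicate) -> RCBFVolume
    manifest: pd.DataFrame
    clinical: pd.DataFrame
    masks: list[ROIMask]  # region masks in config order, whole-brain mask last
    ground_truth: GroundTruth


def grid_coordinates_mm(grid_shape, affine) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-center mm coordinates."""
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return (vox @ np.asarray(affine).T)[..., :3]


def _region_mask(region: RegionSpec, coords: np.ndarray) -> np.ndarray:
    delta = coords - np.asarray(region.center_mm)
    if region.shape == "sphere":
        return (delta ** 2).sum(axis=-1) <= region.extent_mm ** 2
    return (np.abs(delta) <= region.extent_mm).all(axis=-1)


def _check_region_in_grid(region: RegionSpec, coords: np.ndarray) -> None:
    lo = coords.reshape(-1, 3).min(axis=0)
    hi = coords.reshape(-1, 3).max(axis=0)
    c = np.asarray(region.center_mm)
    if ((c - region.extent_mm) < lo - 1e-9).any() or ((c + region.extent_mm) > hi + 1e-9).any():
        raise ValueError(
            f"region {region.name!r} (center {region.center_mm}, extent "
            f"{region.extent_mm} mm) does not fit inside the grid "
            f"[{lo.round(1)}, {hi.round(1)}] mm"
        )


def generate_masks(config: SyntheticConfig) -> list[ROIMask]:
    """One mask per region spec plus a whole-brain ellipsoid mask (last)."""
    coords = grid_coordinates_mm(config.grid_shape, config.affine)
    masks = []
    for region in config.regions:
        _check_region_in_grid(region, coords)
        data = _region_mask(region, coords)
        if not data.any():
            raise ValueError(f"region {region.name!r} covers no voxel centers")
        masks.append(
            ROIMask(
                name=region.name, data=data, affine=config.affine,
                provenance=f"{region.shape} {region.extent_mm} mm at {region.center_mm}",
            )
        )
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if (a.data & b.data).any():
                raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")
    delta = (coords - np.asarray(config.brain_center_mm)) / np.asarray(
        config.brain_semiaxes_mm
    )
    brain = (delta ** 2).sum(axis=-1) <= 1.0
    masks.append(
        ROIMask(
            name="whole_brain", data=brain, affine=config.affine,
            provenance=f"ellipsoid semiaxes {config.brain_semiaxes_mm} mm "
                       f"at {config.brain_center_mm}",
        )
    )
    return masks


def _scan_keys(config: SyntheticConfig):
    width = max(2, len(str(config.n_participants)))
    for p in range(1, config.n_participants + 1):
        pid = f"sub{p:0{width}d}"
        for sess in config.sessions:
            for cond in config.conditions:
                for rep in range(1, config.replicates_per_condition + 1):
                    yield (pid, sess, cond, rep)


def generate_cohort(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Draw the full synthetic study.

    Each scan volume is a sum of per-region latent levels painted onto the
    region masks, a scan-wide global level painted onto the brain mask, and
    iid voxel noise, optionally smoothed. Scan latents are zero-mean
    unit-variance multivariate normal with the session's inter-region
    correlation matrix; scans are exchangeable draws within a session.

    The clinical table plants ``response = intercept + response_effect * m_p
    + noise`` where ``m_p`` is participant *p*'s mean product of the two
    ``response_edge`` latents over scans of ``response_session``.

    With ``out_dir`` set, volumes are written as float32 NIfTI-1 (.nii.gz),
    masks as NIfTI, and the manifest/clinical tables as TSV; outputs are
    byte-identical for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    masks = generate_masks(config)
    region_masks, brain_mask = masks[:-1], masks[-1]
    chol = {
        s: np.linalg.cholesky(np.asarray(config.session_edge_corr[s], dtype=float))
        for s in config.sessions
    }

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)
        for m in masks:
            write_mask(m, out_dir / "masks" / f"{m.name}.nii.gz")

    volumes: dict = {}
    manifest_rows = []
    latent_rows = []
    for key in _scan_keys(config):
        pid, sess, cond, rep = key
        latents = chol[sess] @ rng.standard_normal(len(config.regions))
        g = rng.normal(0.0, config.global_sd) if config.global_sd > 0 else 0.0
        vol = np.zeros(config.grid_shape, dtype=float)
        for m, lat in zip(region_masks, latents):
            vol[m.data] += lat
        if g != 0.0:
            vol[brain_mask.data] += g
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        if config.smooth_fwhm_mm > 0:
            vol = smooth_data(vol, config.affine, config.smooth_fwhm_mm)
        volumes[key] = RCBFVolume(data=vol, affine=config.affine, scan_key=key)
        path = f"{pid}_{sess}_{cond}_{rep}.nii.gz"
        if out_dir is not None:
            nib.Nifti1Image(vol.astype(np.float32), config.affine).to_filename(
                str(out_dir / path)
            )
        manifest_rows.append(dict(participant=pid, session=sess, condition=cond,
                                  replicate=rep, path=path))
        latent_rows.append(
            dict(participant=pid, session=sess, condition=cond, replicate=rep,
                 **{n: lat for n, lat in zip(config.region_names, latents)},
                 global_signal=g)
        )

    manifest = pd.DataFrame(manifest_rows)
    latent_signals = pd.DataFrame(latent_rows)

    sess_lat = latent_signals[latent_signals["session"] == config.response_session]
    prod = sess_lat[config.response_edge[0]] * sess_lat[config.response_edge[1]]
    edge_products = prod.groupby(sess_lat["participant"]).mean()

    participants = sorted(latent_signals["participant"].unique())
    baseline = rng.normal(config.bprs_baseline_mean, config.bprs_baseline_sd,
                          size=len(participants))
    resp_noise = rng.normal(0.0, config.response_noise_sd, size=len(participants))
    response = (
        config.response_intercept
        + config.response_effect * edge_products.reindex(participants).to_numpy()
        + resp_noise
    )
    clinical = pd.DataFrame(
        dict(
            participant=participants,
            bprs_psychosis_baseline=np.round(baseline, 4),
            bprs_psychosis_week6=np.round(baseline - response, 4),
        )
    )

    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        clinical.to_csv(out_dir / "clinical.tsv", sep="\t", index=False)

    truth = GroundTruth(
        latent_signals=latent_signals,
        true_edge_corr={s: np.asarray(m, dtype=float)
                        for s, m in config.session_edge_corr.items()},
        true_response_slope=config.response_effect,
        per_participant_scores=clinical,
        edge_products=edge_products,
    )
    return CohortResult(volumes=volumes, manifest=manifest, clinical=clinical,
                        masks=masks, ground_truth=truth)


def default_config(**overrides) -> SyntheticConfig:
    """Study-shaped default config; keyword overrides replace any field."""
    return SyntheticConfig(**overrides)
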