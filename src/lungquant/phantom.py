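"""Synthetic thoracic CT phantoms with exact ground-truth label maps.

The phantom is deliberately schematic: a soft-tissue body ellipsoid containing
two lung ellipsoids, with contusion built by accreting random ellipsoidal
blobs (biased toward the posterior, gravity-dependent lung) and pneumothorax
modeled as a pleural crescent of pure air along the anterior lung surface.
Tissue HU values are drawn from truncated normals so no voxel can leak across
the segmentation thresholds — the truth masks are unambiguous by
construction.

Only the normal-lung HU window (−950…−450) is anchored to published practice;
the remaining tissue distributions are conventional radiology ranges and are
configurable through ``hu_model``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .ct_io import CTVolume, MaskVolume
from .errors import ConfigError

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "phantom_suite",
           "DEFAULT_HU_MODEL"]

# tissue -> (mean, sd, lower, upper) in HU
DEFAULT_HU_MODEL: dict[str, tuple[float, float, float, float]] = {
    "background_air": (-1000.0, 5.0, -1024.0, -980.0),
    "soft_tissue": (40.0, 10.0, 0.0, 80.0),
    "normal_lung": (-750.0, 60.0, -949.0, -451.0),
    "ggo": (-300.0, 80.0, -449.0, -100.0),
    "consolidation": (20.0, 30.0, -99.0, 200.0),
    "pleural_air": (-990.0, 8.0, -1024.0, -951.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration for one synthetic phantom."""

    shape: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)
    target_contusion_fraction: float = 0.0  # % of total lung volume
    pneumothorax_fraction: float = 0.0  # % of total lung volume
    contusion_texture: str = "ggo"  # or "ggo+consolidation"
    hu_model: dict = field(default_factory=lambda: dict(DEFAULT_HU_MODEL))
    airway: bool = True
    seed: int = 0

    def __post_init__(self):
        if tuple(self.shape) < (32, 64, 64) or len(self.shape) != 3:
            raise ConfigError(f"grid {self.shape} below minimum (32, 64, 64)")
        if not 0 <= self.target_contusion_fraction <= 100:
            raise ConfigError("target_contusion_fraction must be in [0, 100]")
        if not 0 <= self.pneumothorax_fraction <= 50:
            raise ConfigError("pneumothorax_fraction must be in [0, 50]")
        if self.contusion_texture not in ("ggo", "ggo+consolidation"):
            raise ConfigError(f"unknown contusion_texture {self.contusion_texture!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class PhantomTruth:
    """Generated CT plus exact truth masks and achieved fractions (%)."""

    ct: CTVolume
    total_lung: MaskVolume
    normal_lung: MaskVolume
    contusion: MaskVolume
    pneumothorax: MaskVolume
    achieved_contusion_fraction: float
    achieved_pneumothorax_fraction: float
    config: PhantomConfig


def _ellipsoid_r2(shape, center, semi):
    """Squared normalized ellipsoid radius field (r2 <= 1 is inside)."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )


def _sample_hu(rng, params, size):
    mean, sd, lo, hi = params
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build a phantom CT and its truth partition.

    The contusion and pneumothorax masks hit their target voxel counts
    exactly (well within the ±1 percentage-point contract); a
    :class:`~lungquant.errors.ConfigError` reports the best achievable
    fraction when the target cannot be met.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    cz, cy, cx = nz / 2, ny / 2, nx / 2

    body_r2 = _ellipsoid_r2(config.shape, (cz, cy, cx), (0.48 * nz, 0.42 * ny, 0.45 * nx))
    body = body_r2 <= 1.0

    lung_semi = (0.36 * nz, 0.28 * ny, 0.17 * nx)
    lung_centers = [(cz, cy, cx - 0.22 * nx), (cz, cy, cx + 0.22 * nx)]
    lung_r2 = [_ellipsoid_r2(config.shape, c, lung_semi) for c in lung_centers]
    lungs = (lung_r2[0] <= 1.0) | (lung_r2[1] <= 1.0)
    lungs &= body
    n_lung = int(lungs.sum())

    # --- pneumothorax: anterior pleural crescent of the right (x-low) lung ---
    n_ptx_target = int(round(config.pneumothorax_fraction / 100.0 * n_lung))
    ptx = np.zeros(config.shape, dtype=bool)
    if n_ptx_target > 0:
        # spherical-cap air pocket at the anterior pleural surface of the
        # right (x-low) lung: thick in the middle, as a loculated
        # pneumothorax is, so it survives mean-filter smoothing
        right_lung = (lung_r2[0] <= 1.0) & lungs
        if right_lung.sum() < n_ptx_target:
            best = 100.0 * right_lung.sum() / n_lung
            raise ConfigError(
                f"pneumothorax fraction {config.pneumothorax_fraction}% unreachable; "
                f"best achievable ≈ {best:.1f}%"
            )
        pole = (cz, lung_centers[0][1] - lung_semi[1], lung_centers[0][2])
        zz, yy, xx = np.ogrid[: config.shape[0], : config.shape[1], : config.shape[2]]
        d2 = (zz - pole[0]) ** 2 + (yy - pole[1]) ** 2 + (xx - pole[2]) ** 2
        idx = np.flatnonzero(right_lung)
        order = np.argsort(d2.ravel()[idx], kind="stable")
        ptx.ravel()[idx[order[:n_ptx_target]]] = True

    # --- contusion: accreted random ellipsoid blobs, posterior bias ---
    n_cont_target = int(round(config.target_contusion_fraction / 100.0 * n_lung))
    available = lungs & ~ptx
    if n_cont_target > int(available.sum()):
        best = 100.0 * available.sum() / n_lung
        raise ConfigError(
            f"contusion fraction {config.target_contusion_fraction}% unreachable "
            f"with {config.pneumothorax_fraction}% pneumothorax; "
            f"best achievable ≈ {best:.1f}%"
        )
    contusion = np.zeros(config.shape, dtype=bool)
    n_cont = 0
    attempts = 0
    while n_cont < n_cont_target:
        attempts += 1
        if attempts > 1000:
            raise ConfigError(
                "contusion accretion did not converge; "
                f"achieved {100.0 * n_cont / n_lung:.1f}% of "
                f"{config.target_contusion_fraction}% target"
            )
        free = available & ~contusion
        free_idx = np.flatnonzero(free)
        if free_idx.size == 0:
            break
        # posterior (high-y) gravity bias on the seed voxel
        ys = (free_idx // nx) % ny
        weights = (ys + 1.0) ** 2
        weights /= weights.sum()
        seed_flat = rng.choice(free_idx, p=weights)
        center = np.unravel_index(seed_flat, config.shape)
        semi = (
            rng.uniform(0.04, 0.12) * nz,
            rng.uniform(0.06, 0.16) * ny,
            rng.uniform(0.06, 0.16) * nx,
        )
        blob_r2 = _ellipsoid_r2(config.shape, center, semi)
        new = (blob_r2 <= 1.0) & free
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if n_cont + n_new > n_cont_target:
            # partial blob: innermost voxels first, for a compact remainder
            need = n_cont_target - n_cont
            new_idx = np.flatnonzero(new)
            order = np.argsort(blob_r2.ravel()[new_idx], kind="stable")
            sel = np.zeros(config.shape, dtype=bool)
            sel.ravel()[new_idx[order[:need]]] = True
            new = sel
            n_new = need
        contusion |= new
        n_cont += n_new

    normal = lungs & ~contusion & ~ptx

    # --- optional central airway: pure-air tube reaching the top face ---
    airway = np.zeros(config.shape, dtype=bool)
    if config.airway:
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        # anterior mediastinal tube, kept > 2x closing radius clear of the lungs
        tube = ((yy - 0.2 * ny) ** 2 + (xx - cx) ** 2) <= 4.0**2
        airway = (tube & (zz < 0.55 * nz)) & ~lungs

    # --- HU synthesis ---
    hu = np.empty(config.shape, dtype=np.float32)
    model = config.hu_model
    hu[:] = _sample_hu(rng, model["background_air"], hu.size).reshape(config.shape)
    region = body & ~lungs & ~airway
    hu[region] = _sample_hu(rng, model["soft_tissue"], int(region.sum()))
    hu[normal] = _sample_hu(rng, model["normal_lung"], int(normal.sum()))
    hu[contusion] = _sample_hu(rng, model["ggo"], int(contusion.sum()))
    if config.contusion_texture == "ggo+consolidation" and contusion.any():
        core = ndimage.binary_erosion(contusion, iterations=2)
        if core.any():
            hu[core] = _sample_hu(rng, model["consolidation"], int(core.sum()))
    if ptx.any():
        hu[ptx] = _sample_hu(rng, model["pleural_air"], int(ptx.sum()))
    if airway.any():
        hu[airway] = _sample_hu(rng, model["pleural_air"], int(airway.sum()))

    spacing = config.spacing
    ct = CTVolume(hu, spacing)
    return PhantomTruth(
        ct=ct,
        total_lung=MaskVolume(lungs, spacing),
        normal_lung=MaskVolume(normal, spacing),
        contusion=MaskVolume(contusion, spacing),
        pneumothorax=MaskVolume(ptx, spacing),
        achieved_contusion_fraction=100.0 * n_cont / n_lung,
        achieved_pneumothorax_fraction=100.0 * n_ptx_target / n_lung,
        config=config,
    )


def phantom_suite(seeds, fractions, base: PhantomConfig | None = None):
    """Cartesian product of seeds × contusion fractions → list of phantoms."""
    base = base if base is not None else PhantomConfig()
    out = []
    for seed in seeds:
        for frac in fractions:
            cfg = replace(base, seed=int(seed), target_contusion_fraction=float(frac))
            out.append(generate_phantom(cfg))
    return out
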