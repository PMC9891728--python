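"""Synthetic scenes with known ground truth.

Three generators emulate the statistical structure of the study's data:

* two-channel punctate 3-D stacks (junctional protein clusters that are
  colocalized, displaced by a known vector, or dispersed), blurred by a
  Gaussian PSF and corrupted by Poisson + Gaussian noise;
* stacks with ellipsoidal nuclei and a known nuclear import fraction of
  the signal, plus a nuclear-marker channel;
* immunoblot lane images: one or two Gaussian bands on a sloped baseline.

Every generator records the ground truth needed to score recovery of the
downstream measures.  Identical parameters and seed give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stack_io import ChannelStack

SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this

#: log-normal spread of punctum amplitudes (heterogeneous staining)
AMPLITUDE_SIGMA_LOG = 0.3


@dataclass
class SceneParams:
    """Parameters of a two-channel punctate scene.

    Geometry defaults follow the imaging protocol the generator emulates:
    60 nm x-y pixels, 120 nm z steps, PSF FWHM 350 nm laterally and
    480 nm axially.  The default grid is 256 x 256 x 20 voxels
    (15.4 x 15.4 x 2.4 um).
    """

    grid_shape: tuple[int, int, int] = (256, 256, 20)   # (x, y, z) voxels
    voxel_size: tuple[float, float, float] = (60.0, 60.0, 120.0)  # nm
    n_puncta: int = 150
    coloc_fraction: float = 1.0
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)  # nm, (x, y, z)
    displacement_mode: str = "all"        # "all" or "noncoloc"
    dispersal_sd: float = 0.0             # nm, isotropic jitter
    psf_fwhm: tuple[float, float] = (350.0, 480.0)      # nm (lateral, axial)
    photon_scale: float = 200.0           # expected peak photons per punctum
    read_noise_sd: float = 2.0            # counts
    background: float = 10.0              # counts
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.grid_shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("grid_shape and voxel_size entries must be positive")
        if self.displacement_mode not in ("all", "noncoloc"):
            raise ValueError("displacement_mode must be 'all' or 'noncoloc'")
        if self.dispersal_sd < 0 or self.photon_scale <= 0:
            raise ValueError("dispersal_sd must be >= 0 and photon_scale > 0")

    @property
    def sigma_nm(self) -> tuple[float, float, float]:
        lat, ax = self.psf_fwhm
        s = SIGMA_PER_FWHM
        return (lat * s, lat * s, ax * s)

    @property
    def sigma_px_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.sigma_nm
        dx, dy, dz = self.voxel_size
        return (sz / dz, sy / dy, sx / dx)


@dataclass
class GroundTruth:
    """Everything needed to recompute recovery metrics for a scene."""

    seed: int
    coords_a_nm: np.ndarray | None = None     # (n, 3) in (x, y, z) nm
    coords_b_nm: np.ndarray | None = None
    amplitudes: np.ndarray | None = None      # photon mass per punctum
    displacement_nm: tuple[float, float, float] | None = None
    coloc_fraction: float | None = None
    nuclear_mask: np.ndarray | None = None    # (z, y, x) bool
    import_fraction: float | None = None
    nuclear_volume_vox: int | None = None
    cytosolic_volume_vox: int | None = None
    band_centers: list[float] = field(default_factory=list)
    band_sigmas: list[float] = field(default_factory=list)
    band_areas: list[float] = field(default_factory=list)
    baseline: tuple[float, float] | None = None

    def expected_density_ratio(self, orientation: str = "nc") -> float:
        """Closed-form nuclear/cytosolic density ratio implied by placement."""
        f, vn, vc = self.import_fraction, self.nuclear_volume_vox, self.cytosolic_volume_vox
        if f is None or not vn or not vc:
            raise ValueError("not a nuclear scene")
        nuc = f / vn
        cyt = (1.0 - f) / vc
        if orientation == "nc":
            return nuc / cyt
        if orientation == "cn":
            return cyt / nuc
        raise ValueError("orientation must be 'nc' or 'cn'")

    def to_json(self, path: str | Path) -> Path:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        path = Path(path)
        path.write_text(json.dumps(d, indent=1))
        return path


def _render(coords_nm: np.ndarray, amplitudes: np.ndarray,
            params: SceneParams) -> np.ndarray:
    """Deposit delta impulses with trilinear weights, then Gaussian-blur.

    Blur is normalized, so the total expected photon mass equals the sum
    of punctum amplitudes (up to boundary truncation, which punctum
    placement margins keep below 0.1%).
    """
    nx, ny, nz = params.grid_shape
    field_zyx = np.zeros((nz, ny, nx), dtype=np.float64)
    dx, dy, dz = params.voxel_size
    # voxel-centred index coordinates, order (z, y, x)
    pos = np.column_stack([coords_nm[:, 2] / dz, coords_nm[:, 1] / dy,
                           coords_nm[:, 0] / dx])
    base = np.floor(pos).astype(int)
    frac = pos - base
    for corner in np.ndindex(2, 2, 2):
        off = np.array(corner)
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        idx = base + off
        ok = np.all((idx >= 0) & (idx < [nz, ny, nx]), axis=1)
        np.add.at(field_zyx, tuple(idx[ok].T), amplitudes[ok] * w[ok])
    ndimage.gaussian_filter(field_zyx, sigma=params.sigma_px_zyx,
                            output=field_zyx, mode="constant")
    return field_zyx


def _add_noise(expected: np.ndarray, params: SceneParams,
               rng: np.random.Generator) -> np.ndarray:
    img = expected + params.background
    if params.poisson_noise:
        img = rng.poisson(img).astype(np.float64)
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def make_coloc_stack(params: SceneParams) -> tuple[ChannelStack, ChannelStack, GroundTruth]:
    """Generate a two-channel punctate scene with known colocalization.

    Channel A holds ``n_puncta`` blurred puncta.  Channel B repeats the
    scene: a fraction ``coloc_fraction`` of its puncta sit exactly on the
    A positions; the displacement vector and isotropic dispersal jitter
    are applied to all B puncta (``displacement_mode="all"``) or only to
    the non-colocalized complement (``"noncoloc"``).
    """
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.grid_shape
    dx, dy, dz = params.voxel_size
    extent = np.array([nx * dx, ny * dy, nz * dz])

    disp = np.asarray(params.displacement, dtype=float)
    if np.any(np.abs(disp) > extent / 2.0):
        raise ValueError("displacement exceeds half the grid extent")

    # margin keeps blurred mass inside the grid (4 sigma + displacement);
    # dispersal jitter may push the odd punctum off-grid, which is
    # physical (it left the field) and negligible for the statistics
    sig = np.array(params.sigma_nm)
    margin = 4.0 * sig + np.abs(disp)
    lo, hi = margin, extent - margin
    if np.any(hi <= lo):
        raise ValueError("grid too small for PSF margin and displacement")
    coords_a = rng.uniform(lo, hi, size=(params.n_puncta, 3))
    amplitudes = np.exp(rng.normal(0.0, AMPLITUDE_SIGMA_LOG, params.n_puncta))

    # scale so a unit-amplitude punctum peaks near photon_scale counts
    peak_density = np.prod(1.0 / (np.sqrt(2.0 * np.pi) * np.array(params.sigma_px_zyx)))
    mass_unit = params.photon_scale / peak_density
    amplitudes = amplitudes * mass_unit

    n_coloc = int(round(params.coloc_fraction * params.n_puncta))
    coords_b = coords_a.copy()
    moved = np.zeros(params.n_puncta, dtype=bool)
    if params.displacement_mode == "all":
        moved[:] = True
    else:
        moved[n_coloc:] = True
    coords_b[moved] += disp
    if params.dispersal_sd > 0:
        jitter_set = moved if params.displacement_mode == "noncoloc" else slice(None)
        coords_b[jitter_set] = coords_b[jitter_set] + rng.normal(
            0.0, params.dispersal_sd, size=np.shape(coords_b[jitter_set]))

    exp_a = _render(coords_a, amplitudes, params)
    exp_b = _render(coords_b, amplitudes, params)
    a = ChannelStack(_add_noise(exp_a, params, rng), params.voxel_size, "chA")
    b = ChannelStack(_add_noise(exp_b, params, rng), params.voxel_size, "chB")
    truth = GroundTruth(seed=params.seed, coords_a_nm=coords_a, coords_b_nm=coords_b,
                        amplitudes=amplitudes, displacement_nm=tuple(disp),
                        coloc_fraction=params.coloc_fraction)
    return a, b, truth


def expected_fields(params: SceneParams) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Noise-free expected photon fields (no background), for invariants."""
    noiseless = SceneParams(**{**asdict(params), "poisson_noise": False,
                               "read_noise_sd": 0.0, "background": 0.0})
    a, b, truth = make_coloc_stack(noiseless)
    return a.data, b.data, truth


def make_nuclear_stack(params: SceneParams, n_nuclei: int = 3,
                       import_fraction: float = 0.5,
                       semi_axes_nm: tuple[float, float, float] = (1500.0, 1200.0, 800.0),
                       apply_blur: bool = False,
                       max_retries: int = 200,
                       ) -> tuple[ChannelStack, ChannelStack, GroundTruth]:
    """Generate a signal channel with a known nuclear import fraction.

    Ellipsoidal nuclei (axis-aligned, semi-axes in nm) are placed without
    overlap; ``import_fraction`` of the total signal mass is spread
    uniformly over nuclear voxels and the remainder uniformly outside.
    The marker channel labels nuclei only.  PSF blur is off by default:
    the quantity under test is a region-density ratio, and blur would
    move mass across the nuclear boundary, detaching the scene from its
    closed-form ratio.
    """
    if not 0.0 <= import_fraction <= 1.0:
        raise ValueError("import_fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.grid_shape
    dx, dy, dz = params.voxel_size
    ax_nm = np.asarray(semi_axes_nm, dtype=float)
    semi_vox = ax_nm / np.array([dx, dy, dz])  # (x, y, z) in voxels
    if np.any(2 * semi_vox >= [nx, ny, nz]):
        raise ValueError("nuclei do not fit inside the grid")

    # sufficient non-overlap condition for identical axis-aligned
    # ellipsoids: per-axis-scaled centre distance above 2; the extra 0.4
    # leaves a resolvable gap so downstream segmentation sees separate
    # components after blurring
    centers: list[np.ndarray] = []
    for _restart in range(max_retries):
        centers = []
        for _ in range(n_nuclei):
            for _attempt in range(50):
                c = rng.uniform(ax_nm, [nx * dx, ny * dy, nz * dz] - ax_nm)
                if all(np.linalg.norm((c - p) / ax_nm) > 2.4 for p in centers):
                    centers.append(c)
                    break
            else:
                break  # greedy placement stuck: restart the configuration
        if len(centers) == n_nuclei:
            break
    else:
        raise RuntimeError("could not place non-overlapping nuclei")

    zz, yy, xx = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                             np.arange(nx) * dx, indexing="ij")
    nuclear = np.zeros((nz, ny, nx), dtype=bool)
    for c in centers:
        nuclear |= (((xx - c[0]) / ax_nm[0]) ** 2 + ((yy - c[1]) / ax_nm[1]) ** 2
                    + ((zz - c[2]) / ax_nm[2]) ** 2) <= 1.0

    v_nuc = int(nuclear.sum())
    v_cyt = int((~nuclear).sum())
    total_mass = params.photon_scale * nuclear.size / 10.0  # comfortable dynamic range
    expected = np.empty((nz, ny, nx), dtype=np.float64)
    expected[nuclear] = import_fraction * total_mass / v_nuc
    expected[~nuclear] = (1.0 - import_fraction) * total_mass / v_cyt
    if apply_blur:
        ndimage.gaussian_filter(expected, sigma=params.sigma_px_zyx,
                                output=expected, mode="nearest")
    marker_expected = np.where(nuclear, params.photon_scale, 0.0)

    signal = ChannelStack(_add_noise(expected, params, rng), params.voxel_size, "signal")
    marker = ChannelStack(_add_noise(marker_expected, params, rng), params.voxel_size, "nuclei")
    truth = GroundTruth(seed=params.seed, nuclear_mask=nuclear,
                        import_fraction=import_fraction,
                        nuclear_volume_vox=v_nuc, cytosolic_volume_vox=v_cyt)
    return signal, marker, truth


def make_blot(bands: list[tuple[float, float, float]],
              baseline: tuple[float, float] = (50.0, 0.0),
              noise_sd: float = 0.0,
              seed: int = 0,
              length: int = 400,
              width: int = 60) -> tuple[np.ndarray, GroundTruth]:
    """Generate a lane image: Gaussian bands on a linear baseline.

    Parameters
    ----------
    bands : list of (center_px, sigma_px, area)
        Each band contributes ``area * N(x; center, sigma)`` to the axial
        profile, so ``area`` is its integrated signal mass per row.
    baseline : (intercept, slope)
        Linear baseline in counts (slope per px).
    noise_sd : float
        Gaussian pixel noise, counts.

    Returns the 2-D lane image (axial position along axis 0, lane width
    along axis 1) and the generating truth.
    """
    for c, s, a in bands:
        if s <= 0:
            raise ValueError("band sigma must be positive")
        if a < 0:
            raise ValueError("band area must be non-negative")
        if not 0 <= c < length:
            raise ValueError("band center outside the lane")
    rng = np.random.default_rng(seed)
    x = np.arange(length, dtype=np.float64)
    profile = baseline[0] + baseline[1] * x
    for c, s, a in bands:
        profile = profile + a / (np.sqrt(2.0 * np.pi) * s) * np.exp(-0.5 * ((x - c) / s) ** 2)
    image = np.tile(profile[:, None], (1, width))
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    truth = GroundTruth(seed=seed, band_centers=[b[0] for b in bands],
                        band_sigmas=[b[1] for b in bands],
                        band_areas=[b[2] for b in bands], baseline=tuple(baseline))
    return image, truth
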