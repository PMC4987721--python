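"""Seeded synthetic microscopy data with ground truth.

Generators emulating the three experimental arms:

- per-well focal-adhesion images (nuclei + paxillin + vinculin channels)
  whose adhesion-size distributions shift across the DMSO / nocodazole /
  washout conditions,
- time-lapse nuclei movies of migrating cells with a stimulation-induced
  speed change,
- micropillar-array movies: a hexagonal lattice of blurred discs whose
  cell-coupled pillars follow a 2-D Ornstein–Uhlenbeck deflection
  process, plus an actin channel carrying the cell footprint.

Every generator is driven by a single integer seed and returns the
rendered arrays together with a ground-truth table, so downstream
segmentation, tracking and statistics can be validated against known
truth.  The same seed and config give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "FaImageConfig",
    "MigrationSimConfig",
    "PillarSimConfig",
    "FaImageSet",
    "ScreenDataset",
    "MigrationMovie",
    "PillarMovie",
    "generate_fa_image",
    "generate_screen_dataset",
    "generate_migration_movie",
    "generate_pillar_movie",
    "generate_pillar_localization_set",
    "planted_category",
    "CONDITIONS",
]

CONDITIONS = ("DMSO", "nocodazole", "washout")

# multipliers (DMSO, nocodazole, washout) of a normally responding cell:
# nocodazole enlarges adhesions ~1.6-fold, washout returns them near baseline
NORMAL_RESPONSE = (1.0, 1.6, 1.1)


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FaImageConfig:
    """One synthetic focal-adhesion field of view.

    ``size_lognormal_mu_sigma`` parameterizes the log-normal of true
    adhesion areas in log μm²; ``condition_size_multiplier`` scales the
    drawn areas (>1 mimics nocodazole-induced assembly, <1 disassembly)
    without touching positions, so paired conditions share geometry.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.339
    n_cells: int = 8
    adhesions_per_cell: int = 25
    size_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.5)
    condition_size_multiplier: float = 1.0
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.condition_size_multiplier <= 0:
            raise ValueError("condition_size_multiplier must be positive")
        if min(self.image_size_px) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0 or self.adhesions_per_cell < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MigrationSimConfig:
    """Time-lapse movie of migrating cells with a speed switch.

    Cells perform a persistent random walk at ``speed_pre_um_min`` until
    ``pre_stim_frames`` and at ``speed_post_um_min`` afterwards (the
    growth-factor stimulation).  Frames are 10–14 min apart in the
    emulated assay; default 10 min.
    """

    n_cells: int = 30
    n_frames: int = 60
    frame_interval_min: float = 10.0
    pre_stim_frames: int = 18
    speed_pre_um_min: float = 0.2
    speed_post_um_min: float = 0.5
    position_noise_um: float = 0.3
    heading_sd_rad: float = 0.35
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.64
    nucleus_sigma_um: float = 4.0
    snr: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= self.pre_stim_frames:
            raise ValueError("n_frames must exceed pre_stim_frames")
        if self.speed_pre_um_min < 0 or self.speed_post_um_min < 0:
            raise ValueError("speeds must be non-negative")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")


@dataclass(frozen=True)
class PillarSimConfig:
    """Micropillar-array movie with Ornstein–Uhlenbeck deflections.

    Pillars sit on a hexagonal lattice (default 4 μm pitch).  Pillars
    under the elliptical cell footprint follow a stationary 2-D OU
    process with per-component sd ``ou_sd_um`` and correlation time
    ``ou_tau_min``; the rest stay at their lattice positions.  Pillar
    tops are rendered as 2-μm discs (Gaussian-blurred edge) at 0.2 μm
    pixels; each pillar-frame is dropped with ``miss_rate`` to emulate
    detection failures.
    """

    grid_pitch_um: float = 4.0
    grid_rotation_deg: float = 0.0
    n_pillars: int = 400
    n_frames: int = 80
    frame_interval_min: float = 5.0
    ou_sd_um: float = 0.3
    ou_tau_min: float = 30.0
    detection_noise_um: float = 0.02
    miss_rate: float = 0.0
    cell_footprint_frac: float = 0.35
    pillar_diameter_um: float = 2.0
    pixel_size_um: float = 0.2
    blur_sigma_um: float = 0.3
    snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_pitch_um <= 0:
            raise ValueError("grid_pitch_um must be positive")
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must be in [0, 1)")
        if self.ou_tau_min <= 0:
            raise ValueError("ou_tau_min must be positive")
        if self.cell_footprint_frac > 0.5:
            raise ValueError("cell footprint extends outside the field")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class FaImageSet:
    nuclei: np.ndarray
    paxillin: np.ndarray
    vinculin: np.ndarray
    truth: pd.DataFrame          # one row per adhesion
    nuclei_truth: pd.DataFrame   # one row per cell
    config: FaImageConfig


@dataclass
class ScreenDataset:
    wells: pd.DataFrame          # well/gene/condition/replicate bookkeeping
    truth_areas: pd.DataFrame    # per-adhesion true areas with gene/condition
    gene_truth: pd.DataFrame     # per-gene multipliers + planted category
    images: dict = field(default_factory=dict)  # (well_id) -> list[FaImageSet]


@dataclass
class MigrationMovie:
    movie: np.ndarray            # (n_frames, h, w)
    tracks: pd.DataFrame         # cell, frame, x_um, y_um, phase
    speeds: pd.DataFrame         # cell, phase, true_speed_um_min
    config: MigrationSimConfig


@dataclass
class PillarMovie:
    pillar_movie: np.ndarray     # (n_frames, h, w)
    actin_movie: np.ndarray      # (n_frames, h, w)
    pillars: pd.DataFrame        # pillar, i, j, x0_um, y0_um, in_cell
    deflections: np.ndarray      # (n_frames, n_pillars, 2) true δ in μm
    rendered: np.ndarray         # (n_frames, n_pillars) bool
    config: PillarSimConfig

    @property
    def footprint_mask(self) -> np.ndarray:
        cfg = self.config
        h, w = self.pillar_movie.shape[1:]
        yy, xx = np.mgrid[0:h, 0:w] * cfg.pixel_size_um
        cx, cy, rx, ry = self._footprint_um()
        return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    def _footprint_um(self) -> tuple[float, float, float, float]:
        cfg = self.config
        h, w = self.pillar_movie.shape[1:]
        lx, ly = w * cfg.pixel_size_um, h * cfg.pixel_size_um
        return lx / 2, ly / 2, cfg.cell_footprint_frac * lx, cfg.cell_footprint_frac * ly


# --------------------------------------------------------------------------
# rendering helpers
# --------------------------------------------------------------------------

def _apply_noise(clean: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + unit-variance Gaussian read noise.

    ``clean`` is a normalized (peak ~1) intensity field; it is scaled so
    the peak photon count is snr², giving Poisson SNR = snr at the peak.
    """
    photons = np.clip(clean, 0.0, None) * snr**2
    noisy = rng.poisson(photons).astype(np.float32)
    noisy += rng.normal(0.0, 1.0, clean.shape).astype(np.float32)
    return noisy


def _add_gaussian_spot(
    img: np.ndarray,
    cx_px: float,
    cy_px: float,
    sigma_major_px: float,
    sigma_minor_px: float,
    theta_rad: float,
    amplitude: float,
) -> None:
    """Accumulate one anisotropic Gaussian into ``img`` (in place)."""
    h, w = img.shape
    ext = int(math.ceil(4.0 * max(sigma_major_px, sigma_minor_px))) + 1
    x0, x1 = int(cx_px) - ext, int(cx_px) + ext + 1
    y0, y1 = int(cy_px) - ext, int(cy_px) + ext + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx_px
    dy = yy - cy_px
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * (u / sigma_major_px) ** 2 - 0.5 * (v / sigma_minor_px) ** 2
    )


def _add_disc(
    img: np.ndarray,
    cx_px: float,
    cy_px: float,
    radius_px: float,
    edge_sigma_px: float,
    amplitude: float,
) -> None:
    """Soft-edged disc: radial error-function profile, symmetric so that
    intensity-weighted centroids are unbiased estimators of the centre."""
    h, w = img.shape
    ext = int(math.ceil(radius_px + 4.0 * edge_sigma_px)) + 1
    x0, x1 = max(int(cx_px) - ext, 0), min(int(cx_px) + ext + 1, w)
    y0, y1 = max(int(cy_px) - ext, 0), min(int(cy_px) + ext + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx_px, yy - cy_px)
    img[y0:y1, x0:x1] += amplitude * 0.5 * (
        1.0 + erf((radius_px - r) / (math.sqrt(2.0) * edge_sigma_px))
    )


def _place_points(
    rng: np.random.Generator,
    n: int,
    lx: float,
    ly: float,
    min_sep: float,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Random points with a minimum pairwise separation (rejection)."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {n} objects with separation {min_sep} "
                f"in a {lx:.0f}x{ly:.0f} um field"
            )
        p = np.array(
            [rng.uniform(margin, lx - margin), rng.uniform(margin, ly - margin)]
        )
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.asarray(pts).reshape(-1, 2)


# --------------------------------------------------------------------------
# focal-adhesion images
# --------------------------------------------------------------------------

def _sample_fa_geometry(
    cfg: FaImageConfig, rng_geom: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw cell and adhesion geometry (no pixels touched).

    Adhesions live in an annulus near the cell edge with a minimum
    pairwise separation of ``ADHESION_MIN_SEP_UM`` (adhesions are
    discrete, non-overlapping structures); areas are drawn from the
    log-normal and multiplied by ``condition_size_multiplier`` *after*
    drawing, so conditions generated from the same seed share geometry
    and base sizes exactly.
    """
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    lx, ly = w * px, h * px
    rows: list[dict] = []
    cell_rows: list[dict] = []
    if cfg.n_cells == 0:
        return (
            pd.DataFrame(rows, columns=TRUTH_COLUMNS),
            pd.DataFrame(cell_rows, columns=["cell", "x_um", "y_um", "radius_um"]),
        )
    cell_radius_um = min(14.0, 0.45 * min(lx, ly) / max(1.0, math.sqrt(cfg.n_cells)))
    centers = _place_points(
        rng_geom, cfg.n_cells, lx, ly,
        min_sep=1.6 * cell_radius_um, margin=cell_radius_um,
    )
    mu, sigma = cfg.size_lognormal_mu_sigma
    for ci, (cx, cy) in enumerate(centers):
        cell_rows.append({"cell": ci, "x_um": cx, "y_um": cy,
                          "radius_um": cell_radius_um})
        base_areas = rng_geom.lognormal(mu, sigma, cfg.adhesions_per_cell)
        aspects = rng_geom.uniform(1.0, 4.0, cfg.adhesions_per_cell)
        tangent_jitter = rng_geom.normal(0.0, 0.25, cfg.adhesions_per_cell)
        amp_pax = rng_geom.lognormal(0.0, 0.2, cfg.adhesions_per_cell)
        amp_vin = rng_geom.lognormal(0.0, 0.2, cfg.adhesions_per_cell)
        areas = base_areas * cfg.condition_size_multiplier
        placed: list[np.ndarray] = []
        placed_ang: list[float] = []
        tries = 0
        while len(placed) < cfg.adhesions_per_cell and tries < 400 * cfg.adhesions_per_cell:
            tries += 1
            ang = rng_geom.uniform(0.0, 2.0 * math.pi)
            rad = cell_radius_um * rng_geom.uniform(0.6, 0.98)
            p = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
            p[0] = min(max(p[0], 1.0), lx - 1.0)
            p[1] = min(max(p[1], 1.0), ly - 1.0)
            if all(np.linalg.norm(p - q) >= ADHESION_MIN_SEP_UM for q in placed):
                placed.append(p)
                placed_ang.append(ang)
        for ai, (p, ang) in enumerate(zip(placed, placed_ang)):
            rows.append({
                "cell": ci, "adhesion": len(rows),
                "x_um": float(p[0]), "y_um": float(p[1]),
                "area_um2": areas[ai],
                "area_px": areas[ai] / px**2,
                "aspect": aspects[ai],
                "orientation_rad": ang + math.pi / 2.0 + tangent_jitter[ai],
                "amp_paxillin": amp_pax[ai],
                "amp_vinculin": amp_vin[ai],
            })
    return (
        pd.DataFrame(rows, columns=TRUTH_COLUMNS),
        pd.DataFrame(cell_rows, columns=["cell", "x_um", "y_um", "radius_um"]),
    )


TRUTH_COLUMNS = [
    "cell", "adhesion", "x_um", "y_um", "area_um2", "area_px",
    "aspect", "orientation_rad", "amp_paxillin", "amp_vinculin",
]
ADHESION_MIN_SEP_UM = 3.0


def generate_fa_image(config: FaImageConfig) -> FaImageSet:
    """Render one three-channel focal-adhesion field of view.

    Cells are placed with non-overlapping nuclei; each cell carries up
    to ``adhesions_per_cell`` adhesions in an annulus near its edge,
    rendered as anisotropic Gaussian spots (aspect ratio uniform in
    1–4, oriented roughly tangent to the cell border — adhesions are
    peripheral, elongated structures).  Both FA channels share geometry
    with channel-specific intensity jitter; noise is Poisson shot noise
    plus Gaussian read noise set by ``snr``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_geom, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um

    truth, nuclei_truth = _sample_fa_geometry(cfg, rng_geom)

    nuclei = np.zeros((h, w), dtype=np.float64)
    for _, cell in nuclei_truth.iterrows():
        nucleus_sigma_um = 0.28 * cell.radius_um
        _add_gaussian_spot(
            nuclei, cell.x_um / px, cell.y_um / px,
            nucleus_sigma_um / px, nucleus_sigma_um / px, 0.0, 1.0,
        )

    # channel-specific intensity jitter re-renders amplitude-weighted spots
    pax_clean = np.zeros((h, w), dtype=np.float64)
    vin_clean = np.zeros((h, w), dtype=np.float64)
    for _, rrow in truth.iterrows():
        a_um = math.sqrt(rrow.area_um2 * rrow.aspect / math.pi)
        b_um = math.sqrt(rrow.area_um2 / (math.pi * rrow.aspect))
        for img, amp in ((pax_clean, rrow.amp_paxillin), (vin_clean, rrow.amp_vinculin)):
            _add_gaussian_spot(
                img, rrow.x_um / px, rrow.y_um / px,
                max(a_um / 2.0 / px, 0.4), max(b_um / 2.0 / px, 0.4),
                rrow.orientation_rad, amp,
            )

    return FaImageSet(
        nuclei=_apply_noise(nuclei, cfg.snr, rng_noise),
        paxillin=_apply_noise(pax_clean, cfg.snr, rng_noise),
        vinculin=_apply_noise(vin_clean, cfg.snr, rng_noise),
        truth=truth,
        nuclei_truth=nuclei_truth,
        config=cfg,
    )


# --------------------------------------------------------------------------
# screen dataset
# --------------------------------------------------------------------------

def planted_category(multipliers: Sequence[float]) -> str:
    """Ground-truth hit category implied by (DMSO, noco, washout) multipliers.

    Mirrors the hit-calling priority: a baseline size change is an
    increase/decrease hit; otherwise no nocodazole enlargement means
    assembly is blocked; enlargement that fails to reverse on washout
    means disassembly is blocked.
    """
    m_dmso, m_noco, m_wash = multipliers
    if m_dmso >= 1.15:
        return "increase"
    if m_dmso <= 0.87:
        return "decrease"
    if m_noco / m_dmso <= 1.1:
        return "assembly_blocked"
    if m_wash / m_noco >= 0.95:
        return "disassembly_blocked"
    return "none"


def generate_screen_dataset(
    layout: pd.DataFrame,
    effects: Mapping[str, Sequence[float]],
    seed: int = 0,
    images_per_well: int = 4,
    adhesions_per_image: int = 200,
    n_duplicates: int = 2,
    base_config: FaImageConfig | None = None,
    render: bool = False,
) -> ScreenDataset:
    """Generate a plate-format screen with known per-gene effects.

    Parameters
    ----------
    layout : DataFrame
        Columns ``well``, ``gene``, ``is_control``; wells must be unique.
    effects : mapping gene -> (m_dmso, m_noco, m_wash)
        Size multipliers per condition relative to the control baseline.
        Control genes use the normal response (1.0, 1.6, 1.1).
    render : bool
        When True, full images are rendered per well×condition (slow);
        ground-truth areas are generated either way and are identical
        for the same seed.
    """
    if layout["well"].duplicated().any():
        raise ValueError("layout wells must be unique")
    base = base_config or FaImageConfig()
    n_cells = max(3, adhesions_per_image // max(1, base.adhesions_per_cell))
    ss = np.random.SeedSequence(seed)

    gene_rows = []
    for _, row in layout.iterrows():
        gene = row["gene"]
        if row.get("is_control", False):
            mult = NORMAL_RESPONSE
        else:
            if gene not in effects:
                raise ValueError(f"no effect multipliers for gene {gene!r}")
            mult = tuple(float(m) for m in effects[gene])
            if len(mult) != len(CONDITIONS) or any(m <= 0 for m in mult):
                raise ValueError(
                    f"gene {gene!r}: need one positive multiplier per condition "
                    f"{CONDITIONS}"
                )
        gene_rows.append({
            "gene": gene,
            "is_control": bool(row.get("is_control", False)),
            "m_dmso": mult[0], "m_noco": mult[1], "m_wash": mult[2],
            "category": planted_category(mult),
        })
    gene_truth = pd.DataFrame(gene_rows).drop_duplicates("gene").reset_index(drop=True)

    well_rows = []
    area_frames = []
    images: dict[str, list[FaImageSet]] = {}
    child_seeds = iter(ss.spawn(len(layout) * n_duplicates * len(CONDITIONS)))
    for _, row in layout.iterrows():
        gene = row["gene"]
        mult = tuple(
            gene_truth.loc[gene_truth.gene == gene, ["m_dmso", "m_noco", "m_wash"]]
            .iloc[0]
        )
        for rep in range(n_duplicates):
            for cond, m in zip(CONDITIONS, mult):
                child = next(child_seeds)
                well_id = f"{row['well']}_r{rep}_{cond}"
                well_rows.append({
                    "well_id": well_id, "well": row["well"], "gene": gene,
                    "condition": cond, "replicate": rep,
                    "is_control": bool(row.get("is_control", False)),
                })
                sub_seeds = child.spawn(images_per_well)
                sets = []
                for si, sseed in enumerate(sub_seeds):
                    img_seed = int(sseed.generate_state(1)[0] % (2**31))
                    cfg = FaImageConfig(
                        image_size_px=base.image_size_px,
                        pixel_size_um=base.pixel_size_um,
                        n_cells=n_cells,
                        adhesions_per_cell=base.adhesions_per_cell,
                        size_lognormal_mu_sigma=base.size_lognormal_mu_sigma,
                        condition_size_multiplier=float(m),
                        snr=base.snr,
                        seed=img_seed,
                    )
                    if render:
                        img_set = generate_fa_image(cfg)
                        truth = img_set.truth.copy()
                        sets.append(img_set)
                    else:
                        truth = _truth_areas_only(cfg)
                    truth["well_id"] = well_id
                    truth["gene"] = gene
                    truth["condition"] = cond
                    truth["replicate"] = rep
                    truth["image"] = si
                    area_frames.append(truth)
                if render:
                    images[well_id] = sets
    truth_areas = pd.concat(area_frames, ignore_index=True) if area_frames else pd.DataFrame()
    return ScreenDataset(
        wells=pd.DataFrame(well_rows),
        truth_areas=truth_areas,
        gene_truth=gene_truth,
        images=images,
    )


def _truth_areas_only(cfg: FaImageConfig) -> pd.DataFrame:
    """Ground-truth adhesion areas for a config without rendering pixels.

    Runs the same geometry sampler as :func:`generate_fa_image` on the
    same RNG stream, so the areas match a rendered image bit for bit.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_geom = np.random.default_rng(ss.spawn(2)[0])
    truth, _ = _sample_fa_geometry(cfg, rng_geom)
    return truth[["cell", "area_um2", "area_px"]].copy()


# --------------------------------------------------------------------------
# migration movies
# --------------------------------------------------------------------------

def generate_migration_movie(config: MigrationSimConfig) -> MigrationMovie:
    """Persistent-random-walk nuclei movie with a stimulation speed switch.

    Each cell moves a constant step ``speed * frame_interval`` per frame
    along a heading that diffuses with sd ``heading_sd_rad``; the speed
    switches from pre to post at ``pre_stim_frames``.  Nuclei are
    rendered as Gaussian blobs; ``position_noise_um`` jitters the
    rendered (not the true) positions, emulating localization noise.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_geom, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    lx, ly = w * px, h * px
    margin = 4.0 * cfg.nucleus_sigma_um
    min_sep = 6.0 * cfg.nucleus_sigma_um
    start = _place_points(rng_geom, cfg.n_cells, lx, ly, min_sep=min_sep, margin=margin)

    true_pos = np.zeros((cfg.n_frames, cfg.n_cells, 2))
    true_pos[0] = start
    heading = rng_geom.uniform(0.0, 2.0 * math.pi, cfg.n_cells)
    for t in range(1, cfg.n_frames):
        speed = cfg.speed_pre_um_min if t <= cfg.pre_stim_frames else cfg.speed_post_um_min
        step = speed * cfg.frame_interval_min
        heading = heading + rng_geom.normal(0.0, cfg.heading_sd_rad, cfg.n_cells)
        prop = true_pos[t - 1] + step * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        # mirror at the field border so step lengths are preserved
        for axis, hi in ((0, lx - margin), (1, ly - margin)):
            over = prop[:, axis] > hi
            under = prop[:, axis] < margin
            prop[over, axis] = 2 * hi - prop[over, axis]
            prop[under, axis] = 2 * margin - prop[under, axis]
            flipped = over | under
            if axis == 0:
                heading[flipped] = math.pi - heading[flipped]
            else:
                heading[flipped] = -heading[flipped]
        # nuclei exclude each other: push apart pairs closer than 3 sigma
        d_min = 3.0 * cfg.nucleus_sigma_um
        for _ in range(8):
            diff = prop[:, None, :] - prop[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            np.fill_diagonal(dist, np.inf)
            ii, jj = np.where((dist < d_min) & (np.arange(cfg.n_cells)[:, None]
                                                < np.arange(cfg.n_cells)[None, :]))
            if ii.size == 0:
                break
            for a, b in zip(ii, jj):
                v = prop[a] - prop[b]
                nv = np.linalg.norm(v)
                u = v / nv if nv > 1e-9 else np.array([1.0, 0.0])
                push = 0.5 * (d_min - nv)
                prop[a] += push * u
                prop[b] -= push * u
        true_pos[t] = prop

    movie = np.zeros((cfg.n_frames, h, w), dtype=np.float32)
    sigma_px = cfg.nucleus_sigma_um / px
    for t in range(cfg.n_frames):
        clean = np.zeros((h, w))
        jitter = rng_noise.normal(0.0, cfg.position_noise_um, (cfg.n_cells, 2))
        for ci in range(cfg.n_cells):
            x, y = true_pos[t, ci] + jitter[ci]
            _add_gaussian_spot(clean, x / px, y / px, sigma_px, sigma_px, 0.0, 1.0)
        movie[t] = _apply_noise(clean, cfg.snr, rng_noise)

    rows = []
    for ci in range(cfg.n_cells):
        for t in range(cfg.n_frames):
            rows.append({
                "cell": ci, "frame": t,
                "x_um": true_pos[t, ci, 0], "y_um": true_pos[t, ci, 1],
                "phase": "pre" if t <= cfg.pre_stim_frames else "post",
            })
    tracks = pd.DataFrame(rows)

    speed_rows = []
    for ci in range(cfg.n_cells):
        steps = np.linalg.norm(np.diff(true_pos[:, ci, :], axis=0), axis=1)
        pre_steps = steps[: cfg.pre_stim_frames]
        post_steps = steps[cfg.pre_stim_frames:]
        for phase, s in (("pre", pre_steps), ("post", post_steps)):
            speed_rows.append({
                "cell": ci, "phase": phase,
                "true_speed_um_min": float(s.mean() / cfg.frame_interval_min)
                if s.size else 0.0,
            })
    speeds = pd.DataFrame(speed_rows)
    return MigrationMovie(movie=movie, tracks=tracks, speeds=speeds, config=cfg)


# --------------------------------------------------------------------------
# pillar movies
# --------------------------------------------------------------------------

def _hex_lattice(pitch: float, rotation_deg: float, lx: float, ly: float,
                 margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal lattice points covering an lx × ly field (μm)."""
    th = math.radians(rotation_deg)
    a1 = pitch * np.array([math.cos(th), math.sin(th)])
    th2 = th + math.pi / 3.0
    a2 = pitch * np.array([math.cos(th2), math.sin(th2)])
    nmax = int(math.ceil((lx + ly) / pitch)) + 2
    ii, jj = np.mgrid[-nmax : nmax + 1, -nmax : nmax + 1]
    pts = ii[..., None] * a1 + jj[..., None] * a2
    pts = pts.reshape(-1, 2) + np.array([lx / 2.0, ly / 2.0])
    idx = np.column_stack([ii.ravel(), jj.ravel()])
    inside = (
        (pts[:, 0] >= margin) & (pts[:, 0] <= lx - margin)
        & (pts[:, 1] >= margin) & (pts[:, 1] <= ly - margin)
    )
    return pts[inside], idx[inside]


def _ou_series(
    rng: np.random.Generator, n_steps: int, n_series: int,
    sd: float, tau: float, dt: float,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck paths via exact discretization."""
    out = np.zeros((n_steps, n_series))
    if sd == 0:
        return out
    phi = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    out[0] = rng.normal(0.0, sd, n_series)
    for t in range(1, n_steps):
        out[t] = phi * out[t - 1] + rng.normal(0.0, innov_sd, n_series)
    return out


def generate_pillar_movie(config: PillarSimConfig) -> PillarMovie:
    """Two-channel micropillar movie with OU deflections under the cell.

    The field size is chosen so the hexagonal lattice holds roughly
    ``n_pillars`` pillars.  The actin channel is a static soft-edged
    ellipse matching the cell footprint, re-noised per frame.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_dyn, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    px = cfg.pixel_size_um
    cell_area = cfg.grid_pitch_um**2 * math.sqrt(3.0) / 2.0
    side_um = math.sqrt(cfg.n_pillars * cell_area)
    margin = cfg.grid_pitch_um / 2.0
    n_px = int(math.ceil((side_um + 2 * margin) / px))
    lx = ly = n_px * px

    pts, idx = _hex_lattice(cfg.grid_pitch_um, cfg.grid_rotation_deg, lx, ly, margin)
    n = len(pts)
    cx, cy = lx / 2.0, ly / 2.0
    rx = ry = cfg.cell_footprint_frac * lx
    if rx > lx / 2.0 or ry > ly / 2.0:
        raise ValueError("cell footprint extends outside the field")
    in_cell = ((pts[:, 0] - cx) / rx) ** 2 + ((pts[:, 1] - cy) / ry) ** 2 <= 1.0

    defl = np.zeros((cfg.n_frames, n, 2))
    n_in = int(in_cell.sum())
    if n_in:
        dt = cfg.frame_interval_min
        defl[:, in_cell, 0] = _ou_series(rng_dyn, cfg.n_frames, n_in,
                                         cfg.ou_sd_um, cfg.ou_tau_min, dt)
        defl[:, in_cell, 1] = _ou_series(rng_dyn, cfg.n_frames, n_in,
                                         cfg.ou_sd_um, cfg.ou_tau_min, dt)
    rendered = rng_dyn.random((cfg.n_frames, n)) >= cfg.miss_rate

    radius_px = cfg.pillar_diameter_um / 2.0 / px
    blur_px = cfg.blur_sigma_um / px
    pillar_movie = np.zeros((cfg.n_frames, n_px, n_px), dtype=np.float32)
    for t in range(cfg.n_frames):
        clean = np.zeros((n_px, n_px))
        jitter = rng_noise.normal(0.0, cfg.detection_noise_um, (n, 2))
        pos = pts + defl[t] + jitter
        for pi in range(n):
            if not rendered[t, pi]:
                continue
            _add_disc(clean, pos[pi, 0] / px, pos[pi, 1] / px,
                      radius_px, blur_px, 1.0)
        pillar_movie[t] = _apply_noise(clean, cfg.snr, rng_noise)

    yy, xx = np.mgrid[0:n_px, 0:n_px] * px
    dist = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    actin_clean = 0.5 * (1.0 + erf((1.0 - dist) * 8.0))
    actin_movie = np.stack([
        _apply_noise(actin_clean, cfg.snr, rng_noise) for _ in range(cfg.n_frames)
    ])

    pillars = pd.DataFrame({
        "pillar": np.arange(n),
        "i": idx[:, 0], "j": idx[:, 1],
        "x0_um": pts[:, 0], "y0_um": pts[:, 1],
        "in_cell": in_cell,
    })
    return PillarMovie(
        pillar_movie=pillar_movie,
        actin_movie=actin_movie.astype(np.float32),
        pillars=pillars,
        deflections=defl,
        rendered=rendered,
        config=cfg,
    )


def generate_pillar_localization_set(
    n_images: int = 200,
    n_side: int = 5,
    deflection_max_um: float = 1.5,
    pitch_um: float = 8.0,
    pixel_size_um: float = 0.2,
    pillar_diameter_um: float = 2.0,
    blur_sigma_um: float = 0.3,
    snr: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-frame pillar images with known sub-pixel deflections.

    Each image holds an ``n_side``² square patch of a hexagonal lattice;
    every pillar is displaced by a uniformly drawn deflection magnitude
    in [0, ``deflection_max_um``] with random direction.  The default
    8-μm spacing keeps neighbouring disc tails out of each other's
    centroid windows even at maximal opposing deflections, so the
    measured error reflects localization precision rather than blob
    overlap.  Returns the image stack, the undeflected
    positions, and the true deflection vectors — the fixture for
    localization-precision checks.
    """
    rng = np.random.default_rng(seed)
    margin = pitch_um
    side_um = (n_side - 1) * pitch_um + 2 * margin
    n_px = int(math.ceil(side_um / pixel_size_um))
    a1 = pitch_um * np.array([1.0, 0.0])
    a2 = pitch_um * np.array([0.5, math.sqrt(3.0) / 2.0])
    base = []
    for i in range(n_side):
        for j in range(n_side):
            p = margin + i * a1 + j * a2
            p[0] -= j * pitch_um * 0.5  # keep the patch roughly square
            base.append(p)
    base = np.asarray(base)
    keep = (
        (base[:, 0] > margin / 2) & (base[:, 0] < side_um - margin / 2)
        & (base[:, 1] > margin / 2) & (base[:, 1] < side_um - margin / 2)
    )
    base = base[keep]
    radius_px = pillar_diameter_um / 2.0 / pixel_size_um
    blur_px = blur_sigma_um / pixel_size_um

    images = np.zeros((n_images, n_px, n_px), dtype=np.float32)
    true_defl = np.zeros((n_images, len(base), 2))
    for im in range(n_images):
        mag = rng.uniform(0.0, deflection_max_um, len(base))
        ang = rng.uniform(0.0, 2.0 * math.pi, len(base))
        d = np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])
        true_defl[im] = d
        clean = np.zeros((n_px, n_px))
        for p, dp in zip(base, d):
            _add_disc(clean, (p[0] + dp[0]) / pixel_size_um,
                      (p[1] + dp[1]) / pixel_size_um, radius_px, blur_px, 1.0)
        images[im] = _apply_noise(clean, snr, rng)
    return images, base, true_defl
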