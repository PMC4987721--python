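"""Micropillar traction-force microscopy analysis.

Cells seeded on an elastomeric micropillar array (hexagonal lattice,
4 μm pitch) bend the pillars they pull on; the tip deflection times the
pillar bending stiffness gives the local traction force.  This module
covers the full chain:

1. sub-pixel localization of pillar tops in the fluorescent-fibronectin
   channel (:func:`detect_pillars`),
2. fitting the undeflected hexagonal reference grid from pillars outside
   the cell footprint (:func:`fit_reference_grid`),
3. deflection → force conversion (:func:`compute_deflections`),
4. gap-closing nearest-neighbour pillar tracking (:func:`track_pillars`),
5. actin-based cell-mask segmentation and top-deflection pillar selection,
6. force summaries, force-magnitude autocorrelation with exponential
   half-time fits, and the associated hypothesis tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import filters, morphology

__all__ = [
    "PillarSpec",
    "PillarGrid",
    "PillarTrack",
    "AutocorrFit",
    "pillar_stiffness",
    "effective_young_modulus",
    "detect_pillars",
    "fit_reference_grid",
    "compute_deflections",
    "track_pillars",
    "segment_cell_mask",
    "select_top_deflected",
    "force_timeseries_summary",
    "force_autocorrelation",
    "compare_halftimes",
    "compare_forces",
]


# --------------------------------------------------------------------------
# pillar mechanics
# --------------------------------------------------------------------------

def pillar_stiffness(
    height_um: float, diameter_um: float, young_modulus_mpa: float
) -> float:
    """Bending stiffness of a cylindrical pillar, in nN/μm.

    Euler–Bernoulli cantilever loaded at the tip::

        k = 3 E I / h^3,   I = pi r^4 / 4   =>   k = 3 pi E r^4 / (4 h^3)

    Parameters are in μm (geometry) and MPa (Young's modulus of the
    elastomer); 1 MPa·μm = 1000 nN/μm.
    """
    if height_um <= 0 or diameter_um <= 0 or young_modulus_mpa <= 0:
        raise ValueError("height, diameter and Young's modulus must be positive")
    r = diameter_um / 2.0
    return 1000.0 * 3.0 * math.pi * young_modulus_mpa * r**4 / (4.0 * height_um**3)


def effective_young_modulus(k_nn_per_um: float, radius_um: float) -> float:
    """Continuum-equivalent substrate rigidity of a pillar array, in kPa.

    Uses the sphere-indentation equivalence for micropost arrays,
    ``E_eff = 9 k / (4 pi r)`` with k in nN/μm and r in μm
    (nN/μm² = kPa).  k = 0 maps to 0.
    """
    if k_nn_per_um < 0 or radius_um <= 0:
        raise ValueError("stiffness must be >= 0 and radius > 0")
    return 9.0 * k_nn_per_um / (4.0 * math.pi * radius_um)


@dataclass(frozen=True)
class PillarSpec:
    """Geometry and mechanics of the pillar array.

    Defaults are the production array: 4.1 μm tall, 2 μm diameter pillars
    on a 4 μm hexagonal pitch, bending stiffness 65.8 nN/μm, effective
    Young's modulus 47.2 kPa.
    """

    height_um: float = 4.1
    diameter_um: float = 2.0
    pitch_um: float = 4.0
    bending_stiffness_nN_um: float = 65.8
    effective_young_kPa: float = 47.2
    material_young_MPa: float | None = None

    def __post_init__(self) -> None:
        for name in ("height_um", "diameter_um", "pitch_um",
                     "bending_stiffness_nN_um", "effective_young_kPa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = effective_young_modulus(
            self.bending_stiffness_nN_um, self.diameter_um / 2.0
        )
        if abs(expected - self.effective_young_kPa) / expected > 0.01:
            raise ValueError(
                "effective_young_kPa inconsistent with bending stiffness: "
                f"expected {expected:.2f} kPa"
            )


# --------------------------------------------------------------------------
# sub-pixel pillar localization
# --------------------------------------------------------------------------

def detect_pillars(
    frame: np.ndarray,
    pixel_size_um: float = 0.2,
    pillar_diameter_um: float = 2.0,
    min_separation_um: float = 2.8,
    snr_threshold: float = 5.0,
    n_refine: int = 3,
) -> np.ndarray:
    """Locate pillar tops with sub-pixel precision.

    Band-pass filtering (difference of Gaussians) suppresses shot noise
    and illumination gradients, local maxima above a robust noise floor
    seed candidate pillars, and each candidate is refined by an iterated
    intensity-weighted centroid in a circular window re-centred on the
    running estimate (the iteration removes the window-truncation bias
    of a single-pass centroid).

    Returns an (N, 2) array of (x, y) positions in μm; empty with a
    warning for blank or saturated frames.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    r_px = pillar_diameter_um / 2.0 / pixel_size_um
    lo = ndimage.gaussian_filter(frame, 1.0)
    hi = ndimage.gaussian_filter(frame, 4.0 * r_px)
    bp = lo - hi
    mad = float(np.median(np.abs(bp - np.median(bp)))) * 1.4826
    floor = float(np.median(bp)) + snr_threshold * max(mad, 1e-12)
    if bp.max() <= floor:
        warnings.warn("no pillars detected: frame appears blank")
        return np.empty((0, 2))
    min_dist = max(1, int(round(min_separation_um / pixel_size_um * 0.7)))
    peaks = _local_maxima(bp, min_dist, floor)
    if peaks.size == 0:
        warnings.warn("no pillars detected: frame appears blank")
        return np.empty((0, 2))
    win = int(math.ceil(r_px)) + 4
    yy, xx = np.mgrid[-win : win + 1, -win : win + 1]
    disk = (yy**2 + xx**2) <= win**2
    h, w = bp.shape
    out = []
    for pr, pc in peaks:
        cy, cx = float(pr), float(pc)
        ok = True
        for _ in range(n_refine):
            iy, ix = int(round(cy)), int(round(cx))
            if iy - win < 0 or ix - win < 0 or iy + win + 1 > h or ix + win + 1 > w:
                ok = False
                break
            patch = bp[iy - win : iy + win + 1, ix - win : ix + win + 1]
            sig = np.where(disk, np.clip(patch, 0.0, None), 0.0)
            tot = sig.sum()
            if tot <= 0:
                ok = False
                break
            cy = iy + float((sig * yy).sum() / tot)
            cx = ix + float((sig * xx).sum() / tot)
        if ok:
            out.append((cx * pixel_size_um, cy * pixel_size_um))
    return np.asarray(out).reshape(-1, 2)


def _local_maxima(img: np.ndarray, min_dist: int, floor: float) -> np.ndarray:
    size = 2 * min_dist + 1
    mx = ndimage.maximum_filter(img, size=size, mode="nearest")
    cand = np.argwhere((img == mx) & (img > floor))
    if cand.shape[0] == 0:
        return cand
    # enforce separation between equal-valued plateau points
    order = np.argsort(img[cand[:, 0], cand[:, 1]])[::-1]
    kept: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > min_dist for q in kept):
            kept.append(p)
    return np.asarray(kept)


# --------------------------------------------------------------------------
# hexagonal reference grid
# --------------------------------------------------------------------------

@dataclass
class PillarGrid:
    """Undeflected hexagonal reference lattice.

    ``origin + i*a1 + j*a2`` predicts the rest position of pillar (i, j);
    basis vectors are 60° apart with |a1| ≈ |a2| ≈ pitch.
    """

    origin: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    residual_rms_um: float = 0.0

    @property
    def pitch_um(self) -> float:
        return float((np.linalg.norm(self.a1) + np.linalg.norm(self.a2)) / 2.0)

    @property
    def rotation_deg(self) -> float:
        """Orientation of a1 folded into [0, 60)."""
        ang = math.degrees(math.atan2(self.a1[1], self.a1[0]))
        return ang % 60.0

    def predict(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(indices)
        return (
            self.origin[None, :]
            + indices[:, [0]] * self.a1[None, :]
            + indices[:, [1]] * self.a2[None, :]
        )

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest lattice index (i, j) for each point."""
        points = np.atleast_2d(points)
        basis = np.column_stack([self.a1, self.a2])
        frac = np.linalg.solve(basis, (points - self.origin[None, :]).T).T
        return np.round(frac).astype(int)


def _lattice_orientation_and_pitch(pts: np.ndarray, pitch_hint: float) -> tuple[float, float]:
    # nearest-neighbour vectors, folded onto the 60-degree hexagonal sector
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    d, idx = tree.query(pts, k=min(7, len(pts)))
    vecs = []
    for i in range(len(pts)):
        for j, dist in zip(idx[i][1:], d[i][1:]):
            if 0.5 * pitch_hint < dist < 1.5 * pitch_hint:
                vecs.append(pts[j] - pts[i])
    if not vecs:
        raise ValueError("could not find neighbour pairs near the expected pitch")
    vecs = np.asarray(vecs)
    ang = np.arctan2(vecs[:, 1], vecs[:, 0])
    # multiply angles by 6: hexagonal directions collapse onto one angle
    theta6 = np.angle(np.exp(1j * 6.0 * ang).mean()) / 6.0
    pitch = float(np.median(np.linalg.norm(vecs, axis=1)))
    return float(theta6), pitch


def fit_reference_grid(
    centroids: np.ndarray,
    pitch_um: float = 4.0,
    exclude: np.ndarray | None = None,
    n_iter: int = 4,
    trim_frac_pitch: float = 0.2,
) -> PillarGrid:
    """Fit the undeflected hexagonal grid to detected pillar centres.

    Only pillars outside the cell footprint (``exclude`` False) inform
    the fit, since cell-coupled pillars are deflected.  Orientation and
    pitch are seeded from nearest-neighbour vectors, every centroid is
    assigned an integer lattice index, and origin/basis are re-estimated
    by trimmed least squares (residuals above ``trim_frac_pitch`` x pitch
    are dropped each round).

    Parameters
    ----------
    centroids : (N, 2) array of (x, y) μm
    exclude : optional boolean array, True for centroids to leave out
        (e.g. under the cell).  Falls back to all centroids with a
        warning if fewer than 10 remain.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if exclude is not None:
        free = centroids[~np.asarray(exclude, dtype=bool)]
    else:
        free = centroids
    if free.shape[0] < 10:
        warnings.warn(
            "fewer than 10 pillars outside the exclusion region; "
            "fitting the reference grid on all pillars"
        )
        free = centroids
    if free.shape[0] < 3:
        raise ValueError("need at least 3 pillars to fit a grid")

    theta, pitch = _lattice_orientation_and_pitch(free, pitch_um)
    a1 = pitch * np.array([math.cos(theta), math.sin(theta)])
    theta2 = theta + math.pi / 3.0
    a2 = pitch * np.array([math.cos(theta2), math.sin(theta2)])
    origin = free[np.argmin(np.linalg.norm(free - free.mean(0), axis=1))].copy()
    grid = PillarGrid(origin=origin, a1=a1, a2=a2)

    pts = free
    keep = np.ones(len(pts), dtype=bool)
    for _ in range(n_iter):
        idx = grid.assign(pts)
        pred = grid.predict(idx)
        res = np.linalg.norm(pts - pred, axis=1)
        keep = res < trim_frac_pitch * grid.pitch_um
        if keep.sum() < 3:
            break
        # linear LSQ: x = o + i a1 + j a2 (per coordinate)
        A = np.column_stack([np.ones(keep.sum()), idx[keep, 0], idx[keep, 1]])
        sol, *_ = np.linalg.lstsq(A, pts[keep], rcond=None)
        grid = PillarGrid(origin=sol[0], a1=sol[1], a2=sol[2])
    idx = grid.assign(pts)
    res = np.linalg.norm(pts - grid.predict(idx), axis=1)
    inlier = res < trim_frac_pitch * grid.pitch_um
    rms = float(np.sqrt(np.mean(res[inlier] ** 2))) if inlier.any() else float("nan")
    grid.residual_rms_um = rms
    return grid


def compute_deflections(
    centroids: np.ndarray,
    grid: PillarGrid,
    k_nn_per_um: float,
    indices: np.ndarray | None = None,
) -> dict:
    """Deflection and force vectors for assigned pillar centres.

    δ = observed − lattice-predicted position; F = k·δ.  Detections whose
    deflection magnitude exceeds half the pitch are flagged as lattice
    mis-assignments and excluded (``valid`` False).
    """
    if k_nn_per_um <= 0:
        raise ValueError("stiffness must be positive")
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if indices is None:
        indices = grid.assign(centroids)
    pred = grid.predict(indices)
    delta = centroids - pred
    mag = np.linalg.norm(delta, axis=1)
    valid = mag < grid.pitch_um / 2.0
    force = k_nn_per_um * delta
    return {
        "indices": indices,
        "deflection_um": delta,
        "deflection_mag_um": mag,
        "force_nN": force,
        "force_mag_nN": np.linalg.norm(force, axis=1),
        "valid": valid,
    }


# --------------------------------------------------------------------------
# pillar tracking
# --------------------------------------------------------------------------

@dataclass
class PillarTrack:
    """One pillar followed through the movie.

    Frames are the movie frame indices where the pillar was detected
    (gap-closed links may skip one frame).  Deflection/force arrays are
    attached by the analysis pipeline; ``lattice_index`` comes from the
    reference-grid assignment of the first detection.
    """

    pillar_id: int
    frames: list[int] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)
    lattice_index: tuple[int, int] | None = None
    deflection_um: np.ndarray | None = None
    force_mag_nN: np.ndarray | None = None
    cell_coupled: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def spans(self, n_total: int) -> bool:
        return bool(self.frames) and self.frames[0] == 0 and self.frames[-1] == n_total - 1

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


def track_pillars(
    detections: Sequence[np.ndarray],
    max_link_um: float = 2.0,
    lattice_indices: Sequence[np.ndarray] | None = None,
) -> list[PillarTrack]:
    """Link per-frame detections into pillar tracks.

    Nearest-neighbour linking gated at ``max_link_um`` (default 2 μm,
    half the pitch): candidate track–detection pairs are matched greedily
    by ascending displacement.  Tracks that find no match in the next
    frame are retried one frame later (2-frame gap closing); detections
    that match no track start new tracks.
    """
    if len(detections) < 2:
        raise ValueError("need at least 2 frames to track")
    tracks: list[PillarTrack] = []
    open_tracks: list[PillarTrack] = []
    for t0, pts in enumerate(detections):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) if np.size(pts) else np.empty((0, 2))
        idx_frame = lattice_indices[t0] if lattice_indices is not None else None
        unmatched = set(range(len(pts)))
        for gap in (1, 2):
            cands = [
                tr for tr in open_tracks if tr.frames and t0 - tr.frames[-1] == gap
            ]
            if not cands or not unmatched:
                continue
            last = np.array([[tr.x_um[-1], tr.y_um[-1]] for tr in cands])
            det_ids = sorted(unmatched)
            dmat = np.linalg.norm(
                last[:, None, :] - pts[det_ids][None, :, :], axis=2
            )
            pairs = [
                (dmat[a, b], a, b)
                for a in range(len(cands))
                for b in range(len(det_ids))
                if dmat[a, b] <= max_link_um
            ]
            pairs.sort()
            used_tr: set[int] = set()
            for dist, a, b in pairs:
                if a in used_tr or det_ids[b] not in unmatched:
                    continue
                tr = cands[a]
                di = det_ids[b]
                tr.frames.append(t0)
                tr.x_um.append(float(pts[di, 0]))
                tr.y_um.append(float(pts[di, 1]))
                used_tr.add(a)
                unmatched.discard(di)
        for di in sorted(unmatched):
            tr = PillarTrack(pillar_id=len(tracks))
            tr.frames.append(t0)
            tr.x_um.append(float(pts[di, 0]))
            tr.y_um.append(float(pts[di, 1]))
            if idx_frame is not None:
                tr.lattice_index = tuple(int(v) for v in idx_frame[di])
            tracks.append(tr)
            open_tracks.append(tr)
        # drop tracks unseen for more than 2 frames
        open_tracks = [tr for tr in open_tracks if t0 - tr.frames[-1] < 2]
    return tracks


# --------------------------------------------------------------------------
# cell mask and pillar selection
# --------------------------------------------------------------------------

def segment_cell_mask(
    actin_frame: np.ndarray,
    smooth_sigma_px: float = 2.0,
    dilate_radius_px: int = 3,
    min_area_px: int = 500,
) -> np.ndarray:
    """Cell footprint from the actin (LifeAct) channel.

    Gaussian low-pass → background subtraction → Sobel edge map and
    Laplacian-of-Gaussian edge map, each thresholded, dilated and
    hole-filled → union → small components removed → erosion undoing the
    dilation so the footprint hugs the cell outline.
    """
    img = np.asarray(actin_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("actin frame must be 2-D")
    sm = ndimage.gaussian_filter(img, smooth_sigma_px)
    sub = sm - np.median(sm)
    mad = float(np.median(np.abs(sub - np.median(sub)))) * 1.4826
    if sub.max() < 6.0 * max(mad, 1e-12):
        return np.zeros(img.shape, dtype=bool)
    selem = morphology.disk(dilate_radius_px)

    def _edges_to_mask(edge: np.ndarray) -> np.ndarray:
        # edge pixels are a small minority, which defeats Otsu; gate at a
        # robust noise floor as well
        e_med = float(np.median(edge))
        e_mad = float(np.median(np.abs(edge - e_med))) * 1.4826
        thr = max(filters.threshold_otsu(edge), e_med + 8.0 * e_mad)
        m = morphology.dilation(edge > thr, selem)
        return ndimage.binary_fill_holes(m)

    sobel_mask = _edges_to_mask(filters.sobel(sub))
    log_mask = _edges_to_mask(np.abs(ndimage.gaussian_laplace(sub, smooth_sigma_px)))
    mask = sobel_mask | log_mask
    mask = morphology.erosion(mask, selem)
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    return ndimage.binary_fill_holes(mask)


def select_top_deflected(
    tracks: Sequence[PillarTrack],
    cell_masks: Sequence[np.ndarray] | np.ndarray | None,
    pixel_size_um: float = 0.2,
    fraction: float = 0.05,
    coupling_min_frac: float = 0.5,
) -> list[PillarTrack]:
    """Select cell-coupled pillars with the strongest sustained deflection.

    A pillar counts as cell-coupled when it sits inside the cell mask in
    at least ``coupling_min_frac`` of its frames.  Coupled pillars are
    ranked by time-averaged deflection magnitude and the top ``fraction``
    (default 5%, at least one pillar) is returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    coupled = []
    for tr in tracks:
        if tr.deflection_um is None or tr.n_frames == 0:
            continue
        if cell_masks is None:
            inside_frac = 1.0
        else:
            inside = 0
            for f, x, y in zip(tr.frames, tr.x_um, tr.y_um):
                mask = cell_masks if isinstance(cell_masks, np.ndarray) and cell_masks.ndim == 2 else cell_masks[f]
                r = int(round(y / pixel_size_um))
                c = int(round(x / pixel_size_um))
                if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
                    inside += 1
            inside_frac = inside / tr.n_frames
        tr.cell_coupled = inside_frac >= coupling_min_frac
        if tr.cell_coupled:
            coupled.append(tr)
    if not coupled:
        warnings.warn("no cell-coupled pillars found")
        return []
    coupled.sort(
        key=lambda tr: float(np.mean(np.linalg.norm(tr.deflection_um, axis=1))),
        reverse=True,
    )
    n_keep = max(1, math.ceil(fraction * len(coupled)))
    return coupled[:n_keep]


# --------------------------------------------------------------------------
# force summaries and autocorrelation
# --------------------------------------------------------------------------

def force_timeseries_summary(
    tracks: Sequence[PillarTrack], n_frames: int
) -> dict:
    """Per-time-point mean force, per-pillar mean forces, and pooled CDF.

    Returns a dict with ``mean_force_per_frame`` (NaN where no selected
    pillar was detected), ``per_pillar_mean_force``, and the sorted pool
    of all per-pillar-frame force magnitudes with its empirical CDF.
    """
    if not tracks:
        raise ValueError("no selected tracks")
    per_frame: list[list[float]] = [[] for _ in range(n_frames)]
    per_pillar = []
    pooled = []
    for tr in tracks:
        if tr.force_mag_nN is None:
            raise ValueError("tracks must carry force magnitudes")
        for f, fm in zip(tr.frames, tr.force_mag_nN):
            per_frame[f].append(float(fm))
            pooled.append(float(fm))
        per_pillar.append(float(np.mean(tr.force_mag_nN)))
    mean_per_frame = np.array(
        [np.mean(v) if v else np.nan for v in per_frame]
    )
    pooled = np.sort(np.asarray(pooled))
    cdf = np.arange(1, pooled.size + 1) / pooled.size
    return {
        "mean_force_per_frame": mean_per_frame,
        "per_pillar_mean_force": np.asarray(per_pillar),
        "force_values": pooled,
        "force_cdf": cdf,
    }


@dataclass
class AutocorrFit:
    """Averaged force autocorrelation and its exponential fit.

    The fitted form is ``a·exp(−λt) + c``; ``halftime_min = ln 2 / λ``
    is the time at which the fitted autocorrelation falls to half its
    amplitude above the offset.  The free offset absorbs the negative
    baseline that per-series mean removal imprints on finite-length
    sample autocorrelations, which would otherwise masquerade as a
    faster decay.
    """

    lags_min: np.ndarray
    mean_autocorr: np.ndarray
    amplitude: float
    decay_rate: float
    offset: float
    halftime_min: float
    sse: float
    n_series: int


def _acf_normalized(x: np.ndarray, n_lags: int) -> np.ndarray | None:
    """Sample autocorrelation, mean-subtracted, lag-0 normalized to 1.

    Uses the n−lag (unbiased-numerator) normalization: the divide-by-n
    variant tapers the curve by (1 − lag/n), which a half-time fit would
    misread as extra decay.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = float(np.dot(x, x)) / n
    if denom <= 0:
        return None
    ac = np.empty(min(n_lags, n))
    for lag in range(ac.size):
        ac[lag] = float(np.dot(x[: n - lag], x[lag:])) / (n - lag) / denom
    return ac


def mean_autocorrelation(
    force_series: Sequence[np.ndarray],
    n_lags: int,
    cell_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, int]:
    """Average normalized autocorrelation of force-magnitude series.

    Each series is mean-subtracted and its biased (divide-by-n) sample
    autocorrelation normalized to 1 at lag 0.  Zero-variance series are
    excluded with a warning.  With ``cell_ids`` the average is taken per
    cell first, then across cells (the per-condition convention).
    """
    acs, ids = [], []
    for i, s in enumerate(force_series):
        ac = _acf_normalized(np.asarray(s, dtype=float), n_lags)
        if ac is None or ac.size < n_lags:
            warnings.warn(f"series {i} excluded (zero variance or too short)")
            continue
        acs.append(ac)
        ids.append(cell_ids[i] if cell_ids is not None else 0)
    if not acs:
        raise ValueError("no usable force series for autocorrelation")
    acs_arr = np.asarray(acs)
    if cell_ids is None:
        mean = acs_arr.mean(axis=0)
    else:
        per_cell = [acs_arr[np.asarray(ids) == c].mean(axis=0) for c in sorted(set(ids))]
        mean = np.mean(per_cell, axis=0)
    return mean, len(acs)


def fit_exponential_decay(
    lags_min: np.ndarray, values: np.ndarray
) -> tuple[float, float, float, float]:
    """Least-squares fit of a·exp(−λt) + c; returns (a, λ, c, sse)."""
    lags_min = np.asarray(lags_min, dtype=float)
    values = np.asarray(values, dtype=float)

    def model(t, a, lam, c):
        return a * np.exp(-lam * t) + c

    span = lags_min[-1] - lags_min[0] if lags_min.size > 1 else 1.0
    p0 = (max(values[0], 0.1), math.log(2.0) / max(span / 4.0, 1e-6), 0.0)
    popt, _ = optimize.curve_fit(
        model, lags_min, values, p0=p0,
        bounds=([0.0, 1e-9, -1.0], [10.0, np.inf, 1.0]),
        maxfev=20000,
    )
    a, lam, c = (float(v) for v in popt)
    sse = float(np.sum((values - model(lags_min, a, lam, c)) ** 2))
    return a, lam, c, sse


def force_autocorrelation(
    force_series: Sequence[np.ndarray],
    frame_interval_min: float = 5.0,
    fit_window_min: float = 120.0,
    cell_ids: Sequence[int] | None = None,
) -> AutocorrFit:
    """Averaged force autocorrelation with an exponential half-time fit.

    The fit window covers lags 0 .. ``fit_window_min`` inclusive; at the
    default 5-min frame interval the 2-hour window holds 25 lag points.
    The fitted form is a·exp(−λt) and the half-time is ln2/λ.
    """
    n_lags = int(round(fit_window_min / frame_interval_min)) + 1
    for s in force_series:
        if len(s) < n_lags:
            raise ValueError(
                f"series shorter than the fit window ({n_lags} points required)"
            )
    mean, n_used = mean_autocorrelation(force_series, n_lags, cell_ids)
    lags = np.arange(n_lags) * frame_interval_min
    a, lam, c, sse = fit_exponential_decay(lags, mean)
    return AutocorrFit(
        lags_min=lags,
        mean_autocorr=mean,
        amplitude=a,
        decay_rate=lam,
        offset=c,
        halftime_min=math.log(2.0) / lam,
        sse=sse,
        n_series=n_used,
    )


def compare_halftimes(fit_a: AutocorrFit, fit_b: AutocorrFit) -> dict:
    """Extra-sum-of-squares F-test on the two exponential fits.

    Compares a shared-(a, λ, c) fit of both averaged autocorrelation
    curves against the separate fits; rejecting means the two
    conditions' force-turnover kinetics differ.
    """
    t = np.concatenate([fit_a.lags_min, fit_b.lags_min])
    y = np.concatenate([fit_a.mean_autocorr, fit_b.mean_autocorr])
    n = t.size
    if n < 8:
        raise ValueError("not enough points for the nested-model comparison")
    _, _, _, sse_shared = fit_exponential_decay(t, y)
    sse_sep = fit_a.sse + fit_b.sse
    df_sep = n - 6
    d_df = 3
    if sse_sep <= 0:
        sse_sep = 1e-300
    f_stat = max(0.0, (sse_shared - sse_sep) / d_df / (sse_sep / df_sep))
    p = float(stats.f.sf(f_stat, d_df, df_sep))
    return {
        "f_stat": f_stat,
        "p_value": p,
        "df": (d_df, df_sep),
        "halftime_a_min": fit_a.halftime_min,
        "halftime_b_min": fit_b.halftime_min,
    }


def compare_forces(forces_a: Sequence[float], forces_b: Sequence[float]) -> dict:
    """Welch's unequal-variance t-test on per-pillar mean forces."""
    a = np.asarray(forces_a, dtype=float)
    b = np.asarray(forces_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 pillars")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t_stat": float(res.statistic), "p_value": float(res.pvalue),
            "df": float(res.df)}


# --------------------------------------------------------------------------
# movie-level pipeline
# --------------------------------------------------------------------------

def analyze_pillar_movie(
    pillar_movie: np.ndarray,
    actin_movie: np.ndarray | None,
    spec: PillarSpec | None = None,
    pixel_size_um: float = 0.2,
    frame_interval_min: float = 5.0,
    top_fraction: float = 0.05,
    fit_window_min: float = 120.0,
) -> dict:
    """Run the full TFM chain on one two-channel movie.

    detect → reference grid (cell pillars excluded via the actin mask of
    the first frame) → track → deflection/force → top-deflection
    selection → force summaries → autocorrelation half-time.
    """
    spec = spec or PillarSpec()
    n_frames = pillar_movie.shape[0]
    k = spec.bending_stiffness_nN_um
    mask0 = (
        segment_cell_mask(actin_movie[0]) if actin_movie is not None else None
    )
    detections = [
        detect_pillars(pillar_movie[t], pixel_size_um=pixel_size_um,
                       pillar_diameter_um=spec.diameter_um)
        for t in range(n_frames)
    ]
    pts0 = detections[0]
    if mask0 is not None and pts0.size:
        rr = np.clip((pts0[:, 1] / pixel_size_um).round().astype(int), 0, mask0.shape[0] - 1)
        cc = np.clip((pts0[:, 0] / pixel_size_um).round().astype(int), 0, mask0.shape[1] - 1)
        under_cell = mask0[rr, cc]
    else:
        under_cell = None
    grid = fit_reference_grid(pts0, pitch_um=spec.pitch_um, exclude=under_cell)
    tracks = track_pillars(detections, max_link_um=spec.pitch_um / 2.0)
    for tr in tracks:
        res = compute_deflections(tr.positions(), grid, k)
        tr.deflection_um = res["deflection_um"]
        tr.force_mag_nN = res["force_mag_nN"]
        tr.lattice_index = tuple(int(v) for v in res["indices"][0])
    full = [tr for tr in tracks if tr.spans(n_frames)]
    selected = select_top_deflected(
        full, mask0, pixel_size_um=pixel_size_um, fraction=top_fraction
    )
    out: dict = {
        "grid": grid,
        "tracks": tracks,
        "n_full_length": len(full),
        "fraction_full_length": len(full) / max(1, len(detections[0])),
        "selected": selected,
    }
    if selected:
        out["summary"] = force_timeseries_summary(selected, n_frames)
        series = [tr.force_mag_nN for tr in selected
                  if tr.force_mag_nN is not None and len(tr.force_mag_nN) >= int(round(fit_window_min / frame_interval_min)) + 1]
        if series:
            out["autocorr"] = force_autocorrelation(
                series, frame_interval_min, fit_window_min
            )
    return out
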