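"""Nucleus tracking by frame-to-frame overlap and single-cell speed statistics.

Cells are followed through labeled nuclei masks by linking each label to
the label in the previous frame it overlaps most (one-to-one, greedy by
overlap size).  Tracks end at the first miss — no gap closing — so a
track is a contiguous run of frames.  Per-cell average speeds are
computed separately for the pre- and post-stimulation phases and
compared across populations with a Kruskal–Wallis test followed by
Dunn's pairwise post test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CellTrack",
    "SpeedRecord",
    "GroupComparison",
    "track_nuclei",
    "compute_cell_speed",
    "compare_speed_populations",
    "assess_normality",
    "dunn_posthoc",
]


@dataclass
class CellTrack:
    """Contiguous trajectory of one nucleus.

    Positions are centroids in μm; ``frames`` is strictly increasing by
    one (tracks end at the first missed link).
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SpeedRecord:
    track_id: int
    phase: str
    mean_speed_um_min: float
    n_steps: int


@dataclass
class GroupComparison:
    """Kruskal–Wallis result with Dunn's pairwise post test."""

    groups: list[str]
    h_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj


def _overlap_pairs(prev: np.ndarray, curr: np.ndarray) -> dict[tuple[int, int], int]:
    both = (prev > 0) & (curr > 0)
    if not both.any():
        return {}
    pairs, counts = np.unique(
        np.stack([prev[both], curr[both]]), axis=1, return_counts=True
    )
    return {(int(a), int(b)): int(c) for (a, b), c in zip(pairs.T, counts)}


def track_nuclei(
    masks: Sequence[np.ndarray], pixel_size_um: float = 1.0
) -> list[CellTrack]:
    """Link labeled nuclei masks into tracks by maximal pixel overlap.

    Each label in frame t+1 is linked to the frame-t label with which it
    shares the most pixels; links are assigned greedily by descending
    overlap (ties broken by centroid distance) and are one-to-one.
    Labels without an overlapping predecessor start new tracks.
    """
    if len(masks) == 0:
        raise ValueError("empty frame list")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("masks must share shape")

    def centroids(mask: np.ndarray) -> dict[int, np.ndarray]:
        out = {}
        for lab in np.unique(mask):
            if lab == 0:
                continue
            rc = np.asarray(ndimage.center_of_mass(mask == lab))
            out[int(lab)] = np.array([rc[1], rc[0]]) * pixel_size_um  # (x, y)
        return out

    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}  # current-frame label -> track
    cents = centroids(masks[0])
    for lab, c in cents.items():
        tr = CellTrack(track_id=len(tracks))
        tr.frames.append(0)
        tr.x_um.append(float(c[0]))
        tr.y_um.append(float(c[1]))
        tr.labels.append(lab)
        tracks.append(tr)
        active[lab] = tr

    for t in range(1, len(masks)):
        cents_t = centroids(masks[t])
        overlaps = _overlap_pairs(masks[t - 1], masks[t])
        order = sorted(
            overlaps.items(),
            key=lambda kv: (
                -kv[1],
                float(np.linalg.norm(cents_t[kv[0][1]] - np.array([
                    active[kv[0][0]].x_um[-1], active[kv[0][0]].y_um[-1]
                ]))) if kv[0][0] in active else np.inf,
            ),
        )
        new_active: dict[int, CellTrack] = {}
        used_prev: set[int] = set()
        for (prev_lab, curr_lab), _ in order:
            if prev_lab not in active or prev_lab in used_prev:
                continue
            if curr_lab in new_active:
                continue
            tr = active[prev_lab]
            c = cents_t[curr_lab]
            tr.frames.append(t)
            tr.x_um.append(float(c[0]))
            tr.y_um.append(float(c[1]))
            tr.labels.append(curr_lab)
            new_active[curr_lab] = tr
            used_prev.add(prev_lab)
        for lab, c in cents_t.items():
            if lab in new_active:
                continue
            tr = CellTrack(track_id=len(tracks))
            tr.frames.append(t)
            tr.x_um.append(float(c[0]))
            tr.y_um.append(float(c[1]))
            tr.labels.append(lab)
            tracks.append(tr)
            new_active[lab] = tr
        active = new_active
    return tracks


def compute_cell_speed(
    track: CellTrack,
    frame_interval_min: float,
    pre_stim_frames: int | None = None,
    min_steps: int = 5,
) -> list[SpeedRecord]:
    """Average speed of one cell, split by stimulation phase.

    Speed is the mean over consecutive-frame steps of Euclidean
    displacement divided by the frame interval.  A step from frame f to
    f+1 belongs to the pre phase when f+1 <= ``pre_stim_frames``; with
    ``pre_stim_frames`` None a single record with phase ``"all"`` is
    returned.  Phases with fewer than ``min_steps`` steps are omitted.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame interval must be positive")
    pos = np.column_stack([track.x_um, track.y_um])
    frames = np.asarray(track.frames)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    end_frames = frames[1:]
    records = []
    if pre_stim_frames is None:
        phases = {"all": np.ones(steps.size, dtype=bool)}
    else:
        pre = end_frames <= pre_stim_frames
        phases = {"pre": pre, "post": ~pre}
    for phase, sel in phases.items():
        if int(sel.sum()) < min_steps:
            continue
        records.append(
            SpeedRecord(
                track_id=track.track_id,
                phase=phase,
                mean_speed_um_min=float(steps[sel].mean() / frame_interval_min),
                n_steps=int(sel.sum()),
            )
        )
    return records


def dunn_posthoc(
    samples: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    z_ij = (mean rank_i − mean rank_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))
    with the tie correction T = Σ(t³−t)/(12(N−1)); two-sided normal
    p-values, Bonferroni-adjusted over all pairs by default.
    """
    names = list(samples)
    values = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    sizes = {g: len(samples[g]) for g in names}
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = float(ranks[start : start + sizes[g]].mean())
        start += sizes[g]
    n_total = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * len(pairs))
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_raw": float(p_raw), "p_adj": float(p_adj)})
    return pd.DataFrame(rows)


def compare_speed_populations(
    samples: Mapping[str, Sequence[float]],
) -> GroupComparison:
    """Kruskal–Wallis across cell populations with Dunn's post test."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.array_equal(v, next(iter(arrays.values()))) for v in arrays.values()):
        # identical groups: H is 0 by construction, avoid the all-ties error
        pairwise = dunn_posthoc(arrays)
        return GroupComparison(groups=list(arrays), h_stat=0.0, p_value=1.0,
                               pairwise=pairwise)
    h, p = stats.kruskal(*arrays.values())
    pairwise = dunn_posthoc(arrays)
    return GroupComparison(
        groups=list(arrays), h_stat=float(h), p_value=float(p), pairwise=pairwise
    )


def assess_normality(sample: Sequence[float], alpha: float = 0.05) -> bool:
    """All-three-tests normality rule.

    A sample counts as normal only if the Kolmogorov–Smirnov (Lilliefors,
    parameters estimated), d'Agostino–Pearson, and Shapiro–Wilk tests all
    fail to reject at ``alpha``.  Degenerate (constant) samples are not
    normal; fewer than 8 values is an error.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 values to assess normality")
    if np.ptp(x) == 0:
        return False
    _, p_ks = lilliefors(x, dist="norm")
    _, p_dp = stats.normaltest(x)
    _, p_sw = stats.shapiro(x)
    return bool(p_ks > alpha and p_dp > alpha and p_sw > alpha)
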