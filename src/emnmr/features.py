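"""Feature extraction: α-helical densities in maps, helices in NMR secondary
structure, and grouping of detected helices into subunits.

At 6–10 Å resolution an α-helix appears as a rod of density ~5 Å across.
Detection cross-correlates a Gaussian-smoothed solid-cylinder template
(radius 2.5 Å, length 10 Å) with the map over a grid of orientations,
keeps high-scoring local maxima, grows each hit along its axis while the
local template correlation stays high, and merges collinear segments.
Axis polarity is not determined (N→C direction is invisible at these
resolutions), so axes are reported sign-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.special import erf
from sklearn.cluster import DBSCAN

from . import _kernels
from .density import DensityMap, gaussian_sigma
from .model import HELIX_RISE_PER_RES, InputError

__all__ = [
    "HelixDensity", "SequenceHelix", "detect_helices",
    "cluster_into_subunits", "sequence_helices_from_ss",
    "helices_to_tsv", "helices_from_tsv",
]


@dataclasses.dataclass
class HelixDensity:
    """A rod-like density feature: center, sign-free unit axis, length, score."""

    center: np.ndarray
    axis: np.ndarray
    length: float
    score: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        ax = np.asarray(self.axis, dtype=np.float64)
        n = np.linalg.norm(ax)
        if n == 0:
            raise InputError("zero-length axis")
        ax = ax / n
        # canonical sign: first component with |x| > tiny is positive
        for c in ax:
            if abs(c) > 1e-9:
                if c < 0:
                    ax = -ax
                break
        self.axis = ax


@dataclasses.dataclass
class SequenceHelix:
    """A helical stretch along the sequence (1-based inclusive indices)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError("helix end before start")

    @property
    def length_res(self) -> int:
        return self.end - self.start + 1

    @property
    def length_A(self) -> float:
        return self.length_res * HELIX_RISE_PER_RES

    @property
    def central_residue(self) -> int:
        return self.start + (self.length_res - 1) // 2

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


# ---------------------------------------------------------------------------
# helix detection in maps


def _hemisphere_directions(spacing_deg: float) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere, <= spacing apart."""
    n = max(8, int(np.ceil(2 * np.pi / np.radians(spacing_deg) ** 2)))
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere only: z in (0, 1)
    phi = np.pi * (1 + 5 ** 0.5) * i
    r = np.sqrt(1 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _template_cloud(radius: float, length: float, sigma: float,
                    spacing: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Point-sampled smoothed cylinder in a canonical frame (axis = z).

    The sample region is a tight cylindrical box (radius + 3 Å laterally),
    so the correlation is evaluated against the rod and its immediate
    surround only — neighbouring rods in a packed bundle stay outside the
    mask instead of polluting the normalisation.
    """
    lat = np.arange(-(radius + 3.0), radius + 3.0 + 1e-9, spacing)
    zs = np.arange(-(length / 2 + 2.0), length / 2 + 2.0 + 1e-9, spacing)
    x, y, z = np.meshgrid(lat, lat, zs, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2)
    fr = 0.5 * (1 - erf((r - radius) / (sigma * np.sqrt(2))))
    fz = 0.5 * (1 - erf((np.abs(z) - length / 2) / (sigma * np.sqrt(2))))
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    return np.ascontiguousarray(pts), np.ascontiguousarray((fr * fz).ravel())


def _rotation_to(d: np.ndarray) -> np.ndarray:
    """Proper rotation taking the +z axis to direction d."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, d))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, d)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1 + c)


def _point_ncc(dmap: DensityMap, pts_local: np.ndarray, tvals: np.ndarray,
               center: np.ndarray) -> float:
    """Pearson correlation between template values and map samples at center."""
    vals = dmap.interpolate(pts_local + center)
    sv = vals.std()
    if sv == 0:
        return 0.0
    tv = tvals
    return float(np.mean((vals - vals.mean()) * (tv - tv.mean())) / (sv * tv.std()))


def detect_helices(dmap: DensityMap, min_length: float = 12.0,
                   score_threshold: float = 0.6,
                   resolution: float | None = None,
                   orientation_spacing_deg: float = 15.0,
                   template_radius: float = 2.5,
                   template_length: float = 10.0) -> list[HelixDensity]:
    """Detect rod-like (α-helical) densities in a medium-resolution map.

    Returns helices sorted by length (descending).  An empty or constant map
    yields an empty list.
    """
    res = resolution if resolution is not None else (dmap.nominal_resolution or 8.0)
    if not 4.0 <= res <= 12.0:
        raise InputError("helix detection expects a nominal resolution in [4, 12] Å")
    g = dmap.grid.astype(np.float64)
    if g.size == 0 or g.std() == 0:
        return []
    sigma = gaussian_sigma(res)
    dirs = _hemisphere_directions(orientation_spacing_deg)
    cloud, tvals = _template_cloud(template_radius, template_length, sigma)
    rots = [_rotation_to(d) for d in dirs]
    dir_pts = np.ascontiguousarray(
        np.stack([cloud @ r.T for r in rots]))

    # scan candidate voxels (where there is density) over all orientations
    cand = np.argwhere(g > 0.25 * g.max())
    if len(cand) == 0:
        return []
    best_c = np.empty(len(cand))
    bdir_c = np.zeros(len(cand), dtype=np.int64)
    _kernels.masked_ncc_scan(g, dmap.origin, dmap.voxel,
                             np.ascontiguousarray(cand.astype(np.int64)),
                             dir_pts, tvals, best_c, bdir_c)
    best = np.full(g.shape, -2.0)
    best_dir = np.zeros(g.shape, dtype=np.int64)
    best[tuple(cand.T)] = best_c
    best_dir[tuple(cand.T)] = bdir_c

    # local maxima of the best-orientation score above threshold
    foot = max(3, int(round(5.0 / dmap.voxel)) | 1)
    maxima = (best == ndimage.maximum_filter(best, size=foot)) & (best > score_threshold)
    peaks = np.argwhere(maxima)
    if len(peaks) == 0:
        return []
    scores = best[tuple(peaks.T)]
    order = np.argsort(-scores)
    peaks = peaks[order]
    scores = scores[order]

    # growth stops where the sliding-template correlation falls below 90% of
    # its value at the seed; the fixed end correction compensates the partial
    # template overlap that keeps the correlation high past the physical end.
    segments: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    end_correction = 5.0
    for p, sc in zip(peaks, scores):
        pos = dmap.origin + dmap.voxel * p
        # skip peaks already explained by an accepted segment
        if any(_near_segment(pos, c, a, ln, 2.4 * template_radius)
               for c, a, ln, _ in segments):
            continue
        d = dirs[best_dir[tuple(p)]]
        pts_local = np.ascontiguousarray(dir_pts[best_dir[tuple(p)]])
        seed_score = _point_ncc(dmap, pts_local, tvals, pos)
        grow_thr = 0.8 * seed_score
        lo = hi = 0.0
        step = 1.0
        while _point_ncc(dmap, pts_local, tvals, pos + d * (hi + step)) > grow_thr and hi < 80:
            hi += step
        while _point_ncc(dmap, pts_local, tvals, pos - d * (-lo + step)) > grow_thr and -lo < 80:
            lo -= step
        length = (hi - lo) + template_length - end_correction
        center = pos + d * (hi + lo) / 2
        segments.append((center, d, length, sc))

    segments = _merge_collinear(segments, template_radius)
    out = []
    for center, axis, length, sc in segments:
        # final length/center from the axial half-maximum density profile,
        # which tracks the physical rod extent much more tightly than the
        # correlation-growth extent does; iterate because growth seeded at
        # a rod end under-covers the rod at first
        for _ in range(3):
            axis = _refine_axis(dmap, center, axis, length,
                                template_radius + 1.0)
            new_length, new_center = _axial_extent(dmap, center, axis, length)
            if new_length < 0.6 * length:
                break  # half-max run split: unstable, keep last estimate
            converged_len = abs(new_length - length) <= 1.0
            length, center = new_length, new_center
            if converged_len:
                break
        if length < min_length:
            continue
        out.append(HelixDensity(center, axis, float(length), float(sc)))
    out.sort(key=lambda h: -h.length)
    return out


def _axial_extent(dmap: DensityMap, center: np.ndarray, axis: np.ndarray,
                  grown_length: float, lateral: float = 3.0,
                  frac: float = 0.5) -> tuple[float, np.ndarray]:
    """Rod length and recentred midpoint from the half-max axial profile."""
    idx = np.indices(dmap.shape).reshape(3, -1).T
    pts = dmap.origin + dmap.voxel * idx
    v = pts - center
    t = v @ axis
    lat2 = np.einsum("ij,ij->i", v, v) - t ** 2
    half_span = grown_length / 2 + 10.0
    sel = (lat2 <= lateral ** 2) & (np.abs(t) <= half_span)
    if sel.sum() < 5:
        return grown_length, center
    tt = t[sel]
    w = np.clip(dmap.grid.reshape(-1)[sel].astype(np.float64), 0, None)
    edges = np.arange(tt.min() - 0.5, tt.max() + 1.5, 1.0)
    prof = np.zeros(len(edges) - 1)
    cnt = np.zeros(len(edges) - 1)
    bi = np.clip(np.digitize(tt, edges) - 1, 0, len(prof) - 1)
    np.add.at(prof, bi, w)
    np.add.at(cnt, bi, 1)
    prof = prof / np.maximum(cnt, 1)
    if prof.max() <= 0:
        return grown_length, center
    above = prof > frac * prof.max()
    # contiguous above-threshold run containing the segment center (t = 0)
    mid = int(np.clip(np.digitize(0.0, edges) - 1, 0, len(prof) - 1))
    if not above[mid]:
        cand = np.where(above)[0]
        mid = int(cand[np.argmin(np.abs(cand - mid))])
    a = b = mid
    while a > 0 and above[a - 1]:
        a -= 1
    while b < len(prof) - 1 and above[b + 1]:
        b += 1
    t_lo = edges[a]
    t_hi = edges[b + 1]
    return float(t_hi - t_lo), center + axis * (t_lo + t_hi) / 2


def _near_segment(p: np.ndarray, center: np.ndarray, axis: np.ndarray,
                  length: float, radius: float) -> bool:
    v = p - center
    t = float(np.clip(v @ axis, -length / 2, length / 2))
    return bool(np.linalg.norm(v - t * axis) < radius)


def _merge_collinear(segments, radius: float, angle_deg: float = 25.0):
    merged = True
    segs = list(segments)
    cos_thr = np.cos(np.radians(angle_deg))
    while merged:
        merged = False
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                ci, ai, li, si = segs[i]
                cj, aj, lj, sj = segs[j]
                if abs(float(ai @ aj)) < cos_thr:
                    continue
                d = cj - ci
                t = float(d @ ai)
                lateral = float(np.linalg.norm(d - t * ai))
                if lateral > 2 * radius or abs(t) > (li + lj) / 2 + 4.0:
                    continue
                sign = 1.0 if float(ai @ aj) >= 0 else -1.0
                e = sorted([t - sign * lj / 2, t + sign * lj / 2, -li / 2, li / 2])
                new_len = e[-1] - e[0]
                new_center = ci + ai * (e[-1] + e[0]) / 2
                segs[i] = (new_center, ai, new_len, max(si, sj))
                del segs[j]
                merged = True
                break
            if merged:
                break
    return segs


def _refine_axis(dmap: DensityMap, center: np.ndarray, axis: np.ndarray,
                 length: float, radius: float) -> np.ndarray:
    """Density-weighted PCA of voxels near the segment sharpens the axis
    beyond the orientation-grid spacing."""
    idx = np.indices(dmap.shape).reshape(3, -1).T
    pts = dmap.origin + dmap.voxel * idx
    v = pts - center
    t = v @ axis
    lat2 = np.einsum("ij,ij->i", v, v) - t ** 2
    sel = (np.abs(t) <= length / 2) & (lat2 <= radius ** 2)
    if sel.sum() < 10:
        return axis
    w = np.clip(dmap.grid.reshape(-1)[sel].astype(np.float64), 0, None)
    if w.sum() <= 0:
        return axis
    p = pts[sel]
    mu = (w[:, None] * p).sum(axis=0) / w.sum()
    q = (p - mu) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    new_axis = vt[0]
    if new_axis @ axis < 0:
        new_axis = -new_axis
    # short rods are barely anisotropic: if PCA swings the axis far from
    # the correlation-template orientation, the refinement is spurious
    if float(new_axis @ axis) < np.cos(np.radians(30.0)):
        return axis
    return new_axis


# ---------------------------------------------------------------------------
# subunit clustering


def _kmedoids(x: np.ndarray, k: int, n_iter: int = 50) -> np.ndarray:
    """Deterministic PAM-style k-medoids (farthest-point initialisation)."""
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_m = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_m)))
    medoids = np.array(medoids)
    for _ in range(n_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new[c] = members[int(np.argmin(within))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(d[:, medoids], axis=1)


def cluster_into_subunits(helices: list[HelixDensity],
                          expected_per_subunit: int | None = None,
                          min_samples: int = 2
                          ) -> tuple[list[list[HelixDensity]], list[HelixDensity]]:
    """Group detected helices into subunits by spatial proximity.

    DBSCAN on helix centers with the neighbourhood radius chosen by scanning
    for the widest plateau in the cluster count; helices the scan cannot
    attach to any cluster are returned separately as noise.  If
    `expected_per_subunit` is given and violated, falls back to k-medoids
    with k = n_helices / expected_per_subunit.

    Returns (clusters, noise).
    """
    if not helices:
        raise InputError("need at least one helix")
    x = np.array([h.center for h in helices])
    if len(helices) == 1:
        return [list(helices)], []

    eps_grid = np.arange(3.0, 50.0, 1.0)
    counts = []
    for eps in eps_grid:
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(x)
        n = labels.max() + 1
        counts.append(n)
    # widest plateau with at least one cluster
    best_run, run_start, run_len = None, 0, 0
    for i in range(1, len(counts) + 1):
        if i < len(counts) and counts[i] == counts[run_start] and counts[run_start] > 0:
            continue
        length = i - run_start
        if counts[run_start] > 0 and (best_run is None or length > run_len):
            best_run, run_len = run_start + length // 2, length
        run_start = i
    if best_run is None:
        return [], list(helices)
    labels = DBSCAN(eps=float(eps_grid[best_run]), min_samples=min_samples).fit_predict(x)

    if expected_per_subunit is not None:
        sizes = [int(np.sum(labels == c)) for c in range(labels.max() + 1)]
        if -1 in labels or any(s != expected_per_subunit for s in sizes):
            k = max(1, round(len(helices) / expected_per_subunit))
            labels = _kmedoids(x, k)

    clusters = [[h for h, l in zip(helices, labels) if l == c]
                for c in range(labels.max() + 1)]
    noise = [h for h, l in zip(helices, labels) if l == -1]
    return clusters, noise


# ---------------------------------------------------------------------------
# sequence helices


def sequence_helices_from_ss(ss: str, min_len_res: int = 4) -> list[SequenceHelix]:
    """Maximal H-runs of a {H, E, C} string, sorted by length desc, ties by start."""
    if min_len_res < 4:
        raise InputError("min_len_res must be >= 4")
    bad = set(ss) - set("HEC")
    if bad:
        raise InputError(f"secondary-structure string has invalid codes: {bad}")
    out = []
    i = 0
    n = len(ss)
    while i < n:
        if ss[i] == "H":
            j = i
            while j < n and ss[j] == "H":
                j += 1
            if j - i >= min_len_res:
                out.append(SequenceHelix(i + 1, j))
            i = j
        else:
            i += 1
    out.sort(key=lambda h: (-h.length_res, h.start))
    return out


# ---------------------------------------------------------------------------
# simple TSV export of detected helices


def helices_to_tsv(helices: list[HelixDensity], path) -> None:
    with open(path, "w") as fh:
        fh.write("center_x\tcenter_y\tcenter_z\taxis_x\taxis_y\taxis_z\tlength\tscore\n")
        for h in helices:
            fh.write("\t".join(f"{v:.4f}" for v in (*h.center, *h.axis)) +
                     f"\t{h.length:.3f}\t{h.score:.4f}\n")


def helices_from_tsv(path) -> list[HelixDensity]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("center_x"):
            raise InputError("not a helix TSV file")
        for line in fh:
            v = [float(t) for t in line.split()]
            out.append(HelixDensity(v[0:3], v[3:6], v[6], v[7]))
    return out
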