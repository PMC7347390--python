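"""Per-frame image analysis: segmentation, centerline, posture, widths.

The posture representation is the field-standard one: the centerline is
resampled to 1001 evenly spaced points, the 1000 inter-point tangent angles
are fit with 14 quadratic B-spline coefficients, the mean angle is recorded
as the worm's overall orientation and the coefficient vector is
mean-centered, leaving a rotation-invariant description of body shape.

Coordinate conventions: images are indexed (row, col); centerline points
are stored (x, y) = (col, row); angles are measured from the +x axis with y
increasing downward (standard image coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, thin

from . import _splines
from .record import BehaviorRecord, LawnBoundary


@dataclass(frozen=True)
class SegmentationParams:
    """Global-threshold segmentation of a dark worm on a light background."""

    threshold_method: str | float = "otsu"
    morph_radius: int = 2
    component_area_range: tuple[float, float] = (20_000.0, 100_000.0)

    def __post_init__(self) -> None:
        lo, hi = self.component_area_range
        if not lo < hi:
            raise ValueError("component_area_range must be (min, max) with min < max")


@dataclass
class Centerline:
    """1001-point midline (px, head-to-tail once assigned), or the
    self-intersection flag when the skeleton contained a cycle (omega bend)."""

    points: np.ndarray | None  # (1001, 2) as (x, y)
    self_intersecting: bool = False

    @property
    def arc_length(self) -> float:
        if self.points is None:
            raise ValueError("no centerline on a self-intersecting frame")
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PostureVector:
    """14-coefficient body-angle representation of a single frame."""

    coeffs: np.ndarray  # (14,) rad, mean-centered
    orientation: float  # rad, mean tangent angle (head-to-tail direction)
    curvature: np.ndarray  # (1000,) 1/µm along the body

    def reconstruct_angles(self, n: int = 1000) -> np.ndarray:
        return _splines.evaluate(self.coeffs, n) + self.orientation


# ---------------------------------------------------------------------------
# segmentation


def segment_worm(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary mask of the worm: threshold, close, keep the qualifying
    component nearest the frame center.

    Returns an all-False mask when no connected component falls inside the
    configured area range; callers treat that as an invalid frame.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if params.threshold_method == "otsu":
        thresh = threshold_otsu(image)
    else:
        thresh = float(params.threshold_method)
    mask = image <= thresh  # dark worm on light background
    if mask.all():  # constant image: nothing to segment
        return np.zeros_like(mask, dtype=bool)
    if params.morph_radius > 0:
        mask = closing(mask, disk(params.morph_radius))
    labels = label(mask, connectivity=2)
    lo, hi = params.component_area_range
    center = np.array(image.shape, dtype=float) / 2.0
    best, best_dist = None, np.inf
    for prop in regionprops(labels):
        if not lo <= prop.area <= hi:
            continue
        dist = np.linalg.norm(np.asarray(prop.centroid) - center)
        if dist < best_dist:
            best, best_dist = prop.label, dist
    return labels == best if best is not None else np.zeros_like(mask, dtype=bool)


# ---------------------------------------------------------------------------
# centerline


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connectivity graph of skeleton pixels.

    Diagonal edges whose endpoints share a 4-connected skeleton neighbor are
    dropped: they would otherwise create spurious 3-cycles at every diagonal
    step and junction, masking genuine loops.
    """
    pix = set(map(tuple, np.argwhere(skel)))
    g = nx.Graph()
    g.add_nodes_from(pix)
    for r, c in pix:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb not in pix:
                continue
            if dr and dc:  # diagonal: skip if a shared 4-neighbor bridges it
                if ((r, c + dc) in pix) or ((r + dr, c) in pix):
                    continue
            g.add_edge((r, c), nb)
    return g


def _prune_branches(g: nx.Graph, image: np.ndarray | None) -> nx.Graph:
    """Iteratively remove the shortest leaf branch until no branchpoints remain.

    Ties are broken toward the branch whose endpoint pixel is brighter in
    the source image (noise spurs sit near the worm edge, where brightfield
    intensity rises); without an image the tie-break is lexicographic.
    """
    g = g.copy()
    while True:
        branchpoints = [n for n in g if g.degree(n) > 2]
        if not branchpoints:
            return g
        leaves = [n for n in g if g.degree(n) == 1]
        branches = []
        for leaf in leaves:
            path = [leaf]
            prev, cur = None, leaf
            while g.degree(cur) <= 2:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if g.degree(cur) > 2:  # path ends at a branchpoint; drop it from removal
                brightness = float(image[leaf]) if image is not None else 0.0
                branches.append((len(path) - 1, brightness, leaf, path[:-1]))
        if not branches:
            return g
        branches.sort(key=lambda b: (b[0], b[1], b[2]))
        g.remove_nodes_from(branches[0][3])


def _extend_to_boundary(coords: np.ndarray, mask: np.ndarray, span: int = 10
                        ) -> np.ndarray:
    """Prolong both skeleton ends along their local tangent to the mask edge.

    Thinning retracts the skeleton by about half a body width at each blunt
    end; without this step the measured worm length is biased short.
    """
    out = [coords]
    for end, inner in ((coords[0], coords[min(span, len(coords) - 1)]),
                       (coords[-1], coords[-min(span + 1, len(coords))])):
        d = end - inner
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        ext = []
        p = end.copy()
        for _ in range(200):
            p = p + 0.5 * d
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                break
            ext.append(p.copy())
        if ext:
            if np.array_equal(end, coords[0]):
                out.insert(0, np.asarray(ext)[::-1])
            else:
                out.append(np.asarray(ext))
    return np.concatenate(out, axis=0)


def extract_centerline(
    mask: np.ndarray, image: np.ndarray | None = None, n_points: int = 1001
) -> Centerline:
    """Thin the mask to a skeleton, reject cyclic (self-intersecting)
    skeletons, prune side branches, smooth (31-sample running mean) and
    resample the remaining path to 1001 evenly spaced points."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 50:
        raise ValueError("mask too small to carry a centerline (<50 px)")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = mask[r0:r1, c0:c1]
    skel = thin(sub)
    g = _skeleton_graph(skel)
    if len(g) < 2:
        raise ValueError("degenerate skeleton")
    if nx.cycle_basis(g):
        return Centerline(points=None, self_intersecting=True)
    sub_img = image[r0:r1, c0:c1] if image is not None else None
    g = _prune_branches(g, sub_img)

    ends = [n for n in g if g.degree(n) == 1]
    if len(ends) != 2:
        raise ValueError("skeleton did not reduce to a single path")
    path = nx.shortest_path(g, ends[0], ends[1])
    coords = np.asarray(path, dtype=float)  # (n, 2) as (row, col)
    coords = _extend_to_boundary(coords, sub)
    coords = uniform_filter1d(coords, size=31, axis=0, mode="nearest")
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_points)
    resampled = np.stack(
        [np.interp(targets, arc, coords[:, i]) for i in range(2)], axis=1
    )
    points_xy = resampled[:, ::-1] + np.array([c0, r0])  # (x, y)
    return Centerline(points=points_xy, self_intersecting=False)


# ---------------------------------------------------------------------------
# posture


def compute_posture(
    centerline: Centerline, pixel_size: float = 1.44
) -> PostureVector | None:
    """Fit the 1000 inter-point tangent angles with the 14-component basis.

    Returns None for self-intersecting frames (posture is missing there).
    Curvature is the arc-length derivative of the tangent angle, in 1/µm.
    """
    if centerline.self_intersecting or centerline.points is None:
        return None
    d = np.diff(centerline.points, axis=0)
    angles = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    coeffs = _splines.fit_coeffs(angles, _splines.N_ANGLE_COEFFS)
    orientation = float(angles.mean())
    # partition of unity: shifting all coefficients by the reconstruction
    # mean leaves a basis expansion with mean exactly zero
    B = _splines.design_matrix(_splines.N_ANGLE_COEFFS, angles.size)
    coeffs = coeffs - float((B @ coeffs).mean())
    ds_um = centerline.arc_length / (angles.size) * pixel_size
    curvature = np.gradient(angles) / ds_um
    return PostureVector(coeffs=coeffs, orientation=orientation, curvature=curvature)


def flip_angles(angles: np.ndarray) -> np.ndarray:
    """Reverse head/tail on a tangent-angle vector.

    Reverses the order and rotates by pi, choosing the sign of the rotation
    so that the mean stays in (-pi, pi]; this makes the operation an exact
    involution.
    """
    b = np.asarray(angles, dtype=float)[::-1].copy()
    return b + np.pi if b.mean() <= 0 else b - np.pi


def _wrapped_diff(a: float, b: float) -> float:
    return (a - b + np.pi) % (2 * np.pi) - np.pi


def assign_head_tail(
    angle_vectors: np.ndarray,
    intensity_profiles: np.ndarray,
    valid: np.ndarray,
    global_flip: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Make the arbitrary per-frame head/tail choice consistent.

    Stage 1: within each contiguous block of valid frames, a frame whose
    mean angle differs from its (already corrected) predecessor by more
    than pi/2 is flipped — a real worm cannot reverse its orientation in
    one 50 ms frame period.  Stage 2: each block is flipped wholesale if
    the reverse of its mean centerline-intensity profile correlates better
    (Pearson) with the previous block's profile.  Stage 3: ``global_flip``
    flips every frame, for when external evidence says the labeled head is
    actually the tail.

    Returns ``(angles, intensity_profiles, flipped)`` with per-frame net
    flip flags.
    """
    angles = np.array(angle_vectors, dtype=float)
    profiles = np.array(intensity_profiles, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = angles.shape[0]
    flipped = np.zeros(n, dtype=bool)

    # contiguous valid blocks
    blocks: list[np.ndarray] = []
    idx = np.flatnonzero(valid)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        blocks = np.split(idx, splits)

    for block in blocks:
        for prev, cur in zip(block[:-1], block[1:]):
            if abs(_wrapped_diff(angles[cur].mean(), angles[prev].mean())) > np.pi / 2:
                angles[cur] = flip_angles(angles[cur])
                profiles[cur] = profiles[cur][::-1]
                flipped[cur] = ~flipped[cur]

    for j in range(1, len(blocks)):
        ref = profiles[blocks[j - 1]].mean(axis=0)
        mean_prof = profiles[blocks[j]].mean(axis=0)
        c_fwd = np.corrcoef(ref, mean_prof)[0, 1]
        c_rev = np.corrcoef(ref, mean_prof[::-1])[0, 1]
        if c_rev > c_fwd:
            for i in block_iter(blocks[j]):
                angles[i] = flip_angles(angles[i])
                profiles[i] = profiles[i][::-1]
                flipped[i] = ~flipped[i]

    if global_flip:
        for i in np.flatnonzero(valid):
            angles[i] = flip_angles(angles[i])
            profiles[i] = profiles[i][::-1]
            flipped[i] = ~flipped[i]
    return angles, profiles, flipped


def block_iter(block: np.ndarray):
    return (int(i) for i in block)


# ---------------------------------------------------------------------------
# half widths


def compute_half_widths(
    mask: np.ndarray,
    centerline: Centerline,
    max_width_px: float = 40.0,
    step_px: float = 0.5,
) -> np.ndarray | None:
    """Perpendicular centerline-to-edge distance on each side, compressed
    to two 30-coefficient spline vectors.

    Side 0 is the left of the head-to-tail direction of travel along the
    centerline, side 1 the right.  Returns None (missing) when the
    centerline exits the mask.
    """
    if centerline.points is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    pts = centerline.points  # (1001, 2) as (x, y)
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)  # left of travel

    inside0 = _sample_mask(mask, pts)
    if not inside0.all():
        return None
    steps = np.arange(step_px, max_width_px + step_px, step_px)
    out = np.empty((2, _splines.N_WIDTH_COEFFS))
    for side, sign in enumerate((1.0, -1.0)):
        probe = pts[:, None, :] + sign * steps[None, :, None] * normal[:, None, :]
        inside = _sample_mask(mask, probe.reshape(-1, 2)).reshape(pts.shape[0], -1)
        first_out = np.argmin(inside, axis=1).astype(float)
        first_out[inside.all(axis=1)] = steps.size
        widths = first_out * step_px
        out[side] = _splines.fit_coeffs(widths, _splines.N_WIDTH_COEFFS)
    return out


def _sample_mask(mask: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    r = np.clip(np.round(pts_xy[:, 1]).astype(int), 0, mask.shape[0] - 1)
    c = np.clip(np.round(pts_xy[:, 0]).astype(int), 0, mask.shape[1] - 1)
    inb = (
        (pts_xy[:, 1] >= -0.5)
        & (pts_xy[:, 1] < mask.shape[0] - 0.5)
        & (pts_xy[:, 0] >= -0.5)
        & (pts_xy[:, 0] < mask.shape[1] - 0.5)
    )
    return mask[r, c] & inb


# ---------------------------------------------------------------------------
# locomotion


def compute_locomotion(
    record: BehaviorRecord,
    lawn: LawnBoundary | None = None,
    windows_s: tuple[float, ...] = (1.0, 10.0),
) -> dict[str, np.ndarray]:
    """Speed, body-axis velocity, angular velocity and lawn distance.

    Each kinematic quantity is computed as a centered finite difference
    over 1-s and 10-s windows.  Velocity is the signed projection of the
    centroid displacement onto the forward body axis (positive = forward,
    i.e. toward the head); on frames without a valid posture the axis sign
    is carried from the last valid frame.  Speeds/velocities are mm/s,
    angular velocity rad/s, lawn distance µm (0 on the lawn).
    """
    t = record.timestamps
    n = record.n_frames
    fr = record.frame_rate
    pos = record.centroid  # µm

    # forward unit vector: tangent angles run head->tail, so forward is -tangent
    ori = record.orientation.copy()
    if not record.valid_posture.all() and record.valid_posture.any():
        valid_idx = np.flatnonzero(record.valid_posture)
        ori = np.interp(np.arange(n), valid_idx, ori[valid_idx])
    axis = -np.stack([np.cos(ori), np.sin(ori)], axis=1)

    out: dict[str, np.ndarray] = {}
    for w in windows_s:
        half = max(1, int(round(w * fr / 2)))
        disp = np.full((n, 2), np.nan)
        disp[half:-half] = pos[2 * half :] - pos[: -2 * half]
        dt = np.full(n, np.nan)
        dt[half:-half] = t[2 * half :] - t[: -2 * half]
        speed = np.linalg.norm(disp, axis=1) / dt / 1000.0
        velocity = np.einsum("ij,ij->i", disp, axis) / dt / 1000.0
        direction = np.arctan2(disp[:, 1], disp[:, 0])
        finite = np.isfinite(direction)
        unwrapped = np.full(n, np.nan)
        if finite.any():
            unwrapped[finite] = np.unwrap(direction[finite])
        angvel = np.full(n, np.nan)
        angvel[half:-half] = (unwrapped[2 * half :] - unwrapped[: -2 * half]) / dt[
            half:-half
        ]
        tag = f"{w:g}s"
        out[f"speed_{tag}"] = speed
        out[f"velocity_{tag}"] = velocity
        out[f"angular_velocity_{tag}"] = angvel

    if lawn is not None:
        import shapely
        from shapely.geometry import Polygon

        poly = Polygon(lawn.vertices)
        points = shapely.points(pos)
        inside = shapely.covers(poly, points)
        dist = shapely.distance(points, poly.exterior)
        dist[inside] = 0.0
        out["lawn_distance"] = dist
    return out
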