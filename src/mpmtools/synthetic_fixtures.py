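"""Seeded, ground-truthed synthetic images for every pipeline stage.

Three generators emulate the statistical/geometric structure of the
assay images (not their photorealism):

* **well fixtures** — a circular (or superelliptic) well containing
  bright cell regions covering an exactly known fraction of the well;
* **invasion fixtures** — Z-stacks whose planes down to a known index
  carry in-focus cell speckle and are defocus-blurred below it;
* **vessel fixtures** — random embedded trees drawn as Gaussian-profile
  tubes.  Vessels are rendered as chains of bright cell-like beads with
  emphasised tip and junction cells, the way real microvessels image as
  strings of labelled endothelial cells of non-uniform brightness; this
  is also what ridge-based graph extraction keys on.

All generators are bit-reproducible under a fixed seed and return exact
ground truth (constructed, not estimated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import LineString

from mpmtools.errors import FixtureSpecError
from mpmtools.imaging_io import WellBoundary, ZStack
from mpmtools.morse_graph import EmbeddedGraph


# --------------------------------------------------------------------------
# well coverage fixtures
# --------------------------------------------------------------------------

@dataclass
class WellFixtureSpec:
    image_size: int = 256
    well_radius_fraction: float = 0.9      # of min(H, W) / 2
    fraction: float = 0.25                 # requested cell coverage of the well
    mu_background: float = 25.0
    sigma_background: float = 5.0
    mu_foreground: float = 180.0
    sigma_foreground: float = 12.0
    mu_outside: float = 8.0                # out-of-well plastic level
    sigma_outside: float = 3.0
    blob_scale_px: float = 8.0             # correlation length of the cell pattern
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise FixtureSpecError("coverage fraction must lie in [0, 1]")
        sep = self.mu_foreground - self.mu_background
        if sep <= 3.0 * max(self.sigma_background, self.sigma_foreground):
            raise FixtureSpecError("foreground and background intensities must be distinguishable")


def make_well_fixture(spec: WellFixtureSpec) -> tuple[np.ndarray, float, WellBoundary]:
    """Render a well image with an exactly realised coverage fraction.

    The cell region is the top-k set of a smooth random field inside the
    well, with k = round(fraction * well area) pixels, so the realised
    fraction matches the request to within one pixel.  The out-of-well
    region images as dark plastic, giving the rim a detectable edge.
    Returns (image, true_fraction, true_boundary).
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    radius = spec.well_radius_fraction * s / 2.0
    well = (xx - c) ** 2 + (yy - c) ** 2 <= radius**2
    well_area = int(well.sum())

    k = int(round(spec.fraction * well_area))
    cells = np.zeros((s, s), dtype=bool)
    if k > 0:
        phi = ndi.gaussian_filter(rng.normal(size=(s, s)), spec.blob_scale_px)
        vals = phi[well]
        cut = np.partition(vals, well_area - k)[well_area - k]
        cells = well & (phi >= cut)
        # exact count: break ties at the cut value deterministically
        excess = int(cells.sum()) - k
        if excess > 0:
            ties = np.flatnonzero((phi.ravel() == cut) & cells.ravel())
            cells.ravel()[ties[:excess]] = False

    img = rng.normal(spec.mu_background, spec.sigma_background, size=(s, s))
    img[~well] = rng.normal(spec.mu_outside, spec.sigma_outside, size=int((~well).sum()))
    img[cells] = rng.normal(spec.mu_foreground, spec.sigma_foreground, size=int(cells.sum()))
    true_fraction = cells.sum() / well_area

    boundary = WellBoundary(kind="circle", center=(c, c), radius=radius)
    boundary.mask = well
    return img, float(true_fraction), boundary


# --------------------------------------------------------------------------
# invasion Z-stack fixtures
# --------------------------------------------------------------------------

@dataclass
class InvasionFixtureSpec:
    plane_count: int = 8
    z_step_um: float = 10.0
    deepest_invaded_index: int = 3
    image_size: int = 48
    pixel_size_um: float = 5.0
    blur_sigma: float = 3.0        # defocus blur of non-invaded planes
    speckle_scale_px: float = 1.5
    speckle_fraction: float = 0.25
    mu_background: float = 20.0
    mu_cells: float = 200.0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.deepest_invaded_index < self.plane_count:
            raise FixtureSpecError("deepest invaded index must be a valid plane index")


def _speckle_plane(rng: np.random.Generator, spec: InvasionFixtureSpec, sharp: bool) -> np.ndarray:
    s = spec.image_size
    phi = ndi.gaussian_filter(rng.normal(size=(s, s)), spec.speckle_scale_px)
    cut = np.quantile(phi, 1.0 - spec.speckle_fraction)
    img = np.full((s, s), spec.mu_background, dtype=np.float64)
    img[phi >= cut] = spec.mu_cells
    if not sharp:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    return img + rng.normal(0.0, spec.noise_sigma, size=(s, s))


def make_invasion_fixture(spec: InvasionFixtureSpec) -> tuple[ZStack, float]:
    """Z-stack with sharp (in-focus) cell speckle down to the deepest
    invaded plane and defocus-blurred texture below it.

    True depth is ``deepest_invaded_index * z_step_um``.
    """
    rng = np.random.default_rng(spec.seed)
    planes = [
        _speckle_plane(rng, spec, sharp=(i <= spec.deepest_invaded_index))
        for i in range(spec.plane_count)
    ]
    stack = ZStack(planes=planes, z_step_um=spec.z_step_um, pixel_size_um=spec.pixel_size_um, channel_label="cancer")
    return stack, float(spec.deepest_invaded_index * spec.z_step_um)


def make_invasion_training_set(
    n_planes: int = 200,
    spec: InvasionFixtureSpec | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, int]]:
    """Labelled single planes (sharp = invaded = 1, blurred = 0) for
    training the fixture classifier; balanced classes."""
    spec = spec or InvasionFixtureSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_planes):
        sharp = i % 2 == 0
        out.append((_speckle_plane(rng, spec, sharp=sharp), int(sharp)))
    return out


# --------------------------------------------------------------------------
# vessel network fixtures
# --------------------------------------------------------------------------

@dataclass
class VesselFixtureSpec:
    n_branches: int = 5                     # leaves of the generated tree
    image_size: int = 256
    pixel_size_um: float = 2.0
    branch_length_um: tuple[float, float] = (30.0, 300.0)
    tube_width_px: float = 5.0              # Gaussian cross-section sigma ~ width/2.5
    snr: float = 5.0                        # tube amplitude / noise sigma
    bead_spacing_px: float = 12.0           # cell-to-cell spacing along a vessel
    bead_amplitude: float = 0.5             # extra brightness of cell bodies
    tip_amplitude: float = 0.8              # extra brightness of tip/junction cells
    render: str = "projection"              # "projection" | "zstack"
    n_planes: int = 8
    z_step_um: float = 20.0
    margin_px: int = 20
    min_separation_px: float = 10.0         # between non-adjacent branches
    seed: int = 0
    max_seed_retries: int = 80

    def __post_init__(self) -> None:
        if self.n_branches < 0:
            raise FixtureSpecError("n_branches must be nonnegative")
        if self.render not in ("projection", "zstack"):
            raise FixtureSpecError("render must be 'projection' or 'zstack'")


def _grow_tree(spec: VesselFixtureSpec, rng: np.random.Generator) -> list[np.ndarray] | None:
    """Grow a planar tree with ``n_branches`` leaves; returns a list of
    branch polylines (x, y in px) or None when it self-intersects or
    leaves the frame."""
    s = spec.image_size
    lo, hi = spec.margin_px, s - 1 - spec.margin_px
    lmin_px = spec.branch_length_um[0] / spec.pixel_size_um
    lmax_px = spec.branch_length_um[1] / spec.pixel_size_um
    step = 4.0

    centre = np.array([s / 2.0, s / 2.0])

    def grow_branch(start: np.ndarray, heading: float, length: float | None = None) -> np.ndarray | None:
        if length is None:
            length = rng.uniform(lmin_px, lmax_px)
        pts = [start]
        pos = start.copy()
        travelled = 0.0
        while travelled < length:
            heading += rng.normal(0.0, np.deg2rad(6.0))
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            if not (lo <= pos[0] <= hi and lo <= pos[1] <= hi):
                return None
            pts.append(pos.copy())
            travelled += step
        return np.asarray(pts)

    heading0 = rng.uniform(0, 2 * np.pi)
    cap = 0.8 * (hi - lo)
    trunk_len = rng.uniform(min(lmin_px, cap * 0.95), min(lmax_px, cap))
    direction = np.array([np.cos(heading0), np.sin(heading0)])
    start = np.array([s / 2.0, s / 2.0]) - direction * trunk_len / 2.0 + rng.uniform(-s / 10, s / 10, size=2)
    start = np.clip(start, lo + 1, hi - 1)
    trunk = grow_branch(start, heading0, length=trunk_len)
    if trunk is None:
        return None
    branches = [trunk]
    # a bare trunk has 2 endpoints; each split adds one more, so a tree
    # with n_branches endpoints (= barcode bars) needs n_branches - 2 splits
    open_tips = [(trunk, heading0)]
    target_splits = max(0, spec.n_branches - 2)
    splits = 0
    attempts = 0
    while splits < target_splits and attempts < 500:
        attempts += 1
        i = rng.integers(0, len(open_tips))
        parent, heading = open_tips[i]
        tip = parent[-1]
        dtheta = np.deg2rad(rng.uniform(25.0, 55.0))
        kids = []
        ok = True
        for sign in (+1.0, -1.0):
            child = grow_branch(tip, heading + sign * dtheta)
            if child is None:
                ok = False
                break
            kids.append((child, heading + sign * dtheta))
        if not ok:
            continue
        branches.extend(c for c, _ in kids)
        open_tips.pop(i)
        open_tips.extend(kids)
        splits += 1
    if splits != target_splits:
        return None

    # self-intersection check between non-adjacent branches
    lines = [LineString(b) for b in branches]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            touching = (
                np.allclose(branches[i][-1], branches[j][0])
                or np.allclose(branches[j][-1], branches[i][0])
                or np.allclose(branches[i][0], branches[j][0])
            )
            d = lines[i].distance(lines[j])
            if not touching and d < spec.min_separation_px:
                return None
            if touching:
                # adjacent branches may only be close near the shared point
                li, lj = lines[i], lines[j]
                if li.length > 3 * spec.min_separation_px and lj.length > 3 * spec.min_separation_px:
                    mid_i = LineString(branches[i][len(branches[i]) // 3 : 2 * len(branches[i]) // 3 + 1])
                    if mid_i.distance(lj) < spec.min_separation_px / 2 and mid_i.length > 1:
                        return None
    return branches


def _true_graph(branches: list[np.ndarray], pixel_size_um: float) -> EmbeddedGraph:
    g = EmbeddedGraph(pixel_size_um=pixel_size_um)
    key: dict[tuple[int, int], int] = {}

    def vid(pt: np.ndarray) -> int:
        k = (int(round(pt[0] * 10)), int(round(pt[1] * 10)))
        if k not in key:
            key[k] = len(key)
            g.add_vertex(key[k], pt[0], pt[1])
        return key[k]

    for b in branches:
        g.add_edge(vid(b[0]), vid(b[-1]), b)
    return g


def _render_intensity(branches: list[np.ndarray], spec: VesselFixtureSpec, subset: list[int] | None = None) -> np.ndarray:
    """Noise-free tube rendering: Gaussian cross-section tubes with bead,
    tip and junction cells along the centrelines.  Peak amplitude 1."""
    s = spec.image_size
    img = np.zeros((s, s), dtype=np.float64)
    sigma = spec.tube_width_px / 2.5
    idxs = range(len(branches)) if subset is None else subset
    centre = np.zeros((s, s), dtype=bool)
    bead_pts: list[np.ndarray] = []
    tip_pts: list[np.ndarray] = []
    for bi in idxs:
        b = branches[bi]
        # dense resample of the centreline
        seg = np.diff(b, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        total = seglen.sum()
        if total == 0:
            continue
        t = np.concatenate([[0.0], np.cumsum(seglen)])
        u = np.linspace(0.0, total, max(2, int(total * 2)))
        xs = np.interp(u, t, b[:, 0])
        ys = np.interp(u, t, b[:, 1])
        rr = np.clip(np.round(ys).astype(int), 0, s - 1)
        cc = np.clip(np.round(xs).astype(int), 0, s - 1)
        centre[rr, cc] = True
        for d in np.arange(spec.bead_spacing_px, total - spec.bead_spacing_px / 2, spec.bead_spacing_px):
            bead_pts.append(np.array([np.interp(d, t, b[:, 0]), np.interp(d, t, b[:, 1])]))
        tip_pts.append(b[0])
        tip_pts.append(b[-1])

    if centre.any():
        dist = ndi.distance_transform_edt(~centre)
        img = np.exp(-(dist**2) / (2 * sigma**2))

    yy, xx = np.mgrid[0:s, 0:s]

    def add_blobs(points, amp, blob_sigma):
        out = np.zeros((s, s))
        for p in points:
            d2 = (xx - p[0]) ** 2 + (yy - p[1]) ** 2
            out = np.maximum(out, amp * np.exp(-d2 / (2 * blob_sigma**2)))
        return out

    img += add_blobs(bead_pts, spec.bead_amplitude, sigma)
    img += add_blobs(tip_pts, spec.tip_amplitude, sigma * 1.2)
    return img / img.max() if img.max() > 0 else img


def make_vessel_fixture(
    spec: VesselFixtureSpec,
) -> tuple[np.ndarray | ZStack, EmbeddedGraph, np.ndarray]:
    """Render a random vessel tree with exact ground truth.

    Returns (image-or-ZStack, true_graph, true_mask).  The true graph
    carries exact branch polylines and lengths; the mask is the tube
    support (within one tube width of a centreline).  Trees that
    self-intersect or leave the frame are regenerated with the next
    seed (up to ``max_seed_retries``).
    """
    if spec.n_branches == 0:
        s = spec.image_size
        blank = np.zeros((s, s))
        if spec.render == "zstack":
            rng = np.random.default_rng(spec.seed)
            noise = 1.0 / spec.snr if spec.snr > 0 else 0.0
            planes = [np.abs(rng.normal(0, noise, (s, s))) for _ in range(spec.n_planes)]
            return (
                ZStack(planes=planes, z_step_um=spec.z_step_um, pixel_size_um=spec.pixel_size_um),
                EmbeddedGraph(pixel_size_um=spec.pixel_size_um),
                blank.astype(bool),
            )
        return blank, EmbeddedGraph(pixel_size_um=spec.pixel_size_um), blank.astype(bool)

    branches = None
    used_seed = spec.seed
    for trial in range(spec.max_seed_retries):
        used_seed = spec.seed + trial
        rng = np.random.default_rng(used_seed)
        branches = _grow_tree(spec, rng)
        if branches is not None:
            break
    if branches is None:
        raise FixtureSpecError(
            f"could not grow a non-self-intersecting {spec.n_branches}-branch tree "
            f"within {spec.max_seed_retries} seeds from {spec.seed}"
        )
    rng = np.random.default_rng(used_seed + 10_000_019)

    truth = _true_graph(branches, spec.pixel_size_um)
    s = spec.image_size
    clean = _render_intensity(branches, spec)
    centre_mask = clean > 1e-6
    # support mask: within one tube width of the centreline
    dist_all = ndi.distance_transform_edt(clean < np.exp(-0.5))  # ~1 sigma contour of the tube profile
    true_mask = dist_all <= spec.tube_width_px

    noise_sigma = 1.0 / spec.snr if spec.snr > 0 else 0.0

    if spec.render == "projection":
        img = clean + rng.normal(0.0, noise_sigma, size=(s, s))
        return img, truth, true_mask

    # z-stack: each branch lives on one plane, defocused elsewhere
    plane_of = rng.integers(0, spec.n_planes, size=len(branches))
    planes = []
    for k in range(spec.n_planes):
        plane = np.zeros((s, s))
        for bi in range(len(branches)):
            contrib = _render_intensity(branches, spec, subset=[bi])
            dz = abs(int(plane_of[bi]) - k)
            if dz > 0:
                contrib = ndi.gaussian_filter(contrib, sigma=1.5 * dz) * (0.6**dz)
            plane = np.maximum(plane, contrib)
        plane = plane + rng.normal(0.0, noise_sigma, size=(s, s))
        planes.append(plane)
    stack = ZStack(planes=planes, z_step_um=spec.z_step_um, pixel_size_um=spec.pixel_size_um, channel_label="endothelial")
    return stack, truth, true_mask


def make_segmentation_pairs(n: int = 40, seed: int = 0, image_size: int = 128) -> list[tuple[np.ndarray, np.ndarray]]:
    """Desk-scale (image, binary mask) pairs for segmenter training:
    dense small trees at a coarse pixel size so several branches fit a
    small frame."""
    pairs = []
    for i in range(n):
        spec = VesselFixtureSpec(
            n_branches=3 + i % 4,
            seed=seed * 100_003 + 50 * i,
            image_size=image_size,
            branch_length_um=(40.0, 160.0),
            pixel_size_um=4.0,
            margin_px=14,
            tube_width_px=4.0,
            min_separation_px=9.0,
            bead_spacing_px=10.0,
        )
        img, _, mask = make_vessel_fixture(spec)
        pairs.append((np.asarray(img), mask.astype(np.uint8)))
    return pairs


def true_network_stats(truth: EmbeddedGraph) -> dict:
    """Exact ground-truth statistics of a fixture tree, measured with the
    same root-at-centre barcode the analysis pipeline reports, but on the
    exact constructed polylines (no estimation involved)."""
    from mpmtools.topology_stats import network_statistics

    g = truth.graph
    if g.number_of_nodes() == 0:
        return {"branch_count": 0, "total_length_um": 0.0}
    stats, _ = network_statistics(truth)
    return {
        "branch_count": stats.branch_count,
        "total_length_um": stats.total_length_um,
    }
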