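"""Synthetic angiogram generator with exact ground truth.

Emulates the features of contrast X-ray angiograms that matter for the
segmentation task: a branching tree of smooth curvilinear vessels that are
*darker* than the background (contrast medium attenuates the beam), uneven
per-branch filling, a low-frequency illumination gradient, Gaussian noise,
and the two classic confounders — a high-contrast catheter touching the
vessel root (deliberately excluded from the ground-truth mask, mirroring
clinical labelling practice) and broad low-contrast rib-like bands. The
tree is rooted at the left image border for LCA samples and the right
border for RCA samples, so the side label is recoverable from geometry.

Everything is deterministic given (spec, seed).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, interpolate

from .preprocess import RawAngiogram


@dataclass(frozen=True)
class SyntheticSpec:
    size: int = 256
    side: str = "random"                   # LCA | RCA | random
    n_branches: tuple = (3, 7)             # child branches beyond the trunk
    width_root: tuple = (4.0, 9.0)         # px
    taper: tuple = (0.6, 0.9)              # per-generation width decay
    vessel_contrast: tuple = (20.0, 60.0)  # intensity deficit vs background
    noise_sigma: float = 8.0
    background: float = 30.0               # low-frequency gradient amplitude
    catheter_prob: float = 0.3
    rib_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("size must be >= 64")
        for name in ("n_branches", "width_root", "taper", "vessel_contrast"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} range must be positive and ordered")
        if self.side not in ("LCA", "RCA", "random"):
            raise ValueError("side must be LCA, RCA or random")


@dataclass
class SyntheticSample:
    image: RawAngiogram
    mask: np.ndarray                       # (H,W) uint8 in {0,1}
    side: str
    spec: SyntheticSpec = None
    seed: int = 0


def _smooth_curve(rng, start, direction, length, n_ctrl=5, wobble=0.35):
    """Spline through a gently wandering random walk; ~1 px point spacing."""
    pts = [np.asarray(start, dtype=float)]
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    step = length / n_ctrl
    for _ in range(n_ctrl):
        ang = rng.normal(0.0, wobble)
        c, s = np.cos(ang), np.sin(ang)
        d = np.array([d[0] * c - d[1] * s, d[0] * s + d[1] * c])
        pts.append(pts[-1] + d * step)
    pts = np.array(pts)
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
    u = np.linspace(0, 1, max(8, int(2 * length)))
    ys, xs = interpolate.splev(u, tck)
    return np.column_stack([ys, xs]), d


def _stamp_tube(canvas, pts, widths, value):
    """Max-composite disks of radius width/2 along the polyline."""
    h, w = canvas.shape
    for (y, x), wd, v in zip(pts, widths, value):
        r = max(0.5, wd / 2.0)
        ri = int(np.ceil(r))
        y0, y1 = int(np.floor(y - ri)), int(np.ceil(y + ri)) + 1
        x0, x1 = int(np.floor(x - ri)), int(np.ceil(x + ri)) + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, h), min(x1, w)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        region = canvas[y0c:y1c, x0c:x1c]
        np.maximum(region, np.where(disk, v, 0.0), out=region)


def generate_tree(spec: SyntheticSpec | None = None, seed: int | None = None) -> SyntheticSample:
    """Render one synthetic angiogram with its exact vessel mask."""
    spec = spec or SyntheticSpec()
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    n = spec.size

    side = spec.side
    if side == "random":
        side = "LCA" if rng.random() < 0.5 else "RCA"

    n_branches = int(rng.integers(spec.n_branches[0], spec.n_branches[1] + 1))
    if n_branches < 1:
        raise ValueError("degenerate spec: zero branches")
    root_w = rng.uniform(*spec.width_root)

    # trunk roots at the side border, descends along it and curves inward —
    # waypoints keep most vessel mass on the root side, as a catheter-fed
    # arterial tree does
    inward = 1.0 if side == "LCA" else -1.0
    border = 0.0 if side == "LCA" else float(n - 1)
    r0 = rng.uniform(0.08, 0.3) * n
    waypoints = np.array([
        [r0, border],
        [r0 + rng.uniform(0.15, 0.25) * n, border + inward * rng.uniform(0.04, 0.10) * n],
        [r0 + rng.uniform(0.35, 0.50) * n, border + inward * rng.uniform(0.12, 0.22) * n],
        [min(0.92 * n, r0 + rng.uniform(0.55, 0.70) * n),
         border + inward * rng.uniform(0.30, 0.45) * n],
    ])
    root = (r0, border)
    tck, _ = interpolate.splprep([waypoints[:, 0], waypoints[:, 1]], s=0, k=3)
    trunk_len = float(np.hypot(*np.diff(waypoints, axis=0).T).sum())
    u = np.linspace(0, 1, max(8, int(2 * trunk_len)))
    trunk_pts = np.column_stack(interpolate.splev(u, tck))

    vessel = np.zeros((n, n), dtype=np.float64)   # contrast-deficit map
    segments = [(trunk_pts, root_w, 0)]           # (points, width, generation)

    far_limit = 8.0  # keep the tree off the opposite border: side stays decodable
    def _truncate(pts):
        d_far = (n - 1 - pts[:, 1]) if side == "LCA" else pts[:, 1]
        bad = np.nonzero(d_far < far_limit)[0]
        return pts[:bad[0]] if len(bad) else pts

    def draw(pts, width):
        contrast = rng.uniform(*spec.vessel_contrast)
        # uneven filling: smooth multiplicative profile along the branch
        prof = ndimage.gaussian_filter1d(rng.uniform(0.6, 1.0, len(pts)), 25, mode="nearest")
        widths = np.linspace(width, max(1.2, 0.6 * width), len(pts))
        _stamp_tube(vessel, pts, widths, contrast * prof)

    draw(trunk_pts, root_w)
    grown = 0
    frontier = [segments[0]]
    while grown < n_branches and frontier:
        parent_pts, parent_w, gen = frontier.pop(rng.integers(len(frontier)))
        n_child = min(n_branches - grown, int(rng.integers(1, 3)))
        for _ in range(n_child):
            if grown >= n_branches:
                break
            if gen == 0:
                # side-typical morphology: the left main bifurcates early
                # (LAD/LCx); the right coronary branches in its distal half
                lo, hi = (0.08, 0.85) if side == "LCA" else (0.45, 0.95)
            else:
                lo, hi = 0.2, 0.95
            i = int(rng.uniform(lo, hi) * (len(parent_pts) - 1))
            p0 = parent_pts[i]
            d0 = parent_pts[min(i + 3, len(parent_pts) - 1)] - parent_pts[max(i - 3, 0)]
            nd = np.linalg.norm(d0)
            if nd < 1e-6:
                continue
            d0 = d0 / nd
            ang = rng.uniform(0.3, 1.0) * (1 if rng.random() < 0.5 else -1)
            c, s = np.cos(ang), np.sin(ang)
            d = np.array([d0[0] * c - d0[1] * s, d0[0] * s + d0[1] * c])
            length = rng.uniform(0.25, 0.6) * n * (0.8 ** gen)
            w = max(1.5, parent_w * rng.uniform(*spec.taper))
            pts, _ = _smooth_curve(rng, p0, d, length, n_ctrl=4)
            pts = _truncate(pts)
            if len(pts) < 4:
                continue
            draw(pts, w)
            grown += 1
            frontier.append((pts, w, gen + 1))

    mask = (vessel > 0).astype(np.uint8)

    # background: mid-gray + tilted plane + smooth blob field
    yy, xx = np.mgrid[0:n, 0:n] / n
    g1, g2 = rng.uniform(-1, 1, 2)
    plane = spec.background * (g1 * (yy - 0.5) + g2 * (xx - 0.5))
    blob = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), n / 8.0)
    blob *= 0.5 * spec.background / max(blob.std(), 1e-9)
    img = 150.0 + plane + blob

    # rib-like bands: broad, faint, roughly diagonal strips
    if rng.random() < spec.rib_prob:
        for _ in range(int(rng.integers(1, 3))):
            theta = rng.uniform(0.3, 1.2) * (1 if rng.random() < 0.5 else -1)
            nx, ny = np.cos(theta), np.sin(theta)
            offset = rng.uniform(-0.4, 0.4) * n
            dist = (xx - 0.5) * n * nx + (yy - 0.5) * n * ny - offset
            band = np.exp(-0.5 * (dist / rng.uniform(12, 25)) ** 2)
            img -= rng.uniform(8, 15) * band

    # catheter: near-straight high-contrast curve touching the root, NOT in mask
    catheter = np.zeros_like(vessel)
    if rng.random() < spec.catheter_prob:
        entry = (0.0, border + inward * rng.uniform(2.0, 5.0))
        tip = (root[0] + rng.uniform(0.05, 0.12) * n, border + inward * 2.0)
        to_tip = np.asarray(tip) - np.asarray(entry)
        nrm = np.linalg.norm(to_tip)
        cpts, _ = _smooth_curve(rng, entry, to_tip / nrm, nrm, n_ctrl=3, wobble=0.05)
        cw = rng.uniform(3.0, 5.0)
        _stamp_tube(catheter, cpts, np.full(len(cpts), cw),
                    np.full(len(cpts), rng.uniform(70, 100)))

    img = img - vessel - catheter
    img = img + rng.normal(0.0, spec.noise_sigma, (n, n))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticSample(RawAngiogram(img, source_id=f"synthetic-{seed}"),
                           mask, side, spec, seed)


def generate_dataset(n: int, spec: SyntheticSpec | None = None, seed: int = 0,
                     out_dir: str | Path | None = None):
    """Generate ``n`` samples; optionally write PNGs plus a manifest CSV.

    When ``spec.side`` is "random" the LCA/RCA counts are balanced to within
    one. Returns a list of manifest dict rows; with ``out_dir`` the rows
    reference the written files and the list is also saved as manifest.csv.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    if spec.side == "random":
        sides = ["LCA" if i % 2 == 0 else "RCA" for i in range(n)]
        rng.shuffle(sides)
    else:
        sides = [spec.side] * n

    from . import fileio
    rows, samples = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (s, side) in enumerate(zip(sub_seeds, sides)):
        sample_spec = SyntheticSpec(**{**asdict(spec), "side": side})
        sample = generate_tree(sample_spec, int(s))
        samples.append(sample)
        row = {"image_path": f"img_{i:04d}.png", "mask_path": f"mask_{i:04d}.png",
               "patient_id": f"synth-{i:04d}", "side": side}
        if out is not None:
            fileio.save_image(out / row["image_path"], sample.image.pixels)
            fileio.save_mask(out / row["mask_path"], sample.mask)
        rows.append(row)
    if out is not None:
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    return rows, samples
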