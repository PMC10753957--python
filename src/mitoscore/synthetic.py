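"""Synthetic label volumes with controlled segmentation errors.

Two generators are provided:

- :func:`build_fig4_scene` reconstructs a six-instance toy scene (two small,
  three medium, one large MOAS-like mitochondrion, grouped by cable length)
  whose prediction realizes a fixed error plan: three exact matches, one
  small+medium merger whose IoU with each constituent stays below 0.75, a
  four-way split of the large instance into medium-sized pieces each below
  0.75 IoU, and a configurable number of pure background false positives.
- :func:`random_scene` + :func:`random_plan` + :func:`inject_errors` produce
  seeded random blob/tube scenes with parameterized split / merge / FP
  injection, for parameter-recovery and property testing.

Instances are anisotropy-aware: geometry is laid out so cable lengths (at the
default 30 x 8 x 8 nm spacing) land in the intended small / medium / large
bands with margin.  :func:`render_bc_probabilities` turns any label volume
into foreground + contour probability maps for decoder tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import DEFAULT_SPACING_NM, LabelVolume, ProbVolume


@dataclass(frozen=True)
class ToySceneSpec:
    """Geometry and error plan of the six-instance toy scene.

    Instances are 3x3-voxel-section bars along z; at 30 nm z spacing the bar
    lengths below give cable lengths of ~0.57 um (small), ~1.47 um (medium)
    and ~4.77 um (large).  The split pieces (~1.17 um) are medium in their
    own right, and the merged prediction's IoU with its medium constituent is
    450/630 ~ 0.714 < 0.75 by construction.
    """

    n_small: int = 2
    n_medium: int = 3
    n_large: int = 1
    small_len: int = 20
    medium_len: int = 50
    large_len: int = 160
    split_pieces: int = 4
    n_background_fps: int = 17
    grid_shape: tuple[int, int, int] = (170, 40, 40)
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM
    seed: int = 0


@dataclass(frozen=True)
class ErrorPlan:
    """Seeded error-injection plan applied to a ground-truth volume.

    ``split``: gt id -> number of pieces; ``merge``: disjoint groups of gt
    ids fused into one prediction each; ``fp_count`` background blobs of
    radius ``fp_radius`` placed on free background; ``jitter``: per-instance
    boundary dilation (+n) or erosion (-n) in voxels.  Same seed, same
    output.
    """

    split: dict[int, int] = field(default_factory=dict)
    merge: tuple[tuple[int, ...], ...] = ()
    fp_count: int = 0
    fp_radius: int = 2
    jitter: int = 0
    seed: int = 0

    def validate(self, gt_ids: set[int]) -> None:
        touched: set[int] = set()
        for g, k in self.split.items():
            if g not in gt_ids:
                raise ValueError(f"split references unknown gt id {g}")
            if k < 2:
                raise ValueError(f"split of {g} needs >= 2 pieces, got {k}")
            touched.add(g)
        for group in self.merge:
            if len(group) < 2:
                raise ValueError(f"merge group {group} needs >= 2 ids")
            for g in group:
                if g not in gt_ids:
                    raise ValueError(f"merge references unknown gt id {g}")
                if g in touched:
                    raise ValueError(f"gt id {g} appears in more than one error role")
                touched.add(g)
        if self.fp_count < 0:
            raise ValueError("fp_count must be >= 0")


# ---------------------------------------------------------------------------
# toy scene


def build_fig4_scene(spec: ToySceneSpec = ToySceneSpec()) -> tuple[LabelVolume, LabelVolume]:
    """Reconstruct the six-instance toy scene and its error-laden prediction.

    GT ids are 1..6 in the order: smalls, mediums, large.  The prediction
    exactly matches one small and two mediums, merges the remaining
    small+medium pair into one instance, splits the large instance into
    ``split_pieces`` disjoint pieces overlapping only it, and adds
    ``n_background_fps`` blobs on background.
    """
    nz, ny, nx = spec.grid_shape
    lengths = (
        [spec.small_len] * spec.n_small
        + [spec.medium_len] * spec.n_medium
        + [spec.large_len] * spec.n_large
    )
    if max(lengths) + 10 > nz:
        raise ValueError("grid z extent too small for the planned bar lengths")
    lanes = [(y, x) for y in range(2, ny - 3, 5) for x in range(2, nx - 3, 5)]
    if len(lanes) < len(lengths):
        raise ValueError("grid cross-section too small for the planned instances")

    gt = np.zeros(spec.grid_shape, dtype=np.int64)
    for gid, (length, (y, x)) in enumerate(zip(lengths, lanes), start=1):
        gt[5 : 5 + length, y : y + 3, x : x + 3] = gid
    gt_vol = LabelVolume(gt, spec.spacing_nm)

    small_ids = list(range(1, spec.n_small + 1))
    medium_ids = list(range(spec.n_small + 1, spec.n_small + spec.n_medium + 1))
    large_id = spec.n_small + spec.n_medium + 1

    plan = ErrorPlan(
        split={large_id: spec.split_pieces},
        merge=((small_ids[-1], medium_ids[-1]),),
        fp_count=spec.n_background_fps,
        fp_radius=2,
        seed=spec.seed,
    )
    pred_vol = inject_errors(gt_vol, plan)
    return gt_vol, pred_vol


# ---------------------------------------------------------------------------
# random scenes


def random_scene(
    n_instances: int,
    shape: tuple[int, int, int] = (48, 64, 64),
    seed: int = 0,
    kind: str = "blob",
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM,
    cell: int = 16,
    radius_range: tuple[int, int] = (3, 6),
) -> LabelVolume:
    """Seeded random scene of non-overlapping blobs or z-oriented tubes.

    Instances are placed in disjoint lattice cells of edge ``cell``, so any
    two are separated by at least one background voxel; blob radii are drawn
    from ``radius_range`` (half-open) and positions are jittered by the
    seeded generator.  Radii must satisfy ``radius_range[1] + 2 <= cell // 2``
    so jittered blobs stay inside their cells.
    """
    if kind not in ("blob", "tube"):
        raise ValueError(f"kind must be 'blob' or 'tube', got {kind!r}")
    if radius_range[1] + 2 > cell // 2:
        raise ValueError("blob radius too large for the lattice cell")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    cells = [
        (z, y, x)
        for z in range(0, nz - cell + 1, cell)
        for y in range(0, ny - cell + 1, cell)
        for x in range(0, nx - cell + 1, cell)
    ]
    if len(cells) < n_instances:
        raise ValueError(f"{shape} holds at most {len(cells)} instances of cell {cell}")
    chosen = rng.choice(len(cells), size=n_instances, replace=False)
    grid = np.zeros(shape, dtype=np.int64)
    for gid, ci in enumerate(chosen, start=1):
        z0, y0, x0 = cells[ci]
        if kind == "blob":
            r = int(rng.integers(radius_range[0], radius_range[1]))
            cz = z0 + cell // 2 + int(rng.integers(-2, 3))
            cy = y0 + cell // 2 + int(rng.integers(-2, 3))
            cx = x0 + cell // 2 + int(rng.integers(-2, 3))
            zz, yy, xx = np.ogrid[:nz, :ny, :nx]
            ball = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            grid[ball] = gid
        else:
            w = int(rng.integers(2, 4))
            length = int(rng.integers(8, cell - 1))
            y = y0 + int(rng.integers(2, cell - w - 2))
            x = x0 + int(rng.integers(2, cell - w - 2))
            z = z0 + int(rng.integers(1, cell - length)) if cell - length > 1 else z0 + 1
            grid[z : z + length, y : y + w, x : x + w] = gid
    return LabelVolume(grid, spacing_nm)


def random_plan(gt: LabelVolume, seed: int = 0, max_pieces: int = 4) -> ErrorPlan:
    """Sample a valid random :class:`ErrorPlan` for ``gt``.

    Roles are disjoint: some GT are split (2..max_pieces pieces), some merged
    in pairs, the rest exact-matched; 0..5 background FPs.
    """
    rng = np.random.default_rng(seed)
    ids = [int(i) for i in gt.ids()]
    rng.shuffle(ids)
    n = len(ids)
    n_split = int(rng.integers(0, max(1, n // 2) + 1))
    split = {g: int(rng.integers(2, max_pieces + 1)) for g in ids[:n_split]}
    rest = ids[n_split:]
    merge: list[tuple[int, ...]] = []
    while len(rest) >= 2 and rng.random() < 0.5:
        arity = int(rng.integers(2, min(3, len(rest)) + 1))
        merge.append(tuple(sorted(rest[:arity])))
        rest = rest[arity:]
    return ErrorPlan(
        split=split,
        merge=tuple(merge),
        fp_count=int(rng.integers(0, 6)),
        fp_radius=2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# error injection


def _split_support(coords: np.ndarray, k: int) -> list[np.ndarray]:
    """Partition instance voxel coordinates into k contiguous slabs along the
    axis of greatest extent (ties toward z)."""
    extents = coords.max(axis=0) - coords.min(axis=0)
    axis = int(np.argmax(extents))
    order = np.lexsort(tuple(coords[:, a] for a in range(3) if a != axis) + (coords[:, axis],))
    chunks = np.array_split(coords[order], k)
    if any(len(c) == 0 for c in chunks):
        raise ValueError(f"instance too small to split into {k} pieces")
    return chunks


def inject_errors(gt: LabelVolume, plan: ErrorPlan) -> LabelVolume:
    """Realize an :class:`ErrorPlan` as a predicted label volume.

    Exact-matched GT are copied; split GT are partitioned into the requested
    piece counts by slab cuts; merge groups are fused under one id; FP blobs
    are placed on background without touching any instance.  Output ids are
    assigned in the order: copies, mergers, splits, FPs.
    """
    gt_ids = {int(i) for i in gt.ids()}
    plan.validate(gt_ids)
    rng = np.random.default_rng(plan.seed)
    pred = np.zeros(gt.shape, dtype=np.int64)
    next_id = 1

    merged = {g for group in plan.merge for g in group}
    for g in sorted(gt_ids):
        if g in plan.split or g in merged:
            continue
        pred[gt.grid == g] = next_id
        next_id += 1
    for group in plan.merge:
        for g in group:
            pred[gt.grid == g] = next_id
        next_id += 1
    for g in sorted(plan.split):
        coords = np.argwhere(gt.grid == g)
        for chunk in _split_support(coords, plan.split[g]):
            pred[tuple(chunk.T)] = next_id
            next_id += 1

    if plan.jitter:
        pred = _jitter(pred, gt.grid, plan.jitter)

    # background false positives: balls on free space, margin 1 from anything
    occupied = ndimage.binary_dilation((gt.grid > 0) | (pred > 0), iterations=plan.fp_radius + 1)
    nz, ny, nx = gt.shape
    placed = 0
    attempts = 0
    r = plan.fp_radius
    while placed < plan.fp_count:
        attempts += 1
        if attempts > 2000 * max(1, plan.fp_count):
            raise RuntimeError("could not place all planned false positives")
        cz = int(rng.integers(r, nz - r))
        cy = int(rng.integers(r, ny - r))
        cx = int(rng.integers(r, nx - r))
        if occupied[cz, cy, cx]:
            continue
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        ball = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if (occupied & ball).any():
            continue
        pred[ball] = next_id
        occupied |= ndimage.binary_dilation(ball, iterations=r + 1)
        next_id += 1
        placed += 1
    return LabelVolume(pred, gt.spacing_nm)


def _jitter(pred: np.ndarray, gt: np.ndarray, amplitude: int) -> np.ndarray:
    """Dilate (+) each predicted instance into background, or erode (-)."""
    out = pred.copy()
    for pid in np.unique(pred):
        if pid == 0:
            continue
        mask = pred == pid
        if amplitude > 0:
            grown = ndimage.binary_dilation(mask, iterations=amplitude)
            out[grown & (out == 0) & (gt == 0)] = pid
        else:
            shrunk = ndimage.binary_erosion(mask, iterations=-amplitude)
            if shrunk.any():
                out[mask & ~shrunk] = 0
    return out


# ---------------------------------------------------------------------------
# probability rendering


def render_bc_probabilities(
    gt: LabelVolume,
    noise_sd: float = 0.0,
    seed: int = 0,
    smooth_sigma: float = 0.8,
    contour_value: float = 0.9,
) -> tuple[ProbVolume, ProbVolume]:
    """Render foreground + contour probability maps from a label volume.

    Foreground is the smoothed instance indicator (interior near 1,
    background near 0); the contour map carries ``contour_value`` on the
    one-voxel outer shell of every instance — including faces where two
    instances touch — so the decoder's seed rule can separate them.
    Truncated Gaussian noise of standard deviation ``noise_sd`` is added
    with the given seed; outputs are clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fg = (gt.grid > 0).astype(np.float64)
    if smooth_sigma > 0:
        fg = ndimage.gaussian_filter(fg, sigma=smooth_sigma)
        interior = ndimage.binary_erosion(gt.grid > 0, iterations=1)
        fg = np.maximum(fg, interior.astype(np.float64))
    contour = np.zeros(gt.shape, dtype=np.float64)
    for gid in gt.ids():
        mask = gt.grid == gid
        shell = mask & ~ndimage.binary_erosion(mask)
        contour[shell] = contour_value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fg = fg + rng.normal(0.0, noise_sd, size=fg.shape)
        contour = contour + rng.normal(0.0, noise_sd, size=contour.shape)
    return (
        ProbVolume(np.clip(fg, 0.0, 1.0), gt.spacing_nm),
        ProbVolume(np.clip(contour, 0.0, 1.0), gt.spacing_nm),
    )
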