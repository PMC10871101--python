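"""Point-set co-registration of IHC channels onto the H&E reference frame.

Serial tissue sections are scanned independently, so Ki67/pH3 detections
arrive in coordinate frames that are rotated, scaled and translated
relative to the H&E reference. Because the pipeline consumes point
detections rather than pixel data, registration is posed as point-set
alignment: an iterated-closest-point (ICP) loop whose inner step is the
closed-form least-squares similarity fit (Umeyama). Each iteration
assigns every moving point to its nearest reference neighbour (within its
own image region when region labels are supplied), keeps the
best-matching fraction of correspondences, refits the similarity
transform to them, and stops when the trimmed RMS residual stops
improving. The trimming guards against the scale collapse that plain ICP
suffers when the moving set is sparse relative to the reference (e.g. a
handful of mitotic pH3+ cells against thousands of tumor cells): distant,
probably-wrong matches are excluded from the fit, while the trimmed RMS
residual retains ICP's monotone-descent guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InsufficientPointsError, ValidationError

__all__ = [
    "SimilarityTransform",
    "RegistrationResult",
    "fit_similarity",
    "estimate_transform",
    "apply_transform",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """Rigid rotation + isotropic scale + translation in the image plane.

    Maps a point p to ``scale * R(rotation) p + (tx, ty)``.
    """

    rotation: float
    scale: float
    tx: float
    ty: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=0.0, scale=1.0, tx=0.0, ty=0.0)

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return self.scale * pts @ self.rotation_matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        t = -inv_scale * np.array([[c, -s], [s, c]]) @ np.array([self.tx, self.ty])
        return SimilarityTransform(
            rotation=-self.rotation, scale=inv_scale, tx=float(t[0]), ty=float(t[1])
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        t = self.apply(np.array([[other.tx, other.ty]]))[0]
        return SimilarityTransform(
            rotation=self.rotation + other.rotation,
            scale=self.scale * other.scale,
            tx=float(t[0]),
            ty=float(t[1]),
        )


@dataclass
class RegistrationResult:
    """Outcome of ICP: the transform, its residuals, and convergence info.

    ``residual`` is the trimmed RMS nearest-neighbour distance (px) the
    optimisation monitors; ``mean_residual`` is the untrimmed mean
    nearest-neighbour distance under the returned transform.
    """

    transform: SimilarityTransform
    residual: float
    mean_residual: float
    n_iter: int
    converged: bool
    residual_history: list[float]


def apply_transform(transform: SimilarityTransform, points: np.ndarray) -> np.ndarray:
    """Map points through a similarity transform (exact affine map)."""
    return transform.apply(points)


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity fit mapping ``src`` onto ``dst``.

    Umeyama's solution restricted to proper rotations (no reflection).
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if len(src) != len(dst):
        raise ValidationError("src and dst must have equal length")
    if len(src) < 3:
        raise InsufficientPointsError(
            f"need >= 3 point correspondences, got {len(src)}"
        )
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.array([1.0, d])
    rot = u @ np.diag(diag) @ vt
    var_s = (sc**2).sum() / len(src)
    if var_s == 0:
        raise InsufficientPointsError("source points are all coincident")
    scale = float((s * diag).sum() / var_s)
    rotation = math.atan2(rot[1, 0], rot[0, 0])
    t = mu_d - scale * rot @ mu_s
    return SimilarityTransform(rotation=rotation, scale=scale, tx=float(t[0]), ty=float(t[1]))


def _initial_guess(moving: np.ndarray, reference: np.ndarray) -> SimilarityTransform:
    # Centroid alignment plus RMS-radius scale ratio; deterministic.
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    rms_m = math.sqrt(float(((moving - mu_m) ** 2).sum(axis=1).mean()))
    rms_r = math.sqrt(float(((reference - mu_r) ** 2).sum(axis=1).mean()))
    scale = rms_r / rms_m if rms_m > 0 and rms_r > 0 else 1.0
    t = mu_r - scale * mu_m
    return SimilarityTransform(rotation=0.0, scale=scale, tx=float(t[0]), ty=float(t[1]))


def estimate_transform(
    moving_points: np.ndarray,
    reference_points: np.ndarray,
    *,
    moving_regions: np.ndarray | None = None,
    reference_regions: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    trim_fraction: float = 0.5,
    coarse_search: bool = True,
    rotation_range: float = 0.06,
    scale_center: float = 1.0,
    scale_range: float = 0.04,
    coarse_window_px: float = 800.0,
    accept_residual_factor: float = 0.25,
    n_starts: int = 3,
) -> RegistrationResult:
    """Estimate the similarity transform mapping moving points onto the
    reference frame by trimmed ICP with a closed-form similarity inner fit.

    When region labels are given (one label per point), nearest-neighbour
    correspondences are restricted to points of the same region — regions
    are physically disjoint fields that share one slide-level transform,
    so all correspondences feed a single fit.

    Parameters
    ----------
    moving_points, reference_points : (n, 2) arrays in pixel units.
    max_iter : iteration cap; if reached without the residual improvement
        dropping below ``tol`` the best transform found is returned with
        ``converged=False``.
    tol : minimum trimmed-RMS residual improvement (px) to continue.
    trim_fraction : fraction of best (closest) correspondences used for
        the fit and the monitored residual, in (0, 1]. 1.0 gives plain
        ICP; the 0.5 default is robust to sparse moving sets.
    coarse_search : ICP first descends from plain centroid + RMS-radius
        alignment; that solution is accepted if its residual is below
        ``accept_residual_factor`` times the reference nearest-neighbour
        spacing (a converged registration sits well under the spacing,
        a stalled one at its scale). Otherwise — typically for a sparse
        moving set, whose centroid/RMS start errors exceed ICP's
        convergence basin of about half the reference spacing — a grid
        of (rotation, scale) candidates is scored by the mode of
        moving-to-reference pairwise difference vectors (the translation
        where the two point densities coincide, supported by ~n true
        pairs against a diffuse mismatch background), and ICP is rerun
        from the best-scoring starts. Set False to skip escalation.
    rotation_range : half-width (radians) of the candidate rotation grid.
    scale_center, scale_range : the candidate scale grid spans
        ``scale_center * (1 +/- scale_range)``. Serial sections scanned
        on the same instrument have near-unit relative scale, which is a
        far tighter prior than the RMS-radius ratio of a sparse subset.
    coarse_window_px : cap on the translation search window about the
        reference centroid (the window itself adapts to the moving-set
        centroid sampling error).
    accept_residual_factor : fraction of the reference nearest-neighbour
        spacing below which a first-pass ICP solution is accepted.
    n_starts : ICP is rerun from this many of the best-scoring, mutually
        distinct candidate starts; the run with the lowest final
        residual wins.
    """
    moving = np.asarray(moving_points, dtype=float).reshape(-1, 2)
    reference = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    if len(moving) < 3 or len(reference) < 3:
        raise InsufficientPointsError(
            f"need >= 3 points in each set, got {len(moving)} moving / "
            f"{len(reference)} reference"
        )
    if max_iter < 1:
        raise ValidationError(f"max_iter must be >= 1, got {max_iter}")
    if not 0 < trim_fraction <= 1:
        raise ValidationError(f"trim_fraction must be in (0, 1], got {trim_fraction}")

    if moving_regions is None:
        groups = [(np.arange(len(moving)), np.arange(len(reference)))]
    else:
        moving_regions = np.asarray(moving_regions)
        reference_regions = np.asarray(reference_regions)
        if len(moving_regions) != len(moving) or len(reference_regions) != len(reference):
            raise ValidationError("region label arrays must match point counts")
        groups = []
        for region in np.unique(moving_regions):
            ref_idx = np.flatnonzero(reference_regions == region)
            if ref_idx.size == 0:
                raise ValidationError(
                    f"moving region {region!r} has no reference points"
                )
            groups.append((np.flatnonzero(moving_regions == region), ref_idx))

    trees = [cKDTree(reference[ref_idx]) for _, ref_idx in groups]
    n_keep = max(3, int(math.ceil(trim_fraction * len(moving))))
    n_keep = min(n_keep, len(moving))

    def _match(transform: SimilarityTransform):
        mapped = transform.apply(moving)
        matched = np.empty_like(moving)
        dists = np.empty(len(moving))
        for (mov_idx, ref_idx), tree in zip(groups, trees):
            d, nn = tree.query(mapped[mov_idx])
            matched[mov_idx] = reference[ref_idx][nn]
            dists[mov_idx] = d
        keep = np.argsort(dists, kind="stable")[:n_keep]
        trimmed_rms = float(math.sqrt((dists[keep] ** 2).mean()))
        return matched, dists, keep, trimmed_rms

    def _icp(start: SimilarityTransform):
        transform = start
        history: list[float] = []
        best = transform
        best_residual = math.inf
        best_mean = math.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            matched, dists, keep, residual = _match(transform)
            history.append(residual)
            if residual < best_residual:
                best_residual = residual
                best_mean = float(dists.mean())
                best = transform
            if len(history) >= 2 and history[-2] - residual < tol:
                converged = True
                break
            transform = fit_similarity(moving[keep], matched[keep])
        return RegistrationResult(
            transform=best,
            residual=best_residual,
            mean_residual=best_mean,
            n_iter=n_iter,
            converged=converged,
            residual_history=history,
        )

    first = _icp(_initial_guess(moving, reference))
    if not coarse_search:
        return first
    spacing = _reference_spacing(trees)
    if first.residual <= accept_residual_factor * spacing:
        return first
    starts = _coarse_candidates(
        moving,
        reference,
        groups,
        trees,
        rotation_range=rotation_range,
        scale_center=scale_center,
        scale_range=scale_range,
        window=coarse_window_px,
        n_starts=n_starts,
    )
    runs = [first]
    for start in starts:
        run = _icp(start)
        runs.append(run)
        if run.residual <= accept_residual_factor * spacing:
            break
    return min(runs, key=lambda r: r.residual)


def _reference_spacing(trees: list, n_sample: int = 300) -> float:
    """Median nearest-neighbour distance among reference points."""
    dists = []
    for tree in trees:
        pts = np.asarray(tree.data)
        stride = max(1, len(pts) // n_sample)
        sample = pts[::stride]
        d, _ = tree.query(sample, k=2)
        dists.append(d[:, 1])
    return float(np.median(np.concatenate(dists)))


def _coarse_candidates(
    moving: np.ndarray,
    reference: np.ndarray,
    groups: list,
    trees: list,
    *,
    rotation_range: float,
    scale_center: float,
    scale_range: float,
    window: float,
    n_starts: int,
    bin_px: float = 50.0,
    n_sub: int = 200,
) -> list[SimilarityTransform]:
    """Candidate start transforms from a pairwise-difference mode search.

    For every (rotation, scale) on a grid, the translation is estimated
    as the mode of (reference - scaled-rotated-moving) difference
    vectors, binned at ``bin_px``; the candidate's score is the number of
    point pairs supporting the mode. Near the correct rotation and scale,
    true correspondences pile into one bin neighbourhood (signal ~ the
    number of moving points used) while mismatched pairs spread uniformly
    (background per bin ~ points used x reference density x bin area), so
    the peak stands out by several standard deviations even for sparse
    moving sets. Scoring uses points in a mid-radius band about the
    moving centroid: their rotation/scale displacement is bounded, which
    sets the grid step, and the pairing radius stays small. The best
    ``n_starts`` mutually distinct candidates are returned, best first.
    """
    stride = max(1, -(-len(moving) // n_sub))
    sub_idx = np.arange(0, len(moving), stride)

    centroid = reference.mean(axis=0)
    mu_m = moving[sub_idx].mean(axis=0)
    n_mov = len(moving)

    radii = np.sqrt(((moving[sub_idx] - mu_m) ** 2).sum(axis=1))
    lo, hi = np.quantile(radii, [0.40, 0.85])
    band = sub_idx[(radii >= lo) & (radii <= hi)]
    if len(band) < 10:
        band = sub_idx
    r_band = float(np.sqrt(((moving[band] - mu_m) ** 2).sum(axis=1)).max()) or 1.0

    # The translation window covers the moving-centroid sampling error;
    # grid steps keep the within-cell displacement under the peak window.
    rms_m = math.sqrt(float(((moving[sub_idx] - mu_m) ** 2).sum(axis=1).mean())) or 1.0
    trans_sd = scale_center * rms_m / math.sqrt(n_mov)
    window = float(np.clip(3.5 * trans_sd + 3 * bin_px, 4 * bin_px, window))
    step = 0.7 * (1.5 * bin_px) / (scale_center * r_band)

    pair_radius = window + (rotation_range + scale_range) * scale_center * r_band
    pair_index: list[np.ndarray] = []
    pair_ref: list[np.ndarray] = []
    pos_in_band = {int(i): k for k, i in enumerate(band)}
    for (mov_idx, ref_idx), tree in zip(groups, trees):
        take = band[np.isin(band, mov_idx)]
        if take.size == 0:
            continue
        q0 = scale_center * (moving[take] - mu_m) + centroid
        neighbors = tree.query_ball_point(q0, pair_radius)
        ref_pts = np.asarray(tree.data)
        for t_idx, nbrs in zip(take, neighbors):
            if nbrs:
                pair_index.append(np.full(len(nbrs), pos_in_band[int(t_idx)]))
                pair_ref.append(ref_pts[nbrs])
    if not pair_index:
        return []
    pair_index_arr = np.concatenate(pair_index)
    pair_ref_centered = (np.vstack(pair_ref) - centroid).astype(np.float32)
    mov_pts = (moving[band] - mu_m)[pair_index_arr].astype(np.float32)

    n_bins = 2 * int(math.ceil(window / bin_px)) + 1
    half = (n_bins * bin_px) / 2.0
    thetas = np.arange(-rotation_range, rotation_range + step / 2, step)
    scales = scale_center * np.arange(1 - scale_range, 1 + scale_range + step / 2, step)
    n_s = len(scales)
    scales32 = scales.astype(np.float32)

    scored: list[tuple[int, float, float, np.ndarray]] = []
    for theta in thetas:
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]], dtype=np.float32)
        rotated = mov_pts @ rot.T  # (n_pairs, 2)
        # All scales at once: d has shape (n_scales, n_pairs, 2).
        d = pair_ref_centered[None, :, :] - scales32[:, None, None] * rotated[None, :, :]
        ix = np.floor((d[:, :, 0] + half) / bin_px).astype(np.int64)
        iy = np.floor((d[:, :, 1] + half) / bin_px).astype(np.int64)
        inside = (ix >= 0) & (ix < n_bins) & (iy >= 0) & (iy < n_bins)
        flat = np.arange(n_s)[:, None] * (n_bins * n_bins) + ix * n_bins + iy
        counts = np.bincount(flat[inside], minlength=n_s * n_bins * n_bins).reshape(
            n_s, n_bins, n_bins
        )
        # 3x3 neighbourhood sum, then the per-scale peak.
        win = (
            counts[:, :-2, :-2] + counts[:, :-2, 1:-1] + counts[:, :-2, 2:]
            + counts[:, 1:-1, :-2] + counts[:, 1:-1, 1:-1] + counts[:, 1:-1, 2:]
            + counts[:, 2:, :-2] + counts[:, 2:, 1:-1] + counts[:, 2:, 2:]
        )
        for k in range(n_s):
            pk = int(win[k].max(initial=0))
            if pk <= 0:
                continue
            cx, cy = np.unravel_index(np.argmax(win[k]), win[k].shape)
            x_lo, x_hi = -half + cx * bin_px, -half + (cx + 3) * bin_px
            y_lo, y_hi = -half + cy * bin_px, -half + (cy + 3) * bin_px
            sel = (
                (d[k, :, 0] >= x_lo)
                & (d[k, :, 0] < x_hi)
                & (d[k, :, 1] >= y_lo)
                & (d[k, :, 1] < y_hi)
            )
            scored.append((pk, float(theta), float(scales[k]), d[k][sel].mean(axis=0)))
    if not scored:
        return []
    scored.sort(key=lambda item: (-item[0], abs(item[1]), abs(item[2] - scale_center)))

    # Shortlist mutually distinct coarse candidates, then refine each on a
    # finer local grid with all subsampled points and small bins: a true
    # candidate's support rises to ~the full point count, while spurious
    # background peaks do not sharpen.
    shortlist: list[tuple[float, float, np.ndarray]] = []
    for score, theta, scale, t in scored:
        if any(
            abs(theta - th) < 2 * step and abs(scale - sc) < 2 * step * scale_center
            for th, sc, _ in shortlist
        ):
            continue
        shortlist.append((theta, scale, np.asarray(t, dtype=float)))
        if len(shortlist) >= max(4 * n_starts, 12):
            break

    refined: list[tuple[int, float, float, np.ndarray]] = []
    strong_support = 0.8 * len(sub_idx)
    for theta, scale, t in shortlist:
        hit = _refine_candidate(
            moving, sub_idx, mu_m, centroid, groups, trees, theta, scale, t, step
        )
        if hit is not None:
            refined.append(hit)
            if hit[0] >= strong_support:
                break  # essentially every point supports this candidate
    if not refined:
        return []
    refined.sort(key=lambda item: (-item[0], abs(item[1]), abs(item[2] - scale_center)))

    picked: list[SimilarityTransform] = []
    for score, theta, scale, t in refined:
        if any(
            abs(theta - p.rotation) < step and abs(scale - p.scale) < step * scale_center
            for p in picked
        ):
            continue
        # Convert the centred-coordinates mode back to an origin transform:
        # ref - centroid ~= scale*R*(mov - mu_m) + t.
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        trans = centroid + np.asarray(t, dtype=float) - scale * rot @ mu_m
        picked.append(
            SimilarityTransform(
                rotation=theta, scale=scale, tx=float(trans[0]), ty=float(trans[1])
            )
        )
        if len(picked) == n_starts:
            break
    return picked


def _refine_candidate(
    moving: np.ndarray,
    sub_idx: np.ndarray,
    mu_m: np.ndarray,
    centroid: np.ndarray,
    groups: list,
    trees: list,
    theta0: float,
    scale0: float,
    t0: np.ndarray,
    step: float,
    *,
    bin_px: float = 25.0,
    window: float = 300.0,
) -> tuple[int, float, float, np.ndarray] | None:
    """Re-score a coarse candidate on a finer (rotation, scale) grid.

    Pairs are gathered around the candidate's own mapping within
    ``window``; differences are binned at ``bin_px`` about the
    candidate's translation. Returns (score, theta, scale, translation)
    for the best refined cell, or None without supporting pairs.
    """
    c0, s0 = math.cos(theta0), math.sin(theta0)
    rot0 = np.array([[c0, -s0], [s0, c0]])
    pair_index: list[np.ndarray] = []
    pair_ref: list[np.ndarray] = []
    pos = {int(i): k for k, i in enumerate(sub_idx)}
    for (mov_idx, ref_idx), tree in zip(groups, trees):
        take = sub_idx[np.isin(sub_idx, mov_idx)]
        if take.size == 0:
            continue
        q0 = scale0 * (moving[take] - mu_m) @ rot0.T + centroid + t0
        neighbors = tree.query_ball_point(q0, window)
        ref_pts = np.asarray(tree.data)
        for t_idx, nbrs in zip(take, neighbors):
            if nbrs:
                pair_index.append(np.full(len(nbrs), pos[int(t_idx)]))
                pair_ref.append(ref_pts[nbrs])
    if not pair_index:
        return None
    pair_index_arr = np.concatenate(pair_index)
    ref_c = np.vstack(pair_ref) - centroid
    mov_c = (moving[sub_idx] - mu_m)[pair_index_arr]

    n_bins = 2 * int(math.ceil(window / bin_px)) + 1
    half = (n_bins * bin_px) / 2.0
    fine = step / 3.0
    best: tuple[int, float, float, np.ndarray] | None = None
    for dt in (-2, -1, 0, 1, 2):
        theta = theta0 + dt * fine
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        rotated = mov_c @ rot.T
        for ds in (-2, -1, 0, 1, 2):
            scale = scale0 * (1 + ds * fine)
            d = ref_c - scale * rotated - t0
            bx = np.floor((d[:, 0] + half) / bin_px).astype(np.int64)
            by = np.floor((d[:, 1] + half) / bin_px).astype(np.int64)
            inside = (bx >= 0) & (bx < n_bins) & (by >= 0) & (by < n_bins)
            if not inside.any():
                continue
            counts = np.bincount(
                bx[inside] * n_bins + by[inside], minlength=n_bins * n_bins
            ).reshape(n_bins, n_bins)
            ix, iy = np.unravel_index(np.argmax(counts), counts.shape)
            x_lo, x_hi = -half + (ix - 1) * bin_px, -half + (ix + 2) * bin_px
            y_lo, y_hi = -half + (iy - 1) * bin_px, -half + (iy + 2) * bin_px
            sel = (
                (d[:, 0] >= x_lo)
                & (d[:, 0] < x_hi)
                & (d[:, 1] >= y_lo)
                & (d[:, 1] < y_hi)
            )
            score = int(sel.sum())
            if best is None or score > best[0]:
                best = (score, theta, scale, t0 + d[sel].mean(axis=0))
    return best
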