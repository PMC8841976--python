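"""Local fiber radius along the medial axis of a segmented fiber mask.

The measurement chain follows the classic distance-map/skeleton recipe:

1. Euclidean distance transform of the mask (nm, anisotropy honored); the
   volume faces count as background, so distances are truncated at the slab
   surfaces exactly as a physical section truncates a fiber.
2. 3D topological thinning (Lee-Kashyap-Chu) reduces each fiber to a
   one-voxel-thick 26-connected medial curve.
3. The distance map sampled at the skeleton voxels gives one local radius
   per axial position; their histogram summarizes the fiber population, with
   the modal radius refined by 3-point quadratic interpolation around the
   most populated bin. The fiber diameter is reported as twice the mode.

Skeleton voxels whose distance value is face-limited (the nearest background
is a slab z-face rather than the fiber surface) are excluded from the
statistics by default, since their radii are truncated by sectioning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .density import FiberMask
from .errors import EmptySkeletonError, FibertomoError
from .volume import Volume

__all__ = [
    "ThicknessResult",
    "distance_map",
    "regularize_mask",
    "skeletonize",
    "local_thickness",
    "radius_report",
]


@dataclass
class ThicknessResult:
    """Per-skeleton-voxel radii and their summary statistics (all nm)."""

    skeleton_voxels: np.ndarray  # (n, 3) int indices
    radii_nm: np.ndarray  # (n,)
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    modal_radius_nm: float
    sd_nm: float
    se_nm: float
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.radii_nm)

    @property
    def modal_diameter_nm(self) -> float:
        return 2.0 * self.modal_radius_nm

    def radii_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.skeleton_voxels[:, 0],
                "y": self.skeleton_voxels[:, 1],
                "x": self.skeleton_voxels[:, 2],
                "radius_nm": self.radii_nm,
                "plateau_label": self.label,
            }
        )

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_nm": self.bin_edges[:-1],
                "bin_right_nm": self.bin_edges[1:],
                "count": self.bin_counts,
            }
        )


def distance_map(mask: FiberMask) -> Volume:
    """Distance (nm) from each foreground voxel to the nearest background
    voxel centre; background voxels are 0 and the volume faces are treated
    as background (one phantom layer of background voxels beyond each face).
    """
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise FibertomoError("distance map of an empty mask")
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.geometry.voxel_size)
    return Volume(
        dist[1:-1, 1:-1, 1:-1].astype(np.float64),
        mask.geometry.voxel_size,
        mask.geometry.origin,
    )


def _resample_to_isotropic(m: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour resampling of a mask to the finest axis spacing."""
    vs = np.asarray(voxel_size, dtype=float)
    target = vs.min()
    zoom = vs / target
    iso = ndimage.zoom(m.astype(np.uint8), zoom, order=0, grid_mode=True, mode="nearest")
    return iso.astype(bool), zoom


def regularize_mask(mask: np.ndarray, close_radius: int = 1) -> np.ndarray:
    """Binary closing that fills voxel-scale tunnels in a segmentation mask.

    Density maps sampled from discrete particles leave one-voxel tunnels and
    pits in the thresholded mask; topological thinning then preserves every
    tunnel as a loop and degenerates into a web of spurious curves. Closing
    with a small ball (default radius 1 voxel) removes these artifacts while
    changing the mask volume by a fraction of a percent.
    """
    if close_radius < 1:
        return mask
    st = ndimage.generate_binary_structure(3, 1)
    if close_radius > 1:
        st = ndimage.iterate_structure(st, close_radius)
    p = close_radius
    closed = ndimage.binary_closing(
        np.pad(mask, p, constant_values=False), structure=st
    )
    return closed[p:-p, p:-p, p:-p]


def skeletonize(
    mask: FiberMask, prune_branches: int = 3, adaptive_prune: bool = True
) -> np.ndarray:
    """One-voxel-thick medial curves of the mask, as an (n, 3) index array.

    Uses 3D topological thinning that preserves connectivity. Anisotropic
    volumes are resampled to isotropic voxels before thinning and the
    skeleton voxels mapped back onto the original grid. Side branches
    shorter than ``prune_branches`` voxels — or, with ``adaptive_prune``,
    shorter than the local object radius at their junction — are pruned.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise FibertomoError("skeleton of an empty mask")
    vs = np.asarray(mask.geometry.voxel_size, dtype=float)
    if np.allclose(vs, vs[0]):
        skel = _skimage_skeletonize(m).astype(bool)
    else:
        iso, zoom = _resample_to_isotropic(m, vs)
        iso_skel = _skimage_skeletonize(iso).astype(bool)
        idx = np.argwhere(iso_skel)
        back = np.round((idx + 0.5) / zoom - 0.5).astype(int)
        back = np.clip(back, 0, np.asarray(m.shape) - 1)
        skel = np.zeros_like(m)
        skel[tuple(back.T)] = True
        skel &= m
    if prune_branches > 0 or adaptive_prune:
        radius_voxels = None
        if adaptive_prune:
            dist = ndimage.distance_transform_edt(
                np.pad(m, 1, constant_values=False), sampling=vs
            )[1:-1, 1:-1, 1:-1]
            radius_voxels = dist / vs.min()
        skel = _prune_short_branches(skel, prune_branches, radius_voxels)
    skel = _rescue_lost_components(m, skel, vs)
    return np.argwhere(skel)


def _rescue_lost_components(mask, skel, voxel_size) -> np.ndarray:
    """Guarantee every mask component keeps at least one skeleton voxel.

    Thinning a compact (blob-like) component can reduce it to almost
    nothing, and mapping back from an isotropic grid or pruning may then
    drop it entirely; such a component's medial axis degenerates to its
    deepest point, so the voxel of maximal distance-to-background stands in.
    """
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
    present = np.unique(labels[skel])
    lost = np.setdiff1d(np.arange(1, n + 1), present)
    if len(lost):
        dist = ndimage.distance_transform_edt(
            np.pad(mask, 1, constant_values=False), sampling=voxel_size
        )[1:-1, 1:-1, 1:-1]
        out = skel.copy()
        for lab in lost:
            comp = labels == lab
            flat = np.where(comp, dist, -1.0).argmax()
            out[np.unravel_index(flat, mask.shape)] = True
        return out
    return skel


_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def _prune_short_branches(
    skel: np.ndarray, min_len: int, radius_voxels: np.ndarray | None = None
) -> np.ndarray:
    """Remove insignificant leaf branches that terminate at a junction.

    A leaf branch is pruned when it is shorter than ``min_len`` voxels, or —
    when ``radius_voxels`` is given — shorter than the local object radius at
    its junction. The radius criterion removes the spurious branches that
    topological thinning grows into every bump of a rough surface (those are
    at most one local radius long), while genuine axial branches survive.
    Isolated curves without junctions are never pruned.
    """
    voxels = {tuple(v) for v in np.argwhere(skel)}
    offsets = [tuple(o) for o in _NEIGHBOR_OFFSETS]

    def neighbors(v):
        out = []
        for off in offsets:
            n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if n in voxels:
                out.append(n)
        return out

    changed = True
    while changed:
        changed = False
        endpoints = [v for v in voxels if len(neighbors(v)) == 1]
        for ep in endpoints:
            if ep not in voxels or len(neighbors(ep)) != 1:
                continue
            # walk from the endpoint until the path hits a junction voxel
            path = [ep]
            prev, cur = None, ep
            junction = None
            limit = len(voxels)
            while len(path) <= limit:
                nbrs = [n for n in neighbors(cur) if n != prev]
                if not nbrs:
                    break  # isolated curve: other endpoint reached
                nxt = nbrs[0]
                if len(nbrs) > 1 or len(neighbors(nxt)) > 2:
                    junction = nxt if len(nbrs) == 1 else cur
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            if junction is None:
                continue
            threshold = float(min_len)
            if radius_voxels is not None:
                threshold = max(threshold, float(radius_voxels[junction]))
            if len(path) < threshold:
                for v in path:
                    voxels.discard(v)
                changed = True
    out = np.zeros_like(skel)
    if voxels:
        idx = np.array(sorted(voxels))
        out[tuple(idx.T)] = True
    return out


def local_thickness(
    mask: FiberMask,
    bin_width_nm: float = 5.0,
    exclude_border: bool = True,
    prune_branches: int = 3,
    adaptive_prune: bool = True,
    close_radius: int = 2,
    label: str = "",
) -> ThicknessResult:
    """Sample the distance map on the skeleton and summarize the radii.

    The mask is first regularized (see :func:`regularize_mask`) so that
    thinning yields clean medial curves. ``exclude_border`` drops skeleton
    voxels whose distance value is limited by a slab z-face instead of the
    fiber surface (within half a voxel of the distance to the nearer face),
    since sectioning truncates them.

    Raises
    ------
    EmptySkeletonError
        If thinning (or border exclusion) leaves no voxels to sample.
    """
    if close_radius > 0:
        mask = FiberMask(
            regularize_mask(np.asarray(mask.mask, dtype=bool), close_radius),
            mask.geometry,
            mask.radius,
        )
    dmap = distance_map(mask)
    skel = skeletonize(mask, prune_branches=prune_branches, adaptive_prune=adaptive_prune)
    if len(skel) == 0:
        raise EmptySkeletonError("thinning produced an empty skeleton")
    radii = dmap.data[tuple(skel.T)]
    if exclude_border:
        dz = mask.geometry.voxel_size[0]
        nz = mask.geometry.shape[0]
        # distance from the voxel centre to the background layer beyond the
        # nearer z-face (same convention as the EDT padding)
        face_dist = (np.minimum(skel[:, 0], nz - 1 - skel[:, 0]) + 1) * dz
        keep = radii < face_dist - 0.5 * dz
        skel, radii = skel[keep], radii[keep]
    if len(radii) == 0:
        raise EmptySkeletonError(
            "no skeleton voxels left to sample (all face-limited?)"
        )
    return _summarize(skel, radii, bin_width_nm, label)


def _summarize(skel, radii, bin_width_nm, label="") -> ThicknessResult:
    n = len(radii)
    sd = float(np.std(radii, ddof=1)) if n > 1 else 0.0
    se = sd / np.sqrt(n)
    if np.ptp(radii) == 0.0:
        # degenerate: a single radius value; the mode is that value
        mode = float(radii[0])
        edges = np.array([mode - bin_width_nm / 2, mode + bin_width_nm / 2])
        counts = np.array([n])
        return ThicknessResult(skel, radii, edges, counts, mode, sd, se, label)
    nbins = max(int(np.ceil((radii.max() + bin_width_nm) / bin_width_nm)), 1)
    edges = np.arange(nbins + 1) * bin_width_nm
    counts, _ = np.histogram(radii, bins=edges)
    mode = _interpolated_mode(edges, counts)
    return ThicknessResult(skel, radii, edges, counts, mode, sd, se, label)


def _interpolated_mode(edges: np.ndarray, counts: np.ndarray) -> float:
    """Centre of the most populated bin, refined by fitting a parabola
    through that bin and its two neighbours (sub-bin mode estimate)."""
    m = int(np.argmax(counts))
    width = edges[1] - edges[0]
    center = (edges[m] + edges[m + 1]) / 2.0
    if m == 0 or m == len(counts) - 1:
        return float(center)
    c0, c1, c2 = counts[m - 1], counts[m], counts[m + 1]
    denom = c0 - 2 * c1 + c2
    if denom == 0:
        return float(center)
    offset = 0.5 * (c0 - c2) / denom
    return float(center + np.clip(offset, -0.5, 0.5) * width)


def radius_report(
    results: list[ThicknessResult],
    labels: list[str] | None = None,
    outdir: str | os.PathLike | None = None,
    stem: str = "thickness",
) -> pd.DataFrame:
    """Summary table over per-plateau thickness results; diameters = 2 x mode.

    Rows are ordered by label (plateau radius order). When ``outdir`` is
    given, writes the summary CSV, per-result radii + histogram CSVs and a
    histogram figure.
    """
    if not results:
        raise ValueError("need at least one ThicknessResult")
    if labels is not None:
        results = [
            ThicknessResult(
                r.skeleton_voxels, r.radii_nm, r.bin_edges, r.bin_counts,
                r.modal_radius_nm, r.sd_nm, r.se_nm, label,
            )
            for r, label in zip(results, labels)
        ]
    rows = [
        {
            "label": r.label,
            "modal_radius_nm": r.modal_radius_nm,
            "sd_nm": r.sd_nm,
            "se_nm": r.se_nm,
            "n": r.n,
            "diameter_nm": r.modal_diameter_nm,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values("label", kind="stable").reset_index(drop=True)
    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        table.to_csv(os.path.join(outdir, f"{stem}_summary.csv"), index=False)
        for i, r in enumerate(results):
            tag = r.label or str(i)
            r.radii_frame().to_csv(
                os.path.join(outdir, f"{stem}_radii_{tag}.csv"), index=False
            )
            r.histogram_frame().to_csv(
                os.path.join(outdir, f"{stem}_hist_{tag}.csv"), index=False
            )
        _plot_histograms(results, os.path.join(outdir, f"{stem}_hist.png"))
    return table


def _plot_histograms(results, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for r in results:
        centers = (r.bin_edges[:-1] + r.bin_edges[1:]) / 2.0
        ax.step(centers, r.bin_counts, where="mid", label=r.label or None)
        ax.axvline(r.modal_radius_nm, ls="--", lw=1, color="gray")
    ax.set_xlabel("local fiber radius (nm)")
    ax.set_ylabel("skeleton voxels")
    if any(r.label for r in results):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
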