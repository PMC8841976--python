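"""Fourier shell correlation between two independent half-volumes.

FSC(S) = Re( sum_{f in S} A(f) conj(B(f)) ) / sqrt( sum |A|^2 * sum |B|^2 )

per spherical shell S in *physical* frequency (1/nm), so anisotropic voxel
sizes map to ellipsoidal index-space shells. The resolution is read where
the curve first drops through a criterion (0.143 by default), locating the
crossing by linear interpolation between the bracketing shells.

No mask or apodization is applied by default; an optional soft-edge
spherical mask is available for general use.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVolumeError
from .volume import Volume

__all__ = ["FSCCurve", "FSCResolution", "fsc_curve", "resolution_at", "soft_mask"]


@dataclass
class FSCCurve:
    """Per-shell correlation between two half-volumes."""

    frequencies: np.ndarray  # shell centre spatial frequencies, 1/nm
    fsc: np.ndarray  # correlation per shell, in [-1, 1]
    n_voxels: np.ndarray  # Fourier voxels per shell
    shell_width: float  # 1/nm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"freq_per_nm": self.frequencies, "fsc": self.fsc, "n_voxels": self.n_voxels}
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | os.PathLike, criterion: float = 0.143) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.frequencies, self.fsc, "-")
        ax.axhline(criterion, color="crimson", ls="--", lw=1)
        ax.set_xlabel("spatial frequency (1/nm)")
        ax.set_ylabel("FSC")
        ax.set_ylim(-0.2, 1.05)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class FSCResolution:
    """Resolution estimate at a criterion, with quality flags."""

    resolution_nm: float
    criterion: float
    nyquist_limited: bool = False  # curve never dropped below the criterion
    low_quality: bool = False  # curve already below the criterion at the first shell


def fsc_curve(half_a: Volume, half_b: Volume, shell_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation of two same-geometry volumes.

    ``shell_width`` is in 1/nm; the default is one frequency voxel of the
    coarsest axis. Shells run from just above DC to the (lowest-axis)
    Nyquist frequency; the DC term is excluded.
    """
    half_a.require_same_geometry(half_b)
    for name, vol in (("first", half_a), ("second", half_b)):
        if np.ptp(vol.data) == 0:
            raise DegenerateVolumeError(f"{name} half-volume is constant")
    shape = half_a.shape
    vsize = half_a.voxel_size
    if shell_width is None:
        shell_width = max(1.0 / (n * d) for n, d in zip(shape, vsize))
    nyquist = min(1.0 / (2.0 * d) for d in vsize)

    A = np.fft.fftn(half_a.data.astype(np.float64))
    B = np.fft.fftn(half_b.data.astype(np.float64))
    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, vsize)]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    fmag = np.sqrt(fz * fz + fy * fy + fx * fx)

    shell_idx = np.rint(fmag / shell_width).astype(np.int64)
    n_shells = int(np.floor(nyquist / shell_width + 0.5))
    flat = shell_idx.ravel()
    valid = (flat >= 1) & (flat <= n_shells)
    idx = flat[valid]

    cross = (A * np.conj(B)).real.ravel()[valid]
    pa = (A.real**2 + A.imag**2).ravel()[valid]
    pb = (B.real**2 + B.imag**2).ravel()[valid]

    num = np.bincount(idx, weights=cross, minlength=n_shells + 1)[1:]
    da = np.bincount(idx, weights=pa, minlength=n_shells + 1)[1:]
    db = np.bincount(idx, weights=pb, minlength=n_shells + 1)[1:]
    counts = np.bincount(idx, minlength=n_shells + 1)[1:]

    keep = counts > 0
    denom = np.sqrt(da[keep] * db[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[keep] / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    frequencies = (np.arange(1, n_shells + 1) * shell_width)[keep]
    return FSCCurve(
        frequencies=frequencies,
        fsc=corr,
        n_voxels=counts[keep],
        shell_width=float(shell_width),
    )


def resolution_at(curve: FSCCurve, criterion: float = 0.143) -> FSCResolution:
    """First crossing of the criterion from above, by linear interpolation.

    If the curve never drops below the criterion, the Nyquist-limited
    resolution is returned with ``nyquist_limited=True``. If the curve is
    already below the criterion at the first shell, the first shell's
    resolution is returned with ``low_quality=True``.
    """
    if len(curve.fsc) == 0:
        raise ValueError("empty FSC curve")
    f, c = curve.frequencies, curve.fsc
    if c[0] < criterion:
        return FSCResolution(1.0 / f[0], criterion, low_quality=True)
    below = np.flatnonzero(c < criterion)
    if len(below) == 0:
        return FSCResolution(1.0 / f[-1], criterion, nyquist_limited=True)
    i = below[0]
    f0, f1 = f[i - 1], f[i]
    c0, c1 = c[i - 1], c[i]
    f_cross = f0 + (f1 - f0) * (c0 - criterion) / (c0 - c1)
    return FSCResolution(float(1.0 / f_cross), criterion)


def soft_mask(volume: Volume, edge_nm: float = 20.0) -> Volume:
    """Apply a soft-edged (raised-cosine) spherical mask for general FSC use."""
    shape = np.asarray(volume.shape)
    vsize = np.asarray(volume.voxel_size)
    center = (shape / 2.0) * vsize
    grids = [
        ((np.arange(n) + 0.5) * d - c) ** 2
        for n, d, c in zip(shape, vsize, center)
    ]
    r = np.sqrt(grids[0][:, None, None] + grids[1][None, :, None] + grids[2][None, None, :])
    r_out = (shape * vsize).min() / 2.0
    r_in = max(r_out - edge_nm, 0.0)
    w = np.clip((r_out - r) / max(r_out - r_in, 1e-9), 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    return Volume(volume.data * w, volume.voxel_size, volume.origin)
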