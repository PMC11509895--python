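"""Coordinate-space flexibility measures: Kabsch superposition, RMSD, RMSF.

All metrics operate on C-alpha atoms only, without mass weighting, after
least-squares optimal rigid superposition (proper rotations only — no
reflections).  RMSD compares each frame to a reference frame (by default the
first saved frame); RMSF measures the fluctuation of each residue about its
mean position over the superposed frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RmsdSeries:
    """Per-frame C-alpha RMSD (A) against a reference frame."""

    values: np.ndarray  # (F,)
    reference_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class RmsfVector:
    """Per-residue C-alpha RMSF (A)."""

    values: np.ndarray  # (R,)
    positions: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape[0] != len(self.positions):
            raise ValueError("positions length mismatch")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")


def kabsch_superpose(mobile, target):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` in the
    least-squares sense.  The rotation is proper (determinant +1).

    Raises ``ValueError`` for fewer than 3 points or (near-)collinear point
    sets, for which the rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    x = mobile - mc
    y = target - tc
    for name, pts in (("mobile", x), ("target", y)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise ValueError(f"{name} point set is rank-deficient (collinear)")

    rot = _kabsch_rotations(x[None], y[None])[0]
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    translation = tc - rot @ mc
    return rot, translation, rmsd


def _kabsch_rotations(x, y) -> np.ndarray:
    """Batched proper rotations aligning centred ``x[b]`` to ``y[b]``.

    x, y: (B, N, 3) centred point sets -> (B, 3, 3) rotation matrices.
    """
    h = np.einsum("bni,bnj->bij", x, y)  # covariance x^T y
    u, _, vt = np.linalg.svd(h)
    v = vt.transpose(0, 2, 1)
    ut = u.transpose(0, 2, 1)
    # flip the smallest singular direction when the best fit is a reflection
    d = np.sign(np.linalg.det(v @ ut))
    v = v.copy()
    v[:, :, -1] *= d[:, None]
    return v @ ut


def _fit_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, N, 3) onto ``reference`` (N, 3).

    Returns the fitted coordinates, centred on the reference centroid.
    """
    ref_c = reference - reference.mean(axis=0)
    x = coords - coords.mean(axis=1, keepdims=True)
    rots = _kabsch_rotations(x, np.broadcast_to(ref_c, x.shape))
    fitted = np.einsum("bij,bnj->bni", rots, x)
    return fitted + reference.mean(axis=0)


def rmsd_series(ensemble, reference: int = 0) -> RmsdSeries:
    """C-alpha RMSD of every frame against one reference frame.

    Each frame is Kabsch-superposed onto the reference before the deviation
    is measured; the element at the reference frame is exactly 0.
    """
    ca = ensemble.ca_coords()
    if not 0 <= reference < ca.shape[0]:
        raise ValueError(
            f"reference frame {reference} outside 0..{ca.shape[0] - 1}"
        )
    fitted = _fit_frames(ca, ca[reference])
    dev = fitted - ca[reference]
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=1))
    values[reference] = 0.0
    return RmsdSeries(values=values, reference_index=reference)


def rmsf(ensemble, refinement_passes: int = 2) -> RmsfVector:
    """Per-residue C-alpha RMSF about the mean structure.

    Frames are first superposed onto the first frame; the mean structure is
    then refined by repeatedly superposing all frames onto the current mean
    and recomputing it (``refinement_passes`` times, default 2).  The
    fluctuation of residue i is sqrt(mean_t |r_i(t) - <r_i>|^2).
    """
    ca = ensemble.ca_coords()
    if ca.shape[0] < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fitted = _fit_frames(ca, ca[0])
    for _ in range(refinement_passes):
        mean = fitted.mean(axis=0)
        fitted = _fit_frames(ca, mean)
    mean = fitted.mean(axis=0)
    dev = fitted - mean
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return RmsfVector(values=values, positions=list(ensemble.positions))
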