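"""Rigid-body superposition and RMSD primitives.

Two RMSD flavours are exposed, because they answer different questions for
docked poses:

* :func:`kabsch_superpose` — RMSD after optimal rigid-body superposition
  (pose *shape* similarity; discards where the pose sits in the pocket);
* :func:`inplace_rmsd` — plain coordinate RMSD with no fitting (pose
  *placement* similarity, meaningful once all receptor frames share one
  reference alignment).

All RMSDs are unweighted over the supplied points; callers pass heavy-atom
coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "inplace_rmsd",
    "pairwise_superposed_rmsd",
    "pairwise_inplace_rmsd",
    "align_frames",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=tol):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise ValueError("rotation is not proper (det != +1)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _as_points(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return a


def kabsch_superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimising the RMSD between
    corresponding points (correspondence is positional) and the minimal
    RMSD itself. SVD-based with the usual sign correction so the result is
    always a proper rotation (no reflection), even for degenerate
    (collinear/planar) point sets.
    """
    A = _as_points(mobile, "mobile")
    B = _as_points(target, "target")
    if A.shape != B.shape:
        raise ValueError(f"point counts differ: {A.shape[0]} vs {B.shape[0]}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # flip the smallest singular vector if the best orthogonal map is a reflection
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    ssd = np.sum(A0 * A0) + np.sum(B0 * B0) - 2.0 * (S[0] + S[1] + d * S[2])
    rmsd = float(np.sqrt(max(ssd, 0.0) / n))
    return RigidTransform(R, t), rmsd


def inplace_rmsd(A, B) -> float:
    """Root-mean-square deviation with no superposition."""
    A = _as_points(A, "A")
    B = _as_points(B, "B")
    if A.shape != B.shape:
        raise ValueError(f"point counts differ: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 1:
        raise ValueError("need at least one point")
    d = A - B
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def pairwise_inplace_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs in-place RMSD for a (m, N, 3) coordinate stack."""
    X = np.asarray(coords, dtype=float)
    m = X.shape[0]
    # ||xi - xj||^2 summed over atoms, via the Gram trick on flattened coords
    F = X.reshape(m, -1)
    sq = np.sum(F * F, axis=1)
    g = F @ F.T
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    out = np.sqrt(d2 / X.shape[1])
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def pairwise_superposed_rmsd(coords: np.ndarray, block: int = 64) -> np.ndarray:
    """All-pairs minimal (Kabsch) RMSD for a (m, N, 3) coordinate stack.

    Uses batched 3x3 SVDs on cross-covariance matrices; identical to
    calling :func:`kabsch_superpose` per pair but orders of magnitude
    faster for the ~10^3-pose matrices ensemble docking produces.
    """
    X = np.asarray(coords, dtype=float)
    m, n, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.einsum("mij,mij->m", Xc, Xc)
    out = np.zeros((m, m))
    for i0 in range(0, m, block):
        i1 = min(i0 + block, m)
        # H[a, b] = Xc[a]^T @ Xc[b] for a in block, all b
        H = np.einsum("aki,bkj->abij", Xc[i0:i1], Xc)
        S = np.linalg.svd(H, compute_uv=False)
        det = np.linalg.det(H)
        s3 = np.where(det < 0.0, -S[..., 2], S[..., 2])
        trace = S[..., 0] + S[..., 1] + s3
        ssd = norms[i0:i1, None] + norms[None, :] - 2.0 * trace
        out[i0:i1] = np.sqrt(np.maximum(ssd, 0.0) / n)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Frame alignment
# ---------------------------------------------------------------------------

def _default_selection(frame) -> dict[tuple, np.ndarray]:
    """Cα atoms keyed by residue identity."""
    sel = {}
    for atom in frame.atoms:
        if atom.name == "CA" and atom.element == "C":
            rid = frame.residues[atom.residue_ref]
            sel[(rid.chain, rid.resnum, rid.icode)] = atom.coords
    return sel


def align_frames(frames: Sequence, reference,
                 selection: Callable | None = None) -> tuple[list, list[dict]]:
    """Rigidly superpose each frame onto ``reference`` and return a report.

    ``selection`` maps a frame to ``{key: (3,) coords}``; keys common to a
    frame and the reference define the correspondence (default: Cα atoms
    keyed by residue identity). The fitted transform moves *all* atoms and
    waters of the frame. Returns ``(aligned_frames, report)`` where each
    report row has ``frame_id``, ``n_fit_atoms``, ``rmsd_before`` and
    ``rmsd_after`` (the achieved selection RMSD).

    Frames are modified in place (coordinates overwritten) and also
    returned for convenience.
    """
    sel_fn = selection or _default_selection
    ref_sel = sel_fn(reference)
    report: list[dict] = []
    aligned = []
    for frame in frames:
        fsel = sel_fn(frame)
        common = sorted(set(fsel) & set(ref_sel))
        if len(common) < 3:
            raise ValueError(
                f"frame {frame.frame_id}: only {len(common)} selection atoms in "
                f"common with reference (need >= 3)"
            )
        mob = np.array([fsel[k] for k in common])
        tgt = np.array([ref_sel[k] for k in common])
        before = inplace_rmsd(mob, tgt)
        tf, after = kabsch_superpose(mob, tgt)
        for atom in frame.atoms:
            atom.coords = tf.apply(atom.coords[None, :])[0]
        if len(frame.waters):
            frame.waters = tf.apply(frame.waters)
        report.append(
            {
                "frame_id": frame.frame_id,
                "n_fit_atoms": len(common),
                "rmsd_before": before,
                "rmsd_after": after,
            }
        )
        aligned.append(frame)
    return aligned, report
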