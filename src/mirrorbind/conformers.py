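"""Superposition, RMSD, and radius-based clustering of trajectories.

Clustering is deterministic leader-style radius clustering in frame order on
pairwise superposed RMSD, followed by medoid refinement: within each cluster
the representative is the medoid (minimum average RMSD to the members) when
every member stays within the radius of it, otherwise the original leader
(which satisfies the radius by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SuperpositionResult",
    "ClusterSet",
    "ConformerError",
    "superpose",
    "rmsd",
    "cluster",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ConformerError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ClusterSet:
    assignments: np.ndarray           # frame index -> cluster id
    representatives: list[int]        # medoid (or leader) frame index per cluster
    occupancy: np.ndarray             # percent of total frames per cluster
    radius: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _as_frames(traj) -> list[np.ndarray]:
    if hasattr(traj, "frames"):
        return [np.asarray(f, float) for f in traj.frames]
    return [np.asarray(f, float) for f in traj]


def superpose(ref: np.ndarray, mov: np.ndarray, mask=None) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch) of ``mov`` onto
    ``ref``; RMSD is computed on the masked atoms."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if mask is not None:
        mask = np.asarray(mask)
        ref, mov = ref[mask], mov[mask]
    if ref.shape != mov.shape:
        raise ConformerError("coordinate sets differ in shape under mask")
    if ref.shape[0] < 3:
        raise ConformerError("superposition needs >= 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mov_c, tol=1e-8) < 2:
        raise ConformerError("collinear atoms: superposition is degenerate")
    rot, _ = Rotation.align_vectors(ref_c, mov_c)
    rmat = rot.as_matrix()
    trans = ref.mean(axis=0) - rot.apply(mov.mean(axis=0))
    value = float(np.sqrt(np.mean(np.sum((mov @ rmat.T + trans - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rmat, translation=trans, rmsd=value)


def rmsd(a: np.ndarray, b: np.ndarray, mask=None, superposed: bool = True) -> float:
    """Pairwise RMSD, by default after optimal superposition."""
    if superposed:
        return superpose(a, b, mask=mask).rmsd
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mask is not None:
        a, b = a[np.asarray(mask)], b[np.asarray(mask)]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def cluster(traj, radius: float = 2.0, mask=None) -> ClusterSet:
    """Greedy leader radius clustering with medoid refinement.

    Frames are visited in order; a frame joins the first existing cluster
    whose leader is within ``radius`` (superposed RMSD), otherwise it founds
    a new cluster.  Occupancy is the member fraction in percent.
    """
    frames = _as_frames(traj)
    if len(frames) == 0:
        raise ConformerError("empty trajectory")

    leaders: list[int] = []
    assign = np.full(len(frames), -1, dtype=int)
    for fi, frame in enumerate(frames):
        for ci, li in enumerate(leaders):
            if rmsd(frames[li], frame, mask=mask) < radius:
                assign[fi] = ci
                break
        else:
            leaders.append(fi)
            assign[fi] = len(leaders) - 1

    reps: list[int] = []
    for ci, leader in enumerate(leaders):
        members = np.where(assign == ci)[0]
        if len(members) == 1:
            reps.append(int(members[0]))
            continue
        dmat = np.zeros((len(members), len(members)))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                d = rmsd(frames[members[a]], frames[members[b]], mask=mask)
                dmat[a, b] = dmat[b, a] = d
        medoid_local = int(np.argmin(dmat.mean(axis=1)))
        medoid = int(members[medoid_local])
        if np.all(dmat[medoid_local] < radius):
            reps.append(medoid)
        else:
            reps.append(int(leader))

    counts = np.bincount(assign, minlength=len(leaders)).astype(float)
    occupancy = 100.0 * counts / counts.sum()
    return ClusterSet(
        assignments=assign, representatives=reps, occupancy=occupancy, radius=radius
    )


def cluster_table(cs: ClusterSet) -> list[dict]:
    """Cluster summary rows (id, size, occupancy %, representative frame)."""
    counts = np.bincount(cs.assignments, minlength=cs.n_clusters)
    return [
        {
            "cluster": ci,
            "size": int(counts[ci]),
            "occupancy_percent": float(cs.occupancy[ci]),
            "representative_frame": int(cs.representatives[ci]),
        }
        for ci in range(cs.n_clusters)
    ]
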