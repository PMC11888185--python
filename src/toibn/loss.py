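"""Wasserstein-style matching loss between persistence diagrams.

Subject and reference diagrams are compared per homology dimension by sorting
both point sets in descending persistence and pairing rank for rank.  Surplus
subject points — features the reference does not have — are mapped to a zero
target, penalizing their persistence; surplus reference points contribute
nothing (the loss sums over subject points only).

Because every diagram point carries the voxels that determine its birth and
death, the loss gradient lands on at most two voxels per matched pair, making
the topology term differentiable with respect to the subject map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .topology import PersistenceDiagram, PersistencePoint
from .volumes import SubjectScan

__all__ = [
    "Matching",
    "MatchedPair",
    "LossReport",
    "match_diagrams",
    "wasserstein_loss",
    "mse_loss",
    "topo_gradient",
]

ZERO_PERSISTENCE = "zero_persistence"
ORIGIN = "origin"


@dataclass(frozen=True)
class MatchedPair:
    """A subject point and its target (birth, death); ``to_zero`` marks the
    virtual target used for surplus subject points."""

    subject: PersistencePoint
    target_birth: float
    target_death: float
    to_zero: bool = False


@dataclass
class Matching:
    """Per-dimension pairing of subject diagram points with targets."""

    pairs: List[MatchedPair]
    zero_target_mode: str = ZERO_PERSISTENCE

    def for_dim(self, dim: int) -> List[MatchedPair]:
        return [p for p in self.pairs if p.subject.dim == dim]


@dataclass
class LossReport:
    """Loss values at one training iteration."""

    L_top: float
    L_mse: float
    L_full: float
    L_top_h0: float = 0.0
    L_top_h1: float = 0.0


def _sorted_points(pd: PersistenceDiagram, dim: int) -> List[PersistencePoint]:
    pts = [p for p in pd.points if p.dim == dim]
    # descending persistence; ties: higher birth first, then lower birth voxel
    pts.sort(key=lambda p: (-p.persistence, -p.birth, p.birth_voxel))
    return pts


def match_diagrams(
    pd_subject: PersistenceDiagram,
    pd_reference: PersistenceDiagram,
    zero_target_mode: str = ZERO_PERSISTENCE,
) -> Matching:
    """Rank-by-rank pairing in descending persistence, per dimension.

    Surplus subject points pair with a zero target: their own birth with zero
    persistence (default), or the diagram origin (0, 0) under the ``origin``
    mode.  Surplus reference points are left unmatched.
    """
    if pd_subject.filtration != pd_reference.filtration:
        raise ValueError(
            f"mixed filtration conventions: {pd_subject.filtration!r} vs "
            f"{pd_reference.filtration!r}"
        )
    if zero_target_mode not in (ZERO_PERSISTENCE, ORIGIN):
        raise ValueError(f"unknown zero_target_mode {zero_target_mode!r}")
    pairs: List[MatchedPair] = []
    for dim in (0, 1):
        subj = _sorted_points(pd_subject, dim)
        ref = _sorted_points(pd_reference, dim)
        for i, p in enumerate(subj):
            if i < len(ref):
                pairs.append(MatchedPair(p, ref[i].birth, ref[i].death, False))
            elif zero_target_mode == ZERO_PERSISTENCE:
                pairs.append(MatchedPair(p, p.birth, p.birth, True))
            else:
                pairs.append(MatchedPair(p, 0.0, 0.0, True))
    return Matching(pairs, zero_target_mode)


def wasserstein_loss(matching: Matching) -> float:
    """Sum of squared birth and death differences over matched pairs."""
    total = 0.0
    for mp in matching.pairs:
        total += (mp.subject.birth - mp.target_birth) ** 2
        total += (mp.subject.death - mp.target_death) ** 2
    return total


def wasserstein_loss_by_dim(matching: Matching) -> Tuple[float, float]:
    out = [0.0, 0.0]
    for mp in matching.pairs:
        out[mp.subject.dim] += (mp.subject.birth - mp.target_birth) ** 2
        out[mp.subject.dim] += (mp.subject.death - mp.target_death) ** 2
    return out[0], out[1]


def mse_loss(Ys, theta_all: np.ndarray, TC: np.ndarray) -> float:
    """Mean squared reconstruction error of the scan from TC and maps.

    ``Ys`` may be a SubjectScan or a raw T x V array.  The mean runs over all
    T*V entries of the residual Ys - TC @ theta_all.
    """
    Y = Ys.Ys if isinstance(Ys, SubjectScan) else np.asarray(Ys, dtype=np.float64)
    theta_all = np.atleast_2d(np.asarray(theta_all, dtype=np.float64))
    TC = np.atleast_2d(np.asarray(TC, dtype=np.float64))
    if TC.shape[0] != Y.shape[0] or TC.shape[1] != theta_all.shape[0] \
            or theta_all.shape[1] != Y.shape[1]:
        raise ValueError(
            f"inconsistent shapes: Ys {Y.shape}, TC {TC.shape}, theta {theta_all.shape}"
        )
    resid = Y - TC @ theta_all
    return float(np.mean(resid**2))


def topo_gradient(
    grid,
    pd_subject: PersistenceDiagram,
    matching: Matching,
) -> np.ndarray:
    """Gradient of the matching loss w.r.t. subject voxel intensities.

    ``grid`` may be a VolumeGrid (whose masked voxel count sets the output
    length) or the voxel count itself.

    Each pair contributes 2*(b - b_target) at its birth voxel and
    2*(d - d_target) at its death voxel; essential points (no death voxel)
    send their death gradient to the global-minimum voxel, whose intensity is
    the pinned essential death value.  For zero-persistence targets the
    target birth *is* the subject birth, and the exact derivative of the
    resulting (d - b)^2 term is used, so the analytic gradient agrees with
    finite differences of the recomputed loss.
    """
    n_voxels = grid if isinstance(grid, (int, np.integer)) else grid.n_voxels
    g = np.zeros(n_voxels, dtype=np.float64)
    for mp in matching.pairs:
        p = mp.subject
        death_voxel = p.death_voxel if p.death_voxel is not None else pd_subject.min_voxel
        if mp.to_zero and matching.zero_target_mode == ZERO_PERSISTENCE:
            # loss term is (d - b)^2: the target moves with the birth
            diff = p.death - p.birth
            g[p.birth_voxel] += -2.0 * diff
            g[death_voxel] += 2.0 * diff
        else:
            g[p.birth_voxel] += 2.0 * (p.birth - mp.target_birth)
            g[death_voxel] += 2.0 * (p.death - mp.target_death)
    return g
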