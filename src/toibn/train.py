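"""Spatiotemporal regression and the topological correction loop.

Subject network estimation runs in two stages.  First, ordinary least
squares: timecourses TCs = Ys @ pinv(theta_G) regress each scan volume onto
the reference maps, and the joint OLS spatial maps theta = pinv(TCs) @ Ys
initialize every subject network at once.  Second, each network map is
refined independently by gradient descent on

    L_full = lambda * L_top + (1 - lambda) * L_mse

where L_top is the persistence-diagram matching loss against the reference
network's diagram and L_mse is the scan reconstruction error with the other
networks frozen at their OLS fit.  Training stops at a fixed iteration count:
with the topology term the loss can otherwise overfit the subject map onto
the reference topology, so the iteration cap acts as early stopping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import loss as loss_mod
from .topology import build_complex, persistence_diagram, PersistenceDiagram
from .volumes import ReferenceSet, SubjectScan, VolumeGrid

__all__ = [
    "TrainConfig",
    "TrainState",
    "ToibnResult",
    "estimate_timecourses",
    "estimate_spatial_ols",
    "correct_network",
    "run_toibn",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    lambda_weight
        Mixing weight of the topological term, in [0, 1]; 0.5 gives both
        terms equal weight and is the default.
    n_iterations
        Fixed descent length (empirical early stopping), default 150.
    learning_rate
        Step size on z-scored map intensities; default 0.01.
    zscore_before_pd
        Z-score each map within the mask before computing its diagram so
        subject and reference intensities share a scale (default on); the
        mean and SD are treated as constants in the gradient.
    zero_target_mode
        How surplus subject diagram points are penalized: toward zero
        persistence (default) or toward the diagram origin.
    """

    lambda_weight: float = 0.5
    n_iterations: int = 150
    learning_rate: float = 0.01
    zscore_before_pd: bool = True
    zero_target_mode: str = loss_mod.ZERO_PERSISTENCE
    seed: int = 0
    divergence_factor: float = 10.0

    def __post_init__(self) -> None:
        errors = []
        if not 0.0 <= self.lambda_weight <= 1.0:
            errors.append(f"lambda_weight must be in [0, 1], got {self.lambda_weight}")
        if self.n_iterations <= 0:
            errors.append(f"n_iterations must be positive, got {self.n_iterations}")
        if self.learning_rate <= 0:
            errors.append(f"learning_rate must be positive, got {self.learning_rate}")
        if self.zero_target_mode not in (loss_mod.ZERO_PERSISTENCE, loss_mod.ORIGIN):
            errors.append(f"unknown zero_target_mode {self.zero_target_mode!r}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class TrainState:
    """Optimizer bookkeeping for one network's correction."""

    theta_s: np.ndarray
    network_index: int
    iteration: int = 0
    loss_history: List[loss_mod.LossReport] = field(default_factory=list)


@dataclass
class ToibnResult:
    """Per-subject OLS-only and corrected map stacks for a cohort run."""

    ols: np.ndarray      # (n_subjects, K, V)
    toibn: np.ndarray    # (n_subjects, K, V)
    timecourses: List[np.ndarray]
    histories: list      # [subject][network] -> List[LossReport]
    subject_ids: List[str]
    groups: List[str]
    errors: dict = field(default_factory=dict)


def _warn_if_rank_deficient(M: np.ndarray, what: str) -> None:
    if min(M.shape) == 0:
        return
    if np.linalg.matrix_rank(M) < min(M.shape):
        warnings.warn(
            f"{what} is rank deficient; using the minimum-norm solution",
            RuntimeWarning,
        )


def estimate_timecourses(Ys: SubjectScan, refs: ReferenceSet) -> np.ndarray:
    """Least-squares network timecourses, T x K, via pinv of the references.

    The same timecourses are reused by both the OLS-only and the corrected
    estimation paths.
    """
    if Ys.V != refs.theta_G.shape[1]:
        raise ValueError("scan and reference set have different voxel counts")
    _warn_if_rank_deficient(refs.theta_G, "reference set")
    return Ys.Ys @ np.linalg.pinv(refs.theta_G)


def estimate_spatial_ols(Ys: SubjectScan, TCs: np.ndarray) -> np.ndarray:
    """Joint OLS spatial maps, K x V, solving min ||Ys - TCs @ theta||^2."""
    TCs = np.atleast_2d(np.asarray(TCs, dtype=np.float64))
    if TCs.shape[0] != Ys.T:
        raise ValueError("timecourse length does not match scan")
    _warn_if_rank_deficient(TCs, "timecourse matrix")
    return np.linalg.pinv(TCs) @ Ys.Ys


def _zscore(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(v.mean())
    sd = float(v.std())
    if sd == 0.0:
        raise ValueError("constant map cannot be z-scored")
    return (v - mu) / sd, mu, sd


def reference_diagram(
    refs: ReferenceSet, k: int, cfg: TrainConfig
) -> PersistenceDiagram:
    """Diagram of reference network k under the training convention."""
    v = refs.theta_G[k]
    if cfg.zscore_before_pd:
        v = _zscore(v)[0]
    grid = refs.grid.with_flat(v)
    return persistence_diagram(grid, build_complex(refs.grid))


def correct_network(
    Ys: SubjectScan,
    TCs: np.ndarray,
    theta_init: np.ndarray,
    refs: ReferenceSet,
    k: int,
    cfg: TrainConfig,
    pd_ref: Optional[PersistenceDiagram] = None,
) -> tuple[np.ndarray, List[loss_mod.LossReport]]:
    """Gradient-descend network k's map under the combined loss.

    The other networks stay frozen at ``theta_init``; the reference diagram
    is computed once (or passed in, precomputed).  Returns the corrected
    V-vector and the per-iteration loss history.
    """
    theta_init = np.atleast_2d(np.asarray(theta_init, dtype=np.float64))
    K, V = theta_init.shape
    T = Ys.T
    lam = cfg.lambda_weight
    cx = build_complex(Ys.grid)
    if pd_ref is None:
        pd_ref = reference_diagram(refs, k, cfg)

    # residual with network k removed; only the k-th row changes during descent
    others = [j for j in range(K) if j != k]
    R_other = Ys.Ys - TCs[:, others] @ theta_init[others] if others else Ys.Ys.copy()
    tc_k = TCs[:, k]
    tc_k_sq = float(tc_k @ tc_k)

    theta_k = theta_init[k].copy()
    state = TrainState(theta_k, k)
    initial_full: Optional[float] = None
    for it in range(cfg.n_iterations):
        if cfg.zscore_before_pd:
            m, _, sd = _zscore(theta_k)
        else:
            m, sd = theta_k, 1.0
        grid_k = Ys.grid.with_flat(m)
        pd_s = persistence_diagram(grid_k, cx)
        matching = loss_mod.match_diagrams(pd_s, pd_ref, cfg.zero_target_mode)
        l_h0, l_h1 = loss_mod.wasserstein_loss_by_dim(matching)
        l_top = l_h0 + l_h1
        g_top = loss_mod.topo_gradient(V, pd_s, matching) / sd

        resid = R_other - np.outer(tc_k, theta_k)
        l_mse = float(np.mean(resid**2))
        g_mse = (-2.0 / (T * V)) * (tc_k @ resid)

        l_full = lam * l_top + (1.0 - lam) * l_mse
        report = loss_mod.LossReport(l_top, l_mse, l_full, l_h0, l_h1)
        if not np.isfinite(l_full) or not np.isfinite(g_top).all() \
                or not np.isfinite(g_mse).all():
            raise RuntimeError(
                f"non-finite loss or gradient at iteration {it} (network {k})"
            )
        if initial_full is None:
            initial_full = l_full
        elif initial_full > 0 and l_full > cfg.divergence_factor * initial_full:
            raise RuntimeError(
                f"divergence at iteration {it} (network {k}): "
                f"loss {l_full:.3g} > {cfg.divergence_factor:g} x initial "
                f"{initial_full:.3g}; reduce the learning rate"
            )
        theta_k -= cfg.learning_rate * (lam * g_top + (1.0 - lam) * g_mse)
        state.loss_history.append(report)
        state.iteration += 1
    state.theta_s = theta_k
    return theta_k, state.loss_history


def run_toibn(
    cohort: List[SubjectScan],
    refs: ReferenceSet,
    cfg: Optional[TrainConfig] = None,
) -> ToibnResult:
    """OLS-initialize and topologically correct every subject and network.

    Per-subject failures are isolated: the failing subject keeps its OLS maps
    (NaN where even OLS failed) and the error is recorded in ``errors``.
    """
    cfg = cfg or TrainConfig()
    K, V = refs.theta_G.shape
    n = len(cohort)
    ols = np.full((n, K, V), np.nan)
    toibn = np.full((n, K, V), np.nan)
    tcs_list: List[np.ndarray] = []
    histories: list = []
    errors: dict = {}
    pd_refs = [reference_diagram(refs, k, cfg) for k in range(K)]
    for s, scan in enumerate(cohort):
        subj_hist: list = [None] * K
        try:
            TCs = estimate_timecourses(scan, refs)
            theta0 = estimate_spatial_ols(scan, TCs)
            ols[s] = theta0
            for k in range(K):
                theta_k, hist = correct_network(
                    scan, TCs, theta0, refs, k, cfg, pd_ref=pd_refs[k]
                )
                toibn[s, k] = theta_k
                subj_hist[k] = hist
            tcs_list.append(TCs)
        except Exception as exc:  # noqa: BLE001 - isolate per-subject failures
            errors[scan.subject_id or str(s)] = repr(exc)
            tcs_list.append(np.empty((scan.T, 0)))
        histories.append(subj_hist)
    return ToibnResult(
        ols=ols,
        toibn=toibn,
        timecourses=tcs_list,
        histories=histories,
        subject_ids=[sc.subject_id or str(i) for i, sc in enumerate(cohort)],
        groups=[sc.group for sc in cohort],
        errors=errors,
    )
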