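"""Evaluation battery comparing corrected and OLS-only map stacks.

Four families of metrics, each computed per network for both methods:

* topological similarity to the reference — Euler characteristic of the
  z-scored, zero-thresholded map versus the reference's;
* voxel-wise similarity — mean absolute error to the reference (both maps
  z-scored first, since raw OLS and corrected maps live on different scales);
* subject variability — pairwise Pearson correlations between subject maps,
  and the across-subject SD of the reference-relevant voxels (highest-valued
  k-means cluster of the reference map);
* image quality — contrast-to-noise ratio, with in/out regions from a
  3-cluster k-means on each map's non-CSF voxels and the noise floor from
  the SD of the map over CSF voxels.

Group differences are tested per network (two-sample t-test or
Kruskal-Wallis) with Benjamini-Hochberg correction across networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .topology import euler_characteristic
from .volumes import ReferenceSet, VolumeGrid, flatten

__all__ = [
    "EvalReport",
    "binarize_zscore",
    "euler_comparison",
    "mae_to_reference",
    "subject_variability",
    "cnr",
    "group_differences",
    "full_report",
]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant map cannot be z-scored")
    return (v - v.mean()) / sd


def binarize_zscore(map_v: np.ndarray, grid: VolumeGrid) -> VolumeGrid:
    """Z-score within the mask and threshold at zero (strictly greater)."""
    z = _zscore(np.asarray(map_v, dtype=np.float64))
    binary = (z > 0).astype(np.float64)
    return grid.with_flat(binary)


def euler_comparison(
    subject_maps: np.ndarray, reference_map: np.ndarray, grid: VolumeGrid
) -> np.ndarray:
    """chi(binarized subject) - chi(binarized reference) per subject."""
    ref_grid = binarize_zscore(reference_map, grid)
    chi_ref = euler_characteristic(ref_grid, 0.0)
    out = np.empty(len(subject_maps), dtype=np.int64)
    for i, m in enumerate(subject_maps):
        chi = euler_characteristic(binarize_zscore(m, grid), 0.0)
        out[i] = chi - chi_ref
    return out


def mae_to_reference(subject_map: np.ndarray, reference_map: np.ndarray) -> float:
    """Mean absolute error between the z-scored maps."""
    s = np.asarray(subject_map, dtype=np.float64)
    r = np.asarray(reference_map, dtype=np.float64)
    if s.shape != r.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {r.shape}")
    return float(np.mean(np.abs(_zscore(s) - _zscore(r))))


def _kmeans_three(values: np.ndarray, seed: int) -> Optional[np.ndarray]:
    """3-cluster labels of a value vector, identities sorted by cluster mean
    ascending (0 = low, 1 = center, 2 = high); None if degenerate."""
    for attempt in range(3):
        km = KMeans(n_clusters=3, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(values.reshape(-1, 1))
        if len(np.unique(labels)) == 3:
            order = np.argsort(km.cluster_centers_.ravel())
            remap = np.empty(3, dtype=np.int64)
            remap[order] = np.arange(3)
            return remap[labels]
    return None


def subject_variability(
    map_stack: np.ndarray,
    refs_map: np.ndarray,
    grid: VolumeGrid,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise subject correlations and relevant-voxel SDs.

    Returns all unordered-pair Pearson correlations (NaN where a subject map
    is constant) and the across-subject SD of each voxel in the
    highest-valued k-means cluster of the *reference* map.
    """
    stack = np.asarray(map_stack, dtype=np.float64)
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    n = stack.shape[0]
    sds = stack.std(axis=1)
    corrs = []
    for i, j in itertools.combinations(range(n), 2):
        if sds[i] == 0 or sds[j] == 0:
            corrs.append(np.nan)
        else:
            corrs.append(float(np.corrcoef(stack[i], stack[j])[0, 1]))
    labels = _kmeans_three(np.asarray(refs_map, dtype=np.float64), seed)
    if labels is None:
        raise ValueError("degenerate reference clustering")
    relevant = labels == 2
    voxel_sd = stack[:, relevant].std(axis=0, ddof=1)
    return np.asarray(corrs), voxel_sd


def cnr(
    map_v: np.ndarray,
    grid: VolumeGrid,
    csf_mask: VolumeGrid,
    seed: int = 0,
) -> float:
    """Contrast-to-noise ratio of one map.

    K-means (k=3) runs on the map's non-CSF masked values; the CNR is
    (mean of the highest cluster - mean of the center cluster) divided by
    the SD of the map over CSF voxels.  NaN if clustering stays degenerate
    after reseeding.
    """
    v = np.asarray(map_v, dtype=np.float64)
    csf_in_mask = flatten(csf_mask.mask.astype(np.float64), grid.mask) > 0
    if not csf_in_mask.any():
        raise ValueError("CSF mask has no voxels inside the brain mask")
    noise_sd = v[csf_in_mask].std()
    if noise_sd == 0:
        return float("nan")
    labels = _kmeans_three(v[~csf_in_mask], seed)
    if labels is None:
        warnings.warn("degenerate CNR clustering; reporting NaN", RuntimeWarning)
        return float("nan")
    vals = v[~csf_in_mask]
    mu_high = vals[labels == 2].mean()
    mu_center = vals[labels == 1].mean()
    return float((mu_high - mu_center) / noise_sd)


def group_differences(
    values_patients: np.ndarray,
    values_controls: np.ndarray,
    test: str = "t_test",
    network_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-network two-group test with BH correction across networks.

    Inputs are (n_subjects, K) arrays.  A network where both groups have
    zero within-group variance is reported as missing (NaN) and excluded
    from the correction.
    """
    vp = np.atleast_2d(np.asarray(values_patients, dtype=np.float64))
    vc = np.atleast_2d(np.asarray(values_controls, dtype=np.float64))
    if vp.shape[1] != vc.shape[1]:
        raise ValueError("groups must cover the same networks")
    if vp.shape[0] < 2 or vc.shape[0] < 2:
        raise ValueError("need at least 2 values per group")
    K = vp.shape[1]
    names = list(network_names) if network_names else [f"net{k}" for k in range(K)]
    stat = np.full(K, np.nan)
    pval = np.full(K, np.nan)
    for k in range(K):
        a, b = vp[:, k], vc[:, k]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
            continue
        if test == "t_test":
            res = stats.ttest_ind(a, b, equal_var=True)
        elif test == "kruskal_wallis":
            res = stats.kruskal(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        stat[k], pval[k] = float(res.statistic), float(res.pvalue)
    p_adj = np.full(K, np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        p_adj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "network": names,
            "statistic": stat,
            "p_raw": pval,
            "p_adj": p_adj,
            "significant": p_adj < 0.05,
        }
    )


@dataclass
class EvalReport:
    """All per-network metric tables for both map stacks."""

    euler_diff: pd.DataFrame          # per subject x network x method
    mae: pd.DataFrame                 # per subject x network x method
    pairwise_corr: pd.DataFrame       # per pair x network x method
    relevant_voxel_sd: pd.DataFrame   # per voxel x network x method
    cnr: pd.DataFrame                 # per subject x network x method
    group_test: pd.DataFrame          # per network x method

    def summary(self) -> pd.DataFrame:
        """Per-network, per-method means of every metric."""
        parts = []
        for name, df, col in [
            ("abs_euler_diff", self.euler_diff.assign(
                value=self.euler_diff["value"].abs()), "value"),
            ("mae", self.mae, "value"),
            ("pairwise_corr", self.pairwise_corr, "value"),
            ("relevant_voxel_sd", self.relevant_voxel_sd, "value"),
            ("cnr", self.cnr, "value"),
        ]:
            s = df.groupby(["method", "network"])[col].mean().rename(name)
            parts.append(s)
        return pd.concat(parts, axis=1).reset_index()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "euler_diff", "mae", "pairwise_corr", "relevant_voxel_sd",
            "cnr", "group_test",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        self.summary().to_csv(out / "summary.csv", index=False)


def _long(records) -> pd.DataFrame:
    return pd.DataFrame(records, columns=["method", "network", "subject", "value"])


def full_report(
    ols_stack: np.ndarray,
    toibn_stack: np.ndarray,
    refs: ReferenceSet,
    grid: VolumeGrid,
    csf_mask: VolumeGrid,
    groups: Sequence[str],
    seed: int = 0,
    group_test: str = "t_test",
    out_dir=None,
    make_figures: bool = False,
) -> EvalReport:
    """Assemble every metric for both stacks; optionally write tables/figures.

    Stacks are (n_subjects, K, V); ``groups`` labels each subject.  The group
    test compares per-subject Euler characteristics between patients and
    controls for each network.  Per-metric failures are isolated as NaN.
    """
    ols_stack = np.asarray(ols_stack, dtype=np.float64)
    toibn_stack = np.asarray(toibn_stack, dtype=np.float64)
    if ols_stack.shape != toibn_stack.shape:
        raise ValueError("stacks must be aligned over subjects and networks")
    n, K, V = ols_stack.shape
    groups = list(groups)
    stacks = {"ols": ols_stack, "toibn": toibn_stack}

    e_rec, m_rec, c_rec, s_rec, q_rec = [], [], [], [], []
    chi_by_method: Dict[str, np.ndarray] = {}
    for method, stack in stacks.items():
        chis = np.zeros((n, K))
        for k in range(K):
            name = refs.network_names[k]
            try:
                diffs = euler_comparison(stack[:, k], refs.theta_G[k], grid)
            except ValueError:
                diffs = np.full(n, np.nan)
            chis[:, k] = diffs
            for s, d in enumerate(diffs):
                e_rec.append((method, name, s, d))
            for s in range(n):
                try:
                    m_rec.append(
                        (method, name, s, mae_to_reference(stack[s, k], refs.theta_G[k]))
                    )
                except ValueError:
                    m_rec.append((method, name, s, np.nan))
                try:
                    q_rec.append((method, name, s, cnr(stack[s, k], grid, csf_mask, seed)))
                except ValueError:
                    q_rec.append((method, name, s, np.nan))
            try:
                corrs, vox_sd = subject_variability(
                    stack[:, k], refs.theta_G[k], grid, seed
                )
            except ValueError:
                corrs, vox_sd = np.array([np.nan]), np.array([np.nan])
            for i, c in enumerate(corrs):
                c_rec.append((method, name, i, c))
            for i, sd in enumerate(vox_sd):
                s_rec.append((method, name, i, sd))
        chi_by_method[method] = chis

    gt_parts = []
    is_pat = np.array([g == "patient" for g in groups])
    is_con = np.array([g == "control" for g in groups])
    if is_pat.sum() >= 2 and is_con.sum() >= 2:
        for method, chis in chi_by_method.items():
            df = group_differences(
                chis[is_pat], chis[is_con], test=group_test,
                network_names=refs.network_names,
            )
            df.insert(0, "method", method)
            gt_parts.append(df)
        gt = pd.concat(gt_parts, ignore_index=True)
    else:
        gt = pd.DataFrame(
            columns=["method", "network", "statistic", "p_raw", "p_adj", "significant"]
        )

    report = EvalReport(
        euler_diff=_long(e_rec),
        mae=_long(m_rec),
        pairwise_corr=_long(c_rec).rename(columns={"subject": "pair"}),
        relevant_voxel_sd=_long(s_rec).rename(columns={"subject": "voxel"}),
        cnr=_long(q_rec),
        group_test=gt,
    )
    if out_dir is not None:
        report.write(out_dir)
        if make_figures:
            _write_figures(report, Path(out_dir))
    return report


def _write_figures(report: EvalReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("euler_diff", "Euler characteristic difference to reference"),
        ("mae", "MAE to reference"),
        ("pairwise_corr", "Pairwise subject correlation"),
        ("relevant_voxel_sd", "Relevant-voxel subject SD"),
        ("cnr", "Contrast-to-noise ratio"),
    ]
    for name, title in panels:
        df = getattr(report, name)
        networks = sorted(df["network"].unique())
        fig, axes = plt.subplots(
            1, len(networks), figsize=(3 * len(networks), 3), squeeze=False
        )
        for ax, net in zip(axes[0], networks):
            for method, color in (("ols", "tab:green"), ("toibn", "tab:red")):
                vals = df[(df["network"] == net) & (df["method"] == method)][
                    "value"
                ].dropna()
                if len(vals):
                    ax.hist(vals, bins=20, alpha=0.5, label=method, color=color,
                            density=True)
            ax.set_title(net)
        axes[0, 0].legend()
        fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=100)
        plt.close(fig)
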