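"""Synthetic resting-state cohort with planted topological group effects.

The generator emulates the structure the estimation pipeline expects from a
real study: smooth blob-shaped reference networks on an ellipsoidal brain
mask, per-subject AR(1) network timecourses, scans built as
timecourse-weighted ground-truth maps plus Gaussian noise, a small interior
CSF region that carries pure noise (the noise floor for CNR), and two subject
groups.  Patients receive a planted topological effect in a chosen subset of
networks: either an extra connected component (a remote Gaussian bump) or an
extra loop (a cylindrical depression through a blob, which turns its
superlevel sets into an annulus).

Every quantity is a pure function of the spec and its seed; per-subject
randomness is split as SeedSequence((seed, subject_index, group_code)).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import (
    ReferenceSet,
    SubjectScan,
    VolumeGrid,
    flatten,
    masked_indices,
    write_maps,
    write_scan,
    write_volume,
)

__all__ = ["CohortSpec", "make_reference_set", "make_subject", "make_cohort", "write_cohort"]

_GROUP_CODES = {"control": 0, "patient": 1}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Sizes and noise levels are fixed study conditions, not tuning knobs:
    a 16 x 16 x 8 grid with K = 3 networks, 20 subjects per group and
    T = 100 timepoints keeps a full run at desk scale; ``noise_sd`` = 2.0
    against reference peaks of roughly 4 z-units mimics the low
    contrast-to-noise of BOLD fMRI; ``tc_autocorr`` = 0.4 is typical serial
    correlation at a 2 s repetition time; ``perturb_sd`` = 0.15 z-units of
    smooth per-subject map variation gives the variability metrics a known
    generative floor.
    """

    grid_shape: Tuple[int, int, int] = (16, 16, 8)
    n_subjects_per_group: int = 20
    T: int = 100
    K: int = 3
    blob_centers: Optional[List[List[Tuple[float, float, float]]]] = None
    blob_sigma: float = 1.4
    noise_sd: float = 2.0
    noise_smooth: float = 0.85
    tc_autocorr: float = 0.4
    perturb_sd: float = 0.15
    perturb_smooth: float = 2.0
    csf_radius: float = 1.6
    effect_networks: Tuple[int, ...] = (0,)
    effect_kind: str = "extra_component"
    effect_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.tc_autocorr < 1.0:
            raise ValueError("tc_autocorr must be in [0, 1)")
        if self.effect_kind not in ("extra_component", "extra_hole"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.T < 2:
            raise ValueError("need at least 2 timepoints")
        if self.K < 1:
            raise ValueError("need at least one network")
        if self.blob_centers is None:
            self.blob_centers = _default_blob_centers(self.grid_shape, self.K)
        if len(self.blob_centers) != self.K:
            raise ValueError("blob_centers must list one center set per network")
        nx, ny, nz = self.grid_shape
        for centers in self.blob_centers:
            for c in centers:
                if not (0 <= c[0] < nx and 0 <= c[1] < ny and 0 <= c[2] < nz):
                    raise ValueError(f"blob center {c} lies outside the grid")
        if any(k < 0 or k >= self.K for k in self.effect_networks):
            raise ValueError("effect_networks indices out of range")


def _grid_geometry(shape):
    nx, ny, nz = shape
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    semi = np.array([nx / 2 - 1, ny / 2 - 1, nz / 2 - 1], dtype=float)
    return center, semi


def _default_blob_centers(shape, K: int):
    """Two blobs per network, spread around the ellipsoid at 0.68 radius."""
    center, semi = _grid_geometry(shape)
    r = 0.68
    out = []
    for k in range(K):
        pair = []
        for j in range(2):
            ang = 2 * np.pi * (2 * k + j) / (2 * K)
            z = center[2] + (0.3 if (2 * k + j) % 2 else -0.3) * semi[2]
            pair.append(
                (
                    float(center[0] + r * semi[0] * np.cos(ang)),
                    float(center[1] + r * semi[1] * np.sin(ang)),
                    float(z),
                )
            )
        out.append(pair)
    return out


def _coords(shape):
    nx, ny, nz = shape
    return np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )


def _bump(shape, center, sigma: float) -> np.ndarray:
    X, Y, Z = _coords(shape)
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def make_reference_set(
    spec: CohortSpec,
) -> Tuple[ReferenceSet, VolumeGrid, VolumeGrid]:
    """Reference maps plus the brain and CSF masks.

    Each network map is a sum of isotropic Gaussian bumps, z-scored within
    the ellipsoidal brain mask.  The CSF mask is a small interior sphere;
    any blob center within 2 sigma of a CSF voxel is rejected because the
    CSF region must stay free of network signal.
    """
    shape = spec.grid_shape
    center, semi = _grid_geometry(shape)
    X, Y, Z = _coords(shape)
    mask = (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0
    csf = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= (
        spec.csf_radius**2
    )
    csf &= mask
    if not csf.any():
        raise ValueError("CSF region is empty; increase csf_radius")

    csf_pts = np.stack(np.nonzero(csf), axis=1).astype(float)
    for k, centers in enumerate(spec.blob_centers):
        for c in centers:
            d = np.sqrt(((csf_pts - np.asarray(c)) ** 2).sum(axis=1)).min()
            if d < 2.0 * spec.blob_sigma:
                raise ValueError(
                    f"network {k} blob at {c} overlaps the CSF region "
                    f"(distance {d:.2f} < 2 sigma)"
                )

    grid = VolumeGrid(mask.astype(float), mask)
    csf_grid = VolumeGrid(csf.astype(float), csf)

    maps = np.zeros((spec.K, int(mask.sum())))
    csf_in_mask = flatten(csf.astype(float), mask) > 0
    for k, centers in enumerate(spec.blob_centers):
        vol = np.zeros(shape)
        for c in centers:
            vol += _bump(shape, c, spec.blob_sigma)
        v = flatten(vol, mask)
        v = (v - v.mean()) / v.std()
        # reference networks carry no CSF signal; the CSF region is the
        # pure-noise floor for CNR
        v[csf_in_mask] = 0.0
        maps[k] = v
    refs = ReferenceSet(maps, grid, [f"net{k}" for k in range(spec.K)])
    return refs, grid, csf_grid


def _effect_center(spec: CohortSpec, k: int):
    """Deterministic location of the planted extra component for network k:
    the point diametrically opposite the midpoint of the network's blobs,
    at the same ellipse radius, mid-plane in z."""
    center, semi = _grid_geometry(spec.grid_shape)
    blobs = np.asarray(spec.blob_centers[k], dtype=float)
    mid = blobs.mean(axis=0) - center
    ang = np.arctan2(mid[1] / semi[1], mid[0] / semi[0]) + np.pi
    r = 0.68
    return (
        float(center[0] + r * semi[0] * np.cos(ang)),
        float(center[1] + r * semi[1] * np.sin(ang)),
        float(center[2]),
    )


def ground_truth_maps(
    spec: CohortSpec,
    refs: ReferenceSet,
    csf: VolumeGrid,
    subject_index: int,
    group: str,
) -> np.ndarray:
    """Per-subject K x V ground-truth maps (reference + smooth perturbation
    + any planted group effect; zero inside the CSF region)."""
    if group not in _GROUP_CODES:
        raise ValueError(f"unknown group label {group!r}")
    mask = refs.grid.mask
    shape = mask.shape
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, subject_index, _GROUP_CODES[group]))
    )
    truth = np.empty_like(refs.theta_G)
    csf_in_mask = flatten(csf.mask.astype(float), mask) > 0
    for k in range(refs.K):
        field3d = gaussian_filter(rng.standard_normal(shape), spec.perturb_smooth)
        pert = flatten(field3d, mask)
        sd = pert.std()
        if sd > 0 and spec.perturb_sd > 0:
            pert = pert / sd * spec.perturb_sd
        else:
            pert = np.zeros_like(pert)
        truth[k] = refs.theta_G[k] + pert
        if group == "patient" and k in spec.effect_networks:
            if spec.effect_kind == "extra_component":
                bump = _bump(shape, _effect_center(spec, k), spec.blob_sigma)
                truth[k] += spec.effect_amplitude * flatten(bump, mask)
            else:  # extra_hole: in-plane cylindrical depression through blob 0
                cx, cy, _ = spec.blob_centers[k][0]
                X, Y, _Z = _coords(shape)
                r2 = (X - cx) ** 2 + (Y - cy) ** 2
                ring = np.exp(-r2 / (2.0 * (0.6 * spec.blob_sigma) ** 2))
                truth[k] -= spec.effect_amplitude * flatten(ring, mask)
        truth[k, csf_in_mask] = 0.0
    return truth


def ground_truth_timecourses(
    spec: CohortSpec, K: int, subject_index: int, group: str
) -> np.ndarray:
    """The T x K AR(1) timecourses a subject's scan was generated from.

    Regenerated from the documented seed split, so tests can compare
    estimated timecourses against the generative truth.
    """
    if group not in _GROUP_CODES:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, subject_index, _GROUP_CODES[group], 7))
    )
    return np.stack([_ar1(rng, spec.T, spec.tc_autocorr) for _ in range(K)], axis=1)


def _ar1(rng, T: int, phi: float) -> np.ndarray:
    x = np.empty(T)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(T - 1)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + innov_sd * eps[t - 1]
    return x


def _smooth_noise(rng, spec: CohortSpec, mask: np.ndarray) -> np.ndarray:
    """T x V unit-variance Gaussian noise, spatially smoothed.

    Scanner noise in preprocessed fMRI is spatially correlated because the
    volumes are smoothed with a Gaussian kernel; ``noise_smooth`` (in voxels)
    emulates that.  The filtered field is rescaled so the marginal per-voxel
    SD stays 1 (exact in the grid interior).
    """
    shape = mask.shape
    if spec.noise_smooth <= 0:
        white = rng.standard_normal((spec.T,) + shape)
        return np.stack([flatten(white[t], mask) for t in range(spec.T)])
    # SD shrinkage factor of the smoothing kernel, from an impulse response
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    factor = np.sqrt((gaussian_filter(impulse, spec.noise_smooth) ** 2).sum())
    out = np.empty((spec.T, int(mask.sum())))
    for t in range(spec.T):
        vol = gaussian_filter(rng.standard_normal(shape), spec.noise_smooth)
        out[t] = flatten(vol, mask) / factor
    return out


def make_subject(
    spec: CohortSpec,
    refs: ReferenceSet,
    csf: VolumeGrid,
    subject_index: int,
    group: str,
) -> Tuple[SubjectScan, np.ndarray]:
    """One subject's scan (T x V) and ground-truth maps (K x V).

    The scan is TC @ truth + Gaussian noise; because the truth maps are zero
    inside the CSF region, CSF voxels carry pure noise by construction.
    """
    if group not in _GROUP_CODES:
        raise ValueError(f"unknown group label {group!r}")
    truth = ground_truth_maps(spec, refs, csf, subject_index, group)
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, subject_index, _GROUP_CODES[group], 7))
    )
    TC = np.stack([_ar1(rng, spec.T, spec.tc_autocorr) for _ in range(refs.K)], axis=1)
    noise = _smooth_noise(rng, spec, refs.grid.mask)
    Ys = TC @ truth + spec.noise_sd * noise
    scan = SubjectScan(
        Ys,
        refs.grid,
        subject_id=f"{group}{subject_index:03d}",
        group=group,
    )
    return scan, truth


@dataclass
class Cohort:
    """A fully generated synthetic study."""

    spec: CohortSpec
    refs: ReferenceSet
    mask: VolumeGrid
    csf: VolumeGrid
    scans: List[SubjectScan]
    truths: np.ndarray  # (n_subjects, K, V)
    groups: List[str]


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group study (patients first, then controls)."""
    refs, mask, csf = make_reference_set(spec)
    scans: List[SubjectScan] = []
    truths = []
    groups = []
    for group in ("patient", "control"):
        for i in range(spec.n_subjects_per_group):
            scan, truth = make_subject(spec, refs, csf, i, group)
            scans.append(scan)
            truths.append(truth)
            groups.append(group)
    return Cohort(spec, refs, mask, csf, scans, np.stack(truths), groups)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort as NIfTI files plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(cohort.mask, out / "mask.nii.gz")
    write_volume(cohort.csf, out / "csf.nii.gz")
    write_maps(cohort.refs.theta_G, cohort.refs.grid, out / "references.nii.gz")
    rows = []
    for scan, truth in zip(cohort.scans, cohort.truths):
        write_scan(scan, out / f"{scan.subject_id}_scan.nii.gz")
        write_maps(truth, cohort.refs.grid, out / f"{scan.subject_id}_truth.nii.gz")
        rows.append(
            {
                "subject_id": scan.subject_id,
                "group": scan.group,
                "truth_map_sha256": hashlib.sha256(
                    np.ascontiguousarray(truth).tobytes()
                ).hexdigest(),
            }
        )
    spec_dict = asdict(cohort.spec)
    with open(out / "cohort.json", "w") as fh:
        json.dump({"spec": spec_dict, "subjects": rows}, fh, indent=2)
    with open(out / "groups.tsv", "w") as fh:
        for scan in cohort.scans:
            fh.write(f"{scan.subject_id}\t{scan.group}\n")
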