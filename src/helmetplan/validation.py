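"""Comparison of approximated against reference SAR distributions.

Beyond the voxelwise relative error, plan quality hinges on whether the
approximation identifies the same hot and cold spots as the reference, so
the overlap of the q-tail hot-spot masks (in remaining tissue) and p-tail
cold-spot masks (in the target), each derived independently from the two
distributions, is reported as a coverage fraction. Both SARs are
normalized to unit mean over the evaluation domain before differencing
(the mask metrics are invariant to any monotone rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import TissueModel
from .fieldsim import oracle_antenna_field, complex_refractive_index
from .interp import FieldErrorReport, field_error_metrics, interpolate_antenna_field
from .planning import MaskSet

__all__ = ["ComparisonReport", "sar_comparison_metrics", "location_sweep_report"]


@dataclass
class ComparisonReport:
    eps_dis: float            # mean relative absolute SAR difference
    eta_hotspot: float        # fractional overlap of hot-spot masks
    eta_coldspot: float       # fractional overlap of cold-spot masks
    hot_voxels: int
    cold_voxels: int
    n_zero_reference: int
    per_antenna: list = field(default_factory=list)  # FieldErrorReports


def _tail_mask(flat_sar, voxel_idx, count, hottest: bool):
    order = np.argsort(flat_sar[voxel_idx], kind="stable")
    chosen = voxel_idx[order[-count:]] if hottest else voxel_idx[order[:count]]
    return set(chosen.tolist())


def sar_comparison_metrics(sar_ref: np.ndarray, sar_approx: np.ndarray,
                           masks: MaskSet, normalize: bool = True,
                           per_antenna=None) -> ComparisonReport:
    """eps_DIS plus hot-/cold-spot mask coverage between two SAR maps."""
    if sar_ref.shape != sar_approx.shape:
        raise ValueError("SAR maps must share one lattice")
    domain = masks.target | masks.remaining
    a = sar_ref.astype(float).copy()
    b = sar_approx.astype(float).copy()
    if normalize:
        ma, mb = a[domain].mean(), b[domain].mean()
        if ma > 0:
            a /= ma
        if mb > 0:
            b /= mb
    ref_d = a[domain]
    ok = ref_d > 0
    n_zero = int((~ok).sum())
    eps_dis = float(np.mean(np.abs(ref_d[ok] - b[domain][ok]) / ref_d[ok]))

    fa, fb = a.reshape(-1), b.reshape(-1)
    tgt = np.flatnonzero(masks.target.reshape(-1))
    rem = np.flatnonzero(masks.remaining.reshape(-1))
    n_hot = max(1, int(np.ceil(masks.q / 100.0 * len(rem))))
    n_cold = max(1, int(np.ceil(masks.p / 100.0 * len(tgt))))
    H_ref = _tail_mask(fa, rem, n_hot, hottest=True)
    H_apx = _tail_mask(fb, rem, n_hot, hottest=True)
    C_ref = _tail_mask(fa, tgt, n_cold, hottest=False)
    C_apx = _tail_mask(fb, tgt, n_cold, hottest=False)
    return ComparisonReport(
        eps_dis=eps_dis,
        eta_hotspot=len(H_ref & H_apx) / len(H_ref),
        eta_coldspot=len(C_ref & C_apx) / len(C_ref),
        hot_voxels=n_hot, cold_voxels=n_cold, n_zero_reference=n_zero,
        per_antenna=list(per_antenna or []))


def location_sweep_report(bank, model: TissueModel, mask: np.ndarray,
                          patch: int = None, n_steps: int = 5,
                          frequencies=None, mass_average: bool = True):
    """Interpolation error at poses of increasing distance from a grid node.

    ``n_steps`` poses run from a corner of the chosen patch (default: the
    largest-area patch) to the midpoint of the opposite edge, through the
    patch center. For each pose and frequency the interpolated field is
    compared against a direct oracle field on ``mask``. Returns a dict
    ``{(step, f): FieldErrorReport}``.
    """
    grid = bank.grid
    pts = grid.points
    if patch is None:
        tri = pts[grid.triangles]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=-1)
        patch = int(np.argmax(areas))
    nodes = grid.triangles[patch]
    e = grid.ellipsoid
    st = np.sin(grid.thetas[nodes])
    Un = np.stack([st * np.cos(grid.phis[nodes]),
                   st * np.sin(grid.phis[nodes]),
                   np.cos(grid.thetas[nodes])], axis=-1)

    freqs = list(frequencies or bank.fields.frequencies)
    reports = {}
    for step in range(n_steps):
        t = step / max(n_steps - 1, 1)
        lam = np.array([1.0 - t, t / 2.0, t / 2.0])
        q = lam @ Un
        q /= np.linalg.norm(q)
        theta = float(np.arccos(np.clip(q[2], -1, 1)))
        phi = float(np.arctan2(q[1], q[0]))
        pose = None
        for f in freqs:
            E_int, rep = interpolate_antenna_field(bank, theta, phi, f,
                                                   return_report=True)
            pose = rep["pose"]
            nvol = complex_refractive_index(model, f)
            E_sim = oracle_antenna_field(model, pose, f, _n_volume=nvol)
            reports[(step, f)] = field_error_metrics(
                E_sim, E_int, mask, pose.U, model=model,
                mass_average=mass_average,
                mask_description=f"sweep step {step}, f={f/1e6:.0f} MHz")
    return reports
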