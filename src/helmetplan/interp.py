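"""Fast single-antenna E-field approximation by surface-grid interpolation.

Given a bank of pre-computed per-node, per-frequency antenna fields on the
bolus surface grid, the field of an antenna at an arbitrary surface pose is
approximated in six steps: locate the triangular patch containing the
query; divide each corner field pointwise by the local material impedance
(an H-field surrogate that factors out most of the anatomy dependence,
tissues being non-magnetic); rigidly transform each surrogate from its
corner frame to the query frame (positions and vector components); multiply
back by the impedance; and blend the three transformed fields with
barycentric area weights.

The approximation error against a reference field is quantified by four
normalized metrics (distribution, amplitude, phase, direction), averaged
over an evaluation mask after both fields are 5 g mass averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .anatomy import TissueModel
from .fieldsim import FieldSet, complex_refractive_index, oracle_antenna_field
from .geometry import AntennaPose, SurfaceGrid, antenna_frame, locate_patch
from .planning import mass_average_5g

__all__ = [
    "InterpolationBank",
    "FieldErrorReport",
    "to_h_surrogate",
    "from_h_surrogate",
    "transform_field",
    "interpolate_antenna_field",
    "field_error_metrics",
]


def to_h_surrogate(E: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Pointwise division by the local impedance (H-field surrogate)."""
    eta = np.asarray(eta)
    if np.any(np.abs(eta) < 1e-12):
        raise ValueError("zero-impedance voxel in the impedance map")
    return E / eta[..., None]


def from_h_surrogate(H: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_h_surrogate` (exact round trip)."""
    return H * np.asarray(eta)[..., None]


def transform_field(H: np.ndarray, frame_src: AntennaPose,
                    frame_dst: AntennaPose, spacing, origin):
    """Rigidly map a vector field from one antenna frame to another.

    The map translates the source origin to (0,0,0), rotates the source
    frame onto the destination frame, and translates to the destination
    origin; vector components rotate with the frame. The result is
    resampled (trilinear, per real/imaginary component) onto the fixed
    lattice; samples falling outside the domain are zero. Returns
    ``(H_new, out_of_domain_fraction)``.
    """
    Fs, Fd = frame_src.frame, frame_dst.frame
    for F in (Fs, Fd):
        if not np.allclose(F @ F.T, np.eye(3), atol=1e-8):
            raise ValueError("antenna frame is not orthonormal")
    R = Fd @ Fs.T
    if np.allclose(R, np.eye(3), atol=1e-12) and \
       np.allclose(frame_src.O, frame_dst.O, atol=1e-12):
        return H.copy(), 0.0

    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    shape = H.shape[:3]
    idx = np.indices(shape, dtype=float)
    Y = np.stack([origin[k] + spacing[k] * idx[k] for k in range(3)], axis=-1)
    # pull-back sample positions: x = R^T (y - O_dst) + O_src
    Xs = (Y - frame_dst.O) @ R + frame_src.O
    coords = [(Xs[..., k] - origin[k]) / spacing[k] for k in range(3)]
    coords = np.stack(coords)

    oob = np.zeros(shape, dtype=bool)
    for k in range(3):
        oob |= (coords[k] < -0.5) | (coords[k] > shape[k] - 0.5)

    sampled = np.empty(shape + (3,), dtype=complex)
    for c in range(3):
        sampled[..., c] = (map_coordinates(H[..., c].real, coords, order=1, cval=0.0)
                           + 1j * map_coordinates(H[..., c].imag, coords, order=1,
                                                  cval=0.0))
    H_new = sampled @ R.T  # rotate vector components: v' = R v
    return H_new, float(oob.mean())


@dataclass
class InterpolationBank:
    """Pre-computed per-node, per-frequency antenna fields on one lattice."""

    grid: SurfaceGrid
    model: TissueModel
    fields: FieldSet
    lossy_eta: bool = True
    _eta_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, model: TissueModel, grid: SurfaceGrid, frequencies,
              n_steps: int = 32, lossy_eta: bool = True) -> "InterpolationBank":
        """Generate the bank with the analytic field oracle (one field per
        grid node and frequency)."""
        fs = FieldSet(spacing=model.spacing, origin=model.origin)
        for f in frequencies:
            nvol = complex_refractive_index(model, f)
            for i in range(grid.n_points):
                E = oracle_antenna_field(model, grid.pose(i), f,
                                         n_steps=n_steps, _n_volume=nvol)
                fs.add(i, f, E)
        return cls(grid=grid, model=model, fields=fs, lossy_eta=lossy_eta)

    def eta(self, f: float) -> np.ndarray:
        if f not in self._eta_cache:
            self._eta_cache[f] = self.model.eta_map(f, lossy=self.lossy_eta)
        return self._eta_cache[f]


def interpolate_antenna_field(bank: InterpolationBank, theta: float,
                              phi: float, f: float,
                              return_report: bool = False):
    """Approximate the E-field of an antenna at (theta, phi) from the bank."""
    e = bank.grid.ellipsoid
    clamped = False
    if theta > e.theta_max:
        theta, clamped = e.theta_max, True
    nodes, weights, clamp2 = locate_patch(bank.grid, theta, phi)
    clamped |= clamp2
    pose_q = antenna_frame(e, theta, phi)
    eta = bank.eta(f)

    E_out = None
    oob_frac = 0.0
    for node, w in zip(nodes, weights):
        if w <= 1e-12:
            continue
        E_node = bank.fields.get(int(node), f)
        H = to_h_surrogate(E_node, eta)
        H_t, oob = transform_field(H, bank.grid.pose(int(node)), pose_q,
                                   bank.fields.spacing, bank.fields.origin)
        E_t = from_h_surrogate(H_t, eta)
        E_out = w * E_t if E_out is None else E_out + w * E_t
        oob_frac += w * oob
    if return_report:
        return E_out, {"clamped": clamped, "out_of_domain_fraction": oob_frac,
                       "nodes": nodes, "weights": weights, "pose": pose_q}
    return E_out


@dataclass
class FieldErrorReport:
    """Normalized field approximation errors (fractions, per Eq. below).

    eps_dis: mean relative magnitude of the complex vector difference;
    eps_abs: mean relative error of the polarization-projected amplitude;
    eps_ang: mean wrapped phase difference of the projection, / pi;
    eps_dir: mean angle between per-voxel amplitude vectors, / (pi/2).
    """

    eps_dis: float
    eps_abs: float
    eps_ang: float
    eps_dir: float
    n_voxels: int
    n_excluded: int
    mask_description: str = ""


def field_error_metrics(E_sim: np.ndarray, E_int: np.ndarray,
                        mask: np.ndarray, U: np.ndarray,
                        model: TissueModel = None,
                        mass_average: bool = True,
                        mask_description: str = "") -> FieldErrorReport:
    """Compare an approximated field against a reference on a mask.

    Both fields are (complex-component-wise) 5 g mass averaged before
    comparison when ``mass_average`` is set (requires ``model``). Voxels
    where the reference denominator vanishes are excluded and counted.
    """
    if E_sim.shape != E_int.shape:
        raise ValueError("fields must share one lattice")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    if mass_average:
        if model is None:
            raise ValueError("mass averaging requires the tissue model")
        rho = model.property_map("rho")
        pmask = model.patient_mask
        avg = []
        for E in (E_sim, E_int):
            out = np.empty_like(E)
            for c in range(3):
                out[..., c] = (mass_average_5g(E[..., c].real, rho, pmask,
                                               model.spacing)
                               + 1j * mass_average_5g(E[..., c].imag, rho, pmask,
                                                      model.spacing))
            avg.append(out)
        E_sim, E_int = avg

    S = E_sim[mask]
    I = E_int[mask]
    U = np.asarray(U, dtype=float)
    U = U / np.linalg.norm(U)

    mag_s = np.linalg.norm(S, axis=-1)
    ok = mag_s > 0
    n_excl = int((~ok).sum())
    eps_dis = float(np.mean(np.linalg.norm(S[ok] - I[ok], axis=-1) / mag_s[ok]))

    a_s = S @ U.astype(complex)
    a_i = I @ U.astype(complex)
    ok_a = np.abs(a_s) > 0
    eps_abs = float(np.mean(np.abs(np.abs(a_s[ok_a]) - np.abs(a_i[ok_a]))
                            / np.abs(a_s[ok_a])))
    dphi = np.angle(a_s[ok_a]) - np.angle(a_i[ok_a])
    dphi = np.angle(np.exp(1j * dphi))  # wrap to (-pi, pi]
    eps_ang = float(np.mean(np.abs(dphi)) / np.pi)

    As = np.abs(S)
    Ai = np.abs(I)
    ns = np.linalg.norm(As, axis=-1)
    ni = np.linalg.norm(Ai, axis=-1)
    ok_d = (ns > 0) & (ni > 0)
    cosang = np.clip(np.sum(As[ok_d] * Ai[ok_d], axis=-1)
                     / (ns[ok_d] * ni[ok_d]), -1.0, 1.0)
    eps_dir = float(np.mean(np.arccos(cosang)) / (np.pi / 2.0))

    return FieldErrorReport(eps_dis=eps_dis, eps_abs=eps_abs,
                            eps_ang=eps_ang, eps_dir=eps_dir,
                            n_voxels=int(mask.sum()), n_excluded=n_excl,
                            mask_description=mask_description)
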