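"""Analytic antenna-field oracle and the per-channel field container.

The oracle produces, for any antenna pose and operating frequency, a
complex vector E-field volume on the tissue lattice. It models an outgoing
polarized spherical wave from the antenna phase center O':

    E(x) = A * D(psi) * p(x) * exp(-j k0 * nbar(x) * s(x)) / max(s, s0)

with s the distance from O', D(psi) = cos^2(psi/2) a smooth forward
directivity taper about the pointing axis W, p the polarization axis U
transported transversally along the ray, and nbar the complex refractive
index line-averaged over the straight ray from O' to x (so phase advance
and attenuation accumulate through the traversed tissues). Fields are
normalized to unit accepted power, taken as the power absorbed in the lossy
domain. The oracle is deliberately ray-based — no diffraction or multiple
scattering — its role is to provide smooth, polarized, dispersive,
anatomy-dependent fields against which the interpolation, coupling and
optimization machinery can be validated, not to replace a full-wave solver.

Externally computed field volumes (e.g. FEM exports) can be carried through
the same ``FieldSet`` container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

from .anatomy import TissueModel
from .constants import C0, EPS0
from .geometry import AntennaPose

__all__ = [
    "FieldSet",
    "complex_refractive_index",
    "oracle_antenna_field",
    "oracle_pair_experiment",
    "sample_vector_field",
    "absorbed_power",
]


def complex_refractive_index(model: TissueModel, f: float) -> np.ndarray:
    """Per-voxel n = sqrt(eps_r - j sigma / (omega eps0)), Re > 0, Im <= 0."""
    eps = model.property_map("eps_r", f)
    sig = model.property_map("sigma", f)
    return np.sqrt(eps - 1j * sig / (2.0 * np.pi * f * EPS0))


def sample_vector_field(E: np.ndarray, origin, spacing, points_mm,
                        order: int = 1) -> np.ndarray:
    """Trilinear sample of a complex (nx,ny,nz,3) field at points (mm)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    idx = ((pts - np.asarray(origin)) / np.asarray(spacing)).T
    out = np.empty((len(pts), 3), dtype=complex)
    for c in range(3):
        out[:, c] = (map_coordinates(E[..., c].real, idx, order=order, cval=0.0)
                     + 1j * map_coordinates(E[..., c].imag, idx, order=order, cval=0.0))
    return out[0] if np.ndim(points_mm) == 1 else out


def absorbed_power(E: np.ndarray, model: TissueModel, f: float) -> float:
    """Total power 1/2 sigma |E|^2 dV absorbed in the lossy domain, W."""
    sigma = model.property_map("sigma", f)
    dv_m3 = model.voxel_volume_mm3 * 1e-9
    return float(0.5 * np.sum(sigma * np.sum(np.abs(E) ** 2, axis=-1)) * dv_m3)


def oracle_antenna_field(model: TissueModel, pose: AntennaPose, f: float,
                         n_steps: int = 32, s0_mm: float | None = None,
                         normalize_power: bool = True,
                         _n_volume: np.ndarray | None = None) -> np.ndarray:
    """Complex vector E-field volume (V/m) of one antenna at one frequency.

    ``_n_volume`` lets callers reuse the per-(model, f) refractive-index
    volume when generating many fields.
    """
    if s0_mm is None:
        s0_mm = float(model.spacing.min())
    Oc = pose.phase_center
    if np.any(model.point_to_index(Oc) < -0.5) or \
       np.any(model.point_to_index(Oc) > np.asarray(model.shape) - 0.5):
        raise ValueError("antenna phase center lies outside the simulated domain")

    nvol = complex_refractive_index(model, f) if _n_volume is None else _n_volume

    X = model.voxel_centers().reshape(-1, 3)
    d = X - Oc
    s = np.linalg.norm(d, axis=1)
    s_safe = np.maximum(s, 1e-9)
    shat = d / s_safe[:, None]

    cospsi = shat @ pose.W
    taper = 0.5 * (1.0 + cospsi)  # cos^2(psi/2)
    pol = pose.U[None, :] - (shat @ pose.U)[:, None] * shat

    # line-averaged refractive index along the ray O' -> x
    nbar = np.zeros(len(X), dtype=complex)
    spacing = model.spacing
    origin = model.origin
    for i in range(n_steps):
        t = (i + 0.5) / n_steps
        pts = Oc + t * d
        idx = ((pts - origin) / spacing).T
        nbar += (map_coordinates(nvol.real, idx, order=1, mode="nearest")
                 + 1j * map_coordinates(nvol.imag, idx, order=1, mode="nearest"))
    nbar /= n_steps

    k0 = 2.0 * np.pi * f / C0          # 1/m
    phase = np.exp(-1j * k0 * nbar * (s * 1e-3))
    amp = taper * phase / np.maximum(s, s0_mm)
    E = (pol * amp[:, None]).reshape(model.shape + (3,))

    if normalize_power:
        p = absorbed_power(E, model, f)
        if p > 0:
            E /= np.sqrt(p)
    return E


@dataclass
class FieldSet:
    """Complex 3-vector E-field volumes indexed by (channel, frequency).

    All volumes share one lattice (``spacing``/``origin``, mm). Accepted
    power per entry is tracked alongside (W).
    """

    spacing: np.ndarray
    origin: np.ndarray
    fields: dict = field(default_factory=dict)          # (channel, f) -> array
    accepted_power: dict = field(default_factory=dict)  # (channel, f) -> W

    def __post_init__(self):
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)

    def add(self, channel, f, E, accepted_power: float = 1.0):
        E = np.asarray(E)
        if not np.all(np.isfinite(E.view(float))):
            raise ValueError("field volume contains non-finite values")
        if self.fields:
            ref = next(iter(self.fields.values()))
            if E.shape != ref.shape:
                raise ValueError("all channels must share one lattice")
        self.fields[(channel, float(f))] = E
        self.accepted_power[(channel, float(f))] = float(accepted_power)

    def get(self, channel, f) -> np.ndarray:
        return self.fields[(channel, float(f))]

    @property
    def channels(self):
        return sorted({c for c, _ in self.fields})

    @property
    def frequencies(self):
        return sorted({f for _, f in self.fields})

    def save(self, path):
        with h5py.File(path, "w") as h5:
            h5.attrs["spacing_mm"] = self.spacing
            h5.attrs["origin_mm"] = self.origin
            for (c, f), E in self.fields.items():
                ds = h5.create_dataset(f"E/{c}/{f:.0f}", data=E, compression="gzip")
                ds.attrs["accepted_power_w"] = self.accepted_power[(c, f)]

    @classmethod
    def load(cls, path) -> "FieldSet":
        with h5py.File(path, "r") as h5:
            fs = cls(spacing=h5.attrs["spacing_mm"], origin=h5.attrs["origin_mm"])
            for c in h5["E"]:
                for fkey in h5[f"E/{c}"]:
                    ds = h5[f"E/{c}/{fkey}"]
                    try:
                        chan = int(c)
                    except ValueError:
                        chan = c
                    fs.add(chan, float(fkey), ds[()],
                           float(ds.attrs.get("accepted_power_w", 1.0)))
        return fs


def oracle_pair_experiment(model: TissueModel, active: AntennaPose,
                           passive: AntennaPose, f: float, c_true: complex,
                           noise: float = 0.0, seed: int = 0,
                           n_steps: int = 32):
    """Synthesize a two-antenna coupling experiment with known ground truth.

    Returns ``(E_A, E_P, E_AP, k_true)`` where ``E_AP = E_A + k_true * E_P``
    (plus optional decorrelated complex Gaussian noise of relative RMS
    amplitude ``noise``) and ``k_true = c_true * <U_P, E_A(O'_P)>``.
    """
    if np.allclose(active.O, passive.O):
        raise ValueError("active and passive poses must be distinct")
    nvol = complex_refractive_index(model, f)
    E_A = oracle_antenna_field(model, active, f, n_steps=n_steps, _n_volume=nvol)
    E_P = oracle_antenna_field(model, passive, f, n_steps=n_steps, _n_volume=nvol)
    e_ap = np.dot(passive.U,
                  sample_vector_field(E_A, model.origin, model.spacing,
                                      passive.phase_center))
    k_true = complex(c_true) * e_ap
    E_AP = E_A + k_true * E_P
    if noise > 0:
        rng = np.random.default_rng(seed)
        rms = np.sqrt(np.mean(np.abs(E_A) ** 2))
        E_AP = E_AP + noise * rms * (rng.standard_normal(E_A.shape)
                                     + 1j * rng.standard_normal(E_A.shape)) / np.sqrt(2)
    return E_A, E_P, E_AP, k_true
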