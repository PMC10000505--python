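"""Array mutual-coupling model: fit and field correction.

A passive antenna re-radiates a scaled copy of its own individual field
when illuminated. The scale k_AP is, to first order, proportional to the
illuminating field projected on the passive element's polarization axis at
its phase center: k_AP = c * e_AP with e_AP = <U_P, E_A(O'_P)> and c a
complex per-frequency constant of the antenna design. c is fitted from a
set of synthetic two-antenna experiments on the layered-sphere phantom
(k_AP estimated by decorrelating the remainder field against E_P); the
array correction then multiplies the stack of individual fields by the
(K-1)-th power of the coupling matrix (ones on the diagonal, c*e_ij off
it), K being the number of wave propagations accounted for (K=3 suffices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fieldsim import FieldSet, sample_vector_field
from .geometry import AntennaPose

__all__ = [
    "CouplingModel",
    "project_coupling_drive",
    "estimate_k_by_decorrelation",
    "fit_coupling_coefficient",
    "apply_array_coupling",
]


def project_coupling_drive(E_A: np.ndarray, passive: AntennaPose,
                           origin, spacing) -> complex:
    """e_AP = <U_P, E_A(O'_P)>: the active field at the passive phase
    center projected on the passive polarization axis."""
    Oc = passive.phase_center
    shape = np.asarray(E_A.shape[:3])
    idx = (Oc - np.asarray(origin)) / np.asarray(spacing)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError("passive phase center lies outside the field domain")
    Ev = sample_vector_field(E_A, origin, spacing, Oc)
    return complex(np.dot(passive.U, Ev))


def estimate_k_by_decorrelation(E_A: np.ndarray, E_P: np.ndarray,
                                E_AP: np.ndarray,
                                domain: np.ndarray = None) -> complex:
    """Least-squares complex scalar fitting E_AP - E_A onto E_P.

    k = int_M <conj(E_P), (E_AP - E_A)> / int_M <conj(E_P), E_P>.
    """
    if domain is not None:
        sel = domain.astype(bool)
        E_A, E_P, E_AP = E_A[sel], E_P[sel], E_AP[sel]
    denom = np.sum(np.conj(E_P) * E_P).real
    if denom <= 0:
        raise ValueError("passive field has zero energy on the domain")
    num = np.sum(np.conj(E_P) * (E_AP - E_A))
    return complex(num / denom)


def fit_coupling_coefficient(pairs) -> tuple:
    """Complex slope through the origin of k against e.

    ``pairs`` is a sequence of ``(e_AP, k_AP)``; the fit minimizes
    sum |k - c e|^2 over complex c. Returns ``(c, correlation)`` where the
    correlation is |sum conj(e) k| / sqrt(sum |e|^2 sum |k|^2).
    """
    e = np.asarray([p[0] for p in pairs], dtype=complex)
    k = np.asarray([p[1] for p in pairs], dtype=complex)
    if len(e) < 1:
        raise ValueError("need at least one pair")
    ee = np.sum(np.abs(e) ** 2)
    if ee == 0:
        raise ValueError("all drive projections are zero: cannot fit c")
    c = complex(np.sum(np.conj(e) * k) / ee)
    kk = np.sum(np.abs(k) ** 2)
    corr = float(np.abs(np.sum(np.conj(e) * k)) / np.sqrt(ee * kk)) if kk > 0 else 0.0
    return c, corr


@dataclass
class CouplingModel:
    """Per-frequency complex coupling coefficient with fit diagnostics."""

    c: dict                      # f -> complex
    K: int = 3                   # number of wave propagations
    n_pairs: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)

    def __post_init__(self):
        if int(self.K) != self.K or self.K < 1:
            raise ValueError("K must be a positive integer")
        self.K = int(self.K)
        self.c = {float(f): complex(v) for f, v in self.c.items()}

    def to_json(self, path):
        payload = {
            "K": self.K,
            "c": {f"{f:.0f}": [v.real, v.imag] for f, v in self.c.items()},
            "n_pairs": {f"{float(f):.0f}": int(n) for f, n in self.n_pairs.items()},
            "correlation": {f"{float(f):.0f}": float(r)
                            for f, r in self.correlation.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CouplingModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(c={float(f): complex(re, im) for f, (re, im) in d["c"].items()},
                   K=d["K"],
                   n_pairs={float(f): n for f, n in d.get("n_pairs", {}).items()},
                   correlation={float(f): r
                                for f, r in d.get("correlation", {}).items()})


def coupling_matrix(fields: FieldSet, poses, c: complex, f: float) -> np.ndarray:
    """Array coupling matrix: ones on the diagonal, c*e_ij off it, with
    e_ij the field of (active) antenna i projected on (passive) antenna j."""
    n = len(poses)
    M = np.eye(n, dtype=complex)
    for i, ci in enumerate(fields.channels[:n]):
        E_i = fields.get(ci, f)
        for j in range(n):
            if i == j:
                continue
            e_ij = project_coupling_drive(E_i, poses[j],
                                          fields.origin, fields.spacing)
            M[i, j] = c * e_ij
    return M


def apply_array_coupling(fields: FieldSet, poses, model: CouplingModel,
                         frequencies=None) -> FieldSet:
    """Coupling-corrected per-channel fields: E_hat = M^(K-1) E stackwise.

    K=1 (or c=0) returns the fields unchanged. The matrix power is computed
    by repeated multiplication (K is small in practice).
    """
    if len(poses) != len(fields.channels):
        raise ValueError("pose count does not match the number of channels")
    out = FieldSet(spacing=fields.spacing, origin=fields.origin)
    for f in (frequencies or fields.frequencies):
        stack = np.stack([fields.get(c, f) for c in fields.channels])
        if model.K == 1 or model.c.get(float(f), 0) == 0:
            corrected = stack
        else:
            M = coupling_matrix(fields, poses, model.c[float(f)], f)
            P = np.linalg.matrix_power(M, model.K - 1)
            corrected = np.tensordot(P, stack, axes=(1, 0))
        for c_idx, chan in enumerate(fields.channels):
            out.add(chan, f, corrected[c_idx],
                    fields.accepted_power[(chan, float(f))])
    return out
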