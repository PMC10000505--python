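"""Steady-state Pennes bioheat solution on the voxel lattice.

Solves div(k grad T) - rho_b c_b w (T - T_b) + PLD = 0 over the patient
voxels with a 7-point finite-volume discretization. Heat exchange with the
surroundings enters through Robin (convective) conditions on exterior
faces: h = 100 W/m^2/K toward 30 degC water at the bolus contact and
h = 8 W/m^2/K toward 20 degC air elsewhere; faces on the lattice boundary
are adiabatic. The water bolus itself is not meshed — its entire thermal
effect is the Robin condition. Perfusion uses constant per-tissue rates
(no thermoregulation) with blood rho_b c_b = 3.6e6 J/m^3/K at 37 degC.

The deposited power is scaled by a factor kappa so that the maximum
temperature in healthy tissue equals the tolerated limit (42 degC);
because T depends affinely on kappa, the maximum is strictly increasing in
kappa and the scaling is found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .anatomy import LABELS, TissueModel
from .constants import RHO_CP_BLOOD, T_BLOOD
from .fieldsim import FieldSet
from .planning import SteeringSet

__all__ = [
    "ThermalResult",
    "BoundaryConditions",
    "pld_from_plan",
    "solve_pennes_steady",
    "scale_power_to_limit",
    "temperature_indexes",
]


@dataclass
class BoundaryConditions:
    h_air: float = 8.0       # W/m^2/K, skin-air convection
    t_air: float = 20.0      # degC
    h_water: float = 100.0   # W/m^2/K, skin-water convection
    t_water: float = 30.0    # degC


@dataclass
class ThermalResult:
    T: np.ndarray            # degC over the lattice (NaN outside tissue)
    kappa: float
    max_healthy_t: float
    t50: float
    t90: float

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "max_healthy_t": self.max_healthy_t,
                "t50": self.t50, "t90": self.t90}


def pld_from_plan(fields: FieldSet, chi: SteeringSet, model: TissueModel,
                  kappa: float = 1.0) -> np.ndarray:
    """Power loss density kappa * sum_f 1/2 sigma_f |E_f|^2, W/m^3.

    Unlike the planning SAR, the PLD is neither mass averaged nor masked.
    """
    channels = fields.channels
    pld = np.zeros(model.shape)
    for f in chi.frequencies:
        w = chi.chi[f]
        if len(w) != len(channels):
            raise ValueError("steering channel count does not match fields")
        if not np.any(w):
            continue
        Etot = None
        for c, x in zip(channels, w):
            if x == 0:
                continue
            term = x * fields.get(c, f)
            Etot = term if Etot is None else Etot + term
        sigma = model.property_map("sigma", f)
        pld += 0.5 * sigma * np.sum(np.abs(Etot) ** 2, axis=-1)
    return kappa * pld


def _face_class(model: TissueModel):
    """Per-voxel class: 1 tissue, 2 water, 0 air (background or airway)."""
    cls = np.zeros(model.shape, dtype=np.int8)
    cls[model.patient_mask] = 1
    cls[model.labels == LABELS["water"]] = 2
    return cls


def solve_pennes_steady(model: TissueModel, pld: np.ndarray,
                        bc: BoundaryConditions = BoundaryConditions(),
                        baseline_metabolic: float = 0.0) -> np.ndarray:
    """Steady-state temperature over the patient voxels (NaN elsewhere)."""
    tissue = model.patient_mask
    if not tissue.any():
        raise ValueError("no tissue voxels to solve on")
    cls = _face_class(model)
    k_map = model.property_map("k_th")
    rho = model.property_map("rho")
    perf = model.property_map("perfusion")           # ml/min/kg
    omega = perf * rho * 1e-6 / 60.0                 # 1/s (m^3 blood / m^3 / s)

    h_m = model.spacing * 1e-3                        # m
    vol = float(np.prod(h_m))
    areas = np.array([h_m[1] * h_m[2], h_m[0] * h_m[2], h_m[0] * h_m[1]])

    idx = -np.ones(model.shape, dtype=int)
    ii = np.argwhere(tissue)
    idx[tissue] = np.arange(len(ii))
    n = len(ii)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs = np.zeros(n)

    pld_flat = pld[tissue] if pld is not None else np.zeros(n)
    rhs += (pld_flat + baseline_metabolic) * vol
    sink = RHO_CP_BLOOD * omega[tissue] * vol
    diag += sink
    rhs += sink * T_BLOOD

    for axis in range(3):
        for sgn in (-1, 1):
            nb = ii.copy()
            nb[:, axis] += sgn
            inside = (nb[:, axis] >= 0) & (nb[:, axis] < model.shape[axis])
            A = areas[axis]
            h_len = h_m[axis]

            here = ii[inside]
            there = nb[inside]
            cls_nb = cls[there[:, 0], there[:, 1], there[:, 2]]
            i_here = idx[here[:, 0], here[:, 1], here[:, 2]]

            # tissue-tissue conduction (harmonic-mean face conductivity)
            tt = cls_nb == 1
            kh = k_map[here[tt, 0], here[tt, 1], here[tt, 2]]
            kn = k_map[there[tt, 0], there[tt, 1], there[tt, 2]]
            kf = 2.0 * kh * kn / (kh + kn)
            g = kf * A / h_len
            i_t = i_here[tt]
            j_t = idx[there[tt, 0], there[tt, 1], there[tt, 2]]
            rows.append(i_t)
            cols.append(j_t)
            vals.append(-g)
            np.add.at(diag, i_t, g)

            # convective faces toward water or air
            for klass, h_c, t_inf in ((2, bc.h_water, bc.t_water),
                                      (0, bc.h_air, bc.t_air)):
                sel = cls_nb == klass
                if not sel.any():
                    continue
                # series of half-cell conduction and surface convection
                kh = k_map[here[sel, 0], here[sel, 1], here[sel, 2]]
                g_cond = kh * A / (h_len / 2.0)
                g_conv = h_c * A
                g_eff = g_cond * g_conv / (g_cond + g_conv)
                np.add.at(diag, i_here[sel], g_eff)
                np.add.at(rhs, i_here[sel], g_eff * t_inf)
            # lattice-boundary faces: adiabatic (no terms)

    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    vals = np.concatenate(vals) if vals else np.array([])
    A_sys = coo_matrix((np.concatenate([vals, diag]),
                        (np.concatenate([rows, np.arange(n)]),
                         np.concatenate([cols, np.arange(n)]))),
                       shape=(n, n)).tocsr()
    if diag.min() <= 0:
        raise ValueError("singular bioheat system: a voxel has neither "
                         "boundary exchange nor perfusion nor conduction")
    T_flat = spsolve(A_sys, rhs)
    T = np.full(model.shape, np.nan)
    T[tissue] = T_flat
    return T


def temperature_indexes(T: np.ndarray, target: np.ndarray):
    """T50 and T90: the minimum temperature reached within the hottest 50%
    and 90% of the target temperature distribution (nearest rank)."""
    vals = np.sort(T[target])
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n == 0:
        raise ValueError("empty target mask")

    def t_index(frac):
        count = int(np.ceil(frac * n))
        return float(vals[n - count])

    return t_index(0.5), t_index(0.9)


def scale_power_to_limit(model: TissueModel, fields: FieldSet,
                         chi: SteeringSet, limit_c: float = 42.0,
                         bc: BoundaryConditions = BoundaryConditions(),
                         tol_c: float = 0.01) -> ThermalResult:
    """Find kappa so the maximum healthy-tissue temperature equals the
    limit, and evaluate the resulting target temperature indexes.

    T is affine in kappa (the system is linear and PLD enters linearly),
    so only two solves are needed; the root is then bisected on the cached
    affine response to within ``tol_c``.
    """
    pld_unit = pld_from_plan(fields, chi, model, kappa=1.0)
    T0 = solve_pennes_steady(model, None, bc=bc)
    T1 = solve_pennes_steady(model, pld_unit, bc=bc)
    healthy = model.patient_mask & (model.labels != LABELS["tumor"])
    D = T1 - T0

    def max_healthy(kappa):
        return float(np.nanmax((T0 + kappa * D)[healthy]))

    base = max_healthy(0.0)
    if limit_c < base - tol_c:
        raise ValueError(f"limit {limit_c} degC below the zero-power "
                         f"temperature {base:.2f} degC")
    gain = float(np.nanmax(D[healthy]))
    if gain <= 0:
        raise ValueError("deposited power does not heat healthy tissue")

    lo, hi = 0.0, max((limit_c - base) / gain * 2.0, 1e-6)
    while max_healthy(hi) < limit_c:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("kappa search diverged")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if max_healthy(mid) < limit_c:
            lo = mid
        else:
            hi = mid
        if abs(max_healthy(0.5 * (lo + hi)) - limit_c) <= 0.25 * tol_c:
            break
    kappa = 0.5 * (lo + hi)
    T = T0 + kappa * D
    t50, t90 = temperature_indexes(T, model.labels == LABELS["tumor"])
    return ThermalResult(T=T, kappa=kappa, max_healthy_t=max_healthy(kappa),
                         t50=t50, t90=t90)
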