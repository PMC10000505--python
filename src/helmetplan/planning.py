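"""Multi-frequency SAR treatment planning.

The plan quality metric is the hot-to-cold spot quotient

    HCQ_p = mean SAR over the hottest q-percentile of healthy tissue
          / mean SAR over the coldest p-percentile of the target,

with q = p * |T| / |R| tying the two tail volumes together (they contain
the same number of voxels on a uniform lattice). SAR is assembled
coherently within each operating frequency and incoherently across
frequencies from per-channel complex steering parameters, 5 g mass
averaged, and evaluated on masks that exclude the first 20 mm of tissue
under the water bolus (whose losses are counteracted by surface cooling).

The steering optimizer iterates a time-reversal-flavoured scheme: per
frequency, the steering vector maximizing cold-tail target SAR against
hot-tail healthy SAR is the dominant generalized eigenvector of the two
tail covariance matrices; tails are re-identified and frequency weights
re-balanced each sweep, with monotone acceptance of the best plan seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.ndimage import distance_transform_edt

from .anatomy import LABELS, TissueModel
from .fieldsim import FieldSet

__all__ = [
    "SteeringSet",
    "MaskSet",
    "PlanResult",
    "MassAverager",
    "assemble_sar",
    "mass_average_5g",
    "build_evaluation_masks",
    "hcq",
    "optimize_steering",
]


# ---------------------------------------------------------------------------
# steering parameters
# ---------------------------------------------------------------------------

@dataclass
class SteeringSet:
    """Complex steering parameters chi[f] -> (n_channels,).

    The convention is unit total accepted power: with unit-power per-channel
    fields, sum_f sum_c |chi|^2 = 1 after :meth:`normalized`.
    """

    chi: dict

    def __post_init__(self):
        self.chi = {float(f): np.asarray(v, dtype=complex)
                    for f, v in self.chi.items()}
        if not any(np.any(v != 0) for v in self.chi.values()):
            raise ValueError("steering set has no nonzero entry")

    @property
    def frequencies(self):
        return sorted(self.chi)

    @property
    def n_channels(self) -> int:
        return len(next(iter(self.chi.values())))

    def total_power(self) -> float:
        return float(sum(np.sum(np.abs(v) ** 2) for v in self.chi.values()))

    def normalized(self) -> "SteeringSet":
        s = np.sqrt(self.total_power())
        return SteeringSet({f: v / s for f, v in self.chi.items()})

    def power_fractions(self) -> np.ndarray:
        """(n_channels, n_frequencies) accepted-power fractions in percent
        (summing to 100 over the whole table)."""
        tot = self.total_power()
        cols = [np.abs(self.chi[f]) ** 2 / tot * 100.0 for f in self.frequencies]
        return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# SAR assembly
# ---------------------------------------------------------------------------

def assemble_sar(fields: FieldSet, chi: SteeringSet,
                 model: TissueModel) -> np.ndarray:
    """SAR (W/kg): coherent within each frequency, incoherent across.

    SAR = sum_f (sigma_f / 2 rho) |sum_c chi_{f,c} E_{f,c}|^2.
    """
    channels = fields.channels
    sar = None
    for f in chi.frequencies:
        w = chi.chi[f]
        if len(w) != len(channels):
            raise ValueError("steering channel count does not match fields")
        Etot = None
        for c, x in zip(channels, w):
            if x == 0:
                continue
            term = x * fields.get(c, f)
            Etot = term if Etot is None else Etot + term
        if Etot is None:
            continue
        sigma = model.property_map("sigma", f)
        rho = model.property_map("rho")
        contrib = 0.5 * sigma / rho * np.sum(np.abs(Etot) ** 2, axis=-1)
        contrib[sigma == 0] = 0.0
        sar = contrib if sar is None else sar + contrib
    if sar is None:
        raise ValueError("no active frequency in the steering set")
    return sar


# ---------------------------------------------------------------------------
# 5 g mass averaging (growing cubic kernel)
# ---------------------------------------------------------------------------

def _integral_image(a: np.ndarray) -> np.ndarray:
    p = np.zeros(tuple(s + 1 for s in a.shape))
    p[1:, 1:, 1:] = a.cumsum(0).cumsum(1).cumsum(2)
    return p


def _box_sum(P: np.ndarray, r: int) -> np.ndarray:
    """Sum over the centered cube of half-width r for every voxel."""
    n = np.array(P.shape) - 1
    lo = [np.clip(np.arange(n[k]) - r, 0, n[k]) for k in range(3)]
    hi = [np.clip(np.arange(n[k]) + r + 1, 0, n[k]) for k in range(3)]

    def take(P, idx, axis):
        return np.take(P, idx, axis=axis)

    out = np.zeros(tuple(n))
    for sx, ix in ((1, hi[0]), (-1, lo[0])):
        Px = take(P, ix, 0)
        for sy, iy in ((1, hi[1]), (-1, lo[1])):
            Pxy = take(Px, iy, 1)
            for sz, iz in ((1, hi[2]), (-1, lo[2])):
                out += sx * sy * sz * take(Pxy, iz, 2)
    return out


class MassAverager:
    """Per-voxel cubic-kernel averaging to a target in-mask tissue mass.

    For every in-mask voxel the smallest centered cubic kernel whose
    in-mask mass reaches the target (default 5 g) is found once; fields are
    then averaged mass-weighted over that kernel (voxels outside the mask
    contribute nothing). Out-of-mask voxels pass through unchanged.
    """

    def __init__(self, rho: np.ndarray, mask: np.ndarray, spacing,
                 target_mass_g: float = 5.0):
        if not mask.any():
            raise ValueError("empty mask")
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        vox_kg = float(np.prod(spacing)) * 1e-9 * 1.0  # mm^3 -> m^3, rho kg/m^3
        self.mask = mask
        self.m = np.where(mask, rho * vox_kg, 0.0)  # kg per voxel
        target_kg = target_mass_g * 1e-3
        if self.m.sum() < target_kg:
            raise ValueError("total in-mask tissue mass below the target mass")
        self._Pm = _integral_image(self.m)
        radius = np.full(mask.shape, -1, dtype=int)
        todo = mask.copy()
        r = 0
        while todo.any():
            bm = _box_sum(self._Pm, r)
            done = todo & (bm >= target_kg)
            radius[done] = r
            self._mass_at_r = bm
            todo &= ~done
            r += 1
            if r > max(mask.shape):
                raise ValueError("kernel growth exceeded the domain")
        self.radius = radius
        self._radii = np.unique(radius[mask])

    def apply(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float, copy=True)
        Pvm = _integral_image(values * self.m)
        for r in self._radii:
            sel = self.radius == r
            num = _box_sum(Pvm, int(r))
            den = _box_sum(self._Pm, int(r))
            out[sel] = num[sel] / den[sel]
        return out


def mass_average_5g(values: np.ndarray, rho: np.ndarray, mask: np.ndarray,
                    spacing, target_mass_g: float = 5.0) -> np.ndarray:
    """One-shot 5 g mass averaging (see :class:`MassAverager`)."""
    return MassAverager(rho, mask, spacing, target_mass_g).apply(values)


# ---------------------------------------------------------------------------
# evaluation masks and HCQ
# ---------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Target and remaining-tissue evaluation masks with tail percentages."""

    target: np.ndarray
    remaining: np.ndarray
    p: float
    q: float
    voxel_volume_mm3: float

    def __post_init__(self):
        if np.any(self.target & self.remaining):
            raise ValueError("target and remaining masks overlap")

    @property
    def n_target(self) -> int:
        return int(self.target.sum())

    @property
    def n_remaining(self) -> int:
        return int(self.remaining.sum())


def build_evaluation_masks(model: TissueModel, p: float = 50.0,
                           exclusion_depth_mm: float = 20.0,
                           target_label: str = "tumor") -> MaskSet:
    """Target mask, and remaining tissue minus the cooled surface layer.

    The exclusion layer is the set of patient voxels within
    ``exclusion_depth_mm`` (Euclidean distance) of the water/air contact
    surface; q follows from p by the fixed volume relation
    q = p |T| / |R|.
    """
    if not (0 < p <= 100):
        raise ValueError("p must be in (0, 100]")
    target = model.labels == LABELS[target_label]
    if not target.any():
        raise ValueError(f"no {target_label} label in the model")
    patient = model.patient_mask
    depth = distance_transform_edt(patient, sampling=model.spacing)
    remaining = patient & ~target & (depth > exclusion_depth_mm)
    if not remaining.any():
        raise ValueError("surface exclusion removed all remaining tissue")
    q = p * target.sum() / remaining.sum()
    return MaskSet(target=target, remaining=remaining, p=float(p), q=float(q),
                   voxel_volume_mm3=model.voxel_volume_mm3)


def _tail_mean(values: np.ndarray, weights: np.ndarray, count: int,
               lowest: bool) -> float:
    order = np.argsort(values, kind="stable")
    idx = order[:count] if lowest else order[-count:]
    return float(np.average(values[idx], weights=weights[idx]))


def hcq(sar_avg: np.ndarray, masks: MaskSet, rho: np.ndarray = None):
    """Hot-to-cold spot quotient and its two tail means.

    Tail sizes follow nearest-rank counts: ceil(p% of |T|) coldest target
    voxels and ceil(q% of |R|) hottest remaining voxels (the same count by
    construction of q); tail means are mass weighted when ``rho`` is given.
    Returns ``(HCQ, mean_target_tail, mean_remaining_tail)``.
    """
    t_vals = sar_avg[masks.target]
    r_vals = sar_avg[masks.remaining]
    if np.all(t_vals == 0):
        return np.inf, 0.0, float(r_vals.max(initial=0.0))
    w_t = rho[masks.target] if rho is not None else np.ones_like(t_vals)
    w_r = rho[masks.remaining] if rho is not None else np.ones_like(r_vals)
    n_cold = max(1, int(np.ceil(masks.p / 100.0 * masks.n_target)))
    n_hot = max(1, int(np.ceil(masks.q / 100.0 * masks.n_remaining)))
    sar_t = _tail_mean(t_vals, w_t, n_cold, lowest=True)
    sar_r = _tail_mean(r_vals, w_r, n_hot, lowest=False)
    if sar_t == 0:
        return np.inf, 0.0, sar_r
    return sar_r / sar_t, sar_t, sar_r


# ---------------------------------------------------------------------------
# steering optimization
# ---------------------------------------------------------------------------

@dataclass
class PlanResult:
    """Optimized steering with its SAR map and quality figures."""

    chi: SteeringSet
    sar: np.ndarray
    sar_avg: np.ndarray
    hcq: float
    sar_target_tail: float
    sar_remaining_tail: float
    masks: MaskSet
    n_evaluations: int = 0
    seed: int = 0

    @property
    def power_fractions(self) -> np.ndarray:
        return self.chi.power_fractions()

    @property
    def frequency_power_totals(self) -> np.ndarray:
        return self.power_fractions.sum(axis=0)

    @property
    def channel_power_totals(self) -> np.ndarray:
        return self.power_fractions.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "hcq": self.hcq,
            "sar_target_tail": self.sar_target_tail,
            "sar_remaining_tail": self.sar_remaining_tail,
            "p": self.masks.p, "q": self.masks.q,
            "chi": {f"{f:.0f}": np.stack([v.real, v.imag], axis=-1).tolist()
                    for f, v in self.chi.chi.items()},
            "power_fractions_percent": self.power_fractions.tolist(),
            "seed": self.seed,
        }


class _PlanEvaluator:
    """Caches per-frequency stacked fields and the mass averager so that a
    steering set can be scored cheaply."""

    def __init__(self, fields: FieldSet, model: TissueModel, masks: MaskSet,
                 frequencies=None, mass_average: bool = True):
        self.frequencies = list(frequencies or fields.frequencies)
        self.channels = fields.channels
        self.model = model
        self.masks = masks
        self.rho = model.property_map("rho")
        self.shape = model.shape
        self.stacks = {}
        self.coef = {}
        for f in self.frequencies:
            E = np.stack([fields.get(c, f).reshape(-1, 3)
                          for c in self.channels])  # (nc, N, 3)
            if not np.all(np.isfinite(E.view(float))):
                raise ValueError("non-finite field volume")
            self.stacks[f] = E
            sigma = model.property_map("sigma", f).reshape(-1)
            self.coef[f] = 0.5 * sigma / self.rho.reshape(-1)
        self.averager = (MassAverager(self.rho, model.patient_mask,
                                      model.spacing)
                         if mass_average else None)
        self.n_evaluations = 0

    def sar(self, chi: SteeringSet) -> np.ndarray:
        out = np.zeros(np.prod(self.shape))
        for f in chi.frequencies:
            w = chi.chi[f]
            if not np.any(w):
                continue
            Etot = np.tensordot(w, self.stacks[f], axes=(0, 0))
            out += self.coef[f] * np.sum(np.abs(Etot) ** 2, axis=-1)
        return out.reshape(self.shape)

    def score(self, chi: SteeringSet):
        self.n_evaluations += 1
        s = self.sar(chi)
        s_avg = self.averager.apply(s) if self.averager is not None else s
        h, st, sr = hcq(s_avg, self.masks, rho=self.rho)
        return h, s, s_avg, st, sr

    # -- tail covariance matrices for the eigen step ----------------------
    def covariances(self, sar_avg: np.ndarray):
        flat = sar_avg.reshape(-1)
        tgt = np.flatnonzero(self.masks.target.reshape(-1))
        rem = np.flatnonzero(self.masks.remaining.reshape(-1))
        n_cold = max(1, int(np.ceil(self.masks.p / 100.0 * len(tgt))))
        n_hot = max(1, int(np.ceil(self.masks.q / 100.0 * len(rem))))
        cold = tgt[np.argsort(flat[tgt], kind="stable")[:n_cold]]
        hot = rem[np.argsort(flat[rem], kind="stable")[-n_hot:]]
        S_T, S_R = {}, {}
        for f in self.frequencies:
            E = self.stacks[f]
            for name, vox in (("T", cold), ("R", hot)):
                B = E[:, vox, :] * np.sqrt(self.coef[f][vox])[None, :, None]
                B = B.reshape(len(self.channels), -1)
                (S_T if name == "T" else S_R)[f] = B @ B.conj().T
        return S_T, S_R


def optimize_steering(fields: FieldSet, model: TissueModel, masks: MaskSet,
                      frequencies=None, seed: int = 0, n_random: int = 200,
                      max_iter: int = 10, tol: float = 1e-4,
                      mass_average: bool = True,
                      initial_candidates=None) -> PlanResult:
    """Minimize HCQ over per-channel, per-frequency complex steering.

    The search evaluates a uniform-phase equal-amplitude start (all
    frequencies, and each frequency alone), ``n_random`` seeded random
    steerings, and any caller-supplied ``initial_candidates`` (e.g. a plan
    for a nested sub-array padded with zero channels); it then iterates the
    generalized-eigenvector update on the best plan found, accepting only
    improvements, so the result is never worse than the best
    initialization. Deterministic for a fixed seed.
    """
    ev = _PlanEvaluator(fields, model, masks, frequencies,
                        mass_average=mass_average)
    freqs = ev.frequencies
    nc = len(ev.channels)
    rng = np.random.default_rng(seed)

    def make(chi_dict):
        return SteeringSet(chi_dict).normalized()

    candidates = [c.normalized() for c in (initial_candidates or [])]
    candidates.append(make({f: np.ones(nc) for f in freqs}))
    for f in freqs:
        candidates.append(make({g: (np.ones(nc) if g == f else np.zeros(nc))
                                for g in freqs}))
    for _ in range(n_random):
        candidates.append(make({f: rng.standard_normal(nc)
                                + 1j * rng.standard_normal(nc) for f in freqs}))

    best = None
    for chi in candidates:
        h, s, s_avg, st, sr = ev.score(chi)
        if best is None or h < best[0]:
            best = (h, chi, s, s_avg, st, sr)

    # iterative time-reversal-style refinement
    for _ in range(max_iter):
        h0 = best[0]
        S_T, S_R = ev.covariances(best[3])
        per_freq = {}
        for f in freqs:
            A = S_T[f]
            Bm = S_R[f]
            ridge = 1e-9 * max(np.trace(Bm).real, 1e-30)
            vals, vecs = eigh(A, Bm + ridge * np.eye(nc))
            v = vecs[:, -1]
            nv = np.linalg.norm(v)
            per_freq[f] = v / nv if nv > 0 else np.ones(nc) / np.sqrt(nc)
        # frequency re-weighting: single frequencies, uniform mix, seeded
        # Dirichlet mixes, and the current best amplitudes
        weight_sets = [np.eye(len(freqs))[k] for k in range(len(freqs))]
        weight_sets.append(np.ones(len(freqs)) / len(freqs))
        for _ in range(6):
            weight_sets.append(rng.dirichlet(np.ones(len(freqs))))
        cur = np.array([np.sum(np.abs(best[1].chi[f]) ** 2) for f in freqs])
        if cur.sum() > 0:
            weight_sets.append(cur / cur.sum())
        for alpha in weight_sets:
            if not np.any(alpha):
                continue
            chi = make({f: np.sqrt(a) * per_freq[f]
                        for f, a in zip(freqs, alpha)})
            try:
                h, s, s_avg, st, sr = ev.score(chi)
            except ValueError:
                continue
            if h < best[0]:
                best = (h, chi, s, s_avg, st, sr)
        if h0 - best[0] <= tol * max(h0, 1e-30):
            break

    h, chi, s, s_avg, st, sr = best
    return PlanResult(chi=chi, sar=s, sar_avg=s_avg, hcq=float(h),
                      sar_target_tail=st, sar_remaining_tail=sr,
                      masks=masks, n_evaluations=ev.n_evaluations, seed=seed)
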