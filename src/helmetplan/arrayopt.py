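"""Global antenna-arrangement optimization.

The array layout — the surface coordinates (theta, phi) of each of the nc
antennas — is optimized in two stages. A random-search (RS) stage draws
n_r = round(n_patches / n_c) feasible arrangements area-uniformly over the
bolus surface (rejecting overlapping antennas and poses in front of the
eyes); every candidate is scored by the full interpolation + coupling +
steering-optimization pipeline. Candidates are then sorted by cost and
refined locally (LR) with a constrained SQP using finite-difference
gradients on (theta, phi); refinement proceeds down the sorted list and
stops at the first candidate whose refined cost is worse than the best
refined cost so far. Channel order is semantically redundant (permuting
antennas leaves the array unchanged), which is why population-based global
optimizers are a poor fit and RS + LR is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coupling import CouplingModel, apply_array_coupling
from .fieldsim import FieldSet
from .geometry import (ANTENNA_RADIUS_MM, SurfaceGrid, antenna_frame,
                       clearance_constraints, uniform_surface_sample)
from .interp import InterpolationBank, interpolate_antenna_field
from .planning import MaskSet, PlanResult, optimize_steering

__all__ = [
    "Arrangement",
    "DesignResult",
    "ArrangementEvaluator",
    "sample_random_arrangements",
    "evaluate_arrangement",
    "refine_and_select",
]


@dataclass
class Arrangement:
    """Candidate antenna layout with its feasibility record."""

    thetas: np.ndarray
    phis: np.ndarray
    pair_values: np.ndarray = None
    eye_values: np.ndarray = None

    def __post_init__(self):
        self.thetas = np.atleast_1d(np.asarray(self.thetas, dtype=float))
        self.phis = np.atleast_1d(np.asarray(self.phis, dtype=float))

    @property
    def n_channels(self) -> int:
        return len(self.thetas)

    @property
    def feasible(self) -> bool:
        ok = True
        if self.pair_values is not None and self.n_channels > 1:
            off = self.pair_values[~np.isnan(self.pair_values)]
            ok &= bool(np.all(off > 0))
        if self.eye_values is not None and self.eye_values.size:
            ok &= bool(np.all(self.eye_values > 0))
        return ok


def _constraint_values(ellipsoid, thetas, phis, r, eye_exclusions):
    poses = [antenna_frame(ellipsoid, t, p, retract=True)
             for t, p in zip(thetas, phis)]
    return clearance_constraints(poses, r=r, eye_exclusions=eye_exclusions,
                                 ellipsoid=ellipsoid)


def make_arrangement(ellipsoid, thetas, phis, r=ANTENNA_RADIUS_MM,
                     eye_exclusions=None) -> Arrangement:
    pair, eye = _constraint_values(ellipsoid, thetas, phis, r, eye_exclusions)
    return Arrangement(thetas=thetas, phis=phis, pair_values=pair,
                       eye_values=eye)


def sample_random_arrangements(grid: SurfaceGrid, nc: int, seed: int = 0,
                               r: float = ANTENNA_RADIUS_MM,
                               eye_exclusions=None,
                               n_arrangements: int = None,
                               max_attempts_per: int = 500):
    """Draw round(n_patches / nc) feasible arrangements area-uniformly."""
    if nc < 1:
        raise ValueError("need at least one channel")
    n_r = n_arrangements if n_arrangements is not None \
        else max(1, int(round(grid.n_patches / nc)))
    rng = np.random.default_rng(seed)
    e = grid.ellipsoid
    out = []
    for _ in range(n_r):
        for attempt in range(max_attempts_per):
            th, ph = uniform_surface_sample(e, nc, rng)
            arr = make_arrangement(e, th, ph, r=r,
                                   eye_exclusions=eye_exclusions)
            if arr.feasible:
                out.append(arr)
                break
        else:
            raise RuntimeError(
                f"could not draw a feasible arrangement of nc={nc} antennas"
                f" within {max_attempts_per} attempts")
    return out


class ArrangementEvaluator:
    """Scores an arrangement with the full approximation pipeline:
    per-channel field interpolation, array-coupling correction, and
    steering optimization; returns the optimized (interpolated) HCQ."""

    def __init__(self, bank: InterpolationBank, coupling: CouplingModel,
                 masks: MaskSet, frequencies=None, seed: int = 0,
                 steering_kwargs: dict = None):
        self.bank = bank
        self.coupling = coupling
        self.masks = masks
        self.frequencies = list(frequencies or bank.fields.frequencies)
        self.seed = seed
        self.steering_kwargs = dict(steering_kwargs or {})
        self.n_pipeline_runs = 0

    def plan(self, arr: Arrangement) -> PlanResult:
        self.n_pipeline_runs += 1
        e = self.bank.grid.ellipsoid
        fs = FieldSet(spacing=self.bank.fields.spacing,
                      origin=self.bank.fields.origin)
        poses = []
        for c, (th, ph) in enumerate(zip(arr.thetas, arr.phis)):
            th = min(max(th, 1e-6), e.theta_max)
            poses.append(antenna_frame(e, th, ph))
            for f in self.frequencies:
                fs.add(c, f, interpolate_antenna_field(self.bank, th, ph, f))
        corrected = apply_array_coupling(fs, poses, self.coupling,
                                         frequencies=self.frequencies)
        return optimize_steering(corrected, self.bank.model, self.masks,
                                 frequencies=self.frequencies, seed=self.seed,
                                 **self.steering_kwargs)

    def __call__(self, arr: Arrangement) -> float:
        return self.plan(arr).hcq


def evaluate_arrangement(arr: Arrangement, bank: InterpolationBank,
                         coupling: CouplingModel, masks: MaskSet,
                         frequencies=None, seed: int = 0,
                         steering_kwargs: dict = None) -> float:
    """One-shot interpolated HCQ of an arrangement (see
    :class:`ArrangementEvaluator`)."""
    return ArrangementEvaluator(bank, coupling, masks, frequencies=frequencies,
                                seed=seed, steering_kwargs=steering_kwargs)(arr)


@dataclass
class DesignResult:
    best: Arrangement
    best_hcq: float
    trajectory: list = field(default_factory=list)  # (stage, hcq) records
    n_candidates: int = 0
    n_refined: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"thetas": self.best.thetas.tolist(),
                "phis": self.best.phis.tolist(),
                "hcq": self.best_hcq,
                "trajectory": self.trajectory,
                "n_candidates": self.n_candidates,
                "n_refined": self.n_refined,
                "seed": self.seed}


def _local_refine(arr: Arrangement, evaluator, r, eye_exclusions,
                  fd_step_deg: float = 0.5, maxiter: int = 10):
    """Constrained SQP refinement of one candidate (descent-or-fallback)."""
    e = evaluator.bank.grid.ellipsoid
    nc = arr.n_channels
    x0 = np.concatenate([arr.thetas, arr.phis])

    def unpack(x):
        return np.clip(x[:nc], 1e-3, e.theta_max), x[nc:]

    def cost(x):
        th, ph = unpack(x)
        return evaluator(Arrangement(thetas=th, phis=ph))

    def cons_vec(x):
        th, ph = unpack(x)
        pair, eye = _constraint_values(e, th, ph, r, eye_exclusions)
        vals = []
        if nc > 1:
            iu = np.triu_indices(nc, 1)
            vals.append(pair[iu])
        if eye is not None and eye.size:
            vals.append(eye.reshape(-1))
        return np.concatenate(vals) if vals else np.array([1.0])

    h0 = cost(x0)
    bounds = [(1e-3, e.theta_max)] * nc + [(None, None)] * nc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(cost, x0, method="SLSQP", bounds=bounds,
                       constraints=[{"type": "ineq", "fun": cons_vec}],
                       options={"eps": np.radians(fd_step_deg),
                                "maxiter": maxiter, "ftol": 1e-4})
    th, ph = unpack(res.x)
    refined = make_arrangement(e, th, ph, r=r, eye_exclusions=eye_exclusions)
    if not refined.feasible or not np.isfinite(res.fun) or res.fun > h0:
        if not refined.feasible:
            warnings.warn("refiner left the feasible region; keeping the "
                          "unrefined candidate")
        return make_arrangement(e, arr.thetas, arr.phis, r=r,
                                eye_exclusions=eye_exclusions), float(h0)
    return refined, float(res.fun)


def refine_and_select(candidates, evaluator: ArrangementEvaluator,
                      r: float = ANTENNA_RADIUS_MM, eye_exclusions=None,
                      fd_step_deg: float = 0.5, maxiter: int = 10,
                      seed: int = 0) -> DesignResult:
    """Sort candidates by cost, refine down the list with early stopping.

    Local refinement is applied to candidates in ascending cost order; the
    loop stops at the first candidate whose refined cost is worse than the
    best refined cost so far (the remaining, costlier qualitative
    arrangements are then unlikely to do better).
    """
    if not candidates:
        raise ValueError("need at least one feasible candidate")
    scored = sorted(((evaluator(c), i, c) for i, c in enumerate(candidates)),
                    key=lambda t: t[0])
    traj = [("rs", float(h)) for h, _, _ in scored]

    best_arr, best_h = None, np.inf
    n_ref = 0
    for h0, _, cand in scored:
        refined, h = _local_refine(cand, evaluator, r, eye_exclusions,
                                   fd_step_deg=fd_step_deg, maxiter=maxiter)
        n_ref += 1
        traj.append(("lr", float(h)))
        if h < best_h:
            best_arr, best_h = refined, h
        else:
            break
    return DesignResult(best=best_arr, best_hcq=float(best_h),
                        trajectory=traj, n_candidates=len(candidates),
                        n_refined=n_ref, seed=seed)
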