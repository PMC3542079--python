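"""Membrane-cytosol compartment model of asymmetric membrane density.

A population of molecules shuttles between a shared cytosolic pool and
one or more membrane regions.  Each cytosolic molecule associates with
the membrane entering state ``j`` at the association frequency ``μ_j``
(1/s per cytosolic molecule, whole-membrane rate for a uniform cell);
once bound it follows the region's multi-state kinetics (transitions
``k_ij``, apparent dissociation rates ``λ'_j``) until it returns to the
cytosol.  Because the ``μ_j`` are proportional to the initial binding
probabilities ``q_j``, the full vector can be recovered from a single
bulk measurement: the steady-state membrane-to-cytosol molecule ratio.

The steady state of the bound occupancy is a linear solve; time courses
(including step or ramp perturbations of the association frequencies)
integrate the mass-conserving compartmental ODEs.  An exact stochastic
(Gillespie) mode on the aggregated counts is provided as an independent
cross-check of the deterministic integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .models import (InfiniteLifetimeError, KineticModel, build_rate_matrix,
                     mean_binding_lifetime)

__all__ = [
    "AssociationRates", "Region", "CompartmentSystem", "Schedule",
    "association_frequencies", "steady_state_occupancy",
    "density_timecourse", "stochastic_timecourse",
]


@dataclass(frozen=True)
class AssociationRates:
    """Per-state membrane association frequencies ``μ_j`` (1/s).

    ``μ_j / Σμ`` equals the initial binding probability ``q_j`` of the
    kinetic model the rates were derived from.
    """

    mu: np.ndarray
    mem_cyt_ratio: float

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if np.any(self.mu < 0):
            raise ValueError("association frequencies must be >= 0")

    @property
    def total(self) -> float:
        return float(self.mu.sum())


def association_frequencies(model: KineticModel, mem_cyt_ratio: float,
                            use_apparent: bool = True) -> AssociationRates:
    """Estimate ``μ_j`` from the bulk membrane/cytosol molecule ratio.

    At steady state ``bound/cytosol = μ_total · τ`` with ``τ`` the mean
    binding lifetime, so ``μ_total = ratio / τ`` and ``μ_j = q_j μ_total``.
    By default the lifetime uses the apparent rates ``λ'`` (the printed
    per-state decay constants); set ``use_apparent=False`` for true rates.
    """
    if mem_cyt_ratio < 0:
        raise ValueError("membrane/cytosol ratio must be >= 0")
    if mem_cyt_ratio == 0:
        return AssociationRates(mu=np.zeros(model.n_states), mem_cyt_ratio=0.0)
    tau = mean_binding_lifetime(model, use_apparent=use_apparent)
    mu_total = mem_cyt_ratio / tau
    return AssociationRates(mu=model.q * mu_total, mem_cyt_ratio=mem_cyt_ratio)


def steady_state_occupancy(rates: AssociationRates, model: KineticModel,
                           cytosol_level: float = 1.0) -> np.ndarray:
    """Per-state bound occupancy solving ``K n = −μ · c``.

    Units follow ``cytosol_level``: with the per-area association flux
    ``μ_j·c`` the result is a per-area density.  Raises when the rate
    matrix is singular (no dissociation path anywhere).
    """
    K = build_rate_matrix(model, include_photobleach=True)
    try:
        n = np.linalg.solve(K, -rates.mu * cytosol_level)
    except np.linalg.LinAlgError as exc:
        raise InfiniteLifetimeError(f"singular rate matrix: {exc}") from exc
    if np.any(n < -1e-9 * max(abs(n).max(), 1.0)):
        raise InfiniteLifetimeError("steady state has negative occupancy")
    return n


@dataclass
class Region:
    """One membrane region with its own kinetics and association rates."""

    name: str
    model: KineticModel
    mu: np.ndarray
    area_fraction: float = 1.0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.size != self.model.n_states:
            raise ValueError("mu must have one entry per state")
        if np.any(self.mu < 0) or not (0 < self.area_fraction <= 1):
            raise ValueError("invalid region parameters")


@dataclass
class Schedule:
    """Piecewise-linear time dependence of a region's association rates.

    ``breakpoints`` maps region name to a list of ``(time, mu_vector)``
    pairs; between breakpoints ``μ`` is interpolated linearly, outside
    them it is held constant.  Regions without an entry keep their
    baseline ``μ``.
    """

    breakpoints: dict = field(default_factory=dict)

    def mu_at(self, region: Region, t: float) -> np.ndarray:
        pts = self.breakpoints.get(region.name)
        if not pts:
            return region.mu
        times = np.array([p[0] for p in pts], dtype=float)
        vals = np.array([np.asarray(p[1], dtype=float) for p in pts])
        if np.any(vals < 0):
            raise ValueError("schedule contains negative association rates")
        if t <= times[0]:
            return vals[0]
        if t >= times[-1]:
            return vals[-1]
        return np.array([np.interp(t, times, vals[:, j])
                         for j in range(vals.shape[1])])


@dataclass
class CompartmentSystem:
    """A spherical cell with membrane regions sharing one cytosolic pool.

    ``n_cytosol`` is the cytosolic molecule count at the reference steady
    state; total molecule number (cytosol + bound) is conserved along any
    trajectory.
    """

    regions: List[Region]
    radius: float = 5.0
    n_cytosol: float = 20000.0

    def __post_init__(self):
        total_area = sum(r.area_fraction for r in self.regions)
        if abs(total_area - 1.0) > 1e-9:
            raise ValueError("region area fractions must sum to 1")

    @property
    def membrane_area(self) -> float:
        """Total membrane area, µm²."""
        return 4.0 * np.pi * self.radius**2

    @property
    def volume(self) -> float:
        """Cytosolic volume, µm³."""
        return 4.0 / 3.0 * np.pi * self.radius**3

    def steady_state_counts(self, cytosol: Optional[float] = None) -> dict:
        """Bound molecule counts per region at fixed cytosolic count."""
        c = self.n_cytosol if cytosol is None else cytosol
        out = {}
        for reg in self.regions:
            rates = AssociationRates(mu=reg.mu * reg.area_fraction,
                                     mem_cyt_ratio=np.nan)
            out[reg.name] = steady_state_occupancy(rates, reg.model, c)
        return out

    def steady_state_density(self, cytosol: Optional[float] = None) -> dict:
        """Bound density per region, molecules/µm²."""
        counts = self.steady_state_counts(cytosol)
        return {name: n.sum() / (self.membrane_area *
                                 self._region(name).area_fraction)
                for name, n in counts.items()}

    def _region(self, name: str) -> Region:
        return next(r for r in self.regions if r.name == name)


def _rhs_factory(system: CompartmentSystem, schedule: Optional[Schedule]):
    Ks = [build_rate_matrix(r.model, include_photobleach=True)
          for r in system.regions]
    lams = [r.model.lam_apparent for r in system.regions]
    sizes = [r.model.n_states for r in system.regions]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def rhs(t, y):
        n_c = y[-1]
        dy = np.empty_like(y)
        d_cyt = 0.0
        for i, reg in enumerate(system.regions):
            n = y[offsets[i]:offsets[i + 1]]
            mu = schedule.mu_at(reg, t) if schedule else reg.mu
            influx = mu * reg.area_fraction * n_c
            dn = Ks[i] @ n + influx
            dy[offsets[i]:offsets[i + 1]] = dn
            d_cyt += float(lams[i] @ n) - influx.sum()
        dy[-1] = d_cyt
        return dy

    return rhs, offsets


def density_timecourse(system: CompartmentSystem, t_grid,
                       schedule: Optional[Schedule] = None,
                       y0: Optional[np.ndarray] = None,
                       rtol: float = 1e-9, atol: float = 1e-9) -> dict:
    """Integrate the compartmental ODEs and report densities over time.

    Starts from the reference steady state (bound counts solved at
    ``n_cytosol``) unless ``y0`` is given.  Returns a dict with per-region
    bound densities (molecules/µm²), the cytosol concentration
    (molecules/µm³), raw counts, and the conserved total.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    rhs, offsets = _rhs_factory(system, schedule)
    if y0 is None:
        counts = system.steady_state_counts()
        y0 = np.concatenate([counts[r.name] for r in system.regions]
                            + [[system.n_cytosol]])
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = {"t": t_grid, "cytosol_count": sol.y[-1],
           "cytosol_concentration": sol.y[-1] / system.volume,
           "total": sol.y.sum(axis=0)}
    for i, reg in enumerate(system.regions):
        n = sol.y[offsets[i]:offsets[i + 1]]
        area = system.membrane_area * reg.area_fraction
        out[f"{reg.name}_counts"] = n
        out[f"{reg.name}_density"] = n.sum(axis=0) / area
    return out


def stochastic_timecourse(system: CompartmentSystem, t_grid, seed: int = 0,
                          y0: Optional[np.ndarray] = None) -> dict:
    """Exact event-driven (Gillespie) simulation on aggregated counts.

    Reaction channels per region: association into each state
    (rate ``μ_j f_r N_cyt``), dissociation from each state
    (``λ'_j n_j``) and each allowed transition (``k_ij n_i``).  Intended
    as a Monte-Carlo cross-check of :func:`density_timecourse` at modest
    molecule numbers.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    sizes = [r.model.n_states for r in system.regions]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    if y0 is None:
        counts = system.steady_state_counts()
        y = np.concatenate([np.round(counts[r.name]) for r in system.regions]
                           + [[system.n_cytosol]])
    else:
        y = np.asarray(y0, dtype=float).copy()

    # enumerate channels: (delta_vector_index pairs, rate function)
    channels = []
    for i, reg in enumerate(system.regions):
        off = offsets[i]
        lam = reg.model.lam_apparent
        for j in range(sizes[i]):
            channels.append(("assoc", i, j, off + j))
            channels.append(("dissoc", i, j, off + j))
        for a in range(sizes[i]):
            for b in range(sizes[i]):
                if a != b and reg.model.k[a, b] > 0:
                    channels.append(("trans", i, (a, b), off))

    out_y = np.empty((t_grid.size, y.size))
    t = t_grid[0]
    gi = 0
    while gi < t_grid.size:
        rates = []
        for ch in channels:
            kind, i, j, off = ch
            reg = system.regions[i]
            if kind == "assoc":
                rates.append(reg.mu[j] * reg.area_fraction * y[-1])
            elif kind == "dissoc":
                rates.append(reg.model.lam_apparent[j] * y[off])
            else:
                a, b = j
                rates.append(reg.model.k[a, b] * y[off + a])
        rates = np.asarray(rates)
        total = rates.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        while gi < t_grid.size and t_grid[gi] < t + dt:
            out_y[gi] = y
            gi += 1
        t += dt
        ci = rng.choice(len(channels), p=rates / total)
        kind, i, j, off = channels[ci]
        if kind == "assoc":
            y[off] += 1
            y[-1] -= 1
        elif kind == "dissoc":
            y[off] -= 1
            y[-1] += 1
        else:
            a, b = j
            y[off + a] -= 1
            y[off + b] += 1
    out_y[gi:] = y
    out = {"t": t_grid, "cytosol_count": out_y[:, -1],
           "total": out_y.sum(axis=1)}
    for i, reg in enumerate(system.regions):
        n = out_y[:, offsets[i]:offsets[i + 1]]
        area = system.membrane_area * reg.area_fraction
        out[f"{reg.name}_counts"] = n.T
        out[f"{reg.name}_density"] = n.sum(axis=1) / area
    return out
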