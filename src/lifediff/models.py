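"""Reaction-diffusion kinetics of membrane-shuttling molecules.

A molecule that binds a membrane can occupy one of ``n`` kinetically
distinct binding states, each with its own lateral diffusion coefficient
``D_j`` (µm²/s) and dissociation rate constant ``λ_j`` (1/s).  While bound
it may hop between states with first-order rates ``k_ij`` (from state *i*
to state *j*).  Fluorophore photobleaching at rate ``λ_b`` removes the
molecule from observation exactly like dissociation, so every observable
decay is governed by the *apparent* rates ``λ'_j = λ_j + λ_b``.

This module evaluates the model exactly:

* the state-space rate matrix ``K`` with ``dQ/dt = K Q``;
* the membrane residence probability ``R(t)`` and the per-state
  subpopulation probabilities ``Q_j(t)`` (so that ``Σ_j Q_j = R``);
* the planar position density ``P_j(x, y, t)`` of a molecule that bound
  at the origin at ``t = 0``, including Gaussian localization error;
* the one-lag displacement density, a mixture of Rayleigh-form
  components with scales ``σ_j² = D_j Δt + ε²``;
* the mean membrane-binding lifetime (first-step analysis).

Survival/subpopulation curves are computed by matrix exponential with a
spectral (eigendecomposition) fast path; the position density is obtained
by a zeroth-order Hankel inversion of the transform-space solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "KineticModel",
    "SpectralDecomposition",
    "PositionPDF",
    "InvalidModelError",
    "NumericalError",
    "InfiniteLifetimeError",
    "build_rate_matrix",
    "spectral_decomposition",
    "residence_probability",
    "subpopulation_probabilities",
    "position_pdf",
    "displacement_pdf",
    "displacement_scale2",
    "mean_binding_lifetime",
    "photobleach_decay",
]


class InvalidModelError(ValueError):
    """Raised when kinetic-model parameters violate their constraints."""


class NumericalError(RuntimeError):
    """Raised when a quadrature or linear-algebra step fails to converge."""


class InfiniteLifetimeError(ValueError):
    """Raised when a mean binding lifetime is requested but no state can exit."""


def _as_rate_table(k, n: int) -> np.ndarray:
    """Normalize transition-rate input to a dense (n, n) array, k[i, j] = i->j."""
    table = np.zeros((n, n), dtype=float)
    if k is None:
        return table
    if isinstance(k, Mapping):
        for (i, j), v in k.items():
            if i == j:
                raise InvalidModelError(f"self-transition k[{i},{j}] is undefined")
            table[i, j] = float(v)
        return table
    arr = np.asarray(k, dtype=float)
    if arr.shape != (n, n):
        raise InvalidModelError(f"transition table must be ({n}, {n}), got {arr.shape}")
    table[:] = arr
    np.fill_diagonal(table, 0.0)
    return table


@dataclass(frozen=True)
class KineticModel:
    """An ``n``-state membrane-binding kinetic model.

    Parameters
    ----------
    D
        Per-state diffusion coefficients, µm²/s.
    lam
        Per-state dissociation rate constants ``λ_j``, 1/s.  When a model is
        specified through apparent rates (``λ'``), store them here and set
        ``lam_b = 0``.
    k
        Transition rates, either a dict ``{(i, j): rate}`` or an (n, n)
        array with ``k[i, j]`` the rate from state ``i`` to state ``j``
        (0-based).  Diagonal entries are ignored.
    q
        Initial binding probabilities (must sum to 1).
    lam_b
        Photobleaching rate constant ``λ_b``, 1/s.
    eps
        Localization-error standard deviation ``ε``, µm.
    name
        Optional label for reports.
    """

    D: np.ndarray
    lam: np.ndarray
    k: np.ndarray = None
    q: np.ndarray = None
    lam_b: float = 0.0
    eps: float = 0.0
    name: str = ""
    note: str = field(default="", compare=False)

    def __post_init__(self):
        D = np.atleast_1d(np.asarray(self.D, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        n = D.size
        if lam.size != n:
            raise InvalidModelError("D and lam must have the same length")
        if self.q is None:
            q = np.full(n, 1.0 / n)
        else:
            q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if q.size != n:
            raise InvalidModelError("q must have one entry per state")
        k = _as_rate_table(self.k, n)
        if np.any(D < 0) or np.any(lam < 0) or np.any(k < 0):
            raise InvalidModelError("rates and diffusion coefficients must be >= 0")
        if self.lam_b < 0 or self.eps < 0:
            raise InvalidModelError("lam_b and eps must be >= 0")
        if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-6:
            raise InvalidModelError("q must be a probability vector summing to 1")
        q = q / q.sum()
        for attr, val in (("D", D), ("lam", lam), ("k", k), ("q", q)):
            object.__setattr__(self, attr, val)
        self.D.setflags(write=False)
        self.lam.setflags(write=False)
        self.k.setflags(write=False)
        self.q.setflags(write=False)

    @property
    def n_states(self) -> int:
        return self.D.size

    @property
    def lam_apparent(self) -> np.ndarray:
        """Apparent dissociation rates ``λ' = λ + λ_b``."""
        return self.lam + self.lam_b

    def with_(self, **changes) -> "KineticModel":
        """Return a copy with the given fields replaced."""
        fields = dict(D=self.D, lam=self.lam, k=self.k, q=self.q,
                      lam_b=self.lam_b, eps=self.eps, name=self.name,
                      note=self.note)
        fields.update(changes)
        return KineticModel(**fields)

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "D": self.D.tolist(),
            "lam": self.lam.tolist(),
            "lam_b": float(self.lam_b),
            "k": self.k.tolist(),
            "q": self.q.tolist(),
            "eps": float(self.eps),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticModel":
        return cls(D=d["D"], lam=d["lam"], k=d.get("k"), q=d.get("q"),
                   lam_b=d.get("lam_b", 0.0), eps=d.get("eps", 0.0),
                   name=d.get("name", ""))


def build_rate_matrix(model: KineticModel, include_photobleach: bool = True) -> np.ndarray:
    """State-space rate matrix ``K`` governing ``dQ/dt = K Q``.

    ``K[j, i] = k_ij`` for ``i != j`` and
    ``K[i, i] = -(λ'_i + Σ_j k_ij)``, so the (negative) column sums equal
    the per-state exit-to-cytosol rates: probability mass leaves the
    system only by dissociation (and photobleaching when included).
    """
    lam = model.lam_apparent if include_photobleach else model.lam
    K = model.k.T.copy()
    np.fill_diagonal(K, -(lam + model.k.sum(axis=1)))
    return K


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition of the rate matrix applied to the initial vector.

    ``Q_j(t) = Σ_m amplitudes[j, m] · exp(eigenvalues[m] · t)``.
    """

    eigenvalues: np.ndarray
    amplitudes: np.ndarray

    def subpopulations(self, t) -> np.ndarray:
        """Q_j(t); shape (n_states,) for scalar t, (len(t), n_states) else."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.real(np.exp(np.outer(t_arr, self.eigenvalues)) @ self.amplitudes.T)
        return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def residence(self, t) -> np.ndarray:
        q = self.subpopulations(t)
        return q.sum(axis=-1)


def spectral_decomposition(model: KineticModel,
                           include_photobleach: bool = True) -> SpectralDecomposition:
    """Diagonalize the rate matrix; raises :class:`NumericalError` if defective."""
    K = build_rate_matrix(model, include_photobleach)
    w, V = np.linalg.eig(K)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e10:
        raise NumericalError(
            f"rate matrix is (nearly) defective, eigenvector condition {cond:.2e}")
    c = np.linalg.solve(V, model.q.astype(complex))
    return SpectralDecomposition(eigenvalues=w, amplitudes=V * c)


def subpopulation_probabilities(model: KineticModel, t,
                                include_photobleach: bool = True) -> np.ndarray:
    """Per-state bound probabilities ``Q_j(t) = [exp(K t) q]_j``.

    Uses a scaling-and-squaring matrix exponential; robust also for
    defective (non-diagonalizable) rate matrices.
    """
    K = build_rate_matrix(model, include_photobleach)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.empty((t_arr.size, model.n_states))
    for i, ti in enumerate(t_arr):
        out[i] = expm(K * ti) @ model.q
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return out[0]
    return out


def residence_probability(model: KineticModel, t,
                          include_photobleach: bool = True):
    """Membrane residence probability ``R(t) = Σ_j Q_j(t)``; ``R(0) = 1``."""
    q = subpopulation_probabilities(model, t, include_photobleach)
    return q.sum(axis=-1)


@dataclass(frozen=True)
class PositionPDF:
    """Radial position density of a molecule that bound at the origin.

    ``per_state[j, i]`` is the planar density (1/µm²) of being bound in
    state ``j`` at radius ``r[i]`` at time ``t``; ``total`` is the sum over
    states.  The planar integral ``2π ∫ total(r) r dr`` equals ``R(t)``.
    """

    r: np.ndarray
    per_state: np.ndarray
    total: np.ndarray
    t: float

    def planar_integral(self) -> float:
        return float(np.trapezoid(2.0 * np.pi * self.r * self.total, self.r))


def position_pdf(model: KineticModel, t: float, r=None,
                 include_photobleach: bool = True,
                 n_quad: int = 256, tol: float = 1e-6) -> PositionPDF:
    """Planar position density ``P_j(r, t)`` including localization error.

    The diffusion equations are solved in transform space, where the
    radially symmetric solution is ``Q̂(κ, t) = exp[(K − κ² diag(D)) t] q``
    damped by the error factor ``exp(−ε² κ²)``, and inverted numerically
    with a zeroth-order Hankel quadrature

        ``P_j(r, t) = (1/2π) ∫₀^∞ Q̂_j(κ, t) e^{−ε²κ²} J₀(κ r) κ dκ``.

    The Gauss-Legendre grid is doubled until successive evaluations agree
    to ``tol``; failure to converge raises :class:`NumericalError`.
    """
    from scipy.special import j0

    if t <= 0:
        raise ValueError("position_pdf requires t > 0")
    sigma2_min = float(model.D.min() * t + model.eps**2)
    if sigma2_min < 1e-12:
        raise NumericalError(
            "degenerate position density: D·t + ε² ≈ 0 (delta mass at origin)")
    if r is None:
        sigma_max = np.sqrt(model.D.max() * t + model.eps**2)
        r = np.linspace(0.0, 8.0 * sigma_max, 321)
    r = np.asarray(r, dtype=float)

    K = build_rate_matrix(model, include_photobleach)
    k_max = np.sqrt(41.0 / sigma2_min)  # integrand ~ exp(-sigma2_min k^2)

    def _evaluate(nq: int) -> np.ndarray:
        nodes, weights = np.polynomial.legendre.leggauss(nq)
        kk = 0.5 * k_max * (nodes + 1.0)
        wk = 0.5 * k_max * weights
        A = K[None, :, :] - kk[:, None, None] ** 2 * np.diag(model.D)[None, :, :]
        w, V = np.linalg.eig(A)
        b = np.broadcast_to(model.q.astype(complex),
                            (kk.size, model.n_states))[..., None]
        c = np.linalg.solve(V, b)[..., 0]
        qhat = np.real(np.einsum("kjm,km->kj", V, np.exp(w * t) * c))
        qhat = qhat * np.exp(-(model.eps**2) * kk[:, None] ** 2)
        bessel = j0(np.outer(kk, r))
        # P_j(r) = (1/2pi) sum_k w_k qhat_j(k) J0(k r) k
        return np.einsum("kj,kr,k->jr", qhat, bessel, wk * kk) / (2.0 * np.pi)

    prev = _evaluate(n_quad)
    nq = n_quad
    while True:
        nq *= 2
        cur = _evaluate(nq)
        err = float(np.max(np.abs(cur - prev)))
        if err < tol:
            break
        if nq >= 4096:
            raise NumericalError(
                f"Hankel quadrature did not converge (error {err:.2e} at {nq} nodes)")
        prev = cur
    per_state = np.clip(cur, 0.0, None)
    return PositionPDF(r=r, per_state=per_state, total=per_state.sum(axis=0), t=float(t))


def displacement_scale2(D, eps: float, dt: float) -> np.ndarray:
    """Mixture scale parameters ``σ_j² = D_j Δt + ε²`` (µm²)."""
    return np.asarray(D, dtype=float) * dt + eps**2


def displacement_pdf(D, p, eps: float, dt: float, dr) -> np.ndarray:
    """One-lag displacement density, a Rayleigh-form mixture.

    ``f(Δr) = Σ_j p_j · Δr / (2σ_j²) · exp(−Δr² / (4σ_j²))`` with
    ``σ_j² = D_j Δt + ε²``; each component has ``E[Δr²] = 4σ_j²`` and the
    mixture integrates to 1.  A component with ``σ_j² = 0`` is a point
    mass at zero and contributes ``inf`` at ``Δr = 0`` only.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if D.size != p.size:
        raise ValueError("D and p must have the same length")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector")
    r = np.asarray(dr, dtype=float)
    if np.any(r < 0):
        raise ValueError("displacements must be >= 0")
    sigma2 = displacement_scale2(D, eps, dt)
    out = np.zeros_like(r, dtype=float)
    for pj, s2 in zip(p, sigma2):
        if s2 <= 0.0:
            out = out + np.where(r == 0.0, np.inf, 0.0) * pj
        else:
            out = out + pj * r / (2.0 * s2) * np.exp(-(r**2) / (4.0 * s2))
    return out


def mean_binding_lifetime(model: KineticModel, use_apparent: bool = True) -> float:
    """Expected membrane-binding duration averaged over the initial states.

    First-step analysis on the rate matrix: the expected per-state
    occupation times ``m`` solve ``K m = −q`` and the lifetime is
    ``Σ_j m_j``, which equals ``∫₀^∞ R(t) dt``.
    """
    lam = model.lam_apparent if use_apparent else model.lam
    if np.all(lam <= 0):
        raise InfiniteLifetimeError("no state has a positive exit rate")
    K = build_rate_matrix(model, include_photobleach=use_apparent)
    try:
        m = np.linalg.solve(K, -model.q)
    except np.linalg.LinAlgError as exc:
        raise InfiniteLifetimeError(f"rate matrix is singular: {exc}") from exc
    tau = float(m.sum())
    if not np.isfinite(tau) or tau <= 0:
        raise InfiniteLifetimeError(f"ill-defined mean lifetime {tau}")
    return tau


def photobleach_decay(n0: float, lam_b: float, t) -> np.ndarray:
    """Expected surviving fluorophore count ``n0 · exp(−λ_b t)``."""
    if n0 < 0 or lam_b < 0:
        raise ValueError("n0 and lam_b must be >= 0")
    return n0 * np.exp(-lam_b * np.asarray(t, dtype=float))
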