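"""Lifetime-diffusion analysis of single-molecule trajectory ensembles.

The pipeline infers multi-state membrane-binding kinetics from tracks in
four steps:

1. *Dissociation test* — the empirical survival (dissociation) curve of
   binding durations is compared with the photobleaching rate; a decay
   faster than ``λ_b`` indicates genuine membrane dissociation.
2. *State counting* — one-frame displacements are fitted with a mixture
   of Rayleigh-form components (scales ``σ_j² = D_j Δt + ε²``) by maximum
   likelihood for each candidate state number; the Akaike Information
   Criterion selects the minimal adequate number of states.
3. *Transition test* — displacements are re-fitted in sliding time
   windows with the diffusion coefficients frozen, yielding time-resolved
   state fractions ``p_j(t)``.  Multiplying by the survival curve gives
   decay profiles ``Q_obs,j(t) = R_obs(t) p_j(t)``.  State transitions
   mix the subpopulations, so all profiles eventually decay at the same
   (slowest-eigenvalue) rate; without transitions each profile is
   mono-exponential at its own rate.
4. *Kinetic fit* — the decay profiles are fitted simultaneously with the
   model subpopulation probabilities ``Q_j(t)`` to estimate apparent
   dissociation rates ``λ'_j``, transition rates ``k_ij`` and initial
   probabilities ``q_j``; true rates follow as ``λ_j = λ'_j − λ_b``.

A position-density consistency check and the displacement
autocorrelation (an independent signature of mobility switching) round
out the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .models import (KineticModel, NumericalError, build_rate_matrix,
                     displacement_pdf, displacement_scale2, position_pdf,
                     subpopulation_probabilities)
from .simulate import TrajectoryEnsemble

__all__ = [
    "DissociationCurve", "MSDCurve", "MixtureFit", "DecayProfiles",
    "TransitionTest", "KineticFitResult", "AutocorrFit", "AnalysisReport",
    "dissociation_curve", "estimate_epsilon", "fit_displacement_mixture",
    "select_state_number", "windowed_fractions", "detect_transitions",
    "fit_state_kinetics", "consistency_check", "displacement_autocorrelation",
    "run_full_analysis",
]


# ---------------------------------------------------------------------------
# step 1: dissociation curve


@dataclass
class DissociationCurve:
    """Kaplan-Meier estimate of the membrane residence probability.

    ``survival[m]`` estimates ``R(times[m]) = P(duration ≥ times[m])`` on
    the frame grid.  Tracks still bound at the observation horizon enter
    as right-censored.
    """

    times: np.ndarray
    survival: np.ndarray
    n_tracks: int
    frame_dt: float
    _km_times: np.ndarray = field(repr=False, default=None)
    _km_surv: np.ndarray = field(repr=False, default=None)

    def at(self, t) -> np.ndarray:
        """``P(duration ≥ t)`` (left-continuous evaluation of the KM step)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._km_times, t - 1e-9, side="left") - 1
        out = np.where(idx < 0, 1.0, self._km_surv[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def decay_rate(self) -> Tuple[float, float]:
        """Effective decay rate from a log-linear fit; returns (rate, SE)."""
        mask = (self.survival > 0.01) & (self.times >= 0)
        t, s = self.times[mask], self.survival[mask]
        if t.size < 3:
            raise ValueError("too few survival points for a rate fit")
        res = stats.linregress(t, np.log(s))
        return -res.slope, res.stderr


def dissociation_curve(ensemble: TrajectoryEnsemble,
                       include_single_frame: bool = True) -> DissociationCurve:
    """Empirical survival of binding durations, right-censored at the horizon.

    A track observed on ``m+1`` frames has duration ``m·Δt`` (first to
    last frame); the fraction of tracks with duration ≥ ``m·Δt`` estimates
    ``R(m·Δt)``.
    """
    from lifelines import KaplanMeierFitter

    durations = ensemble.durations()
    events = ~ensemble.censored()
    if not include_single_frame:
        keep = durations > 0
        durations, events = durations[keep], events[keep]
    if durations.size == 0 or not events.any():
        raise ValueError("no uncensored tracks: survival curve undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    km_times = kmf.survival_function_.index.to_numpy(dtype=float)
    km_surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    grid = np.arange(0, int(round(durations.max() / ensemble.frame_dt)) + 1)
    times = grid * ensemble.frame_dt
    curve = DissociationCurve(times=times, survival=None,
                              n_tracks=int(durations.size),
                              frame_dt=ensemble.frame_dt,
                              _km_times=km_times, _km_surv=km_surv)
    curve.survival = curve.at(times)
    return curve


# ---------------------------------------------------------------------------
# localization error from MSD


@dataclass
class MSDCurve:
    """Ensemble MSD at the first lags with the short-lag linear fit.

    ``MSD(Δt) = 4 D* Δt + 4 ε²``: the intercept measures the localization
    error, the slope the (occupancy-averaged) diffusion coefficient.
    """

    lags: np.ndarray
    msd: np.ndarray
    D_star: float
    eps: float


def estimate_epsilon(ensemble: TrajectoryEnsemble, n_lags: int = 2) -> MSDCurve:
    """Estimate the localization error ε from the MSD intercept.

    Fits ``MSD(Δt) = 4 D* Δt + 4 ε²`` through the MSD at lags
    ``Δt .. n_lags·Δt`` (default: the first two lags).  A negative
    intercept is clipped to ``ε = 0`` with a warning.
    """
    lags = np.arange(1, n_lags + 1)
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        sq = [tr.displacements(lag) ** 2 for tr in ensemble
              if tr.n_frames > lag]
        if not sq:
            raise ValueError(f"no track long enough for lag {lag}")
        msd[i] = np.concatenate(sq).mean()
    t = lags * ensemble.frame_dt
    slope, intercept = np.polyfit(t, msd, 1)
    if intercept < 0:
        warnings.warn("negative MSD intercept; clipping ε to 0")
        intercept = 0.0
    return MSDCurve(lags=t, msd=msd, D_star=slope / 4.0,
                    eps=float(np.sqrt(intercept / 4.0)))


# ---------------------------------------------------------------------------
# step 2: mixture MLE and AIC state counting


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of a Rayleigh-form displacement mixture.

    ``aic = -2 logL + 2 (2N - 1)``: N diffusion coefficients plus N−1 free
    fractions; ε is measured beforehand and frozen, so it does not count.
    Components are sorted by ascending D.
    """

    n_states: int
    D: np.ndarray
    p: np.ndarray
    eps: float
    dt: float
    log_likelihood: float
    aic: float
    converged: bool
    n_iter: int
    n_samples: int
    D_ci: Optional[np.ndarray] = None

    def pdf(self, r):
        return displacement_pdf(self.D, self.p, self.eps, self.dt, r)


def _mixture_loglik(r2: np.ndarray, sigma2: np.ndarray, p: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> float:
    comp = np.log(np.sqrt(r2))[:, None] - np.log(2.0 * sigma2)[None, :] \
        - r2[:, None] / (4.0 * sigma2)[None, :]
    m = comp.max(axis=1)
    ll_i = m + np.log(np.exp(comp - m[:, None]) @ p)
    return float(ll_i.sum() if weights is None else weights @ ll_i)


def _em_mixture(r2: np.ndarray, weights: np.ndarray, sigma2_init: np.ndarray,
                p_init: np.ndarray, eps2: float,
                max_iter: int = 5000, tol: float = 1e-9):
    """Weighted EM for the Rayleigh-scale mixture; scales constrained to σ² ≥ ε²."""
    sigma2 = sigma2_init.copy()
    p = p_init.copy()
    n_eff = weights.sum()
    log_r = 0.5 * np.log(r2)
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logc = -np.log(2.0 * sigma2)[None, :] - r2[:, None] / (4.0 * sigma2)[None, :]
        logc = logc + np.log(np.maximum(p, 1e-300))[None, :]
        m = logc.max(axis=1, keepdims=True)
        w = np.exp(logc - m)
        den = w.sum(axis=1, keepdims=True)
        gamma = w / den
        ll = float(weights @ (log_r + m[:, 0] + np.log(den[:, 0])))
        gw = gamma * weights[:, None]
        gsum = gw.sum(axis=0)
        p = gsum / n_eff
        sigma2 = np.maximum((gw * r2[:, None]).sum(axis=0) / (4.0 * gsum), eps2)
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    ll = _mixture_loglik(r2, sigma2, p, weights)
    return sigma2, p, ll, converged, it


def _wald_ci_D(r: np.ndarray, sigma2: np.ndarray, p: np.ndarray,
               eps2: float, dt: float) -> np.ndarray:
    """95% Wald intervals for D from the observed information matrix.

    Non-identifiable fits (e.g. two components with equal D) have a
    singular information matrix and report infinite-width intervals.
    """
    n = sigma2.size
    r2 = r**2
    theta0 = np.concatenate([sigma2, p[:-1]])

    def nll(theta):
        s2 = theta[:n]
        pf = np.concatenate([theta[n:], [1.0 - theta[n:].sum()]])
        if np.any(s2 <= 0) or np.any(pf < 0):
            return np.inf
        return -_mixture_loglik(r2, s2, pf)

    h = 1e-5 * np.maximum(np.abs(theta0), 1e-3)
    dim = theta0.size
    H = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            ei = np.eye(dim)[i] * h[i]
            ej = np.eye(dim)[j] * h[j]
            H[i, j] = H[j, i] = (
                nll(theta0 + ei + ej) - nll(theta0 + ei - ej)
                - nll(theta0 - ei + ej) + nll(theta0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:n]
        if np.any(var <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se_D = np.sqrt(var) / dt
    except np.linalg.LinAlgError:
        se_D = np.full(n, np.inf)
    D = np.maximum(sigma2 - eps2, 0.0) / dt
    return np.column_stack([D - 1.96 * se_D, D + 1.96 * se_D])


def fit_displacement_mixture(displacements, n_states: int, eps: float,
                             dt: float, D_init=None, n_restarts: int = 10,
                             compute_ci: bool = False,
                             bin_threshold: int = 3000,
                             n_bins: int = 4000) -> MixtureFit:
    """MLE of an ``n_states`` Rayleigh-form mixture with ε fixed.

    Initialization is deterministic: component scales start at the
    k-quantiles of ``Δr²/4`` plus a fixed set of multiplicative
    perturbation restarts; the best likelihood wins and components are
    returned sorted by ascending D.

    Samples larger than ``bin_threshold`` are histogrammed onto
    ``n_bins`` equal-width bins and fitted by weighted EM on the bin
    centers; at the default resolution the quantization is far below the
    statistical error and the AIC comparison is unaffected.
    """
    r = np.asarray(displacements, dtype=float)
    r = r[r > 0]
    if r.size == 0:
        raise ValueError("no positive displacements to fit")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    eps2 = eps**2
    n_total = r.size
    if r.size > bin_threshold:
        counts, edges = np.histogram(r, bins=n_bins)
        keep = counts > 0
        r_fit = (0.5 * (edges[:-1] + edges[1:]))[keep]
        weights = counts[keep].astype(float)
    else:
        r_fit = r
        weights = np.ones(r.size)
    r2_fit = r_fit**2
    quant = np.quantile(r**2 / 4.0, (np.arange(n_states) + 0.5) / n_states)
    if D_init is not None:
        sigma2_base = displacement_scale2(np.asarray(D_init, float), eps, dt)
    else:
        sigma2_base = np.maximum(quant, eps2 * (1.0 + 1e-6) + 1e-9)
    p0 = np.full(n_states, 1.0 / n_states)

    rng = np.random.default_rng(12345)  # fixed policy: restarts are part of the estimator
    inits = [sigma2_base]
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(np.maximum(sigma2_base * rng.lognormal(0.0, 0.6, n_states),
                                eps2 * (1.0 + 1e-6) + 1e-9))
    best = None
    for s2_init in inits:
        sigma2, p, ll, conv, it = _em_mixture(r2_fit, weights, np.sort(s2_init),
                                              p0, eps2)
        if best is None or ll > best[2]:
            best = (sigma2, p, ll, conv, it)
    sigma2, p, ll, conv, it = best
    order = np.argsort(sigma2)
    sigma2, p = sigma2[order], p[order]
    D = np.maximum((sigma2 - eps2) / dt, 0.0)
    aic = -2.0 * ll + 2.0 * (2 * n_states - 1)
    ci = _wald_ci_D(r, sigma2, p, eps2, dt) if compute_ci else None
    return MixtureFit(n_states=n_states, D=D, p=p, eps=eps, dt=dt,
                      log_likelihood=ll, aic=aic, converged=conv, n_iter=it,
                      n_samples=n_total, D_ci=ci)


def select_state_number(displacements, eps: float, dt: float,
                        n_max: int = 4, **kw) -> Tuple[List[MixtureFit], int]:
    """Fit mixtures for N = 1..n_max and pick the AIC-minimizing state count.

    Returns ``(fits, chosen_n)``; non-converged candidates are kept in the
    table but excluded from the argmin.
    """
    fits = [fit_displacement_mixture(displacements, n, eps, dt, **kw)
            for n in range(1, n_max + 1)]
    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no mixture fit converged")
    chosen = min(usable, key=lambda f: f.aic).n_states
    return fits, chosen


# ---------------------------------------------------------------------------
# step 3: decay profiles


@dataclass
class DecayProfiles:
    """Time-resolved subpopulation fractions and decay profiles.

    For each window ``[t, t+τ)`` the state fractions ``p_j(t)`` are
    re-estimated with the diffusion coefficients frozen; the decay
    profiles are ``Q_obs,j(t) = R_obs(t) · p_j(t)`` and sum to the
    dissociation curve by construction.
    """

    t: np.ndarray
    tau: float
    p_t: np.ndarray
    R_obs: np.ndarray
    Q_obs: np.ndarray
    counts: np.ndarray
    D: np.ndarray
    eps: float
    frame_dt: float
    n_tracks: int
    se_p: np.ndarray = None

    @property
    def n_states(self) -> int:
        return self.D.size

    def se_Q(self) -> np.ndarray:
        """Standard error of the decay profiles.

        Combines the Fisher-information error of the window fractions
        with the binomial error of the survival estimate:
        ``Var(Q) = R² Var(p̂) + p² Var(R̂)``.
        """
        var_R = np.clip(self.R_obs * (1.0 - self.R_obs), 0.0, None) / self.n_tracks
        var = (self.R_obs[:, None] ** 2 * self.se_p**2
               + self.p_t**2 * var_R[:, None])
        return np.sqrt(np.clip(var, 1e-12, None))


def _em_fractions(r2: np.ndarray, sigma2: np.ndarray, p0: np.ndarray,
                  max_iter: int = 500, tol: float = 1e-10):
    """EM over the mixing fractions only (scales frozen).

    Returns ``(p̂, se_p)`` with the standard error from the observed
    Fisher information of the fraction-only likelihood (the last
    component eliminated by the simplex constraint); the overlap of the
    mixture components is what limits the attainable precision.
    """
    logf = -np.log(2.0 * sigma2)[None, :] - r2[:, None] / (4.0 * sigma2)[None, :]
    f = np.exp(logf - logf.max(axis=1, keepdims=True))
    p = p0.copy()
    for _ in range(max_iter):
        w = f * p
        gamma = w / w.sum(axis=1, keepdims=True)
        p_new = gamma.mean(axis=0)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    mix = np.clip(f @ p, 1e-300, None)
    n_comp = p.size
    diff = f[:, : n_comp - 1] - f[:, -1:]
    info = np.einsum("ia,ib->ab", diff / mix[:, None], diff / mix[:, None])
    se = np.empty(n_comp)
    try:
        cov = np.linalg.inv(info)
        var_free = np.clip(np.diag(cov), 0.0, None)
        se[: n_comp - 1] = np.sqrt(var_free)
        ones = np.ones(n_comp - 1)
        se[-1] = np.sqrt(max(ones @ cov @ ones, 0.0))
    except np.linalg.LinAlgError:
        se[:] = np.inf
    return p, se


def windowed_fractions(ensemble: TrajectoryEnsemble, D_fixed, eps: float,
                       tau: Optional[float] = None,
                       bin_spacing: Optional[float] = None,
                       min_count: int = 50,
                       include_single_frame: bool = True) -> DecayProfiles:
    """Estimate ``p_j(t)`` in sliding windows and build the decay profiles.

    ``D_fixed`` comes from the global mixture fit; windows of width
    ``τ`` (default one frame interval, so each window sees a single
    displacement lag and no within-window kinetic averaging) advance by
    ``bin_spacing`` (default one frame interval).  Windows with fewer
    than ``min_count`` displacements are dropped with a warning.
    """
    D_fixed = np.atleast_1d(np.asarray(D_fixed, dtype=float))
    dt = ensemble.frame_dt
    tau = dt if tau is None else tau
    if tau < dt:
        raise ValueError("window tau must be at least one frame interval")
    bin_spacing = dt if bin_spacing is None else bin_spacing
    sigma2 = displacement_scale2(D_fixed, eps, dt)

    r, t_start = ensemble.displacements(lag=1, with_times=True)
    keep = r > 0
    r, t_start = r[keep], t_start[keep]
    if r.size == 0:
        raise ValueError("ensemble has no displacements")
    curve = dissociation_curve(ensemble, include_single_frame=include_single_frame)

    t_bins, p_rows, se_rows, counts = [], [], [], []
    n_dropped = 0
    t_max = t_start.max()
    p_prev = np.full(D_fixed.size, 1.0 / D_fixed.size)
    for i in range(int(np.floor(t_max / bin_spacing + 1e-9)) + 1):
        t0 = i * bin_spacing
        sel = (t_start >= t0 - 1e-9) & (t_start < t0 + tau - 1e-9)
        n = int(sel.sum())
        if n >= min_count:
            p_hat, se_hat = _em_fractions(r[sel] ** 2, sigma2, p_prev)
            p_prev = p_hat
            t_bins.append(t0)
            p_rows.append(p_hat)
            se_rows.append(se_hat)
            counts.append(n)
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} windows with fewer than "
                      f"{min_count} displacements")
    if not t_bins:
        raise ValueError("no window reached the minimum displacement count")
    t_arr = np.array(t_bins)
    p_t = np.vstack(p_rows)
    R = np.asarray(curve.at(t_arr))
    return DecayProfiles(t=t_arr, tau=tau, p_t=p_t, R_obs=R,
                         Q_obs=R[:, None] * p_t, counts=np.array(counts),
                         D=D_fixed, eps=eps, frame_dt=dt,
                         n_tracks=ensemble.n_tracks, se_p=np.vstack(se_rows))


# ---------------------------------------------------------------------------
# transition test


@dataclass
class TransitionTest:
    """Outcome of the state-transition test on decay profiles.

    ``present`` is True when the decay profiles start at significantly
    different log-slopes but converge to a common late-time slope (the
    signature of mixing into the slowest eigenmode), False when each
    profile decays mono-exponentially at its own rate, and None when
    there is not enough informative data to decide.  ``t_late`` reports
    the onset of the late-time region actually used.
    """

    present: Optional[bool]
    late_slopes: np.ndarray
    late_se: np.ndarray
    early_slopes: np.ndarray
    early_se: np.ndarray
    t_late: float


def _wls_slope(t: np.ndarray, y: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    W = w.sum()
    tb = (w * t).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (t - tb) ** 2).sum()
    if sxx <= 0:
        return np.nan, np.nan
    slope = (w * (t - tb) * (y - yb)).sum() / sxx
    resid = y - yb - slope * (t - tb)
    dof = max(t.size - 2, 1)
    s2 = (w * resid**2).sum() / dof
    return float(slope), float(np.sqrt(s2 / sxx))


def _slopes(t: np.ndarray, Q: np.ndarray,
            w: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Per-state log-slopes of the decay profiles, optionally weighted."""
    slopes = np.full(Q.shape[1], np.nan)
    ses = np.full(Q.shape[1], np.nan)
    for j in range(Q.shape[1]):
        mask = Q[:, j] > 0
        if mask.sum() >= 3:
            wj = np.ones(mask.sum()) if w is None else w[mask, j]
            slopes[j], ses[j] = _wls_slope(t[mask], np.log(Q[mask, j]), wj)
    return slopes, ses


def detect_transitions(profiles: DecayProfiles, t_late="auto",
                       t_early: float = 0.3,
                       rel_se_max: float = 0.5) -> TransitionTest:
    """Test for state transitions from late-time slope convergence.

    Log-slopes are fitted by weighted least squares with the binomial
    counting error of each profile point; bins whose relative error
    exceeds ``rel_se_max`` for any state carry no usable slope
    information and are excluded.  With ``t_late="auto"`` the onset of
    the common-slope region is detected by scanning candidate onsets and
    taking the earliest one past which all late slopes agree within
    their joint 95% intervals.
    """
    if profiles.n_states < 2:
        raise ValueError("transition test requires at least two states")
    n = profiles.n_states
    nan = np.full(n, np.nan)
    Q = profiles.Q_obs
    se = profiles.se_Q()
    valid = (Q > 0) & (se < rel_se_max * np.clip(Q, 1e-12, None))
    w = np.where(valid, (Q / se) ** 2, 0.0)  # delta-method weights for log Q

    def slopes_on(mask_t):
        slopes, ses = np.full(n, np.nan), np.full(n, np.nan)
        for j in range(n):
            mj = mask_t & valid[:, j]
            if mj.sum() >= 3:
                slopes[j], ses[j] = _wls_slope(profiles.t[mj],
                                               np.log(Q[mj, j]), w[mj, j])
        return slopes, ses

    es, ese = slopes_on(profiles.t < t_early)
    if np.any(~np.isfinite(es)):
        return TransitionTest(None, nan, nan, es, ese, np.nan)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    differ_early = any(abs(es[i] - es[j]) > 1.96 * np.hypot(ese[i], ese[j])
                       for i, j in pairs)

    if t_late == "auto":
        t_max = profiles.t[valid.any(axis=1)].max()
        candidates = [c for c in (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0) if c < t_max]
    else:
        candidates = [float(t_late)]
    ls = lse = nan
    converged = False
    t_used = np.nan
    for cand in candidates:
        mask_t = profiles.t >= cand
        # states with enough late data to carry a slope; sparse states
        # (e.g. a rare fast-dissociating state) cannot be tested
        late_states = [j for j in range(n) if (mask_t & valid[:, j]).sum() >= 4]
        if len(late_states) < 2:
            continue
        ls, lse = slopes_on(mask_t)
        t_used = cand
        if all(abs(ls[i] - ls[j]) <= 1.96 * np.hypot(lse[i], lse[j])
               for i in late_states for j in late_states if i < j):
            converged = True
            break
    if not np.isfinite(t_used):
        return TransitionTest(None, ls, lse, es, ese, t_used)
    # transitions bend at least one profile: its early and late slopes differ
    bent = any(abs(es[j] - ls[j]) > 1.96 * np.hypot(ese[j], lse[j])
               for j in range(n) if np.isfinite(ls[j]))
    return TransitionTest(present=bool(differ_early and converged and bent),
                          late_slopes=ls, late_se=lse,
                          early_slopes=es, early_se=ese, t_late=t_used)


# ---------------------------------------------------------------------------
# step 4: kinetic fit


@dataclass
class KineticFitResult:
    """Kinetic parameters estimated from the decay profiles.

    ``lam`` holds the photobleaching-corrected rates ``λ = λ' − λ_b``;
    entries whose apparent rate does not exceed ``λ_b`` are flagged in
    ``not_determined`` (dissociation too rare to resolve against
    bleaching).
    """

    lam_apparent: np.ndarray
    lam: np.ndarray
    k: np.ndarray
    q: np.ndarray
    lam_b: float
    not_determined: np.ndarray
    residual_norm: float
    success: bool
    message: str = ""

    def to_model(self, D, eps: float = 0.0) -> KineticModel:
        """Kinetic model with the *apparent* rates (λ_b folded in)."""
        return KineticModel(D=D, lam=self.lam_apparent, k=self.k, q=self.q,
                            lam_b=0.0, eps=eps)


def _topology_edges(n: int, topology) -> List[Tuple[int, int]]:
    if isinstance(topology, str):
        if topology == "chain":
            edges = []
            for i in range(n - 1):
                edges += [(i, i + 1), (i + 1, i)]
            return edges
        if topology == "full":
            return [(i, j) for i in range(n) for j in range(n) if i != j]
        if topology == "none":
            return []
        raise ValueError(f"unknown topology {topology!r}")
    return [tuple(e) for e in topology]


def _stick_to_q(v: np.ndarray) -> np.ndarray:
    q = np.empty(v.size + 1)
    rest = 1.0
    for i, vi in enumerate(v):
        q[i] = rest * vi
        rest *= (1.0 - vi)
    q[-1] = rest
    return q


def _q_to_stick(q: np.ndarray) -> np.ndarray:
    v = np.empty(q.size - 1)
    rest = 1.0
    for i in range(q.size - 1):
        v[i] = np.clip(q[i] / rest if rest > 1e-12 else 0.0, 1e-6, 1 - 1e-6)
        rest -= q[i]
    return v


def _q_curve(K: np.ndarray, q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Q_j at many times via eigendecomposition (expm fallback)."""
    w, V = np.linalg.eig(K)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < 1e10:
        c = np.linalg.solve(V, q.astype(complex))
        return np.real(np.exp(np.outer(t, w)) @ (V * c).T)
    from scipy.linalg import expm
    return np.vstack([expm(K * ti) @ q for ti in t])


def fit_state_kinetics(profiles: DecayProfiles, topology="chain",
                       lam_b: float = 0.0,
                       x0: Optional[dict] = None) -> KineticFitResult:
    """Weighted least-squares fit of the decay profiles to ``Q_j(t)``.

    All profiles are fitted simultaneously with parameters
    (apparent rates ``λ'``, transition rates on the allowed topology,
    initial probabilities ``q``).  Per-bin weights follow the binomial
    counting error of ``Q_obs``; the fit is performed in linear space.
    """
    n = profiles.n_states
    edges = _topology_edges(n, topology)
    t = profiles.t
    Q_obs = profiles.Q_obs
    se = profiles.se_Q()

    # crude per-state rate guesses from whole-range log-slopes
    slopes, _ = _slopes(t, np.clip(Q_obs, 1e-12, None))
    lam0 = np.clip(-slopes, 0.02, None)
    lam0[~np.isfinite(lam0)] = 1.0
    k0 = np.full(len(edges), 0.25 * lam0.mean())
    v0 = _q_to_stick(np.clip(profiles.p_t[0], 1e-3, None)
                     / np.clip(profiles.p_t[0], 1e-3, None).sum())
    if x0 is not None:
        lam0 = np.asarray(x0.get("lam_apparent", lam0), dtype=float)
        if "k" in x0:
            kmat = np.asarray(x0["k"], dtype=float)
            k0 = np.array([kmat[i, j] for i, j in edges])
        if "q" in x0:
            v0 = _q_to_stick(np.asarray(x0["q"], dtype=float))

    def unpack(theta):
        lam_ap = theta[:n]
        kvals = theta[n:n + len(edges)]
        v = theta[n + len(edges):]
        kmat = np.zeros((n, n))
        for (i, j), val in zip(edges, kvals):
            kmat[i, j] = val
        return lam_ap, kmat, _stick_to_q(v)

    def residuals(theta):
        lam_ap, kmat, q = unpack(theta)
        K = kmat.T - np.diag(lam_ap + kmat.sum(axis=1))
        Q = _q_curve(K, q, t)
        return ((Q - Q_obs) / se).ravel()

    theta0 = np.concatenate([lam0, k0, v0])
    lb = np.concatenate([np.zeros(n + len(edges)), np.full(n - 1, 1e-9)])
    ub = np.concatenate([np.full(n + len(edges), np.inf),
                         np.full(n - 1, 1.0 - 1e-9)])
    res = optimize.least_squares(residuals, theta0, bounds=(lb, ub),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    lam_ap, kmat, q = unpack(res.x)
    not_det = lam_ap <= lam_b
    return KineticFitResult(lam_apparent=lam_ap, lam=lam_ap - lam_b, k=kmat,
                            q=q, lam_b=lam_b, not_determined=not_det,
                            residual_norm=float(np.linalg.norm(res.fun)),
                            success=bool(res.success), message=res.message)


# ---------------------------------------------------------------------------
# consistency check and autocorrelation


def consistency_check(ensemble: TrajectoryEnsemble, model: KineticModel,
                      times: Sequence[float], n_bins: int = 15) -> List[dict]:
    """Compare radial position histograms with the model position density.

    For each requested time since binding onset, the radial distances of
    still-bound molecules from their first observed position are binned
    and tested (χ²) against the conditional density
    ``2π r P(r, t) / R(t)``.
    """
    records = []
    for t in times:
        m = int(round(t / ensemble.frame_dt))
        rs = [np.hypot(*(tr.xy[m] - tr.xy[0])) for tr in ensemble
              if tr.n_frames > m]
        r_obs = np.asarray(rs)
        rec = {"t": float(t), "n": int(r_obs.size)}
        if r_obs.size < 5 * n_bins:
            rec.update(chi2=np.nan, p_value=np.nan, dof=0,
                       note="too few molecules")
            records.append(rec)
            continue
        edges = np.linspace(0.0, r_obs.max() * 1.001, n_bins + 1)
        obs, _ = np.histogram(r_obs, bins=edges)
        grid = np.linspace(0.0, edges[-1], 400)
        pdf = position_pdf(model, t, grid)
        dens = 2.0 * np.pi * grid * pdf.total
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cdf_at = np.interp(edges, grid, cdf)
        probs = np.diff(cdf_at)
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        exp = probs * r_obs.size
        # merge sparse tail bins so every expected count is >= 5
        while exp.size > 2 and exp[-1] < 5:
            exp = np.concatenate([exp[:-2], [exp[-2] + exp[-1]]])
            obs = np.concatenate([obs[:-2], [obs[-2] + obs[-1]]])
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        dof = exp.size - 1
        rec.update(chi2=chi2, p_value=float(stats.chi2.sf(chi2, dof)), dof=dof)
        records.append(rec)
    return records


@dataclass
class AutocorrFit:
    """Displacement-series autocorrelation with exponential fit.

    Mobility switching makes successive displacement magnitudes
    correlated; the normalized autocorrelation decays as
    ``y = a exp(−K t) + b`` with ``K`` the relaxation rate of the
    switching chain.
    """

    lags: np.ndarray
    acf: np.ndarray
    a: float
    b: float
    K: float
    n_tracks: int


def displacement_autocorrelation(ensemble: TrajectoryEnsemble,
                                 max_lag: int = 20) -> AutocorrFit:
    """Averaged displacement autocorrelation with ``a·exp(−K t)+b`` fit.

    Tracks shorter than ``max_lag + 2`` frames are excluded.  Lag 0 (the
    normalization point, dominated by within-state noise) is excluded
    from the fit.
    """
    num = np.zeros(max_lag + 1)
    wsum = np.zeros(max_lag + 1)
    n_used = 0
    for tr in ensemble:
        d = tr.displacements(1)
        if d.size < max_lag + 1:
            continue
        n_used += 1
        dc = d - d.mean()
        var = np.mean(dc**2)
        if var <= 0:
            continue
        for lag in range(max_lag + 1):
            c = np.mean(dc[: d.size - lag] * dc[lag:]) / var
            w = d.size - lag
            num[lag] += w * c
            wsum[lag] += w
    if n_used == 0:
        raise ValueError(f"no track has at least {max_lag + 2} frames")
    acf = num / wsum
    lags = np.arange(max_lag + 1) * ensemble.frame_dt

    def f(t, a, K, b):
        return a * np.exp(-K * t) + b

    p0 = (max(acf[1], 0.05), 1.0, 0.0)
    popt, _ = optimize.curve_fit(f, lags[1:], acf[1:], p0=p0, maxfev=10000)
    return AutocorrFit(lags=lags, acf=acf, a=float(popt[0]), b=float(popt[2]),
                       K=float(popt[1]), n_tracks=n_used)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisReport:
    """Machine-readable result bundle of the full four-step pipeline."""

    n_tracks: int
    frame_dt: float
    eps: float
    eps_estimated: bool
    dissociation_rate: float
    dissociation_rate_se: float
    lam_b: float
    membrane_dissociation: bool
    mixture_fits: List[MixtureFit]
    chosen_n: int
    profiles: DecayProfiles
    transition_test: TransitionTest
    kinetic_fit: KineticFitResult
    consistency: List[dict]

    @property
    def model(self) -> KineticModel:
        fit = next(f for f in self.mixture_fits if f.n_states == self.chosen_n)
        return self.kinetic_fit.to_model(fit.D, eps=self.eps)

    def to_dict(self) -> dict:
        fit = self.kinetic_fit
        return {
            "schema_version": 1,
            "n_tracks": self.n_tracks,
            "frame_dt_s": self.frame_dt,
            "eps_um": self.eps,
            "eps_estimated": self.eps_estimated,
            "dissociation": {
                "rate_per_s": self.dissociation_rate,
                "rate_se": self.dissociation_rate_se,
                "lam_b_per_s": self.lam_b,
                "membrane_dissociation": self.membrane_dissociation,
            },
            "state_number": {
                "chosen_n": self.chosen_n,
                "candidates": [
                    {"n_states": f.n_states, "D_um2_s": f.D.tolist(),
                     "p": f.p.tolist(), "log_likelihood": f.log_likelihood,
                     "aic": f.aic, "converged": f.converged,
                     "ci_method": "wald" if f.D_ci is not None else None,
                     "D_ci": None if f.D_ci is None else f.D_ci.tolist()}
                    for f in self.mixture_fits
                ],
            },
            "transition_test": {
                "present": self.transition_test.present,
                "late_slopes": self.transition_test.late_slopes.tolist(),
                "late_se": self.transition_test.late_se.tolist(),
                "early_slopes": self.transition_test.early_slopes.tolist(),
                "t_late_s": self.transition_test.t_late,
            },
            "kinetics": {
                "lam_apparent_per_s": fit.lam_apparent.tolist(),
                "lam_per_s": [None if nd else float(l)
                              for l, nd in zip(fit.lam, fit.not_determined)],
                "not_determined": fit.not_determined.tolist(),
                "k_per_s": fit.k.tolist(),
                "q": fit.q.tolist(),
                "residual_norm": fit.residual_norm,
                "success": fit.success,
            },
            "consistency_chi2": self.consistency,
        }


def run_full_analysis(ensemble: TrajectoryEnsemble, config=None,
                      **overrides) -> AnalysisReport:
    """Execute the four analysis steps on a trajectory ensemble.

    ``config`` is an :class:`lifediff.config.AnalysisConfig`; keyword
    overrides take precedence over its fields.
    """
    from .config import AnalysisConfig

    if ensemble.n_tracks == 0:
        raise ValueError("empty ensemble")
    cfg = config or AnalysisConfig()
    if overrides:
        cfg = cfg.replace(**overrides)
    dt = ensemble.frame_dt

    # step 1: dissociation test
    curve = dissociation_curve(ensemble, cfg.include_single_frame)
    rate, rate_se = curve.decay_rate()
    membrane_diss = (rate - 1.96 * rate_se) > cfg.lam_b

    # localization error
    if cfg.eps is None:
        msd = estimate_epsilon(ensemble)
        eps, eps_est = msd.eps, True
    else:
        eps, eps_est = float(cfg.eps), False

    # step 2: state number by AIC
    r = ensemble.displacements(lag=1)
    fits, chosen_n = select_state_number(r, eps, dt, n_max=cfg.n_max,
                                         compute_ci=cfg.compute_ci)
    best = next(f for f in fits if f.n_states == chosen_n)

    # step 3: decay profiles and transition test
    profiles = windowed_fractions(ensemble, best.D, eps, tau=cfg.tau,
                                  bin_spacing=cfg.bin_spacing,
                                  min_count=cfg.min_bin_count,
                                  include_single_frame=cfg.include_single_frame)
    if chosen_n >= 2:
        ttest = detect_transitions(profiles, t_late=cfg.t_late)
    else:
        ttest = TransitionTest(present=False, late_slopes=np.array([np.nan]),
                               late_se=np.array([np.nan]),
                               early_slopes=np.array([np.nan]),
                               early_se=np.array([np.nan]), t_late=cfg.t_late)

    # step 4: kinetic fit + consistency check
    # an explicit negative transition test removes the transition terms;
    # an indeterminate one keeps the configured topology
    topology = "none" if ttest.present is False else cfg.topology
    if cfg.force_topology is not None:
        topology = cfg.force_topology
    kin = fit_state_kinetics(profiles, topology=topology, lam_b=cfg.lam_b)
    model_hat = kin.to_model(best.D, eps=eps)
    consist = consistency_check(ensemble, model_hat, cfg.consistency_times)

    return AnalysisReport(n_tracks=ensemble.n_tracks, frame_dt=dt, eps=eps,
                          eps_estimated=eps_est, dissociation_rate=rate,
                          dissociation_rate_se=rate_se, lam_b=cfg.lam_b,
                          membrane_dissociation=bool(membrane_diss),
                          mixture_fits=fits, chosen_n=chosen_n,
                          profiles=profiles, transition_test=ttest,
                          kinetic_fit=kin, consistency=consist)
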