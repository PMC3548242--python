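"""Variational (Laplace) inversion of the stochastic DCM.

``SdcmModel`` wraps a regional BOLD series and exposes ``fit()``, which
returns an :class:`SdcmResults` carrying Gaussian posteriors over the
latent state trajectories (neural + hemodynamic) and over the model
parameters, together with a free-energy trace.

The scheme is a variational Laplace treatment with two Gaussian factors:

* **States** — given parameters, the state posterior is obtained by an
  extended Kalman filter over scans (locally linearized flow, ``TR /
  sub_steps`` integration sub-steps) followed by Rauch-Tung-Striebel
  smoothing.  The filter's innovations decomposition simultaneously yields
  the log-likelihood of the data with the states integrated out, i.e. the
  accuracy part of the free energy under the Laplace approximation.
* **Parameters** — the connectivity matrix ``A`` and the log noise
  precisions are updated jointly by regularized Gauss-Newton on the
  penalized log-likelihood: exact finite-difference gradients, curvature
  from Fisher scoring on the innovation Jacobians patched with
  finite-difference diagonal terms, Levenberg damping and a trust
  region.  Steps are accepted only if the free energy does not decrease;
  a rejected step restores the previous iterate exactly, so the reported
  free-energy trace is non-decreasing by construction.

State noise is modelled as white at scan resolution on the neural states;
smooth (generalized-coordinate) noise models are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from slowmodes import _kernels
from slowmodes.generative import (
    BoldSeries,
    HemodynamicParams,
    hemo_param_array,
    obs_const_array,
)

__all__ = ["PriorSpec", "SdcmModel", "SdcmResults", "build_priors", "free_energy"]


@dataclass
class PriorSpec:
    """Gaussian priors of the sDCM parameters.

    ``a_mean``/``a_var`` cover the flattened connectivity matrix;
    ``hemo_mean``/``hemo_var`` the per-region log-scaling factors of
    (kappa_s, kappa_f, tau0, alpha, E0, epsilon0) — zero scaling reproduces
    the default 1.5 T values exactly; ``log_prec_*`` the log precisions of
    state and measurement noise.
    """

    n_regions: int
    a_mean: np.ndarray
    a_var: np.ndarray
    hemo_mean: np.ndarray  # (n_regions, 6)
    hemo_var: np.ndarray
    log_prec_state_mean: float = 0.0
    log_prec_state_var: float = 1.0
    log_prec_meas_mean: float = 0.0
    log_prec_meas_var: float = 1.0

    def __post_init__(self) -> None:
        n = self.n_regions
        self.a_mean = np.asarray(self.a_mean, dtype=float).reshape(n, n)
        self.a_var = np.asarray(self.a_var, dtype=float).reshape(n, n)
        self.hemo_mean = np.asarray(self.hemo_mean, dtype=float).reshape(n, 6)
        self.hemo_var = np.asarray(self.hemo_var, dtype=float).reshape(n, 6)
        for arr in (self.a_var, self.hemo_var):
            if np.any(arr <= 0):
                raise ValueError("prior variances must be positive")
        if self.log_prec_state_var <= 0 or self.log_prec_meas_var <= 0:
            raise ValueError("prior variances must be positive")


def build_priors(
    n_regions: int,
    a_offdiag_var: float = 1.0 / 16.0,
    a_diag_mean: float = -1.0,
    a_diag_var: float = 1.0 / 16.0,
    hemo_var: float = 0.015,
    noise_log_prec_var: float = 1.0,
) -> PriorSpec:
    """Default priors: off-diagonal couplings N(0, 1/16) Hz, self-inhibition
    N(-1, 1/16) Hz, tight lognormal scalings of the hemodynamic constants,
    unit-variance log precisions for both noise sources.

    The prior-mean connectivity ``-I`` is a stable system, so prior
    predictive state trajectories are well behaved.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    a_mean = a_diag_mean * np.eye(n_regions)
    a_var = np.full((n_regions, n_regions), a_offdiag_var)
    np.fill_diagonal(a_var, a_diag_var)
    return PriorSpec(
        n_regions=n_regions,
        a_mean=a_mean,
        a_var=a_var,
        hemo_mean=np.zeros((n_regions, 6)),
        hemo_var=np.full((n_regions, 6), hemo_var),
        log_prec_state_var=noise_log_prec_var,
        log_prec_meas_var=noise_log_prec_var,
    )


def free_energy(
    log_joint: Callable[[np.ndarray], float],
    mean: np.ndarray,
    cov: np.ndarray,
    hess: np.ndarray | None = None,
) -> float:
    """Variational free energy of a Gaussian ``q = N(mean, cov)``.

    ``F = <ln p(y, theta)>_q + H[q]`` evaluated under the Laplace
    approximation: ``ln p(y, theta)`` (the ``log_joint``) is expanded to
    second order about the mean.  If ``hess`` (the negative curvature
    ``-d^2 log_joint``) is omitted, ``cov`` is assumed to equal its
    inverse, in which case the trace and entropy constants cancel to
    ``F = log_joint(mean) + 0.5 ln|cov| + (d/2) ln(2 pi)``.

    For a linear-Gaussian model with ``q`` the exact posterior this equals
    the exact log marginal likelihood.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = mean.size
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err
    _, logdet = np.linalg.slogdet(cov)
    lj = float(log_joint(mean))
    if hess is None:
        return lj + 0.5 * logdet + 0.5 * d * np.log(2.0 * np.pi)
    hess = np.atleast_2d(np.asarray(hess, dtype=float))
    trace_term = 0.5 * float(np.trace(cov @ hess))
    entropy = 0.5 * logdet + 0.5 * d * (1.0 + np.log(2.0 * np.pi))
    return lj - trace_term + entropy


@dataclass
class SdcmResults:
    """Posterior summaries of one sDCM fit.

    ``state_mean``/``state_sd`` are the smoothed neural states (scans x
    regions) — the pipeline's key intermediate x-hat; ``full_state_mean``
    additionally carries the four hemodynamic states per region.
    """

    model: "SdcmModel"
    state_mean: np.ndarray
    state_sd: np.ndarray
    full_state_mean: np.ndarray
    full_state_sd: np.ndarray
    param_mean: np.ndarray
    param_cov: np.ndarray
    param_names: list
    A: np.ndarray
    state_noise_var: float
    measurement_noise_var: float
    free_energy_trace: np.ndarray
    free_energy: float
    converged: bool
    n_iter: int

    @property
    def posterior_correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.param_cov))
        corr = self.param_cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return np.clip(corr, -1.0, 1.0)

    def summary(self) -> str:
        n = self.model.n_regions
        lines = ["Stochastic DCM fit", "=" * 40]
        lines.append(f"regions: {n}, scans: {self.model.n_scans}, TR: {self.model.tr} s")
        lines.append(
            f"converged: {self.converged} after {self.n_iter} iterations, "
            f"free energy: {self.free_energy:.2f} nats"
        )
        lines.append("connectivity A (Hz), posterior mean +/- sd:")
        sd = np.sqrt(np.diag(self.param_cov))[: n * n].reshape(n, n)
        for i in range(n):
            row = "  ".join(
                f"{self.A[i, j]:+7.3f}±{sd[i, j]:.3f}" for j in range(n)
            )
            lines.append("  " + row)
        lines.append(
            f"noise variances: state {self.state_noise_var:.4f}, "
            f"measurement {self.measurement_noise_var:.4f}"
        )
        return "\n".join(lines)

    def to_frames(self):
        """Export (states, params) as pandas DataFrames."""
        import pandas as pd

        labels = list(self.model.region_labels)
        states = pd.DataFrame(
            {
                "time_s": self.model.times,
                **{f"xhat_{l}": self.state_mean[:, i] for i, l in enumerate(labels)},
                **{f"sd_{l}": self.state_sd[:, i] for i, l in enumerate(labels)},
            }
        )
        params = pd.DataFrame(
            {
                "name": self.param_names,
                "mean": self.param_mean,
                "sd": np.sqrt(np.diag(self.param_cov)),
            }
        )
        return states, params


class SdcmModel:
    """Stochastic DCM of a regional BOLD series.

    Parameters
    ----------
    bold : BoldSeries or array (scans x regions)
        Observed percent-signal-change series.  NaN rows mark scan-nulled
        (missing) volumes and are skipped by the filter, which inflates the
        state posterior variance there.
    tr : float
        Repetition time in seconds (ignored if ``bold`` is a BoldSeries).
    priors : PriorSpec, optional
        Defaults to :func:`build_priors`.
    sub_steps : int
        Integration sub-steps per scan interval (default 8, i.e. TR/8).
    """

    def __init__(
        self,
        bold: BoldSeries | np.ndarray,
        tr: float | None = None,
        priors: PriorSpec | None = None,
        sub_steps: int = 8,
        region_labels: tuple | None = None,
    ) -> None:
        if isinstance(bold, BoldSeries):
            y = bold.y
            self.tr = bold.TR
            self.region_labels = bold.region_labels
            self.times = bold.times
        else:
            y = np.atleast_2d(np.asarray(bold, dtype=float))
            if tr is None:
                raise ValueError("tr is required when bold is a plain array")
            self.tr = float(tr)
            self.region_labels = region_labels or tuple(
                f"roi{i}" for i in range(y.shape[1])
            )
            self.times = np.arange(y.shape[0]) * self.tr
        if y.shape[1] < 2:
            import warnings

            warnings.warn("inverting a single-region model; connectivity is a scalar", stacklevel=2)
        self.n_scans, self.n_regions = y.shape
        self.mask = (~np.any(np.isnan(y), axis=1)).astype(np.int8)
        self.y = np.nan_to_num(y, nan=0.0)
        self.priors = priors if priors is not None else build_priors(self.n_regions)
        if self.priors.n_regions != self.n_regions:
            raise ValueError("priors built for a different number of regions")
        self.sub_steps = int(sub_steps)
        self.base_hemo = HemodynamicParams()
        n = self.n_regions
        self.param_names = [f"A_{i}{j}" for i in range(n) for j in range(n)] + [
            "log_prec_state",
            "log_prec_meas",
        ]

    # -- likelihood machinery -------------------------------------------------

    def _hemo_arrays(self, hemo_scaling: np.ndarray | None):
        scal = (
            self.priors.hemo_mean if hemo_scaling is None else np.asarray(hemo_scaling)
        )
        hps = [self.base_hemo.scaled(scal[r]) for r in range(self.n_regions)]
        return hemo_param_array(hps), obs_const_array(hps)

    def _init_state(self, q_var: float):
        d = 5 * self.n_regions
        m0 = np.zeros(d)
        p0 = np.zeros((d, d))
        # stationary neural variance under the prior-mean dynamics (decay 1 Hz)
        p0[: self.n_regions, : self.n_regions] = np.eye(self.n_regions) * max(
            q_var / 2.0, 1e-4
        )
        p0[self.n_regions :, self.n_regions :] = np.eye(4 * self.n_regions) * 1e-2
        return m0, p0

    def filter_pass(
        self,
        a: np.ndarray,
        q_var: float,
        r_var: float,
        hemo_scaling: np.ndarray | None = None,
    ):
        """One extended-Kalman pass; returns the kernel outputs."""
        hp, oc = self._hemo_arrays(hemo_scaling)
        m0, p0 = self._init_state(q_var)
        return _kernels.ekf_pass(
            self.y,
            self.mask,
            np.ascontiguousarray(a, dtype=float),
            hp,
            oc,
            q_var,
            r_var,
            self.sub_steps,
            self.tr,
            m0,
            p0,
        )

    def loglik(self, a: np.ndarray, q_var: float, r_var: float, hemo_scaling=None) -> float:
        """Innovations log-likelihood ln p(y | A, precisions) with the
        states integrated out under the local linearization."""
        return float(self.filter_pass(a, q_var, r_var, hemo_scaling)[0])

    def _log_prior_a(self, a: np.ndarray) -> float:
        pr = self.priors
        dev = (a - pr.a_mean).ravel()
        var = pr.a_var.ravel()
        return float(-0.5 * np.sum(dev**2 / var + np.log(2.0 * np.pi * var)))

    def _log_prior_prec(self, q_var: float, r_var: float) -> float:
        pr = self.priors
        lp = 0.0
        for logp, mu, var in (
            (-np.log(q_var), pr.log_prec_state_mean, pr.log_prec_state_var),
            (-np.log(r_var), pr.log_prec_meas_mean, pr.log_prec_meas_var),
        ):
            lp += -0.5 * ((logp - mu) ** 2 / var + np.log(2.0 * np.pi * var))
        return lp

    def penalized_loglik(self, a: np.ndarray, q_var: float, r_var: float) -> float:
        """ln p(y | theta) + ln p(theta): the quantity tracked by the
        free-energy trace (the entropy of q(theta) is added only in the
        final Laplace free energy, where the curvature is available)."""
        return (
            self.loglik(a, q_var, r_var)
            + self._log_prior_a(a)
            + self._log_prior_prec(q_var, r_var)
        )

    # -- state estimation -----------------------------------------------------

    def estimate_states(
        self, a: np.ndarray, q_var: float, r_var: float, hemo_scaling=None
    ):
        """Gaussian state posterior by EKF + RTS smoothing.

        Returns ``(ms, Ps)``: smoothed means (scans x 5n) and covariances
        (scans x 5n x 5n).
        """
        try:
            out = self.filter_pass(a, q_var, r_var, hemo_scaling)
        except (np.linalg.LinAlgError, FloatingPointError) as err:
            raise RuntimeError(
                "EKF diverged (non-finite filter quantities); the innovation "
                "gain is numerically unstable at these parameters — check "
                "data scaling, noise precisions and priors"
            ) from err
        loglik, mf, pf, mp, pp, phi = out[:6]
        if not np.isfinite(loglik):
            raise RuntimeError(
                "EKF diverged (non-finite innovations log-likelihood); "
                "check data scaling and priors"
            )
        ms, ps, cs = _kernels.rts_pass(mf, pf, mp, pp, phi)
        return ms, ps, cs

    # -- parameter updates ----------------------------------------------------

    def _pass_stats(self, theta: np.ndarray):
        """Penalized objective, innovations and their covariances at theta
        (A flattened + two log precisions)."""
        n = self.n_regions
        obs_t = self.mask == 1
        a = theta[: n * n].reshape(n, n)
        logp = np.clip(theta[n * n : n * n + 2], -20.0, 20.0)
        q_var = float(np.exp(-logp[0]))
        r_var = float(np.exp(-logp[1]))
        try:
            out = self.filter_pass(a, q_var, r_var)
        except (np.linalg.LinAlgError, FloatingPointError):
            n_obs = int(obs_t.sum())
            return -np.inf, np.zeros((n_obs, n)), np.tile(np.eye(n), (n_obs, 1, 1))
        loglik, innov, smat = out[0], out[6], out[7]
        pen = (
            float(loglik)
            + self._log_prior_a(a)
            + self._log_prior_prec(q_var, r_var)
        )
        return pen, innov[obs_t], smat[obs_t]

    def update_parameters(
        self,
        theta: np.ndarray,
        lam: float = 1.0,
        fd_step: float = 1e-4,
    ) -> tuple[np.ndarray, float, float]:
        """One regularized Gauss-Newton step on the penalized
        log-likelihood over all free parameters (A and log precisions).

        The gradient is the exact forward finite difference of the
        objective; the curvature combines the Fisher-scoring approximation
        ``sum_t J_t' S_t^-1 J_t`` over the innovation Jacobians for the
        connectivity block with finite-difference curvatures for the
        precision block, plus the prior precision.  The Levenberg-damped
        step is backtracked (step halving) until the objective does not
        decrease; if no step length succeeds, the previous iterate is
        returned exactly.

        Returns ``(theta_new, objective_old, objective_new)``.
        """
        n = self.n_regions
        p_a = n * n
        p_all = p_a + 2
        theta = np.asarray(theta, dtype=float).copy()
        f0, grad, hess = self._curvature(theta, fd_step)
        damped = hess + lam * np.diag(np.diag(hess)) + 1e-10 * np.eye(p_all)
        direction = np.linalg.solve(damped, grad)
        biggest = float(np.max(np.abs(direction)))
        if biggest > 1.0:  # trust region on a single proposal
            direction *= 1.0 / biggest
        for alpha in (1.0, 0.5, 0.25, 0.125, 0.0625):
            cand = theta + alpha * direction
            f_new = self._objective(cand)
            if np.isfinite(f_new) and f_new >= f0 - 1e-9:
                return cand, f0, f_new
        return theta, f0, f0

    def _curvature(self, theta: np.ndarray, fd_step: float = 1e-4):
        """Objective, finite-difference gradient and (scoring + FD)
        curvature of the penalized log-likelihood, prior precision
        included."""
        n = self.n_regions
        p_a = n * n
        p_all = p_a + 2
        f0, base, s0 = self._pass_stats(theta)
        grad = np.zeros(p_all)
        jac = np.zeros((base.shape[0], n, p_a))
        for k in range(p_a):
            pert = theta.copy()
            pert[k] += fd_step
            f_k, innov_k, _ = self._pass_stats(pert)
            if np.isfinite(f_k):
                grad[k] = (f_k - f0) / fd_step
                jac[:, :, k] = (innov_k - base) / fd_step
        s_inv = np.linalg.inv(s0)
        hess = np.zeros((p_all, p_all))
        hess[:p_a, :p_a] = np.einsum("tik,tij,tjl->kl", jac, s_inv, jac)
        # the scoring form ignores the |S| terms, which carry most of the
        # curvature for the noise precisions and part of it for the
        # self-connections; patch those diagonal entries with central FD
        diag_a = [i * (n + 1) for i in range(n)]
        hq = 1e-2
        for k in diag_a + [p_a, p_a + 1]:
            plus = theta.copy()
            plus[k] += hq
            minus = theta.copy()
            minus[k] -= hq
            f_p, _, _ = self._pass_stats(plus)
            f_m, _, _ = self._pass_stats(minus)
            if not (np.isfinite(f_p) and np.isfinite(f_m)):
                hess[k, k] = max(hess[k, k], 1.0)
                continue
            if k >= p_a:
                grad[k] = (f_p - f_m) / (2.0 * hq)
            fd_curv = -(f_p - 2.0 * f0 + f_m) / hq**2
            hess[k, k] = max(hess[k, k], fd_curv, 1.0)
        _, prior_prec = self._prior_moments()
        hess[np.diag_indices_from(hess)] += prior_prec
        return f0, grad, hess

    def _prior_moments(self):
        pr = self.priors
        mean = np.concatenate(
            [pr.a_mean.ravel(), [pr.log_prec_state_mean, pr.log_prec_meas_mean]]
        )
        prec = np.concatenate(
            [1.0 / pr.a_var.ravel(), [1.0 / pr.log_prec_state_var, 1.0 / pr.log_prec_meas_var]]
        )
        return mean, prec

    def _objective(self, theta: np.ndarray) -> float:
        n = self.n_regions
        a = theta[: n * n].reshape(n, n)
        logp = np.clip(theta[n * n : n * n + 2], -20.0, 20.0)
        q_var = float(np.exp(-logp[0]))
        r_var = float(np.exp(-logp[1]))
        try:
            return self.penalized_loglik(a, q_var, r_var)
        except (np.linalg.LinAlgError, FloatingPointError):
            return -np.inf

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        max_iter: int = 64,
        tol: float = 0.01,
        verbose: bool = False,
    ) -> SdcmResults:
        """Alternate state estimation and regularized Gauss-Newton
        parameter/precision steps until the free energy improves by less
        than ``tol`` nats (default 0.01) or ``max_iter`` is reached.

        The connectivity is fully reciprocal: every entry of ``A`` is a
        free parameter.  The hemodynamic log-scalings are held at their
        (tight) prior means; their prior covariance block is propagated
        into the reported posterior.
        """
        n = self.n_regions
        prior_mean, prior_prec = self._prior_moments()
        theta = prior_mean.copy()
        # data-driven starting point for the noise precisions: half the
        # observed variance to measurement noise, a modest state noise —
        # initialization only, the priors are unchanged
        var_y = float(np.var(self.y[self.mask == 1]))
        theta[n * n + 1] = -np.log(max(0.5 * var_y, 1e-3))
        theta[n * n] = -np.log(0.05)
        f_cur = self._objective(theta)
        trace = [f_cur]
        lam = 0.1
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            new, _, f_new = self.update_parameters(theta, lam=lam)
            stepped = np.any(new != theta)
            delta = max(f_new - f_cur, 0.0)
            if stepped:
                theta, f_cur = new, f_new
                lam = max(lam / 3.0, 1e-3)
            else:
                lam = min(lam * 10.0, 1e6)  # full rejection: previous iterate kept
            trace.append(f_cur)
            if verbose:
                print(f"iter {it:3d}  F = {f_cur:12.3f}  (lambda={lam:.2g})")
            if stepped and delta < tol:
                converged = True
                break
            if not stepped and lam >= 1e6:
                break

        a = theta[: n * n].reshape(n, n)
        q_var = float(np.exp(-theta[n * n]))
        r_var = float(np.exp(-theta[n * n + 1]))
        ms, ps, _ = self.estimate_states(a, q_var, r_var)
        state_sd_full = np.sqrt(np.maximum(np.diagonal(ps, axis1=1, axis2=2), 1e-30))

        # Laplace posterior over (A, log precisions) from the scoring curvature
        cov = self._posterior_cov(theta)
        f_final = (
            self._objective(theta)
            + 0.5 * np.linalg.slogdet(cov)[1]
            + 0.5 * theta.size * np.log(2.0 * np.pi)
        )
        return SdcmResults(
            model=self,
            state_mean=ms[:, :n],
            state_sd=state_sd_full[:, :n],
            full_state_mean=ms,
            full_state_sd=state_sd_full,
            param_mean=theta.copy(),
            param_cov=cov,
            param_names=list(self.param_names),
            A=a,
            state_noise_var=q_var,
            measurement_noise_var=r_var,
            free_energy_trace=np.asarray(trace),
            free_energy=float(f_final),
            converged=converged,
            n_iter=it,
        )

    def _posterior_cov(self, theta: np.ndarray) -> np.ndarray:
        """Laplace posterior covariance of (A, log precisions) from the
        scoring/FD curvature at the posterior mean."""
        _, _, hess = self._curvature(theta)
        return np.linalg.inv(hess + 1e-10 * np.eye(hess.shape[0]))
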