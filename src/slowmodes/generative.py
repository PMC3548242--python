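"""Generative model from regional neural states to BOLD.

Three stages:

1. *Langevin neural dynamics*: the slow regional states ``x`` (the
   fundamental-mode amplitudes of the regions' neural fields, in arbitrary
   units) follow ``dx/dt = A x + u(t) + v``, where ``A`` is the effective
   connectivity matrix (Hz), ``u`` an optional deterministic drive (used by
   the synthetic cohort to emulate epileptic discharge blocks; the inversion
   never sees it and must absorb it into the state noise ``v``).
2. *Hemodynamics*: each region's neural state drives a four-state balloon
   model — vasodilatory signal, log blood flow, log venous volume and log
   deoxyhemoglobin content — written in log space so that positivity of
   flow/volume/dHb is automatic and rest is the exact fixed point zero.
3. *BOLD observation*: a volume-weighted mixture of intra- and
   extravascular signal changes evaluated at scan times, in percent signal
   change, with optional additive measurement noise.

Default hemodynamic constants correspond to a 1.5 T acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = [
    "ConnectivityParams",
    "HemodynamicParams",
    "RegionTrajectory",
    "BoldSeries",
    "neural_flow",
    "hemodynamic_flow",
    "bold_observation",
    "integrate_generative",
]


@dataclass(frozen=True)
class ConnectivityParams:
    """Effective connectivity matrix ``A`` (Hz) with region labels."""

    A: np.ndarray
    region_labels: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("A must be square")
        if not np.all(np.isfinite(a)):
            raise ValueError("A must be finite")
        object.__setattr__(self, "A", a)
        if not self.region_labels:
            object.__setattr__(
                self, "region_labels", tuple(f"roi{i}" for i in range(a.shape[0]))
            )
        elif len(self.region_labels) != a.shape[0]:
            raise ValueError("region_labels length must match A")
        if np.any(np.linalg.eigvals(a).real > 0):
            import warnings

            warnings.warn("connectivity matrix A is unstable (eigenvalue with Re > 0)", stacklevel=2)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model parameters and BOLD observation constants.

    kappa_s : vasodilatory signal decay rate (Hz)
    kappa_f : vasodilatory feedback rate (Hz)
    tau0    : mean venous transit time (s)
    alpha   : vessel stiffness exponent (dimensionless, in (0, 1))
    E0      : resting oxygen extraction fraction (in (0, 1))
    epsilon0: ratio of intra- to extravascular signal (dimensionless)
    V0      : resting venous volume fraction (percent signal scale)
    nu0     : frequency offset of deoxygenated vessels (Hz)
    TE      : echo time (s)
    r0      : intravascular relaxation slope (Hz)
    """

    kappa_s: float = 0.65
    kappa_f: float = 0.41
    tau0: float = 2.0
    alpha: float = 0.32
    E0: float = 0.34
    epsilon0: float = 1.0
    V0: float = 4.0
    nu0: float = 40.3
    TE: float = 0.04
    r0: float = 25.0

    def __post_init__(self) -> None:
        for name in ("kappa_s", "kappa_f", "tau0", "V0", "nu0", "TE", "r0", "epsilon0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HemodynamicParams.{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must be in (0, 1)")

    @property
    def k1(self) -> float:
        """Extravascular BOLD coefficient ``4.3 nu0 E0 TE``."""
        return 4.3 * self.nu0 * self.E0 * self.TE

    @property
    def k2(self) -> float:
        """Intravascular BOLD coefficient ``epsilon0 r0 E0 TE``."""
        return self.epsilon0 * self.r0 * self.E0 * self.TE

    def scaled(self, log_scaling: np.ndarray) -> "HemodynamicParams":
        """Apply multiplicative log-scalings to (kappa_s, kappa_f, tau0,
        alpha, E0, epsilon0); zero scaling returns the defaults exactly."""
        ls = np.asarray(log_scaling, dtype=float)
        if ls.shape != (6,):
            raise ValueError("log_scaling must have 6 entries")
        return replace(
            self,
            kappa_s=self.kappa_s * np.exp(ls[0]),
            kappa_f=self.kappa_f * np.exp(ls[1]),
            tau0=self.tau0 * np.exp(ls[2]),
            alpha=self.alpha * np.exp(ls[3]),
            E0=self.E0 * np.exp(ls[4]),
            epsilon0=self.epsilon0 * np.exp(ls[5]),
        )


@dataclass
class RegionTrajectory:
    """Dense state trajectories: times (s), neural states ``x_n``
    (time x regions) and hemodynamic states ``x_h`` (time x regions x 4:
    vasodilatory signal, log flow, log volume, log dHb)."""

    times: np.ndarray
    x_n: np.ndarray
    x_h: np.ndarray


@dataclass
class BoldSeries:
    """BOLD observations (% signal change) at scan times (spacing = TR)."""

    times: np.ndarray
    y: np.ndarray
    TR: float
    region_labels: tuple = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] != self.times.shape[0]:
            raise ValueError("y must have one row per scan")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("BOLD series contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.y.shape[1]


def neural_flow(x: np.ndarray, A: ConnectivityParams | np.ndarray) -> np.ndarray:
    """Deterministic part of the Langevin neural dynamics: ``A x``."""
    a = A.A if isinstance(A, ConnectivityParams) else np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != a.shape[0]:
        raise ValueError(f"shape mismatch: A is {a.shape}, x has {x.shape[-1]} regions")
    return x @ a.T if x.ndim > 1 else a @ x


def hemodynamic_flow(x_h: np.ndarray, x_n: float, p: HemodynamicParams) -> np.ndarray:
    """Balloon-model flow in the log-state formulation.

    With ``x_h = (s, ln f, ln v, ln q)``:

    * ``ds/dt      = x_n - kappa_s s - kappa_f (e^{ln f} - 1)``
    * ``d ln f/dt  = s e^{-ln f}``
    * ``d ln v/dt  = (e^{ln f} - e^{ln v / alpha}) e^{-ln v} / tau0``
    * ``d ln q/dt  = (e^{ln f - ln q} E(f)/E0 - e^{(1-alpha) ln v / alpha}) / tau0``

    where ``E(f) = 1 - (1 - E0)^{1/f}`` is the flow-dependent oxygen
    extraction.  Rest (all states zero, no drive) is an exact fixed point.
    """
    x_h = np.asarray(x_h, dtype=float)
    if x_h.shape != (4,) or not np.all(np.isfinite(x_h)):
        raise ValueError("x_h must be a finite 4-vector")
    s, lf, lv, lq = x_h
    if max(abs(lf), abs(lv), abs(lq)) > 50:
        raise OverflowError(f"hemodynamic state out of range: {x_h}")
    f = np.exp(lf)
    extraction = 1.0 - (1.0 - p.E0) ** np.exp(-lf)
    return np.array(
        [
            x_n - p.kappa_s * s - p.kappa_f * (f - 1.0),
            s * np.exp(-lf),
            (f - np.exp(lv / p.alpha)) * np.exp(-lv) / p.tau0,
            (np.exp(lf - lq) * extraction / p.E0 - np.exp((1.0 - p.alpha) * lv / p.alpha))
            / p.tau0,
        ]
    )


def bold_observation(x_h: np.ndarray, p: HemodynamicParams) -> float:
    """BOLD percent signal change from the hemodynamic log-states.

    ``y = V0 (k1 (1 - e^{lq}) + k2 (1 - e^{lq - lv}) + (1 - eps0)(1 - e^{lv}))``
    with ``k1 = 4.3 nu0 E0 TE`` and ``k2 = eps0 r0 E0 TE``.
    """
    x_h = np.asarray(x_h, dtype=float)
    lv = x_h[..., 2]
    lq = x_h[..., 3]
    y = p.V0 * (
        p.k1 * (1.0 - np.exp(lq))
        + p.k2 * (1.0 - np.exp(lq - lv))
        + (1.0 - p.epsilon0) * (1.0 - np.exp(lv))
    )
    return y if np.ndim(y) else float(y)


def hemo_param_array(hps: list[HemodynamicParams]) -> np.ndarray:
    """Pack per-region balloon parameters for the compiled kernels."""
    return np.array(
        [[p.kappa_s, p.kappa_f, p.tau0, p.alpha, p.E0, p.epsilon0] for p in hps]
    )


def obs_const_array(hps: list[HemodynamicParams]) -> np.ndarray:
    """Pack per-region BOLD observation constants (V0, k1, k2, eps0)."""
    return np.array([[p.V0, p.k1, p.k2, p.epsilon0] for p in hps])


def integrate_generative(
    A: ConnectivityParams | np.ndarray,
    p: HemodynamicParams | list[HemodynamicParams],
    state_noise_sd: float = 0.0,
    drive: Callable[[float], np.ndarray] | np.ndarray | None = None,
    n_scans: int = 700,
    TR: float = 3.0,
    dt: float = 0.01,
    seed: int | None = None,
    measurement_noise_sd: float = 0.0,
) -> tuple[RegionTrajectory, BoldSeries]:
    """Simulate the full generative model and sample BOLD at scan times.

    Neural states are integrated by Euler-Maruyama (white noise of standard
    deviation ``state_noise_sd`` per sqrt-second), hemodynamic states by
    deterministic RK4 nested inside each Euler step.  ``drive`` may be a
    callable ``u(t) -> (n,)`` or an array of shape ``(n_steps or n_scans, n)``
    giving a deterministic input added to the neural flow.

    Returns the dense :class:`RegionTrajectory` (at resolution ``dt``) and
    the :class:`BoldSeries` at scan times ``0, TR, ..., (n_scans-1) TR``.
    """
    conn = A if isinstance(A, ConnectivityParams) else ConnectivityParams(np.asarray(A, dtype=float))
    a = conn.A
    n = conn.n_regions
    if dt > 0.05 + 1e-12:
        raise ValueError("dt must be <= 50 ms")
    steps_per_tr = TR / dt
    if abs(steps_per_tr - round(steps_per_tr)) > 1e-9:
        raise ValueError("TR must be an integer multiple of dt")
    steps_per_tr = int(round(steps_per_tr))
    hps = p if isinstance(p, list) else [p] * n
    n_steps = (n_scans - 1) * steps_per_tr + 1
    times = np.arange(n_steps) * dt

    if drive is None:
        u = np.zeros((n_steps, n))
    elif callable(drive):
        u = np.array([np.broadcast_to(drive(t), (n,)) for t in times], dtype=float)
    else:
        u = np.asarray(drive, dtype=float)
        if u.shape == (n_scans, n):  # scan-resolution blocks: hold over each TR
            u = np.repeat(u, steps_per_tr, axis=0)[:n_steps]
        if u.shape != (n_steps, n):
            raise ValueError(f"drive must have shape ({n_steps}, {n}) or ({n_scans}, {n})")

    rng = np.random.default_rng(seed)
    noise = (
        state_noise_sd * np.sqrt(dt) * rng.standard_normal((n_steps - 1, n))
        if state_noise_sd > 0
        else np.zeros((n_steps - 1, n))
    )

    from slowmodes import _kernels

    try:
        x_n, x_h, y = _kernels.simulate_dense(
            a,
            hemo_param_array(hps),
            obs_const_array(hps),
            u[:-1],
            noise,
            dt,
            steps_per_tr,
            n_scans,
        )
    except FloatingPointError as err:
        raise RuntimeError(
            f"neural state diverged (|x| > 1e6) for regions {conn.region_labels}"
        ) from err
    scan_idx = np.arange(n_scans) * steps_per_tr
    if measurement_noise_sd > 0:
        y = y + measurement_noise_sd * rng.standard_normal(y.shape)
    traj = RegionTrajectory(times=times, x_n=x_n, x_h=x_h)
    bold = BoldSeries(times=scan_idx * dt, y=y, TR=TR, region_labels=conn.region_labels)
    return traj, bold
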