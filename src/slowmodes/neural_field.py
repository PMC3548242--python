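"""Neural-field forward model of the EEG power spectrum.

A single cortical region is modelled as a continuum field of mean membrane
depolarization eta(r, t).  Dense lateral connectivity with a dispersive
(finite conduction velocity) propagator induces a separation of time scales
between the spatial Laplacian eigenmodes of the field: the fundamental
(spatially uniform, k = 0) mode decays arbitrarily slowly, while higher
modes are fast.  The fundamental-mode amplitude ``z1`` enters the linearized
dynamics of every fast mode through a gain ``c(z1)`` proportional to the
derivative of the ensemble firing-rate sigmoid, so the *frequency content*
of the fast modes — and hence of the EEG — is controlled by the *amplitude*
of the slow mode.

This module provides the pieces of that forward model:

* the ensemble firing-rate sigmoid,
* the dispersive synaptic propagator ``G(r, t)``,
* Laplacian eigenvalues on a 1-D interval (Neumann convention),
* the per-mode 3x3 flow (Jacobian) matrices and the slow-mode coupling gain,
* the analytic EEG power spectrum summed over modes, its band-normalized
  form, and the spectral first moment (center frequency),
* an Euler-Maruyama simulator of the per-mode stochastic dynamics used as a
  numerical oracle for the analytic spectrum.

Internal units are mV, mm and s throughout; conduction velocity given in
m/s is converted to mm/s at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "NeuralFieldParams",
    "ModeBasis",
    "ModeState",
    "PowerSpectrum",
    "firing_rate_sigmoid",
    "dispersive_propagator",
    "laplacian_eigenvalues",
    "coupling_gain",
    "mode_jacobian",
    "simulate_mode_sde",
    "power_spectrum",
    "normalize_spectrum",
    "center_frequency",
    "center_frequency_curve",
]


@dataclass(frozen=True)
class NeuralFieldParams:
    """Biophysical constants of the neural-field model.

    Parameters
    ----------
    gamma : float
        Maximum post-synaptic potential following one action potential (mV).
    tau : float
        Post-synaptic impulse-response time constant (s).
    g0 : float
        Total number of synaptic connections (dimensionless).
    sigma : float
        Spatial dispersion (decay scale) of lateral connections (mm).
    rho : float
        Slope of the firing sigmoid; inverse of the within-ensemble
        depolarization standard deviation (mV^-1).
    chi : float
        Action-potential firing threshold relative to steady state (mV).
    nu_bar : float
        Average axonal conduction velocity (mm/s).  Use
        :meth:`from_velocity_m_per_s` or the config loader to convert m/s.
    """

    gamma: float = 8.0
    tau: float = 0.004
    g0: float = 2000.0
    sigma: float = 3.0
    rho: float = 0.54
    chi: float = 30.0
    nu_bar: float = 3000.0

    def __post_init__(self) -> None:
        for name in ("gamma", "tau", "g0", "sigma", "rho", "chi", "nu_bar"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"NeuralFieldParams.{name} must be strictly positive, got {v!r}")

    @classmethod
    def from_velocity_m_per_s(cls, velocity: float = 3.0, **kw) -> "NeuralFieldParams":
        """Build parameters with the conduction velocity given in m/s."""
        return cls(nu_bar=velocity * 1000.0, **kw)

    @property
    def axonal_rate(self) -> float:
        """Fundamental temporal decay rate nu_bar / (2 sigma), in s^-1."""
        return self.nu_bar / (2.0 * self.sigma)

    def with_(self, **kw) -> "NeuralFieldParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModeBasis:
    """Laplacian eigenvalues of the region's spatial domain.

    The geometry of the cortical patch is not constrained by the slaving
    argument itself; we adopt the simplest convention consistent with
    ``lambda_k < lambda_0 = 0``: a 1-D interval of length ``domain_length``
    with Neumann boundaries, whose eigenvalues are ``-(k pi / L)**2``.

    The default ``domain_length = 3`` mm is the largest round value for
    which every *fast* mode (k >= 1) remains linearly stable over the whole
    depolarization sweep ``z1 in [0, 2 chi]`` at the default biophysical
    constants: mode k is stable at the worst case ``z1 = chi`` iff
    ``1 + sigma^2 (k pi / L)^2 > gamma tau c(chi) / (nu_bar / 2 sigma)``
    (~8.64 at defaults), which requires ``L < 3.41`` mm for ``k = 1``.
    Stability of the fast modes is what makes the analytic spectrum a
    stationary quantity that a stochastic simulation can reproduce, and it
    is also the regime in which the center frequency decreases
    monotonically with ``z1`` toward its minimum at the firing threshold.
    """

    domain_length: float = 3.0
    kc: int = 16
    eigenvalues: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")
        if int(self.kc) < 1:
            raise ValueError("kc must be >= 1")
        object.__setattr__(self, "kc", int(self.kc))
        if self.eigenvalues is None:
            k = np.arange(self.kc + 1)
            lam = -((k * np.pi / self.domain_length) ** 2)
            object.__setattr__(self, "eigenvalues", tuple(lam))
        lam = np.asarray(self.eigenvalues, dtype=float)
        if lam[0] != 0.0 or np.any(lam[1:] >= 0.0) or np.any(np.diff(lam) >= 0.0):
            raise ValueError("eigenvalues must satisfy 0 = lambda_0 > lambda_1 > ...")

    @property
    def lam(self) -> np.ndarray:
        return np.asarray(self.eigenvalues, dtype=float)


@dataclass
class ModeState:
    """Trajectory of one eigenmode: depolarization ``z1``, pre-synaptic
    input ``z2`` and the depolarization rate ``z3 = dz1/dt``."""

    z1: np.ndarray
    z2: np.ndarray
    z3: np.ndarray


@dataclass
class PowerSpectrum:
    """A power spectrum on a strictly increasing frequency grid (Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))

    def to_frame(self, omega0: float | None = None):
        """Export as a DataFrame with columns freq_hz, power and
        normalized_power (band-restricted normalization from ``omega0``,
        defaulting to the grid's lower edge)."""
        import pandas as pd

        norm = normalize_spectrum(self, self.freqs[0] if omega0 is None else omega0)
        df = pd.DataFrame({"freq_hz": self.freqs, "power": self.power})
        df = df[df.freq_hz >= norm.freqs[0] - 1e-12].reset_index(drop=True)
        df["normalized_power"] = norm.power
        return df


def firing_rate_sigmoid(eta, params: NeuralFieldParams):
    """Mean firing rate of the ensemble as a function of depolarization.

    ``S(eta) = 1 / (1 + exp(-rho (eta - chi)))`` — the probability that a
    neuron's membrane potential exceeds the firing threshold ``chi``, under
    a logistic approximation to the ensemble density.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("membrane potential must be finite")
    out = 1.0 / (1.0 + np.exp(-params.rho * (eta - params.chi)))
    return out if out.ndim else float(out)


def dispersive_propagator(r, t, params: NeuralFieldParams):
    """Dispersive connectivity Green function ``G(r, t)``.

    Density of synaptic connections reached at distance ``r`` (mm) a time
    ``t`` (s) after an action potential is emitted at the origin, assuming a
    Gaussian falloff of connection density (scale ``sigma``) and a
    distribution of conduction velocities with large-distance mode
    ``nu_bar``.  Causality is enforced by a Heaviside factor: the density is
    zero for ``t <= 0``.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        g = (
            params.g0
            / (4.0 * np.pi * params.sigma**2)
            * np.where(t > 0, 1.0 / np.where(t > 0, t, 1.0), 0.0)
            * np.exp(
                np.where(
                    t > 0,
                    -(r**2 + params.nu_bar**2 * t**2)
                    / (2.0 * params.sigma * params.nu_bar * np.where(t > 0, t, 1.0)),
                    -np.inf,
                )
            )
        )
    g = np.where(t > 0, g, 0.0)
    return g if g.ndim else float(g)


def laplacian_eigenvalues(domain_length: float, kc: int) -> ModeBasis:
    """Eigenvalues ``lambda_k = -(k pi / L)^2`` for ``k = 0..kc`` (mm^-2)."""
    return ModeBasis(domain_length=domain_length, kc=kc)


def coupling_gain(z1_fundamental, params: NeuralFieldParams):
    """Slow-mode coupling gain ``c(z1) = rho G0 (nu_bar / 2 sigma) S (1 - S)``.

    This is the gain with which the fundamental-mode amplitude modulates the
    firing-rate feedback onto every fast mode; it is maximal when ``z1``
    sits at the firing threshold ``chi`` (where ``S = 1/2``).
    """
    z1 = np.asarray(z1_fundamental, dtype=float)
    s = firing_rate_sigmoid(z1, params)
    c = params.rho * params.g0 * params.axonal_rate * s * (1.0 - s)
    return c if np.ndim(c) else float(c)


def mode_jacobian(lambda_k: float, z1_fundamental: float, params: NeuralFieldParams) -> np.ndarray:
    """Linear flow matrix of one eigenmode's state ``(z1, z2, z3)``.

    Derived by projecting the field equations onto eigenmode ``k``: the
    pre-synaptic input mode ``z2`` relaxes at rate ``(nu_bar/2 sigma)
    (1 - sigma^2 lambda_k)`` and is driven by firing-rate feedback with gain
    ``c(z1^0)``; the synaptic kernel turns ``z2`` into depolarization ``z1``
    through a critically damped second-order stage with rate ``1/tau`` and
    gain ``gamma/tau``.
    """
    c = coupling_gain(z1_fundamental, params)
    a_k = params.axonal_rate * (params.sigma**2 * lambda_k - 1.0)
    return np.array(
        [
            [0.0, 0.0, 1.0],
            [c, a_k, 0.0],
            [-1.0 / params.tau**2, params.gamma / params.tau, -2.0 / params.tau],
        ]
    )


def assert_stable_modes(basis: ModeBasis, z1_fundamental: float, params: NeuralFieldParams) -> None:
    """Raise if any *fast* mode Jacobian has an eigenvalue with positive real part.

    The fundamental mode (``lambda_0 = 0``) is deliberately excluded: it is
    the quasi-static order parameter whose amplitude conditions the fast
    dynamics, and its own linearization is unstable for ``z1`` near the
    firing threshold at the default constants — that near-marginal slowness
    is precisely the separation of time scales the model relies on.
    """
    for lam in basis.lam[1:]:
        j = mode_jacobian(lam, z1_fundamental, params)
        ev = np.linalg.eigvals(j)
        if np.any(ev.real > 1e-9):
            raise ValueError(
                f"unstable mode (lambda={lam:.4g}, z1={z1_fundamental:.4g}): "
                f"max Re(eig) = {ev.real.max():.4g} s^-1"
            )


def _discrete_step_matrices(j: np.ndarray, dt: float, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    """One-step transition ``F`` and input vector ``Bd`` for one mode.

    ``scheme="exact"`` uses the matrix exponential with a zero-order hold on
    the (shared) noise input; ``scheme="euler"`` is the plain explicit step,
    which is only usable when ``dt`` resolves the fastest mode decay rate.
    """
    b = np.array([0.0, 1.0, 0.0])
    if scheme == "euler":
        f = np.eye(3) + dt * j
        if np.any(np.abs(np.linalg.eigvals(f)) >= 1.0):
            raise ValueError(
                f"Euler step unstable at dt={dt} (|I + dt J| has modulus >= 1); "
                "use scheme='exact' or reduce dt"
            )
        return f, b
    if scheme != "exact":
        raise ValueError(f"unknown scheme {scheme!r}")
    from scipy.linalg import expm

    f = expm(dt * j)
    # zero-order-hold input: Bd = (1/dt) * int_0^dt expm(J s) b ds, via the
    # standard augmented-exponential construction
    aug = np.zeros((4, 4))
    aug[:3, :3] = j
    aug[:3, 3] = b
    e = expm(dt * aug)
    bd = e[:3, 3] / dt
    return f, bd


def simulate_mode_sde(
    basis: ModeBasis,
    z1_fundamental: float,
    params: NeuralFieldParams,
    noise_sd: float = 1.0,
    duration: float = 10.0,
    dt: float = 2e-4,
    seed: int | None = None,
    scheme: str = "exact",
) -> tuple[np.ndarray, list[ModeState]]:
    """Stochastic simulation of the linearized fast-mode dynamics.

    One shared white-noise sequence of standard deviation ``noise_sd`` (per
    sqrt-second) drives the pre-synaptic input component ``z2`` of every
    fast mode (k >= 1) — the common drive is what makes the modes' outputs
    sum coherently, matching the analytic spectrum.  Each mode's linear
    recursion ``z <- F z + Bd sd sqrt(dt) xi`` is executed through
    ``scipy.signal.lfilter`` per state component, which makes 10^6-step
    oracle runs cheap.  The default exponential discretization is
    unconditionally stable, which matters because small domains make the
    high-order modes stiff (decay rates up to ~1e6 s^-1).

    Returns the time grid and one :class:`ModeState` per fast mode
    (ordered k = 1..kc).
    """
    if dt > params.tau / 10.0 + 1e-15:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau/10 = {params.tau / 10.0}")
    assert_stable_modes(basis, z1_fundamental, params)
    n = int(round(duration / dt))
    times = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    w = noise_sd * np.sqrt(dt) * rng.standard_normal(n)
    drive = np.concatenate([[0.0], w[:-1]])  # z_t responds to noise up to t-1
    states: list[ModeState] = []
    for lam in basis.lam[1:]:
        j = mode_jacobian(lam, z1_fundamental, params)
        f, bd = _discrete_step_matrices(j, dt, scheme)
        z = np.empty((n, 3))
        for comp in range(3):
            cvec = np.zeros((1, 3))
            cvec[0, comp] = 1.0
            num, den = _signal.ss2tf(f, bd[:, None], cvec, np.zeros((1, 1)))
            z[:, comp] = _signal.lfilter(num[0], den, drive)
        states.append(ModeState(z1=z[:, 0], z2=z[:, 1], z3=z[:, 2]))
    return times, states


def _mode_transfer(freqs_hz: np.ndarray, basis: ModeBasis, z1: float, params: NeuralFieldParams) -> np.ndarray:
    """Summed noise-to-depolarization transfer function over fast modes.

    For each fast mode (k >= 1) the transfer from the shared ``z2`` noise
    input to ``z1`` is ``(gamma/tau) / det(i w I - J_k)`` with
    ``det = (i w + (nu_bar/2 sigma)(1 - sigma^2 lambda_k))
    (i w (i w + 2/tau) + 1/tau^2) - (gamma/tau) c(z1)``.  The fundamental
    mode is the conditioning variable and is not part of the EEG sum.
    """
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float)
    s = 1j * w[None, :]
    c = coupling_gain(z1, params)
    a_k = params.axonal_rate * (1.0 - params.sigma**2 * basis.lam[1:])[:, None]
    det = (s + a_k) * (s * (s + 2.0 / params.tau) + 1.0 / params.tau**2) - (
        params.gamma / params.tau
    ) * c
    if np.any(np.abs(det) < 1e-300):
        raise ValueError("marginally stable mode: transfer function pole on the frequency grid")
    return ((params.gamma / params.tau) / det).sum(axis=0)


def power_spectrum(
    z1_fundamental: float,
    freqs_hz: np.ndarray,
    basis: ModeBasis,
    params: NeuralFieldParams,
    check_stability: bool = True,
) -> PowerSpectrum:
    """Analytic EEG power spectrum ``P(w) = |sum_{1<=k<=kc} H_k(i w)|^2``.

    The EEG is taken to reflect post-synaptic depolarization, i.e. the
    coherent sum of the fast modes' ``z1`` components driven by a shared
    white noise on the pre-synaptic input, conditioned on the slow
    fundamental amplitude ``z1_fundamental``.  Frequencies in Hz.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.ndim != 1 or np.any(freqs_hz <= 0) or np.any(np.diff(freqs_hz) <= 0):
        raise ValueError("freqs_hz must be strictly positive and increasing")
    if check_stability:
        assert_stable_modes(basis, z1_fundamental, params)
    h = _mode_transfer(freqs_hz, basis, z1_fundamental, params)
    return PowerSpectrum(freqs=freqs_hz, power=np.abs(h) ** 2, normalized=False)


def power_spectrum_grid(
    z1_values: np.ndarray,
    freqs_hz: np.ndarray,
    basis: ModeBasis,
    params: NeuralFieldParams,
) -> np.ndarray:
    """Vectorized ``P(w; z1)`` for many fundamental-mode amplitudes.

    Returns an array of shape ``(len(z1_values), len(freqs_hz))``.  Used by
    the synthetic EEG generator, which needs one spectrum per scan window
    per region.
    """
    z1_values = np.atleast_1d(np.asarray(z1_values, dtype=float))
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    w = 2.0 * np.pi * freqs_hz
    s = 1j * w[None, None, :]
    c = np.asarray(coupling_gain(z1_values, params))[:, None, None]
    a_k = (params.axonal_rate * (1.0 - params.sigma**2 * basis.lam[1:]))[None, :, None]
    det = (s + a_k) * (s * (s + 2.0 / params.tau) + 1.0 / params.tau**2) - (
        params.gamma / params.tau
    ) * c
    h = ((params.gamma / params.tau) / det).sum(axis=1)
    return np.abs(h) ** 2


def normalize_spectrum(spec: PowerSpectrum, omega0: float = 1.0) -> PowerSpectrum:
    """Restrict to ``[omega0, f_max]`` and normalize to unit trapezoidal mass.

    The normalized spectrum is a probability density over frequencies: the
    proportion of total band power attributed to each frequency.
    """
    keep = spec.freqs >= omega0 - 1e-12
    if keep.sum() < 2:
        raise ValueError("spectrum has no support above omega0")
    f = spec.freqs[keep]
    p = spec.power[keep]
    total = np.trapezoid(p, f)
    if total <= 0:
        raise ValueError("zero total power in band; cannot normalize")
    return PowerSpectrum(freqs=f, power=p / total, normalized=True)


def center_frequency(spec: PowerSpectrum) -> float:
    """First moment of a normalized power spectrum (Hz)."""
    if not spec.normalized:
        raise ValueError("center_frequency requires a normalized spectrum")
    if abs(spec.integral() - 1.0) > 1e-6:
        raise ValueError("spectrum flagged normalized but does not integrate to 1")
    return float(np.trapezoid(spec.freqs * spec.power, spec.freqs))


def center_frequency_curve(
    z1_grid: np.ndarray,
    basis: ModeBasis,
    params: NeuralFieldParams,
    omega0: float = 1.0,
    freqs_hz: np.ndarray | None = None,
) -> np.ndarray:
    """Center frequency as a function of fundamental-mode amplitude.

    Composes ``power_spectrum -> normalize_spectrum -> center_frequency``
    per grid point and returns an array of shape ``(len(z1_grid), 2)`` with
    columns ``(z1, center_frequency_hz)``.
    """
    z1_grid = np.atleast_1d(np.asarray(z1_grid, dtype=float))
    if freqs_hz is None:
        freqs_hz = default_frequency_grid(omega0)
    out = np.empty((z1_grid.size, 2))
    for i, z1 in enumerate(z1_grid):
        spec = power_spectrum(z1, freqs_hz, basis, params)
        out[i] = z1, center_frequency(normalize_spectrum(spec, omega0))
    return out


def default_frequency_grid(omega0: float = 1.0, omega_max: float = 60.0, df: float = 0.25) -> np.ndarray:
    """Default analysis band: ``omega0`` to ``omega_max`` Hz in ``df`` steps."""
    n = int(round((omega_max - omega0) / df))
    return omega0 + df * np.arange(n + 1)
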