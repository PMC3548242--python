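"""Synthetic EEG-fMRI cohort with ground-truth slow neural states.

Each subject gets:

* a stable random effective-connectivity matrix ``A`` (3 regions:
  thalamus, prefrontal cortex, precuneus);
* slow neural states integrating Langevin dynamics with white state noise
  plus block-shaped epileptic-discharge (GSW) drive entering all three
  regions with region-specific gains — the regions of interest in such
  studies are selected for showing discharge-related BOLD responses;
* BOLD series through the balloon observation model, with a shared
  measurement-noise floor scaled to a target signal-to-noise ratio, and a
  small fraction of motion-corrupted (scan-nulled) volumes;
* multichannel EEG whose windowed spectra follow the neural-field
  forward model evaluated at the depolarization implied by each region's
  state (spectral shaping of white noise, 50 %-overlap Hann overlap-add),
  mixed into channels, plus drift and cardiac artifact components; EOG and
  ECG channels carry artifact only;
* confound matrices (drifts / full nuisance set) and scan-nulling flags.

The statistical structure is exactly what the analysis assumes: the same
latent states drive the BOLD (through hemodynamics) and the EEG spectral
content (through the slow-mode coupling), so the pipeline's positive
control has a well-defined ground truth, and the ``null`` variant severs
the state-to-EEG link while keeping everything else identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from slowmodes import neural_field as nf
from slowmodes.eeg import EegRecording
from slowmodes.generative import (
    BoldSeries,
    ConnectivityParams,
    HemodynamicParams,
    integrate_generative,
)

__all__ = ["CohortSpec", "SyntheticSubject", "sample_connectivity", "simulate_subject", "synthesize_eeg", "make_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated acquisition: 9 subjects, 3 regions,
    700 scans at TR = 3 s, 10 EEG channels (plus EOG and ECG) at 250 Hz.
    Neural amplitudes are in arbitrary state units.  The depolarization
    implied by a state ``x`` is ``baseline_mv + state_to_mv * x``: resting
    activity sits at ``baseline_mv`` (near-threshold, where the center
    frequency is sensitive to slow fluctuations — the critical-slowing
    operating point), and ``state_to_mv = None`` auto-scales the maximum
    excursion to 95 % of the firing threshold so depolarization stays in
    the monotone region of the center-frequency curve.
    """

    n_subjects: int = 9
    n_regions: int = 3
    n_scans: int = 700
    tr: float = 3.0
    eeg_fs: float = 250.0
    n_eeg_channels: int = 10
    n_artifact_channels: int = 2
    coupling_scale: float = 0.1
    state_noise_sd: float = 0.05
    measurement_snr: float = 1.0
    gsw_n_blocks: int = 10
    gsw_block_scans: tuple = (6, 8, 10, 12)
    gsw_amplitude: float = 1.0
    gsw_gains: tuple = (1.0, 0.7, 0.5)
    baseline_mv: float = 22.0
    state_to_mv: float | None = None
    eeg_rms_uv: float = 30.0
    drift_uv: float = 8.0
    cardiac_freq_hz: float = 1.1
    cardiac_uv_eeg: float = 4.0
    cardiac_uv_artifact: float = 120.0
    spike_fraction: float = 0.01
    band: tuple = (1.0, 60.0)
    region_labels: tuple = ("thalamus", "pfc", "precuneus")
    null: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_regions", "n_scans", "n_eeg_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if len(self.gsw_gains) != self.n_regions:
            raise ValueError("gsw_gains must have one entry per region")


@dataclass
class SyntheticSubject:
    """Ground truth and observables for one synthetic subject."""

    subject_id: int
    A: np.ndarray
    states: np.ndarray  # scans x regions, at scan times
    bold: BoldSeries
    eeg: EegRecording
    true_omega: np.ndarray  # channels x scans, from the target spectra
    confounds: dict
    spike_scans: np.ndarray
    gsw_blocks: list
    mixing: np.ndarray
    state_to_mv: float


def sample_connectivity(
    n_regions: int, scale: float = 0.3, seed: int | None = None, max_tries: int = 100
) -> ConnectivityParams:
    """Random stable connectivity: off-diagonals ~ N(0, scale^2) Hz,
    self-connections fixed at -1 Hz, redrawn until all eigenvalues have
    negative real part."""
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        a = scale * rng.standard_normal((n_regions, n_regions))
        np.fill_diagonal(a, -1.0)
        if np.all(np.linalg.eigvals(a).real < 0):
            return ConnectivityParams(A=a)
    raise RuntimeError(f"no stable connectivity found in {max_tries} draws")


def _gsw_blocks(spec: CohortSpec, rng: np.random.Generator) -> list:
    """Block onsets/lengths (in scans), roughly evenly spread with jitter."""
    lengths = [spec.gsw_block_scans[i % len(spec.gsw_block_scans)] for i in range(spec.gsw_n_blocks)]
    slots = np.linspace(30, spec.n_scans - 40, spec.gsw_n_blocks)
    blocks = []
    for c, ln in zip(slots, lengths):
        onset = int(c + rng.integers(-10, 11))
        onset = max(5, min(onset, spec.n_scans - ln - 5))
        blocks.append((onset, ln))
    return blocks


def synthesize_eeg(
    states: np.ndarray,
    mixing: np.ndarray,
    spec: CohortSpec,
    params: nf.NeuralFieldParams | None = None,
    seed: int | None = None,
    state_to_mv: float | None = None,
    baseline_mv: float | None = None,
    basis: nf.ModeBasis | None = None,
    return_true_omega: bool = False,
):
    """Generate multichannel EEG whose windowed spectrum follows the
    neural-field forward model at the current slow-state amplitudes.

    For scan ``s`` and channel ``c`` the target spectrum is
    ``Q_c(w) = sum_j M_cj P(w; z1 = z0 + s_mv * x_j)`` plus the channel's
    artifact spectrum; it is realized by shaping white noise in the
    frequency domain with ``sqrt(Q)`` over 50 %-overlap Hann windows
    (hop = TR), then adding drift and cardiac components in the time
    domain.  Rows of ``mixing`` for artifact (EOG/ECG) channels must be
    zero; negative mixing weights are rejected.
    """
    params = params or nf.NeuralFieldParams()
    basis = basis or nf.ModeBasis()
    states = np.atleast_2d(np.asarray(states, dtype=float))
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if np.any(mixing < 0):
        raise ValueError("mixing weights must be nonnegative")
    n_scans, n_regions = states.shape
    n_channels = mixing.shape[0]
    if mixing.shape[1] != n_regions:
        raise ValueError("mixing must be channels x regions")
    rng = np.random.default_rng(seed)
    fs = spec.eeg_fs
    hop = int(round(spec.tr * fs))
    win = 2 * hop
    n_samp = n_scans * hop

    if baseline_mv is None:
        baseline_mv = spec.baseline_mv
    if state_to_mv is None:
        state_to_mv = (0.95 * params.chi - baseline_mv) / max(np.abs(states).max(), 1e-12)
    z1 = baseline_mv + state_to_mv * states  # scans x regions, mV

    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    pos = freqs > 0
    # region spectra per scan (unique z1 values evaluated vectorized)
    flat = z1.ravel()
    p_flat = np.zeros((flat.size, freqs.size))
    p_flat[:, pos] = nf.power_spectrum_grid(flat, freqs[pos], basis, params)
    p_scan = p_flat.reshape(n_scans, n_regions, freqs.size)
    q = np.einsum("cr,srf->scf", mixing, p_scan)  # scans x channels x freqs

    # scale the target spectra so neural channels come out at the target
    # RMS: one window of shaped noise has variance ~ sum_k Q_k / win, and
    # the 50 %-overlap squared-Hann windows sum to 3/4
    neural = np.array([np.any(mixing[c] > 0) for c in range(n_channels)])
    if np.any(neural):
        var_now = 0.75 * q[:, neural, :].sum(axis=-1).mean() / win
        if var_now > 0:
            q = q * (spec.eeg_rms_uv**2 / var_now)

    taper = np.hanning(win)
    x = np.zeros((n_channels, n_samp + win))
    for s in range(n_scans):
        noise = rng.standard_normal((n_channels, win))
        spec_noise = np.fft.rfft(noise, axis=1)
        shaped = np.fft.irfft(spec_noise * np.sqrt(q[s]), n=win, axis=1)
        x[:, s * hop : s * hop + win] += shaped * taper[None, :]
    x = x[:, hop // 2 : hop // 2 + n_samp]  # center-align windows on scans

    t = np.arange(n_samp) / fs
    # slow drift: random-walk low-pass realization per channel
    drift = np.cumsum(rng.standard_normal((n_channels, n_samp)), axis=1)
    drift -= drift.mean(axis=1, keepdims=True)
    denom = np.maximum(drift.std(axis=1, keepdims=True), 1e-12)
    x += spec.drift_uv * drift / denom
    # cardiac: frequency-wandering oscillation, strong on artifact channels
    freq_walk = spec.cardiac_freq_hz + 0.05 * np.cumsum(rng.standard_normal(n_samp)) / np.sqrt(n_samp)
    phase = 2.0 * np.pi * np.cumsum(freq_walk) / fs
    is_artifact = ~np.array([np.any(mixing[c] > 0) for c in range(n_channels)])
    card_amp = np.where(is_artifact, spec.cardiac_uv_artifact, spec.cardiac_uv_eeg)
    x += card_amp[:, None] * np.sin(phase)[None, :]

    labels = tuple(
        [f"eeg{i + 1}" for i in range(spec.n_eeg_channels)]
        + ["eog", "ecg"][: spec.n_artifact_channels]
    )[:n_channels]
    kind = tuple(
        ["eeg"] * spec.n_eeg_channels + ["eog", "ecg"][: spec.n_artifact_channels]
    )[:n_channels]
    rec = EegRecording(samples=x, fs=fs, labels=labels, kind=kind)
    if not return_true_omega:
        return rec
    # ground-truth center frequency from the neural part of the target
    # spectra, band-limited like the analysis
    lo, hi = spec.band
    bandsel = (freqs >= lo) & (freqs <= hi)
    fb = freqs[bandsel]
    qn = q[:, :, bandsel]
    tot = np.trapezoid(qn, fb, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega_true = np.trapezoid(qn * fb, fb, axis=-1) / np.where(tot > 0, tot, np.nan)
    return rec, omega_true.T  # channels x scans


def _motion_confounds(n_scans: int, rng: np.random.Generator) -> np.ndarray:
    """Realignment-like nuisance set: 6 smooth random-walk parameters plus
    their derivatives and squares (24 columns)."""
    base = np.cumsum(rng.standard_normal((n_scans, 6)), axis=0)
    kernel = np.ones(9) / 9.0
    base = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, base)
    base -= base.mean(axis=0)
    base /= np.maximum(base.std(axis=0), 1e-12)
    deriv = np.vstack([np.zeros(6), np.diff(base, axis=0)])
    return np.column_stack([base, deriv, base**2, deriv**2])


def _cardiac_confounds(n_scans: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Cardiac and respiratory phase regressors (4 harmonics each, 16
    columns) plus pulse-amplitude traces, RETROICOR-style."""
    cols = []
    for f0, jitter in ((1.1, 0.05), (0.3, 0.02)):
        freq = f0 + jitter * np.cumsum(rng.standard_normal(n_scans)) / np.sqrt(n_scans)
        phase = 2.0 * np.pi * np.cumsum(freq) * tr
        for h in (1, 2, 3, 4):
            cols += [np.sin(h * phase), np.cos(h * phase)]
        cols.append(freq - freq.mean())
    return np.column_stack(cols)


def simulate_subject(spec: CohortSpec, subject_seed: int, subject_id: int = 0) -> SyntheticSubject:
    """Simulate one subject: connectivity, states, BOLD, EEG, confounds.

    With ``spec.null`` the EEG mixing of neural states is zeroed (the EEG
    carries artifact and stationary background only), which makes the
    cohort a negative control for the validation GLM.
    """
    rng = np.random.default_rng(subject_seed)
    conn = sample_connectivity(
        spec.n_regions, spec.coupling_scale, seed=int(rng.integers(2**31))
    )
    blocks = _gsw_blocks(spec, rng)
    drive = np.zeros((spec.n_scans, spec.n_regions))
    gains = np.asarray(spec.gsw_gains, dtype=float)
    for onset, ln in blocks:
        drive[onset : onset + ln] = spec.gsw_amplitude * gains

    traj, bold_clean = integrate_generative(
        conn,
        HemodynamicParams(),
        state_noise_sd=spec.state_noise_sd,
        drive=drive,
        n_scans=spec.n_scans,
        TR=spec.tr,
        dt=0.01,
        seed=int(rng.integers(2**31)),
    )
    steps_per_tr = int(round(spec.tr / 0.01))
    states = traj.x_n[:: steps_per_tr][: spec.n_scans]

    noise_sd = bold_clean.y.std(axis=0).mean() / spec.measurement_snr
    y = bold_clean.y + noise_sd * rng.standard_normal(bold_clean.y.shape)

    # scan-nulling: a small fraction of volumes corrupted by motion
    n_spikes = int(round(spec.spike_fraction * spec.n_scans))
    spike_scans = np.sort(rng.choice(spec.n_scans, size=n_spikes, replace=False))
    y[spike_scans] += 5.0 * noise_sd * rng.standard_normal((n_spikes, spec.n_regions))
    bold = BoldSeries(times=bold_clean.times, y=y, TR=spec.tr, region_labels=spec.region_labels)

    n_channels = spec.n_eeg_channels + spec.n_artifact_channels
    mixing = np.zeros((n_channels, spec.n_regions))
    mixing[: spec.n_eeg_channels] = 0.3 + rng.random((spec.n_eeg_channels, spec.n_regions))
    if spec.null:
        mixing[:] = 0.0

    chi = nf.NeuralFieldParams().chi
    state_to_mv = (
        spec.state_to_mv
        if spec.state_to_mv is not None
        else (0.95 * chi - spec.baseline_mv) / max(np.abs(states).max(), 1e-12)
    )
    eeg, true_omega = synthesize_eeg(
        states,
        mixing,
        spec,
        seed=int(rng.integers(2**31)),
        state_to_mv=state_to_mv,
        baseline_mv=spec.baseline_mv,
        return_true_omega=True,
    )

    confounds = {
        "motion": _motion_confounds(spec.n_scans, rng),
        "cardiac": _cardiac_confounds(spec.n_scans, spec.tr, rng),
        "eye": np.column_stack(
            [np.cumsum(rng.standard_normal(spec.n_scans)) for _ in range(4)]
        ),
        "spikes": spike_scans,
    }
    return SyntheticSubject(
        subject_id=subject_id,
        A=conn.A,
        states=states,
        bold=bold,
        eeg=eeg,
        true_omega=true_omega,
        confounds=confounds,
        spike_scans=spike_scans,
        gsw_blocks=blocks,
        mixing=mixing,
        state_to_mv=state_to_mv,
    )


def make_cohort(
    spec: CohortSpec | None = None,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> list[SyntheticSubject]:
    """Simulate the full cohort; per-subject seeds are spawned
    deterministically from the master seed.

    If ``out_dir`` is given, writes per-subject BOLD TSV, EEG TSV (+ JSON
    sidecar), confound TSVs and a manifest JSON with the ground truth.
    """
    spec = spec or CohortSpec()
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_subjects) % (2**31)
    subjects = [
        simulate_subject(spec, int(s), subject_id=i) for i, s in enumerate(seeds)
    ]
    if out_dir is not None:
        _write_cohort(spec, subjects, Path(out_dir), force)
    return subjects


def _write_cohort(spec: CohortSpec, subjects: list, out: Path, force: bool) -> None:
    import pandas as pd

    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"spec": asdict(spec), "subjects": []}
    for sub in subjects:
        sdir = out / f"sub-{sub.subject_id + 1:02d}"
        sdir.mkdir(exist_ok=True)
        bold_df = pd.DataFrame(
            {"time_s": sub.bold.times, **{l: sub.bold.y[:, i] for i, l in enumerate(spec.region_labels)}}
        )
        bold_df.to_csv(sdir / "bold.tsv", sep="\t", index=False)
        (sdir / "bold.json").write_text(
            json.dumps({"TR": spec.tr, "units": "%", "regions": list(spec.region_labels)})
        )
        eeg_df = pd.DataFrame(sub.eeg.samples.T, columns=list(sub.eeg.labels))
        eeg_df.to_csv(sdir / "eeg.tsv", sep="\t", index=False, float_format="%.3f")
        (sdir / "eeg.json").write_text(
            json.dumps({"fs": spec.eeg_fs, "labels": list(sub.eeg.labels), "kind": list(sub.eeg.kind)})
        )
        for name in ("motion", "cardiac", "eye"):
            pd.DataFrame(sub.confounds[name]).to_csv(
                sdir / f"confound_{name}.tsv", sep="\t", index=False
            )
        manifest["subjects"].append(
            {
                "id": sub.subject_id,
                "dir": sdir.name,
                "A": sub.A.tolist(),
                "gsw_blocks": [list(map(int, b)) for b in sub.gsw_blocks],
                "spike_scans": sub.spike_scans.tolist(),
                "state_to_mv": sub.state_to_mv,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
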