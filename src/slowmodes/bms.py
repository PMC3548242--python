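"""Group-level random-effects Bayesian model selection (RFX-BMS).

Given a subjects x models matrix of log evidences, a variational
Dirichlet-multinomial scheme estimates the population frequency of each
model: subject-wise model responsibilities are softmaxed log evidences
augmented with digamma terms, and the Dirichlet concentrations accumulate
the responsibilities.  On top of the model-level posterior:

* *exceedance probabilities* — the probability that one model (or family
  of models) is more frequent than every alternative, computed exactly via
  the Beta distribution in the two-way case (Dirichlet aggregation makes
  family-level questions two-way as well) and by seeded Monte-Carlo
  sampling otherwise;
* *family inference* — models are partitioned into families (here: with
  vs without the neural states, marginalizing over confound sets); the
  prior is reallocated uniformly over families, frequencies are summed
  within families;
* the *Bayesian omnibus test* — the posterior probability that all models
  are equally frequent, from the free-energy difference between the RFX
  model and the fixed-equal-frequency null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "EvidenceMatrix",
    "BmsResult",
    "rfx_bms",
    "exceedance_probability",
    "family_inference",
    "bayesian_omnibus",
    "RandomEffectsBMS",
]


@dataclass
class EvidenceMatrix:
    """Log evidences, subjects x models, with model labels."""

    log_evidence: np.ndarray
    models: tuple = ()

    def __post_init__(self) -> None:
        self.log_evidence = np.atleast_2d(np.asarray(self.log_evidence, dtype=float))
        if not np.all(np.isfinite(self.log_evidence)):
            raise ValueError("log evidences must be finite")
        if self.log_evidence.shape[1] < 2:
            raise ValueError("need at least two models")
        if not self.models:
            self.models = tuple(f"m{i}" for i in range(self.log_evidence.shape[1]))
        if len(self.models) != self.log_evidence.shape[1]:
            raise ValueError("model labels must match the number of columns")

    @property
    def n_subjects(self) -> int:
        return self.log_evidence.shape[0]

    @property
    def n_models(self) -> int:
        return self.log_evidence.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log_evidence, columns=list(self.models))


@dataclass
class BmsResult:
    """Posterior over model (or family) frequencies."""

    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance: np.ndarray
    labels: tuple
    free_energy: float
    responsibilities: np.ndarray
    family_alpha: np.ndarray | None = None
    family_frequency: np.ndarray | None = None
    family_exceedance: np.ndarray | None = None
    family_labels: tuple = ()
    omnibus: float | None = None

    def summary(self) -> str:
        lines = ["Random-effects BMS", "=" * 40]
        for l, a, f, e in zip(self.labels, self.alpha, self.expected_frequency, self.exceedance):
            lines.append(f"  {l:>12}: alpha={a:7.3f}  freq={f:6.3f}  EP={e:6.3f}")
        if self.family_alpha is not None:
            lines.append("families:")
            for l, a, f, e in zip(
                self.family_labels, self.family_alpha, self.family_frequency, self.family_exceedance
            ):
                lines.append(f"  {l:>12}: alpha={a:7.3f}  freq={f:6.3f}  EP={e:6.3f}")
        if self.omnibus is not None:
            lines.append(f"P(all frequencies equal) = {self.omnibus:.4f}")
        return "\n".join(lines)


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, max_iter: int = 10_000, tol: float = 1e-6):
    """Variational updates of the Dirichlet-multinomial RFX model."""
    n, k = lme.shape
    alpha = alpha0.copy().astype(float)
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logu = lme + (special.digamma(alpha) - special.digamma(alpha.sum()))[None, :]
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError("RFX-BMS did not converge")
    # free energy of the RFX model (constant terms of the multinomial
    # likelihood cancel against the null model in the omnibus test)
    dig = special.digamma(alpha) - special.digamma(alpha.sum())
    f = (
        special.gammaln(alpha0.sum())
        - special.gammaln(alpha0).sum()
        - special.gammaln(alpha.sum())
        + special.gammaln(alpha).sum()
        + float(np.sum((alpha0 - alpha + u.sum(axis=0)) * dig))
        + float(np.sum(u * (lme - np.log(np.maximum(u, 1e-300)))))
    )
    return alpha, u, f


def rfx_bms(ev: EvidenceMatrix, alpha0: float | np.ndarray = 1.0, seed: int = 0) -> BmsResult:
    """Model-level random-effects BMS.

    ``alpha0`` is the symmetric prior concentration (scalar) or a full
    prior concentration vector.  Requires at least two subjects.
    """
    if ev.n_subjects < 2:
        raise ValueError("random-effects BMS needs at least two subjects")
    a0 = (
        np.full(ev.n_models, float(alpha0))
        if np.ndim(alpha0) == 0
        else np.asarray(alpha0, dtype=float)
    )
    if a0.shape != (ev.n_models,) or np.any(a0 <= 0):
        raise ValueError("invalid prior concentrations")
    alpha, u, f = _vb_dirichlet(ev.log_evidence, a0)
    ep = exceedance_probability(alpha, seed=seed)
    return BmsResult(
        alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance=ep,
        labels=ev.models,
        free_energy=f,
        responsibilities=u,
    )


def exceedance_probability(
    alpha: np.ndarray,
    partition: list | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Probability that each (family-aggregated) frequency exceeds all
    others under a Dirichlet posterior.

    Aggregation over a partition is exact (sums of Dirichlet components
    are Dirichlet in the aggregated concentrations).  The two-way case
    uses the exact Beta tail probability; otherwise seeded Monte Carlo.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("concentrations must be positive")
    if partition is not None:
        groups = [np.asarray(g, dtype=int) for g in partition]
        flat = np.concatenate(groups)
        if len(set(flat.tolist())) != flat.size or flat.size != alpha.size:
            raise ValueError("partition must cover all models and be disjoint")
        alpha = np.array([alpha[g].sum() for g in groups])
    k = alpha.size
    if k == 2:
        # r1 ~ Beta(a1, a2); EP1 = P(r1 > 1/2)
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    win = np.argmax(draws, axis=1)
    return np.bincount(win, minlength=k) / float(n_samples)


def family_inference(
    ev: EvidenceMatrix,
    partition: dict,
    seed: int = 0,
) -> BmsResult:
    """Family-level inference: uniform prior mass over families (split
    equally within each family), model-level VB, frequencies summed within
    families and family exceedance probabilities.

    ``partition`` maps family labels to lists of model labels; it must
    cover all models exactly once.
    """
    idx = {m: j for j, m in enumerate(ev.models)}
    fam_labels = tuple(partition.keys())
    groups = []
    for fam in fam_labels:
        members = partition[fam]
        groups.append(np.array([idx[m] for m in members], dtype=int))
    flat = np.concatenate(groups)
    if len(set(flat.tolist())) != flat.size or flat.size != ev.n_models:
        raise ValueError("partition must cover all models exactly once")
    a0 = np.empty(ev.n_models)
    for g in groups:
        a0[g] = 1.0 / g.size
    res = rfx_bms(ev, alpha0=a0, seed=seed)
    fam_alpha = np.array([res.alpha[g].sum() for g in groups])
    fam_freq = np.array([res.expected_frequency[g].sum() for g in groups])
    fam_ep = exceedance_probability(res.alpha, partition=[g for g in groups], seed=seed)
    res.family_alpha = fam_alpha
    res.family_frequency = fam_freq
    res.family_exceedance = fam_ep
    res.family_labels = fam_labels
    res.omnibus = bayesian_omnibus(ev)
    return res


def bayesian_omnibus(ev: EvidenceMatrix) -> float:
    """Posterior probability that all models are equally frequent.

    Compares the free energy of the RFX Dirichlet model (uniform prior)
    with the null model in which every subject's data are explained by an
    equal mixture of the models:
    ``p = 1 / (1 + exp(F_rfx - F_null))``.
    """
    a0 = np.ones(ev.n_models)
    _, _, f_rfx = _vb_dirichlet(ev.log_evidence, a0)
    f_null = float(
        np.sum(special.logsumexp(ev.log_evidence - np.log(ev.n_models), axis=1))
    )
    return float(1.0 / (1.0 + np.exp(f_rfx - f_null)))


class RandomEffectsBMS:
    """Model-object wrapper: ``RandomEffectsBMS(ev, families=...).fit()``."""

    def __init__(
        self,
        ev: EvidenceMatrix,
        families: dict | None = None,
        alpha0: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.ev = ev
        self.families = families
        self.alpha0 = alpha0
        self.seed = seed

    def fit(self) -> BmsResult:
        if self.families:
            return family_inference(self.ev, self.families, seed=self.seed)
        res = rfx_bms(self.ev, alpha0=self.alpha0, seed=self.seed)
        res.omnibus = bayesian_omnibus(self.ev)
        return res
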