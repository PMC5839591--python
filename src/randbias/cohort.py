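"""Synthetic expression–survival cohorts.

Three generative structures cover the mechanisms invoked to explain the
random-bias phenomenon:

``null``
    Expression iid Gaussian and independent of survival — the calibration
    condition under which random gene sets should be significant 5% of the
    time.
``global_signature``
    A latent per-sample meta-gene (think proliferation activity) loads on a
    stated fraction of genes and drives the hazard proportionally — the
    positive-bias mechanism.
``subclasses``
    Discrete sample classes with diffuse differential expression across a
    fraction of the genome and per-class hazards — with equal hazards this
    produces negative bias (consistent splits with identical survival), with
    unequal hazards positive bias that sub-classification removes.

Survival is exponential with independent exponential censoring, so event
fractions have the closed form ``hazard / (hazard + censoring_rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, SurvivalTable

__all__ = [
    "SyntheticCohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_assignment_cohort",
]

STRUCTURES = ("null", "global_signature", "subclasses")


@dataclass
class SyntheticCohortSpec:
    """Generative recipe for one synthetic cohort.

    Defaults give a mid-sized cohort (300 samples x 2000 genes) with a
    baseline hazard of 0.01 per day and exponential censoring at one third
    of that rate, i.e. ~25% censored — a follow-up pattern typical of the
    better-powered TCGA cohorts.
    """

    n_samples: int = 300
    n_genes: int = 2000
    structure: str = "null"
    signature_fraction: float = 0.0
    loading_sd: float = 1.0
    n_subclasses: int = 1
    mixing: tuple[float, ...] = (1.0,)
    de_fraction: float = 0.0
    de_effect: float = 0.0
    baseline_hazard: float = 0.01
    log_hazard_ratio: float = 0.0
    per_class_log_hazard: tuple[float, ...] = (0.0,)
    censoring_rate: float = 0.01 / 3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0 <= self.signature_fraction <= 1:
            raise ValueError("signature_fraction must be in [0, 1]")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.loading_sd < 0 or self.de_effect < 0:
            raise ValueError("loading_sd and de_effect must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate <= 0:
            raise ValueError("censoring_rate must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_subclasses < 1:
            raise ValueError("n_subclasses must be >= 1")
        self.mixing = tuple(float(m) for m in self.mixing)
        self.per_class_log_hazard = tuple(float(h) for h in self.per_class_log_hazard)
        if len(self.mixing) != self.n_subclasses:
            raise ValueError("mixing length must equal n_subclasses")
        if len(self.per_class_log_hazard) != self.n_subclasses:
            raise ValueError("per_class_log_hazard length must equal n_subclasses")
        if abs(sum(self.mixing) - 1.0) > 1e-12:
            raise ValueError("mixing must sum to 1")
        if self.structure == "null" and (
            self.signature_fraction != 0 or self.de_fraction != 0
        ):
            raise ValueError("structure='null' forces signature_fraction=de_fraction=0")


@dataclass
class CohortTruth:
    """Ground truth stored with a generated cohort (never recomputed)."""

    latent: np.ndarray | None
    subclass: np.ndarray | None
    signature_genes: np.ndarray
    de_genes: np.ndarray


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    truth: CohortTruth
    spec: SyntheticCohortSpec


def _survival_from_hazard(
    hazard: np.ndarray, censoring_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / censoring_rate, size=hazard.shape)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return time, event


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate one cohort from a :class:`SyntheticCohortSpec`.

    A fixed spec (including seed) yields a bit-identical cohort. Expression
    is marked ``log_transformed`` since synthetic values are Gaussian and
    may be negative.
    """
    rng = np.random.default_rng(spec.seed)
    g, n = spec.n_genes, spec.n_samples
    X = rng.normal(0.0, spec.noise_sd, size=(g, n))
    latent: np.ndarray | None = None
    subclass: np.ndarray | None = None
    sig_genes = np.empty(0, dtype=int)
    de_genes = np.empty(0, dtype=int)

    if spec.structure == "null":
        hazard = np.full(n, spec.baseline_hazard)
    elif spec.structure == "global_signature":
        latent = rng.normal(size=n)
        n_sig = int(round(spec.signature_fraction * g))
        sig_genes = np.sort(rng.choice(g, size=n_sig, replace=False))
        loadings = rng.normal(0.0, spec.loading_sd, size=n_sig)
        X[sig_genes] += loadings[:, None] * latent[None, :]
        hazard = spec.baseline_hazard * np.exp(spec.log_hazard_ratio * latent)
    else:  # subclasses
        subclass = rng.choice(spec.n_subclasses, size=n, p=spec.mixing)
        n_de = int(round(spec.de_fraction * g))
        de_genes = np.sort(rng.choice(g, size=n_de, replace=False))
        # each DE gene gets its own random high/low pattern over classes so
        # that class signal is diffuse and no gene is a perfect marker
        patterns = rng.integers(0, 2, size=(n_de, spec.n_subclasses))
        constant = patterns.min(axis=1) == patterns.max(axis=1)
        while constant.any():
            patterns[constant] = rng.integers(
                0, 2, size=(int(constant.sum()), spec.n_subclasses)
            )
            constant = patterns.min(axis=1) == patterns.max(axis=1)
        shift = spec.de_effect * spec.noise_sd
        X[de_genes] += shift * patterns[:, subclass]
        hazard = spec.baseline_hazard * np.exp(
            np.asarray(spec.per_class_log_hazard)[subclass]
        )

    time, event = _survival_from_hazard(hazard, spec.censoring_rate, rng)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        X, [f"G{i:05d}" for i in range(g)], sample_ids, log_transformed=True
    )
    surv = SurvivalTable(sample_ids, time, event)
    truth = CohortTruth(latent, subclass, sig_genes, de_genes)
    return SyntheticCohort(expr, surv, truth, spec)


def generate_null_assignment_cohort(
    n_samples: int, baseline_hazard: float, censoring_rate: float, seed: int
) -> SurvivalTable:
    """Survival-only cohort for null calibration (no expression needed).

    Exponential event times with independent exponential censoring; the
    expected event fraction is ``baseline_hazard / (baseline_hazard +
    censoring_rate)``.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if baseline_hazard <= 0 or censoring_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    hazard = np.full(n_samples, baseline_hazard)
    time, event = _survival_from_hazard(hazard, censoring_rate, rng)
    return SurvivalTable([f"S{i:04d}" for i in range(n_samples)], time, event)
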