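"""Synthetic time-use cohorts with the statistical structure the models assume.

The generator emulates a free-living accelerometer cohort: each subject
has a latent 5-part wake-time composition drawn logistic-normally around
a cohort center; a label stream is built by alternately drawing a
behavior class (with probability proportional to the time share still
owed to it) and a lognormal sequence duration; health outcomes follow a
compositional linear model

    Y_i = alpha + <beta, x_i>_A + gamma . z_i + eps_i,

where beta is the direction composition powered by its Aitchison norm and
<.,.>_A is the Aitchison inner product.

One global seed fans out deterministically: ``numpy.random.SeedSequence(seed)``
is spawned into independent child streams, one per subject for streams and
one each for compositions, covariates and outcome noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    aitchison_norm,
    clr,
    clr_inv,
    close,
    neutral,
    power,
)
from .streams import BEHAVIORS, BehaviorStream

__all__ = ["SimulationTruth", "SyntheticCohort", "generate_stream", "generate_cohort", "generate_outcomes", "default_truth"]

#: cohort center: closed geometric mean of the wake-time composition
#: (lie, sit, stand, LPA, MVPA)
DEFAULT_MEAN_COMPOSITION = np.array([0.0564, 0.5472, 0.2794, 0.0364, 0.0801])
DEFAULT_MEAN_COMPOSITION = DEFAULT_MEAN_COMPOSITION / DEFAULT_MEAN_COMPOSITION.sum()

#: lognormal (mu, sigma) of sequence durations, seconds, per behavior.
#: Chosen so that default streams land in realistic ranges: sedentary and
#: standing time accumulates through few long and many short sequences
#: (class-set Gini ~0.7-0.85), MVPA through shorter, more even sequences
#: (Gini ~0.5-0.65), with median bout lengths of a few minutes.
DEFAULT_DURATION_PARAMS = {
    "LIE": (5.8, 1.7),
    "SIT": (5.2, 1.8),
    "STAND": (4.8, 1.5),
    "LPA": (3.8, 1.0),
    "MVPA": (3.5, 1.1),
}

COVARIATE_COLUMNS = ("sex", "age", "income", "education", "nutrition1", "nutrition2")


@dataclass
class SimulationTruth:
    """Ground-truth parameters of the synthetic cohort.

    mean_composition: cohort center on the simplex (sums to 1).
    clr_dispersion: 5x5 PSD matrix; logistic-normal scatter of subject
        compositions in clr space.
    duration_params: per-behavior lognormal (mu, sigma) of sequence
        durations in seconds.
    alpha / beta_direction / beta_norm / gamma / sigma_eps: the outcome
        model — intercept, unit-Aitchison-norm direction composition,
        coefficient magnitude, covariate coefficients, residual SD.
    epoch_length_s, n_days, day_hours: stream geometry.
    """

    mean_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_MEAN_COMPOSITION.copy()
    )
    clr_dispersion: np.ndarray = field(default_factory=lambda: 0.25 * np.eye(5))
    duration_params: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_PARAMS))
    alpha: float = 100.0
    beta_direction: np.ndarray = field(
        default_factory=lambda: close(np.array([0.2183, 0.3025, 0.1347, 0.2551, 0.0895]))
    )
    beta_norm: float = 0.29
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(len(COVARIATE_COLUMNS)))
    sigma_eps: float = 1.0
    epoch_length_s: float = 1.0
    n_days: int = 7
    day_hours: float = 14.0

    def __post_init__(self):
        self.mean_composition = np.asarray(self.mean_composition, dtype=float)
        self.clr_dispersion = np.asarray(self.clr_dispersion, dtype=float)
        self.beta_direction = np.asarray(self.beta_direction, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.mean_composition <= 0):
            raise ValueError("mean_composition must be strictly positive")
        if abs(self.mean_composition.sum() - 1.0) > 1e-9:
            raise ValueError("mean_composition must sum to 1")
        # direction is stored closed; its clr must have unit Euclidean norm
        nrm = aitchison_norm(self.beta_direction)
        if abs(nrm - 1.0) > 1e-6:
            if nrm == 0:
                raise ValueError("beta_direction cannot be the neutral element")
            self.beta_direction = clr_inv(clr(self.beta_direction) / nrm)
        if self.beta_norm < 0:
            raise ValueError("beta_norm must be nonnegative")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be nonnegative")
        for b, (mu, sigma) in self.duration_params.items():
            if sigma <= 0:
                raise ValueError(f"duration sigma for {b} must be positive")
        # symmetric PSD check
        S = self.clr_dispersion
        if S.shape != (5, 5) or np.abs(S - S.T).max() > 1e-8:
            raise ValueError("clr_dispersion must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(S).min() < -1e-8:
            raise ValueError("clr_dispersion must be positive semidefinite")

    @property
    def epochs_per_day(self) -> int:
        return int(round(self.day_hours * 3600.0 / self.epoch_length_s))

    @property
    def beta(self) -> np.ndarray:
        """The full coefficient composition: direction powered by the norm."""
        if self.beta_norm == 0:
            return neutral(5)
        return power(self.beta_norm, self.beta_direction)

    def to_file(self, path) -> None:
        """Serialize to YAML (arrays become lists)."""
        import yaml

        data = {
            "mean_composition": self.mean_composition.tolist(),
            "clr_dispersion": self.clr_dispersion.tolist(),
            "duration_params": {k: list(v) for k, v in self.duration_params.items()},
            "alpha": self.alpha,
            "beta_direction": self.beta_direction.tolist(),
            "beta_norm": self.beta_norm,
            "gamma": self.gamma.tolist(),
            "sigma_eps": self.sigma_eps,
            "epoch_length_s": self.epoch_length_s,
            "n_days": self.n_days,
            "day_hours": self.day_hours,
        }
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_file(cls, path) -> "SimulationTruth":
        import yaml
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text())
        if "duration_params" in data:
            data["duration_params"] = {k: tuple(v) for k, v in data["duration_params"].items()}
        return cls(**data)


@dataclass
class SyntheticCohort:
    streams: list
    compositions: pd.DataFrame  # latent target composition per subject
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: SimulationTruth


def default_truth(**overrides) -> SimulationTruth:
    return SimulationTruth(**overrides)


def generate_stream(
    truth: SimulationTruth, subject_composition, rng_or_seed, subject_id: str = "s0"
) -> BehaviorStream:
    """Build one subject's label stream.

    Alternately samples a behavior (probability proportional to the time
    share still owed to it, so realized shares converge to the target) and
    a lognormal duration rounded to whole epochs (minimum one), truncating
    runs at day boundaries.
    """
    x = np.asarray(subject_composition, dtype=float)
    if np.any(x <= 0):
        raise ValueError("subject composition must be strictly positive")
    x = x / x.sum()
    rng = np.random.default_rng(rng_or_seed)

    epd = truth.epochs_per_day
    total = truth.n_days * epd
    target = x * total
    realized = np.zeros(5)
    mus = np.array([truth.duration_params[b][0] for b in BEHAVIORS])
    sigmas = np.array([truth.duration_params[b][1] for b in BEHAVIORS])

    labels = np.empty(total, dtype=object)
    pos = 0
    while pos < total:
        deficit = np.maximum(target - realized, 0.0)
        probs = deficit if deficit.sum() > 0 else target.copy()
        probs = probs / probs.sum()
        k = rng.choice(5, p=probs)
        dur_s = rng.lognormal(mus[k], sigmas[k])
        n = max(1, int(round(dur_s / truth.epoch_length_s)))
        # cap at the class's remaining time deficit (so realized shares
        # track the target) and truncate at the day boundary
        if deficit[k] > 0:
            n = min(n, int(np.ceil(deficit[k])))
        day_end = (pos // epd + 1) * epd
        n = min(n, day_end - pos, total - pos)
        labels[pos : pos + n] = BEHAVIORS[k]
        realized[k] += n
        pos += n

    day_index = np.repeat(np.arange(truth.n_days), epd)[:total]
    return BehaviorStream(
        subject_id=subject_id,
        epoch_length_s=truth.epoch_length_s,
        labels=labels,
        day_index=day_index,
    )


def _draw_compositions(truth: SimulationTruth, n: int, rng) -> np.ndarray:
    mean_clr = clr(truth.mean_composition)
    noise = rng.multivariate_normal(np.zeros(5), truth.clr_dispersion, size=n)
    noise -= noise.mean(axis=1, keepdims=True)  # project onto the clr plane
    return np.stack([clr_inv(mean_clr + v) for v in noise])


def _draw_covariates(n: int, rng) -> pd.DataFrame:
    """Simple, documented distributions mirroring the cohort's scales:
    sex Bernoulli(0.64), age Normal(50.6, 9.6) clipped at 18, the rest
    standard Normal.  Purely for realism of the design matrix."""
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, 0.64, n).astype(float),
            "age": np.clip(rng.normal(50.6, 9.6, n), 18.0, None),
            "income": rng.normal(0.0, 1.0, n),
            "education": rng.normal(0.0, 1.0, n),
            "nutrition1": rng.normal(0.0, 1.0, n),
            "nutrition2": rng.normal(0.0, 1.0, n),
        }
    )


def generate_outcomes(compositions, covariates, truth: SimulationTruth, rng_or_seed) -> np.ndarray:
    """Outcomes from the compositional linear model; exactly linear in clr
    space (doubling beta_norm doubles the compositional term)."""
    X = np.asarray(compositions, dtype=float)
    if np.any(X <= 0):
        raise ValueError("compositions must be strictly positive")
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != X.shape[0]:
        raise ValueError("covariate table row count does not match compositions")
    rng = np.random.default_rng(rng_or_seed)
    beta_clr = truth.beta_norm * clr(truth.beta_direction)
    comp_term = np.stack([clr(row) for row in X]) @ beta_clr
    gamma = truth.gamma[: Z.shape[1]]
    eps = rng.normal(0.0, truth.sigma_eps, X.shape[0]) if truth.sigma_eps > 0 else 0.0
    return truth.alpha + comp_term + Z @ gamma + eps


def generate_cohort(
    truth: SimulationTruth, n_subjects: int, seed: int, with_streams: bool = True
) -> SyntheticCohort:
    """Draw a full synthetic cohort.

    Subject compositions are logistic-normal around the cohort center;
    covariates come from the documented simple distributions; outcomes from
    :func:`generate_outcomes`.  ``with_streams=False`` skips the (slow)
    label-stream construction when only compositions and outcomes are
    needed, e.g. for model-recovery simulations.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    root = np.random.SeedSequence(seed)
    ss_comp, ss_cov, ss_out, ss_streams = root.spawn(4)
    comps = _draw_compositions(truth, n_subjects, np.random.default_rng(ss_comp))
    covs = _draw_covariates(n_subjects, np.random.default_rng(ss_cov))
    y = generate_outcomes(comps, covs.to_numpy(), truth, np.random.default_rng(ss_out))

    ids = [f"s{i:04d}" for i in range(n_subjects)]
    streams = []
    if with_streams:
        for i, child in enumerate(ss_streams.spawn(n_subjects)):
            streams.append(
                generate_stream(truth, comps[i], np.random.default_rng(child), subject_id=ids[i])
            )
    comp_df = pd.DataFrame(comps, columns=[b.lower() for b in BEHAVIORS])
    comp_df.insert(0, "subject_id", ids)
    covs = covs.copy()
    covs.insert(0, "subject_id", ids)
    out_df = pd.DataFrame({"subject_id": ids, "outcome": y})
    return SyntheticCohort(streams, comp_df, covs, out_df, truth)
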