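"""Synthetic cohorts with the statistical structure the analysis assumes.

A cohort couples four layers:

1. child-level early predictors (binary prevalences or Normal mean/SD on the
   transformed scale of the descriptive table);
2. a latent trajectory class per child, drawn from a multinomial logistic
   model on the mean-centered predictors (reference class 1); with all
   class-logit coefficients zero the class marginals equal the stated
   proportions exactly;
3. an irregularly timed aggression panel: each of up to 21 scheduled waves
   gets a jittered age, is observed with a per-wave participation
   probability, and records the class's quartic curve value plus Normal
   noise — and, optionally, item responses drawn from the Rasch /
   partial-credit measurement model at that score;
4. four distal outcomes with class-specific means plus direct predictor
   effects and Normal residuals.

The defaults emulate the study conditions: 1,141 children, nine classes
with proportions (.14, .22, .16, .07, .05, .17, .09, .07, .03), roughly
twelve realized waves per child between ages 1 and 5 in two response
formats, and quartic class curves with the published qualitative taxonomy
(low-stable, medium-peak, high-start/low-endpoint, intermediate-endpoint,
high-stable with a peak near age 2.2).  The exact curve coefficients are
synthetic: the source figure prints no numbers, so the shipped matrix is a
hand-tuned reconstruction of the shapes, not measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from trajmix.lcga import AGE_CENTER, N_COEF
from trajmix.rasch import ItemBank

# ---------------------------------------------------------------------------
# config types
# ---------------------------------------------------------------------------


@dataclass
class Wave:
    """One scheduled measurement occasion."""

    target_age: float
    jitter_sd: float
    format: str  # "binary" | "7cat"
    missing_prob: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.target_age <= 5.5:
            raise ValueError("wave ages must lie in [0.5, 5.5]")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be a probability")
        if self.format not in ("binary", "7cat"):
            raise ValueError(f"unknown format {self.format!r}")


@dataclass
class PredictorSpec:
    name: str
    kind: str  # "binary" | "normal"
    prevalence: float | None = None
    mean: float | None = None
    sd: float | None = None
    transform: str | None = None  # descriptive tag only

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.prevalence is None or not 0 <= self.prevalence <= 1:
                raise ValueError(f"binary predictor {self.name!r} needs prevalence in [0,1]")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"normal predictor {self.name!r} needs mean and sd > 0")
        else:
            raise ValueError(f"unknown predictor kind {self.kind!r}")

    @property
    def expectation(self) -> float:
        return self.prevalence if self.kind == "binary" else self.mean


@dataclass
class OutcomeSpec:
    name: str
    class_means: np.ndarray  # length K
    direct_coefs: np.ndarray  # length P, raw scale, applied to centered predictors
    residual_sd: float

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.direct_coefs = np.asarray(self.direct_coefs, dtype=float)
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic cohort."""

    n_children: int
    class_proportions: np.ndarray
    growth_coefficients: np.ndarray  # K x 5 on the centered-age scale
    gamma: np.ndarray  # (K-1) x P multinomial effects on class (ref class 1)
    residual_sd: float
    schedule: list[Wave]
    predictor_specs: list[PredictorSpec]
    outcome_specs: list[OutcomeSpec]
    seed: int = 0
    include_items: bool = True
    item_bank: ItemBank | None = None

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.growth_coefficients = np.atleast_2d(np.asarray(self.growth_coefficients, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        K = len(self.class_proportions)
        if K < 1:
            raise ValueError("need at least one class")
        if abs(self.class_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1 (within 1e-12)")
        if np.any(self.class_proportions < 0) or np.any(self.class_proportions > 1):
            raise ValueError("class proportions must lie in [0, 1]")
        if self.growth_coefficients.shape != (K, N_COEF):
            raise ValueError(f"growth_coefficients must be K x {N_COEF}")
        P = len(self.predictor_specs)
        if self.gamma.size == 0:
            self.gamma = np.zeros((max(K - 1, 1), P))
        if K > 1 and self.gamma.shape != (K - 1, P):
            raise ValueError("gamma must be (K-1) x P")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for o in self.outcome_specs:
            if len(o.class_means) != K:
                raise ValueError(f"outcome {o.name!r} class_means length != K")
            if len(o.direct_coefs) != P:
                raise ValueError(f"outcome {o.name!r} direct_coefs length != P")

    @property
    def K(self) -> int:
        return len(self.class_proportions)

    def to_dict(self) -> dict:
        d = {
            "n_children": self.n_children,
            "class_proportions": self.class_proportions.tolist(),
            "growth_coefficients": self.growth_coefficients.tolist(),
            "gamma": self.gamma.tolist(),
            "residual_sd": self.residual_sd,
            "schedule": [asdict(w) for w in self.schedule],
            "predictor_specs": [asdict(p) for p in self.predictor_specs],
            "outcome_specs": [
                {
                    "name": o.name,
                    "class_means": o.class_means.tolist(),
                    "direct_coefs": o.direct_coefs.tolist(),
                    "residual_sd": o.residual_sd,
                }
                for o in self.outcome_specs
            ],
            "seed": self.seed,
            "include_items": self.include_items,
        }
        return d


@dataclass
class SyntheticCohort:
    """Generated data tables plus the ground truth behind them."""

    predictors: pd.DataFrame
    true_class: np.ndarray  # 1-based labels
    panel: pd.DataFrame
    item_responses: pd.DataFrame | None
    outcomes: pd.DataFrame
    dropped_children: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    config: SimulationConfig | None = None
    seed: int | None = None

    def write_csv(self, directory) -> None:
        """Panel (long), predictors (wide), outcomes (wide) + JSON sidecar."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        panel = self.panel if self.item_responses is None else self.item_responses
        panel.to_csv(d / "panel.csv", index=False)
        self.predictors.to_csv(d / "predictors.csv", index=False)
        self.outcomes.to_csv(d / "outcomes.csv", index=False)
        sidecar = {"seed": self.seed}
        if self.config is not None:
            sidecar["config"] = self.config.to_dict()
        (d / "cohort.json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# defaults: the study conditions
# ---------------------------------------------------------------------------

DEFAULT_PROPORTIONS = np.array([0.14, 0.22, 0.16, 0.07, 0.05, 0.17, 0.09, 0.07, 0.03])

# Anchor values of the nine class curves at five ages; the quartic through
# the anchors reproduces the qualitative taxonomy (see module docstring).
_ANCHOR_AGES = np.array([1.0, 1.6, 2.2, 3.5, 5.0])
_ANCHOR_VALUES = np.array(
    [
        [-4.5, -4.2, -4.0, -4.3, -4.6],   # 1 low-stable / no aggression
        [-4.0, -3.1, -2.7, -3.4, -4.2],   # 2 medium flat peak, low endpoint
        [-3.3, -1.7, -1.3, -2.8, -3.9],   # 3 early higher peak, low endpoint
        [-1.4, -1.8, -1.7, -2.3, -3.6],   # 4 high start, late flat peak, low endpoint
        [-0.7, -1.2, -1.0, -1.7, -3.2],   # 5 as 4 on a higher path
        [-3.6, -2.6, -2.0, -1.4, -2.1],   # 6 low start, late flat peak, elevated endpoint
        [-3.0, -1.0, -0.2, -1.2, -1.8],   # 7 low start, peak and decline, elevated endpoint
        [-1.0,  0.2,  0.7, -0.6, -1.5],   # 8 high start, high peak, elevated endpoint
        [-0.5,  1.4,  2.2,  2.1,  1.8],   # 9 high-stable
    ]
)


def _quartic_through(ages: np.ndarray, values: np.ndarray) -> np.ndarray:
    V = np.vander(ages - AGE_CENTER, N_COEF, increasing=True)
    return np.linalg.solve(V, values)


DEFAULT_B = np.array([_quartic_through(_ANCHOR_AGES, v) for v in _ANCHOR_VALUES])

DEFAULT_PREDICTORS = [
    PredictorSpec("child_gender", "binary", prevalence=0.52),
    PredictorSpec("similar_aged_sibling", "binary", prevalence=0.38),
    PredictorSpec("maternal_harsh_parenting", "normal", mean=-0.01, sd=0.47,
                  transform="center+trim"),
    PredictorSpec("paternal_harsh_parenting", "normal", mean=-0.01, sd=0.44,
                  transform="center+trim"),
    PredictorSpec("maternal_education", "normal", mean=0.0, sd=2.57, transform="center"),
    PredictorSpec("couple_relationship_rev", "normal", mean=0.70, sd=0.39,
                  transform="trim+reverse+recenter+sqrt"),
    PredictorSpec("maternal_dep_anx", "normal", mean=0.47, sd=0.32,
                  transform="trim+recenter+sqrt"),
    PredictorSpec("child_activity_level", "normal", mean=0.0, sd=0.27,
                  transform="center+trim"),
]

# Standardized (per predictor SD) class-vs-class-1 log-odds effects, columns
# follow DEFAULT_PREDICTORS; magnitudes echo the published unadjusted pattern.
_STD_GAMMA = np.array(
    # gender sibling  m.harsh p.harsh m.educ couple m.depanx activity
    [
        [0.59, 0.33, -0.64, 0.23, 0.15, -0.13, 0.09, -0.04],   # class 2
        [0.59, 0.37, 0.88, 0.51, 0.00, 0.21, 0.45, 0.06],      # class 3
        [0.47, 0.07, 0.68, 0.45, -0.27, -0.22, 0.30, 0.45],    # class 4
        [0.73, 0.55, 0.72, 0.48, 0.12, 0.23, 0.33, 0.35],      # class 5
        [0.80, 0.53, 0.65, 0.54, 0.13, 0.28, 0.32, -0.09],     # class 6
        [0.90, 0.90, 0.64, 0.75, 0.21, 0.17, 0.57, 0.18],      # class 7
        [0.76, 0.80, 1.15, 0.47, -0.24, 0.24, 0.63, 0.50],     # class 8
        [0.98, 1.00, 0.47, 1.00, -0.40, 0.45, 0.84, 0.37],     # class 9
    ]
)

DEFAULT_STD_GAMMA = _STD_GAMMA  # public alias: per-SD class-logit effects

# Outcome layer: overall mean / SD on the analysis scale, class standardized
# mean differences relative to class 1, and the class->outcome R used to set
# the residual SD.
_OUTCOMES = {
    "externalizing": (1.83, 1.21, [0, 0.32, 0.37, 0.47, 0.48, 0.71, 0.99, 0.63, 0.75], 0.27),
    "internalizing": (1.42, 1.00, [0, 0.06, 0.19, 0.25, -0.03, 0.16, 0.17, 0.31, 0.46], 0.11),
    "academic_competence": (25.03, 7.12, [0, -0.19, -0.24, -0.11, 0.08, -0.19, -0.34, -0.38, -1.09], 0.19),
    "social_skills": (103.79, 19.56, [0, -0.06, -0.15, -0.43, -0.35, -0.42, -0.45, -0.33, -0.80], 0.19),
}

# Standardized direct effects of child gender on the four outcomes (adjusted
# pattern); the other predictors act on outcomes only through class.
_GENDER_DIRECT_STD = {
    "externalizing": 0.25,
    "internalizing": 0.11,
    "academic_competence": -0.10,
    "social_skills": -0.27,
}

DEFAULT_ITEM_BANK = ItemBank(
    b=np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]),
    tau=np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])[:, None]
    + np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])[None, :],
    latent_mean=-1.86,
    latent_sd=1.87,
)


def _default_schedule() -> list[Wave]:
    waves = [Wave(a, 0.08, "7cat", 0.15) for a in (1.0, 2.0, 3.0, 4.0)]
    phone_ages = (1.1, 1.25, 1.4, 1.5, 1.75, 1.9, 2.1, 2.33, 2.5, 2.67,
                  2.9, 3.2, 3.5, 3.8, 4.3, 4.6, 5.0)
    waves += [Wave(a, 0.06, "binary", 0.494) for a in phone_ages]
    return sorted(waves, key=lambda w: w.target_age)


def default_config(n_children: int = 1141, seed: int = 0, include_items: bool = True) -> SimulationConfig:
    """The study conditions: 9 classes, 21 mixed-format waves, ~12 per child.

    With the default schedule the expected number of realized waves per
    child is 4 x 0.85 + 17 x 0.506 = 12.0, matching the reported average of
    twelve repeated measures.
    """
    sds = np.array([
        np.sqrt(p.prevalence * (1 - p.prevalence)) if p.kind == "binary" else p.sd
        for p in DEFAULT_PREDICTORS
    ])
    gamma = _STD_GAMMA / sds[None, :]

    outcome_specs = []
    for name, (mean, sd, diffs, r) in _OUTCOMES.items():
        diffs = np.asarray(diffs, dtype=float)
        centered = diffs - DEFAULT_PROPORTIONS @ diffs
        direct = np.zeros(len(DEFAULT_PREDICTORS))
        direct[0] = _GENDER_DIRECT_STD[name] * sd / sds[0]
        outcome_specs.append(
            OutcomeSpec(
                name=name,
                class_means=mean + sd * centered,
                direct_coefs=direct,
                residual_sd=sd * np.sqrt(1 - r**2),
            )
        )

    return SimulationConfig(
        n_children=n_children,
        class_proportions=DEFAULT_PROPORTIONS.copy(),
        growth_coefficients=DEFAULT_B.copy(),
        gamma=gamma,
        residual_sd=1.0,
        schedule=_default_schedule(),
        predictor_specs=list(DEFAULT_PREDICTORS),
        outcome_specs=outcome_specs,
        seed=seed,
        include_items=include_items,
        item_bank=DEFAULT_ITEM_BANK,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def class_logit_probabilities(config: SimulationConfig, X: np.ndarray) -> np.ndarray:
    """Per-child class probabilities implied by the multinomial logistic model.

    ``X`` holds raw predictor values (children x P); predictors enter
    centered at their specified expectations.  Baseline logits are
    ``log(pi_k / pi_1)`` so that with zero coefficients the probabilities
    equal the stated proportions exactly.
    """
    pi = config.class_proportions
    K = config.K
    if K == 1:
        return np.ones((len(X), 1))
    with np.errstate(divide="ignore"):
        alpha = np.log(pi[1:]) - np.log(pi[0])
    mu = np.array([p.expectation for p in config.predictor_specs])
    Xc = X - mu[None, :]
    logits = np.concatenate(
        [np.zeros((len(X), 1)), alpha[None, :] + Xc @ config.gamma.T], axis=1
    )
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _draw_items(bank: ItemBank, theta: np.ndarray, fmt: str, rng) -> np.ndarray:
    """Item responses (rows = occasions) at the given latent scores."""
    n = len(theta)
    if fmt == "binary":
        lp1, _ = bank.binary_logprob(theta)
        p1 = np.exp(lp1).T  # occasions x items
        return (rng.random((n, len(bank.behaviors))) < p1).astype(float)
    LP = bank.pcm_logprob(theta)  # items x occasions x cats
    P = np.exp(LP)
    u = rng.random((len(bank.behaviors), n))
    cum = np.cumsum(P, axis=2)
    cat = (u[:, :, None] > cum).sum(axis=2) + 1  # categories 1..7
    return cat.T.astype(float)


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw a complete cohort; identical (config, seed) gives identical data."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, K = config.n_children, config.K
    P = len(config.predictor_specs)

    # predictors
    X = np.empty((n, P))
    for j, spec in enumerate(config.predictor_specs):
        if spec.kind == "binary":
            X[:, j] = (rng.random(n) < spec.prevalence).astype(float)
        else:
            X[:, j] = rng.normal(spec.mean, spec.sd, size=n)
    predictors = pd.DataFrame(X, columns=[p.name for p in config.predictor_specs])
    predictors.insert(0, "child_id", np.arange(n))

    # latent class
    probs = class_logit_probabilities(config, X)
    u = rng.random(n)
    true_class = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)  # 0-based

    # panel
    rows = []
    for w_idx, wave in enumerate(config.schedule):
        ages = np.clip(
            wave.target_age + rng.normal(0.0, wave.jitter_sd, size=n), 0.6, 5.4
        )
        present = rng.random(n) >= wave.missing_prob
        latent = np.vander(ages - AGE_CENTER, N_COEF, increasing=True) @ config.growth_coefficients.T
        latent = latent[np.arange(n), true_class]
        noise = rng.normal(0.0, config.residual_sd, size=n) if config.residual_sd > 0 else np.zeros(n)
        score = latent + noise
        rows.append(
            pd.DataFrame(
                {
                    "child_id": np.arange(n)[present],
                    "wave": w_idx,
                    "age": ages[present],
                    "format": wave.format,
                    "latent": latent[present],
                    "score": score[present],
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True).sort_values(["child_id", "age"], kind="stable")
    panel = panel.reset_index(drop=True)
    observed = np.unique(panel["child_id"].to_numpy())
    dropped = np.setdiff1d(np.arange(n), observed)

    # item responses from the measurement model at theta = noisy score
    item_responses = None
    if config.include_items:
        bank = config.item_bank or DEFAULT_ITEM_BANK
        blocks = []
        for fmt in ("binary", "7cat"):
            sub = panel[panel["format"] == fmt]
            if not len(sub):
                continue
            items = _draw_items(bank, sub["score"].to_numpy(), fmt, rng)
            block = sub.reset_index(drop=True).copy()
            for i, b in enumerate(bank.behaviors):
                block[f"item_{b}"] = items[:, i]
            blocks.append(block)
        item_responses = (
            pd.concat(blocks, ignore_index=True)
            .sort_values(["child_id", "age"], kind="stable")
            .reset_index(drop=True)
        )

    # distal outcomes
    mu = np.array([p.expectation for p in config.predictor_specs])
    Xc = X - mu[None, :]
    outcomes = pd.DataFrame({"child_id": np.arange(n)})
    for spec in config.outcome_specs:
        y = (
            spec.class_means[true_class]
            + Xc @ spec.direct_coefs
            + rng.normal(0.0, spec.residual_sd, size=n)
        )
        outcomes[spec.name] = y

    return SyntheticCohort(
        predictors=predictors,
        true_class=true_class + 1,
        panel=panel,
        item_responses=item_responses,
        outcomes=outcomes,
        dropped_children=dropped,
        config=config,
        seed=seed,
    )
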