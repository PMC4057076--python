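"""Synthetic cohorts with known ground truth.

Two generators:

* :func:`sample_latent_cohort` draws directly from the 2PL latent-trait
  model — severity theta from N(0, 1), rule endorsements from the item
  characteristic curves, onset from the logistic link — so the estimation
  machinery can be tested against exact generative truth.

* :func:`sample_marker_cohort` emulates a prevention-trial baseline cohort:
  mixed-scale markers with missingness, severity driven by planted
  conjunctive threshold rules, and exponential onset times with
  administrative censoring, so rule induction and survival validation can
  be tested end to end.

One global integer seed is split into per-stage substreams so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import MarkerTable
from .errors import ConfigError
from .latent import icc
from .rules import Condition, EndorsementMatrix, Rule, binarize

__all__ = [
    "LatentGenConfig",
    "MarkerSpec",
    "MarkerGenConfig",
    "SyntheticCohort",
    "sample_latent_cohort",
    "sample_marker_cohort",
]


@dataclass(frozen=True)
class LatentGenConfig:
    """Pure latent-trait generative sampler configuration.

    ``item_params`` is a sequence of (discrimination a, difficulty b)
    pairs; ``link`` is (beta0, beta1) for the onset logit. Severity is
    standard normal by identification convention.
    """

    n_subjects: int
    item_params: tuple
    link: tuple = (0.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        if len(self.item_params) == 0:
            raise ConfigError("item_params must be non-empty")


def sample_latent_cohort(cfg: LatentGenConfig):
    """Draw (endorsements, outcomes, true severity) from the 2PL model.

    theta_i ~ N(0, 1); x_ij ~ Bernoulli(icc(theta_i, a_j, b_j));
    y_i ~ Bernoulli(sigmoid(beta0 + beta1 theta_i)). Bit-identical under a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    items = np.asarray(cfg.item_params, dtype=float)
    a, b = items[:, 0], items[:, 1]
    beta0, beta1 = float(cfg.link[0]), float(cfg.link[1])

    theta = rng.standard_normal(n)
    P = icc(theta[:, None], a[None, :], b[None, :])
    X = (rng.random(P.shape) < P).astype(np.int8)
    y = (rng.random(n) < expit(beta0 + beta1 * theta)).astype(int)
    # abstract items: a placeholder condition names each latent rule
    rules = [
        Rule(conditions=(Condition(f"item_{j}", lower=0.0),), provenance=f"latent_item_{j}")
        for j in range(len(a))
    ]
    em = EndorsementMatrix(X, rules)
    return em, y, theta


@dataclass(frozen=True)
class MarkerSpec:
    """Marginal distribution of one marker column.

    ``dist`` is ``"normal"`` or ``"lognormal"``; ``loc``/``scale`` are the
    underlying normal's parameters; ``missing_rate`` is the MCAR deletion
    probability (must be < 1).
    """

    name: str
    dist: str = "normal"
    loc: float = 0.0
    scale: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.dist not in ("normal", "lognormal"):
            raise ConfigError(f"unknown distribution family {self.dist!r}")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")


@dataclass(frozen=True)
class MarkerGenConfig:
    """Marker-level cohort generator configuration.

    ``planted_rules`` is a sequence of (Rule, effect) pairs: each endorsed
    rule adds ``effect`` to the raw severity score before standardization.
    Onset times are exponential with rate
    ``hazard_scale * exp(hazard_gamma * theta)`` (``hazard_gamma`` is the
    log-hazard ratio per severity SD) and administrative censoring at
    ``censor_time``.
    """

    n_subjects: int
    marker_specs: tuple
    planted_rules: tuple = ()
    hazard_scale: float = 0.1
    censor_time: float = 5.0
    noise_sd: float = 0.5
    hazard_gamma: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        if self.hazard_scale <= 0 or self.censor_time <= 0:
            raise ConfigError("hazard_scale and censor_time must be positive")
        declared = {s.name for s in self.marker_specs}
        for rule, _ in self.planted_rules:
            undeclared = rule.markers - declared
            if undeclared:
                raise ConfigError(f"planted rule references undeclared markers: {sorted(undeclared)}")


@dataclass
class SyntheticCohort:
    """A generated cohort together with all ground truth."""

    markers: MarkerTable
    true_theta: np.ndarray
    true_rules: list
    outcome: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def write(self, csv_path, truth_path=None):
        """Write the cohort CSV; optionally a JSON sidecar with the truth."""
        self.markers.to_csv(csv_path)
        if truth_path is not None:
            import json

            from .rules import RuleSet, rules_to_json

            payload = {
                "true_theta": self.true_theta.tolist(),
                "true_rules": json.loads(rules_to_json(RuleSet(list(self.true_rules))))["rules"],
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def sample_marker_cohort(cfg: MarkerGenConfig) -> SyntheticCohort:
    """Generate a marker-level cohort with planted conjunctive risk rules.

    Severity is the standardized sum of planted-rule endorsements weighted
    by their effects plus N(0, noise_sd^2) noise (pure noise when no rules
    are planted), onset times are exponential with rate
    ``hazard_scale * exp(hazard_gamma * theta)``, the event indicator marks onset within
    ``censor_time``, and the binary outcome equals event-within-horizon.
    Missingness is applied completely at random per marker after the ground
    truth is computed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_markers, rng_theta, rng_time, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = cfg.n_subjects

    cols = {}
    for spec in cfg.marker_specs:
        z = rng_markers.standard_normal(n) * spec.scale + spec.loc
        cols[spec.name] = np.exp(z) if spec.dist == "lognormal" else z
    df = pd.DataFrame(cols)
    marker_names = [s.name for s in cfg.marker_specs]
    complete = MarkerTable(
        df.assign(outcome=0), marker_cols=marker_names, outcome_col="outcome"
    )

    raw = rng_theta.standard_normal(n) * cfg.noise_sd
    true_rules = [r for r, _ in cfg.planted_rules]
    if cfg.planted_rules:
        em = binarize(true_rules, complete)
        effects = np.array([e for _, e in cfg.planted_rules], dtype=float)
        raw = raw + em.values @ effects
    theta = (raw - raw.mean()) / (raw.std() + 1e-12)

    rate = cfg.hazard_scale * np.exp(cfg.hazard_gamma * theta)
    t_onset = rng_time.exponential(1.0 / rate)
    event = (t_onset <= cfg.censor_time).astype(int)
    time = np.minimum(t_onset, cfg.censor_time)
    outcome = event.copy()

    for spec in cfg.marker_specs:
        if spec.missing_rate > 0:
            mask = rng_miss.random(n) < spec.missing_rate
            df.loc[mask, spec.name] = np.nan

    data = df.assign(outcome=outcome, time=time, event=event)
    table = MarkerTable(
        data, marker_cols=marker_names, outcome_col="outcome",
        time_col="time", event_col="event",
    )
    return SyntheticCohort(
        markers=table,
        true_theta=theta,
        true_rules=true_rules,
        outcome=outcome,
        time=time,
        event=event,
    )
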