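"""Evaluation machinery: Kaplan-Meier curves, logrank tests, AUC, and a
repeated 80/20 hold-out harness for the full rule + latent-trait pipeline.

Each selected rule splits the cohort into an endorsing and a non-endorsing
group; the prognostic value of the rule is judged by the separation of the
two Kaplan-Meier curves and the two-group logrank test. Predictive accuracy
of the synthesized model is judged by AUC on repeated stratified 80/20
splits, inducing rules and fitting the latent-trait model on the training
split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .cohort import MarkerTable
from .errors import ConfigError, EmptyGroupError, SchemaError, UndefinedTestError
from .induction import generate_candidate_rules, prune_rules
from .latent import fit_mcmc, point_estimates, predict_risk
from .rules import RuleSet, binarize

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CVReport",
    "km_estimate",
    "logrank_test",
    "auc",
    "cv_80_20",
    "validate_rules",
    "RuleValidation",
]

Z95 = 1.959963984540054


@dataclass
class SurvivalData:
    """Follow-up times, event indicators and a binary grouping."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        if not (len(self.time) == len(self.event) == len(self.group)):
            raise SchemaError("time, event and group must have equal length")
        if not np.isfinite(self.time).all() or self.time.min() < 0:
            raise SchemaError("times must be finite and nonnegative")


@dataclass
class KMCurve:
    """Product-limit estimate at each distinct event time with 95% bands."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(data: SurvivalData, group_value: int) -> KMCurve:
    """Kaplan-Meier curve for one group with Greenwood log-scale bands.

    The product-limit estimator is evaluated at each distinct event time;
    the 95% interval is ``S * exp(±1.96 * sqrt(sum d / (n (n - d))))``
    (Greenwood variance of log S), clipped to (0, 1].
    """
    mask = data.group == group_value
    if not mask.any():
        raise EmptyGroupError(f"no subjects with group == {group_value}")
    t, e = data.time[mask], data.event[mask]
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    at_event = table[table["observed"] > 0]
    times = at_event.index.to_numpy(dtype=float)
    d = at_event["observed"].to_numpy(dtype=float)
    n = at_event["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood variance of log S, accumulated over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
    se = np.sqrt(var_log)
    lower = np.clip(surv * np.exp(-Z95 * se), 0.0, 1.0)
    upper = np.clip(surv * np.exp(Z95 * se), 0.0, 1.0)
    lower[~np.isfinite(se)] = 0.0
    upper[~np.isfinite(se)] = np.clip(surv[~np.isfinite(se)], 0.0, 1.0)
    return KMCurve(times, surv, lower, upper, n_at_risk=n)


def logrank_test(data: SurvivalData):
    """Two-group logrank test: ``(sum(O - E))^2 / sum(V)`` against chi2(1).

    Requires both groups non-empty and at least one event.
    """
    if not (data.group == 0).any() or not (data.group == 1).any():
        raise EmptyGroupError("both groups must be non-empty")
    if data.event.sum() == 0:
        raise UndefinedTestError("no events; logrank statistic undefined")
    res = _ll_logrank(
        data.time[data.group == 0],
        data.time[data.group == 1],
        event_observed_A=data.event[data.group == 0],
        event_observed_B=data.event[data.group == 1],
    )
    stat = float(res.test_statistic)
    p = float(chi2.sf(stat, df=1))
    return stat, p


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ConfigError("labels contain a single class; AUC undefined")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class RuleValidation:
    """Survival validation of one rule."""

    rule_index: int
    testable: bool
    support: float
    km_endorsed: KMCurve | None = None
    km_not_endorsed: KMCurve | None = None
    statistic: float | None = None
    p_value: float | None = None


def validate_rules(table: MarkerTable, rules: RuleSet) -> list[RuleValidation]:
    """Kaplan-Meier curves and logrank tests for every rule's two groups.

    Rules endorsed by everyone or no one define a single group and are
    flagged untestable rather than raising.
    """
    if table.time_col is None or table.event_col is None:
        raise SchemaError("survival validation requires time and event columns")
    em = binarize(rules, table)
    out = []
    for j in range(em.n_rules):
        g = em.values[:, j]
        support = float(g.mean())
        if support in (0.0, 1.0):
            out.append(RuleValidation(j, testable=False, support=support))
            continue
        data = SurvivalData(table.time, table.event, g)
        stat, p = logrank_test(data)
        out.append(
            RuleValidation(
                j,
                testable=True,
                support=support,
                km_endorsed=km_estimate(data, 1),
                km_not_endorsed=km_estimate(data, 0),
                statistic=stat,
                p_value=p,
            )
        )
    return out


@dataclass
class CVReport:
    """Per-repeat AUCs from the repeated hold-out protocol."""

    results: pd.DataFrame  # columns: repeat, method, auc
    n_repeats: int
    split_fraction: float
    seed: int | None
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return self.results.groupby("method")["auc"].agg(["mean", "std", "count"])


def _fit_and_score(train: MarkerTable, test: MarkerTable, rng, induce_kwargs, mcmc_kwargs):
    """One repeat of the latent-trait pipeline; returns test scores."""
    cands = generate_candidate_rules(train, seed=int(rng.integers(2**31 - 1)), **induce_kwargs)
    if len(cands) == 0:
        return np.full(test.n_subjects, float(train.outcome.mean()))
    selected = prune_rules(
        binarize(cands, train), train.outcome, seed=int(rng.integers(2**31 - 1))
    )
    if len(selected) == 0:
        return np.full(test.n_subjects, float(train.outcome.mean()))
    etr = binarize(selected, train)
    # keep only items informative on the training split
    means = etr.values.mean(axis=0)
    keep = np.where((means > 0) & (means < 1))[0]
    if len(keep) < 2:
        # fall back to the single rule (or prevalence) as the score
        if len(keep) == 1:
            ete = binarize(selected, test)
            return ete.values[:, keep[0]].astype(float)
        return np.full(test.n_subjects, float(train.outcome.mean()))
    kept_rules = RuleSet([selected.rules[j] for j in keep])
    etr = binarize(kept_rules, train)
    ete = binarize(kept_rules, test)
    samples = fit_mcmc(
        etr, train.outcome, seed=int(rng.integers(2**31 - 1)), **mcmc_kwargs
    )
    model = point_estimates(samples)
    return predict_risk(model, ete)


def cv_80_20(
    table: MarkerTable,
    n_repeats: int = 100,
    seed: int | None = None,
    split_fraction: float = 0.8,
    induce_kwargs: dict | None = None,
    mcmc_kwargs: dict | None = None,
    comparators: dict | None = None,
    stratified: bool = True,
) -> CVReport:
    """Repeated stratified 80/20 hold-out evaluation.

    Per repeat: rules are induced and pruned on the training split only,
    the latent-trait model is fitted on the training endorsements, and the
    held-out subjects are scored with the posterior-averaged onset
    probability; the AUC is recorded. ``comparators`` maps method names to
    scikit-learn classifiers fitted on the raw (median-imputed) markers in
    the same splits. A repeat whose training split loses an outcome class
    is redrawn (logged); with stratified splitting this cannot occur.
    """
    y = table.outcome
    if len(np.unique(y)) < 2:
        raise ConfigError("both outcome classes must be present")
    induce_kwargs = dict(induce_kwargs or {})
    mcmc_kwargs = dict(mcmc_kwargs or {"n_samples": 3000, "n_burn": 1000})
    rng = np.random.default_rng(seed)
    rows = []

    n = table.n_subjects
    X_raw = table.numeric_markers().to_numpy(dtype=float)
    med = np.nanmedian(X_raw, axis=0)
    X_imp = np.where(np.isnan(X_raw), med[None, :], X_raw)

    rep = 0
    attempts = 0
    while rep < n_repeats:
        attempts += 1
        split_seed = int(rng.integers(2**31 - 1))
        if stratified:
            sss = StratifiedShuffleSplit(
                n_splits=1, train_size=split_fraction, random_state=split_seed
            )
            tr_idx, te_idx = next(sss.split(np.zeros(n), y))
        else:
            perm = np.random.default_rng(split_seed).permutation(n)
            cut = int(round(split_fraction * n))
            tr_idx, te_idx = perm[:cut], perm[cut:]
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[te_idx])) < 2:
            logger.warning("repeat %d lost an outcome class; redrawing split", rep)
            continue
        train, test = table.subset(tr_idx), table.subset(te_idx)
        scores = _fit_and_score(train, test, rng, induce_kwargs, mcmc_kwargs)
        if len(np.unique(scores)) < 2:
            auc_val = 0.5  # constant scorer: all pairs tie
        else:
            auc_val = auc(scores, y[te_idx])
        rows.append({"repeat": rep, "method": "latent-trait", "auc": auc_val})
        for name, clf in (comparators or {}).items():
            from sklearn.base import clone

            c = clone(clf)
            c.fit(X_imp[tr_idx], y[tr_idx])
            if hasattr(c, "predict_proba"):
                s = c.predict_proba(X_imp[te_idx])[:, 1]
            else:
                s = c.decision_function(X_imp[te_idx])
            rows.append({"repeat": rep, "method": name, "auc": auc(s, y[te_idx])})
        rep += 1

    return CVReport(
        results=pd.DataFrame(rows),
        n_repeats=n_repeats,
        split_fraction=split_fraction,
        seed=seed,
        config={
            "induce_kwargs": induce_kwargs,
            "mcmc_kwargs": mcmc_kwargs,
            "stratified": stratified,
            "attempts": attempts,
        },
    )
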