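"""Rule discovery: tree-ensemble generation and L1-penalized pruning.

The two-phase procedure mirrors RuleFit. Phase one fits many shallow
classification trees on bootstrap subsamples and reads every root-to-node
path off as a candidate conjunctive rule. Phase two treats each rule's
endorsement column as a binary predictor and fits an L1-penalized logistic
regression of the outcome on all candidates, keeping only rules with
nonzero coefficients; the penalty is chosen by cross-validated deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import MarkerTable
from .errors import ConfigError, DegenerateOutcomeError
from .rules import (
    RISK_DECREASING,
    RISK_INCREASING,
    Condition,
    EndorsementMatrix,
    Rule,
    RuleSet,
    binarize,
    canonicalize_rule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "generate_candidate_rules",
    "prune_rules",
    "selection_path",
    "rule_stability",
    "StabilityRecord",
]


def _leaf_budgets(rng: np.random.Generator, n_trees: int, avg_terminal_nodes: float) -> np.ndarray:
    """Per-tree terminal-node budgets with the requested mean.

    Budgets are ``2 + Geometric(p)`` so the smallest tree is a stump with one
    split; ``p`` is set so the mean equals ``avg_terminal_nodes``.
    """
    if avg_terminal_nodes <= 3.0:
        return np.full(n_trees, max(2, int(round(avg_terminal_nodes))))
    p = 1.0 / (avg_terminal_nodes - 2.0)
    p = min(1.0, p)
    return 2 + rng.geometric(p, size=n_trees)


def _paths_from_tree(tree: DecisionTreeClassifier, feature_names: list[str], tag: str):
    """Every root-to-node path (depth >= 1) of a fitted tree as a rule."""
    t = tree.tree_
    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]):
        if conds:
            try:
                rules.append(
                    canonicalize_rule(Rule(tuple(conds), provenance=f"{tag}/node{node}"))
                )
            except Exception:  # pragma: no cover - cannot arise from one path
                pass
        if t.children_left[node] == -1:
            return
        name = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        if not np.isfinite(thr):
            # pure missingness split: no interval semantics, stop this path
            return
        walk(t.children_left[node], conds + [Condition(name, upper=thr, upper_strict=False)])
        walk(t.children_right[node], conds + [Condition(name, lower=thr, lower_strict=True)])

    walk(0, [])
    return rules


def _consolidate_rules(E: np.ndarray, rules: list[Rule], jaccard: float) -> list[Rule]:
    """Merge near-duplicate candidate rules into one representative each.

    Candidates whose endorsement sets have Jaccard similarity at or above
    the threshold are clustered greedily (fewest-condition, largest-support
    rules first). When a cluster contains several rules with the same
    condition structure, the representative takes the median of each finite
    cutoff across them, which denoises split-point jitter between trees.
    """
    order = sorted(range(E.shape[1]), key=lambda j: (len(rules[j].conditions), -E[:, j].mean(), j))
    Ei = E[:, order].astype(np.float32)
    sizes = Ei.sum(axis=0)
    inter = Ei.T @ Ei
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        Jm = np.where(union > 0, inter / union, 0.0)
    assigned = np.zeros(len(order), dtype=bool)
    out: list[Rule] = []
    for i in range(len(order)):
        if assigned[i]:
            continue
        members = np.where((Jm[i] >= jaccard) & (~assigned))[0]
        assigned |= Jm[i] >= jaccard
        rep = rules[order[i]]
        shape = [(c.marker, np.isfinite(c.lower), np.isfinite(c.upper)) for c in rep.conditions]
        same = [
            rules[order[k]]
            for k in members
            if [(c.marker, np.isfinite(c.lower), np.isfinite(c.upper))
                for c in rules[order[k]].conditions] == shape
        ]
        if len(same) > 1:
            try:
                conds = []
                for ci, c in enumerate(rep.conditions):
                    lo = float(np.median([r.conditions[ci].lower for r in same])) \
                        if np.isfinite(c.lower) else -np.inf
                    hi = float(np.median([r.conditions[ci].upper for r in same])) \
                        if np.isfinite(c.upper) else np.inf
                    conds.append(Condition(c.marker, lo, hi, c.lower_strict, c.upper_strict))
                rep = Rule(tuple(conds), provenance=rep.provenance)
            except Exception:
                pass  # crossed medians: keep the untouched representative
        out.append(rep)
    return out


def generate_candidate_rules(
    table: MarkerTable,
    n_trees: int = 250,
    avg_terminal_nodes: float = 4.5,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
    max_depth: int = 3,
    min_impurity_decrease: float = 5e-3,
    consolidate_jaccard: float = 0.85,
) -> RuleSet:
    """Generate candidate rules from an ensemble of shallow trees.

    Each tree is fit on a bootstrap subsample of ``subsample_fraction * n``
    subjects with a randomized terminal-node budget whose mean is
    ``avg_terminal_nodes``; splits must reduce Gini impurity by at least
    ``min_impurity_decrease`` so refinements driven by sampling noise do
    not enter the candidate pool. Every root-to-node path becomes a
    candidate rule; per-marker conditions are intersected, duplicates
    across trees are dropped, near-duplicate candidates are merged into a
    median-cutoff representative (``consolidate_jaccard``; set to 1 to
    disable), and supports are computed on the full table.

    ``n_trees = 0`` returns an empty rule set. A constant outcome raises
    :class:`DegenerateOutcomeError`.
    """
    if n_trees < 0:
        raise ConfigError("n_trees must be nonnegative")
    if n_trees == 0:
        return RuleSet([])
    if table.n_subjects < 20:
        raise ConfigError("need at least 20 subjects for rule generation")
    y = table.outcome
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is constant; cannot grow discriminating trees")

    rng = np.random.default_rng(seed)
    X = table.numeric_markers()
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    m = max(1, int(round(subsample_fraction * n)))
    budgets = _leaf_budgets(rng, n_trees, avg_terminal_nodes)

    seen: dict[tuple, Rule] = {}
    for t_idx in range(n_trees):
        idx = rng.choice(n, size=m, replace=True)
        yt = y[idx]
        if yt.min() == yt.max():
            continue
        tree = DecisionTreeClassifier(
            max_leaf_nodes=int(budgets[t_idx]),
            max_depth=max_depth,
            min_impurity_decrease=min_impurity_decrease,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xv[idx], yt)
        for r in _paths_from_tree(tree, feature_names, tag=f"tree{t_idx}"):
            seen.setdefault(r.key(), r)

    rules = list(seen.values())
    if rules and consolidate_jaccard < 1.0:
        E = binarize(rules, table).values
        rules = _consolidate_rules(E, rules, consolidate_jaccard)
    if rules:
        supports = binarize(rules, table).supports()
        rules = [Rule(r.conditions, float(s), r.direction, r.provenance)
                 for r, s in zip(rules, supports)]
    logger.info("generated %d unique candidate rules from %d trees", len(rules), n_trees)
    return RuleSet(rules)


DEFAULT_PENALTY_GRID = tuple(np.logspace(-4.0, -1.0, 10))


def _collapse_columns(E: np.ndarray, rules: list[Rule], jaccard: float = 1.0):
    """Collapse duplicate endorsement columns, keeping the shortest rule.

    Exactly identical columns are always merged. With ``jaccard < 1``,
    near-duplicate columns (Jaccard similarity of the endorsement sets at or
    above the threshold) are also merged: a deeper tree path that trims only
    a few subjects off a simpler rule carries no independent signal and
    would otherwise compete with the simpler rule during selection.
    """
    keep: dict[bytes, int] = {}
    for j in range(E.shape[1]):
        h = E[:, j].tobytes()
        if h not in keep:
            keep[h] = j
        else:
            cur = keep[h]
            if len(rules[j].conditions) < len(rules[cur].conditions):
                keep[h] = j
    cols = sorted(keep.values())
    if jaccard >= 1.0 or len(cols) < 2:
        return cols
    # greedy clustering: fewest-condition rules act as representatives
    order = sorted(cols, key=lambda j: (len(rules[j].conditions), -E[:, j].mean(), j))
    Ei = E[:, order].astype(np.float32)
    sizes = Ei.sum(axis=0)
    inter = Ei.T @ Ei
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / union, 0.0)
    assigned = np.zeros(len(order), dtype=bool)
    reps = []
    for i in range(len(order)):
        if assigned[i]:
            continue
        reps.append(order[i])
        assigned |= J[i] >= jaccard
    return sorted(reps)


def _fit_l1(E: np.ndarray, y: np.ndarray, lam: float, n: int) -> LogisticRegression:
    # objective: (1/n) sum loss + lam * ||w||_1, i.e. C = 1 / (n * lam)
    C = 1.0 / max(n * lam, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000, random_state=0
    )
    clf.fit(E, y)
    return clf


def prune_rules(
    endorsements: EndorsementMatrix,
    outcome: np.ndarray,
    penalty_grid=DEFAULT_PENALTY_GRID,
    n_folds: int = 5,
    seed: int | None = None,
    collapse_jaccard: float = 1.0,
    lambda_rule: str = "1se",
) -> RuleSet:
    """Select a minimal predictive rule subset by L1 logistic regression.

    Constant endorsement columns are dropped (logged) and perfectly
    collinear columns are collapsed keeping the shorter rule
    (``collapse_jaccard`` below 1 additionally merges near-duplicates).
    The penalty :math:`\\lambda` is chosen by cross-validated deviance:
    with ``lambda_rule="1se"`` (default) the sparsest grid point whose mean
    deviance is within one standard error of the minimum, which favors a
    minimal rule set; ``lambda_rule="min"`` takes the plain minimizer.
    Rules with nonzero coefficients are returned with their sign recorded
    as direction (positive = risk-increasing).
    """
    y = np.asarray(outcome, dtype=int)
    E = endorsements.values.astype(float)
    rules = list(endorsements.rules)
    if E.shape[0] != len(y):
        raise ConfigError("endorsement matrix and outcome length differ")
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is constant")

    col_means = E.mean(axis=0)
    nonconst = np.where((col_means > 0) & (col_means < 1))[0]
    n_dropped = E.shape[1] - len(nonconst)
    if n_dropped:
        logger.warning("dropping %d constant endorsement columns", n_dropped)
    E = E[:, nonconst]
    rules = [rules[j] for j in nonconst]
    if E.shape[1] == 0:
        return RuleSet([], selection_coefficients=[], penalty_used=None)

    cols = _collapse_columns(E.astype(np.int8), rules, jaccard=collapse_jaccard)
    E = E[:, cols]
    rules = [rules[j] for j in cols]

    if lambda_rule not in ("1se", "min"):
        raise ConfigError("lambda_rule must be '1se' or 'min'")
    lams = sorted(float(l) for l in penalty_grid)
    n = len(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(E, y))
    mean_dev, se_dev = [], []
    for lam in lams:
        devs = []
        for tr, va in splits:
            clf = _fit_l1(E[tr], y[tr], lam, len(tr))
            p = clf.predict_proba(E[va])[:, 1]
            devs.append(log_loss(y[va], p, labels=[0, 1]))
        mean_dev.append(float(np.mean(devs)))
        se_dev.append(float(np.std(devs, ddof=1) / np.sqrt(len(devs))))
    best = int(np.argmin(mean_dev))
    if lambda_rule == "1se":
        cutoff = mean_dev[best] + se_dev[best]
        best = max(i for i in range(len(lams)) if mean_dev[i] <= cutoff)
    lam_star = lams[best]

    clf = _fit_l1(E, y, lam_star, n)
    coefs = clf.coef_.ravel()
    sel = np.where(coefs != 0)[0]
    out_rules, out_coefs = [], []
    for j in sel:
        r = rules[j]
        direction = RISK_INCREASING if coefs[j] > 0 else RISK_DECREASING
        out_rules.append(Rule(r.conditions, r.support, direction, r.provenance))
        out_coefs.append(float(coefs[j]))
    logger.info(
        "pruning kept %d of %d rules at penalty %.4g", len(out_rules), len(rules), lam_star
    )
    return RuleSet(out_rules, selection_coefficients=out_coefs, penalty_used=lam_star)


def selection_path(
    endorsements: EndorsementMatrix, outcome: np.ndarray, penalty_grid=DEFAULT_PENALTY_GRID
) -> list[tuple[float, int]]:
    """Number of selected rules at each penalty on the grid (ascending).

    On the solver's own grid, a larger penalty never selects more rules.
    """
    y = np.asarray(outcome, dtype=int)
    E = endorsements.values.astype(float)
    col_means = E.mean(axis=0)
    nonconst = (col_means > 0) & (col_means < 1)
    E = E[:, nonconst]
    out = []
    for lam in sorted(float(l) for l in penalty_grid):
        clf = _fit_l1(E, y, lam, len(y))
        out.append((lam, int(np.count_nonzero(clf.coef_))))
    return out


@dataclass
class StabilityRecord:
    """Reappearance frequency and cutoff dispersion for one marker set."""

    markers: frozenset[str]
    frequency: float
    cutoff_sd: dict = field(default_factory=dict)
    cutoff_mean: dict = field(default_factory=dict)
    n_seen: int = 0


def rule_stability(
    table: MarkerTable,
    n_repeats: int = 20,
    split_fraction: float = 0.8,
    seed: int | None = None,
    induce_kwargs: dict | None = None,
    prune_kwargs: dict | None = None,
) -> list[StabilityRecord]:
    """Repeat induce+prune on random subsamples and measure rule stability.

    Each repeat draws a stratified ``split_fraction`` subsample (without
    replacement), reruns :func:`generate_candidate_rules` and
    :func:`prune_rules`, and records the selected rules. Rules are matched
    across repeats by their marker set; for each matched set the
    reappearance frequency and the standard deviation of each finite cutoff
    (keyed by ``(marker, "lower"|"upper")``) are reported. With
    ``n_repeats = 2`` the SD is computed from two values; that is legitimate
    but noisy.
    """
    if n_repeats < 2:
        raise ConfigError("n_repeats must be at least 2")
    induce_kwargs = dict(induce_kwargs or {})
    prune_kwargs = dict(prune_kwargs or {})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)
    y = table.outcome
    idx0 = np.where(y == 0)[0]
    idx1 = np.where(y == 1)[0]

    hits: dict[frozenset, dict] = {}
    for rep in range(n_repeats):
        rng = np.random.default_rng(children[rep])
        pick = np.concatenate([
            rng.choice(idx0, size=max(1, int(round(split_fraction * len(idx0)))), replace=False),
            rng.choice(idx1, size=max(1, int(round(split_fraction * len(idx1)))), replace=False),
        ])
        sub = table.subset(np.sort(pick))
        cands = generate_candidate_rules(
            sub, seed=int(rng.integers(2**31 - 1)), **induce_kwargs
        )
        if len(cands) == 0:
            continue
        selected = prune_rules(
            binarize(cands, sub), sub.outcome,
            seed=int(rng.integers(2**31 - 1)), **prune_kwargs
        )
        seen_this_rep = set()
        for r in selected:
            key = r.markers
            rec = hits.setdefault(key, {"reps": set(), "cuts": {}})
            if key not in seen_this_rep:
                rec["reps"].add(rep)
                seen_this_rep.add(key)
            for c in r.conditions:
                if np.isfinite(c.lower):
                    rec["cuts"].setdefault((c.marker, "lower"), []).append(c.lower)
                if np.isfinite(c.upper):
                    rec["cuts"].setdefault((c.marker, "upper"), []).append(c.upper)

    records = []
    for key, rec in sorted(hits.items(), key=lambda kv: -len(kv[1]["reps"])):
        sds = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in rec["cuts"].items()}
        means = {k: float(np.mean(v)) for k, v in rec["cuts"].items()}
        records.append(
            StabilityRecord(
                markers=key,
                frequency=len(rec["reps"]) / n_repeats,
                cutoff_sd=sds,
                cutoff_mean=means,
                n_seen=len(rec["reps"]),
            )
        )
    return records
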