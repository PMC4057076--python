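"""Conjunctive interval rules over baseline markers.

A rule is a conjunction of interval conditions such as
``24.5 < FPIR < 56.5``; a subject *endorses* a rule when every condition
holds on their marker values. The fraction of the cohort endorsing a rule
is its *support*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import MarkerTable
from .errors import InfeasibleRuleError, SchemaError

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "EndorsementMatrix",
    "canonicalize_rule",
    "binarize",
    "rules_to_json",
    "rules_from_json",
]

RISK_INCREASING = "risk-increasing"
RISK_DECREASING = "risk-decreasing"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Condition:
    """One interval condition ``lower (<|<=) marker (<|<=) upper``.

    ``lower_strict`` means the lower bound is exclusive (``marker > lower``);
    ``upper_strict`` means the upper bound is exclusive (``marker < upper``).
    At least one bound must be finite and the interval must be non-empty.
    """

    marker: str
    lower: float = -math.inf
    upper: float = math.inf
    lower_strict: bool = True
    upper_strict: bool = True

    def __post_init__(self):
        if not (self.lower < self.upper):
            raise InfeasibleRuleError(
                f"empty interval on {self.marker!r}: ({self.lower}, {self.upper})"
            )
        if math.isinf(self.lower) and math.isinf(self.upper):
            raise InfeasibleRuleError(f"unbounded condition on {self.marker!r}")

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        """Boolean endorsement per subject; missing values evaluate False."""
        v = np.asarray(values, dtype=float)
        ok = ~np.isnan(v)
        lo = (v > self.lower) if self.lower_strict else (v >= self.lower)
        hi = (v < self.upper) if self.upper_strict else (v <= self.upper)
        return ok & lo & hi

    def __str__(self) -> str:
        parts = []
        if math.isfinite(self.lower):
            parts.append(f"{self.lower:g} {'<' if self.lower_strict else '<='} ")
        parts.append(self.marker)
        if math.isfinite(self.upper):
            parts.append(f" {'<' if self.upper_strict else '<='} {self.upper:g}")
        return "".join(parts)


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions with bookkeeping.

    ``support`` is the endorsement fraction on the table it was computed
    from; ``direction`` records whether selection found the rule
    risk-increasing or risk-decreasing; ``provenance`` identifies the tree
    path that produced it.
    """

    conditions: tuple[Condition, ...]
    support: float | None = None
    direction: str = UNKNOWN
    provenance: str = ""

    def __post_init__(self):
        if len(self.conditions) == 0:
            raise InfeasibleRuleError("rule must have at least one condition")

    @property
    def markers(self) -> frozenset[str]:
        return frozenset(c.marker for c in self.conditions)

    def key(self) -> tuple:
        """Identity of the canonical rule, ignoring bookkeeping fields."""
        return tuple(
            (c.marker, c.lower, c.upper, c.lower_strict, c.upper_strict)
            for c in self.conditions
        )

    def __str__(self) -> str:
        return " AND ".join(str(c) for c in self.conditions)


@dataclass
class RuleSet:
    """Candidate or selected rules, with L1-selection coefficients if pruned."""

    rules: list[Rule] = field(default_factory=list)
    selection_coefficients: list[float] | None = None
    penalty_used: float | None = None

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass
class EndorsementMatrix:
    """Binary subjects x rules matrix: ``values[i, j] = 1`` iff subject *i*
    satisfies every condition of rule *j*."""

    values: np.ndarray
    rules: list[Rule]
    subject_ids: pd.Index | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.rules):
            raise SchemaError("endorsement matrix shape does not match rule count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rules(self) -> int:
        return self.values.shape[1]

    def supports(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rule_{j}" for j in range(self.n_rules)]
        return pd.DataFrame(self.values, columns=cols, index=self.subject_ids)


def _merge_conditions(conds: list[Condition]) -> Condition:
    marker = conds[0].marker
    lower, lower_strict = -math.inf, True
    upper, upper_strict = math.inf, True
    for c in conds:
        if c.lower > lower:
            lower, lower_strict = c.lower, c.lower_strict
        elif c.lower == lower:
            lower_strict = lower_strict or c.lower_strict
        if c.upper < upper:
            upper, upper_strict = c.upper, c.upper_strict
        elif c.upper == upper:
            upper_strict = upper_strict or c.upper_strict
    if lower > upper or (lower == upper and (lower_strict or upper_strict)):
        raise InfeasibleRuleError(
            f"contradictory conditions on {marker!r}: intersection is empty"
        )
    if lower == upper:
        # closed point interval; treated as empty because a rule interval
        # must satisfy lower < upper
        raise InfeasibleRuleError(f"degenerate point interval on {marker!r}")
    return Condition(marker, lower, upper, lower_strict, upper_strict)


def canonicalize_rule(rule: Rule) -> Rule:
    """Intersect same-marker conditions and sort conditions by marker name.

    Raises :class:`InfeasibleRuleError` when some marker's intersection is
    empty. Idempotent: canonicalizing a canonical rule is a no-op.
    """
    by_marker: dict[str, list[Condition]] = {}
    for c in rule.conditions:
        by_marker.setdefault(c.marker, []).append(c)
    merged = tuple(_merge_conditions(by_marker[m]) for m in sorted(by_marker))
    return replace(rule, conditions=merged)


def binarize(rules: RuleSet | list[Rule], table: MarkerTable) -> EndorsementMatrix:
    """Evaluate each rule on each subject.

    A condition on a missing marker value evaluates False, so a subject with
    missing data never endorses a rule that mentions the missing marker.
    """
    rule_list = list(rules.rules if isinstance(rules, RuleSet) else rules)
    X = table.numeric_markers()
    known = set(X.columns)
    for r in rule_list:
        bad = r.markers - known
        if bad:
            raise SchemaError(f"rule references unknown markers: {sorted(bad)}")
    n = len(X)
    out = np.ones((n, len(rule_list)), dtype=bool)
    for j, r in enumerate(rule_list):
        for c in r.conditions:
            out[:, j] &= c.evaluate(X[c.marker].to_numpy())
    return EndorsementMatrix(out.astype(np.int8), rule_list, subject_ids=table.subject_ids)


# -- serialization -----------------------------------------------------

def _cond_to_dict(c: Condition) -> dict:
    return {
        "marker": c.marker,
        "lower": None if math.isinf(c.lower) else c.lower,
        "upper": None if math.isinf(c.upper) else c.upper,
        "lower_strict": c.lower_strict,
        "upper_strict": c.upper_strict,
    }


def rules_to_json(ruleset: RuleSet, path=None, extra: dict | None = None) -> str:
    """Serialize a rule set to JSON (optionally writing ``path``)."""
    coefs = ruleset.selection_coefficients
    payload = {
        "rules": [
            {
                "conditions": [_cond_to_dict(c) for c in r.conditions],
                "support": r.support,
                "direction": r.direction,
                "provenance": r.provenance,
                "coefficient": None if coefs is None else coefs[j],
            }
            for j, r in enumerate(ruleset.rules)
        ],
        "penalty_used": ruleset.penalty_used,
    }
    if extra:
        payload.update(extra)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def rules_from_json(source) -> RuleSet:
    """Inverse of :func:`rules_to_json`; ``source`` is a path or JSON string."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    rules, coefs = [], []
    for rec in payload["rules"]:
        conds = tuple(
            Condition(
                d["marker"],
                -math.inf if d["lower"] is None else float(d["lower"]),
                math.inf if d["upper"] is None else float(d["upper"]),
                bool(d["lower_strict"]),
                bool(d["upper_strict"]),
            )
            for d in rec["conditions"]
        )
        rules.append(
            Rule(conds, rec.get("support"), rec.get("direction", UNKNOWN), rec.get("provenance", ""))
        )
        coefs.append(rec.get("coefficient"))
    have_coefs = all(c is not None for c in coefs) and len(coefs) > 0
    return RuleSet(
        rules,
        selection_coefficients=[float(c) for c in coefs] if have_coefs else None,
        penalty_used=payload.get("penalty_used"),
    )
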