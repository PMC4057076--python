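"""End-to-end pipeline: induce -> fit -> predict -> validate.

A :class:`RunConfig` gathers every stage parameter plus one global seed;
all artifacts embed the config hash and seed so a rerun with an identical
config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import read_cohort
from .errors import ConfigError
from .induction import generate_candidate_rules, prune_rules
from .latent import fit_mcmc, model_to_json, point_estimates, predict_risk
from .rules import binarize, rules_to_json
from .validation import validate_rules

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "input", "outcome_col", "time_col", "event_col", "out_dir", "seed",
    "n_trees", "avg_terminal_nodes", "subsample_fraction",
    "n_samples", "n_burn", "verbosity",
}


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; every field has a logged default."""

    input: str = ""
    outcome_col: str = "outcome"
    time_col: str | None = None
    event_col: str | None = None
    out_dir: str = "report"
    seed: int = 0
    n_trees: int = 250
    avg_terminal_nodes: float = 4.5
    subsample_fraction: float = 0.8
    n_samples: int = 25000
    n_burn: int = 5000
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific configuration (artifact paths excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "verbosity")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stamp(config: RunConfig) -> dict:
    from . import __version__

    return {"config_hash": config.hash(), "seed": config.seed, "version": __version__}


def run_pipeline(config: RunConfig) -> dict:
    """Execute induce -> fit -> predict (-> validate) and write artifacts.

    Writes ``rules.json``, ``model.json`` and ``risk.csv`` under
    ``config.out_dir``, plus per-rule survival validation CSVs when the
    cohort has time/event columns. Partial outputs are removed on failure.
    Returns a dict of artifact paths.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    try:
        t0 = time.perf_counter()
        table = read_cohort(
            config.input,
            outcome_col=config.outcome_col,
            time_col=config.time_col,
            event_col=config.event_col,
        )
        logger.info("read cohort: %d subjects, %d markers", table.n_subjects, len(table.marker_cols))

        cands = generate_candidate_rules(
            table,
            n_trees=config.n_trees,
            avg_terminal_nodes=config.avg_terminal_nodes,
            subsample_fraction=config.subsample_fraction,
            seed=seeds[0],
        )
        selected = prune_rules(binarize(cands, table), table.outcome, seed=seeds[1])
        rules_path = out / "rules.json"
        rules_to_json(selected, rules_path, extra=_stamp(config))
        written.append(rules_path)
        logger.info("induction: %d candidates -> %d selected (%.1fs)",
                    len(cands), len(selected), time.perf_counter() - t0)

        em = binarize(selected, table)
        means = em.values.mean(axis=0)
        keep = np.where((means > 0) & (means < 1))[0]
        if len(keep) < 2:
            raise ConfigError("fewer than 2 informative rules selected; cannot fit the model")
        from .rules import RuleSet

        kept = RuleSet([selected.rules[j] for j in keep])
        em = binarize(kept, table)
        samples = fit_mcmc(
            em, table.outcome, n_samples=config.n_samples, n_burn=config.n_burn, seed=seeds[2]
        )
        model = point_estimates(samples)
        model_path = out / "model.json"
        model_to_json(model, model_path, extra=_stamp(config))
        written.append(model_path)

        risk = predict_risk(model, em)
        risk_path = out / "risk.csv"
        pd.DataFrame({"subject_id": table.subject_ids, "risk": risk}).to_csv(
            risk_path, index=False
        )
        written.append(risk_path)

        artifacts = {"rules": str(rules_path), "model": str(model_path), "risk": str(risk_path)}

        if config.time_col is not None and config.event_col is not None:
            vals = validate_rules(table, kept)
            recs = []
            for v in vals:
                recs.append(
                    {
                        "rule_index": v.rule_index,
                        "testable": v.testable,
                        "support": v.support,
                        "logrank_statistic": v.statistic,
                        "p_value": v.p_value,
                    }
                )
                for tag, curve in (("endorsed", v.km_endorsed), ("not_endorsed", v.km_not_endorsed)):
                    if curve is not None:
                        p = out / f"km_rule{v.rule_index}_{tag}.csv"
                        curve.to_frame().to_csv(p, index=False)
                        written.append(p)
            vpath = out / "validation.json"
            with open(vpath, "w") as fh:
                json.dump({"rules": recs, **_stamp(config)}, fh, indent=2, sort_keys=True)
            written.append(vpath)
            artifacts["validation"] = str(vpath)

        logger.info("pipeline complete in %.1fs", time.perf_counter() - t0)
        return artifacts
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
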