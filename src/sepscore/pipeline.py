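"""End-to-end orchestration: simulate -> resolve -> score -> evaluate -> report.

A :class:`RunConfig` names either an input cohort file or a simulation
request (never both), plus the scores, CI methods and seed.  ``full_run``
materializes a deterministic artifact set in the output directory:

* ``cohort.csv``       — the input or simulated cohort
* ``scores.csv``       — per-patient totals for every requested score
* ``auc.csv``          — AUC with 95% CI per score x CI method
* ``summary.txt``      — human-readable cohort report
* ``summary.json``     — machine-readable summary (counts, mortality,
                         categories, score medians, AUCs)
* ``manifest.json``    — seed, config hash, package version, artifact
                         checksums

Rerunning with the same config reproduces every artifact bit-exactly: all
randomness flows from the single configured seed, and no artifact embeds a
timestamp.  Failures abort with a stage-named error; no partial artifact
set is left behind silently.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort_stats import format_summary, round_half_up, summarize
from .patient_model import read_cohort, resolve, write_cohort
from .roc_analysis import compare_scores
from .severity_scores import SCORE_NAMES, SCORERS
from .synthetic_cohort import coupling_knob, default_spec, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "full_run", "PipelineError"]

DEFAULT_SCORES = SCORE_NAMES
DEFAULT_ROC_METHODS = ("delong", "bootstrap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    input_path: Optional[Path] = None
    simulate: bool = False
    n_survivors: int = 145
    n_deaths: int = 71
    coupling_strength: float = 1.0
    scores: Sequence[str] = DEFAULT_SCORES
    roc_methods: Sequence[str] = DEFAULT_ROC_METHODS
    n_boot: int = 2000
    seed: Optional[int] = None
    delimiter: str = ","
    column_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)
        if self.simulate == (self.input_path is not None):
            raise ValueError(
                "exactly one of input_path / simulate must be specified")
        if (self.simulate or "bootstrap" in self.roc_methods) \
                and self.seed is None:
            raise ValueError(
                "a seed is mandatory when simulation or bootstrap is requested")
        unknown = set(self.scores) - set(SCORERS)
        if unknown:
            raise ValueError(f"unknown scores requested: {sorted(unknown)}")

    def semantic_dict(self) -> dict:
        """Everything that affects outputs, for hashing and the manifest."""
        return {
            "input_path": str(self.input_path) if self.input_path else None,
            "simulate": self.simulate,
            "n_survivors": self.n_survivors,
            "n_deaths": self.n_deaths,
            "coupling_strength": self.coupling_strength,
            "scores": list(self.scores),
            "roc_methods": list(self.roc_methods),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "delimiter": self.delimiter,
            "column_map": dict(self.column_map),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse a sectioned key = value config file into a :class:`RunConfig`.

    Sections mirror the module boundaries::

        [run]
        outdir = out
        seed = 7
        [input]
        simulate = true
        n_survivors = 145
        n_deaths = 71
        [evaluate]
        scores = MEDS, mREMS, CURB65
        roc_methods = delong, bootstrap
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise PipelineError(f"config: cannot read {path}")
    kw: dict = {}
    run = cp["run"] if "run" in cp else {}
    kw["outdir"] = Path(run.get("outdir", "sepscore-run"))
    if "seed" in run:
        kw["seed"] = int(run["seed"])
    inp = cp["input"] if "input" in cp else {}
    if inp.get("path"):
        kw["input_path"] = Path(inp["path"])
    kw["simulate"] = inp.get("simulate", "false").strip().lower() in (
        "true", "yes", "1")
    for key in ("n_survivors", "n_deaths"):
        if key in inp:
            kw[key] = int(inp[key])
    if "coupling_strength" in inp:
        kw["coupling_strength"] = float(inp["coupling_strength"])
    if "delimiter" in inp:
        kw["delimiter"] = inp["delimiter"]
    ev = cp["evaluate"] if "evaluate" in cp else {}
    if "scores" in ev:
        kw["scores"] = tuple(s.strip() for s in ev["scores"].split(","))
    if "roc_methods" in ev:
        kw["roc_methods"] = tuple(
            s.strip() for s in ev["roc_methods"].split(","))
    if "n_boot" in ev:
        kw["n_boot"] = int(ev["n_boot"])
    if "columns" in cp:
        kw["column_map"] = dict(cp["columns"])
    return RunConfig(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def full_run(config: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline; returns artifact name -> path.

    Deterministic under a fixed config: same seed, same bytes.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.simulate:
            spec = default_spec(
                n_survivors=config.n_survivors,
                n_deaths=config.n_deaths,
                seed=config.seed,
            )
            if config.coupling_strength != 1.0:
                spec = coupling_knob(spec, config.coupling_strength)
            records = generate(spec)
        else:
            records = read_cohort(
                str(config.input_path),
                column_map=config.column_map,
                delimiter=config.delimiter,
                require_outcome=True,
            )
        cohort_path = out / "cohort.csv"
        write_cohort(records, str(cohort_path), delimiter=config.delimiter)
        artifacts["cohort"] = cohort_path
        logger.info("stage cohort: %d patients", len(records))
    except Exception as e:  # noqa: BLE001 - stage-named abort
        raise PipelineError(f"stage cohort failed: {e}") from e

    # --- stage: resolve + score -------------------------------------------
    try:
        resolved = [resolve(r) for r in records]
        rows = []
        for r in resolved:
            row: dict[str, object] = {
                "id": r.id,
                "survived_to_discharge": r.survived_to_discharge,
                "n_imputed": r.n_imputed,
            }
            for name in config.scores:
                row[name] = SCORERS[name](r).total
            rows.append(row)
        score_path = out / "scores.csv"
        pd.DataFrame(rows).to_csv(score_path, index=False)
        artifacts["scores"] = score_path
    except Exception as e:
        raise PipelineError(f"stage score failed: {e}") from e

    # --- stage: evaluate ---------------------------------------------------
    try:
        auc_rows = []
        auc_json: dict[str, dict] = {}
        for method in config.roc_methods:
            for res in compare_scores(
                resolved, config.scores, method=method,
                n_boot=config.n_boot, seed=config.seed,
            ):
                auc_rows.append({
                    "score": res.score_name, "method": method,
                    "auc": round(res.auc, 4),
                    "ci_low": round(res.ci_low, 4),
                    "ci_high": round(res.ci_high, 4),
                    "n_deaths": res.n_pos, "n_survivors": res.n_neg,
                })
                auc_json.setdefault(res.score_name, {})[method] = {
                    "auc": res.auc, "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
        auc_path = out / "auc.csv"
        pd.DataFrame(auc_rows).to_csv(auc_path, index=False)
        artifacts["auc"] = auc_path
    except Exception as e:
        raise PipelineError(f"stage evaluate failed: {e}") from e

    # --- stage: report -----------------------------------------------------
    try:
        summary = summarize(resolved, score_names=config.scores)
        summary_txt = out / "summary.txt"
        summary_txt.write_text(format_summary(summary) + "\n")
        artifacts["summary_txt"] = summary_txt

        payload = {
            "n": summary.n,
            "n_survived": summary.n_survived,
            "n_died": summary.n_died,
            "mortality_pct": round_half_up(summary.mortality_pct),
            "mortality_ci_pct": [round_half_up(v) for v in summary.mortality_ci],
            "categories": {
                c.value: {
                    "n": summary.category_counts[c],
                    "pct": round_half_up(summary.category_pct[c][0]),
                }
                for c in summary.category_counts
            },
            "score_medians": {
                name: {
                    "median": s.median, "q1": s.q1, "q3": s.q3,
                }
                for name, s in summary.score_overall.items()
            },
            "auc": auc_json,
        }
        summary_json = out / "summary.json"
        summary_json.write_text(json.dumps(payload, indent=2, sort_keys=True))
        artifacts["summary_json"] = summary_json
    except Exception as e:
        raise PipelineError(f"stage report failed: {e}") from e

    manifest = {
        "package": "sepscore",
        "version": __version__,
        "seed": config.seed,
        "config": config.semantic_dict(),
        "config_hash": config.config_hash(),
        "artifacts": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return artifacts
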