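"""Table reading, run configuration, exclusion accounting and the pipeline.

The full relative-validity pipeline mirrors how such studies are run:
read the three input tables (questionnaire, FFQ, outcomes), exclude
incomplete records with per-cause accounting, score both instruments,
compute per-item and total-score agreement, a Bland-Altman summary,
quartile gradients of intake, and adjusted score-outcome associations.
All outputs are delimited text stamped with the package version and a
configuration hash; a fixed seed makes runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, SchemaError
from . import agreement as agreement_mod
from . import analysis as analysis_mod
from . import ffq as ffq_mod
from . import scoring as scoring_mod

logger = logging.getLogger("med4child")

QUESTIONNAIRE_COLUMNS = [f"q{i:02d}" for i in range(1, 19)]
BIOCHEMICAL_COLUMNS = ("total_chol", "hdl", "ldl", "tg", "glucose", "insulin")


def read_table(
    path: str | Path,
    column_dictionary: Mapping[str, str] | None = None,
    required: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a delimited table, canonicalise column names, validate schema.

    ``column_dictionary`` maps user column names to canonical ones.
    Missing mandatory columns raise :class:`SchemaError` naming them all.
    """
    df = pd.read_csv(path)
    if column_dictionary:
        df = df.rename(columns=dict(column_dictionary))
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory columns {missing}", missing_columns=missing
            )
    return df


class ExclusionFlow:
    """Sequential participant-flow accounting.

    Records the starting cohort size and per-cause exclusion counts in
    order, so the analysed n and the arithmetic of the flow (recruited
    minus excluded) are reproducible and loggable.
    """

    def __init__(self, n_start: int):
        if n_start < 0:
            raise ConfigurationError("n_start must be >= 0")
        self.n_start = int(n_start)
        self.steps: list[tuple[str, int]] = []

    def exclude(self, reason: str, n: int) -> None:
        if n < 0:
            raise ConfigurationError("exclusion count must be >= 0")
        if n > self.n_remaining:
            raise ConfigurationError(
                f"cannot exclude {n} of {self.n_remaining} remaining"
            )
        self.steps.append((reason, int(n)))
        logger.info("excluded %d (%s); %d remaining", n, reason, self.n_remaining)

    @property
    def n_excluded(self) -> int:
        return sum(n for _, n in self.steps)

    @property
    def n_remaining(self) -> int:
        return self.n_start - self.n_excluded

    def summary(self) -> pd.DataFrame:
        rows = [{"step": "recruited", "n_excluded": 0, "n_remaining": self.n_start}]
        remaining = self.n_start
        for reason, n in self.steps:
            remaining -= n
            rows.append({"step": reason, "n_excluded": n, "n_remaining": remaining})
        rows.append(
            {"step": "analysed", "n_excluded": self.n_excluded, "n_remaining": remaining}
        )
        return pd.DataFrame(rows)


def account_exclusions(
    questionnaire: pd.DataFrame,
    ffq_table: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> tuple[ExclusionFlow, pd.Index]:
    """Complete-case exclusion with per-cause sequential attribution.

    A child is excluded at the *first* failing stage: missing or
    incomplete questionnaire, then missing/incomplete FFQ food groups,
    then missing BMI, then missing biochemical parameters.  Returns the
    flow record and the child_ids retained for analysis.
    """
    all_ids = pd.Index(questionnaire["child_id"].astype(str)).union(
        pd.Index(ffq_table["child_id"].astype(str))
    ).union(pd.Index(outcomes["child_id"].astype(str)))
    flow = ExclusionFlow(len(all_ids))

    q = questionnaire.set_index(questionnaire["child_id"].astype(str))
    q_cols = [c for c in QUESTIONNAIRE_COLUMNS if c in q.columns]
    ok_q = pd.Series(False, index=all_ids)
    common = all_ids.intersection(q.index)
    ok_q.loc[common] = q.loc[common, q_cols].notna().all(axis=1)
    flow.exclude("missing questionnaire", int((~ok_q).sum()))
    remaining = all_ids[ok_q]

    f = ffq_table.set_index(ffq_table["child_id"].astype(str))
    needed = [g for g in ffq_mod.CANONICAL_GROUPS if g in f.columns]
    ok_f = pd.Series(False, index=remaining)
    common = remaining.intersection(f.index)
    ok_f.loc[common] = f.loc[common, needed].notna().all(axis=1)
    flow.exclude("missing FFQ", int((~ok_f).sum()))
    remaining = remaining[ok_f]

    o = outcomes.set_index(outcomes["child_id"].astype(str))
    ok_b = pd.Series(False, index=remaining)
    common = remaining.intersection(o.index)
    if "bmi" in o.columns:
        ok_b.loc[common] = o.loc[common, "bmi"].notna()
    else:
        ok_b.loc[common] = True
    flow.exclude("missing BMI", int((~ok_b).sum()))
    remaining = remaining[ok_b]

    bio = [c for c in BIOCHEMICAL_COLUMNS if c in o.columns]
    ok_bio = pd.Series(False, index=remaining)
    common = remaining.intersection(o.index)
    ok_bio.loc[common] = o.loc[common, bio].notna().all(axis=1) if bio else True
    flow.exclude("missing biochemical parameters", int((~ok_bio).sum()))
    remaining = remaining[ok_bio]

    return flow, remaining


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    questionnaire_path: str
    ffq_path: str
    outcomes_path: str
    output_dir: str
    registry_path: str | None = None
    mapping_path: str | None = None
    questionnaire_columns: Mapping[str, str] = field(default_factory=dict)
    ffq_columns: Mapping[str, str] = field(default_factory=dict)
    outcome_columns: Mapping[str, str] = field(default_factory=dict)
    quartile_mode: str = "fixed"  # "fixed" or "empirical"
    quartile_cutpoints: tuple[int, int, int] = scoring_mod.DEFAULT_QUARTILE_CUTPOINTS
    dichotomy_cutoff: int = scoring_mod.DEFAULT_DICHOTOMY_CUTOFF
    missing_policy: str = "complete_case"
    exclude_from_validation: tuple[int, ...] = (11,)
    sensitivity_items: tuple[int, ...] = ()
    quartile_variables: tuple[str, ...] = ()
    outcome_names: tuple[str, ...] = (
        "bmi", "wc", "hdl", "ldl", "tg", "total_chol", "homa",
    )
    seed: int = 0
    make_plot: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys {sorted(unknown)}")
        for key in ("quartile_cutpoints", "exclude_from_validation",
                    "sensitivity_items", "quartile_variables", "outcome_names"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v
             for k, v in self.__dict__.items()},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    flow: ExclusionFlow
    scored_questionnaire: pd.DataFrame
    scored_ffq: pd.DataFrame
    validation: pd.DataFrame
    bland_altman: "agreement_mod.BlandAltmanResult"
    quartile_summary: pd.DataFrame | None
    associations: pd.DataFrame
    sensitivity: pd.DataFrame | None
    config_hash: str


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full relative-validity pipeline and write the reports."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    registry = scoring_mod.load_registry(config.registry_path)
    mapping = ffq_mod.load_mapping(config.mapping_path)

    questionnaire = read_table(
        config.questionnaire_path,
        config.questionnaire_columns,
        required=["child_id", *QUESTIONNAIRE_COLUMNS],
    )
    ffq_table = read_table(config.ffq_path, config.ffq_columns, required=["child_id"])
    outcomes = read_table(
        config.outcomes_path, config.outcome_columns, required=["child_id"]
    )
    for df in (questionnaire, ffq_table, outcomes):
        df["child_id"] = df["child_id"].astype(str)

    flow, kept = account_exclusions(questionnaire, ffq_table, outcomes)
    questionnaire = questionnaire[questionnaire["child_id"].isin(kept)]
    ffq_table = ffq_table[ffq_table["child_id"].isin(kept)]
    outcomes = outcomes[outcomes["child_id"].isin(kept)]

    cutpoints = (
        "empirical" if config.quartile_mode == "empirical" else config.quartile_cutpoints
    )
    scored_q = scoring_mod.score_table(
        questionnaire,
        registry,
        policy=config.missing_policy,
        dichotomy_cutoff=config.dichotomy_cutoff,
        quartile_cutpoints=cutpoints,
    )
    scored_f = ffq_mod.derive_table(
        ffq_table, registry, mapping, dichotomy_cutoff=config.dichotomy_cutoff
    )

    results = agreement_mod.validate_items(
        questionnaire,
        ffq_table,
        registry,
        mapping,
        exclude_items=config.exclude_from_validation,
        dichotomy_cutoff=config.dichotomy_cutoff,
        policy=config.missing_policy,
    )
    validation = agreement_mod.validation_report(results)

    paired = scored_q.merge(scored_f, on="child_id", suffixes=("_q", "_f"))
    ba = agreement_mod.bland_altman(paired["total_q"], paired["total_f"])

    qsummary = None
    if config.quartile_variables:
        qsummary = analysis_mod.quartile_summary(
            ffq_table, scored_q, list(config.quartile_variables)
        )

    associations = analysis_mod.association_table(
        scored_q, outcomes, list(config.outcome_names)
    )

    sensitivity = None
    if config.sensitivity_items:
        sensitivity = analysis_mod.sensitivity_exclude(
            config.sensitivity_items,
            questionnaire,
            outcomes,
            list(config.outcome_names),
            registry,
            policy=config.missing_policy,
        )

    # ---- write the report bundle -------------------------------------
    stamp = {"med4child_version": __version__, "config_hash": config.hash(),
             "seed": config.seed}
    validation.to_csv(out_dir / "validation_report.csv", index=False)
    flow.summary().to_csv(out_dir / "participant_flow.csv", index=False)
    associations.to_csv(out_dir / "associations.csv", index=False)
    if qsummary is not None:
        qsummary.to_csv(out_dir / "quartile_summary.csv", index=False)
    if sensitivity is not None:
        sensitivity.to_csv(out_dir / "sensitivity.csv", index=False)
    pd.DataFrame(
        [{
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "n": len(ba.pairs),
        }]
    ).to_csv(out_dir / "bland_altman.csv", index=False)
    if config.make_plot:
        agreement_mod.bland_altman_plot(ba, out_dir / "bland_altman.png")
    (out_dir / "run_metadata.json").write_text(json.dumps(stamp, indent=2))

    return PipelineResult(
        flow=flow,
        scored_questionnaire=scored_q,
        scored_ffq=scored_f,
        validation=validation,
        bland_altman=ba,
        quartile_summary=qsummary,
        associations=associations,
        sensitivity=sensitivity,
        config_hash=config.hash(),
    )
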