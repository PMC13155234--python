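"""End-to-end study harness.

Simulates (or ingests) a 2-group x 3-condition walking cohort, runs the
three mixed ANOVAs (stride-time %CV, stride-length %CV, LDE) with condition
post hocs and per-condition simple main effects, and assembles a report whose
significance-pattern summary can be compared against the published findings
at the qualitative level (which effects and contrasts reject), never at the
level of exact F values — those depend on the original participants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .stats import AnovaResult, condition_posthoc, mixed_anova, simple_main_effects
from .synthetic import CONDITIONS, MEASURES, Cohort, CohortSpec, simulate_cohort

INGEST_COLUMNS = [
    "participant",
    "group",
    "condition",
    "stride_time_cv",
    "stride_length_cv",
    "lde",
]


@dataclass
class MeasureReport:
    measure: str
    anova: AnovaResult
    posthoc: pd.DataFrame
    simple_effects: pd.DataFrame


@dataclass
class StudyReport:
    measures: dict  # measure -> MeasureReport
    cohort_summary: pd.DataFrame
    pattern: dict
    provenance: dict

    def anova_tables(self) -> pd.DataFrame:
        frames = []
        for name, rep in self.measures.items():
            frame = rep.anova.to_frame()
            frame.insert(0, "measure", name)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_measurements_csv(path) -> pd.DataFrame:
    """Read a wide per-participant measurement CSV into the long table format.

    Expected columns: participant, group, condition, stride_time_cv,
    stride_length_cv, lde — one row per participant x condition. Raises with
    the missing column names on schema mismatch.
    """
    df = pd.read_csv(path)
    missing = [c for c in INGEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"measurement CSV missing columns {missing}; expected {INGEST_COLUMNS}"
        )
    long = df.melt(
        id_vars=["participant", "group", "condition"],
        value_vars=["stride_time_cv", "stride_length_cv", "lde"],
        var_name="measure",
        value_name="value",
    )
    return long


def significance_pattern(report_measures: dict, alpha: float = 0.05) -> dict:
    """Which effects and contrasts reject, per measure — the unit of
    comparison against the published results."""
    out: dict = {}
    for name, rep in report_measures.items():
        effects = {
            e.effect: bool(e.p < alpha) for e in rep.anova.effects()
        }
        posthoc = {
            f"{r.condition_a} vs {r.condition_b}": bool(r.p_holm < alpha)
            for r in rep.posthoc[rep.posthoc["family"] == "pooled"].itertuples()
        }
        simple = {
            r.condition: bool(r.p_holm < alpha)
            for r in rep.simple_effects.itertuples()
        }
        out[name] = {
            "effects": effects,
            "condition_pairs": posthoc,
            "group_within_condition": simple,
        }
    return out


def run_study(
    spec: CohortSpec | None = None,
    measurements: pd.DataFrame | None = None,
    alpha: float = 0.05,
    gg_policy: str = "auto",
    seed: int | None = None,
) -> StudyReport:
    """Run the full analysis over a synthetic cohort or ingested measurements.

    Exactly one of ``spec`` (synthetic path) or ``measurements`` (a long
    table with participant/group/condition/measure/value) drives the run;
    ``seed`` overrides the spec's seed. Deterministic given the inputs.
    """
    if (spec is None) == (measurements is None):
        raise ValueError("provide exactly one of spec or measurements")
    if spec is not None:
        if seed is not None:
            from dataclasses import replace

            spec = replace(spec, seed=seed)
        cohort = simulate_cohort(spec)
        table = cohort.table
        config = {"mode": "synthetic", "seed": spec.seed,
                  "n_per_group": spec.n_per_group, "alpha": alpha,
                  "gg_policy": gg_policy}
    else:
        table = measurements
        config = {"mode": "ingest", "alpha": alpha, "gg_policy": gg_policy}
        missing = {"participant", "group", "condition", "measure", "value"} - set(
            table.columns
        )
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")

    measures = {}
    for measure in MEASURES:
        long = table[table["measure"] == measure][
            ["participant", "group", "condition", "value"]
        ].reset_index(drop=True)
        if long.empty:
            raise ValueError(f"no rows for measure {measure!r}")
        measures[measure] = MeasureReport(
            measure=measure,
            anova=mixed_anova(long, gg_policy=gg_policy),
            posthoc=condition_posthoc(long, per_group=True),
            simple_effects=simple_main_effects(long),
        )

    summary = (
        table.groupby(["group", "condition", "measure"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return StudyReport(
        measures=measures,
        cohort_summary=summary,
        pattern=significance_pattern(measures, alpha=alpha),
        provenance={
            "config": config,
            "config_hash": _config_hash(config),
            "package_version": __version__,
        },
    )


def condition_means(report: StudyReport, measure: str) -> pd.DataFrame:
    """Group x condition mean table for one measure, columns ordered as the
    protocol's condition sequence."""
    sub = report.cohort_summary[report.cohort_summary["measure"] == measure]
    wide = sub.pivot(index="group", columns="condition", values="mean")
    return wide[list(CONDITIONS)]
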