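"""End-to-end study orchestration.

``run_study`` chains the stages in assay order — plate normalization,
effect calls against the plasmid-free reference, triplet dominance
classification, contingency tabulation and exact testing, conjugation
and growth summaries, correlation — writing every intermediate table so
each stage is auditable. The pipeline is a pure function of
(inputs, configuration): identical inputs and config give byte-identical
outputs.

Condition-label conventions: ``WT`` is the plasmid-free reference,
``BLANK`` an uninoculated well, ``A+B`` a strain carrying both plasmids
(intracellular) and ``A|B`` two co-cultured single-plasmid strains
(intercellular); any other label is a single-plasmid strain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, conjugation, growth, plates, regression, stats
from .classify import EffectCall, OutcomeClass, TripletMeasurements
from .plates import BLANK_CONDITION, REFERENCE_CONDITION, NormalizedSample

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyReport", "run_study", "summarize_outcomes", "co_habitation_of"]


@dataclass(frozen=True)
class RunConfig:
    plate_csv: Path | str
    out_dir: Path | str
    mating_csv: Path | str | None = None
    growth_csv: Path | str | None = None
    alpha: float = 0.05
    seed: int = 0
    max_outlier_removals: int = 2
    gate_on_omnibus: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")


@dataclass
class StudyReport:
    """In-memory results mirror of the files written by ``run_study``."""

    samples: list[NormalizedSample]
    effect_calls: list[EffectCall]
    outcomes: dict[str, OutcomeClass]
    direction_table: stats.ContingencyTable | None
    direction_p: float | None
    outcome_table: stats.ContingencyTable | None
    outcome_p: float | None
    summary: dict
    efficiencies: dict[str, float] = field(default_factory=dict)
    relative_rates: dict[str, list[float]] = field(default_factory=dict)
    correlation: regression.RegressionResult | None = None


def co_habitation_of(condition: str) -> plates.CoHabitation:
    if condition == REFERENCE_CONDITION:
        return "reference"
    if "+" in condition:
        return "intracellular"
    if "|" in condition:
        return "intercellular"
    return "single"


def summarize_outcomes(
    outcomes_by_mode: Mapping[str, Sequence[OutcomeClass]],
) -> dict:
    """Per-category counts per condition mode plus the dominance fraction.

    The dominance fraction is (DOMINANCE_HIGHEST + DOMINANCE_LOWEST)
    divided by the total number of classified pairs across modes.
    """
    total = sum(len(v) for v in outcomes_by_mode.values())
    if total == 0:
        raise ValueError("no outcomes to summarize")
    counts = {
        mode: {
            cat: sum(1 for o in items if o.category.value == cat)
            for cat in classify.OUTCOME_CATEGORIES
        }
        for mode, items in outcomes_by_mode.items()
    }
    n_dom = sum(
        c["DOMINANCE_HIGHEST"] + c["DOMINANCE_LOWEST"] for c in counts.values()
    )
    return {"counts": counts, "total": total, "dominance_fraction": n_dom / total}


def _build_triplets(
    samples: Sequence[NormalizedSample],
) -> list[TripletMeasurements]:
    by_cond = {s.condition: s for s in samples}
    triplets = []
    for s in samples:
        for sep, mode in (("+", "intracellular"), ("|", "intercellular")):
            if sep in s.condition:
                a, b = s.condition.split(sep, 1)
                if a in by_cond and b in by_cond and min(
                    len(s.values), len(by_cond[a].values), len(by_cond[b].values)
                ) >= 3:
                    triplets.append(
                        TripletMeasurements(
                            pair_id=s.condition,
                            condition_mode=mode,  # type: ignore[arg-type]
                            label_a=a,
                            label_b=b,
                            values_ab=s.values,
                            values_a=by_cond[a].values,
                            values_b=by_cond[b].values,
                        )
                    )
    return triplets


def _read_mating_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"pair_id", "role", "colonies", "dilution_factor", "plated_volume_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _conjugation_stage(path: Path, out_dir: Path) -> dict[str, float]:
    df = _read_mating_csv(path)
    rows = []
    efficiencies: dict[str, list[float]] = {}
    for (pair_id, rep), grp in df.groupby(
        ["pair_id", "replicate_id"] if "replicate_id" in df.columns else ["pair_id", "role"]
    ):
        densities = {}
        for _, r in grp.iterrows():
            densities[r["role"]] = conjugation.cfu_per_ml(
                conjugation.CfuCount(
                    int(r["colonies"]), float(r["dilution_factor"]), float(r["plated_volume_ml"])
                )
            )
        if {"T", "D", "R"} <= set(densities):
            eff = conjugation.conjugation_efficiency(
                conjugation.MatingCounts(densities["T"], densities["D"], densities["R"])
            )
            efficiencies.setdefault(str(pair_id), []).append(eff.value)
            rows.append(
                {"pair_id": pair_id, "replicate": rep, "efficiency_ml_per_cfu": eff.value,
                 "zero_transconjugants": eff.zero_transconjugants}
            )
        if {"double", "total"} <= set(densities):
            dsub = grp[grp["role"] == "double"].iloc[0]
            tsub = grp[grp["role"] == "total"].iloc[0]
            prop = conjugation.double_plasmid_proportion(
                conjugation.CfuCount(int(dsub["colonies"]), float(dsub["dilution_factor"]),
                                     float(dsub["plated_volume_ml"])),
                conjugation.CfuCount(int(tsub["colonies"]), float(tsub["dilution_factor"]),
                                     float(tsub["plated_volume_ml"])),
            )
            rows.append({"pair_id": pair_id, "replicate": rep, "double_proportion": prop})
    pd.DataFrame(rows).to_csv(out_dir / "conjugation.csv", index=False)
    return {p: float(np.mean(v)) for p, v in efficiencies.items()}


def _growth_stage(path: Path, out_dir: Path) -> dict[str, list[float]]:
    df = pd.read_csv(path)
    required = {"strain", "replicate_id", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    per_strain_rates: dict[str, list[float]] = {}
    rows = []
    for (strain, rep), grp in df.sort_values("time_min").groupby(["strain", "replicate_id"]):
        curve = growth.GrowthCurve(
            times=tuple(grp["time_min"]), od600=tuple(grp["od600"]), replicate_id=str(rep)
        )
        est = growth.fit_growth_rate(curve)
        rows.append(
            {"strain": strain, "replicate_id": rep, "rate_per_min": est.rate,
             "r_squared": est.r_squared, "accepted": est.accepted}
        )
        if est.accepted:
            per_strain_rates.setdefault(str(strain), []).append(est.rate)
    if REFERENCE_CONDITION not in per_strain_rates:
        raise ValueError("growth stage: no accepted plasmid-free reference curves")
    relative = {
        strain: growth.relative_growth_rate(rates, per_strain_rates[REFERENCE_CONDITION])
        for strain, rates in per_strain_rates.items()
    }
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "growth_rates.csv", index=False)
    pd.DataFrame(
        [
            {"strain": s, "relative_rate_mean": float(np.mean(v)), "n": len(v)}
            for s, v in relative.items()
        ]
    ).to_csv(out_dir / "relative_growth_rates.csv", index=False)
    return relative


def run_study(cfg: RunConfig) -> StudyReport:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Stages: read + normalize plates; aggregate replicates; effect calls
    (Welch omnibus + Dunnett vs. WT); triplet classification (Welch +
    Tukey); direction and outcome contingency tables with exact p-values;
    optional conjugation and growth stages; correlation of mean relative
    biofilm against log10 efficiency when both are available. Any stage
    failure aborts with the stage name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("normalize")
    try:
        readings = plates.read_plate_csv(cfg.plate_csv)
        if not readings:
            raise ValueError("no well readings in input")
        by_plate: dict[str, list] = {}
        for w in readings:
            by_plate.setdefault(w.plate_id, []).append(w)
        normalized = []
        for plate in by_plate.values():
            plates.check_raw_envelopes(plate)
            normalized.extend(plates.normalize_plate(plate))
        co_hab = {w.condition: co_habitation_of(w.condition) for w, _ in normalized}
        samples = plates.aggregate_replicates(normalized, co_habitation=co_hab)
        pd.DataFrame(
            [
                {"condition": s.condition, "co_habitation": s.co_habitation,
                 "replicate_index": i + 1, "relative_value": v}
                for s in samples
                for i, v in enumerate(s.values)
            ]
        ).to_csv(out_dir / "normalized.csv", index=False)

        current = stage("effects")
        reference = next(s for s in samples if s.condition == REFERENCE_CONDITION)
        others = [s for s in samples if s.condition != REFERENCE_CONDITION]
        calls = classify.call_effects(
            others, reference, alpha=cfg.alpha, gate_on_omnibus=cfg.gate_on_omnibus
        )
        pd.DataFrame(
            [
                {"condition": c.condition, "direction": c.direction,
                 "p_adjusted": c.p_adjusted}
                for c in calls
            ]
        ).to_csv(out_dir / "effect_calls.csv", index=False)

        current = stage("dominance")
        triplets = _build_triplets(samples)
        outcomes: dict[str, OutcomeClass] = {}
        outcome_rows = []
        for t in triplets:
            oc = classify.classify_triplet(t, alpha=cfg.alpha, gate_on_omnibus=cfg.gate_on_omnibus)
            outcomes[t.pair_id] = oc
            outcome_rows.append(
                {"pair_id": t.pair_id, "condition_mode": t.condition_mode,
                 "category": oc.category.value, "dominant_plasmid": oc.dominant_plasmid or ""}
            )
        pd.DataFrame(outcome_rows).to_csv(out_dir / "outcomes.csv", index=False)

        current = stage("tabulate")

        def exact_p(table: stats.ContingencyTable) -> float | None:
            # empty categories carry no information; the exact test needs
            # positive margins, so all-zero columns are dropped first
            arr = table.array
            keep = arr.sum(axis=0) > 0
            if keep.sum() < 2:
                return None
            trimmed = stats.ContingencyTable(
                counts=tuple(tuple(int(v) for v in row[keep]) for row in arr),
                row_labels=table.row_labels,
                col_labels=tuple(np.array(table.col_labels)[keep]),
            )
            return stats.fisher_exact_rxc(trimmed)

        call_mode = {c.condition: co_habitation_of(c.condition) for c in calls}
        pair_calls = {
            mode: [c for c in calls if call_mode[c.condition] == mode]
            for mode in ("intracellular", "intercellular")
        }
        direction_table = direction_p = None
        if all(pair_calls.values()):
            direction_table = classify.tabulate_outcomes(pair_calls)
            direction_p = exact_p(direction_table)
        outcome_table = outcome_p = None
        by_mode = {
            mode: [outcomes[t.pair_id] for t in triplets if t.condition_mode == mode]
            for mode in ("intracellular", "intercellular")
        }
        by_mode = {m: v for m, v in by_mode.items() if v}
        if len(by_mode) >= 2:
            outcome_table = classify.tabulate_outcomes(by_mode)
            outcome_p = exact_p(outcome_table)
        summary = summarize_outcomes(by_mode) if by_mode else {}

        efficiencies: dict[str, float] = {}
        relative_rates: dict[str, list[float]] = {}
        if cfg.mating_csv is not None:
            current = stage("conjugation")
            efficiencies = _conjugation_stage(Path(cfg.mating_csv), out_dir)
        if cfg.growth_csv is not None:
            current = stage("growth")
            relative_rates = _growth_stage(Path(cfg.growth_csv), out_dir)

        correlation_result = None
        if efficiencies:
            current = stage("correlate")
            labels = [l for l in efficiencies if l in {s.condition for s in samples}]
            kept_labels, logx = regression.log10_positive(
                labels, [efficiencies[l] for l in labels]
            )
            if len(kept_labels) >= 5:
                sample_of = {s.condition: s for s in samples}
                series = regression.PairedSeries(
                    labels=tuple(kept_labels),
                    x=tuple(logx),
                    y=tuple(float(np.mean(sample_of[l].values)) for l in kept_labels),
                )
                correlation_result = regression.correlate_with_exclusion(
                    series, max_removals=cfg.max_outlier_removals, alpha=cfg.alpha
                )
                (out_dir / "correlation.json").write_text(
                    json.dumps(correlation_result.__dict__, indent=2, default=list)
                )

        current = stage("report")
        report_json = {
            "alpha": cfg.alpha,
            "seed": cfg.seed,
            "n_conditions": len(samples),
            "direction_table": direction_table.counts if direction_table else None,
            "direction_fisher_p": direction_p,
            "outcome_table": outcome_table.counts if outcome_table else None,
            "outcome_fisher_p": outcome_p,
            "summary": summary,
        }
        (out_dir / "contingency.json").write_text(json.dumps(report_json, indent=2))
        (out_dir / "run_log.txt").write_text(
            f"alpha={cfg.alpha}\nseed={cfg.seed}\n"
            f"gate_on_omnibus={cfg.gate_on_omnibus}\n"
            f"max_outlier_removals={cfg.max_outlier_removals}\n"
            f"n_readings={len(readings)}\nn_conditions={len(samples)}\n"
            f"n_triplets={len(triplets)}\n"
        )
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    return StudyReport(
        samples=samples,
        effect_calls=calls,
        outcomes=outcomes,
        direction_table=direction_table,
        direction_p=direction_p,
        outcome_table=outcome_table,
        outcome_p=outcome_p,
        summary=summary,
        efficiencies=efficiencies,
        relative_rates=relative_rates,
        correlation=correlation_result,
    )
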