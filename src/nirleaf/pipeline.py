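"""End-to-end drivers chaining the stages into the three experiments.

Experiment 1 (fertilization) fits the four calibrations (leaf N and leaf P,
each on fresh and dried spectra; leaf N under a natural-log response).
Experiment 2 (conservation) applies the dried-leaf N reference calibration
to fresh, dried and treated spectra and compares treatment groups and
measurement sources with Kruskal-Wallis / Dunn tests.  Experiment 3
(storage) predicts leaf N from two scan sessions of the same specimens and
reports the three Pearson correlations (t0-t1, t0-lab, t1-lab).

A master seed fans out to per-stage seeds through a SeedSequence-based
splitting rule, so a full run is deterministic end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    evaluate_model,
    optimize_calibration,
    transform_response,
)
from .group_stats import KWResult, dunn_test, kruskal_wallis, pearson_cor
from .spectra import SpectraSet, average_replicates, splice_correct
from .synthetic import (
    SimConfig,
    generate_fertilization_experiment,
    generate_storage_experiment,
    generate_treatment_experiment,
)

#: The four calibrations of experiment 1: (trait, state, response transform).
EXPERIMENT1_MODELS = (
    ("leaf_N", "fresh", "natural_log"),
    ("leaf_N", "dried", "natural_log"),
    ("leaf_P", "fresh", "identity"),
    ("leaf_P", "dried", "identity"),
)

#: Key of the reference calibration reused in experiments 2 and 3.
REFERENCE_MODEL_KEY = "leaf_N_dried"

ALPHA = 0.05


def stage_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds from one master seed (all < 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def preprocess(s: SpectraSet) -> SpectraSet:
    """Standard preprocessing: splice-correct each scan, then average
    replicates per leaf and state."""
    return average_replicates(splice_correct(s))


@dataclass
class ExperimentReport:
    """Serializable record of one experiment run: metrics, comparisons and
    the file paths of persisted artifacts, plus the seed it ran under."""

    name: str
    metrics: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metrics": self.metrics,
            "comparisons": self.comparisons,
            "artifacts": self.artifacts,
            "config": self.config,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = [f"# {self.name}", ""]
        if self.metrics:
            lines += ["## Metrics", ""]
            for key in sorted(self.metrics):
                lines.append(f"- **{key}**: {json.dumps(self.metrics[key], sort_keys=True)}")
            lines.append("")
        if self.comparisons:
            lines += ["## Comparisons", ""]
            for key in sorted(self.comparisons):
                lines.append(f"- **{key}**: {json.dumps(self.comparisons[key], sort_keys=True)}")
            lines.append("")
        if self.artifacts:
            lines += ["## Artifacts", ""]
            for key in sorted(self.artifacts):
                lines.append(f"- {key}: `{self.artifacts[key]}`")
            lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# experiment 1: fertilization
# ---------------------------------------------------------------------------

def run_experiment1(
    cfg: SimConfig,
    seed: int,
    out_dir: str | Path | None = None,
    per_species: bool = False,
    n_iterations: int = 200,
) -> tuple[ExperimentReport, dict[str, CalibrationModel]]:
    """Generate fertilization data and fit the four calibrations."""
    seeds = stage_seeds(seed, 5)
    fresh, dried, ref = generate_fertilization_experiment(cfg, seed=seeds[0])
    spectra = {"fresh": preprocess(fresh), "dried": preprocess(dried)}

    report = ExperimentReport(name="experiment1_fertilization", config={"seed": seed})
    models: dict[str, CalibrationModel] = {}
    out = _ensure_dir(out_dir)
    for i, (trait, state, transform) in enumerate(EXPERIMENT1_MODELS):
        model = optimize_calibration(
            spectra[state],
            ref,
            trait=trait,
            state=state,
            transform=transform,
            n_iterations=n_iterations,
            seed=seeds[i + 1],
        )
        key = f"{trait}_{state}"
        models[key] = model
        report.metrics[key] = model.metrics.to_dict() | {"transform": transform}
        if per_species:
            report.metrics[key]["per_species"] = _per_species_metrics(
                model, spectra[state], ref
            )
        if out is not None:
            mpath = out / f"model_{key}.json"
            model.to_json(mpath)
            model.iteration_log.to_csv(out / f"iterations_{key}.csv", index=False)
            preds = _validation_predictions(model, spectra[state], ref)
            ppath = out / f"predictions_{key}.csv"
            preds.to_csv(ppath, index=False)
            report.artifacts[key] = mpath.name
            report.artifacts[f"{key}_predictions"] = ppath.name
    return report, models


def _validation_predictions(model, s, ref) -> pd.DataFrame:
    val_ids = set(model.split.validation_ids)
    sub = s.for_state(model.state)
    sub = sub.select(sub.meta["sample_id"].isin(val_ids).to_numpy())
    preds = model.predict(sub)
    obs = ref.trait(model.trait).loc[preds["sample_id"]].to_numpy()
    preds[f"observed_{model.trait}"] = obs
    return preds


def _per_species_metrics(model, s, ref) -> dict:
    preds = _validation_predictions(model, s, ref)
    merged = preds.merge(
        ref.table[["sample_id", "species"]], on="sample_id", how="left"
    )
    out = {}
    for sp, g in merged.groupby("species", sort=True):
        obs = transform_response(g[f"observed_{model.trait}"], model.transform)
        pred = g[f"predicted_{model.trait}_transformed"].to_numpy()
        if len(g) >= 3 and np.ptp(obs) > 0:
            rep = evaluate_model(obs, pred)
            out[sp] = {"r_squared": rep.r_squared, "rmsep": rep.rmsep, "n": len(g)}
    return out


# ---------------------------------------------------------------------------
# experiment 2: conservation treatments
# ---------------------------------------------------------------------------

def run_experiment2(
    cfg: SimConfig,
    reference_model: CalibrationModel,
    seed: int,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Apply the reference calibration to fresh/dried/treated spectra and
    compare treatment groups and measurement sources."""
    fresh, dried, treated, ref = generate_treatment_experiment(cfg, seed=seed)
    sets = {
        "fresh": preprocess(fresh),
        "dried": preprocess(dried),
        "treated": preprocess(treated),
    }
    trait = reference_model.trait
    preds = {name: reference_model.predict(s) for name, s in sets.items()}
    lab = ref.trait(trait)

    report = ExperimentReport(name="experiment2_conservation", config={"seed": seed})
    out = _ensure_dir(out_dir)
    if out is not None:
        for name, p in preds.items():
            path = out / f"predictions_{name}.csv"
            p.to_csv(path, index=False)
            report.artifacts[f"predictions_{name}"] = path.name

    # treatment groups: predicted leaf N of treated-state scans by group
    tp = preds["treated"]
    by_group = {
        g: grp[f"predicted_{trait}"].to_numpy()
        for g, grp in tp.groupby("group", sort=True)
    }
    kw_groups = kruskal_wallis(by_group)
    report.comparisons["kw_treatment_groups"] = kw_groups.to_dict()
    if kw_groups.p_value < ALPHA:
        report.comparisons["dunn_treatment_groups"] = dunn_test(by_group).to_dict()

    # four measurement sources, treated as independent groups (as reported)
    sources = {
        name: p[f"predicted_{trait}"].to_numpy() for name, p in preds.items()
    }
    sources["laboratory"] = lab.to_numpy()
    kw_sources = kruskal_wallis(sources)
    report.comparisons["kw_sources"] = kw_sources.to_dict()
    if kw_sources.p_value < ALPHA:
        report.comparisons["dunn_sources"] = dunn_test(sources).to_dict()
    return report


def treatment_group_test(
    cfg: SimConfig, reference_model: CalibrationModel, seed: int
) -> KWResult:
    """Just the treatment-group Kruskal-Wallis of experiment 2 (cheap path
    for repeated-replicate studies): generate, predict treated scans, test."""
    _, _, treated, _ = generate_treatment_experiment(cfg, seed=seed)
    tp = reference_model.predict(preprocess(treated))
    trait = reference_model.trait
    by_group = {
        g: grp[f"predicted_{trait}"].to_numpy()
        for g, grp in tp.groupby("group", sort=True)
    }
    return kruskal_wallis(by_group)


# ---------------------------------------------------------------------------
# experiment 3: storage duration
# ---------------------------------------------------------------------------

def run_experiment3(
    cfg: SimConfig,
    reference_model: CalibrationModel,
    seed: int,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Predict leaf N from both scan sessions and correlate with the lab."""
    scan_t0, scan_t1, ref = generate_storage_experiment(cfg, seed=seed)
    trait = reference_model.trait
    p0 = reference_model.predict(preprocess(scan_t0))
    p1 = reference_model.predict(preprocess(scan_t1))
    lab = ref.trait(trait).loc[p0["sample_id"]].to_numpy()
    y0 = p0[f"predicted_{trait}"].to_numpy()
    y1 = p1[f"predicted_{trait}"].to_numpy()

    report = ExperimentReport(name="experiment3_storage", config={"seed": seed})
    report.comparisons["pearson"] = {
        "t0_t1": pearson_cor(y0, y1),
        "t0_laboratory": pearson_cor(y0, lab),
        "t1_laboratory": pearson_cor(y1, lab),
    }
    out = _ensure_dir(out_dir)
    if out is not None:
        for name, p in (("t0", p0), ("t1", p1)):
            path = out / f"predictions_{name}.csv"
            p.to_csv(path, index=False)
            report.artifacts[f"predictions_{name}"] = path.name
    return report


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(
    cfg: SimConfig,
    seed: int,
    out_dir: str | Path | None = None,
    n_iterations: int = 200,
) -> dict[str, ExperimentReport]:
    """Run all three experiments under one master seed.

    The master seed is split into one stage seed per experiment; the
    dried-leaf N calibration from experiment 1 serves as the reference
    model for experiments 2 and 3.
    """
    s1, s2, s3 = stage_seeds(seed, 3)
    out = _ensure_dir(out_dir)
    sub = {k: (None if out is None else out / k) for k in ("exp1", "exp2", "exp3")}

    rep1, models = run_experiment1(cfg, s1, out_dir=sub["exp1"], n_iterations=n_iterations)
    reference = models[REFERENCE_MODEL_KEY]
    rep2 = run_experiment2(cfg, reference, s2, out_dir=sub["exp2"])
    rep3 = run_experiment3(cfg, reference, s3, out_dir=sub["exp3"])

    reports = {"experiment1": rep1, "experiment2": rep2, "experiment3": rep3}
    subdir = {"experiment1": "exp1", "experiment2": "exp2", "experiment3": "exp3"}
    for k, r in reports.items():
        r.artifacts = {a: f"{subdir[k]}/{v}" for a, v in r.artifacts.items()}
    if out is not None:
        combined = {
            "master_seed": seed,
            "stage_seeds": {"experiment1": s1, "experiment2": s2, "experiment3": s3},
            "reports": {k: r.to_dict() for k, r in reports.items()},
        }
        (out / "report.json").write_text(json.dumps(combined, indent=2, sort_keys=True))
        md = "\n\n".join(r.to_markdown() for r in reports.values())
        (out / "report.md").write_text(md)
    return reports


def _ensure_dir(out_dir) -> Path | None:
    if out_dir is None:
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
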