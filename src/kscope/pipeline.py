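"""End-to-end orchestration: simulate -> score -> type -> cluster -> select
-> classify, with a reproducibility manifest.

A single :class:`RunConfig` carries every stage parameter (rarefaction
depth 1391, generalized-UniFrac alpha 0.5, 50% prevalence, Kruskal-Wallis
alpha 0.05, LDA threshold 2.0, 999 permutations, 80/20 split, aging
cutpoints 35/51 or cohort-detected) plus one global seed from which each
stage derives its own seed, so individual stages re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biophys, bsti, ksc, models, synthetic
from . import microbiome as mb

__all__ = ["RunConfig", "run", "stage_seed"]

_STAGES = ("simulate", "bsti", "metrics", "ksc", "cluster", "core", "classify")


@dataclass
class RunConfig:
    """All stage parameters and toggles for one pipeline run."""

    n_subjects: int = 300
    seed: int = 0
    rarefaction_depth: int = 1391
    gunifrac_alpha: float = 0.5
    prevalence_threshold: float = 0.5
    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_permutations: int = 999
    split_fraction: float = 0.8
    cutpoints: tuple[int, int] | str = (35, 51)   # or "detect"
    missing_rate: float = 0.05
    stages: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must be in (0, 1]")
        if not 0 < self.kw_alpha < 1:
            raise ValueError("kw_alpha must be in (0, 1)")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "cutpoints" in data and isinstance(data["cutpoints"], list):
            data["cutpoints"] = tuple(data["cutpoints"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        if isinstance(self.cutpoints, tuple):
            data["cutpoints"] = list(self.cutpoints)
        Path(path).write_text(yaml.safe_dump(data))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order.

    Writes per-stage outputs under ``out_dir`` and a ``manifest.json``
    recording parameters, derived seeds and output hashes; re-running with
    an identical config reproduces byte-identical numeric outputs.  A stage
    failure aborts with a stage-tagged error, keeping earlier outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    state: dict = {}

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        seed = stage_seed(config.seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        try:
            _run_stage(stage, config, seed, state, out, manifest)
        except Exception as exc:                       # noqa: BLE001
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for name, path in manifest["outputs"].items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    import kscope

    manifest["versions"] = {
        "kscope": kscope.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _run_stage(stage, config, seed, state, out, manifest) -> None:
    if stage == "simulate":
        cohort = synthetic.simulate_cohort(
            synthetic.CohortConfig(n_subjects=config.n_subjects, seed=seed)
        )
        state["cohort"] = cohort
        state["responses"] = synthetic.simulate_responses(
            cohort, missing_rate=config.missing_rate, seed=seed + 1
        )
        paths = synthetic.write_cohort(cohort, out / "cohort")
        state["responses"].to_csv(out / "cohort" / "questionnaire.csv")
        manifest["outputs"].update({f"cohort_{k}": p for k, p in paths.items()})
        manifest["outputs"]["questionnaire"] = out / "cohort" / "questionnaire.csv"

    elif stage == "bsti":
        resp = state["responses"]
        scores = bsti.score_table(resp, categories=resp.attrs.get("categories"))
        dist = bsti.type_distribution(scores["bsti"])
        scores.to_csv(out / "bsti_scores.csv")
        dist.to_csv(out / "bsti_distribution.csv")
        state["bsti"] = scores
        manifest["outputs"]["bsti_scores"] = out / "bsti_scores.csv"
        manifest["outputs"]["bsti_distribution"] = out / "bsti_distribution.csv"

    elif stage == "metrics":
        panel = biophys.build_metric_panel(state["cohort"].subjects)
        panel.to_csv(out / "metrics.csv")
        state["panel"] = panel
        manifest["stages"]["metrics"]["representatives"] = panel.attrs["representatives"]
        manifest["outputs"]["metrics"] = out / "metrics.csv"

    elif stage == "ksc":
        panel = state["panel"]
        ages = state["cohort"].subjects["age"]
        composites = panel[["tone_elasticity", "oil_moisture"]]
        if config.cutpoints == "detect":
            tone_rep = ksc.proportion_curves(composites["tone_elasticity"], ages, "tone_elasticity")
            oil_rep = ksc.proportion_curves(composites["oil_moisture"], ages, "oil_moisture")
            ksc.detect_crossovers(tone_rep)
            ksc.detect_crossovers(oil_rep)
            c1, c2 = ksc.select_cutpoints(tone_rep, oil_rep)
        else:
            c1, c2 = config.cutpoints
        labels = ksc.assign_ksc(composites, ages, c1, c2)
        labels.to_csv(out / "ksc_labels.csv")
        state["labels"] = labels
        manifest["stages"]["ksc"]["cutpoints"] = [int(c1), int(c2)]
        manifest["outputs"]["ksc_labels"] = out / "ksc_labels.csv"

    elif stage == "cluster":
        table = mb.rarefy(state["cohort"].counts, config.rarefaction_depth, seed=seed)
        dist = mb.generalized_unifrac(table, state["cohort"].tree, alpha=config.gunifrac_alpha)
        top = mb.optimal_k(dist, seed=seed)
        div = mb.divcom_subcluster(dist, top.solutions[top.consensus_k], seed=seed)
        state.update(table=table, dist=dist, top=top, divcom=div)
        div.subcluster.rename("subcluster").to_csv(out / "subclusters.csv")
        manifest["stages"]["cluster"].update(
            consensus_k=top.consensus_k, votes=top.votes,
            n_unclassified=len(div.unclassified),
            n_dropped=len(table.dropped_samples),
        )
        manifest["outputs"]["subclusters"] = out / "subclusters.csv"

    elif stage == "core":
        report = mb.core_genus_selection(
            state["table"], state["divcom"].subcluster,
            prevalence_threshold=config.prevalence_threshold,
            alpha=config.kw_alpha,
        )
        state["core"] = report
        pd.DataFrame(
            {"prevalence": report.prevalence,
             "kw_p": report.pvalues.reindex(report.prevalence.index),
             "prevalent": report.prevalence.index.isin(report.prevalent),
             "core": report.prevalence.index.isin(report.core)}
        ).to_csv(out / "core_genera.csv")
        manifest["stages"]["core"].update(
            n_prevalent=len(report.prevalent), n_core=len(report.core)
        )
        manifest["outputs"]["core_genera"] = out / "core_genera.csv"

    elif stage == "classify":
        table, report = state["table"], state["core"]
        rel = table.relative_abundance()[report.core]
        labels = state["labels"].loc[rel.index]
        spec = models.ModelSpec(split_fraction=config.split_fraction, seed=seed)
        results = models.train_type_models(rel, labels, spec)
        summary = pd.DataFrame(
            [{"group": r.group, "type": r.type_label, "test_auc": r.test_auc,
              "n_train": r.n_train, "n_test": r.n_test} for r in results]
        )
        summary.to_csv(out / "type_models.csv", index=False)
        if len(results) >= 2:
            models.feature_importance_heatmap(results).to_csv(out / "importance_matrix.csv")
            manifest["outputs"]["importance_matrix"] = out / "importance_matrix.csv"
        state["models"] = results
        manifest["stages"]["classify"]["model"] = spec.metadata
        manifest["outputs"]["type_models"] = out / "type_models.csv"
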