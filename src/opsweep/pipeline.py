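"""End-to-end pipeline: generate -> classify -> train -> sweep -> stats.

One global seed expands deterministically into per-stage seeds (cohort
generation, each surrogate fit, the reliability ratings) so stages can be
re-run in isolation and chained runs equal the all-in-one run.  Every
artifact directory gets a JSON manifest embedding the config hash and the
seeds, sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import tables
from .classify import ClassificationRuleSet, classify_cohort
from .data import Cohort, write_cohort
from .stats import build_table56, reliability_report
from .surrogate import SurrogateRegression, SurrogateResults
from .sweep import SweepGrid, run_sweep, summarize_slopes
from .synthetic import GeneratorConfig, generate_cohort, repeated_measures

__all__ = ["RunConfig", "stage_seeds", "run_all"]

_STAGES = ("generate", "fit_FHR", "fit_FA", "ratings")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    vals = ss.generate_state(len(_STAGES)) % (2**31)
    return {stage: int(v) for stage, v in zip(_STAGES, vals)}


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    rules: ClassificationRuleSet = field(default_factory=ClassificationRuleSet)
    grid: SweepGrid = field(default_factory=SweepGrid)
    hidden: int = 10
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    patience: int = 20
    max_epochs: int = 1000
    restarts: int = 3
    alpha: float = 0.05
    reliability_subjects: int = 50
    n_raters: int = 3
    n_sessions: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:16]

    def to_yaml_str(self) -> str:
        d = {
            "seed": self.seed, "hidden": self.hidden,
            "ratios": list(self.ratios), "patience": self.patience,
            "max_epochs": self.max_epochs, "restarts": self.restarts,
            "alpha": self.alpha,
            "reliability_subjects": self.reliability_subjects,
            "n_raters": self.n_raters, "n_sessions": self.n_sessions,
            "grid": {"start": self.grid.start, "stop": self.grid.stop,
                     "step": self.grid.step},
            "generator": {"n": self.generator.n,
                          "allocation": self.generator.allocation,
                          "sigma_fhr": self.generator.sigma_fhr,
                          "sigma_fa": self.generator.sigma_fa},
        }
        return yaml.safe_dump(d, sort_keys=False)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml_str())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("seed", "hidden", "patience", "max_epochs", "restarts",
                    "alpha", "reliability_subjects", "n_raters",
                    "n_sessions"):
            if key in d:
                setattr(cfg, key, d[key])
        if "ratios" in d:
            cfg.ratios = tuple(d["ratios"])
        if "grid" in d:
            cfg.grid = SweepGrid(**d["grid"])
        if "generator" in d:
            g = d["generator"]
            cfg.generator = GeneratorConfig(
                n=g.get("n", tables.TOTAL_N),
                allocation=g.get("allocation", "table3_exact"),
                sigma_fhr=g.get("sigma_fhr", 0.5),
                sigma_fa=g.get("sigma_fa", 0.8))
        return cfg


def _fit_surrogate(cohort: Cohort, outcome: str, config: RunConfig,
                   seed: int) -> SurrogateResults:
    model = SurrogateRegression.from_dataframe(
        cohort.to_frame(), outcome, hidden=config.hidden,
        ratios=config.ratios, patience=config.patience,
        max_epochs=config.max_epochs, restarts=config.restarts)
    return model.fit(seed=seed)


def run_all(config: RunConfig, outdir: str | Path,
            log=lambda msg: None) -> dict:
    """Run every stage, write flat CSV/JSON artifacts, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "seed": config.seed,
                      "stage_seeds": seeds, "files": []}
    report: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    def emit(name: str, path: Path):
        manifest["files"].append({"name": name, "path": path.name})

    t0 = time.time()
    gen_cfg = dataclasses.replace(config.generator, seed=seeds["generate"])
    cohort, truth = generate_cohort(gen_cfg)
    write_cohort(cohort, outdir / "cohort.csv")
    truth.to_csv(outdir / "truth.csv", index=False, float_format="%.6f")
    emit("cohort", outdir / "cohort.csv")
    emit("truth", outdir / "truth.csv")
    log(f"generate: {len(cohort)} records in {time.time() - t0:.1f}s "
        f"(seed {seeds['generate']})")
    report["stages"]["generate"] = {"n": len(cohort),
                                    "seed": seeds["generate"]}

    cls = classify_cohort(cohort, config.rules)
    labeled = cohort.to_frame()
    labeled["sagittal"] = [l.sagittal for l in cls["labels"]]
    labeled["vertical"] = [l.vertical for l in cls["labels"]]
    labeled.to_csv(outdir / "cohort_labeled.csv", index=False,
                   float_format="%.6f")
    emit("cohort_labeled", outdir / "cohort_labeled.csv")
    report["stages"]["classify"] = {
        "agreement": cls["agreement"],
        "table": cls["table"].to_dict()}
    log(f"classify: agreement {cls['agreement']}")

    labels = cls["labels"]
    for outcome in ("FHR", "FA"):
        t1 = time.time()
        res = _fit_surrogate(cohort, outcome, config,
                             seeds[f"fit_{outcome}"])
        res.to_json(outdir / f"model_{outcome}.json")
        res.training_curves().to_csv(outdir / f"curves_{outcome}.csv",
                                     index=False)
        emit(f"model_{outcome}", outdir / f"model_{outcome}.json")
        emit(f"curves_{outcome}", outdir / f"curves_{outcome}.csv")
        agree = res.agreement("test")
        sw = run_sweep(res, cohort, config.grid, outcome)
        sw.with_labels(labels).to_csv(outdir / f"slopes_{outcome}.csv",
                                      index=False, float_format="%.6f")
        emit(f"slopes_{outcome}", outdir / f"slopes_{outcome}.csv")
        summary = summarize_slopes(sw, labels)
        summary.to_csv(outdir / f"summary_{outcome}.csv", index=False,
                       float_format="%.4f")
        emit(f"summary_{outcome}", outdir / f"summary_{outcome}.csv")
        t56 = {q: build_table56(sw.with_labels(labels), q, config.alpha)
               for q in ("k", "b")}
        for q in ("k", "b"):
            t56[q]["table"].to_csv(outdir / f"table_{outcome}_{q}.csv")
            emit(f"table_{outcome}_{q}", outdir / f"table_{outcome}_{q}.csv")
        report["stages"][f"surrogate_{outcome}"] = {
            "seed": seeds[f"fit_{outcome}"],
            "test_r": agree.pearson_r,
            "best_epoch": res.best_epoch,
            "epochs_run": len(res.trace) - 1,
            "val_mse": float(res.trace["val"].iloc[res.best_epoch]),
        }
        report["stages"][f"sweep_{outcome}"] = {
            "grand_mean_k": float(sw.k.mean()),
            "grand_sd_k": float(sw.k.std(ddof=1)),
            "grand_mean_b": float(sw.b.mean()),
            "n_low_r2": int(len(sw.low_r2())),
            "inter_row_k": t56["k"]["inter_row"],
        }
        log(f"{outcome}: test r {agree.pearson_r:.3f}, grand k "
            f"{sw.k.mean():+.3f} in {time.time() - t1:.1f}s")

    n_sub = min(config.reliability_subjects, len(cohort))
    rng = np.random.default_rng(seeds["ratings"])
    pick = np.sort(rng.choice(len(cohort), size=n_sub, replace=False))
    sub = Cohort([cohort.records[i] for i in pick], provenance="generated")
    ratings, fields = repeated_measures(
        sub, n_raters=config.n_raters, n_sessions=config.n_sessions,
        seed=seeds["ratings"])
    rel = reliability_report(ratings, fields)
    report["stages"]["reliability"] = {
        "inter_range": rel.inter_range(), "intra_range": rel.intra_range(),
        "n_subjects": n_sub}
    (outdir / "reliability.json").write_text(json.dumps(
        {"inter_operator": rel.inter_operator,
         "intra_operator": rel.intra_operator}, indent=2))
    emit("reliability", outdir / "reliability.json")

    config.to_yaml(outdir / "config.yaml")
    emit("config", outdir / "config.yaml")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log(f"run-all done in {time.time() - t0:.1f}s -> {outdir}")
    return report
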