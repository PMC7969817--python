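"""End-to-end orchestration: simulate -> preprocess -> diagnose -> model ->
consensus -> controls -> contrasts -> metabolites.

A single :class:`PipelineConfig` drives every stage; its numeric defaults
are the analysis constants used throughout (rarefaction depth 5,000, 90/10
split, sevenfold-3-times CV, RFE step 2, top-30 consensus, top-1%
confound cutoff, 10% prevalence, adjusted p < 0.05). One master seed fans
out to per-stage seeds through a splittable seed sequence, so any stage can
be re-run in isolation and two runs with the same seed produce identical
output files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance_io, consensus, contrasts, controls, diagnostics, metabolite, synthetic_data
from .abundance_io import HEALTHY_LABEL, TaxonomicProfile
from .errors import AutosigError, ConfigurationError
from .model_suite import ALGORITHMS, ModelSpec, run_model_suite
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "diagnose",
    "model",
    "controls",
    "contrasts",
    "metabolites",
)

AUTOIMMUNE_LABEL = "autoimmune"


@dataclass
class PipelineConfig:
    """All tunable parameters of a full run (defaults = analysis constants)."""

    rarefaction_depth: int = 5000
    test_fraction: float = 0.10
    cv_folds: int = 7
    cv_repeats: int = 3
    rfe_step: int = 2
    top_k: int = 30
    confound_percentile: float = 99.0
    prevalence_min_fraction: float = 0.10
    alpha: float = 0.05
    adults_only: bool = False
    level: str = "genus"
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS
    contrast_algorithms: tuple[str, ...] = ("random_forest",)
    n_null_repeats: int = 20
    permanova_permutations: int = 999
    min_models: int = 2
    grids: dict | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> list[str]:
        """All violations, without running anything."""
        problems: list[str] = []
        if self.rarefaction_depth <= 0:
            problems.append(f"rarefaction_depth must be positive, got {self.rarefaction_depth}")
        if not 0 < self.test_fraction < 1:
            problems.append(f"test_fraction must be in (0,1), got {self.test_fraction}")
        if self.cv_folds < 2:
            problems.append(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_repeats < 1:
            problems.append(f"cv_repeats must be >= 1, got {self.cv_repeats}")
        if self.rfe_step < 1:
            problems.append(f"rfe_step must be >= 1, got {self.rfe_step}")
        if self.top_k < 1:
            problems.append(f"top_k must be >= 1, got {self.top_k}")
        if not 0 < self.confound_percentile < 100:
            problems.append(
                f"confound_percentile must be in (0,100), got {self.confound_percentile}"
            )
        if not 0 <= self.prevalence_min_fraction <= 1:
            problems.append(
                f"prevalence_min_fraction must be in [0,1], got {self.prevalence_min_fraction}"
            )
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0,1), got {self.alpha}")
        if self.level not in ("genus", "species"):
            problems.append(f"level must be genus|species, got {self.level!r}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            problems.append(f"unknown algorithms {sorted(unknown)}")
        if self.n_null_repeats < 1:
            problems.append(f"n_null_repeats must be >= 1, got {self.n_null_repeats}")
        if self.permanova_permutations < 1:
            problems.append(f"permanova_permutations must be >= 1, got {self.permanova_permutations}")
        try:
            self.simulation.validate()
        except ConfigurationError as exc:
            problems.append(f"simulation: {exc}")
        return problems

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        for key in unknown:
            logger.warning("ignoring unknown config key %r", key)
            raw.pop(key)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = synthetic_data.config_from_dict(raw["simulation"])
        for key in ("algorithms", "contrast_algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        d["contrast_algorithms"] = list(self.contrast_algorithms)
        d["simulation"] = synthetic_data.config_to_yaml_dict(self.simulation)
        return d


def validate_config(config_path: str | Path) -> list[str]:
    """Parse a YAML config and list all violations without running."""
    return PipelineConfig.from_yaml(config_path).validate()


def _det_hash(text: str) -> int:
    """Process-independent small hash (Python's str hash is salted)."""
    return zlib.crc32(text.encode()) % 1000


def stage_seed(master: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    key = (STAGES.index(stage) if stage in STAGES else 97, extra)
    return int(np.random.SeedSequence(entropy=master, spawn_key=key).generate_state(1)[0] % 2**31)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


class PipelineRun:
    """Executes requested stages in dependency order into an output directory."""

    def __init__(self, config: PipelineConfig, outdir: str | Path):
        problems = config.validate()
        if problems:
            raise ConfigurationError("invalid configuration: " + "; ".join(problems))
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report: dict = {"config": config.to_dict(), "stages": {}, "files": []}
        # shared state across stages
        self.profile: TaxonomicProfile | None = None
        self.metadata: pd.DataFrame | None = None
        self.truth: synthetic_data.SyntheticTruth | None = None
        self.metabolome: pd.DataFrame | None = None
        self.relative: TaxonomicProfile | None = None
        self.flags: controls.ConfoundFlags | None = None
        self.consensus_tables: dict[str, pd.DataFrame] = {}
        self.contrast_tables: dict[str, pd.DataFrame] = {}
        self.metrics_rows: list[dict] = []

    # -- helpers -----------------------------------------------------------
    def _save_tsv(self, frame: pd.DataFrame, relpath: str, index_label: str = "sample_id") -> None:
        path = self.outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        self.report["files"].append(relpath)

    def _model_grids(self) -> dict | None:
        return self.config.grids

    def _suite_kwargs(self) -> dict:
        c = self.config
        return dict(
            test_fraction=c.test_fraction,
            cv_folds=c.cv_folds,
            cv_repeats=c.cv_repeats,
            rfe_step=c.rfe_step,
            grids=self._model_grids(),
        )

    def _diseases(self) -> list[str]:
        assert self.metadata is not None
        return sorted(set(self.metadata["disease"]) - {HEALTHY_LABEL})

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        cfg = dataclasses.replace(self.config.simulation)
        self.profile, self.metadata, self.truth = synthetic_data.generate_cohort(cfg)
        self.metabolome = synthetic_data.generate_metabolome(self.profile, self.truth, cfg)
        self._save_tsv(self.profile.data, "synthetic/abundance.tsv")
        self._save_tsv(self.metadata, "synthetic/metadata.tsv")
        self._save_tsv(self.metabolome, "synthetic/metabolites.tsv")
        self.truth.to_json(self.outdir / "synthetic/truth.json")
        self.report["files"].append("synthetic/truth.json")
        self.report["stages"]["simulate"] = {
            "n_samples": self.profile.n_samples,
            "n_taxa": self.profile.n_taxa,
            "n_metabolites": self.metabolome.shape[1],
        }

    def preprocess(self) -> None:
        assert self.profile is not None and self.metadata is not None
        c = self.config
        prof, meta = abundance_io.select_first_timepoint(self.profile, self.metadata)
        prof = abundance_io.rarefy(prof, c.rarefaction_depth, seed=stage_seed(c.seed, "preprocess"))
        meta = meta.loc[prof.sample_ids]
        prof = abundance_io.collapse(prof, c.level)
        self.relative = abundance_io.to_relative(prof)
        self.metadata = meta
        self._save_tsv(self.relative.data, "preprocess/relative_abundance.tsv")
        self.report["stages"]["preprocess"] = {
            "n_samples": self.relative.n_samples,
            "n_taxa": self.relative.n_taxa,
            "rarefaction_depth": c.rarefaction_depth,
            "level": c.level,
        }

    def diagnose(self) -> None:
        assert self.relative is not None and self.metadata is not None
        c = self.config
        dm = diagnostics.bray_curtis(self.relative)
        coords, eigvals = diagnostics.pcoa(dm, k=2)
        coord_frame = pd.DataFrame(coords, index=dm.sample_ids, columns=["PCo1", "PCo2"])
        self._save_tsv(dm.to_frame(), "diagnostics/bray_curtis.tsv")
        self._save_tsv(coord_frame, "diagnostics/pcoa.tsv")
        results = {}
        for factor in ("study_id", "disease"):
            res = diagnostics.permanova(
                dm,
                self.metadata.loc[dm.sample_ids, factor],
                n_perm=c.permanova_permutations,
                seed=stage_seed(c.seed, "diagnose"),
            )
            results[factor] = dataclasses.asdict(res)
        _write_json(self.outdir / "diagnostics/permanova.json", results)
        self.report["files"].append("diagnostics/permanova.json")
        self.report["stages"]["diagnose"] = {
            "permanova": results,
            "top_eigenvalues": [float(v) for v in eigvals[:2]],
        }

    def _binary_cohort(
        self, disease: str
    ) -> tuple[pd.DataFrame, pd.Series, str, bool]:
        """Balanced data+labels for one disease-vs-healthy (or autoimmunity) model."""
        assert self.relative is not None and self.metadata is not None
        c = self.config
        meta = self.metadata.copy()
        if disease == AUTOIMMUNE_LABEL:
            meta["disease"] = np.where(
                meta["disease"] == HEALTHY_LABEL, HEALTHY_LABEL, AUTOIMMUNE_LABEL
            )
            adults = c.adults_only
        else:
            adults = c.adults_only or disease in contrasts.ADULT_ONLY_DISEASES
        prof, meta = abundance_io.filter_cohort(
            self.relative, meta, {disease, HEALTHY_LABEL}, adults_only=adults
        )
        prof, meta = abundance_io.balance_classes(
            prof, meta, seed=stage_seed(c.seed, "model", _det_hash(disease) + 1)
        )
        return prof.data, meta["disease"], disease, adults

    def model(self) -> None:
        c = self.config
        model_names = [AUTOIMMUNE_LABEL] + self._diseases()
        for disease in model_names:
            data, labels, positive, adults = self._binary_cohort(disease)
            fits, removed = run_model_suite(
                data,
                labels,
                positive=positive,
                algorithms=c.algorithms,
                seed=stage_seed(c.seed, "model", _det_hash(disease)),
                **self._suite_kwargs(),
            )
            table = consensus.build_consensus(
                {a: f.importance for a, f in fits.items()},
                data,
                labels,
                positive=positive,
                k=c.top_k,
                flagged=self.flags.flagged_taxa if self.flags else None,
            )
            self.consensus_tables[disease] = table
            self._save_tsv(table, f"models/{disease}_consensus.tsv", index_label="taxon")
            for algo, fit in fits.items():
                self.metrics_rows.append(
                    {
                        "model": f"{disease}_vs_{HEALTHY_LABEL}",
                        "algorithm": algo,
                        "auc": fit.auc,
                        "macro_f1": fit.macro_f1,
                        "n_train": len(fit.train_sample_ids),
                        "n_test": len(fit.test_sample_ids),
                        "n_features": len(fit.features_used),
                        "adults_only": adults,
                        "tuned": json.dumps(fit.tuned_parameters, sort_keys=True, default=str),
                    }
                )
            self.report["stages"].setdefault("model", {})[disease] = {
                "n_samples": int(len(labels)),
                "n_features_after_nzv": int(data.shape[1] - len(removed)),
                "nzv_removed": len(removed),
            }
        metrics = pd.DataFrame(self.metrics_rows)
        self._save_tsv(metrics.set_index("model"), "models/metrics.tsv", index_label="model")

    def controls_stage(self) -> None:
        assert self.relative is not None and self.metadata is not None
        c = self.config
        imps = controls.fit_study_model(
            self.relative.data, self.metadata, seed=stage_seed(c.seed, "controls")
        )
        if imps is None:
            self.flags = controls.ConfoundFlags.empty(
                list(self.relative.data.columns), c.confound_percentile
            )
        else:
            self.flags = controls.flag_confounded(imps, percentile=c.confound_percentile)
        self._save_tsv(self.flags.table, "controls/study_flags.tsv", index_label="taxon")
        # propagate flags into the consensus tables written by the model stage
        for disease, table in self.consensus_tables.items():
            table["study_flagged"] = [t in self.flags.flagged_taxa for t in table.index]
            self._save_tsv(table, f"models/{disease}_consensus.tsv", index_label="taxon")

        data, labels, positive, _ = self._binary_cohort(AUTOIMMUNE_LABEL)
        spec = ModelSpec(
            algorithm="random_forest",
            hyperparameter_grid=(c.grids or {}).get("random_forest"),
            cv_folds=c.cv_folds,
            cv_repeats=c.cv_repeats,
            rfe_step=c.rfe_step,
        )
        aucs, mean_auc = controls.random_label_null(
            data,
            labels,
            positive,
            spec,
            n_repeats=c.n_null_repeats,
            seed=stage_seed(c.seed, "controls", 1),
            test_fraction=c.test_fraction,
        )
        null_frame = pd.DataFrame({"repeat": range(len(aucs)), "auc": aucs}).set_index("repeat")
        self._save_tsv(null_frame, "controls/null_aucs.tsv", index_label="repeat")
        self.report["stages"]["controls"] = {
            "n_flagged": int(self.flags.table["flagged"].sum()),
            "cutoff_value": float(self.flags.cutoff_value),
            "null_mean_auc": mean_auc,
            "null_repeats": len(aucs),
        }

    def contrasts_stage(self) -> None:
        assert self.relative is not None and self.metadata is not None
        c = self.config
        diseases = self._diseases()
        top_sets: dict[str, set[str]] = {}
        rows = []
        for disease, table in self.consensus_tables.items():
            if disease == AUTOIMMUNE_LABEL:
                continue
            top_sets[f"{disease}_vs_{HEALTHY_LABEL}"] = set(table.index[table["selected"]])
        for i, a in enumerate(diseases):
            for b in diseases[i + 1 :]:
                fits, table = contrasts.pairwise_model(
                    self.relative,
                    self.metadata,
                    a,
                    b,
                    algorithms=c.contrast_algorithms,
                    seed=stage_seed(c.seed, "contrasts", i * 100 + diseases.index(b)),
                    top_k=c.top_k,
                    adults_only=True if c.adults_only else None,
                    **self._suite_kwargs(),
                )
                name = f"{a}_vs_{b}"
                self.contrast_tables[name] = table
                top = set(table.index[table["selected"]])
                top_sets[name] = top
                top_sets[f"{b}_vs_{a}"] = top
                for algo, fit in fits.items():
                    rows.append(
                        {"model": name, "algorithm": algo, "auc": fit.auc, "macro_f1": fit.macro_f1}
                    )
        self._save_tsv(
            pd.DataFrame(rows).set_index("model"), "contrasts/metrics.tsv", index_label="model"
        )
        flagged = self.flags.flagged_taxa if self.flags else set()
        self.overlaps: dict[str, pd.DataFrame] = {}
        for d in diseases:
            others = [x for x in diseases if x != d]
            names = contrasts.disease_contrast_names(d, others)
            sets_d = {n: top_sets[n] for n in names if n in top_sets}
            directions = (
                self.consensus_tables[d]["log2_fold_change"].to_dict()
                if d in self.consensus_tables
                else None
            )
            summary = contrasts.overlap(
                sets_d, min_models=c.min_models, flagged=flagged, directions=directions
            )
            self.overlaps[d] = summary
            self._save_tsv(summary, f"contrasts/overlap_{d}.tsv", index_label="taxon")
        self.report["stages"]["contrasts"] = {
            "n_pairwise_models": len(self.contrast_tables),
            "consistent_taxa": {
                d: int(s["consistent"].sum()) for d, s in sorted(self.overlaps.items())
            },
        }

    def metabolites_stage(self) -> None:
        assert self.relative is not None
        c = self.config
        overlap_all = pd.concat(self.overlaps.values()) if getattr(self, "overlaps", None) else None
        if self.metabolome is None:
            logger.warning("metabolite stage: no metabolome available; skipping")
            self.report["stages"]["metabolites"] = {"n_candidates": 0, "n_significant": 0}
            return
        if overlap_all is None or overlap_all.empty:
            logger.warning("metabolite stage: no overlap table; skipping correlation")
            self.report["stages"]["metabolites"] = {"n_candidates": 0, "n_significant": 0}
            return
        # keep the max n_models_present per taxon across diseases
        overlap_best = (
            overlap_all.reset_index()
            .sort_values(["taxon", "n_models_present"], ascending=[True, False])
            .drop_duplicates("taxon")
            .set_index("taxon")
        )
        metabolome = self.metabolome.loc[self.relative.sample_ids]
        candidates = metabolite.select_candidates(
            overlap_best,
            available_taxa=set(self.relative.data.columns),
            flags=self.flags,
            min_models=c.min_models,
            level=c.level,
        )
        kept = metabolite.prevalence_filter(
            self.relative.data[candidates], min_fraction=c.prevalence_min_fraction
        ) if candidates else []
        if kept:
            table = metabolite.spearman_bh(
                self.relative.data[kept], metabolome, alpha=c.alpha
            )
        else:
            table = pd.DataFrame(
                columns=["taxon", "metabolite", "rho", "p_value", "p_adjusted", "significant"]
            )
        self._save_tsv(table.set_index("taxon"), "metabolites/correlations.tsv", index_label="taxon")
        self.report["stages"]["metabolites"] = {
            "n_candidates": len(candidates),
            "n_prevalence_kept": len(kept),
            "n_pairs": int(len(table)),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }

    # -- driver ------------------------------------------------------------
    def run(self, stages: Sequence[str] | None = None) -> dict:
        wanted = list(stages) if stages else list(STAGES)
        unknown = set(wanted) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        # execute in canonical dependency order regardless of request order
        order = [s for s in STAGES if s in wanted]
        impl = {
            "simulate": self.simulate,
            "preprocess": self.preprocess,
            "diagnose": self.diagnose,
            "model": self.model,
            "controls": self.controls_stage,
            "contrasts": self.contrasts_stage,
            "metabolites": self.metabolites_stage,
        }
        for name in order:
            logger.info("stage %s: start", name)
            try:
                impl[name]()
            except AutosigError:
                logger.error("stage %s failed", name)
                raise
        _write_json(self.outdir / "report.json", self.report)
        self.report["files"].append("report.json")
        return self.report


def run(config: PipelineConfig | str | Path, outdir: str | Path, stages: Sequence[str] | None = None) -> dict:
    """Run the pipeline from a config object or YAML path into ``outdir``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    return PipelineRun(config, outdir).run(stages)
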