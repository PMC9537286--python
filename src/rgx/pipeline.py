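"""End-to-end orchestration of the three study tasks.

Stage graph (plain files between stages for restartability):

* ``simulate``  — write a synthetic paired cohort to the standard layout;
* ``extract``   — radiomics features for every patient -> ``features.csv``;
* ``stability`` — augmentation + ICC filter on discovery -> ``stability_report.csv``;
* ``harmonise`` — consensus-cluster reference ComBat on features, batch
  ComBat on expression -> ``features_harmonised.csv``;
* ``subtype``   — centroid subtyping + one OVA logistic model per subtype;
* ``surrogate`` — k-means gene-signature classes + radiomics classifier each;
* ``prognose``  — radiomics Cox (GTV forced), GSVA metagene Cox, combined Cox;
* ``evaluate``  — recompute metrics for the stored models.

Every stage fits parameters on the discovery cohort only and applies them
frozen to validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io as rgx_io
from .cohort import CohortConfig, E2F_SET, HEDGEHOG_SET, generate_cohort
from .errors import ConfigError, ModelError, RgxError
from .features import extract_features
from .gsva import gsva
from .harmonise import ConsensusConfig, combat, reference_cluster
from .images import PreprocessConfig, preprocess
from .modeling import (
    CoxPH,
    LogisticOVA,
    cluster_representatives,
    cv_rank_aggregate,
    volume_correlation_filter,
)
from .stability import AugmentationScheme, augment, stability_filter
from .transcriptome import SUBTYPES, UNCLASSIFIED, assign_subtypes, filter_gene_sets, read_gmt, signature_classes
from .transforms import fit_transforms, apply_transforms

logger = logging.getLogger(__name__)

TASKS = (
    "simulate", "extract", "stability", "harmonise",
    "subtype", "surrogate", "prognose", "evaluate", "all",
)
#: feature used as the gross tumour volume covariate (cm^3)
GTV_FEATURE = "morph_volume"
CALIBRATION_HORIZON_MONTHS = 24.0


@dataclass
class PipelineConfig:
    """Schema-validated run configuration; unknown keys are rejected."""

    task: str = "all"
    outdir: str = "rgx_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    augmentation: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    combat_mode: str = "nonparametric"
    cv_reps: int = 33
    cv_folds: int = 3
    s_max: int = 10
    n_boot: int = 600
    metagene_keep: tuple[str, ...] = (HEDGEHOG_SET, E2F_SET)
    surrogate_signatures: tuple[str, ...] = (HEDGEHOG_SET, E2F_SET)
    subtypes: tuple[str, ...] = SUBTYPES

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        if cfg.task not in TASKS:
            raise ConfigError(f"task must be one of {TASKS}, got {cfg.task!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def cohort_config(self) -> CohortConfig:
        extra = dict(self.cohort)
        extra.setdefault("seed", self.seed)
        return CohortConfig(**extra)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {artifact: digest}
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, outdir: Path, names: list[str]) -> None:
        digests = {}
        for name in names:
            path = outdir / name
            if path.exists():
                digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.stages[stage] = digests

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class PipelineRun:
    """Holds disk paths plus in-memory artifacts while stages execute."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        from . import __version__

        self.manifest = RunManifest(config.config_hash(), __version__)
        self.cohort = None
        self._tables: dict = {}

    # -- helpers ------------------------------------------------------------
    def _clinical(self) -> pd.DataFrame:
        if "clinical" not in self._tables:
            self._tables["clinical"] = rgx_io.read_clinical(self.outdir / "clinical.csv")
        return self._tables["clinical"]

    def _features(self, harmonised: bool = True) -> pd.DataFrame:
        name = "features_harmonised.csv" if harmonised else "features.csv"
        path = self.outdir / name
        if not path.exists() and harmonised:
            path = self.outdir / "features.csv"
        return rgx_io.read_matrix_csv(path, "patient")

    def _expression(self, harmonised: bool = True) -> pd.DataFrame:
        name = "expression_harmonised.csv" if harmonised else "expression.csv"
        path = self.outdir / name
        if not path.exists():
            path = self.outdir / "expression.csv"
        return rgx_io.read_matrix_csv(path)

    def _split_ids(self) -> tuple[list[str], list[str]]:
        clin = self._clinical()
        disc = list(clin.loc[clin["split"] == "discovery", "id"])
        val = list(clin.loc[clin["split"] == "validation", "id"])
        return disc, val

    def _load_image(self, pid: str):
        if self.cohort is not None and pid in self.cohort.volumes:
            return self.cohort.volumes[pid]
        return rgx_io.load_patient_image(self.outdir, pid)

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.cohort_config()
        logger.info("simulate: %d + %d patients, seed %d", cfg.n_discovery, cfg.n_validation, cfg.seed)
        self.cohort = generate_cohort(cfg, self.outdir)
        self.manifest.record(
            "simulate", self.outdir,
            ["expression.csv", "clinical.csv", "centroids.csv", "truth.json", "gene_sets.gmt"],
        )
        self.manifest.parameters["cohort"] = {
            k: v for k, v in asdict(cfg).items() if np.isscalar(v)
        }

    def stage_extract(self) -> None:
        clin = self._clinical()
        cfg = PreprocessConfig()
        rows = {}
        meta = None
        for pid in clin["id"]:
            vol, mask = self._load_image(pid)
            base, logv, mask_p = preprocess(vol, mask, cfg)
            fv = extract_features(base, logv, mask_p, cfg)
            rows[pid] = fv.values
            meta = meta or fv.metadata
        feats = pd.DataFrame.from_dict(rows, orient="index")
        feats.rename_axis("id").to_csv(self.outdir / "features.csv")
        with open(self.outdir / "feature_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        logger.info("extract: %d patients x %d features", *feats.shape)
        self.manifest.record("extract", self.outdir, ["features.csv", "feature_metadata.json"])

    def stage_stability(self) -> None:
        clin = self._clinical()
        disc, _ = self._split_ids()
        scheme = AugmentationScheme(**self.config.augmentation)
        cfg = PreprocessConfig()
        rows = {}
        for pid in disc:
            vol, mask = self._load_image(pid)
            variants = augment(vol, mask, scheme)
            for v_idx, (v_vol, v_mask) in enumerate(variants):
                base, logv, mask_p = preprocess(v_vol, v_mask, cfg)
                rows[(pid, v_idx)] = extract_features(base, logv, mask_p, cfg).values
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index = pd.MultiIndex.from_tuples(table.index, names=["patient", "variant"])
        report = stability_filter(table)
        report.table.rename_axis("feature").to_csv(self.outdir / "stability_report.csv")
        logger.info(
            "stability: %d/%d features retained", len(report.retained), table.shape[1]
        )
        self.manifest.record("stability", self.outdir, ["stability_report.csv"])

    def _retained_features(self) -> list[str]:
        path = self.outdir / "stability_report.csv"
        feats = self._features(harmonised=False)
        if not path.exists():
            return list(feats.columns)
        rep = pd.read_csv(path, index_col=0)
        return [f for f in rep.index[rep["retained"]] if f in feats.columns]

    def stage_harmonise(self) -> None:
        feats = self._features(harmonised=False)[self._retained_features()]
        with open(self.outdir / "feature_metadata.json") as fh:
            meta = json.load(fh)
        cluster_cols = [
            f for f in feats.columns
            if meta.get(f, {}).get("family")
            in {"statistical", "intensity_histogram", "texture"}
        ]
        cons = ConsensusConfig(seed=self.config.seed, **self.config.consensus)
        reference, outliers = reference_cluster(feats[cluster_cols], cons)
        if outliers:
            batch = pd.Series(
                ["reference" if i in set(reference) else "outlier" for i in feats.index],
                index=feats.index,
            )
            adjusted = combat(feats, batch, "reference", self.config.combat_mode)
        else:
            adjusted = feats.copy()
        adjusted.rename_axis("id").to_csv(self.outdir / "features_harmonised.csv")

        # expression: batch labels from the clinical table, discovery as reference
        clin = self._clinical().set_index("id")
        expr = self._expression(harmonised=False)
        batches = clin.loc[expr.columns, "batch"]
        ref_batch = clin.loc[clin.index[clin["split"] == "discovery"][0], "batch"]
        if batches.nunique() > 1:
            adj_expr = combat(expr.T, batches, ref_batch, self.config.combat_mode).T
        else:
            adj_expr = expr
        adj_expr.rename_axis("gene").to_csv(self.outdir / "expression_harmonised.csv")
        with open(self.outdir / "harmonisation.json", "w") as fh:
            json.dump(
                {
                    "reference_ids": reference,
                    "outlier_ids": outliers,
                    "expression_reference_batch": str(ref_batch),
                    "mode": self.config.combat_mode,
                },
                fh,
                indent=2,
            )
        logger.info("harmonise: %d reference / %d outlier patients", len(reference), len(outliers))
        self.manifest.record(
            "harmonise", self.outdir,
            ["features_harmonised.csv", "expression_harmonised.csv", "harmonisation.json"],
        )

    # -- classification machinery -------------------------------------------
    def _develop_classifier(
        self, feats: pd.DataFrame, y: pd.Series, disc: list[str], val: list[str],
        positive_label, model_name: str,
    ) -> dict:
        """Shared OVA pipeline: cluster reps -> transforms -> CV rank -> fit -> evaluate."""
        n_boot, seed = self.config.n_boot, self.config.seed
        disc = [i for i in disc if i in y.index]
        val = [i for i in val if i in y.index]
        reps, _ = cluster_representatives(feats.loc[disc])
        params = fit_transforms(feats.loc[disc, reps])
        z_disc = apply_transforms(feats.loc[disc, reps], params)
        y_disc = (y.loc[disc] == positive_label).astype(int).to_numpy()
        if y_disc.sum() < self.config.cv_folds or (1 - y_disc).sum() < self.config.cv_folds:
            raise ModelError(f"class {positive_label!r} too small for cross-validation")
        ranking = cv_rank_aggregate(
            z_disc, y_disc, task="classification",
            reps=self.config.cv_reps, folds=self.config.cv_folds,
            seed=seed, s_max=min(self.config.s_max, len(reps)),
        )
        selected = ranking.top()
        model = LogisticOVA(z_disc[selected], y_disc, 1, params).fit(seed=seed)
        p_disc = model.predict(feats.loc[disc])
        p_val = model.predict(feats.loc[val])
        y_val = (y.loc[val] == positive_label).astype(int).to_numpy()
        auc_d = evaluation.roc_auc(p_disc, y_disc, n_boot, seed)
        cutoff, f1_d = evaluation.f1_with_cutoff(p_disc, y_disc, "fit", n_boot=n_boot, seed=seed)
        model.cutoff = cutoff
        report = {
            "model": model_name,
            "features": selected,
            "auc_discovery": auc_d.as_dict(),
            "f1_discovery": f1_d.as_dict(),
            "cutoff": cutoff,
            "cv_median_size": ranking.median_size,
        }
        if len(np.unique(y_val)) == 2:
            auc_v = evaluation.roc_auc(p_val, y_val, n_boot, seed)
            _, f1_v = evaluation.f1_with_cutoff(p_val, y_val, "apply", cutoff, n_boot, seed)
            hl_chi2, hl_p = evaluation.hosmer_lemeshow(p_val, y_val, g=min(10, len(val) // 2))
            report.update(
                auc_validation=auc_v.as_dict(),
                f1_validation=f1_v.as_dict(),
                hl_validation={"chi2": hl_chi2, "p": hl_p},
            )
        model.provenance.update(
            cv_reps=self.config.cv_reps, cv_folds=self.config.cv_folds,
            median_size=ranking.median_size,
        )
        model.to_json(self.outdir / f"model_{model_name}.json")
        ranking.table.rename_axis("feature").to_csv(self.outdir / f"ranking_{model_name}.csv")
        return report

    def stage_subtype(self) -> None:
        expr = self._expression()
        centroids = rgx_io.read_matrix_csv(self.outdir / "centroids.csv")
        assignment = assign_subtypes(expr, centroids)
        pd.DataFrame(
            {"subtype": assignment.labels}
        ).join(assignment.correlations).rename_axis("id").to_csv(self.outdir / "subtypes.csv")
        feats = self._features()
        disc, val = self._split_ids()
        labelled = assignment.labels[assignment.labels != UNCLASSIFIED]
        reports = {}
        for subtype in self.config.subtypes:
            try:
                reports[subtype] = self._develop_classifier(
                    feats, labelled, disc, val, subtype, f"subtype_{subtype}"
                )
            except (ModelError, RgxError) as exc:
                warnings.warn(f"subtype {subtype!r} model skipped: {exc}")
                reports[subtype] = {"error": str(exc)}
        with open(self.outdir / "evaluation_subtype.json", "w") as fh:
            json.dump(reports, fh, indent=2, default=float)
        self.manifest.record(
            "subtype", self.outdir,
            ["subtypes.csv", "evaluation_subtype.json"]
            + [f"model_subtype_{s}.json" for s in self.config.subtypes],
        )

    def stage_surrogate(self) -> None:
        expr = self._expression()
        gene_sets = {s.name: s for s in read_gmt(self.outdir / "gene_sets.gmt")}
        feats = self._features()
        disc, val = self._split_ids()
        reports = {}
        classes = {}
        for name in self.config.surrogate_signatures:
            if name not in gene_sets:
                raise ConfigError(f"surrogate signature {name!r} not in gene_sets.gmt")
            labels_d, fitted = signature_classes(
                expr[disc], gene_sets[name], "fit", seed=self.config.seed
            )
            labels_v, _ = signature_classes(expr[val], gene_sets[name], "transfer", fitted)
            labels = pd.concat([labels_d, labels_v])
            classes[name] = labels
            try:
                reports[name] = self._develop_classifier(
                    feats, labels, disc, val, 1, f"surrogate_{name}"
                )
            except (ModelError, RgxError) as exc:
                warnings.warn(f"surrogate {name!r} model skipped: {exc}")
                reports[name] = {"error": str(exc)}
        pd.DataFrame(classes).rename_axis("id").to_csv(self.outdir / "signature_classes.csv")
        with open(self.outdir / "evaluation_surrogate.json", "w") as fh:
            json.dump(reports, fh, indent=2, default=float)
        self.manifest.record(
            "surrogate", self.outdir, ["signature_classes.csv", "evaluation_surrogate.json"]
        )

    # -- survival machinery ---------------------------------------------------
    def _develop_cox(
        self, X: pd.DataFrame, clin: pd.DataFrame, disc: list[str], val: list[str],
        model_name: str, forced: tuple[str, ...] = (), select: bool = True,
    ) -> tuple[dict, "pd.Series"]:
        n_boot, seed = self.config.n_boot, self.config.seed
        t = clin.set_index("id")["time_months"]
        e = clin.set_index("id")["event"]
        params = fit_transforms(X.loc[disc])
        z_disc = apply_transforms(X.loc[disc], params)
        if select and X.shape[1] > len(forced):
            ranking = cv_rank_aggregate(
                z_disc, None, task="survival",
                time=t.loc[disc].to_numpy(), event=e.loc[disc].to_numpy(),
                reps=self.config.cv_reps, folds=self.config.cv_folds,
                seed=seed, s_max=min(self.config.s_max, X.shape[1] - len(forced)),
                horizon=CALIBRATION_HORIZON_MONTHS, forced=forced,
            )
            selected = list(forced) + ranking.top()
            ranking.table.rename_axis("feature").to_csv(
                self.outdir / f"ranking_{model_name}.csv"
            )
        else:
            selected = list(X.columns)
        model = CoxPH(
            z_disc[selected], t.loc[disc].to_numpy(), e.loc[disc].to_numpy(),
            params, forced=forced,
        ).fit(seed=seed)
        risk_d = model.predict(X.loc[disc])
        risk_v = model.predict(X.loc[val])
        c_d = evaluation.concordance(risk_d, t.loc[disc], e.loc[disc], n_boot, seed)
        c_v = evaluation.concordance(risk_v, t.loc[val], e.loc[val], n_boot, seed)
        rule, p_disc = evaluation.stratification_threshold(
            risk_d, t.loc[disc], e.loc[disc], "fit"
        )
        model.risk_threshold = rule.threshold
        _, p_val = evaluation.stratification_threshold(
            risk_v, t.loc[val], e.loc[val], "apply", rule
        )
        report = {
            "model": model_name,
            "features": selected,
            "c_index_discovery": c_d.as_dict(),
            "c_index_validation": c_v.as_dict(),
            "risk_threshold": rule.threshold,
            "logrank_p_discovery": p_disc,
            "logrank_p_validation": p_val,
        }
        try:
            s_pred = model.predict_survival(X.loc[val], CALIBRATION_HORIZON_MONTHS)
            chi2, p_gnd, table = evaluation.gnd_calibration(
                s_pred, t.loc[val], e.loc[val],
                n_groups=min(10, max(2, len(val) // 15)),
                horizon=CALIBRATION_HORIZON_MONTHS,
            )
            report["gnd_validation"] = {"chi2": chi2, "p": p_gnd}
        except (ModelError, RgxError) as exc:
            report["gnd_validation"] = {"error": str(exc)}
        try:
            ph = evaluation.schoenfeld_ph_test(
                model, z_disc[selected], t.loc[disc].to_numpy(), e.loc[disc].to_numpy()
            )
            report["ph_global_p"] = float(ph.loc["GLOBAL", "p"])
        except (ModelError, RgxError) as exc:
            report["ph_global_p"] = str(exc)
        model.to_json(self.outdir / f"model_{model_name}.json")
        return report, pd.concat([risk_d, risk_v])

    def stage_prognose(self) -> None:
        feats = self._features()
        clin = self._clinical()
        disc, val = self._split_ids()
        expr = self._expression()

        # radiomics signature: GTV forced, volume-redundant features discarded
        pool = feats.drop(columns=[GTV_FEATURE])
        keep = volume_correlation_filter(pool.loc[disc], feats.loc[disc, GTV_FEATURE])
        reps, _ = cluster_representatives(pool.loc[disc, keep])
        rad_X = feats[[GTV_FEATURE] + reps]
        rep_rad, risk_rad = self._develop_cox(
            rad_X, clin, disc, val, "prognosis_radiomics", forced=(GTV_FEATURE,)
        )
        radiomics_features = rep_rad["features"]

        # metagene signature: GSVA per cohort (leak-free), keep-list filter
        gene_sets = read_gmt(self.outdir / "gene_sets.gmt")
        kept_sets = filter_gene_sets(gene_sets, list(self.config.metagene_keep))
        scores_d = gsva(expr[disc], kept_sets)
        scores_v = gsva(expr[val], kept_sets)
        metagenes = pd.concat([scores_d, scores_v])
        metagenes.rename_axis("id").to_csv(self.outdir / "metagenes.csv")
        rep_meta, risk_meta = self._develop_cox(
            metagenes, clin, disc, val, "prognosis_metagenes", select=False
        )

        # combined model on the whole discovery cohort
        combined_X = feats[radiomics_features].join(metagenes)
        rep_comb, risk_comb = self._develop_cox(
            combined_X, clin, disc, val, "prognosis_combined", select=False
        )
        reports = {
            "radiomics": rep_rad,
            "metagenes": rep_meta,
            "combined": rep_comb,
        }
        with open(self.outdir / "evaluation_prognosis.json", "w") as fh:
            json.dump(reports, fh, indent=2, default=float)
        self.manifest.record(
            "prognose", self.outdir,
            ["evaluation_prognosis.json", "metagenes.csv"]
            + [f"model_prognosis_{m}.json" for m in ("radiomics", "metagenes", "combined")],
        )

    def stage_evaluate(self) -> None:
        """Aggregate the per-task evaluation reports into one file."""
        summary = {}
        for name in ("subtype", "surrogate", "prognosis"):
            path = self.outdir / f"evaluation_{name}.json"
            if path.exists():
                with open(path) as fh:
                    summary[name] = json.load(fh)
        with open(self.outdir / "evaluation_report.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        self.manifest.record("evaluate", self.outdir, ["evaluation_report.json"])


def run_task(config: PipelineConfig) -> RunManifest:
    """Execute the requested stage(s); returns the run manifest."""
    run = PipelineRun(config)
    order = {
        "simulate": [run.stage_simulate],
        "extract": [run.stage_extract],
        "stability": [run.stage_stability],
        "harmonise": [run.stage_harmonise],
        "subtype": [run.stage_subtype],
        "surrogate": [run.stage_surrogate],
        "prognose": [run.stage_prognose],
        "evaluate": [run.stage_evaluate],
        "all": [
            run.stage_simulate, run.stage_extract, run.stage_stability,
            run.stage_harmonise, run.stage_subtype, run.stage_surrogate,
            run.stage_prognose, run.stage_evaluate,
        ],
    }[config.task]
    for stage in order:
        name = stage.__name__.replace("stage_", "")
        try:
            stage()
        except RgxError:
            logger.error("stage %s failed; artifacts preserved in %s", name, run.outdir)
            raise
    run.manifest.parameters.setdefault("seed", config.seed)
    run.manifest.write(run.outdir / "manifest.json")
    return run.manifest
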