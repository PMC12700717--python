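"""End-to-end pipeline driver.

``run_pipeline`` chains all stages — simulate -> extract -> perfusion ->
differential expression / Venn -> feature selection -> integration ->
classification -> regulatory network — and writes per-stage TSV/CSV/JSON
artifacts plus the fully-resolved configuration and a run log into the
output directory.  With a fixed seed reruns are byte-identical.

Merged-table column contract: clinical columns are prefixed ``clin_``,
perfusion columns ``perf_``, expression columns carry the feature id, and
radiomic columns the canonical feature name prefixed by the modality
(``Bmode:`` / ``CEUS:``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .classify import evaluate
from .expression import biomarker_filter, de_test, normalize, cpm, stage_specific_sets
from .integration import cca, correlate
from .network import build_grn, trend_filter
from .perfusion import perfusion_table
from .selection import SelectionParams, select_features
from .synthetic import (BIOMARKER_MIRNAS, BIOMARKER_MRNAS, BIOMARKER_PANEL,
                        StudyConfig, generate_study)
from .texture import extract_all

logger = logging.getLogger("sonotx")

GLEASON_ORDINAL = {"none": 0, "3+3": 1, "3+4": 2, "4+3": 3, ">=8": 4}
CLINICAL_COVARIATES = ("age", "tPSA", "fPSA_ratio", "trus_volume", "psa_density")


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline parameters; unknown keys are rejected."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # imaging
    ng: int = 32
    wavelet: str = "haar"
    # selection
    drop_ratio: float = 0.5
    max_features: int = 20
    redundancy_sign: str = "minus"
    # differential expression
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    # classification
    runs: int = 10
    test_size: float = 0.3
    # network
    hub_min_degree: int = 2
    trend_delta: float = 0.0
    # synthetic study (used when simulate is true)
    simulate: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)
    # external inputs (used when simulate is false)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "study" in raw and isinstance(raw["study"], dict):
            study_known = {f.name for f in dataclasses.fields(StudyConfig)}
            bad = set(raw["study"]) - study_known
            if bad:
                raise ValueError(f"unknown study config keys: {sorted(bad)}")
            raw["study"] = StudyConfig(**raw["study"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig):
    """Load an externally supplied study (simulate disabled)."""
    req = ("tics", "mrna_counts", "mirna_counts", "clinical", "interactions")
    missing = [k for k in req if k not in config.inputs
               or not Path(config.inputs[k]).exists()]
    if missing:
        raise FileNotFoundError(
            f"simulate is disabled and transcriptomics/perfusion inputs are "
            f"missing: {missing}")
    from .perfusion import read_tic_csv

    study = generate_study(config.study, with_images=False)  # container shell
    study.tics = read_tic_csv(config.inputs["tics"])
    study.mrna_counts = sio.read_table(config.inputs["mrna_counts"])
    study.mirna_counts = sio.read_table(config.inputs["mirna_counts"])
    study.clinical = sio.read_table(config.inputs["clinical"])
    study.interactions = sio.read_table(config.inputs["interactions"], index_col=None)
    return study


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True))

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            study_cfg = dataclasses.replace(config.study, seed=config.seed)
            study = generate_study(study_cfg)
        else:
            study = _load_inputs(config)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    groups = study.clinical["group"]
    tumor = groups[groups.isin(["T2c", "T3b"])]
    sio.write_table(study.clinical, out / "clinical.csv")
    sio.write_table(study.mrna_counts, out / "mrna_counts.tsv")
    sio.write_table(study.mirna_counts, out / "mirna_counts.tsv")
    sio.write_table(study.interactions, out / "interactions.tsv", index=False)
    sio.write_tics_csv(study.tics, out / "tics.csv")

    # --- extract ----------------------------------------------------------
    stage = "extract"
    try:
        rows = {}
        for im in study.images:
            feats = extract_all(im.image, im.mask, ng=config.ng,
                                wavelet=config.wavelet)
            rows.setdefault(im.subject_id, {}).update(
                {f"{im.modality}:{k}": v for k, v in feats.items()})
        radiomic = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    except Exception as exc:
        raise StageError(stage, exc) from exc
    if not radiomic.empty:
        sio.write_table(radiomic, out / "radiomic_features.csv")
    report["n_radiomic_features"] = int(radiomic.shape[1])

    # --- perfusion --------------------------------------------------------
    stage = "perfusion"
    try:
        perf = perfusion_table(study.tics)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    sio.write_table(perf, out / "perfusion.csv")
    perf_ok = perf[perf["fit_ok"]].drop(columns="fit_ok")
    perf_ok = perf_ok.add_prefix("perf_")

    # --- differential expression / venn ----------------------------------
    stage = "transcriptomics"
    try:
        sample_sets = {g: list(groups.index[groups == g]) for g in
                       ("healthy", "T2c", "T3b")}
        all_tumor = sample_sets["T2c"] + sample_sets["T3b"]
        de = {}
        for mod, counts in (("mrna", study.mrna_counts),
                            ("mirna", study.mirna_counts)):
            de[mod] = {
                "t2c_vs_h": de_test(counts, sample_sets["healthy"],
                                    sample_sets["T2c"], config.p_cutoff,
                                    config.fc_cutoff),
                "t3b_vs_h": de_test(counts, sample_sets["healthy"],
                                    sample_sets["T3b"], config.p_cutoff,
                                    config.fc_cutoff),
                "tumor_vs_h": de_test(counts, sample_sets["healthy"], all_tumor,
                                      config.p_cutoff, config.fc_cutoff),
                "t3b_vs_t2c": de_test(counts, sample_sets["T2c"],
                                      sample_sets["T3b"], config.p_cutoff,
                                      config.fc_cutoff),
            }
            for name, res in de[mod].items():
                sio.write_table(res.table, out / f"de_{mod}_{name}.tsv")
        venn = {mod: stage_specific_sets(de[mod]["t2c_vs_h"], de[mod]["t3b_vs_h"],
                                         de[mod]["tumor_vs_h"])
                for mod in de}
        panel_mrna = biomarker_filter(de["mrna"]["t3b_vs_t2c"],
                                      list(BIOMARKER_MRNAS))
        panel_mirna = biomarker_filter(de["mirna"]["t3b_vs_t2c"],
                                       list(BIOMARKER_MIRNAS))
        panel = pd.concat([panel_mrna, panel_mirna])
        sio.write_table(panel, out / "biomarker_panel.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    report["venn"] = {
        mod: {"specific_T2c": len(v.specific_T2c),
              "specific_T3b": len(v.specific_T3b),
              "shared": len(v.shared)}
        for mod, v in venn.items()}
    report["biomarkers_passing"] = int(len(panel))

    # --- feature selection ------------------------------------------------
    stage = "select"
    selected_cols: list[str] = []
    try:
        if not radiomic.empty:
            rad_tumor = radiomic.loc[tumor.index]
            trace = select_features(
                rad_tumor, tumor.to_numpy(),
                SelectionParams(drop_ratio=config.drop_ratio,
                                max_features=config.max_features,
                                redundancy_sign=config.redundancy_sign))
            selected_cols = trace.selected
            (out / "selection_trace.json").write_text(json.dumps({
                "selected": trace.selected, "scores": trace.scores,
                "relevances": trace.relevances,
                "redundancies": trace.redundancies,
                "termination": trace.termination}, indent=2))
            report["n_selected_features"] = len(selected_cols)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- integration ------------------------------------------------------
    stage = "integrate"
    try:
        expr_norm = pd.concat([normalize(study.mrna_counts),
                               normalize(study.mirna_counts)])
        panel_expr = expr_norm.loc[list(BIOMARKER_PANEL)].T
        rad_cols = selected_cols or list(radiomic.columns[:8])
        rad_perf = perf_ok.join(radiomic[rad_cols], how="inner") \
            if not radiomic.empty else perf_ok
        t3b_samples = list(groups.index[groups == "T3b"])
        corr = correlate(rad_perf, panel_expr, samples=t3b_samples)
        sio.write_table(corr.table, out / "correlation_map.tsv", index=False)
        abundance = pd.concat([cpm(study.mrna_counts),
                               cpm(study.mirna_counts)]).loc[
            list(BIOMARKER_PANEL), tumor.index].T
        constraint = (tumor == "T3b").astype(float).rename("is_T3b")
        cca_res = cca(abundance, constraint)
        sio.write_table(cca_res.site_scores, out / "cca_site_scores.tsv")
        sio.write_table(cca_res.species_scores, out / "cca_species_scores.tsv")
        report["cca_eigenvalue_1"] = float(cca_res.eigenvalues[0])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- classification ---------------------------------------------------
    stage = "classify"
    try:
        clin = study.clinical.loc[tumor.index, list(CLINICAL_COVARIATES)].copy()
        clin["gleason_ord"] = study.clinical.loc[tumor.index, "gleason"].map(
            GLEASON_ORDINAL)
        clin = clin.add_prefix("clin_")
        trans = panel_expr.loc[tumor.index]
        radio = rad_perf.loc[rad_perf.index.intersection(tumor.index)]
        radio = radio.reindex(tumor.index).fillna(radio.mean())
        tables = {"clinical": clin, "transcriptomic": trans, "radiomic": radio,
                  "combined": pd.concat([clin, trans, radio], axis=1)}
        eval_res = evaluate(tables, tumor, runs=config.runs, seed=config.seed,
                            test_size=config.test_size)
        sio.write_table(eval_res.runs, out / "auc_runs.csv", index=False)
        sio.write_table(eval_res.summary(), out / "auc_summary.csv", index=False)
        report["auc_mean"] = {
            f"{r.feature_set}/{r.model}": round(float(r.auc_mean), 6)
            for r in eval_res.summary().itertuples()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- regulatory network ----------------------------------------------
    stage = "grn"
    try:
        dec_genes = trend_filter(normalize(study.mrna_counts), groups,
                                 "decreasing", config.trend_delta)
        inc_mirnas = trend_filter(normalize(study.mirna_counts), groups,
                                  "increasing", config.trend_delta)
        grn = build_grn(inc_mirnas, dec_genes, study.interactions,
                        hub_min_degree=config.hub_min_degree)
        nodes, edges = grn.to_tables()
        sio.write_table(nodes, out / "grn_nodes.tsv", index=False)
        sio.write_table(edges, out / "grn_edges.tsv", index=False)
        grn_summary = {"hubs": grn.hubs,
                       "degrees": {m: int(k) for m, k in grn.degrees.items()},
                       "covered_genes": sorted(grn.covered_genes())}
        (out / "grn_summary.json").write_text(json.dumps(grn_summary, indent=2))
        report["grn"] = {"n_hubs": len(grn.hubs),
                         "n_covered_genes": len(grn.covered_genes())}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return report
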