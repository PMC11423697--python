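"""End-to-end pipeline: simulate -> preprocess -> screen -> causal/twin ->
predictor -> validate, with a manifest of hashes for reproducibility checks.

Every stage reads and writes the delimited-text contracts in
:mod:`twinsurv.io`; no stage mutates its inputs.  A run directory contains
the stage outputs plus ``manifest.json`` recording, per stage, the input and
output file hashes, the seed in force and the wall time, so any stage can be
re-run and verified against the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal, ewas, io, predictor, preprocess, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulation (None -> read input paths instead)
    simulate: dict | None = field(default_factory=dict)
    methylation_path: str | None = None
    phenotypes_path: str | None = None
    outcomes_path: str | None = None
    # screen
    fdr_threshold: float = 0.05
    dual_p_threshold: float = 1e-7
    candidate_p_threshold: float = 1e-7  # predictor candidate rule
    ph_alpha: float = 0.05
    # causal stage
    ate_horizon: float = 5.0
    ate_n_boot: int = 200
    max_markers: int = 10
    # predictor stage
    stability_replicates: int = 100
    stability_subsample: float = 0.5
    stability_threshold: float = 0.8
    lambda_rule: str = "min_plus_half_se"
    cv_folds_lambda: int = 10
    cv_folds_validation: int = 5
    auc_horizons: tuple[float, ...] = (3.0, 5.0, 7.0)
    # external validation (simulated sibling cohort; None -> skip)
    external_n_pairs: int | None = 200
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "auc_horizons" in raw:
            raw["auc_horizons"] = tuple(float(v) for v in raw["auc_horizons"])
        return cls(**raw)

    def validate_paths(self) -> None:
        if self.simulate is None:
            for name in ("methylation_path", "phenotypes_path", "outcomes_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config missing {name} (no simulation stage)")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = out_dir
        self.seed = seed
        self.stages: list[dict] = []

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], t0: float, note: str = ""):
        self.stages.append(
            {
                "stage": stage,
                "seed": self.seed,
                "inputs": {p.name: _sha256(p) for p in inputs},
                "outputs": {p.name: _sha256(p) for p in outputs},
                "wall_seconds": round(_time.perf_counter() - t0, 3),
                "note": note,
            }
        )

    def write(self):
        (self.out_dir / "manifest.json").write_text(
            json.dumps({"stages": self.stages}, indent=2, sort_keys=True)
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory."""
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.seed)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "stability", "cv", "ate", "external"), ss.spawn(5)
        )
    }

    # ---- stage 1: simulate or load ---------------------------------------
    t0 = _time.perf_counter()
    meth_p = out / "methylation.tsv.gz"
    pheno_p = out / "phenotypes.csv"
    oc_p = out / "outcomes.csv"
    if config.simulate is not None:
        sim_cfg = synthetic.config_from_dict(
            {**config.simulate, "seed": seeds["simulate"]}
        )
        cohort, meth, outcomes, truth = synthetic.generate_cohort(sim_cfg)
        io.write_methylation(meth, meth_p)
        io.write_phenotypes(cohort, pheno_p)
        io.write_outcomes(outcomes, oc_p)
        truth.to_csv(out / "truth.csv", index=False)
        manifest.record("simulate", [], [meth_p, pheno_p, oc_p, out / "truth.csv"], t0)
    else:
        meth = io.read_methylation(config.methylation_path)
        cohort = io.read_phenotypes(config.phenotypes_path)
        outcomes = io.read_outcomes(config.outcomes_path)
        sim_cfg = None
        manifest.record(
            "load",
            [Path(config.methylation_path), Path(config.phenotypes_path),
             Path(config.outcomes_path)],
            [], t0,
        )

    # ---- stage 2: preprocess ---------------------------------------------
    t0 = _time.perf_counter()
    imputed = preprocess.impute_missing(meth, cohort)
    residuals = preprocess.residualize(imputed, cohort)
    resid_p = out / "residuals.tsv.gz"
    io.write_methylation(residuals, resid_p)
    manifest.record("preprocess", [meth_p, pheno_p], [resid_p], t0)

    # ---- stage 3: EWAS screen --------------------------------------------
    t0 = _time.perf_counter()
    ew_cfg = ewas.EwasConfig(
        fdr_threshold=config.fdr_threshold,
        dual_p_threshold=config.dual_p_threshold,
        ph_alpha=config.ph_alpha,
    )
    table = ewas.run_ewas(residuals, outcomes, cohort, ew_cfg)
    table.to_csv(out / "ewas_results.csv", index=False)
    markers = ewas.select_markers(table, ew_cfg)
    (out / "markers.txt").write_text("".join(m + "\n" for m in markers))
    manifest.record(
        "ewas", [resid_p, oc_p, pheno_p],
        [out / "ewas_results.csv", out / "markers.txt"], t0,
        note=f"{len(markers)} markers",
    )

    # ---- stage 4: causal / twin analyses ---------------------------------
    t0 = _time.perf_counter()
    candidates = table.loc[
        (table["hr_p"] < config.candidate_p_threshold)
        & (table["shr_p"] < config.candidate_p_threshold),
        "cpg_id",
    ].tolist()
    focus = (markers or candidates)[: config.max_markers]
    expo = preprocess.dichotomize(residuals)
    pair = cohort["pair_id"].to_numpy()
    ate_rows, icc_rows = [], []
    if focus:
        for cpg in focus:
            res = causal.ate_risk_ratio(
                expo[cpg].to_numpy(), outcomes, pair,
                horizon=config.ate_horizon, n_boot=config.ate_n_boot,
                seed=seeds["ate"], cpg_id=cpg,
            )
            ate_rows.append(dataclasses.asdict(res))
        for r in causal.icc_by_zygosity(residuals, cohort, focus):
            d = dataclasses.asdict(r)
            d["heritability_upper_bound"] = r.heritability_upper_bound
            icc_rows.append(d)
        try:
            matched = causal.matched_pair_analysis(
                residuals[focus], outcomes, cohort
            )
        except ValueError as err:
            matched = pd.DataFrame({"error": [str(err)]})
        matched.to_csv(out / "matched_results.csv")
    pd.DataFrame(ate_rows).to_csv(out / "ate_results.csv", index=False)
    pd.DataFrame(icc_rows).to_csv(out / "icc_results.csv", index=False)
    manifest.record(
        "causal", [resid_p, oc_p, pheno_p],
        [out / "ate_results.csv", out / "icc_results.csv"], t0,
        note=f"{len(focus)} CpGs analysed",
    )

    # ---- stage 5: predictor ----------------------------------------------
    t0 = _time.perf_counter()
    model = None
    if candidates:
        X = pd.concat(
            [residuals[candidates], predictor.sex_age_design(cohort)], axis=1
        )
        freq = predictor.stability_selection(
            X, outcomes, pair,
            n_replicates=config.stability_replicates,
            subsample=config.stability_subsample,
            threshold=config.stability_threshold,
            seed=seeds["stability"],
            cv_folds=config.cv_folds_lambda,
            rule=config.lambda_rule,
        )
        freq.to_csv(out / "stability_frequencies.csv", index=False)
        selected = freq.loc[freq["selected"], "cpg_id"].tolist()
        if not selected:  # fall back to the top-frequency CpG for a usable model
            selected = [freq.sort_values("selection_frequency").iloc[-1]["cpg_id"]]
        model = predictor.build_predictor(
            selected, residuals, outcomes, cohort,
            auc_horizons=np.asarray(config.auc_horizons),
        )
        model.lambda_rule = config.lambda_rule
        model.seed = config.seed
        (out / "predictor_model.json").write_text(model.to_json())
        cv = predictor.cross_validate(
            selected, residuals, outcomes, cohort,
            k=config.cv_folds_validation, seed=seeds["cv"],
            auc_horizons=np.asarray(config.auc_horizons),
        )
        pd.DataFrame(
            {
                "metric": ["cv_c_full", "cv_c_basic"],
                "value": [cv["cv_c_full"], cv["cv_c_basic"]],
            }
        ).to_csv(out / "cv_metrics.csv", index=False)
        pd.DataFrame(
            {
                "horizon": cv["auc_full"].horizons,
                "auc_full": cv["auc_full"].auc,
                "auc_basic": cv["auc_basic"].auc,
            }
        ).to_csv(out / "auc_curve.csv", index=False)
        manifest.record(
            "predictor", [resid_p, oc_p],
            [out / "stability_frequencies.csv", out / "predictor_model.json",
             out / "cv_metrics.csv", out / "auc_curve.csv"], t0,
            note=f"{len(selected)} CpGs selected",
        )
    else:
        manifest.record("predictor", [resid_p, oc_p], [], t0,
                        note="skipped: no candidate CpGs")

    # ---- stage 6: external validation ------------------------------------
    t0 = _time.perf_counter()
    if model is not None and config.external_n_pairs and sim_cfg is not None:
        ext_cfg = dataclasses.replace(
            sim_cfg, n_pairs=config.external_n_pairs, seed=seeds["external"]
        )
        ecohort, emeth, eoutcomes, _ = synthetic.generate_cohort(ext_cfg)
        eres = preprocess.residualize(
            preprocess.impute_missing(emeth, ecohort), ecohort
        )
        ext = predictor.external_validate(model, eres, eoutcomes, ecohort)
        (out / "external_validation.json").write_text(
            json.dumps(
                {k: v for k, v in ext.items()}, indent=2, sort_keys=True,
                default=float,
            )
        )
        manifest.record(
            "external", [], [out / "external_validation.json"], t0,
            note=f"{len(ext['dropped_cpgs'])} CpGs dropped",
        )
    else:
        manifest.record("external", [], [], t0, note="skipped")

    manifest.write()
    return out
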