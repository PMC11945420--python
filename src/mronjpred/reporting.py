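"""Pipeline orchestration: simulate -> ETL -> signals -> QSAR -> report.

``run_pipeline`` executes the stages in order on synthetic inputs (or on
tables read from disk), writes every table as CSV, every figure alongside
its underlying numbers, and a JSON summary stamped with the configuration
hash and seeds so a rerun with the same configuration reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import etl, modeling, signals, synthetic
from .errors import StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-serializable)."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig)
    descriptor_sim: synthetic.DescriptorSimConfig = field(
        default_factory=synthetic.DescriptorSimConfig)
    criteria: signals.LabelCriteria = field(
        default_factory=signals.LabelCriteria)
    model: modeling.ModelConfig = field(default_factory=modeling.ModelConfig)
    target_term: str = synthetic.TARGET_EVENT_TERM
    k_list: tuple[int, ...] = modeling.DEFAULT_K_LIST
    ad_bands: tuple[float, ...] = (0.0, 0.1, 0.2)
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compare_descriptor_by_class(matrix: pd.DataFrame, descriptor: str,
                                plot_path=None) -> dict:
    """Class means/sds and rank-sum p for one descriptor, plus a boxplot."""
    summary = desc.class_summary(matrix, descriptor)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups = [matrix.loc[matrix["label"] == lab, descriptor].dropna()
                  for lab in ("positive", "negative")]
        fig, ax = plt.subplots(figsize=(4, 5))
        ax.boxplot(groups, tick_labels=["positive", "negative"])
        ax.set_ylabel(descriptor)
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return summary


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage, writing tables/figures/summary into ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage failures abort with a stage-tagged error after writing a manifest
    of the outputs produced so far.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config_hash": config.config_hash(),
                     "seeds": {"simulation": config.simulation.seed,
                               "descriptors": config.descriptor_sim.seed,
                               "model": config.model.seed}}

    def emit(frame: pd.DataFrame, name: str) -> None:
        _write_csv(frame, outdir / name)
        manifest.append(name)

    stage = "simulate"
    try:
        sim = synthetic.generate_report_tables(config.simulation)
        emit(sim.ground_truth, "ground_truth.csv")

        stage = "etl"
        analysis = etl.run_etl(sim.drug, sim.therapy, sim.demographic,
                               sim.reaction, target_term=config.target_term)
        emit(analysis.frame, "analysis_table.csv")
        summary["etl_provenance"] = asdict(analysis.provenance)

        stage = "signals"
        sig = signals.compute_signals(analysis.frame, config.criteria,
                                      config.target_term)
        emit(sig, "signals.csv")
        coords = signals.volcano_coordinates(
            sig, config.criteria.min_total_reports)
        emit(coords, "volcano_coordinates.csv")
        if config.make_plots and not coords.empty:
            signals.plot_volcano(coords, outdir / "volcano.png",
                                 config.criteria.alpha)
            manifest.append("volcano.png")
        summary["signals"] = {
            "n_drugs": int(len(sig)),
            "n_positive": int((sig["label"] == "positive").sum()),
            "n_negative": int((sig["label"] == "negative").sum()),
            "n_unclassified": int((sig["label"] == "unclassified").sum()),
            "target_event_fraction": float(
                analysis.frame["is_target_event"].mean()),
        }

        stage = "descriptor_prep"
        # Descriptor rows are generated for the signal-labeled drugs so the
        # QSAR stage mirrors the labeled-drug table of the real workflow.
        labeled = sig[sig["label"] != "unclassified"]
        dcfg = config.descriptor_sim
        dcfg = synthetic.DescriptorSimConfig(
            n_positive=max(int((labeled["label"] == "positive").sum()),
                           dcfg.n_positive),
            n_negative=max(int((labeled["label"] == "negative").sum()),
                           dcfg.n_negative),
            informative_features=dcfg.informative_features,
            n_noise_features=dcfg.n_noise_features,
            n_collinear_duplicates=dcfg.n_collinear_duplicates,
            n_missing_columns=dcfg.n_missing_columns,
            truncate_at_zero=dcfg.truncate_at_zero,
            seed=dcfg.seed)
        dsim = synthetic.generate_descriptor_matrix(dcfg)
        prepared, row_log, prune_report = desc.prepare_qsar_table(dsim.matrix)
        emit(prepared, "qsar_table.csv")
        (outdir / "pruning_report.json").write_text(
            json.dumps({"rows": row_log, **prune_report.to_dict()}, indent=2))
        manifest.append("pruning_report.json")
        first_feature = desc.feature_columns(prepared)[0]
        summary["descriptor_comparison"] = compare_descriptor_by_class(
            prepared, first_feature,
            plot_path=(outdir / "descriptor_boxplot.png"
                       if config.make_plots else None))
        if config.make_plots:
            manifest.append("descriptor_boxplot.png")

        stage = "modeling"
        feats = desc.feature_columns(prepared)
        train, validation = modeling.split_train_validation(
            prepared, validation_fraction=config.model.validation_fraction,
            seed=config.model.seed)
        comparison = modeling.compare_algorithms(
            train, validation, feats, config.model)
        emit(comparison, "algorithm_comparison.csv")

        rf_cfg = modeling.ModelConfig(algorithm="random_forest",
                                      rf=config.model.rf,
                                      seed=config.model.seed)
        rf = modeling.fit_model(train[feats], train["label"], rf_cfg)
        ranking = modeling.rf_importance_ranking(rf, feats)
        emit(ranking, "importance_ranking.csv")

        k_list = [k for k in config.k_list if k <= len(feats)]
        sweep = modeling.top_k_model_sweep(train, validation, ranking,
                                           config.model, k_list)
        emit(sweep, "topk_sweep.csv")
        best = sweep.loc[sweep["validation_auroc"].idxmax()]
        best_k = int(best["n_descriptors"])
        best_feats = ranking["descriptor"].tolist()[:best_k]

        nn_cfg = modeling.ModelConfig(algorithm="neural_network",
                                      nn=config.model.nn,
                                      seed=config.model.seed)
        final = modeling.fit_model(train[best_feats], train["label"], nn_cfg)
        ev = modeling.evaluate_model(final, train, validation, best_feats)
        ad_rows = []
        for band in config.ad_bands:
            ad = modeling.applicability_domain(
                ev["validation_scores"], validation["label"], band)
            ad_rows.append({"band": band, "retained_drugs": ad.retained_drugs,
                            **ad.metrics.as_dict()})
        ad_table = pd.DataFrame(ad_rows)
        emit(ad_table, "applicability_domain.csv")

        atc_map = dict(zip(sim.ground_truth["drug_name"],
                           sim.ground_truth["atc_code"]))
        # Map validation compounds back to labeled drug names for the
        # per-ATC tabulation (synthetic descriptor rows are per-drug).
        pred = (np.asarray(ev["validation_scores"]) > 0.5).astype(int)
        per_atc = modeling.per_class_accuracy(
            validation["drug_name"], validation["label"], pred, atc_map)
        emit(per_atc, "per_class_accuracy.csv")

        summary["modeling"] = {
            "best_k": best_k,
            "best_validation_auroc": float(best["validation_auroc"]),
            "final_cutoff": float(ev["cutoff"]),
            "final_metrics": ev["metrics"].as_dict(),
            "algorithm_comparison": comparison.to_dict(orient="records"),
            "topk_sweep": sweep.to_dict(orient="records"),
            "applicability_domain": ad_table.to_dict(orient="records"),
        }
    except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
        (outdir / "manifest.json").write_text(json.dumps(
            {"completed": manifest, "failed_stage": stage}, indent=2))
        raise StageError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(
        json.dumps({"completed": manifest}, indent=2))
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return summary
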