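"""End-to-end orchestration of the biomarker discovery workflow.

Stages run in a fixed order — cohort acquisition (simulation or file
input), preprocessing, single-sample networks, candidate ranking, survival
modelling, coexpression — each writing its artifact to the output
directory, plus a JSON manifest recording parameters, seeds, library
versions and SHA-256 digests of every artifact, so a run is reproducible
and auditable.  A single top-level seed is fanned out to per-stage
substreams (simulation and the cohort split), so either can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    ExpressionMatrix,
    read_clinical_tsv,
    read_expression_tsv,
    write_clinical_tsv,
    write_expression_tsv,
)
from .coexpression import coexpressed_genes
from .preprocess import (
    differential_expression,
    filter_low_expression,
    normalize_counts,
    remove_duplicate_symbols,
)
from .ranking import DEFAULT_FRACTION, DEFAULT_KS, candidate_intersection
from .ssn import DELTA, perturbation_matrix
from .survival import (
    FIVE_YEARS_DAYS,
    assign_risk_groups,
    build_risk_model,
    independence_analysis,
    kaplan_meier,
    logrank_test,
    risk_score,
    split_cohort,
    time_dependent_roc,
    truncate_follow_up,
    univariate_cox_screen,
)
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger("lncssn")

# machine-readable error codes by failure domain
CONFIG_ERROR = 2
DATA_ERROR = 3
CONVERGENCE_ERROR = 4


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and an exit-style error code."""

    def __init__(self, stage: str, code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one run.

    Either ``simulation`` (a :class:`SimulationConfig`) or both
    ``expression_path`` and ``clinical_path`` must be provided.  Threshold
    defaults are the standard analysis settings: 10% zero-expression
    filter, FDR < 0.05 and |log2FC| > 1 for differential expression, top
    5% retention at K in {5, 10, 20, 30}, screening alpha 0.05, r > 0.45
    and p < 0.01 for coexpression, and a 5-year (1825-day) horizon.
    """

    outdir: str = "lncssn_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    max_zero_fraction: float = 0.10
    de_filter: bool = True
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fraction: float = DEFAULT_FRACTION
    ks: tuple[int, ...] = DEFAULT_KS
    alpha: float = 0.05
    r_threshold: float = 0.45
    p_threshold: float = 0.01
    horizon_days: float = FIVE_YEARS_DAYS
    ssn_mode: str = DELTA
    make_plots: bool = False

    def validate(self) -> None:
        if self.simulation is None and (
            self.expression_path is None or self.clinical_path is None
        ):
            raise ValueError(
                "provide a simulation config or expression_path + clinical_path"
            )
        for name in ("max_zero_fraction", "fdr_threshold", "alpha", "p_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [-1, 1]")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if not self.ks or any(int(k) != k or k < 1 for k in self.ks):
            raise ValueError("ks must be positive integers")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        config = cls(**raw)
        if sim is not None:
            if "hazard_coefficients" in sim:
                sim["hazard_coefficients"] = tuple(sim["hazard_coefficients"])
            config.simulation = SimulationConfig(**sim)
        if "ks" in raw:
            config.ks = tuple(raw["ks"])
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
            d["simulation"]["hazard_coefficients"] = list(
                self.simulation.hazard_coefficients
            )
        d["ks"] = list(self.ks)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON).

    Identical config and seed produce identical artifacts and manifest
    digests.  Any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    try:
        config.validate()
    except ValueError as err:
        raise PipelineError("config", CONFIG_ERROR, str(err)) from err

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # seed fan-out: one child stream per seeded stage
    seed_seq = np.random.SeedSequence(config.seed)
    sim_seed, split_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2)
    ]

    # -- stage: data -------------------------------------------------------
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=sim_seed)
            logger.info("simulating cohort (seed %d)", sim_seed)
            expr, clinical, truth = simulate_cohort(sim)
            write_expression_tsv(expr, outdir / "expression.tsv")
            write_clinical_tsv(clinical, outdir / "clinical.tsv")
            truth.to_json(outdir / "truth.json")
            artifacts["expression"] = outdir / "expression.tsv"
            artifacts["clinical"] = outdir / "clinical.tsv"
            artifacts["truth"] = outdir / "truth.json"
            report["stages"]["data"] = {
                "source": "simulation",
                "drivers": truth.driver_lnc_ids,
            }
        else:
            clinical = read_clinical_tsv(config.clinical_path)
            expr = read_expression_tsv(config.expression_path, clinical=clinical)
            truth = None
            report["stages"]["data"] = {"source": "files"}
    except (OSError, ValueError) as err:
        raise PipelineError("data", DATA_ERROR, str(err)) from err

    # -- stage: preprocess -------------------------------------------------
    try:
        filtered = filter_low_expression(expr, config.max_zero_fraction)
        normalized = normalize_counts(filtered)
        de_table = differential_expression(
            normalized, config.fdr_threshold, config.lfc_threshold
        )
        de_table.to_csv(outdir / "de_table.tsv", sep="\t")
        artifacts["de_table"] = outdir / "de_table.tsv"
        # with the DE filter off, the whole detected panel enters the network
        de = de_table[de_table["is_de"]] if config.de_filter else de_table
        lnc_symbols = de.loc[de["biotype"] == "lncRNA", "symbol"]
        mrna_symbols = de.loc[de["biotype"] == "mRNA", "symbol"]
        lnc_panel, mrna_panel = remove_duplicate_symbols(lnc_symbols, mrna_symbols)
        if not lnc_panel:
            raise ValueError("no differentially expressed lncRNAs remain")
        report["stages"]["preprocess"] = {
            "genes_after_zero_filter": len(filtered.gene_ids),
            "de_lncRNAs": len(lnc_panel),
            "de_mRNAs": len(mrna_panel),
        }
        logger.info(
            "preprocess: %d DE lncRNAs, %d DE mRNAs", len(lnc_panel), len(mrna_panel)
        )
    except ValueError as err:
        raise PipelineError("preprocess", DATA_ERROR, str(err)) from err

    # -- stage: ssn --------------------------------------------------------
    try:
        pert = perturbation_matrix(
            normalized, normalized, lnc_panel, mrna_panel, mode=config.ssn_mode
        )
        pert.to_csv(outdir / "perturbation_matrix.tsv", sep="\t")
        artifacts["perturbation_matrix"] = outdir / "perturbation_matrix.tsv"
        report["stages"]["ssn"] = {
            "n_lncRNAs": pert.shape[0],
            "n_tumor_samples": pert.shape[1],
        }
    except ValueError as err:
        raise PipelineError("ssn", DATA_ERROR, str(err)) from err

    # -- stage: ranking ----------------------------------------------------
    try:
        usable_ks = tuple(k for k in config.ks if k <= pert.shape[0])
        if not usable_ks:
            usable_ks = (pert.shape[0],)
        if usable_ks != tuple(config.ks):
            logger.warning(
                "dropping K values larger than the %d-lncRNA panel: using %s",
                pert.shape[0],
                usable_ks,
            )
        candidates = candidate_intersection(pert, ks=usable_ks, fraction=config.fraction)
        _write_json(
            {
                "per_k_sets": candidates.per_k_sets,
                "frequencies": {
                    str(k): f.to_dict() for k, f in candidates.frequencies.items()
                },
                "final": candidates.final,
            },
            outdir / "candidates.json",
        )
        artifacts["candidates"] = outdir / "candidates.json"
        report["stages"]["ranking"] = {"final_candidates": candidates.final}
        logger.info("ranking: %d final candidates", len(candidates.final))
    except ValueError as err:
        raise PipelineError("ranking", DATA_ERROR, str(err)) from err

    # -- stage: survival ---------------------------------------------------
    survival_report: dict = {}
    biomarkers: list[str] = []
    try:
        tumor_expr = normalized.values[normalized.tumor_sample_ids]
        clin = clinical.loc[[s for s in tumor_expr.columns if s in clinical.index]]
        if candidates.final:
            selected, screen_models = univariate_cox_screen(
                tumor_expr,
                clin,
                candidates.final,
                alpha=config.alpha,
                horizon=config.horizon_days,
            )
            screen_table = pd.concat(
                {lnc: m.summary for lnc, m in screen_models.items()},
                names=["lnc_id", "covariate"],
            )
            screen_table.to_csv(outdir / "univariate_screen.tsv", sep="\t")
            artifacts["univariate_screen"] = outdir / "univariate_screen.tsv"
            biomarkers = selected
        survival_report["biomarkers"] = biomarkers
        if biomarkers:
            train_ids, test_ids = split_cohort(clin, split_seed)
            model = build_risk_model(
                tumor_expr[train_ids],
                clin.loc[train_ids],
                biomarkers,
                horizon=config.horizon_days,
            )
            _write_json(
                {
                    "lnc_ids": model.lnc_ids,
                    "coefficients": model.coefficients,
                    "cutoff": model.cutoff,
                },
                outdir / "risk_model.json",
            )
            artifacts["risk_model"] = outdir / "risk_model.json"
            trunc = truncate_follow_up(clin, config.horizon_days)
            sets = {
                "training": train_ids,
                "testing": test_ids,
                "entire": list(clin.index),
            }
            independence = {}
            for name, ids in sets.items():
                scores = risk_score(model, tumor_expr[ids])
                groups = assign_risk_groups(scores, model.cutoff)
                t, e = trunc.loc[ids, "os_days"], trunc.loc[ids, "event"]
                km = kaplan_meier(t, e, groups)
                entry: dict = {
                    "n": len(ids),
                    "n_high": int((groups == "high").sum()),
                    "n_low": int((groups == "low").sum()),
                    "median_survival_days": {g: km[g][1] for g in km},
                }
                if entry["n_high"] > 0 and entry["n_low"] > 0:
                    stat, p = logrank_test(t, e, groups)
                    entry["logrank_statistic"] = stat
                    entry["logrank_p"] = p
                    try:
                        roc = time_dependent_roc(
                            scores, t, e, horizon=config.horizon_days
                        )
                        entry["auc_5yr"] = roc.auc
                    except ValueError as err:
                        entry["auc_5yr"] = None
                        logger.warning("ROC skipped for %s set: %s", name, err)
                    independence[name] = independence_analysis(
                        clin.loc[ids], groups, horizon=config.horizon_days
                    )
                survival_report[name] = entry
            if independence:
                combined = pd.concat(independence, names=["dataset", "variable"])
                combined.to_csv(outdir / "independence_analysis.tsv", sep="\t")
                artifacts["independence_analysis"] = outdir / "independence_analysis.tsv"
        report["stages"]["survival"] = survival_report
    except (ValueError, RuntimeError) as err:
        code = CONVERGENCE_ERROR if "converge" in str(err).lower() else DATA_ERROR
        raise PipelineError("survival", code, str(err)) from err

    # -- stage: coexpression -----------------------------------------------
    try:
        if biomarkers:
            coexp = coexpressed_genes(
                tumor_expr.loc[biomarkers],
                tumor_expr.loc[mrna_panel],
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
            )
            coexp.to_frame().to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
            artifacts["coexpression"] = outdir / "coexpression.tsv"
            report["stages"]["coexpression"] = {
                "union_size": len(coexp.union),
                "per_lnc_counts": {k: len(v) for k, v in coexp.per_lnc.items()},
            }
        else:
            report["stages"]["coexpression"] = {"skipped": "no biomarkers"}
    except ValueError as err:
        raise PipelineError("coexpression", DATA_ERROR, str(err)) from err

    if config.make_plots and biomarkers:
        from .plots import plot_km_by_group, plot_roc

        scores = risk_score(model, tumor_expr[list(clin.index)])
        groups = assign_risk_groups(scores, model.cutoff)
        trunc = truncate_follow_up(clin, config.horizon_days)
        plot_km_by_group(
            trunc["os_days"], trunc["event"], groups, outdir / "km_entire.png"
        )
        try:
            roc = time_dependent_roc(
                scores, trunc["os_days"], trunc["event"], config.horizon_days
            )
            plot_roc(roc, outdir / "roc_entire.png")
        except ValueError:
            pass

    # -- manifest ----------------------------------------------------------
    manifest = {
        "lncssn_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {"simulation": sim_seed, "cohort_split": split_seed},
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    _write_json(manifest, outdir / "manifest.json")
    _write_json(report, outdir / "report.json")
    return report
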