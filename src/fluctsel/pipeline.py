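"""Reproducible simulate -> classify -> fit -> predict -> report workflow.

Each stage reads and writes plain TSV files in a run directory, so a run
is fully described by its config, seed and manifest; deterministic stages
re-run to byte-identical outputs. The report stage tabulates the fitted
parameters, the mean-selection-vs-autocorrelation curve with delta-method
confidence intervals, predicted vs fitted mean trajectories, and the
variance-growth comparison between fluctuating and constant treatments;
plots are an optional convenience layer over those tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcode import CalibrationMap, classify_reads
from .environment import write_salinity_tsv
from .reaction_norms import (
    ReactionNormBi,
    ReactionNormUni,
    bivariate_mean_selection,
    bivariate_var_selection,
    mean_selection_gaussian,
    predicted_trajectory_frame,
    var_selection_gaussian,
)
from . import state_space
from .state_space import FitResult, ModelSpec, SELECTED_MODEL, lines_from_frames, mean_selection_ci
from .synthetic import (
    ExperimentConfig,
    default_treatments,
    demo_panel_and_table,
    generate_experiment,
    generate_reads,
    transfer_pairs,
    write_fastq,
)
from .transfer_model import fit_transfer_model, transfer_lr_tests

ALL_STAGES = ("simulate", "classify", "fit", "transfer_fit", "predict", "report")


class StageDependencyError(RuntimeError):
    """An upstream output required by a stage is missing."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def experiment_config_from_dict(cfg: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from the YAML ``simulate`` section."""
    kwargs = {}
    design = cfg.get("design", {})
    if design:
        kwargs["treatments"] = default_treatments(
            n_fluctuating=design.get("n_fluctuating", 40),
            n_constant=design.get("n_constant", 5),
            n_transfers=design.get("n_transfers", 37),
        )
        kwargs["n_transfers"] = design.get("n_transfers", 37)
    for key in (
        "mode",
        "residual_sd",
        "depth_chloro",
        "depth_its2",
        "depth_dispersion",
        "attrition_fluct",
        "attrition_const",
        "first_duration",
    ):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "sequenced_transfers" in cfg:
        kwargs["sequenced_transfers"] = tuple(cfg["sequenced_transfers"])
    if "fixed_effects" in cfg:
        kwargs["fixed_effects"] = dict(cfg["fixed_effects"])
    if "variance_components" in cfg:
        kwargs["variance_components"] = dict(cfg["variance_components"])
    if "calibration" in cfg:
        kwargs["calibration"] = CalibrationMap(*cfg["calibration"])
    if "reaction_norm" in cfg:
        rn = cfg["reaction_norm"]
        if any(k in rn for k in ("d", "e", "f")):
            kwargs["reaction_norm"] = ReactionNormBi(
                rn.get("a_p", rn.get("a", 0.0)),
                rn.get("b_p", rn.get("b", 0.0)),
                rn.get("c_p", rn.get("c", 0.0)),
                rn.get("d", 0.0),
                rn.get("e", 0.0),
                rn.get("f", 0.0),
            )
        else:
            kwargs["reaction_norm"] = ReactionNormUni(rn["a"], rn["b"], rn["c"])
    return ExperimentConfig(**kwargs)


@dataclass
class RunManifest:
    config: dict
    seed: int
    outdir: str
    stages: List[str]
    outputs: Dict[str, List[str]] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def run_pipeline(
    config: dict | str | Path,
    stages=("simulate", "fit", "report"),
    seed: int = 1,
    outdir: str | Path = "fluctsel_run",
) -> RunManifest:
    """Execute pipeline stages in order, wiring TSV outputs to inputs."""
    if not isinstance(config, dict):
        config = load_config(config)
    stages = list(stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed, outdir=str(outdir), stages=stages)

    for stage in sorted(stages, key=ALL_STAGES.index):
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, seed, outdir)
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs[stage] = [str(p) for p in outputs]
    manifest.save(outdir / "manifest.json")
    return manifest


def _need(outdir: Path, name: str, stage: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise StageDependencyError(f"stage {stage!r} needs {name}; run its producer first")
    return p


def _stage_simulate(config: dict, seed: int, outdir: Path):
    exp = generate_experiment(experiment_config_from_dict(config.get("simulate", {})), seed)
    write_salinity_tsv(exp.salinities, outdir / "salinity.tsv")
    exp.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    exp.treatments.to_csv(outdir / "treatments.tsv", sep="\t", index=False)
    exp.true_latents.to_csv(outdir / "latents_true.tsv", sep="\t", index=False)
    exp.attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
    return ["salinity.tsv", "counts.tsv", "treatments.tsv", "latents_true.tsv", "attrition.tsv"]


def _stage_classify(config: dict, seed: int, outdir: Path):
    """Re-derive counts from emitted reads for a subset of cells.

    Emitting full-depth FASTQ for every cell is wasteful; the stage
    demonstrates read-level closure on ``classify.max_cells`` cells
    (default 20) and passes the remaining counts through unchanged.
    """
    counts = pd.read_csv(_need(outdir, "counts.tsv", "classify"), sep="\t")
    ccfg = config.get("classify", {})
    max_cells = int(ccfg.get("max_cells", 20))
    exp_cfg = experiment_config_from_dict(config.get("simulate", {}))
    exp = generate_experiment(exp_cfg, seed)  # deterministic re-generation
    tables = {"chloroplast": demo_panel_and_table("chloroplast")[1], "its2": demo_panel_and_table("its2")[1]}
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    out = counts.copy()
    out["reclassified"] = False
    cells = counts[["line_id", "transfer", "locus"]].drop_duplicates().head(max_cells)
    for _, cell in cells.iterrows():
        table = tables[cell["locus"]]
        recs = generate_reads(
            exp, cell["locus"], cell["line_id"], int(cell["transfer"]), table, seed=seed
        )
        fq = reads_dir / f"{cell['line_id']}_t{cell['transfer']}_{cell['locus']}.fastq"
        write_fastq(recs, fq)
        rc = classify_reads(fq, table)
        mask = (
            (out["line_id"] == cell["line_id"])
            & (out["transfer"] == cell["transfer"])
            & (out["locus"] == cell["locus"])
        )
        out.loc[mask, ["n_C", "N_total"]] = [rc.n_C, rc.total_matched]
        out.loc[mask, "reclassified"] = True
    out.to_csv(outdir / "counts_classified.tsv", sep="\t", index=False)
    return ["counts_classified.tsv"]


def _fit_from_dir(config: dict, outdir: Path, stage: str) -> FitResult:
    counts_name = (
        "counts_classified.tsv" if (outdir / "counts_classified.tsv").exists() else "counts.tsv"
    )
    counts = pd.read_csv(_need(outdir, counts_name, stage), sep="\t")
    treatments = pd.read_csv(_need(outdir, "treatments.tsv", stage), sep="\t")
    fcfg = config.get("fit", {})
    model = ModelSpec(
        mean_terms=tuple(fcfg.get("mean_terms", SELECTED_MODEL.mean_terms)),
        variance_structure=fcfg.get("variance_structure", "by_fluctuation"),
        estimate_calibration=bool(fcfg.get("estimate_calibration", False)),
    )
    cal = CalibrationMap(*fcfg.get("calibration", (0.19, 0.79)))
    lines = lines_from_frames(counts, treatments)
    return state_space.fit(lines, model=model, calibration=cal)


def _stage_fit(config: dict, seed: int, outdir: Path):
    result = _fit_from_dir(config, outdir, "fit")
    result.summary().to_csv(outdir / "params.tsv", sep="\t", index=False)
    result.latents.to_csv(outdir / "latents.tsv", sep="\t", index=False)
    meta = {"loglik": result.loglik, "converged": result.converged, "n_lines": result.n_lines}
    with open(outdir / "fit_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return ["params.tsv", "latents.tsv", "fit_meta.json"]


def _stage_transfer_fit(config: dict, seed: int, outdir: Path):
    _need(outdir, "counts.tsv", "transfer_fit")
    exp = generate_experiment(experiment_config_from_dict(config.get("simulate", {})), seed)
    pairs = transfer_pairs(exp)
    fit_res = fit_transfer_model(pairs)
    rows = [(k, v, fit_res.se.get(k, np.nan)) for k, v in fit_res.params.items()]
    pd.DataFrame(rows, columns=["term", "estimate", "se"]).to_csv(
        outdir / "transfer_params.tsv", sep="\t", index=False
    )
    tests = transfer_lr_tests(pairs)
    pd.DataFrame(
        [(k, t.statistic, t.df, t.p_value) for k, t in tests.items()],
        columns=["test", "statistic", "df", "p_value"],
    ).to_csv(outdir / "transfer_tests.tsv", sep="\t", index=False)
    return ["transfer_params.tsv", "transfer_tests.tsv"]


def _stage_predict(config: dict, seed: int, outdir: Path):
    params = pd.read_csv(_need(outdir, "params.tsv", "predict"), sep="\t").set_index("term")
    rn = ReactionNormUni(
        params.loc["theta_intercept", "estimate"],
        params.loc["theta_mu", "estimate"],
        params.loc["theta_mu2", "estimate"],
    )
    rows = []
    for rho in np.linspace(-0.95, 0.95, 39):
        rows.append(
            ("univariate", rho, mean_selection_gaussian(rn, 0.0, 1.0), var_selection_gaussian(rn, 0.0, 1.0))
        )
    pd.DataFrame(rows, columns=["norm", "rho", "s_mean_pred", "s_var_pred"]).to_csv(
        outdir / "predictions.tsv", sep="\t", index=False
    )
    # per-line predicted mean trajectories from the realised salinities
    exp = generate_experiment(experiment_config_from_dict(config.get("simulate", {})), seed)
    psi0 = float(params.loc["psi0_mean", "estimate"])
    predicted_trajectory_frame(rn, exp.salinities, psi0).to_csv(
        outdir / "predicted_trajectories.tsv", sep="\t", index=False
    )
    return ["predictions.tsv", "predicted_trajectories.tsv"]


def _stage_report(config: dict, seed: int, outdir: Path):
    result = _fit_from_dir(config, outdir, "report")
    result.summary().to_csv(outdir / "report_params.tsv", sep="\t", index=False)
    outputs = ["report_params.tsv"]

    # mean selection vs autocorrelation with delta-method CIs
    rows = []
    for rho in np.linspace(-0.95, 0.95, 39):
        est, lo, hi = mean_selection_ci(result, rho)
        rows.append((rho, est, lo, hi))
    curve = pd.DataFrame(rows, columns=["rho", "s_mean", "ci_low", "ci_high"])
    curve.to_csv(outdir / "report_selection_vs_rho.tsv", sep="\t", index=False)
    outputs.append("report_selection_vs_rho.tsv")

    # predicted vs fitted mean trajectories, and variance growth
    rn = ReactionNormUni(
        result.params["theta_intercept"],
        result.params.get("theta_mu", 0.0),
        result.params.get("theta_mu2", 0.0),
    )
    comparison = compare_predictions(result, rn)
    comparison.to_csv(outdir / "report_comparison.tsv", sep="\t", index=False)
    outputs.append("report_comparison.tsv")

    if config.get("report", {}).get("plots", False):
        outputs.extend(_report_plots(result, curve, outdir))
    return outputs


def _report_plots(result: FitResult, curve: pd.DataFrame, outdir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["rho"], curve["s_mean"], color="k")
    ax.fill_between(curve["rho"], curve["ci_low"], curve["ci_high"], alpha=0.3)
    ax.set_xlabel("environmental autocorrelation rho")
    ax.set_ylabel("mean selection coefficient (per day)")
    fig.tight_layout()
    fig.savefig(outdir / "selection_vs_rho.png", dpi=120)
    plt.close(fig)
    return ["selection_vs_rho.png"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "fit": _stage_fit,
    "transfer_fit": _stage_transfer_fit,
    "predict": _stage_predict,
    "report": _stage_report,
}


def compare_predictions(
    fit_result: FitResult,
    rn: ReactionNormUni,
    rnb: Optional[ReactionNormBi] = None,
) -> pd.DataFrame:
    """Fitted vs reaction-norm-predicted selection moments per treatment.

    For each fluctuating treatment (mu_E = 0, sigma_E^2 = 1, rho from the
    design) and the constant 2.4 M treatment, tabulates the fitted mean
    selection and selection variance against the univariate (and
    optionally bivariate) norm's predictions, their ratios, and the Wald
    p-value of fitted-vs-predicted mean.
    """
    from .state_space import wald_test

    p = fit_result.params
    rows = []
    design = [("constant_2.4M", 0.0, 0.0, 0.0)] + [
        (f"fluct_rho_{rho:+.1f}", 0.0, 1.0, rho) for rho in (-0.5, 0.0, 0.5, 0.9)
    ]
    for label, mu, s2, rho in design:
        fitted_mean = (
            p["theta_intercept"]
            + p.get("theta_mu", 0.0) * mu
            + p.get("theta_mu2", 0.0) * mu * mu
            + p.get("theta_sigma2", 0.0) * s2
            + p.get("theta_rho2", 0.0) * rho * rho
        )
        fitted_var = p["sigma0_sq"] if s2 == 0 else p["sigma1_sq"]
        pred_mean = mean_selection_gaussian(rn, mu, s2) if s2 > 0 else rn(mu)
        pred_var = var_selection_gaussian(rn, mu, s2)
        if rnb is not None and s2 > 0:
            pred_mean = bivariate_mean_selection(rnb, mu, s2, rho)
            pred_var = bivariate_var_selection(rnb, mu, s2, rho, method="exact")
        contrast = {"theta_intercept": 1.0}
        if s2 > 0:
            for term, wgt in (("theta_sigma2", 1.0), ("theta_rho2", rho * rho)):
                if term in fit_result.params:
                    contrast[term] = wgt
        try:
            p_wald = wald_test(fit_result, contrast, value=pred_mean).p_value
        except (ValueError, KeyError):
            p_wald = np.nan
        rows.append(
            (
                label,
                fitted_mean,
                pred_mean,
                fitted_var,
                pred_var,
                fitted_var / pred_var if pred_var > 0 else np.inf,
                p_wald,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment",
            "fitted_mean_s",
            "predicted_mean_s",
            "fitted_var_s",
            "predicted_var_s",
            "var_ratio",
            "wald_p_mean",
        ],
    )
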