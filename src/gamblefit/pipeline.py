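"""End-to-end study pipeline: simulate or load choices, fit, compare, contrast.

The exchange format is a long-format choice CSV with header

    subject_id, condition, session, trial_index,
    magnitude_a_jpy, prob_a, magnitude_b_jpy, prob_b, choice

(choice is A, B, or MISSING; probabilities are fractions in (0, 1]).
``run_study_pipeline`` produces, under the output directory:

    model_comparison.csv   iBIC per model per condition + ML AIC analogues
    subject_parameters.csv per-subject estimates of the winning model
                           (both fitting methods, both conditions)
    contrasts.csv          paired contrasts for lam, gam, |lam-1|, |gam-1|,
                           beta under both fitting methods
    priors.csv             final population gamma priors per condition
    recovery.csv           truth-vs-estimate summary (simulate mode only)
    manifest.json          config, seeds, versions, and the manifest hash
                           embedded in every CSV

Runs are deterministic: identical config + seed give byte-identical CSVs.
Sessions are recorded by the loader but pooled by every analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hbem import compare_models_hbem, fit_hbem
from .mle import fit_cohort_ml
from .models import (
    CHOICE_A,
    CHOICE_B,
    CONDITIONS,
    MISSING,
    GambleOption,
    GambleTrial,
    SubjectDataset,
)
from .simulate import (
    CrossoverStudy,
    PopulationSpec,
    GammaParams,
    StudyDesign,
    simulate_crossover_study,
)
from .stats import paired_compare, rationality_contrast

log = logging.getLogger("gamblefit")

CSV_COLUMNS = [
    "subject_id",
    "condition",
    "session",
    "trial_index",
    "magnitude_a_jpy",
    "prob_a",
    "magnitude_b_jpy",
    "prob_b",
    "choice",
]

_FLOAT_FMT = "%.10g"


# -- choice CSV I/O -----------------------------------------------------------


def cohort_to_frame(cohort: Sequence[SubjectDataset]) -> pd.DataFrame:
    rows = []
    for data in cohort:
        for i, t in enumerate(data.trials):
            rows.append(
                {
                    "subject_id": data.subject_id,
                    "condition": data.condition,
                    "session": t.session,
                    "trial_index": i,
                    "magnitude_a_jpy": t.option_a.magnitude,
                    "prob_a": t.option_a.probability,
                    "magnitude_b_jpy": t.option_b.magnitude,
                    "prob_b": t.option_b.probability,
                    "choice": t.choice if t.choice is not None else MISSING,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_choices_csv(cohort: Sequence[SubjectDataset], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_choices_csv(path) -> list[SubjectDataset]:
    """Read and validate a long-format choice CSV into per-subject datasets.

    Errors name the offending row (1-based data row, excluding the header).
    Row order within each subject is preserved; subjects appear in order of
    first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    groups: dict[tuple[str, str], list[GambleTrial]] = {}
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        condition = str(row["condition"])
        if condition not in CONDITIONS:
            raise ValueError(
                f"{path} row {rowno}: unknown condition {condition!r}"
            )
        choice = str(row["choice"])
        if choice not in (CHOICE_A, CHOICE_B, MISSING):
            raise ValueError(f"{path} row {rowno}: invalid choice {choice!r}")
        for pcol in ("prob_a", "prob_b"):
            p = float(row[pcol])
            if not 0 < p <= 1:
                raise ValueError(
                    f"{path} row {rowno}: {pcol} = {p} outside (0, 1]"
                )
        for mcol in ("magnitude_a_jpy", "magnitude_b_jpy"):
            if not float(row[mcol]) > 0:
                raise ValueError(
                    f"{path} row {rowno}: {mcol} must be > 0"
                )
        trial = GambleTrial(
            GambleOption(float(row["magnitude_a_jpy"]), float(row["prob_a"])),
            GambleOption(float(row["magnitude_b_jpy"]), float(row["prob_b"])),
            choice=choice,
            session=int(row["session"]),
        )
        groups.setdefault((str(row["subject_id"]), condition), []).append(trial)
    return [
        SubjectDataset(subject_id, condition, trials)
        for (subject_id, condition), trials in groups.items()
    ]


# -- run configuration --------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "simulate"  # "simulate" | "load"
    input_csv: str | None = None
    output_dir: str = "gamblefit_run"
    design: StudyDesign = field(default_factory=StudyDesign)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    generating_model: int = 4
    models: tuple[int, ...] = (1, 2, 3, 4)
    n_samples: int = 100_000
    n_starts: int = 10
    hbem_tol: float = 0.1
    hbem_max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.input_csv:
            raise ValueError("load mode requires input_csv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            dd = dict(d["design"])
            dd["probability_levels"] = tuple(dd.get("probability_levels", ()))
            dd["magnitude_range"] = tuple(dd.get("magnitude_range", (100.0, 10_000.0)))
            d["design"] = StudyDesign(**dd)
        if "population" in d and isinstance(d["population"], dict):
            pp = dict(d["population"])
            for name in ("lam", "gam", "beta"):
                pp[name] = {
                    cond: GammaParams(**gp) if isinstance(gp, dict) else gp
                    for cond, gp in pp[name].items()
                }
            d["population"] = PopulationSpec(**pp)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def manifest_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# -- pipeline -----------------------------------------------------------------


def _estimate_table(
    subject_ids, condition, method, model_id, estimates, extra=None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "condition": condition,
            "method": method,
            "model_id": model_id,
            "lam": [e.lam for e in estimates],
            "gam": [e.gam for e in estimates],
            "beta": [e.beta for e in estimates],
        }
    )
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    return df


def _contrast_row(result, method: str) -> dict:
    return {
        "variable": result.variable,
        "method": method,
        "test_used": result.test_used,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "effect_size_dz": result.effect_size_d,
        "mean_difference": result.mean_difference,
        "n_pairs": result.n_pairs,
        "normality_p": result.normality_p,
    }


@dataclass
class PipelineReport:
    """In-memory handles to everything ``run_study_pipeline`` wrote."""

    config: RunConfig
    manifest: dict
    model_comparison: pd.DataFrame
    subject_parameters: pd.DataFrame
    contrasts: pd.DataFrame
    priors: pd.DataFrame
    recovery: pd.DataFrame | None
    winning_model: int
    output_dir: Path


def run_study_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full study analysis and write the report bundle.

    Stages: acquire choices (simulate or load) -> HBEM fit of every
    candidate model per condition and iBIC comparison -> per-subject ML fits
    (AIC analogue) -> winning-model parameter tables -> paired condition
    contrasts for lam, gam, |lam - 1|, |gam - 1| and beta under both
    methods -> population-prior summaries per condition -> manifest. In
    simulate mode a truth-recovery summary is added.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mhash = config.manifest_hash()
    log.info("pipeline start (manifest %s, seed %d)", mhash, config.seed)

    study: CrossoverStudy | None = None
    if config.mode == "simulate":
        study = simulate_crossover_study(
            config.design, config.population, config.generating_model,
            seed=config.seed,
        )
        cohorts = {c: study.cohort(c) for c in CONDITIONS}
        write_choices_csv(study.all_datasets, outdir / "choices.csv")
        study.truth_to_json(outdir / "truth.json")
    else:
        loaded = load_choices_csv(config.input_csv)
        cohorts = {
            c: [d for d in loaded if d.condition == c] for c in CONDITIONS
        }
        cohorts = {c: cohort for c, cohort in cohorts.items() if cohort}

    # model comparison + fits, per condition
    comparison_rows = []
    hbem_fits: dict[str, dict[int, object]] = {}
    ml_fits: dict[str, dict[int, tuple]] = {}
    for condition, cohort in cohorts.items():
        log.info("fitting condition %s (%d subjects)", condition, len(cohort))
        comp = compare_models_hbem(
            cohort,
            models=config.models,
            n_samples=config.n_samples,
            seed=config.seed,
            tol=config.hbem_tol,
            max_iter=config.hbem_max_iter,
        )
        hbem_fits[condition] = comp.fits
        ml_fits[condition] = {}
        for model_id in config.models:
            results, summary = fit_cohort_ml(
                cohort, model_id, n_starts=config.n_starts, seed=config.seed
            )
            ml_fits[condition][model_id] = (results, summary)
            fit = comp.fits[model_id]
            comparison_rows.append(
                {
                    "condition": condition,
                    "model_id": model_id,
                    "ibic": fit.ibic,
                    "total_log_evidence": fit.total_log_evidence,
                    "hbem_iterations": fit.n_iterations,
                    "mean_aic": summary["mean_aic"],
                    "sum_aic": summary["sum_aic"],
                }
            )
    comparison = pd.DataFrame(comparison_rows)
    total_ibic = comparison.groupby("model_id")["ibic"].sum()
    winning_model = int(total_ibic.idxmin())
    comparison["winner"] = comparison["model_id"] == winning_model
    log.info("winning model by total iBIC: %d", winning_model)

    # winning-model subject tables (both methods)
    est_frames = []
    for condition in cohorts:
        fit = hbem_fits[condition][winning_model]
        est_frames.append(
            _estimate_table(
                fit.subject_ids,
                condition,
                "hbem",
                winning_model,
                fit.per_subject_estimates,
                extra={"log_evidence": fit.per_subject_log_evidence},
            )
        )
        results, _ = ml_fits[condition][winning_model]
        est_frames.append(
            _estimate_table(
                [r.subject_id for r in results],
                condition,
                "ml",
                winning_model,
                [r.estimates for r in results],
                extra={
                    "nll": [r.nll for r in results],
                    "aic": [r.aic for r in results],
                },
            )
        )
    subject_parameters = pd.concat(est_frames, ignore_index=True)

    # paired contrasts per method (requires both conditions)
    contrast_rows = []
    if set(cohorts) == set(CONDITIONS):
        for method in ("hbem", "ml"):
            sub = subject_parameters[subject_parameters["method"] == method]
            wide = {
                c: sub[sub["condition"] == c].set_index("subject_id")
                for c in CONDITIONS
            }
            common = wide["neutral"].index.intersection(wide["positive"].index)
            for name in ("lam", "gam", "beta"):
                pos = wide["positive"].loc[common, name].to_numpy()
                neu = wide["neutral"].loc[common, name].to_numpy()
                contrast_rows.append(
                    _contrast_row(
                        paired_compare(pos, neu, variable=name), method
                    )
                )
            for name in ("lam", "gam"):
                pos = wide["positive"].loc[common, name].to_numpy()
                neu = wide["neutral"].loc[common, name].to_numpy()
                contrast_rows.append(
                    _contrast_row(rationality_contrast(neu, pos, name), method)
                )
    contrasts = pd.DataFrame(contrast_rows)

    # population priors per condition (numeric content of the prior-shift plot)
    prior_rows = []
    for condition in cohorts:
        fit = hbem_fits[condition][winning_model]
        for name in fit.final_priors.names:
            g = fit.final_priors[name]
            prior_rows.append(
                {
                    "condition": condition,
                    "parameter": name,
                    "shape": g.shape,
                    "scale": g.scale,
                    "mean": g.mean,
                    "sd": float(np.sqrt(g.variance)),
                }
            )
    priors = pd.DataFrame(prior_rows)

    # recovery summary in simulate mode
    recovery = None
    if study is not None:
        rec_rows = []
        for condition in CONDITIONS:
            fit = hbem_fits[condition][winning_model]
            for name in ("lam", "gam", "beta"):
                truth = study.true_values(name, condition)
                est = np.array(
                    [getattr(e, name) for e in fit.per_subject_estimates]
                )
                rec_rows.append(
                    {
                        "condition": condition,
                        "parameter": name,
                        "method": "hbem",
                        "mean_true": float(truth.mean()),
                        "mean_estimate": float(est.mean()),
                        "mean_abs_error": float(np.abs(est - truth).mean()),
                        "corr_true_est": float(np.corrcoef(truth, est)[0, 1]),
                    }
                )
        recovery = pd.DataFrame(rec_rows)

    manifest = {
        "manifest_hash": mhash,
        "gamblefit_version": __version__,
        "seed": config.seed,
        "winning_model": winning_model,
        "config": config.to_dict(),
    }

    for name, df in [
        ("model_comparison", comparison),
        ("subject_parameters", subject_parameters),
        ("contrasts", contrasts),
        ("priors", priors),
    ] + ([("recovery", recovery)] if recovery is not None else []):
        df = df.copy()
        df["manifest_hash"] = mhash
        df.to_csv(outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("pipeline done: %s", outdir)

    return PipelineReport(
        config=config,
        manifest=manifest,
        model_comparison=comparison,
        subject_parameters=subject_parameters,
        contrasts=contrasts,
        priors=priors,
        recovery=recovery,
        winning_model=winning_model,
        output_dir=outdir,
    )
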