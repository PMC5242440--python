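"""End-to-end orchestration of the full analysis, reproducible from one config.

Stage order mirrors the study logic:

1. ingest or generate the cohort (per-minute counts + covariates);
2. preprocess to per-subject activity/intensity profiles;
3. pooling check between the two DJD sub-studies (FMPI vs LowDose):
   distribution test plus mean-curve LRTs under the four covariate settings —
   if the check rejects, the sub-studies are still pooled but a warning is
   recorded (automated gatekeeping on p-values is fragile);
4. pooled group mean profiles and the pre-transform cohort summary;
5. FPCA per group x day type on intensity profiles, with variance-explained
   tables, modes of variation and weekend-weekday score correlations;
6. function-on-scalar regressions (Model 1: Normal cats on age, BCS and
   their interaction; Model 2: DJD cats adding TDJD and TPain) with
   subject-bootstrap confidence bands and significance regions;
7. Normal-vs-DJD mean-curve LRT table (weekend/weekday x activity/intensity
   x four covariate settings, Bonferroni-adjusted per row);
8. paired weekend-vs-weekday LRTs per group and Normal-vs-DJD distribution
   tests.

Every artifact is a CSV (plus a JSON run manifest recording the seed and the
analysis decisions in force); reruns with the same config are byte-identical.
All stochastic stages draw from one seeded generator hierarchy.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fosr import ModelSpec, bootstrap_ci, fit_fosr, significance_regions, standardize_covariates
from .fpca import fit_fpca, modes_of_variation, score_correlation
from .grid import DEFAULT_GRID
from .inference import (
    COVARIATE_SETTINGS,
    distribution_test,
    lrt_mean_equality,
    lrt_paired_daytype,
)
from .io import EpochSeries, read_covariates_csv, read_epoch_csv, write_covariates_csv, write_epoch_csv
from .preprocessing import (
    WEEKDAY,
    WEEKEND,
    CatProfile,
    cohort_summary,
    group_mean_profiles,
    mean_preTransform_count,
    profile_from_series,
    profiles_to_frame,
)
from .synthetic import DJD, NORMAL, GeneratorConfig, generate_cohort

log = logging.getLogger("catfda.pipeline")

_CSV_KW = dict(index=False, float_format="%.12g", lineterminator="\n")

DECISIONS = {
    "transform_order": "ln(1+x) per minute, then 5-minute arithmetic mean",
    "quartile_method": "linear interpolation (type 7)",
    "fpca_covariance": "empirical (unsmoothed), direct eigendecomposition",
    "fpca_sign_convention": "integral of phi over [5h, 9h] >= 0",
    "fosr_basis": "cubic B-splines, difference penalty order 2, basis_dim 15",
    "fosr_smoothing": "per-term GCV; bootstrap refits reuse original smoothing",
    "fosr_ci": "subject-level percentile bootstrap, pointwise 95%",
    "lrt_statistic": "profiled working-Gaussian deviance, resampling null",
    "lrt_null": "residual-curve resampling (two-group) / sign flips (paired)",
    "ad_ties": "seeded uniform jitter 1e-9 x range",
    "distribution_overall_p": "Bonferroni min-p combination",
    "pooling": "unconditional-with-warning if the pooling check rejects",
}


@dataclass
class PipelineConfig:
    """Inputs, sizes and seeds for one full run."""

    outdir: Path = Path("catfda_out")
    seed: int = 0
    generator: GeneratorConfig | None = None
    epoch_csv: Path | None = None
    covariates_csv: Path | None = None
    n_sim: int = 200
    n_boot: int = 200
    n_perm: int = 499
    var_threshold: float = 0.95
    responses: tuple[str, ...] = ("activity", "intensity")
    run_pooling_check: bool = True
    run_fosr: bool = True
    run_group_tests: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.generator is None and self.epoch_csv is None:
            self.generator = GeneratorConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "seed", "n_sim", "n_boot", "n_perm", "var_threshold",
            "run_pooling_check", "run_fosr", "run_group_tests", "alpha",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw["outdir"])
        if "epoch_csv" in raw:
            kwargs["epoch_csv"] = Path(raw["epoch_csv"])
        if "covariates_csv" in raw:
            kwargs["covariates_csv"] = Path(raw["covariates_csv"])
        if "generator" in raw:
            gen = dict(raw["generator"])
            gen.setdefault("seed", kwargs.get("seed", 0))
            if "n_per_group" in gen:
                gen["n_per_group"] = tuple(
                    (str(g), int(n)) for g, n in gen["n_per_group"].items()
                )
            if "anchor_date" in gen:
                gen["anchor_date"] = _dt.date.fromisoformat(str(gen["anchor_date"]))
            kwargs["generator"] = GeneratorConfig(**gen)
        return cls(**kwargs)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 for the stage-level generators."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _write(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, **_CSV_KW)


def _mean_test_rows(results, response, daytype, k_family, alpha):
    rows = []
    for r in results:
        adj = alpha / k_family
        rows.append(
            {
                "comparison": r.comparison,
                "response": response,
                "daytype": daytype,
                "covariate_setting": r.covariate_setting,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_sim": r.n_sim,
                "adjusted_alpha": adj,
                "decision": "reject" if r.p_value <= adj else "retain",
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full analysis; returns the key artifacts in memory too."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    grid = DEFAULT_GRID
    seeds = iter(_child_seeds(config.seed, 64))
    artifacts: dict[str, object] = {"outdir": outdir}

    # --- stage 1: ingest or generate -------------------------------------
    if config.epoch_csv is not None:
        log.info("reading epoch data from %s", config.epoch_csv)
        result = read_epoch_csv(config.epoch_csv)
        for line in result.log:
            log.warning(line)
        series = result.series
        covariates = read_covariates_csv(config.covariates_csv)
        truth = None
    else:
        log.info("generating synthetic cohort (seed=%d)", config.generator.seed)
        series, covariates, truth = generate_cohort(config.generator, grid)
        write_epoch_csv(series, outdir / "epoch.csv")
        write_covariates_csv(covariates, outdir / "covariates.csv")
    artifacts["truth"] = truth

    # --- stage 2: preprocessing ------------------------------------------
    by_cat: dict[str, list[EpochSeries]] = {}
    for s in series:
        by_cat.setdefault(s.cat_id, []).append(s)
    profiles: list[CatProfile] = []
    raw_means: dict[str, float] = {}
    for cat_id in sorted(by_cat):
        days = by_cat[cat_id]
        profiles.append(profile_from_series(days))
        raw_means[cat_id] = mean_preTransform_count(days)
    log.info("preprocessed %d subjects (%d subject-days)", len(profiles), len(series))

    groups = dict(zip(covariates["cat_id"], covariates["group"]))
    studies = dict(zip(covariates["cat_id"], covariates["study"]))
    _write(profiles_to_frame(profiles, grid), outdir / "profiles.csv")
    _write(cohort_summary(raw_means, {c: studies[c] for c in raw_means}),
           outdir / "cohort_summary.csv")

    prof_by_id = {p.cat_id: p for p in profiles}
    cov_indexed = covariates.set_index("cat_id", drop=False)

    def curve_matrix(cat_ids, response, daytype):
        rows = [
            prof_by_id[c].activity(daytype) if response == "activity"
            else prof_by_id[c].intensity(daytype)
            for c in cat_ids
        ]
        return np.asarray(rows)

    # --- stage 3: pooling check between DJD sub-studies -------------------
    test_rows: list[dict] = []
    if config.run_pooling_check:
        djd_ids = [c for c in sorted(prof_by_id) if groups[c] == DJD]
        study_labels = np.array([studies[c] for c in djd_ids])
        if len(np.unique(study_labels)) == 2:
            cov_djd = cov_indexed.loc[djd_ids].reset_index(drop=True)
            for daytype in (WEEKEND, WEEKDAY):
                for response in config.responses:
                    Y = curve_matrix(djd_ids, response, daytype)
                    results = [
                        lrt_mean_equality(
                            Y, study_labels, cov_djd, setting,
                            n_sim=config.n_sim, seed=next(seeds),
                            comparison="FMPI-vs-LowDose",
                        )
                        for setting in COVARIATE_SETTINGS
                    ]
                    test_rows += _mean_test_rows(
                        results, response, daytype, len(COVARIATE_SETTINGS), config.alpha
                    )
                dt = distribution_test(
                    curve_matrix([c for c, s in zip(djd_ids, study_labels) if s == "FMPI"],
                                 "activity", daytype),
                    curve_matrix([c for c, s in zip(djd_ids, study_labels) if s == "LowDose"],
                                 "activity", daytype),
                    var_threshold=config.var_threshold,
                    n_perm=config.n_perm, seed=next(seeds),
                    alpha=config.alpha, comparison="FMPI-vs-LowDose",
                )
                test_rows.append(
                    {
                        "comparison": "FMPI-vs-LowDose(distribution)",
                        "response": "activity",
                        "daytype": daytype,
                        "covariate_setting": "none",
                        "statistic": float(dt.statistics.max()),
                        "p_value": dt.overall_p,
                        "n_sim": config.n_perm,
                        "adjusted_alpha": dt.bonferroni_alpha,
                        "decision": dt.decision,
                    }
                )
            rejected = [
                r for r in test_rows
                if r["comparison"].startswith("FMPI") and r["decision"] == "reject"
            ]
            if rejected:
                log.warning(
                    "pooling check rejected in %d comparison(s); "
                    "pooling the DJD sub-studies anyway (recorded)", len(rejected)
                )
            pooling_df = pd.DataFrame(test_rows)
            _write(pooling_df, outdir / "pooling_check.csv")
            artifacts["pooling_check"] = pooling_df
        else:
            log.info("single DJD sub-study; pooling check skipped")

    # --- stage 4: pooled group profiles ----------------------------------
    gm = group_mean_profiles(profiles, groups)
    gm_rows = []
    for (g, daytype), curves in sorted(gm.items()):
        gm_rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "daytype": daytype,
                    "bin_index": np.arange(grid.n_bins),
                    "t_hours": grid.t,
                    "activity": curves["activity"],
                    "intensity": curves["intensity"],
                }
            )
        )
    gm_df = pd.concat(gm_rows, ignore_index=True)
    _write(gm_df, outdir / "group_profiles.csv")
    artifacts["group_profiles"] = gm

    # --- stage 5: FPCA per group x day type on intensity ------------------
    fpca_frames, var_frames, score_frames, mode_frames, corr_rows = [], [], [], [], []
    for g in sorted(set(groups.values())):
        ids = [c for c in sorted(prof_by_id) if groups[c] == g]
        fits = {}
        for daytype in (WEEKEND, WEEKDAY):
            fit = fit_fpca(curve_matrix(ids, "intensity", daytype), k_select=3, grid=grid)
            fits[daytype] = fit
            frames = fit.to_frames()
            fpca_frames.append(frames["eigenfunctions"].assign(group=g, daytype=daytype))
            var_frames.append(frames["variance"].assign(group=g, daytype=daytype))
            for k in range(fit.n_components):
                score_frames.append(
                    pd.DataFrame(
                        {
                            "cat_id": ids,
                            "component": k + 1,
                            "score": fit.scores[:, k],
                            "daytype": daytype,
                            "group": g,
                        }
                    )
                )
                plus, minus = modes_of_variation(fit, k + 1)
                mode_frames.append(
                    pd.DataFrame(
                        {
                            "group": g,
                            "daytype": daytype,
                            "component": k + 1,
                            "bin_index": np.arange(grid.n_bins),
                            "t_hours": grid.t,
                            "mean": fit.mu,
                            "plus": plus,
                            "minus": minus,
                        }
                    )
                )
        for k in range(1, min(fits[WEEKEND].n_components, fits[WEEKDAY].n_components) + 1):
            corr_rows.append(
                {
                    "group": g,
                    "component": k,
                    "weekend_weekday_score_correlation": score_correlation(
                        fits[WEEKEND].scores, fits[WEEKDAY].scores, k
                    ),
                }
            )
        artifacts[f"fpca_{g}"] = fits
    _write(pd.concat(fpca_frames, ignore_index=True), outdir / "fpca_eigenfunctions.csv")
    _write(pd.concat(var_frames, ignore_index=True), outdir / "fpca_variance.csv")
    _write(pd.concat(score_frames, ignore_index=True), outdir / "fpca_scores.csv")
    _write(pd.concat(mode_frames, ignore_index=True), outdir / "fpca_modes.csv")
    corr_df = pd.DataFrame(corr_rows)
    _write(corr_df, outdir / "fpca_score_correlations.csv")
    artifacts["score_correlations"] = corr_df

    # --- stage 6: function-on-scalar regressions --------------------------
    if config.run_fosr:
        coef_frames = []
        region_rows = []
        meta = {}
        models = {
            "model1_normal": (NORMAL, ("age", "bcs", "age:bcs")),
            "model2_djd": (DJD, ("age", "bcs", "age:bcs", "tdjd", "tpain")),
        }
        for model_name, (g, terms) in models.items():
            ids = [c for c in sorted(prof_by_id) if groups[c] == g]
            cov_g = cov_indexed.loc[ids].reset_index(drop=True)
            design, scaling = standardize_covariates(cov_g, terms)
            for daytype in (WEEKEND, WEEKDAY):
                for response in config.responses:
                    spec = ModelSpec(response=response, daytype=daytype, terms=terms)
                    Y = curve_matrix(ids, response, daytype)
                    fit = fit_fosr(Y, design, spec, scaling=scaling, grid=grid)
                    fit = bootstrap_ci(
                        fit, Y, design, n_boot=config.n_boot, seed=next(seeds)
                    )
                    coef_frames.append(
                        fit.to_frame().assign(
                            model=model_name, response=response, daytype=daytype
                        )
                    )
                    for term in fit.terms:
                        for lo, hi in significance_regions(fit, term):
                            region_rows.append(
                                {
                                    "model": model_name,
                                    "response": response,
                                    "daytype": daytype,
                                    "term": term,
                                    "start_hour": lo,
                                    "end_hour": hi,
                                }
                            )
                    meta[f"{model_name}:{response}:{daytype}"] = {
                        "terms": list(fit.terms),
                        "lambda_smooth": [float(l) for l in fit.lambda_smooth],
                        "sigma2": fit.sigma2,
                        "edf": fit.edf,
                        "n_boot": fit.n_boot,
                        "n_subjects": len(ids),
                    }
                    artifacts[f"fosr_{model_name}_{response}_{daytype}"] = fit
        _write(pd.concat(coef_frames, ignore_index=True), outdir / "fosr_coefficients.csv")
        _write(
            pd.DataFrame(
                region_rows,
                columns=["model", "response", "daytype", "term", "start_hour", "end_hour"],
            ),
            outdir / "fosr_significance_regions.csv",
        )
        with open(outdir / "fosr_meta.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    # --- stages 7-8: group comparisons ------------------------------------
    if config.run_group_tests:
        normal_ids = [c for c in sorted(prof_by_id) if groups[c] == NORMAL]
        djd_ids = [c for c in sorted(prof_by_id) if groups[c] == DJD]
        both_ids = normal_ids + djd_ids
        glabels = np.array([groups[c] for c in both_ids])
        cov_both = cov_indexed.loc[both_ids].reset_index(drop=True)

        nd_rows = []
        for daytype in (WEEKEND, WEEKDAY):
            for response in config.responses:
                Y = curve_matrix(both_ids, response, daytype)
                results = [
                    lrt_mean_equality(
                        Y, glabels, cov_both, setting,
                        n_sim=config.n_sim, seed=next(seeds),
                        comparison="Normal-vs-DJD",
                    )
                    for setting in COVARIATE_SETTINGS
                ]
                nd_rows += _mean_test_rows(
                    results, response, daytype, len(COVARIATE_SETTINGS), config.alpha
                )
        nd_df = pd.DataFrame(nd_rows)
        _write(nd_df, outdir / "lrt_normal_vs_djd.csv")
        # wide summary layout: 4 profile rows x 4 covariate-setting columns
        lrt_wide = nd_df.pivot_table(
            index=["daytype", "response"], columns="covariate_setting",
            values="p_value", sort=True,
        ).reset_index()[["daytype", "response"] + list(COVARIATE_SETTINGS)]
        _write(lrt_wide, outdir / "lrt_normal_vs_djd_wide.csv")
        artifacts["lrt_normal_vs_djd"] = nd_df
        artifacts["lrt_wide"] = lrt_wide

        paired_rows = []
        for g, ids in ((NORMAL, normal_ids), (DJD, djd_ids)):
            for response in config.responses:
                r = lrt_paired_daytype(
                    curve_matrix(ids, response, WEEKDAY),
                    curve_matrix(ids, response, WEEKEND),
                    n_sim=config.n_sim, seed=next(seeds),
                    comparison=f"{g}:weekend-vs-weekday",
                )
                paired_rows += _mean_test_rows(
                    [r], response, "paired", len(config.responses), config.alpha
                )
        paired_df = pd.DataFrame(paired_rows)
        _write(paired_df, outdir / "lrt_weekend_vs_weekday.csv")
        artifacts["lrt_paired"] = paired_df

        dist_rows = []
        for daytype in (WEEKEND, WEEKDAY):
            for response in config.responses:
                dt = distribution_test(
                    curve_matrix(normal_ids, response, daytype),
                    curve_matrix(djd_ids, response, daytype),
                    var_threshold=config.var_threshold,
                    n_perm=config.n_perm, seed=next(seeds),
                    alpha=config.alpha, comparison="Normal-vs-DJD",
                )
                dist_rows.append(
                    {
                        "comparison": "Normal-vs-DJD",
                        "response": response,
                        "daytype": daytype,
                        "n_components": dt.n_components,
                        "min_component_p": float(dt.p_values.min()),
                        "overall_p": dt.overall_p,
                        "bonferroni_alpha": dt.bonferroni_alpha,
                        "decision": dt.decision,
                    }
                )
        dist_df = pd.DataFrame(dist_rows)
        _write(dist_df, outdir / "distribution_tests.csv")
        artifacts["distribution_tests"] = dist_df

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "catfda",
        "version": __version__,
        "seed": config.seed,
        "n_sim": config.n_sim,
        "n_boot": config.n_boot,
        "n_perm": config.n_perm,
        "var_threshold": config.var_threshold,
        "alpha": config.alpha,
        "n_subjects": len(profiles),
        "n_subject_days": len(series),
        "generator": None
        if config.generator is None
        else {
            k: (v.isoformat() if isinstance(v, _dt.date) else v)
            for k, v in dataclasses.asdict(config.generator).items()
            if k not in ("beta_spec", "peak_params")
        },
        "decisions": DECISIONS,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    artifacts["manifest"] = manifest
    log.info("pipeline complete: artifacts in %s", outdir)
    return artifacts


def make_report(outdir: Path | str) -> list[Path]:
    """Render summary plots and tables from a completed result bundle.

    Regeneration from the same bundle is deterministic (same figures from the
    same CSVs).  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    required = ["group_profiles.csv", "fpca_modes.csv", "manifest.json"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete result bundle; missing: {missing}")
    written: list[Path] = []

    gm = pd.read_csv(outdir / "group_profiles.csv")
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for ax, response in zip(axes, ("activity", "intensity")):
        for (g, daytype), sub in gm.groupby(["group", "daytype"]):
            ax.plot(sub["t_hours"], sub[response], label=f"{g} {daytype}")
        if response == "intensity":
            ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("hour of day")
        ax.set_ylabel(f"mean {response} (log scale)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "report_group_profiles.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    modes = pd.read_csv(outdir / "fpca_modes.csv")
    for g, sub_g in modes.groupby("group"):
        comps = sorted(sub_g["component"].unique())
        fig, axes = plt.subplots(
            2, len(comps), figsize=(3.2 * len(comps), 5.5), sharex=True, squeeze=False
        )
        for row, daytype in enumerate(("weekend", "weekday")):
            for col, k in enumerate(comps):
                ax = axes[row][col]
                sub = sub_g[(sub_g["daytype"] == daytype) & (sub_g["component"] == k)]
                ax.plot(sub["t_hours"], sub["mean"], "k-", lw=1)
                ax.plot(sub["t_hours"], sub["plus"], "r+", ms=2)
                ax.plot(sub["t_hours"], sub["minus"], "b_", ms=2)
                ax.set_title(f"{daytype} FPC{k}", fontsize=8)
        fig.tight_layout()
        p = outdir / f"report_fpca_modes_{g}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    coef_path = outdir / "fosr_coefficients.csv"
    if coef_path.exists():
        coef = pd.read_csv(coef_path)
        for model, sub_m in coef.groupby("model"):
            sub_m = sub_m[sub_m["response"] == "activity"]
            terms = [t for t in sub_m["term"].unique() if t != "intercept"]
            fig, axes = plt.subplots(
                2, len(terms), figsize=(3.0 * len(terms), 5.5), sharex=True, squeeze=False
            )
            for row, daytype in enumerate(("weekend", "weekday")):
                for col, term in enumerate(terms):
                    ax = axes[row][col]
                    sub = sub_m[(sub_m["daytype"] == daytype) & (sub_m["term"] == term)]
                    ax.plot(sub["t_hours"], sub["beta"], "k-", lw=1)
                    if sub["ci_lower"].notna().any():
                        ax.plot(sub["t_hours"], sub["ci_lower"], "b-", lw=0.7)
                        ax.plot(sub["t_hours"], sub["ci_upper"], "b-", lw=0.7)
                    ax.axhline(0.0, color="r", lw=0.7)
                    ax.set_title(f"{daytype} {term}", fontsize=8)
            fig.tight_layout()
            p = outdir / f"report_fosr_{model}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

    summary_frames = []
    for name in ("lrt_normal_vs_djd_wide.csv", "lrt_weekend_vs_weekday.csv", "distribution_tests.csv"):
        path = outdir / name
        if path.exists():
            summary_frames.append(pd.read_csv(path).assign(source=name))
    if summary_frames:
        p = outdir / "report_test_summary.csv"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            pd.concat(summary_frames, ignore_index=True).to_csv(fh, **_CSV_KW)
        written.append(p)
    return written
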