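"""End-to-end orchestration with run manifests and seeded reproducibility.

A run executes a fixed stage order —

    ingest -> screen -> classify -> sensitivity -> fit_mlm -> trends -> report

— writing each stage's artifacts as CSV/JSON into the run directory and
appending exactly one manifest entry per stage with its input/output
record counts. Identical config + seed produces byte-identical artifacts.
One master seed fans out to per-stage seeds through numpy's SeedSequence
spawning, so stages are individually reproducible without seed collisions.

Ingest either generates synthetic data (the default) or loads user CSVs.
Floating-point artifacts are serialized at full precision; display
rounding happens only in the rendered report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datamodel, lmm, screening, simulate, trends, typology

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_report"]

STAGES = ("ingest", "screen", "classify", "sensitivity", "fit_mlm", "trends", "report")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    # ingest: synthetic by default, or paths to user CSVs
    indicator_csv: str | None = None
    indicator_dialect: str = "long"
    flp_csv: str | None = None
    indicator_sim: dict = field(default_factory=dict)
    flp_sim: dict = field(default_factory=dict)
    # typology
    lambda_grid: list[float] = field(
        default_factory=lambda: [round(l, 2) for l in np.arange(0.0, 0.5001, 0.05)]
    )
    reference_lambda: float = 0.20
    k: int = 2
    restarts: int = 50
    standardize: bool = True
    # screening
    min_obs: int = 30
    min_countries: int = 3
    min_years: int = 3
    # modelling
    alpha: float = 0.05
    df_method: str = "normal"

    def validate(self) -> "RunConfig":
        if not self.lambda_grid:
            raise PipelineError("lambda_grid is empty")
        if float(self.reference_lambda) not in [float(l) for l in self.lambda_grid]:
            raise PipelineError("reference_lambda must be on lambda_grid")
        if (self.indicator_csv is None) != (self.flp_csv is None):
            raise PipelineError("provide both indicator_csv and flp_csv, or neither")
        screening.ExclusionRule(self.min_obs, self.min_countries, self.min_years)
        lmm.LMMSpec(df_method=self.df_method)
        if not (0 < self.alpha < 1):
            raise PipelineError("alpha must lie in (0, 1)")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    master_seed: int
    stage_seeds: dict[str, int]
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def append(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def _stage_seeds(master: int) -> dict[str, int]:
    spawned = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        stage: int(ss.generate_state(1)[0] % 2**31)
        for stage, ss in zip(STAGES, spawned)
    }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float) + "\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk)."""
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        master_seed=config.seed,
        stage_seeds=seeds,
    )

    try:
        _run_stages(config, outdir, seeds, manifest)
    finally:
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _run_stages(
    config: RunConfig, outdir: Path, seeds: dict[str, int], manifest: RunManifest
) -> None:
    # ---- ingest -----------------------------------------------------------
    if config.indicator_csv is None:
        icfg = simulate.IndicatorSimConfig(
            **{"seed": seeds["ingest"], **config.indicator_sim}
        )
        panel, labels_true = simulate.generate_indicator_panel(icfg)
        fcfg = simulate.FLPSimConfig(
            **{"seed": seeds["ingest"] + 1, **config.flp_sim}
        )
        records, truth = simulate.generate_flp_panel(fcfg, labels_true)
        labels_true.rename("development").to_csv(outdir / "true_labels.csv")
        _write_json(
            {
                "sigma_u": truth.sigma_u,
                "sigma_e": truth.sigma_e,
                "n_clipped": truth.n_clipped,
                "effects": {k: list(v) for k, v in truth.effects.items()},
            },
            outdir / "simulation_truth.json",
        )
    else:
        table = datamodel.HarmonizationTable.default()
        panel = datamodel.read_indicator_panel(
            config.indicator_csv, config.indicator_dialect
        )
        panel, unmatched_p = datamodel.harmonize_frame(panel, table)
        records = datamodel.read_flp_records(config.flp_csv)
        records, unmatched_f = datamodel.harmonize_frame(records, table)
        if unmatched_p or unmatched_f:
            manifest.warnings.append(
                f"unmatched country names: panel={unmatched_p}, flp={unmatched_f}"
            )
    unified = datamodel.build_unified_dataset(panel, records)
    panel, records = unified.panel, unified.records
    datamodel.write_indicator_panel(panel, outdir / "indicator_panel.csv")
    datamodel.write_flp_records(records, outdir / "flp_records.csv")
    manifest.append(
        "ingest",
        n_panel_rows=len(panel),
        n_flp_records=len(records),
        n_common_countries=unified.n_common,
    )

    # ---- screen -----------------------------------------------------------
    records, cat_report = screening.categorize(records)
    miss = screening.missingness_report(records)
    rule = screening.ExclusionRule(
        config.min_obs, config.min_countries, config.min_years
    )
    screened, excl = screening.apply_exclusions(records, rule)
    datamodel.write_flp_records(screened, outdir / "screened_records.csv")
    _write_json(miss.to_dict(), outdir / "missingness.json")
    _write_json(
        {
            "rule": dataclasses.asdict(rule),
            "excluded_groups": excl.excluded_groups,
            "n_input": excl.n_input,
            "n_retained": excl.n_retained,
            "n_group_dropped": excl.n_group_dropped,
            "n_listwise_dropped": excl.n_listwise_dropped,
            "unmapped_commodities": cat_report.unmapped_commodities,
            "unmapped_activities": cat_report.unmapped_activities,
        },
        outdir / "exclusions.json",
    )
    manifest.append(
        "screen",
        n_input=excl.n_input,
        n_retained=excl.n_retained,
        n_group_dropped=excl.n_group_dropped,
        n_listwise_dropped=excl.n_listwise_dropped,
    )

    # ---- classify ---------------------------------------------------------
    profiles, dropped = typology.country_profiles(panel, config.reference_lambda)
    result = typology.kmeans_fit(
        profiles,
        config.k,
        lam=config.reference_lambda,
        restarts=config.restarts,
        seed=seeds["classify"],
        standardize=config.standardize,
        dropped=dropped,
    )
    result.labels.rename("label").to_csv(outdir / "labels.csv")
    elbow = typology.elbow_curve(
        profiles,
        restarts=config.restarts,
        seed=seeds["classify"],
        standardize=config.standardize,
    )
    _write_json(
        {
            "lambda": result.lam,
            "k": result.k,
            "silhouette": result.silhouette,
            "wcss": result.wcss,
            "sizes": result.sizes,
            "centroids": result.centroids.to_dict(orient="index"),
            "centroids_standardized": result.centroids_std.to_dict(orient="index"),
            "dropped_countries": result.dropped_countries,
            "elbow": elbow.to_dict(orient="list"),
        },
        outdir / "typology_metrics.json",
    )
    manifest.append(
        "classify",
        n_countries=len(result.labels),
        n_dropped=len(dropped),
        n_developed=result.n_developed,
        n_developing=result.n_developing,
    )

    # ---- sensitivity ------------------------------------------------------
    grid = typology.sensitivity_analysis(
        panel,
        lam_grid=config.lambda_grid,
        reference_lam=config.reference_lambda,
        k=config.k,
        restarts=config.restarts,
        seed=seeds["classify"],  # same clustering seed: rows differ only in lambda
        standardize=config.standardize,
    )
    grid.table.to_csv(outdir / "sensitivity.csv", index=False)
    typology.borderline_report(grid).to_csv(outdir / "borderline.csv", index=False)
    manifest.append(
        "sensitivity",
        n_lambdas=len(grid.table),
        n_changed_countries=len(grid.changed_countries),
        stability=grid.stability,
    )

    # ---- fit_mlm ----------------------------------------------------------
    spec = lmm.LMMSpec(df_method=config.df_method)
    development = result.labels
    n_rows = 0
    for axis, tag in (("commodity_group", "commodity"), ("activity_group", "activity")):
        fits, table = lmm.fit_all_strata(screened, development, by=axis, spec=spec)
        table.to_csv(outdir / f"lmm_{tag}.csv", index=False)
        lmm.hypothesis_report(fits, alpha=config.alpha).to_csv(
            outdir / f"hypotheses_{tag}.csv", index=False
        )
        n_rows += len(table)
    manifest.append("fit_mlm", n_strata_rows=n_rows)

    # ---- trends -----------------------------------------------------------
    borderline = tuple(grid.changed_countries)
    n_cells = 0
    for axis, tag in (("commodity_group", "commodity"), ("activity_group", "activity")):
        means = trends.group_means(screened, development, by=axis, borderline=borderline)
        means.to_csv(outdir / f"group_means_{tag}.csv", index=False)
        tt = trends.trend_table(screened, development, by=axis, borderline=borderline)
        tt.to_csv(outdir / f"trends_{tag}.csv", index=False)
        n_cells += len(means)
    trends.borderline_profiles(screened, list(borderline)).to_csv(
        outdir / "borderline_profiles.csv", index=False
    )
    manifest.append("trends", n_cells=n_cells, n_borderline=len(borderline))

    # ---- report -----------------------------------------------------------
    text = render_report(outdir)
    (outdir / "report.txt").write_text(text)
    manifest.append("report", n_chars=len(text))


def _section(title: str) -> str:
    return f"\n{title}\n{'-' * len(title)}\n"


def _maybe_table(outdir: Path, name: str, round_to: int = 4) -> str:
    path = outdir / name
    if not path.exists():
        return "not run\n"
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return "(empty)\n"
    if df.empty:
        return "(empty)\n"
    return df.round(round_to).to_string(index=False) + "\n"


def render_report(outdir) -> str:
    """Render the human-readable summary purely from saved artifacts.

    Never recomputes a statistic: every number comes from a CSV/JSON file
    written by an earlier stage, with rounding applied only for display.
    Regenerating the report from the same artifacts yields identical text.
    """
    outdir = Path(outdir)
    parts = ["Food-loss typology and modelling run\n"]

    metrics_path = outdir / "typology_metrics.json"
    parts.append(_section("Typology (reference configuration)"))
    if metrics_path.exists():
        m = json.loads(metrics_path.read_text())
        parts.append(
            f"lambda={m['lambda']} k={m['k']} silhouette={m['silhouette']:.4f} "
            f"wcss={m['wcss']:.2f} sizes={m['sizes']}\n"
        )
        cents = pd.DataFrame.from_dict(m["centroids"], orient="index")
        parts.append(cents.round(2).to_string() + "\n")
    else:
        parts.append("not run\n")

    parts.append(_section("Lambda sensitivity"))
    parts.append(_maybe_table(outdir, "sensitivity.csv"))
    parts.append(_section("Borderline countries"))
    parts.append(_maybe_table(outdir, "borderline.csv"))
    for tag in ("commodity", "activity"):
        parts.append(_section(f"Random-intercept models by {tag} group"))
        parts.append(_maybe_table(outdir, f"lmm_{tag}.csv"))
        parts.append(_section(f"Hypothesis decisions by {tag} group"))
        parts.append(_maybe_table(outdir, f"hypotheses_{tag}.csv"))
        parts.append(_section(f"Group means by {tag} group"))
        parts.append(_maybe_table(outdir, f"group_means_{tag}.csv"))
        parts.append(_section(f"Linear trends by {tag} group"))
        parts.append(_maybe_table(outdir, f"trends_{tag}.csv"))
    parts.append(_section("Borderline country profiles"))
    parts.append(_maybe_table(outdir, "borderline_profiles.csv"))
    return "".join(parts)
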