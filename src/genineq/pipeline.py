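"""End-to-end orchestration: filter -> scores -> heterogeneity -> between-area
comparisons -> correlations -> tertiles, with CSV outputs and seed provenance.

The report bundle mirrors the shape of a small-area gender-inequality
surveillance report: a descriptive table (per-indicator sex-specific
percentages, score summaries and heterogeneity p-values), a between-area
table, a score/overall-level correlation table, and per-indicator tertile
grids for the indicators passing the correlation gate.
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

from . import __version__
from .comparisons import (
    between_area_comparison,
    population_weighted_tertiles,
    score_level_correlations,
    select_correlated_indicators,
    tertile_score_summary,
)
from .heterogeneity import heterogeneity_all
from .indicators import (
    INDICATORS,
    ExclusionLog,
    filter_das,
    get_indicator,
    overall_level_table,
)
from .io import read_census_csv, write_census_csv, write_exclusion_log, write_table
from .scores import score_table, summarize_scores, sex_value_arrays
from .synthetic import GeneratorConfig, generate_census

logger = logging.getLogger("genineq")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "format_pvalue"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Input is either a census CSV path or a synthetic-generator config; the
    master seed drives the generator and spawns an independent substream for
    the Monte Carlo stage, so changing the replicate count does not perturb
    the generated data.
    """

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    replicates: int = 999
    seed: int = 0
    alpha: float = 0.05
    r_threshold: float = 0.4
    outdir: str = "genineq_out"

    def __post_init__(self) -> None:
        if self.replicates < 19:
            raise ValueError(f"replicates must be >= 19, got {self.replicates}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file (YAML syntax).

        Generator keys are nested under ``generator:`` or given flat with a
        ``generator_`` prefix; ``sex_rates`` entries map an indicator name
        to ``[p_female, p_male]``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", None)
        flat_gen = {k[len("generator_"):]: raw.pop(k)
                    for k in list(raw) if k.startswith("generator_")}
        if gen_raw is None and flat_gen:
            gen_raw = flat_gen
        generator = None
        if gen_raw is not None:
            from .synthetic import DEFAULT_SEX_RATES, SexRates

            rates = gen_raw.pop("sex_rates", None)
            if rates is not None:
                merged = dict(DEFAULT_SEX_RATES)
                merged.update({k: SexRates(*v) for k, v in rates.items()})
                gen_raw["sex_rates"] = merged
            if "population_range" in gen_raw:
                gen_raw["population_range"] = tuple(gen_raw["population_range"])
            if "area_type_shares" in gen_raw:
                gen_raw["area_type_shares"] = tuple(gen_raw["area_type_shares"])
            generator = GeneratorConfig(**gen_raw)
        return cls(generator=generator, **raw)


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    census: pd.DataFrame
    retained: pd.DataFrame
    exclusions: ExclusionLog
    scores: pd.DataFrame
    descriptive: pd.DataFrame
    heterogeneity: pd.DataFrame
    between_area: pd.DataFrame
    pairwise: pd.DataFrame
    correlations: pd.DataFrame
    tertiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    tertile_boundaries: dict[str, tuple[float, float]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def format_pvalue(p: float) -> str:
    """Render a p-value the way surveillance tables print them."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "< 0.001"
    if p < 0.01:
        return "< 0.01"
    return f"{p:.2f}"


def _descriptive_table(retained: pd.DataFrame, scores: pd.DataFrame,
                       het: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator sex-specific levels plus score summaries and het p-value.

    Proportion levels are on the percent scale; income stays in thousand CAD.
    """
    summary = summarize_scores(scores)
    rows = []
    for ind in INDICATORS:
        f, m = sex_value_arrays(retained, ind)
        scale = 1.0 if ind.kind == "mean_value" else 100.0
        f, m = f * scale, m * scale
        row = {"indicator": ind.name, "dimension": ind.dimension}
        for label, vals in (("female", f), ("male", m)):
            vals = vals[~np.isnan(vals)]
            row[f"{label}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{label}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            row[f"{label}_median"] = float(np.median(vals)) if len(vals) else np.nan
        srow = summary.loc[summary["indicator"] == ind.name]
        if len(srow):
            srow = srow.iloc[0]
            row.update(score_mean=srow["mean"], score_sd=srow["sd"],
                       score_median=srow["median"], score_q1=srow["q1"],
                       score_q3=srow["q3"], n_das=srow["n_das"])
        hrow = het.loc[het["indicator"] == ind.name] if len(het) else het
        row["heterogeneity_p"] = float(hrow["p_value"].iloc[0]) if len(hrow) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _between_area_tables(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    area_rows, pair_rows = [], []
    for res in results:
        row = {"indicator": res.indicator}
        for _, g in res.group_stats.iterrows():
            row[f"{g['group']}_mean"] = g["mean"]
            row[f"{g['group']}_sd"] = g["sd"]
            row[f"{g['group']}_n"] = g["n"]
        row["kw_h"] = res.h_statistic
        row["kw_p"] = res.p_value
        area_rows.append(row)
        for _, pr in res.pairwise.iterrows():
            pair_rows.append({"indicator": res.indicator, **pr.to_dict()})
    pair_cols = ["indicator", "group_a", "group_b", "u_statistic", "p_raw",
                 "p_adjusted"]
    return (pd.DataFrame(area_rows),
            pd.DataFrame(pair_rows, columns=pair_cols))


def _correlation_table(retained: pd.DataFrame, correlations: dict[str, float]
                       ) -> pd.DataFrame:
    levels = overall_level_table(retained, INDICATORS)
    rows = []
    for ind in INDICATORS:
        lv = levels.loc[levels["indicator"] == ind.name, "level"].to_numpy(float)
        scale = 1.0 if ind.kind == "mean_value" else 100.0
        lv = lv * scale
        rows.append({
            "indicator": ind.name,
            "overall_mean": float(np.mean(lv)) if len(lv) else np.nan,
            "overall_sd": float(np.std(lv, ddof=1)) if len(lv) > 1 else np.nan,
            "overall_median": float(np.median(lv)) if len(lv) else np.nan,
            "spearman_r": correlations.get(ind.name, np.nan),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write every artifact to ``config.outdir``.

    Stages run in order (filter, scores, heterogeneity, between-area,
    correlations, tertiles); a stage failure aborts with the stage named and
    already-written outputs retained next to a FAILED marker.  Deterministic
    given the config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    gen_seed, het_seed = (int(s.generate_state(1)[0] % 2**31)
                          for s in master.spawn(2))
    stage = "input"
    try:
        if config.input_csv is not None:
            census = read_census_csv(config.input_csv)
        else:
            gen = config.generator or GeneratorConfig()
            gen = dataclasses.replace(gen, seed=gen_seed)
            census = generate_census(gen)
        write_census_csv(census, outdir / "census.csv")
        logger.info("input: %d DAs", len(census))

        stage = "filter"
        retained, log = filter_das(census)
        write_exclusion_log(log, outdir / "exclusions.csv")
        logger.info("filter: %d in, %d retained (%d missing, %d single-sex, "
                    "%d zero-labour flagged)", log.n_input, log.n_retained,
                    log.n_missing, log.n_single_sex, log.n_zero_labour)

        stage = "scores"
        scores = score_table(retained)
        write_table(scores, outdir / "scores.csv")

        stage = "heterogeneity"
        het = heterogeneity_all(retained, INDICATORS, config.replicates, het_seed)
        write_table(het, outdir / "heterogeneity.csv")

        stage = "descriptive"
        descriptive = _descriptive_table(retained, scores, het)
        write_table(descriptive, outdir / "descriptive.csv")
        rendered = descriptive.copy()
        rendered["heterogeneity_p"] = rendered["heterogeneity_p"].map(format_pvalue)
        for c in rendered.columns:
            if rendered[c].dtype.kind == "f":
                dp = 1 if ("female" in c or "male" in c or "overall" in c) else 2
                rendered[c] = rendered[c].round(dp)
        write_table(rendered, outdir / "descriptive_rendered.csv")

        stage = "between_area"
        results = between_area_comparison(scores, retained, INDICATORS,
                                          alpha=config.alpha)
        between_area, pairwise = _between_area_tables(results)
        write_table(between_area, outdir / "between_area.csv")
        write_table(pairwise, outdir / "pairwise.csv")

        stage = "correlations"
        corr = score_level_correlations(retained, scores, INDICATORS)
        corr_table = _correlation_table(retained, corr)
        write_table(corr_table, outdir / "correlations.csv")

        stage = "tertiles"
        selected = select_correlated_indicators(corr, config.r_threshold)
        tertiles: dict[str, pd.DataFrame] = {}
        boundaries: dict[str, tuple[float, float]] = {}
        for name in selected:
            assignment = population_weighted_tertiles(retained, get_indicator(name))
            grid, kw_p = tertile_score_summary(scores, assignment, retained)
            grid_rows = grid.reset_index()
            p_row = pd.DataFrame([{"tertile": "kw_p", **kw_p}])
            tert_table = pd.concat([grid_rows, p_row], ignore_index=True)
            write_table(tert_table, outdir / f"tertiles_{name}.csv")
            tertiles[name] = tert_table
            boundaries[name] = assignment.boundaries

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "generator_seed": gen_seed if config.input_csv is None else None,
            "heterogeneity_seed": het_seed,
            "replicates": config.replicates,
            "alpha": config.alpha,
            "r_threshold": config.r_threshold,
            "input_csv": config.input_csv,
            "generator": (dataclasses.asdict(
                dataclasses.replace(config.generator or GeneratorConfig(),
                                    seed=gen_seed))
                if config.input_csv is None else None),
            "n_input": log.n_input,
            "n_retained": log.n_retained,
            "selected_indicators": selected,
            "tertile_boundaries": {k: list(v) for k, v in boundaries.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return ReportBundle(
        census=census, retained=retained, exclusions=log, scores=scores,
        descriptive=descriptive, heterogeneity=het, between_area=between_area,
        pairwise=pairwise, correlations=corr_table, tertiles=tertiles,
        tertile_boundaries=boundaries, manifest=manifest,
    )
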