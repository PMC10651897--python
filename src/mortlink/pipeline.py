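"""Stage orchestration: generate -> link -> weight -> estimate -> report.

Every stage reads its inputs from and writes its outputs to a single output
directory as headered CSV, so any stage can be re-run in isolation from the
on-disk intermediates and reproduce its outputs byte-for-byte under the same
config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, default_config
from .errors import IntegrityError
from .linkage import abe_conservative_match, evaluate_linkage, match_women
from .mortality import (
    cohort_death_counts,
    extinct_cohort_rates,
    fit_gompertz_trunc,
    make_truncated_sample,
    ols_age_at_death,
)
from .synthetic import (
    build_census_file,
    build_death_register,
    build_reference_totals,
    generate_population,
    simulate_mortality,
)
from .weighting import (
    RULE_CELL,
    WeightingUniverse,
    assign_fallback_weights,
    compute_cell_weights,
    margins_from_totals,
    rake_trim_iterate,
    trim,
)

log = logging.getLogger("mortlink")

STAGES = ("generate", "link", "weight", "estimate", "report")

#: public linked-file column layouts (unmodelled fields emitted empty)
DMF_SCHEMA = ("histid", "byear", "bmonth", "dyear", "dmonth", "death_age", "weight")
NUMIDENT_SCHEMA = DMF_SCHEMA + (
    "sex", "race_first", "race_last", "bpl", "socstate", "age_first_application", "zip_residence",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _csv(outdir: Path, name: str) -> Path:
    return Path(outdir) / f"{name}.csv"


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(_csv(outdir, name), index=False)
    log.info("wrote %s (%d rows)", name, len(df))


def merge_on_histid(censoc_like: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Inner join of a linked mortality file with a census extract on histid.

    Duplicate histids on either side abort with the offending id; disjoint id
    sets produce an empty result with a logged warning.
    """
    for side, df in (("left", censoc_like), ("right", census)):
        dup = df["histid"][df["histid"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate histid on {side} side: {dup.iloc[0]!r}")
    merged = censoc_like.merge(census, on="histid", how="inner")
    if merged.empty:
        log.warning("merge_on_histid: no overlapping histids (%d vs %d rows)", len(censoc_like), len(census))
    return merged


# ---------------------------------------------------------------------------
# stages

def stage_generate(cfg: PipelineConfig, outdir: Path) -> dict:
    pop = generate_population(cfg.population)
    pop = simulate_mortality(pop, cfg.gompertz, cfg.effect, seed=cfg.seed)
    census = build_census_file(pop, noise=cfg.noise, seed=cfg.seed)
    _write(pop, outdir, "population")
    _write(census, outdir, "census")
    counts = {"population": len(pop), "census": len(census)}
    for name, spec in cfg.registers.items():
        register, truth = build_death_register(pop, spec, cfg.noise, seed=cfg.seed)
        suppress = cfg.weighting.cutoff_year if spec.kind == "dmf-like" else None
        totals = build_reference_totals(pop, years=spec.window, suppress_bstate_before=suppress)
        _write(register, outdir, f"register_{name}")
        _write(truth, outdir, f"truth_{name}")
        _write(totals, outdir, f"totals_{name}")
        counts[f"register_{name}"] = len(register)
    return counts


def stage_link(cfg: PipelineConfig, outdir: Path) -> dict:
    census = pd.read_csv(_csv(outdir, "census"), keep_default_na=False)
    counts = {}
    for name, spec in cfg.registers.items():
        register = pd.read_csv(_csv(outdir, f"register_{name}"), keep_default_na=False)
        truth = pd.read_csv(_csv(outdir, f"truth_{name}"))
        register = register[register["dyear"].between(*spec.window)].reset_index(drop=True)

        if spec.kind == "dmf-like":
            men = census[census["sex"] == "M"]
            result = abe_conservative_match(men, register, use_birth_state=False)
            eval_census = men
        else:
            men = census[census["sex"] == "M"]
            reg_m = register[register["sex"] == "M"]
            reg_f = register[register["sex"] == "F"]
            res_men = abe_conservative_match(men, reg_m, use_birth_state=True)
            res_women = match_women(census, reg_f, use_birth_state=True)
            pairs = pd.concat([res_men.pairs, res_women.pairs], ignore_index=True)
            exclusions = pd.concat([res_men.exclusions, res_women.exclusions], ignore_index=True)
            result = type(res_men)(
                pairs=pairs.sort_values("histid").reset_index(drop=True),
                exclusions=exclusions,
                n_census=len(census),
                n_register=len(register),
                counts={k: res_men.counts.get(k, 0) + res_women.counts.get(k, 0) for k in res_men.counts},
            )
            eval_census = census

        report = evaluate_linkage(result, truth, eval_census, register)
        linked = (
            result.pairs.merge(census, on="histid")
            .merge(
                register[[c for c in ("rec_id", "byear", "bmonth", "dyear", "dmonth", "death_age") ]],
                on="rec_id",
                suffixes=("", "_register"),
            )
        )
        linked = linked.rename(columns={"birth_state": "bstate"})
        _write(result.pairs, outdir, f"crosswalk_{name}")
        _write(result.exclusions, outdir, f"exclusions_{name}")
        _write(linked, outdir, f"linked_{name}")
        _write(report.representativeness, outdir, f"linkage_report_{name}")
        summary = pd.DataFrame([{**report.summary, "middle_initial_agreement": report.middle_initial_agreement}])
        _write(summary, outdir, f"linkage_summary_{name}")
        counts[f"matched_{name}"] = result.n_matched
    return counts


def stage_weight(cfg: PipelineConfig, outdir: Path) -> dict:
    counts = {}
    for name, spec in cfg.registers.items():
        linked = pd.read_csv(_csv(outdir, f"linked_{name}"), keep_default_na=False)
        totals = pd.read_csv(_csv(outdir, f"totals_{name}"), keep_default_na=False)
        if spec.kind == "dmf-like":
            # men-only file: reference targets restricted to male decedents
            totals = totals[totals["sex"] == "M"].reset_index(drop=True)
        universe = WeightingUniverse(window=spec.window, age_range=cfg.weighting.age_range)
        weighted, cells = compute_cell_weights(linked, totals, universe=universe)
        weighted = assign_fallback_weights(
            weighted, cells, universe, cutoff_year=cfg.weighting.cutoff_year
        )

        # rake + trim the directly weighted records; others are trimmed only
        direct = weighted["weight_rule"] == RULE_CELL
        ceiling = 5.0 * float(weighted.loc[direct, "weight"].mean()) if direct.any() else None
        diag_row = {}
        if direct.any():
            margin_start = max(spec.window[0], cfg.weighting.cutoff_year or spec.window[0])
            in_margin = (
                totals["dyear"].between(margin_start, spec.window[1])
                & totals["death_age"].between(*cfg.weighting.age_range)
                & ~totals["bstate"].isin(universe.foreign_codes)
                & (totals["bstate"] != "")
            )
            margins = margins_from_totals(totals[in_margin], tolerance=cfg.weighting.rake_tolerance)
            # records whose (possibly misstated) level is absent from a margin
            # cannot be calibrated; they keep their ratio weight, trimmed
            feasible = direct.copy()
            for m in margins:
                feasible &= weighted[m.dimension].isin({k for k, v in m.targets.items() if v > 0})
            sub = weighted.loc[feasible]
            w, diag = rake_trim_iterate(
                sub,
                margins,
                floor=cfg.weighting.trim_floor,
                ceiling=ceiling,
                max_rounds=cfg.weighting.max_rounds,
                max_iter=cfg.weighting.max_rake_iter,
            )
            weighted.loc[feasible, "weight"] = w
            diag_row = {
                "coverage_ratio": diag.coverage_ratio,
                "share_above_ceiling": diag.share_above_ceiling,
                "rounds": diag.rounds,
                "rake_iterations": diag.rake_iterations,
                "converged": diag.converged,
                **{f"max_rel_err_{k}": v for k, v in diag.max_margin_rel_error.items()},
            }
            rest = ~feasible
        else:
            rest = weighted.index == weighted.index  # everything
        if ceiling is not None:
            weighted.loc[rest, "weight"] = trim(
                weighted.loc[rest, "weight"], floor=cfg.weighting.trim_floor, ceiling=ceiling
            )
        diag_row.update(weighted["weight_rule"].value_counts().add_prefix("n_rule_").to_dict())

        _write(weighted, outdir, f"weighted_{name}")
        _write(cells, outdir, f"cells_{name}")
        _write(pd.DataFrame([diag_row]), outdir, f"weight_diagnostics_{name}")

        # public-schema file
        schema = NUMIDENT_SCHEMA if spec.kind == "numident-like" else DMF_SCHEMA
        pub = pd.DataFrame({col: "" for col in schema}, index=weighted.index)
        for col in ("histid", "byear", "bmonth", "dyear", "dmonth", "death_age", "weight"):
            pub[col] = weighted[col]
        if spec.kind == "numident-like":
            pub["sex"] = weighted["sex"]
            pub["race_first"] = weighted["race"]
            pub["race_last"] = weighted["race"]
            pub["bpl"] = weighted["bstate"]
        _write(pub, outdir, f"censoc_{name}")
        counts[f"weighted_{name}"] = len(weighted)
    return counts


def stage_estimate(cfg: PipelineConfig, outdir: Path) -> dict:
    est = cfg.estimation
    counts = {}
    for name, spec in cfg.registers.items():
        weighted = pd.read_csv(_csv(outdir, f"weighted_{name}"), keep_default_na=False)
        if spec.kind == "dmf-like":
            continue
        sample = make_truncated_sample(
            weighted,
            window=spec.window,
            covariates=est.covariates,
            min_age=est.min_age,
            max_age=est.max_age,
            jitter=est.jitter,
            weight_col="weight" if est.use_weights else None,
        )
        fit = fit_gompertz_trunc(sample)
        _write(fit.to_frame().assign(converged=fit.converged, loglik=fit.loglik, n=fit.n), outdir, f"fit_{name}")
        ols = ols_age_at_death(weighted, est.covariates)
        _write(ols, outdir, f"ols_{name}")
        counts[f"fitted_{name}"] = fit.n

    # extinct-cohort rates from the widest-window register against truth tail
    name, spec = max(cfg.registers.items(), key=lambda kv: kv[1].window[1] - kv[1].window[0])
    register = pd.read_csv(_csv(outdir, f"register_{name}"), keep_default_na=False)
    pop = pd.read_csv(_csv(outdir, "population"), keep_default_na=False)
    register = register[register["dyear"].between(*spec.window)]
    register["cohort"] = register["byear"]
    frames = []
    for cohort, grp in register.groupby("cohort"):
        tail_true = int(((pop["byear"] == cohort) & (pop["true_dyear"] > spec.window[1])).sum())
        rates = extinct_cohort_rates(
            grp.groupby("death_age").size(), tail_completion=spec.p_in * tail_true
        )
        rates.insert(0, "cohort", cohort)
        frames.append(rates)
    rates = pd.concat(frames, ignore_index=True)
    _write(rates, outdir, f"rates_{name}")
    plot = rates[rates["m"] > 0].assign(log_m=lambda d: np.log(d["m"]))
    _write(plot[["cohort", "age", "log_m"]], outdir, "plotdata_log_mortality")
    counts["rate_rows"] = len(rates)
    return counts


def stage_report(cfg: PipelineConfig, outdir: Path, manifest: RunManifest) -> dict:
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(Path(outdir) / "manifest.json")
    return {}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, stages=STAGES) -> RunManifest:
    """Execute the requested stages in order; abort on the failing stage's name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed, started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    runners = {
        "generate": lambda: stage_generate(cfg, outdir),
        "link": lambda: stage_link(cfg, outdir),
        "weight": lambda: stage_weight(cfg, outdir),
        "estimate": lambda: stage_estimate(cfg, outdir),
        "report": lambda: stage_report(cfg, outdir, manifest),
    }
    for stage in stages:
        if stage not in runners:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        t0 = time.time()
        try:
            manifest.counts.update(runners[stage]() or {})
        except Exception as exc:  # annotate with the failing stage, then re-raise
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)
    manifest.write(outdir / "manifest.json")
    return manifest


def make_demo_fixture(outdir: str | Path, seed: int = 20220401, n_per_cohort: int = 240) -> RunManifest:
    """Small end-to-end fixture (~5,000 persons) used by the test suite."""
    cfg = default_config(seed=seed, n_per_cohort=n_per_cohort)
    return run_pipeline(cfg, outdir)
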