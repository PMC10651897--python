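"""Pipeline configuration: one YAML document covering every stage.

All rates, seeds and thresholds live here; stages never invent defaults of
their own beyond what the dataclasses in :mod:`mortlink.synthetic` declare.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .gompertz import GompertzParams
from .synthetic import CovariateEffect, NoiseSpec, PopulationSpec, RegisterSpec


@dataclass
class WeightingConfig:
    #: first death year with birth state available in the reference totals
    cutoff_year: int | None = None
    age_range: tuple[int, int] = (65, 100)
    rake_tolerance: float = 1e-6
    max_rake_iter: int = 100
    max_rounds: int = 50
    trim_floor: float = 1.0


@dataclass
class EstimationConfig:
    covariates: tuple[str, ...] = ("education_years",)
    min_age: float = 65.0
    max_age: float | None = 100.0
    jitter: str = "midpoint"
    use_weights: bool = False
    extinct_cohort: int = 1910


@dataclass
class PipelineConfig:
    population: PopulationSpec = field(default_factory=PopulationSpec)
    gompertz: GompertzParams = field(default_factory=GompertzParams)
    effect: CovariateEffect = field(default_factory=CovariateEffect)
    registers: dict = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "population" in kw:
            pop = dict(kw["population"])
            for key in ("cohort_range",):
                if key in pop:
                    pop[key] = tuple(pop[key])
            if "cohort_sizes" in pop and isinstance(pop["cohort_sizes"], dict):
                pop["cohort_sizes"] = {int(k): int(v) for k, v in pop["cohort_sizes"].items()}
            if "education_dist" in pop:
                pop["education_dist"] = {int(k): float(v) for k, v in pop["education_dist"].items()}
            kw["population"] = PopulationSpec(**pop)
        if "gompertz" in kw:
            kw["gompertz"] = GompertzParams(**kw["gompertz"])
        if "effect" in kw:
            eff = kw["effect"]
            kw["effect"] = CovariateEffect(betas=eff.get("betas", eff) if isinstance(eff, dict) else eff)
        if "registers" in kw:
            kw["registers"] = {
                name: RegisterSpec(**{**spec, "window": tuple(spec["window"])})
                for name, spec in kw["registers"].items()
            }
        if "noise" in kw:
            noise = dict(kw["noise"])
            if "age_misstatement_dist" in noise:
                noise["age_misstatement_dist"] = {
                    int(k): float(v) for k, v in noise["age_misstatement_dist"].items()
                }
            kw["noise"] = NoiseSpec(**noise)
        if "weighting" in kw:
            w = dict(kw["weighting"])
            if "age_range" in w:
                w["age_range"] = tuple(w["age_range"])
            kw["weighting"] = WeightingConfig(**w)
        if "estimation" in kw:
            e = dict(kw["estimation"])
            if "covariates" in e:
                e["covariates"] = tuple(e["covariates"])
            kw["estimation"] = EstimationConfig(**e)
        return cls(**kw)


def _to_plain(obj):
    """Make an asdict() tree YAML-safe (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def default_config(seed: int = 0, n_per_cohort: int = 1000) -> PipelineConfig:
    """A ready-to-run configuration mirroring the two-register setup.

    The numident-like register covers 1988-2005 and carries sex, birthplace and
    father's surname; the DMF-like register covers 1975-2005 with neither sex
    nor birthplace.  Reference totals for the DMF lack birth state before 1979.
    """
    import numpy as np

    return PipelineConfig(
        population=PopulationSpec(cohort_sizes=n_per_cohort, seed=seed, p_marry_after_census=0.3),
        gompertz=GompertzParams(),
        effect=CovariateEffect(betas={"education_years": float(np.log(0.96))}),
        registers={
            "numident": RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=0.96, p_out=0.05),
            "dmf": RegisterSpec(kind="dmf-like", window=(1975, 2005), p_in=0.96, p_out=0.05),
        },
        noise=NoiseSpec(
            name_typo_rate=0.02,
            nickname_swap_rate=0.02,
            age_misstatement_dist={-2: 0.01, -1: 0.04, 0: 0.9, 1: 0.04, 2: 0.01},
            duplicate_key_rate=0.002,
            middle_initial_missing_rates={"census": 0.6, "numident-like": 0.2, "dmf-like": 0.5},
        ),
        weighting=WeightingConfig(cutoff_year=1979),
        estimation=EstimationConfig(),
        seed=seed,
    )
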