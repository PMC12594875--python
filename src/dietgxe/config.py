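"""Pipeline configuration: a single structured YAML file mirrored by
CLI flags.  All randomness flows from the one seed in the config."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULT_TRAIT_MODELS"]

# Per-trait generating models for the synthetic panel: cell means by
# (diet, age) in trait units, and variance components in trait units^2.
# Cell means follow the observed panel averages (dry weight in mg, HKDT
# in minutes, locomotor activity in total counts); variance components
# are sized so broad-sense heritabilities fall in the range reported
# for these traits in inbred fly panels (~0.1-0.5).
DEFAULT_TRAIT_MODELS = {
    "dry_weight_mg": {
        "cell_means": {
            ("control", 7): 0.182, ("control", 16): 0.183,
            ("restricted", 7): 0.168, ("restricted", 16): 0.171,
        },
        "var_components": {
            "line": 4.0e-4, "line:age": 1.0e-4, "line:diet": 1.0e-4,
            "line:age:diet": 5.0e-5, "rep": 5.0e-5, "e": 1.1e-3,
        },
    },
    "locomotor_activity": {
        "cell_means": {
            ("control", 7): 432.0, ("control", 16): 427.0,
            ("restricted", 7): 438.0, ("restricted", 16): 462.0,
        },
        "var_components": {
            "line": 1200.0, "line:age": 150.0, "line:diet": 150.0,
            "line:age:diet": 60.0, "rep": 100.0, "e": 2400.0,
        },
    },
    "hkdt_min": {
        "cell_means": {
            ("control", 7): 37.11, ("control", 16): 22.38,
            ("restricted", 7): 29.91, ("restricted", 16): 25.40,
        },
        "var_components": {
            "line": 5.0, "line:age": 1.5, "line:diet": 1.5,
            "line:age:diet": 0.8, "rep": 0.6, "e": 20.0,
        },
    },
}


@dataclass
class SimulationBlock:
    n_lines: int = 98
    n_variants: int = 5000
    n_reps: int = 3
    flies_per_rep: int = 4
    ages: tuple = (7, 16)
    n_survival_flies: int = 20000
    cox_beta_diet: float = 0.25859
    baseline_hazard: tuple = ("weibull", 3.0, 24.0)
    frailty_sd: float = 0.9
    maf_law: tuple = ("uniform", 0.05, 0.5)
    causal: tuple = ()   # ({trait, variant, additive, diet_interaction}, ...)
    trait_models: dict = field(default_factory=lambda: DEFAULT_TRAIT_MODELS)


@dataclass
class GwasBlock:
    trait: str = "dry_weight_mg"
    modes: tuple = ("difference",)
    conditions: tuple = ("control", "restricted")
    condition_col: str = "diet"
    maf_min: float = 0.05
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results/run"
    traits: tuple = ("dry_weight_mg", "locomotor_activity", "hkdt_min")
    balance: bool = True
    simulation: SimulationBlock | None = None
    inputs: dict | None = None       # phenotypes / genotypes / covariates paths
    gwas: GwasBlock | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation block or input paths must be given"
            )
        if self.inputs is not None:
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{key} input not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        gw = raw.pop("gwas", None)
        if sim is not None:
            if "trait_models" in sim:
                sim["trait_models"] = _parse_trait_models(sim["trait_models"])
            for tup in ("ages", "causal", "baseline_hazard", "maf_law"):
                if tup in sim and isinstance(sim[tup], list):
                    sim[tup] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in sim[tup]
                    )
            sim = SimulationBlock(**sim)
        if gw is not None:
            for tup in ("modes", "conditions"):
                if tup in gw and isinstance(gw[tup], list):
                    gw[tup] = tuple(gw[tup])
            gw = GwasBlock(**gw)
        for tup in ("traits",):
            if tup in raw and isinstance(raw[tup], list):
                raw[tup] = tuple(raw[tup])
        return cls(simulation=sim, gwas=gw, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(_canon(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _canon(obj):
    """Recursively convert to JSON-serializable form with string keys."""
    if isinstance(obj, dict):
        return {str(k): _canon(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)


def _parse_trait_models(raw: dict) -> dict:
    out = {}
    for trait, spec in raw.items():
        cm = spec.get("cell_means", {})
        parsed = {}
        for key, val in cm.items():
            if isinstance(key, str):
                diet, age = key.split(",")
                parsed[(diet.strip(), int(age))] = float(val)
            else:
                parsed[tuple(key)] = float(val)
        out[trait] = {
            "cell_means": parsed,
            "var_components": {k: float(v) for k, v in
                               spec.get("var_components", {}).items()},
        }
    return out
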