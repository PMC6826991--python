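"""Configuration objects for the synthetic phenomic experiment and the pipeline.

The simulation config is a *stated world*: its defaults encode the published
experimental design — two nucleoside analogs at five doses each
(gemcitabine 0/5/10/20/30 μg/mL, cytarabine 0/10/25/50/100 μg/mL), 768
replicate reference cultures, kinetic imaging on a 0–48 h grid every 2.5 h —
plus documented choices (noise level, reference dose response) where the
design leaves magnitudes unstated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

CPPS = ("K", "r", "L")

#: default dose series, μg/mL
DEFAULT_DOSES = {
    "gemcitabine": (0.0, 5.0, 10.0, 20.0, 30.0),
    "cytarabine": (0.0, 10.0, 25.0, 50.0, 100.0),
}

#: imaging grid, hours (every 2.5 h over 0–48 h)
DEFAULT_TIMEPOINTS = tuple(float(t) for t in np.arange(0.0, 48.0 + 1e-9, 2.5))

#: per-dose linear displacement of the *reference* strain's CPPs (units/μg/mL).
#: Growth inhibition raises L (slower half-saturation) and lowers K and r.
DEFAULT_REFERENCE_DOSE_RESPONSE = {
    "gemcitabine": {"K": -1.5, "r": -0.002, "L": 0.40},
    "cytarabine": {"K": -0.40, "r": -0.0005, "L": 0.10},
}


@dataclass(frozen=True)
class StrainEffects:
    """Planted per-strain perturbation.

    shift
        additive displacement of each CPP at *every* dose, drug-independent
        (the deletion's intrinsic growth phenotype).
    slopes
        drug -> CPP -> additive displacement per μg/mL, the planted
        drug–gene interaction; a positive L slope is an enhancer-like
        effect (drug slows the mutant more than the reference).
    """

    shift: Mapping[str, float] = field(default_factory=dict)
    slopes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def shift_of(self, cpp: str) -> float:
        return float(self.shift.get(cpp, 0.0))

    def slope_of(self, drug: str, cpp: str) -> float:
        return float(self.slopes.get(drug, {}).get(cpp, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_mutant_strains: int = 100
    n_reference_cultures: int = 768
    doses_by_drug: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DOSES)
    )
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    #: (K_true, r_true, l_true) of the untreated reference strain:
    #: intensity units, 1/h, hours.
    reference_params: tuple[float, float, float] = (200.0, 0.3, 10.0)
    #: additive i.i.d. Gaussian intensity noise, intensity units
    #: (~2.5% of carrying capacity).
    noise_sd: float = 5.0
    planted_effects: Mapping[str, StrainEffects] = field(default_factory=dict)
    #: probability that a culture fails to grow at a given (drug, dose);
    #: the default world is a healthy library — blank spots are opt-in
    no_growth_fraction: float = 0.0
    #: residual agar/background intensity emitted by no-growth cultures
    baseline: float = 2.0
    reference_dose_response: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            d: dict(v) for d, v in DEFAULT_REFERENCE_DOSE_RESPONSE.items()
        }
    )
    #: strains (by name) belonging to the knockdown (DAmP) stratum
    knockdown_strains: frozenset[str] = frozenset()
    ref_strain: str = "REF"

    def validate(self) -> list[str]:
        """Return a list of human-readable config errors (empty list = valid)."""
        errors: list[str] = []
        for drug, doses in self.doses_by_drug.items():
            doses = list(doses)
            if not doses or doses[0] != 0:
                errors.append(f"{drug}: dose list must start at 0 (got {doses})")
            if any(b <= a for a, b in zip(doses, doses[1:])):
                errors.append(f"{drug}: doses must be strictly increasing (got {doses})")
        if self.n_reference_cultures < 2:
            errors.append(
                "n_reference_cultures must be >= 2 so that SD(REF_INT) is defined"
            )
        if self.noise_sd < 0:
            errors.append("noise_sd must be non-negative")
        if not 0.0 <= self.no_growth_fraction <= 1.0:
            errors.append("no_growth_fraction must lie in [0, 1]")
        times = list(self.timepoints)
        if len(times) < 4:
            errors.append("need >= 4 timepoints for a 3-parameter logistic fit")
        if any(b <= a for a, b in zip(times, times[1:])):
            errors.append("timepoints must be strictly increasing")
        K, r, l = self.reference_params
        if K <= 0 or r <= 0:
            errors.append("reference K and r must be positive")
        return errors

    def require_valid(self) -> "SimulationConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))
        return self

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings: simulation, thresholds, stage toggles."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    z_threshold: float = 2.0
    alpha: float = 0.05
    gta_threshold: float = 2.0
    # REMc settings
    remc_k_max: int = 10
    remc_min_size: int = 8
    remc_max_depth: int = 4
    remc_n_init: int = 5
    # synthetic annotation / homology / pharmaco settings
    n_go_terms: int = 40
    go_term_size_range: tuple[int, int] = (3, 15)
    n_human_genes: int = 400
    homology_class_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    n_cell_lines: int = 200
    tissues: tuple[str, ...] = ("HaL", "lung", "breast")
    pharmaco_effect_size: float = 1.0

    def validate(self) -> list[str]:
        errors = self.simulation.validate()
        if not 0 < self.alpha < 1:
            errors.append("alpha must lie in (0, 1)")
        if self.z_threshold <= 0:
            errors.append("z_threshold must be positive")
        if self.remc_k_max < 1:
            errors.append("remc_k_max must be >= 1")
        if self.remc_min_size < 1:
            errors.append("remc_min_size must be >= 1")
        if self.remc_max_depth < 1:
            errors.append("remc_max_depth must be >= 1")
        lo, hi = self.go_term_size_range
        if lo > hi:
            errors.append("go_term_size_range inverted")
        if abs(sum(self.homology_class_mix) - 1.0) > 1e-9:
            errors.append("homology_class_mix must sum to 1")
        if self.n_cell_lines < 10:
            errors.append("n_cell_lines must be >= 10")
        return errors


def _simulation_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "planted_effects" in d:
        d["planted_effects"] = {
            strain: StrainEffects(
                shift=eff.get("shift", {}), slopes=eff.get("slopes", {})
            )
            for strain, eff in d["planted_effects"].items()
        }
    if "knockdown_strains" in d:
        d["knockdown_strains"] = frozenset(d["knockdown_strains"])
    if "reference_params" in d:
        d["reference_params"] = tuple(d["reference_params"])
    return SimulationConfig(**d)


def load_pipeline_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a flat YAML file (see README for keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _simulation_from_dict(raw.pop("simulation", {}))
    for key in ("go_term_size_range", "tissues", "homology_class_mix"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(simulation=sim, **raw)
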