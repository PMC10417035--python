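"""Synthetic per-nucleoid comet datasets with the study's statistical structure.

The generator emulates the hierarchical design of the four-strain MMS
genotoxicity study: independent experiments, gels within conditions, and at
least 50 nucleoids per gel, with right-skewed nucleoid tail-moment
distributions (gamma family) around condition means

    mean(strain, dose) = baseline(strain) + induced(strain, dose)
                         + experiment effect + gel effect.

Induced damage is linear in dose for the responsive strains and a plateau
for the double mutant (whose response is flat above the lowest dose,
consistent with cytotoxicity).  The ex vivo generator adds incision
increments to buffer-lane means, scaled by per-extract ground-truth activity
fractions, and perturbs extract lanes by their protein concentrations so the
analysis-side protein adjustment is exercised.

Setting ``shape = inf`` makes the nucleoid distribution degenerate at its
mean (the zero-noise limit used to validate estimators exactly).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneratorParams", "generate_condition", "generate_invivo_study", "generate_exvivo_study"]

_MEAN_FLOOR = 0.05  # random effects may not push a condition mean below this


def _default_baselines() -> dict[str, float]:
    return {"OK": 6.20, "mus201": 4.70, "mus308": 3.29, "mus201;mus308": 2.61}


def _default_slopes() -> dict[str, float]:
    return {"OK": 3.61, "mus201": 4.68, "mus308": 6.02}


def _default_plateau() -> dict[str, float]:
    return {"mus201;mus308": 12.0}


def _default_hedgehog() -> dict[str, float]:
    return {"mus201": 0.04, "mus308": 0.04, "mus201;mus308": 0.10}


def _default_spont_activity() -> dict[str, float]:
    return {"OK": 1.0, "mus201": 0.649, "mus308": 0.817, "mus201;mus308": 0.492}


def _default_induced_activity() -> dict[str, float]:
    return {"OK": 1.0, "mus201": 0.215, "mus308": 0.529, "mus201;mus308": 0.148}


def _default_protein() -> dict[str, float]:
    return {"OK": 2.49, "mus201": 2.83, "mus308": 2.32, "mus201;mus308": 2.55}


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic comet study.

    Baseline tail moments and dose slopes default to the four-strain study
    design (wild-type plus NER, pol-theta and double mutants); strains listed
    in ``plateau_induced`` instead of ``dose_slopes`` get a constant induced
    TM at every non-zero dose.  ``sd_experiment`` is the between-experiment
    random-effect SD (shared by all doses of a strain within one experiment,
    which is what makes paired cross-experiment tests appropriate);
    ``sd_gel`` the between-gel SD; ``shape`` the gamma shape controlling the
    right skew of nucleoid TMs.  Hedgehog (near-total-damage) comets appear
    in mutant strains with probability ``hedgehog_rate[strain] * dose``.
    """

    strains: tuple[str, ...] = ("OK", "mus201", "mus308", "mus201;mus308")
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    baseline_tm: Mapping[str, float] = field(default_factory=_default_baselines)
    dose_slopes: Mapping[str, float] = field(default_factory=_default_slopes)
    plateau_induced: Mapping[str, float] = field(default_factory=_default_plateau)
    n_experiments: int = 3
    n_gels: int = 2
    n_nucleoids: int = 50
    shape: float = 2.0
    sd_experiment: float = 0.78
    sd_gel: float = 0.30
    hedgehog_rate: Mapping[str, float] = field(default_factory=_default_hedgehog)
    # --- ex vivo design ---
    extracts: tuple[str, ...] = ("buffer", "OK", "mus201", "mus308", "mus201;mus308")
    er_extract: str = "OK"
    buffer_baseline: float = 6.20
    invivo_induced: float = 5.0
    incision_spontaneous: Mapping[str, float] = field(default_factory=_default_spont_activity)
    incision_induced: Mapping[str, float] = field(default_factory=_default_induced_activity)
    incision_scale_spontaneous: float = 4.0
    incision_scale_induced: float = 8.0
    protein_conc: Mapping[str, float] = field(default_factory=_default_protein)
    exvivo_treated_dose: float = 1.0

    def __post_init__(self) -> None:
        for name, m in (("baseline_tm", self.baseline_tm),):
            for k, v in m.items():
                if v <= 0:
                    raise ValueError(f"{name}[{k!r}] must be > 0, got {v!r}")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.sd_experiment < 0 or self.sd_gel < 0:
            raise ValueError("random-effect SDs must be >= 0")
        for name in ("n_experiments", "n_gels", "n_nucleoids"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for k, v in self.protein_conc.items():
            if v <= 0:
                raise ValueError(f"protein_conc[{k!r}] must be > 0, got {v!r}")

    def induced_mean(self, strain: str, dose: float) -> float:
        """Ground-truth induced TM for one strain at one dose."""
        if strain in self.dose_slopes:
            return self.dose_slopes[strain] * dose
        if strain in self.plateau_induced:
            return self.plateau_induced[strain] if dose > 0 else 0.0
        return 0.0

    def zero_noise(self) -> "GeneratorParams":
        """Copy with all randomness removed (degenerate nucleoid TMs)."""
        return dataclasses.replace(
            self,
            shape=math.inf,
            sd_experiment=0.0,
            sd_gel=0.0,
            hedgehog_rate={},
        )


def _draw_tms(rng: np.random.Generator, n: int, mean: float, shape: float) -> np.ndarray:
    mean = max(mean, _MEAN_FLOOR)
    if math.isinf(shape):
        return np.full(n, mean)
    return rng.gamma(shape, mean / shape, size=n)


def _backfill(
    rng: np.random.Generator, tms: np.ndarray, hedgehog: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose TMs into (% tail DNA, tail length) consistent with the TM formula.

    % tail DNA is drawn uniform in (5, 95) — (90, 99) for hedgehogs — and the
    tail length solved from TM, so the reconstruction TM = pct x length / 100
    is exact and the percentage can never leave [0, 100].
    """
    pct = np.where(
        hedgehog,
        rng.uniform(90.0, 99.0, size=tms.size),
        rng.uniform(5.0, 95.0, size=tms.size),
    )
    length = 100.0 * tms / pct
    return pct, length


def generate_condition(
    n: int,
    mean_tm: float,
    shape: float = 2.0,
    seed: int | np.random.Generator = 0,
    strain: str = "OK",
    dose: float = 0.0,
    extract: str = "none",
    gel_id: str = "g1",
    experiment_id: str = "e1",
) -> pd.DataFrame:
    """Generate ``n`` nucleoid records for one condition.

    TM ~ gamma(shape, scale = mean_tm / shape), so E[TM] = mean_tm and the
    distribution is right-skewed for small ``shape``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_tm <= 0:
        raise ValueError("mean_tm must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tms = _draw_tms(rng, n, mean_tm, shape)
    hedgehog = np.zeros(n, dtype=bool)
    pct, length = _backfill(rng, tms, hedgehog)
    return pd.DataFrame(
        {
            "strain": strain,
            "dose": dose,
            "extract": extract,
            "experiment_id": experiment_id,
            "gel_id": gel_id,
            "percent_tail_dna": pct,
            "tail_length": length,
            "tail_moment": tms,
            "hedgehog_flag": hedgehog,
        }
    )


def generate_invivo_study(
    params: GeneratorParams = GeneratorParams(), seed: int = 0
) -> pd.DataFrame:
    """Full in vivo dataset: strains x doses x gels x nucleoids x experiments.

    The experiment random effect is drawn once per (strain, experiment) and
    shared across that strain's doses, reflecting that all doses of one
    experiment come from the same larval batch.  Deterministic under a fixed
    seed and parameter set.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for strain in params.strains:
        for e in range(1, params.n_experiments + 1):
            exp_eff = rng.normal(0.0, params.sd_experiment) if params.sd_experiment else 0.0
            for dose in params.doses:
                cond_mean = (
                    params.baseline_tm[strain] + params.induced_mean(strain, dose) + exp_eff
                )
                p_hh = min(params.hedgehog_rate.get(strain, 0.0) * dose, 0.5)
                for g in range(1, params.n_gels + 1):
                    gel_eff = rng.normal(0.0, params.sd_gel) if params.sd_gel else 0.0
                    tms = _draw_tms(
                        rng, params.n_nucleoids, cond_mean + gel_eff, params.shape
                    )
                    hedgehog = rng.random(params.n_nucleoids) < p_hh
                    pct, length = _backfill(rng, tms, hedgehog)
                    frames.append(
                        pd.DataFrame(
                            {
                                "strain": strain,
                                "dose": dose,
                                "extract": "none",
                                "experiment_id": f"e{e}",
                                "gel_id": f"e{e}-{strain}-{dose}-g{g}",
                                "percent_tail_dna": pct,
                                "tail_length": length,
                                "tail_moment": tms,
                                "hedgehog_flag": hedgehog,
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True)


def generate_exvivo_study(
    params: GeneratorParams = GeneratorParams(), seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Ex vivo dataset plus the extract protein concentrations.

    Wild-type larvae are in vivo treated (``exvivo_treated_dose``) or not;
    their nucleoids are incubated with buffer or one of the strain extracts.
    On the protein-adjusted scale the cell means are::

        buffer, untreated : BC  = buffer_baseline
        buffer, treated   : TC  = BC + invivo_induced
        extract, untreated: BC + a_spont(extract) * incision_scale_spontaneous
        extract, treated  : TC + a_ind(extract)   * incision_scale_induced

    so the ground-truth relative activities are exactly the ``a`` fractions.
    Extract-lane raw means are multiplied by conc/reference so that the
    analysis-side protein adjustment has to undo a real imbalance.
    """
    rng = np.random.default_rng(seed)
    ref = float(np.mean([params.protein_conc[e] for e in params.extracts if e != "buffer"]))
    frames = []
    for e in range(1, params.n_experiments + 1):
        exp_eff = rng.normal(0.0, params.sd_experiment) if params.sd_experiment else 0.0
        for extract in params.extracts:
            for dose, treated in ((0.0, False), (params.exvivo_treated_dose, True)):
                mean = params.buffer_baseline + exp_eff
                if treated:
                    mean += params.invivo_induced
                if extract != "buffer":
                    if treated:
                        mean += (
                            params.incision_induced[extract]
                            * params.incision_scale_induced
                        )
                    else:
                        mean += (
                            params.incision_spontaneous[extract]
                            * params.incision_scale_spontaneous
                        )
                factor = (
                    1.0
                    if extract == "buffer"
                    else params.protein_conc[extract] / ref
                )
                for g in range(1, params.n_gels + 1):
                    gel_eff = rng.normal(0.0, params.sd_gel) if params.sd_gel else 0.0
                    raw_mean = (mean + gel_eff) * factor
                    tms = _draw_tms(rng, params.n_nucleoids, raw_mean, params.shape)
                    hedgehog = np.zeros(params.n_nucleoids, dtype=bool)
                    pct, length = _backfill(rng, tms, hedgehog)
                    frames.append(
                        pd.DataFrame(
                            {
                                "strain": params.er_extract,
                                "dose": dose,
                                "extract": extract,
                                "experiment_id": f"e{e}",
                                "gel_id": f"e{e}-{extract}-{dose}-g{g}",
                                "percent_tail_dna": pct,
                                "tail_length": length,
                                "tail_moment": tms,
                                "hedgehog_flag": hedgehog,
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True), dict(params.protein_conc)
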