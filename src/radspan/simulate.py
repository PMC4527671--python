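"""Synthetic data generators for the lifespan and qPCR analyses.

Lifespan cohorts are drawn from the Gompertz mortality law

    mu(x) = R0 * exp(alpha * x),    S(x) = exp(-(R0/alpha) * (exp(alpha*x) - 1)),

by inverse-CDF sampling, then discretised to the daily census grid by
rounding *up* to the next multiple of the census interval (a fly found dead
during day k is recorded at day k).  Default parameter scales follow wild-type
Drosophila imago demography: alpha ~ 0.075-0.099 /day, R0 ~ 1.6e-4-7.1e-4 /day,
cohorts of 150-170 flies in 3 biological replicates.

qPCR simulation plants a known truth: reference-stable genes with zero group
effect, unstable candidates with extra per-sample variability, and target
genes with a specified log2 fold change between groups.  Ct values follow

    Ct = baseline - c * ln(2)/ln(E) + technical noise,

where c is the true log2 concentration (group effect + biological noise) and
E the per-gene amplification efficiency, so with E = 2 one doubling of
template lowers Ct by exactly one cycle.

All generators derive independent substreams per cohort / gene from the
master seed, so adding a group never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .survival import LifespanRecord

__all__ = [
    "GompertzCohortSpec",
    "GroupDesign",
    "ExperimentDesign",
    "GeneSimSpec",
    "QpcrSimSpec",
    "gompertz_median",
    "sample_gompertz_ages",
    "simulate_gompertz_cohort",
    "simulate_experiment",
    "simulate_sm_ensemble",
    "simulate_qpcr",
    "absorbed_dose",
]


@dataclass(frozen=True)
class GompertzCohortSpec:
    """Generative parameters for one cohort of fully followed flies."""

    alpha: float                 # hazard slope, 1/day
    r0: float                    # baseline hazard, 1/day
    n: int                       # cohort size
    census_interval: float = 1.0  # days between censuses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.census_interval <= 0:
            raise ValueError(f"census_interval must be > 0, got {self.census_interval}")


def gompertz_median(alpha: float, r0: float) -> float:
    """Closed-form (continuous) median age: (1/alpha)*ln(1 - alpha*ln(0.5)/r0)."""
    return math.log1p(-alpha * math.log(0.5) / r0) / alpha


def sample_gompertz_ages(alpha: float, r0: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Continuous Gompertz death ages by inverse-CDF sampling."""
    u = rng.uniform(size=n)
    return np.log1p(-alpha * np.log(u) / r0) / alpha


def simulate_gompertz_cohort(
    spec: GompertzCohortSpec, sex: str = "m", dose_cgy: float = 0.0, replicate: str = "r1"
) -> list[LifespanRecord]:
    """Simulate one cohort; ages are census-discretised by ceiling."""
    rng = np.random.default_rng(spec.seed)
    x = sample_gompertz_ages(spec.alpha, spec.r0, spec.n, rng)
    ci = spec.census_interval
    ages = np.ceil(x / ci) * ci
    ages = np.maximum(ages, ci)  # a death in the first interval is recorded at 1 interval
    return [
        LifespanRecord(
            subject_id=f"{sex}-{dose_cgy:g}-{replicate}-{i}",
            sex=sex,
            dose_cgy=dose_cgy,
            replicate=replicate,
            age_days=float(a),
            event=True,
        )
        for i, a in enumerate(ages)
    ]


@dataclass(frozen=True)
class GroupDesign:
    """One experimental arm: label, metadata, and its per-replicate cohort spec."""

    label: str
    sex: str
    dose_cgy: float
    cohort: GompertzCohortSpec
    replicates: int = 3
    control: str | None = None   # label of this arm's control group; None if it is one

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass(frozen=True)
class ExperimentDesign:
    groups: tuple[GroupDesign, ...]
    dose_rate_mgy_h: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = {g.label for g in self.groups}
        if len(labels) != len(self.groups):
            raise ValueError("group labels must be unique")
        for g in self.groups:
            if g.control is not None and g.control not in labels:
                raise ValueError(f"dangling control label {g.control!r} for group {g.label!r}")

    def control_map(self) -> dict[str, str]:
        return {g.label: g.control for g in self.groups if g.control is not None}


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Simulate every (group, replicate) cohort into one lifespan table.

    Returns a DataFrame with columns subject_id, sex, dose_cgy, group,
    replicate, age_days, event.  Per-replicate seeds are substreams of the
    design seed keyed by (group index, replicate index).
    """
    rows = []
    for gi, g in enumerate(design.groups):
        for r in range(g.replicates):
            spec = replace(g.cohort, seed=_child_seed(design.seed, gi, r))
            recs = simulate_gompertz_cohort(spec, sex=g.sex, dose_cgy=g.dose_cgy,
                                            replicate=f"r{r + 1}")
            for rec in recs:
                rows.append({
                    "subject_id": f"{g.label}-{rec.subject_id}",
                    "sex": g.sex,
                    "dose_cgy": g.dose_cgy,
                    "group": g.label,
                    "replicate": rec.replicate,
                    "age_days": rec.age_days,
                    "event": True,
                })
    return pd.DataFrame(rows)


def simulate_sm_ensemble(
    gamma: float,
    beta: float,
    noise_sd: float,
    k: int,
    alpha_range: tuple[float, float] = (0.06, 0.11),
    seed: int = 0,
) -> np.ndarray:
    """(alpha, r0) pairs obeying the Strehler-Mildvan law ln R0 = gamma - beta*alpha.

    Alphas are evenly spaced over ``alpha_range``; Gaussian noise with SD
    ``noise_sd`` perturbs ln R0.  Returns an array of shape (k, 2).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lo, hi = alpha_range
    if lo <= 0 or hi <= lo:
        raise ValueError("alpha_range must be positive and increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    alphas = np.linspace(lo, hi, k)
    rng = np.random.default_rng(seed)
    ln_r0 = gamma - beta * alphas + rng.normal(0.0, noise_sd, size=k)
    return np.column_stack([alphas, np.exp(ln_r0)])


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

GeneRole = Literal["reference", "unstable", "target"]


@dataclass(frozen=True)
class GeneSimSpec:
    """Per-gene generative parameters."""

    role: GeneRole
    efficiency: float            # per-cycle amplification factor, in (1, 2.2]
    baseline_ct: float = 22.0    # Ct at unit (log2 = 0) concentration
    log2_fold_by_group: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(f"efficiency must be in (1, 2.2], got {self.efficiency}")


@dataclass(frozen=True)
class QpcrSimSpec:
    genes: Mapping[str, GeneSimSpec]
    groups: tuple[str, ...]
    bio_replicates: int = 3
    tech_replicates: int = 3
    sigma_bio: float = 0.25      # biological noise SD on the log2-concentration scale
    sigma_tech: float = 0.15     # technical noise SD, cycles
    sigma_unstable: float = 1.5  # extra per-sample instability SD for 'unstable' genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tech_replicates < 1:
            raise ValueError("technical replicates must be >= 1")
        for name, sd in [("sigma_bio", self.sigma_bio), ("sigma_tech", self.sigma_tech),
                         ("sigma_unstable", self.sigma_unstable)]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a long-format raw Ct table with technical replicates.

    Columns: gene, sample_id, group, bio_rep, tech_rep, ct, efficiency.
    Reference-role genes have zero group effect; target genes shift their
    log2 concentration by the planted per-group fold; unstable genes get an
    extra Normal(0, sigma_unstable) per biological sample.
    """
    rows = []
    for gi, (gene, gspec) in enumerate(sorted(spec.genes.items())):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(gi,)))
        slope = math.log(2.0) / math.log(gspec.efficiency)  # cycles per log2 unit
        for group in spec.groups:
            delta = gspec.log2_fold_by_group.get(group, 0.0) if gspec.role == "target" else 0.0
            for b in range(1, spec.bio_replicates + 1):
                c = delta + rng.normal(0.0, spec.sigma_bio) if spec.sigma_bio > 0 else delta
                if gspec.role == "unstable" and spec.sigma_unstable > 0:
                    c += rng.normal(0.0, spec.sigma_unstable)
                ct_mean = gspec.baseline_ct - c * slope
                for t in range(1, spec.tech_replicates + 1):
                    ct = ct_mean + (rng.normal(0.0, spec.sigma_tech) if spec.sigma_tech > 0 else 0.0)
                    rows.append({
                        "gene": gene,
                        "sample_id": f"{group}_b{b}",
                        "group": group,
                        "bio_rep": b,
                        "tech_rep": t,
                        "ct": ct,
                        "efficiency": gspec.efficiency,
                    })
    return pd.DataFrame(rows)


def absorbed_dose(rate_mgy_per_h: float, duration_min: float) -> float:
    """Absorbed dose in cGy from a dose rate (mGy/h) and exposure time (min)."""
    if rate_mgy_per_h < 0 or duration_min < 0:
        raise ValueError("rate and duration must be >= 0")
    return rate_mgy_per_h * duration_min / 60.0 / 10.0
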