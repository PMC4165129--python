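"""Seeded generators for synthetic ripening, qPCR and ethylene experiments.

The ripening generator draws latent event-time pairs from exactly the
generative law the model assumes (bivariate Gaussian fixed effects + plant
random effect + residual) and discretises them through the observation
schedule, so parameter-recovery and calibration studies run against a known
ground truth.  The qPCR and ethylene generators produce fixtures with the
statistical structure the corresponding analyses assume (exponential
amplification with a known base; steady-state cuvette concentration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ethylene import EthyleneMeasurement
from .likelihood import RipeningModelParams
from .qpcr import QpcrWell
from .stages import FruitStageSeries

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "default_design",
    "default_params",
    "simulate_ripening_experiment",
    "simulate_qpcr_dataset",
    "simulate_ethylene_trace",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a greenhouse ripening-timing experiment.

    ``plants_per_genotype`` is either a single count or a mapping from
    genotype to count (the real experiment had unequal group sizes).
    ``observation_days`` are the days from anthesis at which every fruit's
    colour stage is scored.
    """

    genotypes: tuple
    reference: str
    plants_per_genotype: object
    trusses_per_plant: int
    fruits_per_truss: int
    observation_days: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "observation_days", tuple(float(d) for d in self.observation_days))
        if len(self.genotypes) < 1:
            raise ValueError("need at least one genotype")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be unique")
        if self.reference not in self.genotypes:
            raise ValueError(f"reference {self.reference!r} not among genotypes")
        days = self.observation_days
        if any(d < 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("observation_days must be strictly increasing and nonnegative")
        if self.trusses_per_plant < 1 or self.fruits_per_truss < 1:
            raise ValueError("trusses_per_plant and fruits_per_truss must be >= 1")

    def n_plants(self, genotype: str) -> int:
        if isinstance(self.plants_per_genotype, dict):
            return int(self.plants_per_genotype[genotype])
        return int(self.plants_per_genotype)


@dataclass
class GroundTruth:
    """True parameters and latent event times behind a simulated experiment."""

    params: RipeningModelParams
    latent_times: pd.DataFrame  # plant_id, genotype, truss, fruit, Y1, Y2
    n_clamped: int = 0
    plant_effects: pd.DataFrame | None = None


def default_design() -> ExperimentDesign:
    """Twice-weekly scoring over four weeks from day 30, four genotypes.

    Mirrors the greenhouse layout the model was developed for: a wild type
    and three ripening mutants, 2-5 plants each, scored twice a week for
    four weeks starting just before the earliest ripening onset.
    """
    return ExperimentDesign(
        genotypes=("WT", "rin-2", "rin-3", "acs4-1"),
        reference="WT",
        plants_per_genotype={"WT": 5, "rin-2": 5, "rin-3": 2, "acs4-1": 5},
        trusses_per_plant=2,
        fruits_per_truss=3,
        observation_days=(30, 33, 37, 40, 44, 47, 51, 54, 58),
    )


def default_params() -> RipeningModelParams:
    """Plausible greenhouse-scale parameters for the default design.

    Wild type shows its first ripening sign around day 42 and is red around
    day 52; mutants are delayed in onset and/or phase length; later fruit
    positions on a truss ripen slightly later (linear, half a day per
    position); plant and residual variation of a few days squared.
    """
    return RipeningModelParams(
        mu=np.array([42.0, 52.0]),
        alpha={
            "WT": np.zeros(2),
            "rin-2": np.array([5.0, 6.0]),
            "rin-3": np.array([2.0, 4.0]),
            "acs4-1": np.array([4.0, 3.0]),
        },
        beta=None,
        gamma_linear=np.array([0.5, 0.5]),
        sigma0=np.array([[3.0, 1.0], [1.0, 3.0]]),
        sigma=np.array([[2.0, 0.5], [0.5, 2.0]]),
    )


def _stage_at(day: float, y1: float, y2: float) -> str:
    """Colour stage of a fruit at an observation day given its event times.

    The model concerns only the two transitions (into T at y1, into R at
    y2); the intermediate O and LR stages are assigned by splitting
    [y1, y2) into three equal sub-intervals.
    """
    if day < y1:
        return "MG"
    if day >= y2:
        return "R"
    t = (day - y1) / (y2 - y1)
    return "T" if t < 1 / 3 else "O" if t < 2 / 3 else "LR"


def simulate_ripening_experiment(
    design: ExperimentDesign,
    params: RipeningModelParams,
    seed: int,
) -> tuple[list[FruitStageSeries], GroundTruth]:
    """Simulate stage-observation series for a whole experiment.

    Latent times are ``Y = m + Z_p + U`` with ``Z_p ~ N2(0, sigma0)`` per
    plant and ``U ~ N2(0, sigma)`` per fruit, where ``m`` is the linear
    predictor of the fruit's genotype, truss and position.  A draw with
    ``Y2 < Y1`` (possible under the unconstrained bivariate Gaussian) has
    its residual redrawn once; if the order is still inverted, ``Y2`` is
    clamped to ``Y1`` and the clamp counted in the ground truth.
    """
    rng = np.random.default_rng(seed)
    sigma0 = params.sigma0
    sigma = params.sigma
    # draws through cholesky-like factors; eigh handles PSD boundary cases
    def _sampler(cov):
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        A = vecs * np.sqrt(vals)
        return lambda: A @ rng.standard_normal(2)

    draw_z = _sampler(sigma0)
    draw_u = _sampler(sigma)

    series: list[FruitStageSeries] = []
    latent_rows = []
    plant_rows = []
    n_clamped = 0
    for genotype in design.genotypes:
        for ip in range(design.n_plants(genotype)):
            plant_id = f"{genotype}-p{ip + 1}"
            z = draw_z()
            plant_rows.append({"plant_id": plant_id, "genotype": genotype, "z1": z[0], "z2": z[1]})
            for truss in range(1, design.trusses_per_plant + 1):
                for fruit in range(1, design.fruits_per_truss + 1):
                    m = params.mean_for(genotype, truss, fruit)
                    y = m + z + draw_u()
                    if y[1] < y[0]:
                        y = m + z + draw_u()
                        if y[1] < y[0]:
                            y[1] = y[0]
                            n_clamped += 1
                    obs = [(d, _stage_at(d, y[0], y[1])) for d in design.observation_days]
                    series.append(
                        FruitStageSeries(
                            plant_id=plant_id,
                            genotype=genotype,
                            truss=truss,
                            fruit=fruit,
                            observations=obs,
                        )
                    )
                    latent_rows.append(
                        {
                            "plant_id": plant_id,
                            "genotype": genotype,
                            "truss": truss,
                            "fruit": fruit,
                            "Y1": y[0],
                            "Y2": y[1],
                        }
                    )
    truth = GroundTruth(
        params=params,
        latent_times=pd.DataFrame(latent_rows),
        n_clamped=n_clamped,
        plant_effects=pd.DataFrame(plant_rows),
    )
    return series, truth


# -- qPCR ------------------------------------------------------------------

def simulate_qpcr_dataset(
    n_samples: int,
    genes: list[str],
    reference_genes: list[str],
    true_log2_expression,
    efficiency,
    noise_sd: float,
    seed: int,
    replicates: int = 2,
    n_cycles: int = 40,
    base_cq: float = 22.0,
    with_curves: bool = True,
    curve_noise_sd: float = 0.0,
) -> list[QpcrWell]:
    """Simulate qPCR wells with known expression and amplification base.

    ``true_log2_expression`` is an ``(n_samples, n_genes)`` matrix of log2
    relative template amounts; a gene's Cq decreases by ``ln 2 / ln E`` per
    log2 unit.  Reference genes are generated with constant true expression
    across samples (their first-row value), up to Cq noise.  Curves are
    logistic with exponential-phase base equal to the gene's efficiency,
    anchored so that the 10%-of-plateau crossing reproduces the well's Cq.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.asarray(true_log2_expression, dtype=float)
    if x.shape != (n_samples, len(genes)):
        raise ValueError(
            f"true_log2_expression must have shape ({n_samples}, {len(genes)}), got {x.shape}"
        )
    eff = np.broadcast_to(np.asarray(efficiency, dtype=float), (len(genes),)).copy()
    if np.any(eff <= 1.0):
        raise ValueError("efficiency must exceed 1 (no amplification otherwise)")
    if np.any(eff > 2.2):
        raise ValueError("efficiency must be <= 2.2 (one doubling per cycle at most, plus margin)")
    unknown_refs = set(reference_genes) - set(genes)
    if unknown_refs:
        raise ValueError(f"reference genes not among genes: {sorted(unknown_refs)}")

    rng = np.random.default_rng(seed)
    x = x.copy()
    for j, g in enumerate(genes):
        if g in reference_genes:
            x[:, j] = x[0, j]

    wells: list[QpcrWell] = []
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    for s in range(n_samples):
        for j, g in enumerate(genes):
            for rep in range(1, replicates + 1):
                cq = base_cq - x[s, j] * np.log(2.0) / np.log(eff[j])
                cq += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                curve = None
                if with_curves:
                    plateau = 1000.0
                    baseline = 50.0
                    # anchor the logistic so baseline-subtracted fluorescence
                    # crosses plateau/10 exactly at cq
                    mid = cq + np.log(9.0) / np.log(eff[j])
                    f = baseline + plateau / (1.0 + eff[j] ** (-(cycles - mid)))
                    if curve_noise_sd > 0:
                        f = f + rng.normal(0.0, curve_noise_sd * plateau, size=f.shape)
                    curve = np.column_stack([cycles, f])
                wells.append(
                    QpcrWell(
                        sample=f"s{s + 1}",
                        gene=g,
                        replicate=rep,
                        cq=float(cq),
                        curve=curve,
                    )
                )
    return wells


# -- ethylene --------------------------------------------------------------

def simulate_ethylene_trace(
    true_rate: float,
    weight: float,
    flow: float,
    background: float,
    noise_sd: float,
    duration: float,
    seed: int,
    dt_s: float = 5.0,
    stage: str = "T",
    genotype: str = "WT",
    plant_id: str = "p1",
) -> EthyleneMeasurement:
    """Simulate a steady-state cuvette concentration trace.

    At steady state the excess concentration over background is
    ``true_rate * weight / flow`` (nL/h/g * g / (L/h) = nL/L); Gaussian
    noise of ``noise_sd`` (same concentration units) is added per sample.
    ``duration`` is in minutes, sampled every ``dt_s`` seconds.
    """
    if flow <= 0:
        raise ValueError("flow must be positive")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration * 60.0 + dt_s / 2, dt_s)
    level = background + true_rate * weight / flow
    conc = np.full_like(t, level)
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=t.shape)
    return EthyleneMeasurement(
        trace=np.column_stack([t, conc]),
        background=background,
        flow=flow,
        fresh_weight=weight,
        stage=stage,
        genotype=genotype,
        plant_id=plant_id,
    )
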