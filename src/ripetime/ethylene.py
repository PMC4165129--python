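"""Ethylene emission rates from cuvette concentration traces.

A fruit sits in a flow-through cuvette; at steady state the excess ethylene
concentration over background, times the air flow, equals the fruit's total
emission, which is then normalised by fresh weight:

    rate [nL h^-1 g^-1] = (mean excess concentration [nL/L]) * flow [L/h] / weight [g]

The trace is summarised by the mean over its final stable five minutes.
Genotypes are compared within one ripening stage by one-way ANOVA with
Fisher's protected LSD on log-transformed rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qpcr import AnovaLsdResult, anova_lsd

__all__ = [
    "EthyleneMeasurement",
    "EmissionRate",
    "emission_rate",
    "compare_stage_emissions",
]

#: seconds of trace tail averaged when summarising a measurement
SUMMARY_WINDOW_S = 300.0


@dataclass
class EthyleneMeasurement:
    """One cuvette measurement of a single fruit.

    ``trace`` is an (n, 2) array of (time in seconds, ethylene concentration
    in nL/L); ``flow`` in L/h, ``fresh_weight`` in g, ``background`` the
    ambient ethylene concentration in the same units as the trace.
    """

    trace: np.ndarray
    background: float
    flow: float
    fresh_weight: float
    stage: str
    genotype: str
    plant_id: str

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 2 or self.trace.shape[1] != 2 or len(self.trace) == 0:
            raise ValueError("trace must be a nonempty (n, 2) array of (time_s, concentration)")
        if self.flow <= 0:
            raise ValueError(f"flow must be positive, got {self.flow}")
        if self.fresh_weight <= 0:
            raise ValueError(f"fresh_weight must be positive, got {self.fresh_weight}")


@dataclass
class EmissionRate:
    """Ethylene emission in nL per hour per gram fresh weight."""

    value: float
    stage: str
    genotype: str
    plant_id: str
    below_background: bool = False


def emission_rate(m: EthyleneMeasurement, window_s: float = SUMMARY_WINDOW_S) -> EmissionRate:
    """Flow-, weight- and background-corrected emission rate of one fruit.

    The concentration is averaged over the final ``window_s`` seconds of the
    trace (the steady-state tail), the background subtracted, and the excess
    converted to an emission rate.  A rate below zero (background above the
    measured mean) is returned as-is but flagged.
    """
    t = m.trace[:, 0]
    conc = m.trace[:, 1]
    tail = t >= t[-1] - window_s
    mean_conc = float(conc[tail].mean())
    excess = mean_conc - m.background
    rate = excess * m.flow / m.fresh_weight
    return EmissionRate(
        value=float(rate),
        stage=m.stage,
        genotype=m.genotype,
        plant_id=m.plant_id,
        below_background=excess < 0,
    )


def compare_stage_emissions(
    rates: list[EmissionRate], alpha: float = 0.05
) -> AnovaLsdResult:
    """Compare genotype emission rates within one ripening stage.

    Rates are log-transformed (nonpositive rates, which occur only at the
    noise floor, are replaced by half the smallest positive rate and
    flagged) and passed to one-way ANOVA with Fisher's protected LSD.
    """
    stages = {r.stage for r in rates}
    if len(stages) != 1:
        raise ValueError(f"rates mix ripening stages: {sorted(stages)}")
    values = np.array([r.value for r in rates], dtype=float)
    groups = np.array([r.genotype for r in rates])
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("no positive emission rates to compare")
    floor = positive.min() * 0.5
    values = np.where(values > 0, values, floor)
    return anova_lsd(np.log(values), groups, alpha=alpha)
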