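"""Fruit stage series and interval-censoring construction.

A fruit is scored on the ordinal colour scale MG < T < O < LR < R at a fixed
set of observation days.  The two latent event times — entry into T (first
ripening sign) and entry into R (fully red) — are only known to lie between
the last observation before and the first observation after the transition,
which is exactly the interval-censoring rectangle the likelihood integrates
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Ordinal ripening stages: mature green, turning, orange, light red, red.
STAGES = ("MG", "T", "O", "LR", "R")
STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

#: Stage rank at which each of the two events has occurred: event 1 is entry
#: into turning (first ripening sign), event 2 is entry into red.
EVENT_THRESHOLDS = (STAGE_RANK["T"], STAGE_RANK["R"])


@dataclass
class FruitStageSeries:
    """Repeated stage observations of one fruit.

    Parameters
    ----------
    plant_id : str
        Identifier of the plant the fruit grew on.
    genotype : str
        Genotype label of the plant.
    truss : int
        1-based index of the truss (fruit cluster) on the plant.
    fruit : int
        1-based position of the fruit within its truss.
    observations : list of (float, str)
        ``(day, stage)`` pairs, days since anthesis, stage in ``STAGES``.
    """

    plant_id: str
    genotype: str
    truss: int
    fruit: int
    observations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [d for d, _ in self.observations]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"observation days must be strictly increasing for fruit "
                f"{self.plant_id}/t{self.truss}/f{self.fruit}"
            )
        ranks = []
        for d, s in self.observations:
            if s not in STAGE_RANK:
                raise ValueError(f"unknown stage label {s!r} (expected one of {STAGES})")
            if d < 0:
                raise ValueError("observation days must be nonnegative")
            ranks.append(STAGE_RANK[s])
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(
                f"stage sequence must be non-decreasing for fruit "
                f"{self.plant_id}/t{self.truss}/f{self.fruit}"
            )


@dataclass
class CensoredBivariateObservation:
    """Censoring rectangle ``[L1, R1] x [L2, R2]`` for one fruit.

    ``lower[i] <= Y_i <= upper[i]`` where ``Y_1`` is the day of the first
    ripening sign and ``Y_2`` the day the fruit turned red; ``upper`` entries
    are ``math.inf`` when the event was never observed (right censoring).
    """

    plant_id: str
    genotype: str
    truss: int
    fruit: int
    lower: tuple[float, float]
    upper: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.lower, self.upper):
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"invalid censoring interval [{lo}, {hi}] for fruit "
                    f"{self.plant_id}/t{self.truss}/f{self.fruit}"
                )


def derive_censoring_intervals(series: FruitStageSeries) -> CensoredBivariateObservation:
    """Turn one fruit's stage series into its censoring rectangle.

    For each event (entry into T, entry into R), the lower bound is the last
    observation day at which the fruit had not yet reached the event's stage,
    and the upper bound is the first day at or beyond it.  A fruit already at
    or past the stage at its first observation gets lower bound 0 (anthesis:
    no fruit ripens before its flower opens); a fruit never observed at the
    stage is right censored at the last observation day (upper bound +inf).
    """
    if not series.observations:
        raise ValueError(
            f"fruit {series.plant_id}/t{series.truss}/f{series.fruit} has no observations"
        )
    lower = []
    upper = []
    for thresh in EVENT_THRESHOLDS:
        lo = 0.0
        hi = math.inf
        for day, stage in series.observations:
            if STAGE_RANK[stage] < thresh:
                lo = day
            else:
                hi = day
                break
        # if the event was observed, all earlier observations are below the
        # threshold (the series is stage-monotone), so lo is the last such day
        if hi is not math.inf and hi < lo:  # pragma: no cover - monotone series
            raise ValueError("stage series is not monotone")
        if hi is math.inf:
            # never reached the stage: censored to the right of the last visit
            lo = series.observations[-1][0]
        lower.append(lo)
        upper.append(hi)
    return CensoredBivariateObservation(
        plant_id=series.plant_id,
        genotype=series.genotype,
        truss=series.truss,
        fruit=series.fruit,
        lower=(lower[0], lower[1]),
        upper=(upper[0], upper[1]),
    )
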