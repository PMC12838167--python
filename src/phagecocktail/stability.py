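"""Storage-stability assessment of phage titer time series.

A preparation is stable when no time point falls more than an allowance
(default 0.5 log10, the conventional plaque-assay error band) below the
initial titer.  Drop is measured against the initial titer rather than a
fitted decay curve, mirroring plate-count practice.  A pair of phages is
*compatible* when the mix and both singles are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import PhageCocktailError

DEFAULT_ALLOWANCE_LOG10 = 0.5


@dataclass(frozen=True)
class TiterPoint:
    """A plating at ``day`` days since t0.  ``titer`` is PFU/mL; a None titer
    with ``lod`` set marks a below-detection-limit plating."""

    day: float
    titer: float | None
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.titer is None:
            if self.lod is None or self.lod <= 0:
                raise PhageCocktailError(
                    "a below-LOD point needs a positive detection limit"
                )
        elif self.titer <= 0:
            raise PhageCocktailError(
                f"nonpositive titer {self.titer} without below-LOD flag"
            )


@dataclass(frozen=True)
class TiterSeries:
    series_id: str
    members: tuple[str, ...]
    points: tuple[TiterPoint, ...]
    temperature_c: float = 4.0

    def __post_init__(self) -> None:
        if len(self.members) not in (1, 2):
            raise PhageCocktailError("a series tracks one phage or a pair")
        if len(self.points) < 2:
            raise PhageCocktailError("need at least two time points")
        days = [p.day for p in self.points]
        if days[0] < 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise PhageCocktailError("times must be strictly increasing from >= 0")
        if self.points[0].titer is None:
            raise PhageCocktailError("initial titer must be measurable")


@dataclass(frozen=True)
class StabilityVerdict:
    series_id: str
    max_log10_drop: float
    stable: bool
    assay_error_allowance: float
    censored: bool = False  # True when the drop is a lower bound from an LOD


def assess_stability(
    series: TiterSeries, allowance: float = DEFAULT_ALLOWANCE_LOG10
) -> StabilityVerdict:
    """Largest log10 drop from the initial titer, clamped at 0 for increases.

    Below-LOD points contribute log10(t0 / LOD) as a lower bound on the drop
    and force instability whenever that bound exceeds the allowance.
    """
    t0 = series.points[0].titer
    assert t0 is not None
    max_drop = 0.0
    censored = False
    for pt in series.points[1:]:
        if pt.titer is None:
            drop = math.log10(t0 / pt.lod)  # true drop is at least this
            if drop >= max_drop:
                max_drop, censored = drop, True
        else:
            drop = max(0.0, math.log10(t0 / pt.titer))
            if drop > max_drop:
                max_drop, censored = drop, False
    return StabilityVerdict(
        series_id=series.series_id,
        max_log10_drop=max_drop,
        stable=max_drop <= allowance,
        assay_error_allowance=allowance,
        censored=censored,
    )


@dataclass(frozen=True)
class CompatibilityFlag:
    pair: tuple[str, str]
    compatible: bool
    failed_components: tuple[str, ...]
    note: str = ""


def compatibility_from_stability(
    single_verdicts: Mapping[str, StabilityVerdict],
    mix_verdicts: Mapping[tuple[str, str], StabilityVerdict],
) -> list[CompatibilityFlag]:
    """Per-pair compatibility: the mix and both singles must all be stable."""
    flags = []
    for pair, mix in sorted(mix_verdicts.items()):
        missing = [p for p in pair if p not in single_verdicts]
        if missing:
            raise PhageCocktailError(
                f"pair {pair}: no single-phage series for {missing}"
            )
        failed = tuple(p for p in pair if not single_verdicts[p].stable)
        note = ""
        if failed:
            note = "single-phage decay: " + ", ".join(failed)
        elif not mix.stable:
            failed = pair
            note = "mix-specific decay"
        flags.append(
            CompatibilityFlag(
                pair=pair,
                compatible=not failed and mix.stable,
                failed_components=failed,
                note=note,
            )
        )
    return flags
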