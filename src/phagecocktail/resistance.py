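"""Phage-resistance mutation frequencies from plating counts, with censoring.

A resistance frequency is the proportion of plated bacteria that form
colonies on a phage-infused overlay.  The denominator (total CFU challenged)
is back-calculated from serial-dilution titration counts.  When zero
resistant colonies appear the assay only supports an upper bound of
1/denominator — the detection limit — and the estimate is *censored*
(printed ``<value``).  Censored values propagate as intervals (0, bound]:
any comparison the interval cannot decide is reported as indeterminate,
never as a hard class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import IndeterminateDenominatorError, PhageCocktailError

SYNERGY_THRESHOLD_LOG10 = 0.5
ANTAGONISM_FACTOR = 10.0


@dataclass(frozen=True)
class TitrationPlate:
    """One titration replicate: ``count`` colonies from ``volume_ml`` of
    culture diluted by ``dilution`` (a factor in (0, 1])."""

    dilution: float
    volume_ml: float
    count: int
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.dilution <= 1:
            raise PhageCocktailError(f"dilution must be in (0, 1], got {self.dilution}")
        if self.volume_ml <= 0:
            raise PhageCocktailError(f"plated volume must be > 0, got {self.volume_ml}")
        if self.count < 0:
            raise PhageCocktailError(f"colony count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class PlatingAssay:
    """A resistance plating: challenge colonies on the phage overlay plus the
    no-phage titration of the same culture."""

    phage_ids: tuple[str, ...]
    challenge_colonies: int
    challenge_volume_ml: float
    titration: tuple[TitrationPlate, ...]

    def __post_init__(self) -> None:
        if len(self.phage_ids) not in (1, 2):
            raise PhageCocktailError("an assay challenges one phage or a pair")
        if self.challenge_colonies < 0:
            raise PhageCocktailError("challenge colony count must be >= 0")
        if self.challenge_volume_ml <= 0:
            raise PhageCocktailError("challenge volume must be > 0")
        if not self.titration:
            raise PhageCocktailError("at least one titration replicate required")


def total_cfu(
    titration: Sequence[TitrationPlate], challenge_volume_ml: float = 1.0
) -> float:
    """Total CFU in the challenge volume, from serial-dilution counts.

    Each replicate estimates the culture density as count/(dilution x volume);
    the replicate mean is scaled to the challenge volume.
    """
    if not titration:
        raise IndeterminateDenominatorError("no titration replicates")
    if all(t.count == 0 for t in titration):
        raise IndeterminateDenominatorError(
            "all titration replicates have zero colonies; denominator indeterminate"
        )
    per_ml = [t.count / (t.dilution * t.volume_ml) for t in titration]
    return challenge_volume_ml * sum(per_ml) / len(per_ml)


@dataclass(frozen=True)
class ResistanceEstimate:
    """A possibly-censored resistance frequency.

    ``censored`` means zero resistant colonies were observed and ``value`` is
    the detection-limit upper bound 1/denominator; the true frequency lies in
    (0, value].
    """

    value: float
    censored: bool = False
    numerator: int | None = None
    denominator: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise PhageCocktailError(f"frequency must be > 0, got {self.value}")
        if self.censored and self.numerator not in (None, 0):
            raise PhageCocktailError("a censored estimate implies zero colonies")

    @classmethod
    def from_counts(cls, numerator: int, denominator: float) -> "ResistanceEstimate":
        if denominator <= 0:
            raise IndeterminateDenominatorError(
                f"denominator must be > 0, got {denominator}"
            )
        if numerator < 0:
            raise PhageCocktailError("resistant colony count must be >= 0")
        if numerator == 0:
            return cls(
                value=1.0 / denominator,
                censored=True,
                numerator=0,
                denominator=denominator,
            )
        return cls(
            value=numerator / denominator,
            censored=False,
            numerator=numerator,
            denominator=denominator,
        )

    @property
    def lower(self) -> float:
        return 0.0 if self.censored else self.value

    @property
    def upper(self) -> float:
        return self.value

    def __str__(self) -> str:
        return ("<" if self.censored else "") + f"{self.value:.3g}"


def resistance_frequency(assay: PlatingAssay) -> ResistanceEstimate:
    """Resistant CFU divided by total CFU plated; censored at the detection
    limit when no resistant colonies appear."""
    denom = total_cfu(assay.titration, assay.challenge_volume_ml)
    return ResistanceEstimate.from_counts(assay.challenge_colonies, denom)


@dataclass(frozen=True)
class InteractionCall:
    """Classification of a phage pair from single vs mix resistance.

    ``expected`` is the smaller of the two single-phage frequencies: a colony
    on the mix overlay need only resist the more restrictive phage, so the
    mix is expected to track the minimum.  ``log10_shift`` is
    log10(expected / mix) — positive when the mix suppresses resistance below
    expectation; when censoring leaves only a guaranteed bound, the bound is
    reported and flagged in ``censor_note``.
    """

    pair: tuple[str, str]
    single_a: ResistanceEstimate
    single_b: ResistanceEstimate
    mix: ResistanceEstimate
    expected: float
    expected_censored: bool
    log10_shift: float | None
    classification: str
    censor_note: str = ""


def interaction_call(
    single_a: ResistanceEstimate,
    single_b: ResistanceEstimate,
    mix: ResistanceEstimate,
    pair: tuple[str, str] = ("A", "B"),
    synergy_threshold: float = SYNERGY_THRESHOLD_LOG10,
    antagonism_factor: float = ANTAGONISM_FACTOR,
) -> InteractionCall:
    """Classify a pair as synergy / neutral / antagonism (or indeterminate).

    Synergy: the mix frequency sits at least ``synergy_threshold`` logs below
    the expected (minimum single) frequency.  Antagonism: the mix frequency
    is at least ``antagonism_factor`` times the larger single.  Censored
    estimates are intervals; a class is asserted only when the intervals
    guarantee it.
    """
    expected = min(single_a.upper, single_b.upper)
    expected_censored = (single_a.censored and single_a.upper <= single_b.upper) or (
        single_b.censored and single_b.upper <= single_a.upper
    )
    max_single_upper = max(single_a.upper, single_b.upper)

    note = ""
    shift: float | None
    if not expected_censored and not mix.censored:
        shift = math.log10(expected / mix.value)
        if shift >= synergy_threshold:
            cls = "synergy"
        elif mix.value >= antagonism_factor * max_single_upper:
            cls = "antagonism"
        else:
            cls = "neutral"
    elif not expected_censored and mix.censored:
        # mix true value <= bound: the shift is at least log10(expected/bound)
        shift = math.log10(expected / mix.upper)
        if shift >= synergy_threshold:
            cls = "synergy (censored)"
            note = f"mix censored at {mix.upper:.3g}; shift is a guaranteed minimum"
        else:
            cls = "indeterminate"
            note = "mix censored; bound does not guarantee any class"
    else:
        # expected itself is only an upper bound: no shift is defensible
        shift = None
        if not mix.censored and mix.value >= antagonism_factor * max_single_upper:
            cls = "antagonism"
            note = "asserted from single-phage upper bounds"
        else:
            cls = "indeterminate"
            note = "expected frequency censored; comparison undecidable"
    return InteractionCall(
        pair=pair,
        single_a=single_a,
        single_b=single_b,
        mix=mix,
        expected=expected,
        expected_censored=expected_censored,
        log10_shift=shift,
        classification=cls,
        censor_note=note,
    )
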