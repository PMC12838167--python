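"""Efficiency of plating, binarization, and host-range coverage analysis.

Host range is the fraction of a strain diversity panel on which a phage forms
clear plaques; EOP is the phage titer on a test strain divided by its titer
on the reference strain (PAO1).  Coverage of a phage subset counts the
strains lysed by at least one member, and a pair is *complementary* when its
union strictly exceeds both singles (on counts, not rounded percentages).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .errors import BinarizationError, MatrixValidationError
from .panel import SusceptibilityMatrix


@dataclass(frozen=True)
class EopResult:
    phage_id: str
    strain_id: str
    titer_test: float
    titer_reference: float
    eop: float
    no_plaques: bool


def compute_eop(
    titer_test: float,
    titer_reference: float,
    phage_id: str = "",
    strain_id: str = "",
) -> EopResult:
    """EOP = titer on the test strain / titer on the reference strain.

    Raises on a nonpositive reference titer (the ratio is undefined); a zero
    test titer yields EOP 0.0 flagged ``no_plaques``.
    """
    if titer_reference <= 0:
        raise MatrixValidationError(
            f"reference titer must be > 0, got {titer_reference}"
        )
    if titer_test < 0:
        raise MatrixValidationError(f"test titer must be >= 0, got {titer_test}")
    return EopResult(
        phage_id=phage_id,
        strain_id=strain_id,
        titer_test=titer_test,
        titer_reference=titer_reference,
        eop=titer_test / titer_reference,
        no_plaques=titer_test == 0,
    )


@dataclass(frozen=True)
class BinarizationRule:
    """How entries map to susceptible (True) / resistant (False).

    Qualitative calls: ``clear`` is always susceptible, ``none`` always
    resistant; ``turbid`` follows ``turbid_susceptible`` (default False —
    host range counts clear plaques only).  EOP entries are susceptible when
    strictly greater than ``eop_threshold`` (default 0).
    """

    turbid_susceptible: bool = False
    eop_threshold: float = 0.0

    def describe(self) -> str:
        return (
            f"clear->S, turbid->{'S' if self.turbid_susceptible else 'R'}, "
            f"none->R; EOP > {self.eop_threshold:g} -> S"
        )


DEFAULT_RULE = BinarizationRule()


def binarize(
    matrix: SusceptibilityMatrix, rule: BinarizationRule | None = None
) -> np.ndarray:
    """Deterministic boolean susceptible/resistant view of a matrix."""
    rule = rule or DEFAULT_RULE
    out = np.zeros(matrix.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(matrix.entries):
        if isinstance(cell, str):
            if cell == "clear":
                out[i, j] = True
            elif cell == "turbid":
                out[i, j] = rule.turbid_susceptible
            elif cell == "none":
                out[i, j] = False
            else:  # pragma: no cover - excluded by construction
                raise BinarizationError(f"unexpected call {cell!r}")
        else:
            out[i, j] = float(cell) > rule.eop_threshold
    return out


def percent(covered: int, panel: int) -> float:
    """Round-half-up one-decimal percentage, 100*covered/panel."""
    if panel <= 0:
        raise MatrixValidationError(f"panel size must be > 0, got {panel}")
    if not 0 <= covered <= panel:
        raise MatrixValidationError(
            f"covered count {covered} outside [0, {panel}]"
        )
    q = Decimal(100 * covered) / Decimal(panel)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageReport:
    phage_subset: frozenset[str]
    covered_count: int
    panel_size: int

    @property
    def percent(self) -> float:
        return percent(self.covered_count, self.panel_size)


def _subset_rows(
    matrix: SusceptibilityMatrix, binary: np.ndarray, subset: Iterable[str]
) -> list[int]:
    return [matrix.phage_index(p) for p in subset]


def coverage(
    matrix: SusceptibilityMatrix,
    phage_subset: Iterable[str],
    rule: BinarizationRule | None = None,
    binary: np.ndarray | None = None,
) -> CoverageReport:
    """Strains susceptible to at least one member of the subset."""
    if binary is None:
        binary = binarize(matrix, rule)
    subset = list(phage_subset)
    rows = _subset_rows(matrix, binary, subset)
    if rows:
        covered = int(np.any(binary[rows, :], axis=0).sum())
    else:
        covered = 0
    return CoverageReport(
        phage_subset=frozenset(subset),
        covered_count=covered,
        panel_size=len(matrix.strains),
    )


def uncovered_strains(
    matrix: SusceptibilityMatrix,
    phage_subset: Iterable[str],
    rule: BinarizationRule | None = None,
    binary: np.ndarray | None = None,
) -> list[str]:
    """Strains with zero susceptible entries across the subset."""
    if binary is None:
        binary = binarize(matrix, rule)
    rows = _subset_rows(matrix, binary, phage_subset)
    if rows:
        hit = np.any(binary[rows, :], axis=0)
    else:
        hit = np.zeros(len(matrix.strains), dtype=bool)
    return [s for s, h in zip(matrix.strains, hit) if not h]


@dataclass(frozen=True)
class PairComplementarity:
    phage_a: str
    phage_b: str
    coverage_a: CoverageReport
    coverage_b: CoverageReport
    coverage_union: CoverageReport

    @property
    def complementary(self) -> bool:
        """Union strictly exceeds both singles, compared on counts."""
        return self.coverage_union.covered_count > max(
            self.coverage_a.covered_count, self.coverage_b.covered_count
        )


def pairwise_union_table(
    matrix: SusceptibilityMatrix,
    candidates: Sequence[str],
    rule: BinarizationRule | None = None,
) -> list[PairComplementarity]:
    """One complementarity record per unordered candidate pair."""
    if len(candidates) < 2:
        raise MatrixValidationError("need at least two candidate phages")
    binary = binarize(matrix, rule)
    singles = {
        p: coverage(matrix, [p], binary=binary) for p in candidates
    }
    out = []
    for a, b in itertools.combinations(candidates, 2):
        out.append(
            PairComplementarity(
                phage_a=a,
                phage_b=b,
                coverage_a=singles[a],
                coverage_b=singles[b],
                coverage_union=coverage(matrix, [a, b], binary=binary),
            )
        )
    return out
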