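"""The rational-design engine: candidate filtering, complementarity cliques,
and constrained fixed-size cocktail optimization.

A cocktail is a set of k phages chosen to jointly maximize strain coverage
while honoring eligibility constraints: strictly lytic members, minimum
receptor and genus diversity, pairwise host-range complementarity, pairwise
compatibility (storage stability, no resistance antagonism), and caps on
single-phage resistance frequencies.  Exhaustive search enumerates all
C(n, k) subsets within a configurable budget; the greedy mode is the
standard accretive maximum-coverage heuristic, which carries the classical
(1 - 1/e) approximation guarantee before constraint filtering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import MatrixValidationError, PhageCocktailError
from .hostrange import (
    BinarizationRule,
    CoverageReport,
    PairComplementarity,
    binarize,
    coverage,
)
from .panel import PhageRecord, SusceptibilityMatrix
from .resistance import ResistanceEstimate


@dataclass(frozen=True)
class DesignCriteria:
    """Eligibility and diversity constraints for a k-phage cocktail."""

    cocktail_size: int = 5
    require_lytic: bool = True
    min_receptor_classes: int = 3
    min_genera: int = 3
    max_single_resistance: float | None = None
    require_pairwise_complementarity: bool = False
    require_pairwise_compatibility: bool = False
    min_single_host_range: float | None = None  # percent floor

    def __post_init__(self) -> None:
        if self.cocktail_size < 1:
            raise PhageCocktailError("cocktail_size must be >= 1")
        for name in ("max_single_resistance", "min_single_host_range"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise PhageCocktailError(f"{name} must be nonnegative")


@dataclass
class FilterResult:
    eligible: list[str]
    exclusions: dict[str, str]  # phage_id -> reason


def filter_candidates(
    phages: Sequence[PhageRecord],
    matrix: SusceptibilityMatrix,
    criteria: DesignCriteria,
    rule: BinarizationRule | None = None,
) -> FilterResult:
    """Apply per-phage eligibility rules; every exclusion carries a reason.

    Temperate (and undetermined-lifestyle) phages are always excluded when
    strictly lytic members are required: a lysogen can transduce host DNA
    and is unusable for therapy regardless of its host range.
    """
    binary = binarize(matrix, rule)
    eligible: list[str] = []
    exclusions: dict[str, str] = {}
    for rec in phages:
        if rec.phage_id not in matrix.phages:
            exclusions[rec.phage_id] = "not present in susceptibility matrix"
            continue
        if criteria.require_lytic and rec.lifestyle_verdict != "lytic":
            exclusions[rec.phage_id] = (
                f"lifestyle {rec.lifestyle_verdict!r}: not strictly lytic"
            )
            continue
        if criteria.min_single_host_range is not None:
            rep = coverage(matrix, [rec.phage_id], binary=binary)
            if rep.percent < criteria.min_single_host_range:
                exclusions[rec.phage_id] = (
                    f"host range {rep.percent}% below floor "
                    f"{criteria.min_single_host_range}%"
                )
                continue
        eligible.append(rec.phage_id)
    if not eligible:
        binding = (
            "min_single_host_range"
            if criteria.min_single_host_range is not None
            else "require_lytic"
        )
        raise PhageCocktailError(
            f"no eligible candidates; binding constraint: {binding}"
        )
    return FilterResult(eligible=eligible, exclusions=exclusions)


def complementarity_cliques(
    pair_table: Sequence[PairComplementarity],
    size: int | None = None,
) -> list[tuple[str, ...]]:
    """Vertex sets in which every pair is complementary.

    With ``size`` given, all cliques of exactly that size are returned;
    otherwise all maximal cliques.  Output is deterministically ordered
    (members sorted within a clique, cliques sorted lexicographically).
    """
    g = nx.Graph()
    for rec in pair_table:
        g.add_node(rec.phage_a)
        g.add_node(rec.phage_b)
        if rec.complementary:
            g.add_edge(rec.phage_a, rec.phage_b)
    if size is None:
        cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    elif size == 1:
        cliques = [(v,) for v in g.nodes]
    else:
        cliques = [
            tuple(sorted(c))
            for c in nx.enumerate_all_cliques(g)
            if len(c) == size
        ]
    return sorted(cliques)


@dataclass(frozen=True)
class CocktailEvaluation:
    """A phage subset scored against the design criteria.

    ``rank_key`` orders candidate cocktails: coverage first, then worst-case
    single-phage resistance (censored bounds count as their bound), then
    receptor diversity, then genus diversity, with member ids breaking ties.
    """

    members: tuple[str, ...]
    coverage: CoverageReport
    distinct_receptor_classes: int
    distinct_genera: int
    worst_resistance: float | None
    worst_resistance_censored: bool
    constraint_flags: dict[str, bool]

    @property
    def passes(self) -> bool:
        return all(self.constraint_flags.values())

    @property
    def rank_key(self) -> tuple:
        return (
            -self.coverage.covered_count,
            self.worst_resistance if self.worst_resistance is not None else 0.0,
            -self.distinct_receptor_classes,
            -self.distinct_genera,
            self.members,
        )


def evaluate(
    members: Iterable[str],
    matrix: SusceptibilityMatrix,
    catalogs: Mapping[str, PhageRecord],
    criteria: DesignCriteria | None = None,
    resistance: Mapping[str, ResistanceEstimate] | None = None,
    compatibility: Mapping[frozenset[str], bool] | None = None,
    pair_table: Sequence[PairComplementarity] | None = None,
    rule: BinarizationRule | None = None,
    binary: np.ndarray | None = None,
) -> CocktailEvaluation:
    """Populate every score and constraint flag for one cocktail."""
    criteria = criteria or DesignCriteria(cocktail_size=len(tuple(members)))
    members = tuple(sorted(members))
    for pid in members:
        if pid not in catalogs:
            raise MatrixValidationError(f"unresolved cocktail member {pid!r}")
    cov = coverage(matrix, members, rule=rule, binary=binary)
    receptor_classes = {
        catalogs[p].receptor_class
        for p in members
        if catalogs[p].receptor_class != "unknown"
    }
    genera = {catalogs[p].genus for p in members}

    worst: float | None = None
    worst_censored = False
    if resistance:
        known = [resistance[p] for p in members if p in resistance]
        if known:
            est = max(known, key=lambda e: e.upper)
            worst, worst_censored = est.upper, est.censored

    flags: dict[str, bool] = {"size": len(members) == criteria.cocktail_size}
    if criteria.require_lytic:
        flags["lytic"] = all(
            catalogs[p].lifestyle_verdict == "lytic" for p in members
        )
    flags["receptor_diversity"] = (
        len(receptor_classes) >= criteria.min_receptor_classes
    )
    flags["genus_diversity"] = len(genera) >= criteria.min_genera
    if criteria.max_single_resistance is not None:
        # censored bounds count as their bound value: conservative for a cap
        flags["resistance_cap"] = worst is not None and (
            worst <= criteria.max_single_resistance
        )
    if criteria.min_single_host_range is not None:
        flags["host_range_floor"] = all(
            coverage(matrix, [p], rule=rule, binary=binary).percent
            >= criteria.min_single_host_range
            for p in members
        )
    if criteria.require_pairwise_complementarity:
        if pair_table is None:
            raise PhageCocktailError(
                "pairwise complementarity required but no pair table given"
            )
        comp = {
            frozenset((r.phage_a, r.phage_b)): r.complementary for r in pair_table
        }
        flags["complementarity"] = all(
            comp.get(frozenset(pr), False)
            for pr in itertools.combinations(members, 2)
        )
    if criteria.require_pairwise_compatibility:
        if compatibility is None:
            raise PhageCocktailError(
                "pairwise compatibility required but no compatibility map given"
            )
        flags["compatibility"] = all(
            compatibility.get(frozenset(pr), False)
            for pr in itertools.combinations(members, 2)
        )
    return CocktailEvaluation(
        members=members,
        coverage=cov,
        distinct_receptor_classes=len(receptor_classes),
        distinct_genera=len(genera),
        worst_resistance=worst,
        worst_resistance_censored=worst_censored,
        constraint_flags=flags,
    )


@dataclass
class OptimizeResult:
    ranked: list[CocktailEvaluation]
    mode: str
    failure_census: dict[str, int] = field(default_factory=dict)

    @property
    def best(self) -> CocktailEvaluation | None:
        return self.ranked[0] if self.ranked else None


def _greedy_members(binary: np.ndarray, matrix: SusceptibilityMatrix,
                    candidates: Sequence[str], k: int) -> tuple[str, ...]:
    chosen: list[str] = []
    hit = np.zeros(binary.shape[1], dtype=bool)
    remaining = list(candidates)
    for _ in range(min(k, len(remaining))):
        gains = []
        for p in remaining:
            row = binary[matrix.phage_index(p)]
            gains.append((int((row & ~hit).sum()), p))
        gains.sort(key=lambda g: (-g[0], g[1]))  # ties break on phage id
        best_gain, best_p = gains[0]
        chosen.append(best_p)
        remaining.remove(best_p)
        hit |= binary[matrix.phage_index(best_p)]
    return tuple(sorted(chosen))


def optimize(
    matrix: SusceptibilityMatrix,
    catalogs: Mapping[str, PhageRecord],
    criteria: DesignCriteria,
    candidates: Sequence[str] | None = None,
    resistance: Mapping[str, ResistanceEstimate] | None = None,
    compatibility: Mapping[frozenset[str], bool] | None = None,
    pair_table: Sequence[PairComplementarity] | None = None,
    mode: str = "exhaustive",
    budget: int = 10**6,
    rule: BinarizationRule | None = None,
) -> OptimizeResult:
    """Ranked constraint-passing cocktails of the configured size.

    Exhaustive mode enumerates all C(n, k) subsets (refusing beyond
    ``budget``); greedy mode runs plain maximum-coverage accretion and then
    applies the constraints as filters.  Both are deterministic functions of
    their inputs.
    """
    if candidates is None:
        candidates = list(matrix.phages)
    k = criteria.cocktail_size
    if len(candidates) < k:
        raise PhageCocktailError(
            f"{len(candidates)} candidates < cocktail size {k}"
        )
    binary = binarize(matrix, rule)
    kwargs = dict(
        matrix=matrix, catalogs=catalogs, criteria=criteria,
        resistance=resistance, compatibility=compatibility,
        pair_table=pair_table, binary=binary,
    )
    if mode == "exhaustive":
        n_subsets = math.comb(len(candidates), k)
        if n_subsets > budget:
            raise PhageCocktailError(
                f"exhaustive search refused: C({len(candidates)}, {k}) = "
                f"{n_subsets} exceeds budget {budget}"
            )
        evals = [
            evaluate(sub, **kwargs)
            for sub in itertools.combinations(sorted(candidates), k)
        ]
    elif mode == "greedy":
        evals = [evaluate(_greedy_members(binary, matrix, candidates, k), **kwargs)]
    else:
        raise PhageCocktailError(f"unknown mode {mode!r}")

    passing = sorted((e for e in evals if e.passes), key=lambda e: e.rank_key)
    census: dict[str, int] = {}
    if not passing:
        for e in evals:
            for name, ok in e.constraint_flags.items():
                if not ok:
                    census[name] = census.get(name, 0) + 1
    return OptimizeResult(ranked=passing, mode=mode, failure_census=census)
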