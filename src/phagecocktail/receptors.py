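"""Receptor-class inference from plaque assays on PAO1 knockout mutants.

Twelve isogenic knockouts of the reference strain (defective in type IV
pili, flagella, or defined parts of the lipopolysaccharide) are challenged
with each phage.  Loss of lysis on a mutant implicates the missing surface
structure as a receptor.  The five receptor classes combine T4P with an LPS
moiety set:

    1  T4P + A band            (common polysaccharide antigen)
    2  T4P + LPS core
    3  T4P + long / very long B band (wzz-controlled O-antigen chain lengths)
    4  T4P + A, B, long-B, very-long-B
    5  T4P + A, B

A phage that does not plate on the wild-type reference at all cannot be
classified this way and is assigned ``unknown`` (reason: PAO1-nonpermissive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import IncompletePanelError, InconsistentPanelError

GENOTYPES = (
    "rmd",          # no A band
    "wbpL",         # A/B band synthesis initiation defect
    "rmlC",         # truncated core; no A or B bands
    "fliA",         # no flagella
    "pilA",         # no type IV pili
    "fliA_algC_pilA",  # no flagella, A band, or T4P
    "wzz1",         # no long B band
    "wzz2",         # no very long B band
    "wzz1_2",       # no long or very long B band
    "wapQ",         # no phosphate in LPS inner core
    "wbpM",         # no B band
)

CALLS = ("lysis", "no_lysis", "reduced")

# LPS moiety sets reported per class
CLASS_MOIETIES: dict[int, frozenset[str]] = {
    1: frozenset({"A_band"}),
    2: frozenset({"core"}),
    3: frozenset({"long_B", "very_long_B"}),
    4: frozenset({"A_band", "B_band", "long_B", "very_long_B"}),
    5: frozenset({"A_band", "B_band"}),
}


@dataclass(frozen=True)
class MutantPanelResult:
    """Plaque outcomes for one phage across the mutant panel.

    ``outcomes`` maps each genotype (plus ``wild_type``) to a call.  The two
    independently sourced rmlC knockouts may be supplied separately as
    ``rmlC`` and ``rmlC_b``; they must agree.
    """

    phage_id: str
    outcomes: Mapping[str, str]

    def __post_init__(self) -> None:
        extra = set(self.outcomes) - set(GENOTYPES) - {"wild_type", "rmlC_b"}
        if extra:
            raise IncompletePanelError(
                f"{self.phage_id}: unknown genotype key(s) {sorted(extra)}"
            )
        bad = {g: c for g, c in self.outcomes.items() if c not in CALLS}
        if bad:
            raise IncompletePanelError(f"{self.phage_id}: invalid call(s) {bad}")
        if "wild_type" not in self.outcomes:
            raise IncompletePanelError(f"{self.phage_id}: wild_type outcome missing")
        missing = set(GENOTYPES) - set(self.outcomes)
        if missing:
            raise IncompletePanelError(
                f"{self.phage_id}: missing genotype(s) {sorted(missing)}"
            )


@dataclass(frozen=True)
class ReceptorAssignment:
    phage_id: str
    requires_t4p: bool
    lps_moieties: frozenset[str]
    class_code: int | str  # 1..5 or "unknown"
    evidence: tuple[str, ...] = ()


def _lysed(call: str) -> bool:
    # "reduced" counts as lysis for classification but is flagged in evidence
    return call in ("lysis", "reduced")


def infer_receptor(panel: MutantPanelResult) -> ReceptorAssignment:
    """Apply the decision table to a complete mutant panel.

    Raises :class:`InconsistentPanelError` when the outcome pattern
    contradicts the receptor model (e.g. lysis on the pilA mutant of a phage
    that cannot lyse wild type, disagreeing rmlC duplicates, or an LPS loss
    pattern matching none of the five classes).
    """
    o = panel.outcomes
    pid = panel.phage_id
    evidence: list[str] = [
        f"{g}: reduced plaque treated as lysis" for g in sorted(o) if o[g] == "reduced"
    ]

    if "rmlC_b" in o and _lysed(o["rmlC"]) != _lysed(o["rmlC_b"]):
        raise InconsistentPanelError(
            f"{pid}: the two rmlC mutants disagree ({o['rmlC']} vs {o['rmlC_b']})"
        )

    if not _lysed(o["wild_type"]):
        if any(_lysed(o[g]) for g in GENOTYPES):
            raise InconsistentPanelError(
                f"{pid}: lysis on a knockout mutant but not on wild type"
            )
        return ReceptorAssignment(
            phage_id=pid,
            requires_t4p=False,
            lps_moieties=frozenset(),
            class_code="unknown",
            evidence=(*evidence, "PAO1-nonpermissive"),
        )

    loss = {g for g in GENOTYPES if not _lysed(o[g])}
    if "rmlC_b" in o and not _lysed(o["rmlC_b"]):
        loss.add("rmlC")

    if "pilA" in loss and "fliA_algC_pilA" not in loss:
        raise InconsistentPanelError(
            f"{pid}: pilA loss but lysis on the triple mutant lacking T4P"
        )
    requires_t4p = "pilA" in loss
    if requires_t4p:
        evidence.append("pilA (and triple) loss: requires type IV pili")

    if "fliA" in loss:
        evidence.append("fliA loss noted; flagellar dependence never changes class")

    a_dep = "rmd" in loss
    b_dep = "wbpM" in loss
    wzz_loss = bool(loss & {"wzz1", "wzz2", "wzz1_2"})
    core_loss = "rmlC" in loss
    wapq_loss = "wapQ" in loss

    if a_dep and b_dep and wzz_loss:
        code = 4
    elif a_dep and b_dep:
        code = 5
    elif a_dep and not wzz_loss:
        code = 1
    elif wzz_loss and not a_dep:
        code = 3
    elif core_loss:
        code = 2
        evidence.append("loss confined to core mutants: core dependence")
    elif wapq_loss:
        # inner-core phosphate loss with an otherwise clean panel: treat as
        # core dependence, flagged — the mapping is not settled
        code = 2
        evidence.append("wapQ-only loss treated as core dependence (flagged)")
    else:
        raise InconsistentPanelError(
            f"{pid}: LPS loss pattern {sorted(loss)} matches no receptor class"
        )
    return ReceptorAssignment(
        phage_id=pid,
        requires_t4p=requires_t4p,
        lps_moieties=CLASS_MOIETIES[code],
        class_code=code,
        evidence=tuple(evidence),
    )


@dataclass(frozen=True)
class ReceptorDiversity:
    distinct_known: int
    known_classes: frozenset[int]
    unknown_count: int
    all_unknown: bool


def summarize_receptor_diversity(
    assignments: Mapping[str, int | str] | Mapping[str, ReceptorAssignment],
    subset: list[str] | tuple[str, ...] | set[str] | frozenset[str],
) -> ReceptorDiversity:
    """Count distinct known receptor classes within a phage subset.

    Unknown classes are excluded from the distinct count and reported
    separately.  ``assignments`` maps phage_id to either a class code or a
    full :class:`ReceptorAssignment`.
    """
    classes: list[int | str] = []
    for pid in subset:
        if pid not in assignments:
            raise IncompletePanelError(f"no receptor assignment for {pid}")
        a = assignments[pid]
        classes.append(a.class_code if isinstance(a, ReceptorAssignment) else a)
    known = frozenset(c for c in classes if c != "unknown")
    unknown = sum(1 for c in classes if c == "unknown")
    return ReceptorDiversity(
        distinct_known=len(known),
        known_classes=known,  # type: ignore[arg-type]
        unknown_count=unknown,
        all_unknown=bool(classes) and unknown == len(classes),
    )
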