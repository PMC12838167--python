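"""Synthetic inputs: mechanistic panels, marginal-consistent matrix
reconstruction, plating-count simulation, and receptor-panel fixtures.

Two distinct matrix generators live here.

``generate_matrix`` is *mechanistic*: strains carry receptor genotypes
(type IV pili plus a hierarchy of LPS features) drawn from configurable
probabilities, and a strain is susceptible to a phage exactly when it
presents every feature the phage's receptor class requires and an
independent strain-intrinsic immunity draw fails.

``reconstruct_matrix`` is *statistical*: given only published marginals — a
panel size, per-phage host-range percentages, pairwise-union percentages and
named set unions — it searches for a binary matrix consistent with all of
them.  Single coverages are satisfied exactly by construction (the move set
swaps a susceptible and a resistant strain within one phage row, preserving
row sums) and the remaining union constraints are driven to their targets by
simulated annealing on the summed squared count deviations.  The result
always comes with a per-constraint deviation report; an unsatisfied search
returns its best matrix with the deviations stated, never a silent pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InfeasibleSpecError, PhageCocktailError
from .hostrange import percent
from .panel import StrainRecord, SusceptibilityMatrix
from .receptors import GENOTYPES, MutantPanelResult
from .resistance import PlatingAssay, TitrationPlate

# -- receptor mechanics shared by the generator and the fixture factory ------

FEATURES = (
    "t4p",
    "flagella",
    "core",
    "core_phosphate",
    "A_band",
    "B_band",
    "long_B",
    "very_long_B",
)

#: surface features required for adsorption, per receptor class
CLASS_REQUIREMENTS: dict[int, frozenset[str]] = {
    1: frozenset({"t4p", "A_band"}),
    2: frozenset({"t4p", "core"}),
    3: frozenset({"t4p", "long_B", "very_long_B"}),
    4: frozenset({"t4p", "A_band", "B_band", "long_B", "very_long_B"}),
    5: frozenset({"t4p", "A_band", "B_band"}),
}

#: features each knockout mutant loses relative to wild type
MUTANT_LOSSES: dict[str, frozenset[str]] = {
    "rmd": frozenset({"A_band"}),
    "wbpL": frozenset({"A_band", "B_band", "long_B", "very_long_B"}),
    "rmlC": frozenset({"core", "A_band", "B_band", "long_B", "very_long_B"}),
    "fliA": frozenset({"flagella"}),
    "pilA": frozenset({"t4p"}),
    "fliA_algC_pilA": frozenset({"flagella", "A_band", "t4p"}),
    "wzz1": frozenset({"long_B"}),
    "wzz2": frozenset({"very_long_B"}),
    "wzz1_2": frozenset({"long_B", "very_long_B"}),
    "wapQ": frozenset({"core_phosphate"}),
    "wbpM": frozenset({"B_band", "long_B", "very_long_B"}),
}


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic strain panel.

    Receptor-genotype probabilities are conditional on the parent feature
    (A/B bands require an intact core; chain-length classes require the B
    band), so knockouts of upstream genes correctly abolish downstream
    moieties.  ``immunity_prob`` is the per-(strain, phage) probability of
    resistance despite a receptor match — surface receptors are necessary
    but not sufficient, and this stands in for abortive infection, CRISPR
    and restriction systems.
    """

    n_strains: int = 156
    n_phages: int = 25
    st_count: int = 106
    p_t4p: float = 0.9
    p_flagella: float = 0.95
    p_core: float = 0.95
    p_core_phosphate: float = 0.95
    p_a_band: float = 0.7
    p_b_band: float = 0.8
    p_long_b: float = 0.6
    p_very_long_b: float = 0.55
    immunity_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_t4p", "p_flagella", "p_core", "p_core_phosphate", "p_a_band",
            "p_b_band", "p_long_b", "p_very_long_b", "immunity_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PhageCocktailError(f"{name} must be in [0, 1], got {v}")
        if self.n_strains < 1:
            raise PhageCocktailError("n_strains must be >= 1")
        if not 1 <= self.st_count <= self.n_strains:
            raise PhageCocktailError("st_count must be in [1, n_strains]")


def generate_panel(
    config: PanelConfig,
) -> tuple[list[StrainRecord], dict[str, frozenset[str]]]:
    """Strain records plus receptor genotypes, reproducible given the seed.

    Sequence-type labels follow a skewed distribution (a few common STs,
    many rare ones); every one of ``st_count`` distinct STs is guaranteed to
    appear at least once.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_strains, config.st_count
    # one strain per ST first, remainder drawn with Zipf-like weights
    st_of = list(range(k))
    if n > k:
        weights = 1.0 / np.arange(1, k + 1)
        weights /= weights.sum()
        st_of += list(rng.choice(k, size=n - k, p=weights))
    rng.shuffle(st_of)

    resistance_probs = {"susceptible": 0.13, "MDR": 0.62, "XDR": 0.20, "PDR": 0.05}
    classes = rng.choice(
        list(resistance_probs), size=n, p=list(resistance_probs.values())
    )
    core_members = set(rng.choice(n, size=min(100, n), replace=False))

    records: list[StrainRecord] = []
    genotypes: dict[str, frozenset[str]] = {}
    for i in range(n):
        sid = f"S{i + 1:03d}"
        feats = set()
        if rng.random() < config.p_t4p:
            feats.add("t4p")
        if rng.random() < config.p_flagella:
            feats.add("flagella")
        if rng.random() < config.p_core:
            feats.add("core")
            if rng.random() < config.p_core_phosphate:
                feats.add("core_phosphate")
            if rng.random() < config.p_a_band:
                feats.add("A_band")
            if rng.random() < config.p_b_band:
                feats.add("B_band")
                if rng.random() < config.p_long_b:
                    feats.add("long_B")
                if rng.random() < config.p_very_long_b:
                    feats.add("very_long_B")
        records.append(
            StrainRecord(
                strain_id=sid,
                sequence_type=f"ST{st_of[i] + 1:03d}",
                source="synthetic",
                resistance_class=str(classes[i]),
                core_panel_member=i in core_members,
            )
        )
        genotypes[sid] = frozenset(feats)
    return records, genotypes


def generate_matrix(
    genotypes: Mapping[str, frozenset[str]],
    phage_classes: Mapping[str, int],
    immunity_prob: float,
    seed: int,
) -> SusceptibilityMatrix:
    """Mechanistic susceptibility matrix.

    A strain is susceptible to a phage iff its genotype contains every
    feature of the phage's receptor class and the immunity draw fails.  With
    ``immunity_prob`` 0 the matrix is a deterministic function of genotypes.
    """
    for pid, cls in phage_classes.items():
        if cls not in CLASS_REQUIREMENTS:
            raise PhageCocktailError(f"phage {pid}: unknown receptor class {cls!r}")
    rng = np.random.default_rng(seed)
    strains = list(genotypes)
    phages = list(phage_classes)
    binary = np.zeros((len(phages), len(strains)), dtype=bool)
    for i, pid in enumerate(phages):
        req = CLASS_REQUIREMENTS[phage_classes[pid]]
        for j, sid in enumerate(strains):
            if req <= genotypes[sid]:
                binary[i, j] = rng.random() >= immunity_prob
    return SusceptibilityMatrix.from_binary(phages, strains, binary)


# -- marginal-consistent reconstruction ---------------------------------------


def percent_to_count(p: float, panel: int) -> int:
    """Invert a printed one-decimal percentage to a count, round half up."""
    return int(
        (Decimal(str(p)) * panel / 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class MarginalSpec:
    """Published marginals a reconstructed matrix must honor."""

    panel_size: int
    single_coverages: dict[str, float]
    pair_unions: dict[tuple[str, str], float] = field(default_factory=dict)
    set_unions: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    tolerance_pp: float = 0.2

    def __post_init__(self) -> None:
        for pid, p in self.single_coverages.items():
            if not 0 <= p <= 100:
                raise InfeasibleSpecError(f"{pid}: percent {p} outside [0, 100]")
        for pair in self.pair_unions:
            for pid in pair:
                if pid not in self.single_coverages:
                    raise InfeasibleSpecError(
                        f"pair {pair}: {pid} has no single coverage"
                    )
        for name, (members, _) in self.set_unions.items():
            for pid in members:
                if pid not in self.single_coverages:
                    raise InfeasibleSpecError(
                        f"set {name!r}: {pid} has no single coverage"
                    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarginalSpec":
        pairs = {}
        for key, p in d.get("pair_unions", {}).items():
            a, b = key.split("+")
            pairs[(a.strip(), b.strip())] = float(p)
        sets = {
            name: (tuple(entry["members"]), float(entry["percent"]))
            for name, entry in d.get("set_unions", {}).items()
        }
        return cls(
            panel_size=int(d["panel_size"]),
            single_coverages={k: float(v) for k, v in d["single_coverages"].items()},
            pair_unions=pairs,
            set_unions=sets,
            tolerance_pp=float(d.get("tolerance_pp", 0.2)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarginalSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def published(cls) -> "MarginalSpec":
        """The marginal spec shipped with the package (the printed tables)."""
        text = (
            resources.files("phagecocktail") / "data" / "marginal_spec.json"
        ).read_text()
        return cls.from_dict(json.loads(text))


@dataclass
class ReconstructionReport:
    """Achieved-marginal report: one row per union constraint."""

    panel_size: int
    tolerance_pp: float
    rows: list[dict] = field(default_factory=list)
    iterations: int = 0
    restarts: int = 0

    def add(self, name: str, target_percent: float, target_count: int,
            achieved_count: int) -> None:
        achieved_percent = percent(achieved_count, self.panel_size)
        self.rows.append(
            {
                "constraint": name,
                "target_percent": target_percent,
                "target_count": target_count,
                "achieved_count": achieved_count,
                "achieved_percent": achieved_percent,
                "deviation_pp": round(abs(achieved_percent - target_percent), 3),
            }
        )

    @property
    def max_deviation_pp(self) -> float:
        return max((r["deviation_pp"] for r in self.rows), default=0.0)

    @property
    def satisfied(self) -> bool:
        return all(r["deviation_pp"] <= self.tolerance_pp + 1e-9 for r in self.rows)


def _spec_counts(spec: MarginalSpec):
    phages = list(spec.single_coverages)
    idx = {p: i for i, p in enumerate(phages)}
    n = spec.panel_size
    singles = {p: percent_to_count(v, n) for p, v in spec.single_coverages.items()}
    constraints = []  # (name, rows tuple, target_count, target_percent)
    for (a, b), p in spec.pair_unions.items():
        t = percent_to_count(p, n)
        lo, hi = max(singles[a], singles[b]), min(singles[a] + singles[b], n)
        if not lo <= t <= hi:
            raise InfeasibleSpecError(
                f"pair {a}+{b}: union count {t} outside [{lo}, {hi}]"
            )
        constraints.append((f"{a}+{b}", (idx[a], idx[b]), t, p))
    for name, (members, p) in spec.set_unions.items():
        t = percent_to_count(p, n)
        lo = max(singles[m] for m in members)
        hi = min(sum(singles[m] for m in members), n)
        if not lo <= t <= hi:
            raise InfeasibleSpecError(
                f"set {name!r}: union count {t} outside [{lo}, {hi}]"
            )
        constraints.append((name, tuple(idx[m] for m in members), t, p))
    return phages, singles, constraints


def reconstruct_matrix(
    spec: MarginalSpec,
    seed: int = 0,
    max_iters: int = 400_000,
    restarts: int = 8,
) -> tuple[SusceptibilityMatrix, ReconstructionReport]:
    """Search for a binary matrix matching the spec's marginals.

    Column sums (per-phage counts) are exact by construction; pair and set
    unions are annealed toward their target counts.  Returns the best matrix
    found and a per-constraint deviation report — check ``report.satisfied``.
    """
    phages, singles, constraints = _spec_counts(spec)
    n = spec.panel_size
    k = np.array([singles[p] for p in phages])
    # restrict support to the covered region when an all-phage union is given:
    # strains outside it are resistant to everything by construction
    cov_size = n
    for name, rows, t, p in constraints:
        if len(rows) == len(phages):
            cov_size = min(cov_size, t)
    if np.any(k > cov_size):
        raise InfeasibleSpecError(
            "a single coverage exceeds the all-phage union"
        )

    rng = np.random.default_rng(seed)
    best_M = None
    best_obj = math.inf
    best_iters = 0
    used_restarts = 0

    for attempt in range(restarts):
        used_restarts = attempt
        M = np.zeros((len(phages), n), dtype=bool)
        for i in range(len(phages)):
            M[i, rng.choice(cov_size, size=k[i], replace=False)] = True
        # per-constraint coverage counters over strains
        covers = [M[list(rows), :].sum(axis=0) for _, rows, _, _ in constraints]
        unions = [int((c > 0).sum()) for c in covers]
        targets = [t for _, _, t, _ in constraints]
        row_in = [
            [ci for ci, (_, rows, _, _) in enumerate(constraints) if i in rows]
            for i in range(len(phages))
        ]
        obj = sum((u - t) ** 2 for u, t in zip(unions, targets))

        t_hi, t_lo = 4.0, 0.02
        iters = 0
        # precompute row pick probabilities: constrained rows move more often
        weights = np.array([1.0 + 2.0 * len(row_in[i]) for i in range(len(phages))])
        weights /= weights.sum()
        rows_choice = rng.choice(len(phages), size=max_iters, p=weights)
        raw = rng.random(max_iters)
        for it in range(max_iters):
            iters = it + 1
            if obj == 0:
                break
            i = rows_choice[it]
            ones = np.flatnonzero(M[i, :cov_size])
            zeros = np.flatnonzero(~M[i, :cov_size])
            if len(ones) == 0 or len(zeros) == 0:
                continue
            s1 = ones[int(raw[it] * len(ones))]
            s0 = zeros[rng.integers(len(zeros))]
            delta = 0
            touched = []
            for ci in row_in[i]:
                u, t = unions[ci], targets[ci]
                du = 0
                if covers[ci][s1] == 1:
                    du -= 1
                if covers[ci][s0] == 0:
                    du += 1
                if du:
                    delta += (u + du - t) ** 2 - (u - t) ** 2
                touched.append((ci, du))
            temp = t_hi * (t_lo / t_hi) ** (it / max_iters)
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                M[i, s1] = False
                M[i, s0] = True
                for ci, du in touched:
                    covers[ci][s1] -= 1
                    covers[ci][s0] += 1
                    unions[ci] += du
                obj += delta
        if obj < best_obj:
            best_obj, best_M, best_iters = obj, M.copy(), iters
        if best_obj == 0:
            break

    assert best_M is not None
    strains = [f"S{j + 1:03d}" for j in range(n)]
    matrix = SusceptibilityMatrix.from_binary(phages, strains, best_M)
    report = ReconstructionReport(
        panel_size=n, tolerance_pp=spec.tolerance_pp,
        iterations=best_iters, restarts=used_restarts,
    )
    for name, rows, t, p in constraints:
        achieved = int(np.any(best_M[list(rows), :], axis=0).sum())
        report.add(name, p, t, achieved)
    return matrix, report


# -- plating simulation --------------------------------------------------------


def simulate_plating(
    true_frequency: float,
    total_cfu: float,
    seed: int,
    phage_ids: tuple[str, ...] = ("phage",),
    challenge_volume_ml: float = 0.1,
    dilutions: tuple[float, ...] = (1e-5, 1e-6),
    titration_volume_ml: float = 0.1,
    titration_replicates: int = 3,
) -> PlatingAssay:
    """Poisson plating counts at a known resistance frequency.

    Resistant colonies ~ Poisson(frequency x total CFU); titration counts
    are Poisson at the stated dilutions of the same culture.
    """
    if not 0 <= true_frequency < 1:
        raise PhageCocktailError("frequency must be in [0, 1)")
    if total_cfu <= 0:
        raise PhageCocktailError("total CFU must be > 0")
    rng = np.random.default_rng(seed)
    resistant = int(rng.poisson(true_frequency * total_cfu))
    density = total_cfu / challenge_volume_ml
    titration = []
    for d in dilutions:
        for r in range(titration_replicates):
            mean = density * d * titration_volume_ml
            titration.append(
                TitrationPlate(
                    dilution=d,
                    volume_ml=titration_volume_ml,
                    count=int(rng.poisson(mean)),
                    replicate_id=f"d{d:g}-r{r + 1}",
                )
            )
    return PlatingAssay(
        phage_ids=phage_ids,
        challenge_colonies=resistant,
        challenge_volume_ml=challenge_volume_ml,
        titration=tuple(titration),
    )


# -- receptor fixtures ---------------------------------------------------------


def make_receptor_fixture(
    class_code: int | str,
    noise: float = 0.0,
    seed: int = 0,
    phage_id: str = "synthetic-phage",
) -> MutantPanelResult:
    """A mutant-panel outcome map consistent with a receptor class.

    ``class_code`` 1-5 produces the loss pattern the class requirements
    imply; ``"unknown"`` produces a PAO1-nonpermissive pattern (no lysis
    anywhere).  ``noise`` flips each call independently with the given
    probability, to exercise inconsistency error paths.
    """
    if class_code != "unknown" and class_code not in CLASS_REQUIREMENTS:
        raise PhageCocktailError(f"unknown receptor class {class_code!r}")
    rng = np.random.default_rng(seed)
    wild = frozenset(FEATURES)
    outcomes: dict[str, str] = {}
    if class_code == "unknown":
        outcomes["wild_type"] = "no_lysis"
        for g in GENOTYPES:
            outcomes[g] = "no_lysis"
        outcomes["rmlC_b"] = "no_lysis"
    else:
        req = CLASS_REQUIREMENTS[class_code]
        outcomes["wild_type"] = "lysis"
        for g in GENOTYPES:
            feats = wild - MUTANT_LOSSES[g]
            outcomes[g] = "lysis" if req <= feats else "no_lysis"
        outcomes["rmlC_b"] = outcomes["rmlC"]
    if noise:
        for g in list(outcomes):
            if rng.random() < noise:
                outcomes[g] = "no_lysis" if outcomes[g] == "lysis" else "lysis"
    return MutantPanelResult(phage_id=phage_id, outcomes=outcomes)
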