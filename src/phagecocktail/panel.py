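"""Core data model: strain/phage catalogs and the phage x strain susceptibility matrix.

The susceptibility matrix is the central object of the pipeline: rows are
phages, columns are bacterial strains, and each cell records either a
qualitative plaque call (``clear`` / ``turbid`` / ``none``) or a quantitative
efficiency-of-plating (EOP) value.  Everything downstream — host-range
coverage, pairwise complementarity, cocktail optimization — runs on the
binary (susceptible/resistant) view derived from these entries.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MatrixParseError, MatrixValidationError

QUAL_CALLS = ("clear", "turbid", "none")
RESISTANCE_CLASSES = ("susceptible", "MDR", "XDR", "PDR", "unknown")
LIFESTYLE_VERDICTS = ("lytic", "temperate", "undetermined")
RECEPTOR_CLASSES = (1, 2, 3, 4, 5, "unknown")


@dataclass(frozen=True)
class StrainRecord:
    """One bacterial strain of the diversity panel."""

    strain_id: str
    sequence_type: str = "unknown"
    source: str = ""
    resistance_class: str = "unknown"
    core_panel_member: bool = False

    def __post_init__(self) -> None:
        if self.resistance_class not in RESISTANCE_CLASSES:
            raise MatrixValidationError(
                f"strain {self.strain_id!r}: resistance_class must be one of "
                f"{RESISTANCE_CLASSES}, got {self.resistance_class!r}"
            )


@dataclass(frozen=True)
class PhageRecord:
    """Catalog metadata for one phage.

    ``receptor_class`` is the five-class scheme (T4P plus an LPS moiety set);
    ``unknown`` is only legal with a recorded reason, e.g. the phage does not
    plate on the reference strain whose knockout mutants define the classes.
    ``lifestyle_score`` is the virulence-classifier fraction in [0, 1] and may
    be None where unreported; ``lifestyle_verdict`` carries the call that
    actually drives therapeutic eligibility.
    """

    phage_id: str
    genus: str
    family: str = "unclassified"
    genome_size: int = 0
    lifestyle_score: float | None = None
    lifestyle_verdict: str = "undetermined"
    receptor_class: int | str = "unknown"
    receptor_unknown_reason: str = ""
    anti_biofilm_dispersal: bool = False
    anti_biofilm_killing: bool = False

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise MatrixValidationError(
                f"phage {self.phage_id!r}: genome_size must be > 0"
            )
        if self.lifestyle_verdict not in LIFESTYLE_VERDICTS:
            raise MatrixValidationError(
                f"phage {self.phage_id!r}: bad lifestyle_verdict "
                f"{self.lifestyle_verdict!r}"
            )
        if self.lifestyle_score is not None and not 0 <= self.lifestyle_score <= 1:
            raise MatrixValidationError(
                f"phage {self.phage_id!r}: lifestyle_score outside [0, 1]"
            )
        if self.receptor_class not in RECEPTOR_CLASSES:
            raise MatrixValidationError(
                f"phage {self.phage_id!r}: receptor_class must be 1-5 or 'unknown'"
            )
        if self.receptor_class == "unknown" and not self.receptor_unknown_reason:
            raise MatrixValidationError(
                f"phage {self.phage_id!r}: receptor_class 'unknown' requires a "
                "recorded reason"
            )


@dataclass(frozen=True)
class Dialect:
    """Tabular format of a matrix file.

    ``cell_format`` is one of ``auto`` (infer per file), ``qualitative``
    (clear/turbid/none tokens), ``binary`` (1/0 tokens) or ``eop``
    (nonnegative floats).
    """

    delimiter: str = ","
    cell_format: str = "auto"

    @staticmethod
    def for_path(path: str | Path) -> "Dialect":
        return Dialect(delimiter="\t" if str(path).endswith((".tsv", ".tab")) else ",")


def _check_ids(ids: Sequence[str], kind: str) -> list[str]:
    out = [s.strip() for s in ids]
    if any(not s for s in out):
        raise MatrixValidationError(f"empty {kind} id")
    dupes = {s for s in out if out.count(s) > 1}
    if dupes:
        raise MatrixValidationError(f"duplicate {kind} id(s): {sorted(dupes)}")
    return out


class SusceptibilityMatrix:
    """Dense phage x strain matrix of plaque calls or EOP values.

    Entries are stored as a numpy object array; each cell is either one of
    the qualitative tokens or a nonnegative float (EOP).  The matrix is
    validated on construction: dimensions must match the id lists, ids must
    be unique after whitespace trimming (compared case-sensitively), and
    every entry must be present.
    """

    def __init__(
        self,
        phages: Sequence[str],
        strains: Sequence[str],
        entries: Sequence[Sequence[object]],
    ) -> None:
        self.phages = _check_ids(list(phages), "phage")
        self.strains = _check_ids(list(strains), "strain")
        arr = np.empty((len(self.phages), len(self.strains)), dtype=object)
        if len(entries) != len(self.phages):
            raise MatrixValidationError(
                f"entry rows ({len(entries)}) != number of phages ({len(self.phages)})"
            )
        for i, row in enumerate(entries):
            row = list(row)
            if len(row) != len(self.strains):
                raise MatrixValidationError(
                    f"row for phage {self.phages[i]!r} has {len(row)} entries, "
                    f"expected {len(self.strains)}"
                )
            for j, cell in enumerate(row):
                arr[i, j] = _validate_cell(cell, self.phages[i], self.strains[j])
        self.entries = arr

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_binary(
        cls,
        phages: Sequence[str],
        strains: Sequence[str],
        binary: np.ndarray,
    ) -> "SusceptibilityMatrix":
        """Build a qualitative matrix from a boolean array (True = clear lysis)."""
        binary = np.asarray(binary, dtype=bool)
        entries = np.where(binary, "clear", "none")
        return cls(phages, strains, entries.tolist())

    # -- views ----------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def phage_index(self, phage_id: str) -> int:
        try:
            return self.phages.index(phage_id)
        except ValueError:
            raise MatrixValidationError(f"unknown phage id {phage_id!r}") from None

    def is_quantitative(self) -> bool:
        return any(isinstance(c, float) for c in self.entries.flat)

    def is_qualitative(self) -> bool:
        return any(isinstance(c, str) for c in self.entries.flat)

    def binary_view(self, rule=None) -> np.ndarray:
        """Boolean susceptible/resistant view; see :func:`hostrange.binarize`."""
        from .hostrange import binarize

        return binarize(self, rule)

    # -- equality (used by round-trip tests) ----------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SusceptibilityMatrix):
            return NotImplemented
        return (
            self.phages == other.phages
            and self.strains == other.strains
            and bool(np.all(self.entries == other.entries))
        )

    def __repr__(self) -> str:
        return (
            f"<SusceptibilityMatrix {len(self.phages)} phages x "
            f"{len(self.strains)} strains>"
        )


def _validate_cell(cell: object, phage: str, strain: str) -> object:
    if isinstance(cell, str):
        tok = cell.strip()
        if tok in QUAL_CALLS:
            return tok
        if tok in ("1", "0"):
            return "clear" if tok == "1" else "none"
        try:
            cell = float(tok)
        except ValueError:
            raise MatrixParseError(
                f"unknown cell token {tok!r} at (phage {phage!r}, strain {strain!r})"
            ) from None
    if isinstance(cell, bool) or isinstance(cell, (int, np.integer)):
        cell = float(cell)
    if isinstance(cell, (float, np.floating)):
        v = float(cell)
        if not np.isfinite(v) or v < 0:
            raise MatrixValidationError(
                f"EOP must be finite and >= 0 at (phage {phage!r}, strain "
                f"{strain!r}), got {v}"
            )
        return v
    raise MatrixParseError(
        f"unsupported cell value {cell!r} at (phage {phage!r}, strain {strain!r})"
    )


# -- file I/O -----------------------------------------------------------------


def read_matrix(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    known_phages: Iterable[str] | None = None,
    known_strains: Iterable[str] | None = None,
) -> SusceptibilityMatrix:
    """Read a delimited matrix file: first row strain ids, first column phage ids.

    The transposed orientation (strain rows x phage columns) is auto-detected
    only when ``known_phages``/``known_strains`` disambiguate it; an ambiguous
    layout is rejected rather than silently transposed.
    """
    path = Path(path)
    dialect = dialect or Dialect.for_path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=dialect.delimiter))
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    width = len(rows[0])
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixParseError(
                f"{path}: ragged row {k} ({len(row)} fields, expected {width})"
            )
    header = [h.strip() for h in rows[0][1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    cells = [r[1:] for r in rows[1:]]

    if known_phages is not None or known_strains is not None:
        kp = set(known_phages or ())
        ks = set(known_strains or ())
        as_is = (not kp or set(row_ids) <= kp) and (not ks or set(header) <= ks)
        flipped = (not kp or set(header) <= kp) and (not ks or set(row_ids) <= ks)
        if flipped and not as_is:
            row_ids, header = header, row_ids
            cells = [list(col) for col in zip(*cells)]
        elif not as_is and not flipped:
            raise MatrixValidationError(
                f"{path}: ids match neither orientation against the catalogs"
            )
        elif as_is and flipped and kp and ks:
            raise MatrixValidationError(
                f"{path}: orientation ambiguous — ids valid both ways"
            )
    try:
        return SusceptibilityMatrix(row_ids, header, cells)
    except (MatrixParseError, MatrixValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_matrix(
    matrix: SusceptibilityMatrix, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a matrix so that :func:`read_matrix` recovers an identical object."""
    path = Path(path)
    dialect = dialect or Dialect.for_path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow(["phage_id", *matrix.strains])
        for i, pid in enumerate(matrix.phages):
            row: list[object] = [pid]
            for cell in matrix.entries[i]:
                if isinstance(cell, float):
                    row.append(repr(cell))
                elif dialect.cell_format == "binary":
                    row.append("1" if cell == "clear" else "0")
                else:
                    row.append(cell)
            w.writerow(row)


# -- catalog validation -------------------------------------------------------


@dataclass
class ValidationReport:
    """Machine-readable reconciliation of matrix ids against catalogs."""

    unresolved_phages: list[str] = field(default_factory=list)
    uncataloged_phages: list[str] = field(default_factory=list)
    unresolved_strains: list[str] = field(default_factory=list)
    uncataloged_strains: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.unresolved_phages
            or self.unresolved_strains
            or self.uncataloged_phages
            or self.uncataloged_strains
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def validate_catalogs(
    matrix: SusceptibilityMatrix,
    phages: Sequence[PhageRecord],
    strains: Sequence[StrainRecord] | None = None,
) -> ValidationReport:
    """Resolve every matrix id against the catalogs; report-only, never raises."""
    phage_ids = {p.phage_id for p in phages}
    rep = ValidationReport()
    rep.unresolved_phages = sorted(set(matrix.phages) - phage_ids)
    rep.uncataloged_phages = sorted(phage_ids - set(matrix.phages))
    if strains is not None:
        strain_ids = {s.strain_id for s in strains}
        rep.unresolved_strains = sorted(set(matrix.strains) - strain_ids)
        rep.uncataloged_strains = sorted(strain_ids - set(matrix.strains))
    return rep


# -- catalog file readers -----------------------------------------------------

_CATALOG_COLUMNS = [
    "phage_id",
    "genus",
    "family",
    "genome_size_bp",
    "lifestyle_score",
    "lifestyle_verdict",
    "receptor_class",
    "dispersal",
    "killing",
]


def read_phage_catalog(path: str | Path | io.TextIOBase) -> list[PhageRecord]:
    """Read the fixed-column phage catalog CSV.

    Columns: phage_id, genus, family, genome_size_bp, lifestyle_score,
    lifestyle_verdict, receptor_class, dispersal, killing, and optionally
    receptor_unknown_reason.
    """
    if isinstance(path, (str, Path)):
        fh = open(path, newline="")
        close = True
    else:
        fh, close = path, False
    try:
        reader = csv.DictReader(fh)
        missing = set(_CATALOG_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise MatrixValidationError(
                f"phage catalog missing columns: {sorted(missing)}"
            )
        records = []
        for row in reader:
            rc: int | str = row["receptor_class"].strip()
            rc = int(rc) if rc.isdigit() else "unknown"
            score = row["lifestyle_score"].strip()
            records.append(
                PhageRecord(
                    phage_id=row["phage_id"].strip(),
                    genus=row["genus"].strip(),
                    family=row["family"].strip() or "unclassified",
                    genome_size=int(row["genome_size_bp"]),
                    lifestyle_score=float(score) if score else None,
                    lifestyle_verdict=row["lifestyle_verdict"].strip(),
                    receptor_class=rc,
                    receptor_unknown_reason=row.get(
                        "receptor_unknown_reason", ""
                    ).strip(),
                    anti_biofilm_dispersal=row["dispersal"].strip() in ("1", "+", "true"),
                    anti_biofilm_killing=row["killing"].strip() in ("1", "+", "true"),
                )
            )
    finally:
        if close:
            fh.close()
    ids = [r.phage_id for r in records]
    _check_ids(ids, "phage")
    return records


def read_strain_catalog(path: str | Path) -> list[StrainRecord]:
    """Read a strain catalog CSV: strain_id, sequence_type, source,
    resistance_class, core_panel_member."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        records = [
            StrainRecord(
                strain_id=row["strain_id"].strip(),
                sequence_type=row.get("sequence_type", "unknown").strip(),
                source=row.get("source", "").strip(),
                resistance_class=row.get("resistance_class", "unknown").strip(),
                core_panel_member=row.get("core_panel_member", "").strip()
                in ("1", "true", "True"),
            )
            for row in reader
        ]
    _check_ids([r.strain_id for r in records], "strain")
    return records
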