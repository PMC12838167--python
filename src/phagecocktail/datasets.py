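"""Accessors for the published characterization tables shipped with the
package: the 25-phage catalog, per-phage host ranges, pairwise mix host
ranges, and the single/mix resistance-frequency table for the seven cocktail
candidates.  These are the inputs the design pipeline was built around; the
strain-level susceptibility matrix itself is not published and is
reconstructed from these marginals (see :mod:`phagecocktail.simulate`)."""

from __future__ import annotations

import csv
import io
from importlib import resources

from .panel import PhageRecord, read_phage_catalog
from .resistance import InteractionCall, ResistanceEstimate, interaction_call

PAM1 = ("EPa2", "EPa4", "EPa5", "EPa6", "EPa17")
PAM2 = ("EPa11", "EPa17", "EPa22", "EPa24", "EPa43")
MIX7 = ("EPa11", "EPa16", "EPa17", "EPa22", "EPa24", "EPa40", "EPa43")


def _data_text(name: str) -> str:
    return (resources.files("phagecocktail") / "data" / name).read_text()


def phage_catalog() -> list[PhageRecord]:
    """The published 25-phage catalog (genus, family, lifestyle, receptor
    class, anti-biofilm flags)."""
    return read_phage_catalog(io.StringIO(_data_text("phage_catalog.csv")))


def published_host_ranges() -> dict[str, float]:
    """Per-phage host-range percentages on the 156-strain diversity panel."""
    reader = csv.DictReader(io.StringIO(_data_text("phage_catalog.csv")))
    return {r["phage_id"]: float(r["host_range_percent"]) for r in reader}


def genus_prevalence(records: list[PhageRecord] | None = None) -> dict[str, dict]:
    """Tally of phages per genus with round percentages of the panel."""
    records = records if records is not None else phage_catalog()
    n = len(records)
    out: dict[str, dict] = {}
    for rec in records:
        entry = out.setdefault(rec.genus, {"count": 0, "percent": 0.0})
        entry["count"] += 1
    for entry in out.values():
        entry["percent"] = round(100.0 * entry["count"] / n, 1)
    return out


def resistance_table() -> tuple[
    dict[str, ResistanceEstimate], dict[tuple[str, str], ResistanceEstimate]
]:
    """Published single and pairwise-mix resistance frequencies.

    Returns (singles, mixes); censored entries are detection-limit bounds.
    """
    singles: dict[str, ResistanceEstimate] = {}
    mixes: dict[tuple[str, str], ResistanceEstimate] = {}
    for row in csv.DictReader(io.StringIO(_data_text("resistance_frequencies.csv"))):
        a, b = row["phage_a"], row["phage_b"]
        singles.setdefault(
            a,
            ResistanceEstimate(
                value=float(row["single_a"]), censored=row["single_a_censored"] == "1"
            ),
        )
        singles.setdefault(
            b,
            ResistanceEstimate(
                value=float(row["single_b"]), censored=row["single_b_censored"] == "1"
            ),
        )
        mixes[(a, b)] = ResistanceEstimate(
            value=float(row["mix"]), censored=row["mix_censored"] == "1"
        )
    return singles, mixes


def interaction_calls(
    synergy_threshold: float = 0.5, antagonism_factor: float = 10.0
) -> list[InteractionCall]:
    """Interaction classification of every published pair."""
    singles, mixes = resistance_table()
    return [
        interaction_call(
            singles[a], singles[b], mix, pair=(a, b),
            synergy_threshold=synergy_threshold,
            antagonism_factor=antagonism_factor,
        )
        for (a, b), mix in mixes.items()
    ]
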