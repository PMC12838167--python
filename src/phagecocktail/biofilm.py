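"""Biofilm assays: crystal-violet dispersal and bactericidal log reduction.

Dispersal is quantified as the percent reduction of mean eluted-dye optical
density (OD595) in phage-treated versus no-phage control wells, and called
only when the reduction clears an effect floor *and* a two-sample location
test rejects at the configured alpha.  Bactericidal effect is the log10
reduction in viable counts, with colony counts back-calculated from serial
dilutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import PhageCocktailError

DEFAULT_EFFECT_FLOOR_PERCENT = 20.0
DEFAULT_ALPHA = 0.05


def cfu_per_ml(colonies: int, dilution: float, volume_plated_ml: float) -> float:
    """Viable count density: colonies / (dilution x plated volume)."""
    if not 0 < dilution <= 1:
        raise PhageCocktailError(f"dilution must be in (0, 1], got {dilution}")
    if volume_plated_ml <= 0:
        raise PhageCocktailError("plated volume must be > 0")
    if colonies < 0:
        raise PhageCocktailError("colony count must be >= 0")
    return colonies / (dilution * volume_plated_ml)


@dataclass(frozen=True)
class DilutionPlate:
    dilution: float
    volume_plated_ml: float
    colonies: int


def countable_plate(plates: Sequence[DilutionPlate]) -> DilutionPlate | None:
    """Pick the most concentrated dilution giving easily countable colonies.

    Among plates with 3-300 colonies the least-diluted one (largest dilution
    factor) wins; ties break toward more colonies.  Returns None when no
    plate is countable.
    """
    ok = [p for p in plates if 3 <= p.colonies <= 300]
    if not ok:
        return None
    return max(ok, key=lambda p: (p.dilution, p.colonies))


@dataclass(frozen=True)
class CfuReduction:
    phage_id: str
    strain_id: str
    control_cfu_ml: float
    treated_cfu_ml: float | None  # None = below LOD
    treated_lod: float | None
    log10_reduction: float
    censored: bool  # True: reduction is a ">=" bound via the LOD

    def __str__(self) -> str:
        ge = ">=" if self.censored else ""
        return f"{ge}{self.log10_reduction:.1f} logs"


def log_reduction(
    control_cfu_ml: float,
    treated_cfu_ml: float | None,
    treated_lod: float | None = None,
    phage_id: str = "",
    strain_id: str = "",
) -> CfuReduction:
    """Signed log10(control/treated); a below-LOD treated count yields a
    censored '>=' bound computed against the LOD."""
    if control_cfu_ml <= 0:
        raise PhageCocktailError("control count must be > 0 and uncensored")
    if treated_cfu_ml is None:
        if treated_lod is None or treated_lod <= 0:
            raise PhageCocktailError("below-LOD treated count needs a positive LOD")
        return CfuReduction(
            phage_id, strain_id, control_cfu_ml, None, treated_lod,
            math.log10(control_cfu_ml / treated_lod), censored=True,
        )
    if treated_cfu_ml <= 0:
        raise PhageCocktailError("nonpositive treated count without LOD flag")
    return CfuReduction(
        phage_id, strain_id, control_cfu_ml, treated_cfu_ml, None,
        math.log10(control_cfu_ml / treated_cfu_ml), censored=False,
    )


@dataclass(frozen=True)
class CrystalVioletAssay:
    phage_id: str
    strain_id: str
    treated_od: tuple[float, ...]
    control_od: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.treated_od) < 3 or len(self.control_od) < 3:
            raise PhageCocktailError("need >= 3 replicates in each arm")
        if any(v < 0 for v in (*self.treated_od, *self.control_od)):
            raise PhageCocktailError("optical densities must be >= 0")


@dataclass(frozen=True)
class DispersalResult:
    phage_id: str
    strain_id: str
    percent_reduction: float
    p_value: float
    dispersal: bool
    effect_floor_percent: float
    alpha: float


def dispersal_test(
    assay: CrystalVioletAssay,
    effect_floor_percent: float = DEFAULT_EFFECT_FLOOR_PERCENT,
    alpha: float = DEFAULT_ALPHA,
    method: str = "mannwhitney",
) -> DispersalResult:
    """Percent OD reduction plus a dispersal call.

    The call requires the mean reduction to exceed the effect floor and a
    one-sided rank test (treated < control; Welch t available via
    ``method='welch'``) to reject at ``alpha``.
    """
    ctrl = np.asarray(assay.control_od, dtype=float)
    trt = np.asarray(assay.treated_od, dtype=float)
    if ctrl.mean() == 0:
        raise PhageCocktailError("degenerate control arm: zero mean OD")
    reduction = 100.0 * (ctrl.mean() - trt.mean()) / ctrl.mean()
    if np.ptp(ctrl) == 0 and np.ptp(trt) == 0 and ctrl.mean() == trt.mean():
        p = 1.0  # identical constant arms carry no evidence
    elif method == "welch":
        p = stats.ttest_ind(trt, ctrl, equal_var=False, alternative="less").pvalue
    elif method == "mannwhitney":
        p = stats.mannwhitneyu(trt, ctrl, alternative="less").pvalue
    else:
        raise PhageCocktailError(f"unknown dispersal test method {method!r}")
    return DispersalResult(
        phage_id=assay.phage_id,
        strain_id=assay.strain_id,
        percent_reduction=float(reduction),
        p_value=float(p),
        dispersal=bool(reduction >= effect_floor_percent and p < alpha),
        effect_floor_percent=effect_floor_percent,
        alpha=alpha,
    )
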