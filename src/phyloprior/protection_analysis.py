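"""Protected-area coverage of hotspots: scenarios, F_PA and gap species.

A cell counts as protected either as soon as it intersects any protected
area (*minimum* scenario) or only when more than half of its area is covered
(*strong* scenario, strict at exactly 50 %).  Both are evaluated against all
protected areas and against the subset of IUCN management categories I, II
and IV, whose objectives directly target species protection.  F_PA compares
the observed proportion of protected hotspot cells with equal-size random
cell sets and classifies the hotspot network as under-protected
(F_PA ≤ 0.25), as expected (0.25 < F_PA ≤ 0.75) or over-protected
(F_PA > 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import null_models as nm
from .assemblage import AssemblageMatrix
from .hotspot_selection import HotspotSet

__all__ = [
    "ProtectionLayer",
    "load_protection_layer",
    "protected_flags",
    "classify_f_pa",
    "f_pa",
    "FPaResult",
    "species_gap",
]

SCENARIOS = ("minimum", "strong")
CATEGORY_SETS = ("all", "i_ii_iv")


class ProtectionLayer:
    """Per-cell protected-area coverage under the two category sets."""

    REQUIRED = ("covered_fraction_all", "covered_fraction_i_ii_iv")

    def __init__(self, frame: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"protection layer missing column {col!r}")
        frame = frame.copy()
        for col in self.REQUIRED:
            vals = frame[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1) | ~np.isfinite(vals)):
                raise ValueError(f"{col} values must lie in [0, 1]")
        if np.any(
            frame["covered_fraction_i_ii_iv"].to_numpy()
            > frame["covered_fraction_all"].to_numpy() + 1e-12
        ):
            raise ValueError("category I/II/IV coverage cannot exceed total coverage")
        for cat in CATEGORY_SETS:
            icol, fcol = f"intersects_{cat}", f"covered_fraction_{cat}"
            if icol not in frame.columns:
                frame[icol] = (frame[fcol] > 0).astype(int)
            else:
                bad = (frame[fcol] > 0) & (frame[icol] == 0)
                if bad.any():
                    raise ValueError(f"{icol} must be 1 wherever {fcol} > 0")
        self.frame = frame

    @property
    def cells(self) -> list:
        return list(self.frame.index)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="cell")


def load_protection_layer(path) -> ProtectionLayer:
    return ProtectionLayer(pd.read_csv(path, index_col=0))


def protected_flags(layer: ProtectionLayer, scenario: str, categories: str) -> pd.Series:
    """0/1 protected flag per cell for a scenario × category-set choice."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if categories not in CATEGORY_SETS:
        raise ValueError(f"unknown category set {categories!r}")
    if scenario == "minimum":
        flags = layer.frame[f"intersects_{categories}"].astype(int)
    else:  # strong: strictly more than half the cell covered
        flags = (layer.frame[f"covered_fraction_{categories}"] > 0.5).astype(int)
    return flags.rename("protected")


def classify_f_pa(value: float) -> str:
    """Efficiency class on the half-open intervals (ties at 0.25/0.75 go down)."""
    if value <= 0.25:
        return "under"
    if value <= 0.75:
        return "as_expected"
    return "over"


@dataclass
class FPaResult:
    observed_proportion: float
    f_pa: float
    efficiency: str
    degenerate_ties: bool  # every null replicate equalled the observed value


def f_pa(
    hotspots: HotspotSet,
    flags: pd.Series,
    n_rep: int = 1000,
    seed: int = 0,
) -> FPaResult:
    """Randomization test of hotspot protection.

    ``observed`` is the proportion of hotspot cells flagged protected; the
    null designates equal-size random cell sets as hotspots.  F_PA uses a
    strict ``>``, so a fully tied null (e.g. every cell protected) gives
    F_PA = 0; that case is flagged so an "under-protected" reading is not
    taken at face value.
    """
    if len(hotspots) == 0:
        raise ValueError("hotspot set is empty")
    observed = float(flags.loc[hotspots.cells].mean())
    draws = nm.random_cell_sets(list(flags.index), len(hotspots), n_rep, seed=seed)
    sims = np.array([flags.loc[d].mean() for d in draws])
    value = float((observed > sims).mean())
    return FPaResult(
        observed_proportion=observed,
        f_pa=value,
        efficiency=classify_f_pa(value),
        degenerate_ties=bool(np.all(sims == observed)),
    )


def species_gap(matrix: AssemblageMatrix, flags: pd.Series, top_set) -> set[str]:
    """Top-priority species whose entire range lies in unprotected cells."""
    unprotected = flags.loc[matrix.cells].to_numpy() == 0
    gap = set()
    for sp in top_set:
        if sp not in matrix.species:
            continue
        occ = matrix.frame[sp].to_numpy(dtype=bool)
        if occ.any() and np.all(unprotected[occ]):
            gap.add(sp)
    return gap
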