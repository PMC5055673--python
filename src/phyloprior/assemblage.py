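"""Grid-level bookkeeping: occurrence matrix and per-cell score table.

The spatial unit is an abstract grid cell; the binary cells × species
occurrence matrix is the interface to whatever GIS produced it.  Per-cell
aggregation follows the hotspot protocol: Expected PD-loss of the cell
assemblage, sums of species HEDGE and BED scores, species-richness
surrogates, and counts of "top" species (the top decile by score).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import phylo_metrics as pm
from .phylo_metrics import Phylogeny, THREATENED_CATEGORIES

__all__ = ["AssemblageMatrix", "load_matrix", "top_species", "restricted_species", "cell_scores"]

logger = logging.getLogger(__name__)


class AssemblageMatrix:
    """Binary cells × species occurrence matrix with labelled axes."""

    def __init__(self, frame: pd.DataFrame, drop_empty_species: bool = True):
        values = frame.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            c, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary occurrence entry {values[c, s]!r} at "
                f"cell {frame.index[c]!r}, species {frame.columns[s]!r}"
            )
        if frame.index.duplicated().any() or frame.columns.duplicated().any():
            raise ValueError("duplicate cell or species labels in occurrence matrix")
        frame = frame.astype(np.int8)
        empty = frame.columns[frame.sum(axis=0) == 0]
        if len(empty) and drop_empty_species:
            logger.warning("dropping %d species with no occurrences", len(empty))
            frame = frame.drop(columns=empty)
        self.frame = frame

    # -- axes --------------------------------------------------------------

    @property
    def cells(self) -> list:
        return list(self.frame.index)

    @property
    def species(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_cells(self) -> int:
        return self.frame.shape[0]

    def richness(self) -> pd.Series:
        return self.frame.sum(axis=1).rename("richness")

    def range_sizes(self) -> pd.Series:
        """Occupied-cell count per species."""
        return self.frame.sum(axis=0).rename("range_size")

    def cell_species(self, cell) -> set[str]:
        row = self.frame.loc[cell]
        return set(row.index[row > 0])

    def occupancy(self, species_order) -> np.ndarray:
        """Cells × species boolean array in the given species order.

        Species not present as columns (e.g. tips of the tree missing from
        the matrix) come back as all-False columns; callers that require
        non-empty ranges validate downstream.
        """
        out = np.zeros((self.n_cells, len(species_order)), dtype=bool)
        cols = {s: i for i, s in enumerate(self.frame.columns)}
        vals = self.frame.to_numpy(dtype=bool)
        for j, s in enumerate(species_order):
            if s in cols:
                out[:, j] = vals[:, cols[s]]
        return out

    def restrict_species(self, keep) -> "AssemblageMatrix":
        keep = [s for s in self.frame.columns if s in set(keep)]
        return AssemblageMatrix(self.frame[keep], drop_empty_species=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="cell")


def load_matrix(path, tree: Phylogeny | None = None) -> AssemblageMatrix:
    """Read a cells × species 0/1 CSV (first column = cell id).

    When a tree is given, matrix species absent from its tips are reported
    and dropped (a count is logged), mirroring the usual mismatch between
    range maps and phylogenies.
    """
    frame = pd.read_csv(path, index_col=0)
    mat = AssemblageMatrix(frame)
    if tree is not None:
        tips = set(tree.tips)
        missing = [s for s in mat.species if s not in tips]
        if missing:
            logger.warning(
                "dropping %d matrix species absent from the phylogeny: %s",
                len(missing), missing[:10],
            )
            mat = AssemblageMatrix(mat.frame.drop(columns=missing), drop_empty_species=False)
    return mat


def top_species(scores: pd.Series, fraction: float = 0.10) -> set[str]:
    """The ``⌈fraction × n⌉`` species with the highest scores.

    Ties at the cutoff are broken by species id (lexicographic) so the set is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(scores) == 0:
        raise ValueError("empty score table")
    k = math.ceil(fraction * len(scores))
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    return set(order[:k])


def restricted_species(range_sizes: pd.Series, fraction: float = 0.10) -> set[str]:
    """The top ``fraction`` of species with the *smallest* ranges (ties by id)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(range_sizes) == 0:
        raise ValueError("empty range-size table")
    k = math.ceil(fraction * len(range_sizes))
    order = sorted(range_sizes.index, key=lambda s: (range_sizes[s], s))
    return set(order[:k])


def cell_scores(
    tree: Phylogeny,
    matrix: AssemblageMatrix,
    species_table: pd.DataFrame,
    probs: pd.Series,
    hedge_scores: pd.Series,
    bed_scores: pd.Series,
    top_fraction: float = 0.10,
    rooting: str = "regional_root",
) -> pd.DataFrame:
    """Per-cell score table.

    ``probs`` covers the probabilistic-index species pool (DD/EX/RE/NA
    already filtered out); ``hedge_scores`` and ``bed_scores`` are the
    per-species scores on their respective pools.  Per cell this computes:

    * ``exp_pd_loss`` — Expected PD-loss of the cell assemblage;
    * ``sum_hedge`` / ``sum_bed`` — sums of species scores present
      (the randomization statistic of the identity-shuffle null);
    * ``richness`` and the surrogates ``threatened_richness`` (CR/EN/VU
      present) and ``restricted_richness`` (present members of the top
      decile of smallest ranges);
    * ``n_top_hedge`` / ``n_top_bed`` — counts of top-decile species present.

    Empty cells score 0 everywhere.
    """
    bt = tree.branch_table()
    occ = matrix.occupancy(bt.tips)

    scored = np.array([t in probs.index and not pd.isna(probs[t]) for t in bt.tips])
    loss = pm.expected_pd_loss_cells(tree, probs, occ & scored, rooting=rooting)

    def _present_sum(scores: pd.Series) -> np.ndarray:
        vec = np.array([float(scores.get(t, 0.0)) for t in bt.tips])
        has = np.array([t in scores.index for t in bt.tips])
        return (occ & has) @ vec

    tops_hedge = top_species(hedge_scores, top_fraction)
    tops_bed = top_species(bed_scores, top_fraction)
    ranges = matrix.range_sizes()
    restricted = restricted_species(ranges, top_fraction)
    cats = species_table["iucn_category"]
    threatened = set(cats.index[cats.isin(THREATENED_CATEGORIES)])

    full = matrix.occupancy(matrix.species)

    def _present_count(group: set) -> np.ndarray:
        mask = np.array([s in group for s in matrix.species])
        return (full & mask).sum(axis=1)

    table = pd.DataFrame(
        {
            "exp_pd_loss": loss,
            "sum_hedge": _present_sum(hedge_scores),
            "sum_bed": _present_sum(bed_scores),
            "richness": full.sum(axis=1),
            "threatened_richness": _present_count(threatened),
            "restricted_richness": _present_count(restricted),
            "n_top_hedge": _present_count(tops_hedge),
            "n_top_bed": _present_count(tops_bed),
        },
        index=pd.Index(matrix.cells, name="cell"),
    )
    return table
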