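"""Hotspot selection, complementarity capture, surrogacy and sensitivity.

Cells are ranked by their F-value with raw scores breaking ties, and the
top 17 % (the CBD Aïchi land-protection target) become hotspots.  An
alternative, threshold-based selection is provided for hotspot definitions
independent of the areal target.  Downstream checks quantify how much of the
regional threatened/endemic evolutionary history the combined hotspots
capture (against equal-size random cell sets), how the indices correlate
with plain richness surrogates, and how robust cell rankings are to the
placement of species grafted into the tree as within-genus polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import assemblage as asm
from . import null_models as nm
from . import phylo_metrics as pm
from .assemblage import AssemblageMatrix
from .phylo_metrics import Phylogeny

__all__ = [
    "HotspotSet",
    "INDEX_COLUMNS",
    "rank_cells",
    "select_aichi",
    "select_alternative",
    "capture_complementarity",
    "richness_correlations",
    "polytomy_sensitivity",
]

#: index name -> (F column, raw score column, top-count column) of the cell table
INDEX_COLUMNS = {
    "exp_pdloss": ("f_exp_pd_loss", "exp_pd_loss", None),
    "hedge": ("f_sum_hedge", "sum_hedge", "n_top_hedge"),
    "bed": ("f_sum_bed", "sum_bed", "n_top_bed"),
}


@dataclass
class HotspotSet:
    index: str
    rule: str                      # "aichi_17" | "alternative"
    cells: list = field(default_factory=list)
    fraction: float | None = None
    seed: int | None = None
    n_rep: int | None = None

    def __len__(self) -> int:
        return len(self.cells)


def _columns(index: str):
    try:
        return INDEX_COLUMNS[index]
    except KeyError:
        raise ValueError(f"unknown index {index!r}") from None


def rank_cells(table: pd.DataFrame, index: str) -> list:
    """Cells ordered best-first: F descending, raw score descending, id ascending."""
    f_col, raw_col, _ = _columns(index)
    order = sorted(
        table.index,
        key=lambda c: (-table.at[c, f_col], -table.at[c, raw_col], str(c)),
    )
    return order


def select_aichi(ranked_cells, fraction: float = 0.17) -> HotspotSet:
    """The top ``fraction`` of ranked cells, size rounded half-up."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(ranked_cells)
    k = int(np.floor(fraction * n + 0.5))
    if k == 0:
        raise ValueError(f"selection of 0 cells (fraction {fraction}, {n} cells)")
    return HotspotSet(index="", rule="aichi_17", cells=list(ranked_cells)[:k], fraction=fraction)


def select_alternative(table: pd.DataFrame, index: str) -> HotspotSet:
    """Threshold-based hotspots independent of the areal target.

    Expected PD-loss: cells above the mean raw value with F ≥ 0.5.
    HEDGE/BED: cells holding at least one top-decile species with F ≥ 0.5.
    The selected set may be larger or smaller than 17 % of cells.
    """
    f_col, raw_col, top_col = _columns(index)
    f_ok = table[f_col] >= 0.5
    if index == "exp_pdloss":
        keep = (table[raw_col] > table[raw_col].mean()) & f_ok
    else:
        keep = (table[top_col] >= 1) & f_ok
    cells = [c for c in table.index if keep[c]]
    return HotspotSet(index=index, rule="alternative", cells=cells)


def _pooled_metric(
    index: str,
    pool: set,
    tree: Phylogeny,
    probs: pd.Series | None,
    scores: pd.Series | None,
    rooting: str,
) -> float:
    if index == "exp_pdloss":
        usable = sorted(s for s in pool if s in probs.index and not pd.isna(probs[s]))
        return pm.expected_pd_loss(tree, probs, usable, rooting=rooting) if usable else 0.0
    usable = [s for s in pool if s in scores.index]
    return float(scores.loc[usable].sum())


def capture_complementarity(
    hotspots: HotspotSet,
    index: str,
    tree: Phylogeny,
    matrix: AssemblageMatrix,
    probs: pd.Series | None = None,
    scores: pd.Series | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    rooting: str = "regional_root",
) -> tuple[float, float]:
    """Share of the regional metric captured by the combined hotspots.

    The observed value pools the species occurring in at least one hotspot
    cell and evaluates the index on that pool, as a percentage of the value
    on the full regional pool.  The p-value is the frequency with which
    equal-size random cell sets capture at least as much (ties favour the
    null, hence ``≥``).
    """
    if len(hotspots) == 0:
        raise ValueError("hotspot set is empty")
    occ = matrix.frame

    def pooled(cell_set) -> float:
        sub = occ.loc[list(cell_set)]
        pool = set(sub.columns[(sub > 0).any(axis=0)])
        return _pooled_metric(index, pool, tree, probs, scores, rooting)

    regional = _pooled_metric(index, set(matrix.species), tree, probs, scores, rooting)
    observed_raw = pooled(hotspots.cells)
    observed = 100.0 * observed_raw / regional if regional > 0 else 0.0

    draws = nm.random_cell_sets(matrix.cells, len(hotspots), n_rep, seed=seed)
    hits = sum(1 for d in draws if pooled(d) >= observed_raw)
    return observed, hits / n_rep


def richness_correlations(table: pd.DataFrame, pd_per_cell: pd.Series) -> pd.DataFrame:
    """Spearman correlations between richness surrogates and the indices.

    Rows: (richness, PD), (threatened richness, Expected PD-loss),
    (threatened richness, ΣHEDGE), (restricted richness, ΣBED); mid-rank
    ties, two-sided p-values.  Constant vectors yield an undefined rho,
    flagged as NaN with ``degenerate=True``.
    """
    pairs = [
        ("richness", table["richness"], "pd", pd_per_cell.loc[table.index]),
        ("threatened_richness", table["threatened_richness"], "exp_pd_loss", table["exp_pd_loss"]),
        ("threatened_richness", table["threatened_richness"], "sum_hedge", table["sum_hedge"]),
        ("restricted_richness", table["restricted_richness"], "sum_bed", table["sum_bed"]),
    ]
    rows = []
    for xname, x, yname, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        degenerate = np.std(x) == 0 or np.std(y) == 0
        if degenerate:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append(
            {"surrogate": xname, "index": yname, "rho": rho, "p_value": p, "degenerate": degenerate}
        )
    return pd.DataFrame(rows)


def polytomy_sensitivity(
    base_tree: Phylogeny,
    missing: pd.DataFrame,
    matrix: AssemblageMatrix,
    species_table: pd.DataFrame,
    probs_by_species: pd.Series,
    n_rep: int = 100,
    seed: int = 0,
    top_fraction: float = 0.10,
    bed_variant: str = "union_range",
    rooting: str = "regional_root",
) -> dict[str, np.ndarray]:
    """Robustness of cell scores to the placement of grafted species.

    ``missing`` is a DataFrame indexed by species id with a ``genus`` column:
    species absent from ``base_tree`` that are grafted as within-genus
    polytomies.  The observed configuration grafts each at its genus MRCA;
    each replicate regrafts all of them at random within-genus positions and
    the per-cell raw scores are re-computed.  Returns, per index, the
    distribution over replicates of the Spearman correlation between the
    replicate's cell-score ranking and the observed one.  With no missing
    species every replicate is identical to the observed tree and all
    correlations are exactly 1.
    """
    genus_of_tip = species_table["genus"]

    def genus_members(tree: Phylogeny, genus: str) -> list[str]:
        members = [
            t for t in tree.tips if genus_of_tip.get(t) == genus
        ]
        if not members:
            raise pm.PhylogenyError(f"genus {genus!r} absent from tree")
        return members

    def grafted(mode: str, graft_seed: int) -> Phylogeny:
        tree = base_tree
        for i, (sp, row) in enumerate(missing.iterrows()):
            tree = pm.graft_polytomy(
                tree, sp, genus_members(tree, row["genus"]),
                mode=mode, seed=graft_seed + i,
            )
        return tree

    def score_cells(tree: Phylogeny) -> pd.DataFrame:
        mat = matrix.restrict_species(tree.tips)
        probs = probs_by_species.loc[[s for s in tree.tips if s in probs_by_species.index]]
        hh = pm.hed_hedge(tree.prune_to(list(probs.index)), probs) if len(probs) else None
        hedge = hh["hedge"] if hh is not None else pd.Series(dtype=float)
        bed_pool = [s for s in tree.tips if s in mat.species]
        bed = pm.bed(tree.prune_to(bed_pool), mat.restrict_species(bed_pool), variant=bed_variant)
        return asm.cell_scores(
            tree, mat, species_table, probs, hedge, bed,
            top_fraction=top_fraction, rooting=rooting,
        )

    if len(missing) == 0:
        return {idx: np.ones(n_rep) for idx in ("exp_pdloss", "hedge", "bed")}

    observed = score_cells(grafted("mrca_polytomy", seed))
    rng = np.random.default_rng(seed)
    out = {"exp_pdloss": [], "hedge": [], "bed": []}
    col = {"exp_pdloss": "exp_pd_loss", "hedge": "sum_hedge", "bed": "sum_bed"}
    for _ in range(n_rep):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep = score_cells(grafted("random_within_genus", rep_seed))
        for idx, c in col.items():
            x, y = observed[c].to_numpy(), rep[c].to_numpy()
            if np.std(x) == 0 and np.std(y) == 0:
                rho = 1.0
            else:
                rho = stats.spearmanr(x, y).statistic
            out[idx].append(rho)
    return {k: np.asarray(v) for k, v in out.items()}
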