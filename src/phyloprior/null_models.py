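"""Randomization null models and F-values.

Two complementary nulls localize hotspots independently of species richness:

* **risk shuffle** — cell composition is held fixed and the extinction
  probabilities are permuted among the species of the phylogeny; appropriate
  for Expected PD-loss, which is a property of a site.
* **identity shuffle** — each cell's richness is held fixed and its species
  are redrawn uniformly from the regional pool; appropriate for the per-cell
  sums of species HEDGE and BED scores, which are properties of species.

The F-value of a cell is the frequency with which its observed statistic
*strictly* exceeds the null replicates, so ties (including fully degenerate
nulls) count against the observed cell and give F = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo_metrics as pm
from .assemblage import AssemblageMatrix
from .phylo_metrics import Phylogeny

__all__ = [
    "NullEnsemble",
    "shuffle_risks",
    "shuffle_identities",
    "f_values",
    "random_cell_sets",
]


@dataclass
class NullEnsemble:
    """Observed per-cell statistic plus its null replicates."""

    statistic: str
    observed: pd.Series            # indexed by cell
    simulated: np.ndarray          # (cells, n_rep)
    seed: int
    n_rep: int

    def __post_init__(self):
        if self.simulated.shape != (len(self.observed), self.n_rep):
            raise ValueError("simulated block must be (n_cells, n_rep)")


def shuffle_risks(
    tree: Phylogeny,
    probs: pd.Series,
    matrix: AssemblageMatrix,
    n_rep: int = 1000,
    seed: int = 0,
    rooting: str = "regional_root",
    exhaustive: bool = False,
) -> NullEnsemble:
    """Permute extinction probabilities among species; recompute per-cell
    Expected PD-loss for each permutation.

    Only the species carrying a probability (the index-filtered pool)
    participate in the permutation.  With ``exhaustive=True`` all ``n!``
    permutations are enumerated instead of sampled (tiny pools only) and
    ``n_rep`` is ignored.
    """
    bt = tree.branch_table()
    species = [t for t in bt.tips if t in probs.index and not pd.isna(probs[t])]
    p = probs.loc[species].to_numpy(dtype=float)
    occ = matrix.occupancy(bt.tips)
    scored = np.array([t in species for t in bt.tips])
    pres = occ & scored

    observed = pm.expected_pd_loss_cells(tree, probs, pres, rooting=rooting)

    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = [np.array(q) for q in itertools.permutations(range(len(species)))]
        n_rep = len(perms)
    else:
        perms = [rng.permutation(len(species)) for _ in range(n_rep)]

    sims = np.empty((matrix.n_cells, n_rep))
    for r, perm in enumerate(perms):
        rep_probs = pd.Series(p[perm], index=species)
        sims[:, r] = pm.expected_pd_loss_cells(tree, rep_probs, pres, rooting=rooting)
    return NullEnsemble(
        statistic="exp_pd_loss",
        observed=pd.Series(observed, index=pd.Index(matrix.cells, name="cell")),
        simulated=sims,
        seed=seed,
        n_rep=n_rep,
    )


def shuffle_identities(
    scores: pd.Series,
    matrix: AssemblageMatrix,
    n_rep: int = 1000,
    seed: int = 0,
    statistic: str = "score_sum",
) -> NullEnsemble:
    """Redraw each cell's species uniformly from the regional pool.

    Each replicate draws, for a cell of richness ``k`` (row sum of the
    matrix), ``k`` distinct species from the scored pool and sums their
    scores; draws are independent across cells and replicates.  Pass a
    matrix restricted to the scored pool so observed and simulated sums
    count the same species; a cell richer than the whole pool is an error.
    """
    pool = list(scores.index)
    vals = scores.to_numpy(dtype=float)
    m = len(pool)
    richness = matrix.richness().to_numpy()
    if richness.max(initial=0) > m:
        raise ValueError("cell richness exceeds the regional species pool")
    occ = matrix.occupancy(pool)
    observed = occ @ vals

    rng = np.random.default_rng(seed)
    sims = np.zeros((matrix.n_cells, n_rep))
    for c, k in enumerate(richness):
        if k == 0:
            continue
        if k == m:
            sims[c, :] = vals.sum()
            continue
        # k smallest of m random keys = uniform draw without replacement
        keys = rng.random((n_rep, m))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sims[c, :] = vals[picks].sum(axis=1)
    return NullEnsemble(
        statistic=statistic,
        observed=pd.Series(observed, index=pd.Index(matrix.cells, name="cell")),
        simulated=sims,
        seed=seed,
        n_rep=n_rep,
    )


def f_values(ensemble: NullEnsemble) -> pd.Series:
    """Per-cell frequency that the observed value strictly exceeds the null."""
    obs = ensemble.observed.to_numpy()[:, None]
    f = (obs > ensemble.simulated).mean(axis=1)
    return pd.Series(f, index=ensemble.observed.index, name=f"f_{ensemble.statistic}")


def random_cell_sets(cells, k: int, n_rep: int, seed: int = 0) -> list[list]:
    """``n_rep`` uniform draws of ``k`` distinct cells (seeded)."""
    cells = list(cells)
    if not 0 < k <= len(cells):
        raise ValueError(f"cannot draw {k} cells from {len(cells)}")
    rng = np.random.default_rng(seed)
    return [
        [cells[i] for i in rng.choice(len(cells), size=k, replace=False)]
        for _ in range(n_rep)
    ]
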