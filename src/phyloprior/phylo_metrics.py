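"""Species- and assemblage-level evolutionary-history metrics.

Every metric is a branch sum over the tree's incidence table.  Writing
``D(b)`` for the tip set descending from branch ``b`` and ``L_b`` for its
length:

* phylogenetic diversity        ``PD(S) = Σ_b L_b · [D(b) ∩ S ≠ ∅]``
* fair-proportion ED            ``ED_i = Σ_{b ∋ i} L_b / |D(b)|``
* Expected PD-loss              ``E[loss(S)] = Σ_b L_b · Π_{i ∈ D(b) ∩ S} p_i``
  (a branch is lost only when *all* its surviving descendants are lost —
  phylogenetic complementarity of extinction risks)
* HED / HEDGE                   ``HED_i = Σ_{b ∋ i} L_b · Π_{j ∈ D(b)∖{i}} p_j``,
  ``HEDGE_i = p_i · HED_i`` (expected PD secured by guaranteeing species i,
  times its own extinction probability)
* BED                           ``BED_i = Σ_{b ∋ i} L_b / R_b`` with
  ``R_b = |∪_{j ∈ D(b)} range(j)|`` — branch contributions down-weighted by
  the spatial extent of the clade each branch supports.

Probability products are evaluated as exponentiated log sums with explicit
zero counting, so ``p = 0`` is exact and small probabilities do not
underflow.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .tree import (  # noqa: F401  (re-exported module surface)
    BranchTable,
    Phylogeny,
    PhylogenyError,
    graft_polytomy,
    parse_newick,
)

__all__ = [
    "Phylogeny",
    "BranchTable",
    "PhylogenyError",
    "parse_newick",
    "graft_polytomy",
    "IUCN_CATEGORIES",
    "THREATENED_CATEGORIES",
    "load_probability_preset",
    "default_probability_preset",
    "category_to_probability",
    "species_filter",
    "pd_subset",
    "pd_cells",
    "fair_proportion_ed",
    "expected_pd_loss",
    "expected_pd_loss_cells",
    "hed_hedge",
    "bed",
]

#: Threat categories in increasing order of severity, plus the bookkeeping
#: classes handled by the filter rules.
IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD", "EX", "RE", "NA")
THREAT_ORDER = ("LC", "NT", "VU", "EN", "CR")
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR"})
#: Categories never assigned a probability / always excluded from analysis.
ALWAYS_EXCLUDED = frozenset({"EX", "RE", "NA"})


# ---------------------------------------------------------------------------
# IUCN category -> 50-year extinction probability
# ---------------------------------------------------------------------------

def load_probability_preset(path) -> dict[str, float]:
    """Load and validate a ``{category: probability}`` mapping from JSON."""
    with open(path) as fh:
        mapping = json.load(fh)
    _validate_mapping(mapping)
    return {k: float(v) for k, v in mapping.items()}


def default_probability_preset() -> dict[str, float]:
    """The shipped 50-year transformation of the IUCN threat categories."""
    text = resources.files("phyloprior.data").joinpath("iucn50.json").read_text()
    mapping = json.loads(text)
    _validate_mapping(mapping)
    return {k: float(v) for k, v in mapping.items()}


def _validate_mapping(mapping: dict) -> None:
    missing = [c for c in THREAT_ORDER if c not in mapping]
    if missing:
        raise ValueError(f"probability mapping missing categories: {missing}")
    vals = [float(mapping[c]) for c in THREAT_ORDER]
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError("probabilities must lie in [0, 1]")
    if any(a >= b for a, b in zip(vals, vals[1:])):
        raise ValueError(
            "probabilities must be strictly increasing LC < NT < VU < EN < CR"
        )


def category_to_probability(category: str, mapping: dict[str, float]) -> float:
    """Extinction probability for one IUCN category under a validated mapping."""
    _validate_mapping(mapping)
    if category not in mapping:
        raise KeyError(f"no extinction probability mapped for category {category!r}")
    return float(mapping[category])


# ---------------------------------------------------------------------------
# Species filtering
# ---------------------------------------------------------------------------

def species_filter(table: pd.DataFrame, index: str) -> set[str]:
    """Species retained for a given index.

    Extinct (EX), regionally extinct (RE) and not-applicable (NA) species are
    always dropped.  Data-deficient (DD) species carry no extinction
    probability and are dropped for the probabilistic indices
    (``exp_pdloss``, ``hedge``) but retained for ``bed``, which relies on
    range size only.

    Parameters
    ----------
    table : DataFrame indexed by species id with an ``iucn_category`` column.
    index : one of ``exp_pdloss``, ``hedge``, ``bed``.
    """
    index = _check_index(index)
    cats = table["iucn_category"]
    keep = ~cats.isin(ALWAYS_EXCLUDED)
    if index in ("exp_pdloss", "hedge"):
        keep &= cats != "DD"
    return set(table.index[keep])


def _check_index(index: str) -> str:
    if index not in ("exp_pdloss", "hedge", "bed"):
        raise ValueError(f"unknown index {index!r}")
    return index


# ---------------------------------------------------------------------------
# PD and fair-proportion ED
# ---------------------------------------------------------------------------

def pd_subset(tree: Phylogeny, species, rooting: str = "regional_root") -> float:
    """Phylogenetic diversity of a tip subset.

    ``regional_root`` counts every branch on the paths from the subset up to
    the tree root (the regional pool's root); ``subset_mrca`` excludes the
    branches above the subset's own MRCA, i.e. branches whose descendant sets
    contain the whole subset.
    """
    bt = tree.branch_table()
    mask = bt.tip_mask(species)
    if not mask.any():
        return 0.0
    hit = bt.memb @ mask > 0
    if rooting == "subset_mrca":
        hit &= ~bt.memb[:, mask].all(axis=1)
    elif rooting != "regional_root":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    return float(bt.lengths[hit].sum())


def pd_cells(tree: Phylogeny, presence: np.ndarray, rooting: str = "regional_root") -> np.ndarray:
    """Vectorized PD for many assemblages (rows of a cells × tips boolean array)."""
    bt = tree.branch_table()
    presf = np.asarray(presence, dtype=bool).astype(float)
    touch = presf @ bt.memb.T.astype(float) > 0
    if rooting == "subset_mrca":
        whole = (presf @ bt.memb.T.astype(float)) == presf.sum(axis=1, keepdims=True)
        touch &= ~whole
    elif rooting != "regional_root":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    return touch @ bt.lengths


def fair_proportion_ed(tree: Phylogeny) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness of every tip.

    Each branch is divided equally among its descendant tips, so the scores
    partition total tree length: ``Σ_i ED_i = PD(all tips)``.
    """
    bt = tree.branch_table()
    share = bt.lengths / bt.memb.sum(axis=1)
    return pd.Series(share @ bt.memb, index=list(bt.tips), name="ed")


# ---------------------------------------------------------------------------
# Probability products (exact zeros, log-space otherwise)
# ---------------------------------------------------------------------------

def _log_and_zeros(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("extinction probabilities must lie in [0, 1]")
    iszero = p == 0.0
    logp = np.zeros_like(p)
    np.log(p, out=logp, where=~iszero)
    return logp, iszero


def _align_probs(bt: BranchTable, probs: pd.Series, species) -> tuple[np.ndarray, np.ndarray]:
    """p-vector over branch-table columns; NaN where undefined."""
    idx = bt.indices_of(species)
    missing = [s for s in species if s not in probs.index or pd.isna(probs.get(s))]
    if missing:
        raise ValueError(f"missing extinction probability for species: {sorted(missing)}")
    p = np.full(bt.n_tips, np.nan)
    p[idx] = probs.loc[list(species)].to_numpy(dtype=float)
    return p, idx


def expected_pd_loss(
    tree: Phylogeny,
    probs: pd.Series,
    assemblage,
    rooting: str = "regional_root",
) -> float:
    """Expected loss of phylogenetic diversity for one assemblage.

    Species go extinct independently with their mapped probabilities; a
    branch is lost only if every assemblage member descending from it is
    lost, so deep branches are secured by any safe descendant.
    """
    assemblage = sorted(set(assemblage))
    if not assemblage:
        return 0.0
    bt = tree.branch_table()
    p, idx = _align_probs(bt, probs, assemblage)
    pres = np.zeros((1, bt.n_tips), dtype=bool)
    pres[0, idx] = True
    return float(
        expected_pd_loss_cells(tree, pd.Series(p[idx], index=assemblage), pres, rooting)[0]
    )


def expected_pd_loss_cells(
    tree: Phylogeny,
    probs: pd.Series,
    presence: np.ndarray,
    rooting: str = "regional_root",
) -> np.ndarray:
    """Vectorized Expected PD-loss for many assemblages at once.

    ``presence`` is a (cells × tips) boolean array in branch-table tip order,
    already restricted to the species that carry a probability.  Returns one
    value per row.
    """
    bt = tree.branch_table()
    species = [t for t in bt.tips if t in probs.index and not pd.isna(probs[t])]
    p, idx = _align_probs(bt, probs, species)
    presence = np.asarray(presence, dtype=bool)
    if presence.shape[1] != bt.n_tips:
        raise ValueError("presence must have one column per tree tip")
    scored = np.zeros(bt.n_tips, dtype=bool)
    scored[idx] = True
    if np.any(presence & ~scored):
        bad = [bt.tips[i] for i in np.where((presence & ~scored).any(axis=0))[0]]
        raise ValueError(f"missing extinction probability for species: {bad}")

    logp, iszero = _log_and_zeros(np.where(scored, p, 1.0))
    presf = presence.astype(float)
    # Σ_{i in cell ∩ D(b)} log p_i  and zero counts, per (cell, branch)
    membf = bt.memb.astype(float)
    logsum = (presf * logp) @ membf.T          # (C, B)
    nzero = (presf * iszero) @ membf.T          # (C, B)
    touch = presf @ membf.T > 0                 # branch supports the cell
    prod = np.exp(logsum)
    prod[nzero > 0] = 0.0
    prod[~touch] = 0.0
    if rooting == "subset_mrca":
        # drop branches containing the whole assemblage (above its MRCA)
        ncell = presf.sum(axis=1, keepdims=True)
        whole = (presf @ membf.T) == ncell
        prod[whole] = 0.0
    elif rooting != "regional_root":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    return prod @ bt.lengths


def hed_hedge(tree: Phylogeny, probs: pd.Series) -> pd.DataFrame:
    """Heightened ED and HEDGE for every tip with a probability.

    ``HED_i`` is the expected PD secured by making species *i* safe: each
    root-path branch weighted by the probability that all of its *other*
    descendants are lost.  ``HEDGE_i = p_i × HED_i`` folds back the species'
    own risk, ranking species whose rescue would save the most expected
    branch length.
    """
    bt = tree.branch_table()
    species = [t for t in bt.tips if t in probs.index and not pd.isna(probs[t])]
    if set(species) != set(bt.tips):
        missing = sorted(set(bt.tips) - set(species))
        raise ValueError(f"missing extinction probability for species: {missing}")
    p, _ = _align_probs(bt, probs, species)
    logp, iszero = _log_and_zeros(p)

    membf = bt.memb.astype(float)
    logsum = membf @ logp                # Σ log p over D(b)
    nzero = membf @ iszero.astype(float)  # zero count over D(b)
    # leave-one-out product for each (branch, tip in D(b))
    excl_log = logsum[:, None] - logp[None, :]
    excl_zero = nzero[:, None] - iszero[None, :].astype(float)
    prod = np.exp(excl_log)
    prod[excl_zero > 0] = 0.0
    hed = ((bt.lengths[:, None] * prod) * bt.memb).sum(axis=0)
    out = pd.DataFrame({"hed": hed, "hedge": p * hed}, index=list(bt.tips))
    return out


def bed(tree: Phylogeny, matrix, variant: str = "union_range") -> pd.Series:
    """Biogeographically weighted evolutionary distinctiveness.

    Default ``union_range`` weighting divides each branch by the number of
    grid cells occupied by at least one of its descendants, so branches whose
    whole clade is spatially restricted contribute fully.  The
    ``occurrence_sum`` variant partitions each branch among descendants in
    proportion to their own range sizes (the original fair-proportion-style
    formulation): ``BED_i = Σ_b L_b · r_i / Σ_{j∈D(b)} r_j``.

    ``matrix`` is an :class:`~phyloprior.assemblage.AssemblageMatrix` (or any
    object with ``occupancy(tips)`` returning a cells × tips boolean array).
    Species absent from every cell are an error.
    """
    bt = tree.branch_table()
    occ = matrix.occupancy(bt.tips)  # (C, S) boolean
    r = occ.sum(axis=0).astype(float)
    if np.any(r == 0):
        empty = [bt.tips[i] for i in np.where(r == 0)[0]]
        raise ValueError(f"species with empty range: {empty}")
    membf = bt.memb.astype(float)
    if variant == "union_range":
        union_cells = (occ @ bt.memb.T.astype(float)) > 0  # (C, B)
        R = union_cells.sum(axis=0).astype(float)
        scores = (bt.lengths / R) @ membf
    elif variant == "occurrence_sum":
        denom = membf @ r
        scores = ((bt.lengths / denom) @ membf) * r
    else:
        raise ValueError(f"unknown BED variant {variant!r}")
    return pd.Series(scores, index=list(bt.tips), name="bed")
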