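"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's branch-table code path: trees are
re-read with dendropy directly, branches are collected by plain traversal,
and expectations are computed by exhaustive enumeration of all 2^n
extinction outcomes.
"""

from __future__ import annotations

import dendropy
import numpy as np


def branch_list(newick: str):
    """[(length, tip-label frozenset)] for every branch, via raw dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    out = []
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if node.parent_node is None:
            if not length:
                continue
        labels = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append((float(length), labels))
    return out


def _outcome_grid(labels, probs):
    """All 2^n outcomes: bit matrix (outcome × species, 1 = extinct) and
    their probabilities."""
    n = len(labels)
    p = np.array([probs[l] for l in labels])
    outcomes = np.arange(2**n)
    bits = (outcomes[:, None] >> np.arange(n)) & 1
    weights = np.prod(np.where(bits == 1, p, 1 - p), axis=1)
    return bits, weights


def expected_pd_loss_enum(newick: str, probs: dict, assemblage) -> float:
    """Σ over extinction outcomes of P(outcome) × PD lost, regional rooting.

    A branch is lost when every assemblage member below it is extinct;
    branches with no assemblage member below them are never at stake.
    """
    assemblage = sorted(assemblage)
    bits, weights = _outcome_grid(assemblage, probs)
    total = 0.0
    for length, tipset in branch_list(newick):
        idx = [i for i, l in enumerate(assemblage) if l in tipset]
        if not idx:
            continue
        lost = bits[:, idx].all(axis=1)
        total += length * float(weights[lost].sum())
    return total


def hed_enum(newick: str, probs: dict) -> dict:
    """HED via the conditional-expectation identity
    E[surviving PD | i survives] − E[surviving PD | i extinct]."""
    labels = sorted(probs)
    bits, weights = _outcome_grid(labels, probs)
    # surviving PD per outcome
    pd_surv = np.zeros(len(weights))
    for length, tipset in branch_list(newick):
        idx = [i for i, l in enumerate(labels) if l in tipset]
        alive = ~bits[:, idx].all(axis=1)
        pd_surv += length * alive
    out = {}
    for i, lab in enumerate(labels):
        surv = bits[:, i] == 0
        e_surv = float((weights[surv] * pd_surv[surv]).sum() / weights[surv].sum())
        e_ext = float((weights[~surv] * pd_surv[~surv]).sum() / weights[~surv].sum())
        out[lab] = e_surv - e_ext
    return out


def pd_brute(newick: str, species) -> float:
    """Regional-root PD by direct branch scan."""
    species = set(species)
    return sum(
        length for length, tipset in branch_list(newick) if tipset & species
    )


def bed_union_brute(newick: str, ranges: dict) -> dict:
    """BED with union-range weights computed per branch by set union."""
    branches = branch_list(newick)
    out = {}
    for sp in ranges:
        score = 0.0
        for length, tipset in branches:
            if sp not in tipset:
                continue
            union = set()
            for other in tipset:
                union |= set(ranges[other])
            score += length / len(union)
        out[sp] = score
    return out


def spearman_brute(x, y) -> float:
    """Pearson correlation of mid-ranks, straight from the definition."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
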