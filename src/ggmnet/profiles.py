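"""Module expression profiles over ordered sample groups, and
neighbor-voting evaluation of how well a network groups known gene sets.

Profiles average the (log-scale) expression of a module's genes within each
sample group and report each module row relative to its own maximum, the
form used for module heatmaps.  Neighbor voting scores each gene by the
fraction of its network neighbors inside a gene set; the AUROC of that
score for members vs. non-members summarizes the network's
guilt-by-association quality for the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import rankdata

from .preprocessing import ExpressionMatrix
from .network import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass
class ModuleProfile:
    """Module x group mean expression and the same row-relative to its max."""

    means: pd.DataFrame      # index: module_id, columns: group labels (ordered)
    relative: pd.DataFrame   # means / row max; all-zero rows stay all zero


@dataclass
class GeneSetAUROC:
    set_id: str
    auroc: float
    n_positives: int
    n_scored: int


def read_sample_groups(path) -> dict[str, list[str]]:
    """Read a (sample_id, group_label, group_order) TSV into an ordered
    group -> samples mapping."""
    frame = pd.read_csv(path, sep="\t")
    frame = frame.sort_values(["group_order", "sample_id"])
    groups: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        groups.setdefault(str(row.group_label), []).append(str(row.sample_id))
    return groups


def module_mean_expression(
    m: ExpressionMatrix,
    modules: ModuleAssignment,
    groups: dict[str, list[str]],
) -> ModuleProfile:
    """Mean expression of each module's genes within each ordered sample
    group, plus values relative to the module's maximum group mean.

    Module genes missing from the matrix are dropped with a warning; a
    module with no genes in the matrix is omitted.  All-zero rows stay all
    zero rather than dividing by zero.
    """
    sample_set = set(m.sample_ids)
    for label, samples in groups.items():
        missing = [s for s in samples if s not in sample_set]
        if missing:
            raise ValueError(f"group {label!r} references unknown sample {missing[0]!r}")
    matrix_genes = set(m.gene_ids)
    rows = {}
    for mid in sorted(modules.module_sizes):
        genes = sorted(modules.genes_in_module(mid))
        present = [g for g in genes if g in matrix_genes]
        if len(present) < len(genes):
            logger.warning(
                "module %d: %d of %d genes missing from the matrix",
                mid, len(genes) - len(present), len(genes),
            )
        if not present:
            logger.warning("module %d omitted: no genes in the matrix", mid)
            continue
        sub = m.data.loc[present]
        rows[mid] = [float(sub[samples].to_numpy().mean()) for samples in groups.values()]
    means = pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))
    means.index.name = "module_id"
    maxes = means.max(axis=1)
    safe = maxes.replace(0.0, 1.0)
    relative = means.div(safe, axis=0)
    relative[maxes == 0.0] = 0.0
    return ModuleProfile(means=means, relative=relative)


def _auroc_midrank(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUROC via mid-ranks: P(score of a random positive > score of a
    random negative), ties counted half."""
    ranks = rankdata(scores)  # average (mid) ranks
    n_pos = int(positive.sum())
    n_neg = len(scores) - n_pos
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def neighbor_voting_auroc(
    net: nx.Graph, gene_sets: dict[str, set[str]]
) -> list[GeneSetAUROC]:
    """Leave-one-out neighbor-voting AUROC for each gene set.

    Every network gene of degree >= 1 is scored by the fraction of its
    neighbors inside the set (itself excluded).  Sets with fewer than two
    members among the scored genes, or without any negative, are skipped
    with a warning.
    """
    scored = [g for g in net.nodes if net.degree(g) >= 1]
    results = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id])
        pos = np.array([g in members for g in scored])
        n_pos = int(pos.sum())
        if n_pos < 2:
            logger.warning("gene set %r: fewer than 2 members scored; skipped", set_id)
            continue
        if n_pos == len(scored):
            logger.warning("gene set %r: no negatives among scored genes; skipped", set_id)
            continue
        scores = np.array(
            [
                sum(1 for nb in net.neighbors(g) if nb in members and nb != g)
                / net.degree(g)
                for g in scored
            ]
        )
        results.append(
            GeneSetAUROC(
                set_id=set_id,
                auroc=_auroc_midrank(scores, pos),
                n_positives=n_pos,
                n_scored=len(scored),
            )
        )
    return results


def write_module_profile(profile: ModuleProfile, means_path, relative_path) -> None:
    profile.means.to_csv(means_path, sep="\t")
    profile.relative.to_csv(relative_path, sep="\t")
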