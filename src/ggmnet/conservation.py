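"""Cross-species network conservation through a homolog map.

A gene g of network 1 has a *conserved interaction* when some homolog of g
is a node of network 2 and at least one of g's neighbors (group A) is
homologous to at least one neighbor of g's homolog(s) (group B).  Per-module
conservation is the percentage of module genes with a conserved
interaction; by default all module genes count in the denominator,
including genes without any homolog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import networkx as nx

from .network import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass
class ConservationReport:
    per_gene: pd.DataFrame     # gene, has_homolog_in_net2, conserved
    per_module: pd.DataFrame   # module_id, n_genes, n_conserved, percent_conserved
    network_wide_percent: float
    denominator: str = "all"   # "all" or "with_homolog"


def _homolog_index(pairs: pd.DataFrame) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for row in pairs.itertuples(index=False):
        index.setdefault(str(row[0]), set()).add(str(row[1]))
    return index


def conserved_interactions(
    net1: nx.Graph, net2: nx.Graph, homologs: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene conserved-interaction flags for every node of ``net1``.

    ``homologs`` is a two-column table (network-1 gene, network-2 gene);
    many-to-many maps are honored (group B is the union of all homologs'
    neighborhoods).

    Returns a DataFrame (gene, has_homolog_in_net2, conserved).
    """
    hmap = _homolog_index(homologs)
    rows = []
    for g in net1.nodes:
        homs = {h for h in hmap.get(g, ()) if h in net2}
        conserved = False
        if homs:
            A = set(net1.neighbors(g))
            B = set()
            for h in homs:
                B.update(net2.neighbors(h))
            if A and B:
                conserved = any(hmap.get(a, set()) & B for a in A)
        rows.append(
            {"gene": g, "has_homolog_in_net2": bool(homs), "conserved": conserved}
        )
    return pd.DataFrame(rows, columns=["gene", "has_homolog_in_net2", "conserved"])


def module_conservation(
    flags: pd.DataFrame,
    modules: ModuleAssignment,
    denominator: str = "all",
) -> ConservationReport:
    """Aggregate per-gene conservation flags into per-module and
    network-wide percentages.

    ``denominator="all"`` counts every module gene (the default);
    ``"with_homolog"`` restricts to genes that have a homolog in network 2.
    """
    if denominator not in ("all", "with_homolog"):
        raise ValueError("denominator must be 'all' or 'with_homolog'")
    flag = dict(zip(flags["gene"].astype(str), flags["conserved"]))
    hashom = dict(zip(flags["gene"].astype(str), flags["has_homolog_in_net2"]))
    missing = [g for g in modules.assignments if g not in flag]
    if missing:
        raise ValueError(
            f"conservation flags missing for {len(missing)} module gene(s), "
            f"e.g. {missing[0]!r}"
        )

    def _eligible(genes: list[str]) -> list[str]:
        if denominator == "all":
            return genes
        return [g for g in genes if hashom[g]]

    rows = []
    for mid in sorted(modules.module_sizes):
        genes = sorted(modules.genes_in_module(mid))
        elig = _eligible(genes)
        n_cons = sum(bool(flag[g]) for g in genes)
        pct = 100.0 * n_cons / len(elig) if elig else 0.0
        rows.append(
            {
                "module_id": mid,
                "n_genes": len(genes),
                "n_conserved": n_cons,
                "percent_conserved": pct,
            }
        )
    per_module = pd.DataFrame(
        rows, columns=["module_id", "n_genes", "n_conserved", "percent_conserved"]
    )
    all_genes = [str(g) for g in flags["gene"]]
    elig_all = _eligible(all_genes)
    total = sum(bool(flag[g]) for g in all_genes)
    network_wide = 100.0 * total / len(elig_all) if elig_all else 0.0
    return ConservationReport(
        per_gene=flags.copy(),
        per_module=per_module,
        network_wide_percent=network_wide,
        denominator=denominator,
    )


def read_homolog_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_homolog_map(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_conservation_report(report: ConservationReport, gene_path, module_path) -> None:
    report.per_gene.to_csv(gene_path, sep="\t", index=False)
    report.per_module.to_csv(module_path, sep="\t", index=False)
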