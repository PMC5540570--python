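"""Synthetic-data generators with the statistical structure the pipeline
assumes: a planted-module graphical Gaussian model, FPKM-like expression
with a mean-variance dependency, rewired partner networks with homolog
maps, module-enriched annotations, and promoters with implanted IUPAC
motifs.

Ground truth (precision matrix, true edges, true modules) is carried along
so that estimator and clustering accuracy can be measured directly.  All
generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .preprocessing import ExpressionMatrix, SCALE_FPKM
from .network import ModuleAssignment
from .enrichment import IUPAC, MotifPattern

logger = logging.getLogger(__name__)

#: Default range (log2 scale) for gene base expression levels.  2^3-1 = 7 to
#: 2^8-1 = 255 FPKM spans lowly to highly expressed genes while keeping most
#: genes above the max-FPKM filter cutoff of 20 at realistic sample counts.
DEFAULT_BASE_LOG_MEAN_RANGE = (3.0, 8.0)

#: Default within-module partial-correlation magnitude.  The distribution of
#: real-data partial correlations is not characterized beyond being tightly
#: concentrated near zero; 0.3 plants edges well clear of the noise floor at
#: hundreds of samples without threatening positive definiteness.
DEFAULT_WITHIN_PCOR = 0.3


@dataclass
class PlantedModel:
    """A block-structured Gaussian graphical model with known modules.

    ``true_edges`` are exactly the non-zero off-diagonal precision entries;
    ``true_modules`` maps module genes (only) to 1-based module ids.
    """

    n_genes: int
    module_sizes: list[int]
    within_pcor: float
    precision: np.ndarray
    gene_ids: list[str]
    true_edges: set[frozenset[str]]
    true_modules: dict[str, int]

    def true_network(self) -> nx.Graph:
        """The ground-truth conditional-dependence graph."""
        net = nx.Graph()
        for e in self.true_edges:
            a, b = sorted(e)
            i, j = self.gene_ids.index(a), self.gene_ids.index(b)
            om = self.precision
            pcor = -om[i, j] / np.sqrt(om[i, i] * om[j, j])
            net.add_edge(a, b, sign=int(np.sign(pcor)) or 1,
                         pcor=float(pcor), pcc=float("nan"))
        return net

    def module_assignment(self) -> ModuleAssignment:
        sizes: dict[int, int] = {}
        for mid in self.true_modules.values():
            sizes[mid] = sizes.get(mid, 0) + 1
        return ModuleAssignment(dict(self.true_modules), set(), sizes)


@dataclass
class SyntheticScenario:
    """A complete bundle of pipeline inputs generated from one seed."""

    expression: ExpressionMatrix
    model: PlantedModel
    annotations: pd.DataFrame
    homolog_map: pd.DataFrame
    partner_network: nx.Graph
    promoters: dict[str, str]
    seed: int


def _module_pattern(
    size: int, rng: np.random.Generator, n_chords: int | None = None
) -> list[tuple[int, int]]:
    """Sparse within-module connectivity: a ring plus random chords."""
    if size == 1:
        return []
    if size == 2:
        return [(0, 1)]
    edges = [(i, (i + 1) % size) for i in range(size)]
    ring = {frozenset(e) for e in edges}
    if n_chords is None:
        n_chords = size // 3
    candidates = [
        (i, j)
        for i in range(size)
        for j in range(i + 1, size)
        if frozenset((i, j)) not in ring
    ]
    if candidates and n_chords > 0:
        pick = rng.choice(len(candidates), size=min(n_chords, len(candidates)),
                          replace=False)
        edges.extend(candidates[i] for i in pick)
    return edges


def generate_planted_model(
    n_genes: int,
    n_modules: int,
    module_size: int,
    within_pcor: float = DEFAULT_WITHIN_PCOR,
    seed: int = 0,
) -> PlantedModel:
    """Plant ``n_modules`` modules of ``module_size`` genes on a sparse
    ring-plus-chords pattern with partial correlation ``within_pcor``;
    remaining genes are independent background.

    The precision matrix starts as the identity with -within_pcor at
    planted edges; if its smallest eigenvalue drops below 1e-3 a diagonal
    ridge restores positive definiteness (logged, and the realized partial
    correlations shrink accordingly).
    """
    if n_modules * module_size > n_genes:
        raise ValueError("modules do not fit: n_modules * module_size > n_genes")
    if not -1.0 < within_pcor < 1.0:
        raise ValueError("within_pcor must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{idx:0{width}d}" for idx in range(n_genes)]
    omega = np.eye(n_genes)
    true_modules: dict[str, int] = {}
    module_sizes: list[int] = []
    for m in range(n_modules):
        offset = m * module_size
        for local in range(module_size):
            true_modules[gene_ids[offset + local]] = m + 1
        module_sizes.append(module_size)
        for i, j in _module_pattern(module_size, rng):
            omega[offset + i, offset + j] = -within_pcor
            omega[offset + j, offset + i] = -within_pcor
    lam_min = float(np.linalg.eigvalsh(omega)[0])
    if lam_min < 1e-3:
        delta = 1e-3 - lam_min
        logger.info(
            "precision repair: adding %.3g * I (smallest eigenvalue %.3g)",
            delta, lam_min,
        )
        omega += delta * np.eye(n_genes)
        lam_min = float(np.linalg.eigvalsh(omega)[0])
    if lam_min <= 0:
        raise ValueError(
            f"precision matrix not positive definite after repair "
            f"(smallest eigenvalue {lam_min:.3g})"
        )
    ia, ja = np.nonzero(np.triu(omega, 1))
    true_edges = {frozenset((gene_ids[i], gene_ids[j])) for i, j in zip(ia, ja)}
    return PlantedModel(
        n_genes=n_genes,
        module_sizes=module_sizes,
        within_pcor=within_pcor,
        precision=omega,
        gene_ids=gene_ids,
        true_edges=true_edges,
        true_modules=true_modules,
    )


def simulate_expression(
    model: PlantedModel,
    n_samples: int,
    base_log_mean_range: tuple[float, float] = DEFAULT_BASE_LOG_MEAN_RANGE,
    latent_sd_range: tuple[float, float] = (0.6, 1.4),
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw FPKM-like expression from the planted model.

    Latent values come from the multivariate normal with the model's
    precision, are standardized per gene and shifted/scaled to gene-specific
    base means (log2 scale) and SDs, then mapped to FPKM = 2^z - 1 clipped
    at 0 — the exact inverse of the pipeline's log2(FPKM + 1) transform.
    The exponential mapping gives the raw scale its mean-variance
    dependency.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples (no variance estimable)")
    rng = np.random.default_rng(seed)
    k = model.n_genes
    # sample from N(0, Omega^{-1}) via the Cholesky factor of Omega
    from scipy.linalg import solve_triangular

    chol = np.linalg.cholesky(model.precision)
    eps = rng.standard_normal((k, n_samples))
    latent = solve_triangular(chol.T, eps, lower=False)
    sigma_diag = np.sqrt(np.diag(np.linalg.inv(model.precision)))
    latent = latent / sigma_diag[:, None]
    mu = rng.uniform(*base_log_mean_range, size=k)
    sd = rng.uniform(*latent_sd_range, size=k)
    z = mu[:, None] + sd[:, None] * latent
    fpkm = np.clip(2.0**z - 1.0, 0.0, None)
    frame = pd.DataFrame(
        fpkm,
        index=model.gene_ids,
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(frame, scale=SCALE_FPKM)


def generate_conservation_scenario(
    network: nx.Graph,
    homolog_fraction: float,
    edge_rewire_fraction: float,
    seed: int = 0,
    prefix: str = "X_",
) -> tuple[nx.Graph, pd.DataFrame]:
    """Build a partner network for cross-species comparison.

    The partner is a relabeled copy of ``network`` with
    ``edge_rewire_fraction`` of its edges removed and replaced by random
    non-edges; the homolog map links ``homolog_fraction`` of the genes to
    their relabeled copies.
    """
    for name, f in (("homolog_fraction", homolog_fraction),
                    ("edge_rewire_fraction", edge_rewire_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    relabel = {g: f"{prefix}{g}" for g in nodes}
    partner = nx.relabel_nodes(network.copy(), relabel)
    edges = sorted(tuple(sorted(e)) for e in partner.edges)
    n_rewire = int(round(edge_rewire_fraction * len(edges)))
    if n_rewire:
        drop_idx = rng.choice(len(edges), size=n_rewire, replace=False)
        dropped = [edges[i] for i in drop_idx]
        partner.remove_edges_from(dropped)
        pnodes = sorted(partner.nodes)
        added = 0
        while added < n_rewire:
            a, b = rng.choice(len(pnodes), size=2, replace=False)
            u, v = pnodes[a], pnodes[b]
            if not partner.has_edge(u, v):
                partner.add_edge(u, v, sign=1, pcor=float("nan"), pcc=float("nan"))
                added += 1
    n_hom = int(round(homolog_fraction * len(nodes)))
    hom_idx = sorted(rng.choice(len(nodes), size=n_hom, replace=False))
    homolog_map = pd.DataFrame(
        {
            "gene": [nodes[i] for i in hom_idx],
            "partner_gene": [relabel[nodes[i]] for i in hom_idx],
        }
    )
    return partner, homolog_map


def generate_annotations(
    modules: ModuleAssignment,
    terms_per_module: int = 1,
    signal_fraction: float = 0.8,
    background_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Module-enriched annotations: each module's marker term(s) annotate
    ``signal_fraction`` of the module's genes plus ``background_fraction``
    of all other genes."""
    for name, f in (("signal_fraction", signal_fraction),
                    ("background_fraction", background_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = sorted(set(modules.assignments) | modules.small_module_genes)
    rows = []
    for mid in sorted(modules.module_sizes):
        members = sorted(modules.genes_in_module(mid))
        others = [g for g in all_genes if g not in set(members)]
        for t in range(terms_per_module):
            term = f"M{mid}_T{t}"
            n_sig = int(round(signal_fraction * len(members)))
            n_bg = int(round(background_fraction * len(others)))
            sig = rng.choice(len(members), size=n_sig, replace=False)
            rows.extend({"gene": members[i], "term": term} for i in sorted(sig))
            if others and n_bg:
                bg = rng.choice(len(others), size=n_bg, replace=False)
                rows.extend({"gene": others[i], "term": term} for i in sorted(bg))
    return pd.DataFrame(rows, columns=["gene", "term"])


def _expand_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in motif.upper())


def generate_promoters(
    genes: list[str],
    length: int = 1000,
    motif: str = "CGTAC",
    implant_genes: list[str] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Uniform-random ACGT promoters; each implant gene gets one concrete
    expansion of the IUPAC motif written at a random position."""
    motif_obj = MotifPattern(motif)
    if len(motif_obj.iupac) > length:
        raise ValueError("motif longer than promoter")
    implant = set(implant_genes or ())
    if not implant <= set(genes):
        raise ValueError("implant_genes must be a subset of genes")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    for g in genes:
        seq = "".join(bases[rng.integers(4, size=length)])
        if g in implant:
            site = _expand_iupac(motif_obj.iupac, rng)
            pos = int(rng.integers(length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        promoters[g] = seq
    return promoters


def generate_scenario(
    n_genes: int = 200,
    n_modules: int = 8,
    module_size: int = 20,
    within_pcor: float = DEFAULT_WITHIN_PCOR,
    n_samples: int = 400,
    homolog_fraction: float = 0.8,
    edge_rewire_fraction: float = 0.2,
    terms_per_module: int = 1,
    signal_fraction: float = 0.8,
    background_fraction: float = 0.05,
    promoter_length: int = 1000,
    motif: str = "GNATATNC",
    seed: int = 0,
) -> SyntheticScenario:
    """Generate a coherent full set of pipeline inputs from one seed.

    Sub-generators get decorrelated child seeds derived from ``seed`` so
    each input is independently reproducible.
    """
    child = np.random.SeedSequence(seed).generate_state(6)

    def sub_seed(i: int) -> int:
        return int(child[i]) % (2**31)

    model = generate_planted_model(
        n_genes, n_modules, module_size, within_pcor, seed=sub_seed(0)
    )
    expression = simulate_expression(model, n_samples, seed=sub_seed(1))
    true_net = model.true_network()
    partner, homolog_map = generate_conservation_scenario(
        true_net, homolog_fraction, edge_rewire_fraction, seed=sub_seed(2)
    )
    modules = model.module_assignment()
    annotations = generate_annotations(
        modules, terms_per_module, signal_fraction, background_fraction,
        seed=sub_seed(3),
    )
    first_module = sorted(modules.genes_in_module(1))
    promoters = generate_promoters(
        model.gene_ids, promoter_length, motif,
        implant_genes=first_module, seed=sub_seed(4),
    )
    return SyntheticScenario(
        expression=expression,
        model=model,
        annotations=annotations,
        homolog_map=homolog_map,
        partner_network=partner,
        promoters=promoters,
        seed=seed,
    )


def write_promoters_fasta(promoters: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(promoters):
            fh.write(f">{gene}\n{promoters[gene]}\n")


def read_promoters_fasta(path) -> dict[str, str]:
    promoters: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    promoters[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        promoters[name] = "".join(chunks)
    return promoters
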