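"""Module enrichment statistics: GO-style over-representation by the
one-sided hypergeometric test, and promoter-motif enrichment by the
binomial test over IUPAC-pattern scans of both strands.

The hypergeometric test asks, for a term annotating K of N universe genes,
how surprising k hits are in a module of n genes: p = P(X >= k) with
X ~ Hypergeom(N, K, n).  Motif enrichment treats "promoter contains >= 1
match" as a Bernoulli event with universe-wide rate p0 and tests
k of n module genes against Binomial(n, p0).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifPattern:
    """A degenerate nucleotide motif over the IUPAC alphabet."""

    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
        self.iupac = self.iupac.upper()

    def to_regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all counted
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.iupac
        )
        return re.compile(f"(?={body})")


def annotations_from_frame(frame: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse a two-column (gene, term) table to gene -> set of terms."""
    ann: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        ann.setdefault(str(row.gene), set()).add(str(row.term))
    return ann


def read_annotations(path) -> dict[str, set[str]]:
    return annotations_from_frame(pd.read_csv(path, sep="\t"))


def go_enrichment(
    module_genes: set[str],
    universe: set[str],
    annotations: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of every term with at
    least one hit in the module, BH-adjusted across the module's terms.

    Returns a DataFrame (term, k, n, K, N, p_value, p_adjusted) sorted by
    ascending p.  Annotations must already be propagated to ancestor terms
    if DAG-aware results are wanted.
    """
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    N = len(universe)
    n = len(module_genes)
    term_universe: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for g in universe:
        for t in annotations.get(g, ()):
            term_universe[t] = term_universe.get(t, 0) + 1
            if g in module_genes:
                term_hits[t] = term_hits.get(t, 0) + 1
    rows = []
    for t, k in term_hits.items():
        K = term_universe[t]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "n": n, "K": K, "N": N, "p_value": min(p, 1.0)})
    frame = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_value"])
    if len(frame):
        frame = frame.sort_values(["p_value", "term"]).reset_index(drop=True)
        frame["p_adjusted"] = benjamini_hochberg(frame["p_value"].to_numpy())
    else:
        frame["p_adjusted"] = pd.Series(dtype=float)
    return frame


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH FDR adjustment (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.asarray([], dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_promoters(
    promoters: dict[str, str], motif: MotifPattern | str
) -> dict[str, int]:
    """Count occurrences of the IUPAC motif in each promoter on both strands
    (sequence and its reverse complement); overlaps count, ambiguous N bases
    in the sequence never match."""
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    pattern = motif.to_regex()
    hits: dict[str, int] = {}
    for gene, seq in promoters.items():
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"promoter of {gene!r} has letters outside ACGTN")
        hits[gene] = len(pattern.findall(seq)) + len(
            pattern.findall(reverse_complement(seq))
        )
    return hits


@dataclass
class MotifEnrichment:
    k: int        # module genes whose promoter has >= 1 match
    n: int        # module size
    p0: float     # universe-wide fraction of genes with >= 1 match
    p_value: float


def motif_enrichment(
    module_genes: set[str], hits: dict[str, int], universe: set[str]
) -> MotifEnrichment:
    """Binomial over-representation of motif-bearing promoters in a module
    against the universe-wide rate."""
    module_genes = set(module_genes)
    universe = set(universe)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    missing = universe - set(hits)
    if missing:
        raise ValueError(f"hits missing for {len(missing)} universe gene(s)")
    has = {g for g in universe if hits[g] >= 1}
    p0 = len(has) / len(universe)
    n = len(module_genes)
    k = len(module_genes & has)
    if p0 == 0.0 and k > 0:
        logger.warning(
            "motif absent from the universe but present in the module; "
            "inconsistent universe, reporting the smallest positive p"
        )
        p = float(np.nextafter(0.0, 1.0))
    else:
        p = float(stats.binom.sf(k - 1, n, p0))
    return MotifEnrichment(k=k, n=n, p0=p0, p_value=min(p, 1.0))


def write_enrichment(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
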