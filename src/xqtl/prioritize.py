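"""Multi-evidence candidate-gene prioritization by order statistics.

Each gene carries a rank in up to five evidence sources (pQTL nominal p,
eQTL nominal p, colocalization PP4, disease-relevance score, and
PPI-connectivity to known risk genes).  Ranks are turned into rank ratios
r_i / n_i, and a gene's aggregate score is the joint order-statistic tail
probability Q — the probability that k independent uniforms have order
statistics jointly no larger than the gene's sorted ratios — computed by the
standard recursion:

  V_0 = 1,  V_i = sum_{j=1..i} (-1)^(j-1) V_{i-j} q_{i-j+1}^j / j!,  Q = k! V_k

Smaller Q means more consistently strong evidence.  A protein-protein
interaction network (edges kept at combined score >= 700, nodes restricted
to eligible genes) supplies the connectivity source, and top candidates are
mapped onto GWAS loci by TSS overlap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected, deduplicated PPI edge set with STRING-style scores."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: pd.DataFrame, min_score: int = 700) -> "PPINetwork":
        g = nx.Graph()
        kept = edges.loc[edges["combined_score"] >= min_score]
        for a, b, s in kept[["gene_a", "gene_b", "combined_score"]].itertuples(index=False):
            if a == b:
                continue
            g.add_edge(a, b, combined_score=int(s))
        return cls(g)

    def restrict(self, eligible: set[str]) -> "PPINetwork":
        return PPINetwork(self.graph.subgraph([n for n in self.graph if n in eligible]).copy())


def order_statistic_q(rank_ratios: np.ndarray, k: int | None = None) -> float:
    """Joint tail probability Q of sorted-ascending rank ratios in (0, 1].

    Raises on unsorted input (the caller owns the sort; silently sorting
    would hide upstream bugs).
    """
    q = np.asarray(rank_ratios, float)
    k = len(q) if k is None else k
    if k < 1 or len(q) != k:
        raise ValueError("need k >= 1 rank ratios")
    if (q <= 0).any() or (q > 1).any():
        raise ValueError("rank ratios must lie in (0, 1]")
    if (np.diff(q) < 0).any():
        raise ValueError("rank ratios must be sorted ascending")
    V = np.zeros(k + 1)
    V[0] = 1.0
    for i in range(1, k + 1):
        s = 0.0
        for j in range(1, i + 1):
            s += (-1.0) ** (j - 1) * V[i - j] * q[i - j] ** j / math.factorial(j)
        V[i] = s
    return float(math.factorial(k) * V[k])


def connectivity_score(
    network: PPINetwork, risk_genes: set[str], eligible: set[str] | None = None
) -> pd.Series:
    """Per-gene count of distinct risk-gene neighbors in the (restricted)
    PPI network."""
    g = network.restrict(eligible).graph if eligible is not None else network.graph
    if g.number_of_edges() == 0:
        warnings.warn("PPI network empty after filtering; all connectivity scores 0")
    scores = {node: sum(1 for nb in g.neighbors(node) if nb in risk_genes) for node in g}
    return pd.Series(scores, dtype=int).sort_index()


def ranks_from_scores(scores: pd.Series, ascending: bool = True) -> pd.Series:
    """Rank a score column (1 = best); ties get the average rank."""
    return pd.Series(
        stats.rankdata(scores.to_numpy() if ascending else -scores.to_numpy(), method="average"),
        index=scores.index,
    )


def aggregate_and_rank(sources: dict[str, pd.Series]) -> pd.DataFrame:
    """Aggregate per-source gene ranks into a final order-statistic ranking.

    ``sources`` maps source name -> Series of ranks (1 = best) indexed by
    gene; genes may be missing from any source.  For each gene, Q is
    computed over its k available sources' rank ratios.  Final rank orders
    ascending Q, ties broken by more sources available, then gene id.
    """
    genes = sorted(set().union(*[set(s.index) for s in sources.values()]))
    if not genes:
        raise ValueError("no genes present in any source")
    rows = []
    for gene in genes:
        ratios, per_source = [], {}
        for name, s in sources.items():
            if gene in s.index and np.isfinite(s.loc[gene]):
                r = float(s.loc[gene])
                n_i = float(np.isfinite(s).sum())
                if not (1 <= r <= n_i):
                    raise ValueError(f"rank {r} outside [1, {n_i}] in source {name}")
                ratios.append(r / n_i)
                per_source[f"rank_{name}"] = r
            else:
                per_source[f"rank_{name}"] = np.nan
        if not ratios:
            continue
        ratios = np.sort(np.asarray(ratios))
        rows.append(
            dict(gene_id=gene, k_sources=len(ratios), q_score=order_statistic_q(ratios), **per_source)
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["q_score", "k_sources", "gene_id"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def map_to_loci(ranked: pd.DataFrame, loci: pd.DataFrame, tss: pd.Series, top_n: int | None = None) -> pd.DataFrame:
    """Annotate top-ranked genes with overlapping GWAS loci.

    ``loci`` needs chrom, start, end, tier (significant | suggestive);
    ``tss`` maps gene -> (chrom, position) tuples or a DataFrame with chrom /
    tss columns.  A gene is assigned to a locus when its TSS lies inside the
    locus interval; genes overlapping no locus stay in the ranking unassigned.
    """
    for i, row in loci.iterrows():
        if not (int(row["start"]) <= int(row["end"])):
            raise ValueError(f"malformed locus interval at line {i + 1}: start > end")
        if row["tier"] not in ("significant", "suggestive"):
            raise ValueError(f"unknown locus tier at line {i + 1}: {row['tier']!r}")
    sel = ranked.head(top_n) if top_n else ranked
    assignments = []
    for _, g in sel.iterrows():
        gene = g["gene_id"]
        if gene not in tss.index:
            assignments.append((None, None))
            continue
        chrom, pos = tss.loc[gene]
        hit = loci.loc[
            (loci["chrom"] == chrom) & (loci["start"] <= int(pos)) & (int(pos) <= loci["end"])
        ]
        if len(hit):
            assignments.append((f"{chrom}:{int(hit.iloc[0]['start'])}-{int(hit.iloc[0]['end'])}", hit.iloc[0]["tier"]))
        else:
            assignments.append((None, None))
    out = sel.copy()
    out["locus"] = [a[0] for a in assignments]
    out["locus_tier"] = [a[1] for a in assignments]
    return out


def locus_tier(p: float, significant: float = 5e-8, suggestive: float = 1e-6) -> str | None:
    """GWAS locus tier from its lead p-value: significant below 5e-8,
    suggestive between 5e-8 and 1e-6."""
    if p < significant:
        return "significant"
    if p < suggestive:
        return "suggestive"
    return None
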