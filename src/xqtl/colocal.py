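"""Bayesian colocalization of two association signals over a shared window.

Tests five mutually exclusive hypotheses about a genomic region given two
sets of single-variant association summaries (e.g. a cis-pQTL and a
cis-eQTL, or a QTL and a GWAS signal):

  H0  no causal variant for either trait
  H1  causal variant for trait 1 only
  H2  causal variant for trait 2 only
  H3  two distinct causal variants
  H4  one causal variant shared by both traits

Each variant's evidence is the Wakefield asymptotic Bayes factor
``log ABF = 0.5 [log(V/(V+W)) + z^2 W/(V+W)]`` with V = se^2 and W the prior
effect variance.  Hypothesis evidence sums over single-causal-variant
configurations (log-sum-exp), weighted by per-configuration priors p1, p2,
p12, and the five posteriors are normalized to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


@dataclass
class ColocConfig:
    window: int = 500_000
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W: float = 0.15**2

    def __post_init__(self) -> None:
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.W <= 0:
            raise ValueError("prior effect variance W must be positive")


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_snps: int

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, float)
        if abs(self.pp.sum() - 1.0) > 1e-9 or (self.pp < -1e-12).any():
            raise ValueError("posteriors must be a probability vector")

    def __getitem__(self, i: int) -> float:
        return float(self.pp[i])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict:
        return {f"PP{i}": float(self.pp[i]) for i in range(5)} | {"n_snps": self.n_snps}


def reconstruct_se(p: np.ndarray, maf: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Approximate the slope standard error for a standardized phenotype:
    se ~= 1 / sqrt(2 n maf (1 - maf))."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def approximate_bayes_factors(assoc: pd.DataFrame, W: float = 0.15**2) -> np.ndarray:
    """Per-variant Wakefield log approximate Bayes factors.

    Variants with nonpositive se are dropped (logged); if se is absent it is
    reconstructed from p/maf/n.
    """
    a = assoc
    if "se" not in a or a["se"].isna().all():
        se = reconstruct_se(a["p"].to_numpy(), a["maf"].to_numpy(), a["n"].to_numpy())
        z = a["z"].to_numpy()
    else:
        bad = ~(a["se"].to_numpy() > 0)
        if bad.any():
            logger.info("dropping %d variants with nonpositive se", int(bad.sum()))
            a = a.loc[~bad]
        se = a["se"].to_numpy()
        z = (a["b"] / a["se"]).to_numpy() if "b" in a else a["z"].to_numpy()
    V = se**2
    r = W / (V + W)
    return 0.5 * (np.log(V / (V + W)) + z**2 * r)


def align_alleles(a1: pd.DataFrame, a2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two summary tables on variant id and harmonize effect
    alleles, flipping the sign of b/z in the second table where its A1/A2
    are swapped relative to the first.  Variants with incompatible alleles
    are dropped."""
    m = a1.merge(a2, on="variant_id", suffixes=("_1", "_2"))
    same = (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
    swapped = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
    keep = same | swapped
    if not keep.all():
        logger.info("dropping %d variants with incompatible alleles", int((~keep).sum()))
    m = m.loc[keep].reset_index(drop=True)
    flip = np.where(m["A1_1"] == m["A1_2"], 1.0, -1.0)
    left_cols = {"variant_id": m["variant_id"], "A1": m["A1_1"], "A2": m["A2_1"]}
    out1 = pd.DataFrame(left_cols)
    out2 = pd.DataFrame(left_cols)
    for c in ("b", "se", "z", "p", "freq", "n"):
        c1, c2 = f"{c}_1", f"{c}_2"
        if c1 in m:
            out1[c] = m[c1]
        if c2 in m:
            sign = flip if c in ("b", "z") else 1.0
            out2[c] = m[c2] * sign if c in ("b", "z") else m[c2]
    return out1, out2


def colocalize(
    assoc1: pd.DataFrame,
    assoc2: pd.DataFrame,
    cfg: ColocConfig | None = None,
    align: bool = True,
) -> ColocResult:
    """Five-hypothesis colocalization posterior from two summary tables.

    Inputs must share variant ids; alleles are harmonized unless
    ``align=False``.  Refuses windows with fewer than 2 shared variants
    (single-causal-variant configurations degenerate).
    """
    cfg = cfg or ColocConfig()
    if align and "A1" in assoc1 and "A1" in assoc2:
        assoc1, assoc2 = align_alleles(assoc1, assoc2)
    else:
        shared = assoc1.merge(assoc2[["variant_id"]], on="variant_id")["variant_id"]
        assoc1 = assoc1.set_index("variant_id").loc[shared].reset_index()
        assoc2 = assoc2.set_index("variant_id").loc[shared].reset_index()
    m = len(assoc1)
    if m < 2:
        raise ValueError(f"only {m} shared variants; colocalization undefined")

    l1 = approximate_bayes_factors(assoc1, cfg.W)
    l2 = approximate_bayes_factors(assoc2, cfg.W)
    return ColocResult(posteriors_from_log_abf(l1, l2, cfg), n_snps=m)


def posteriors_from_log_abf(l1: np.ndarray, l2: np.ndarray, cfg: ColocConfig | None = None) -> np.ndarray:
    """Five-hypothesis posterior vector from two aligned log-ABF vectors."""
    cfg = cfg or ColocConfig()
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # H3: sum over distinct-variant pairs = S1*S2 - sum of same-variant products
    big = s1 + s2
    s3 = big + np.log1p(-np.exp(np.clip(s12 - big, None, -1e-16)))

    logev = np.array(
        [
            0.0,
            np.log(cfg.p1) + s1,
            np.log(cfg.p2) + s2,
            np.log(cfg.p1) + np.log(cfg.p2) + s3,
            np.log(cfg.p12) + s12,
        ]
    )
    pp = np.exp(logev - logsumexp(logev))
    return pp / pp.sum()


def colocalize_window(
    assoc1: pd.DataFrame,
    assoc2: pd.DataFrame,
    center_pos: int,
    positions: pd.Series | dict,
    cfg: ColocConfig | None = None,
) -> ColocResult:
    """Colocalize restricted to variants within ``cfg.window`` of a center
    position (e.g. 500 kb on either side of the top pQTL variant)."""
    cfg = cfg or ColocConfig()
    pos = pd.Series(positions)
    near = pos.index[(pos - center_pos).abs() <= cfg.window]
    a1 = assoc1.loc[assoc1["variant_id"].isin(near)]
    a2 = assoc2.loc[assoc2["variant_id"].isin(near)]
    return colocalize(a1, a2, cfg)
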