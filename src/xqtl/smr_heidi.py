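"""Summary-based Mendelian randomization (SMR) with the HEIDI linkage test.

SMR uses a molecular trait's top QTL as the instrument for the trait's effect
on a disease: b_xy = b_GWAS / b_QTL, with the chi-square(1) statistic

  T_SMR = z_QTL^2 z_GWAS^2 / (z_QTL^2 + z_GWAS^2).

A significant T_SMR is consistent with either a shared causal variant
(causality or pleiotropy) or two distinct variants in LD (linkage).  HEIDI
(heterogeneity in dependent instruments) distinguishes them: under a single
shared variant, b_xy estimated from any LD partner of the instrument equals
the instrument's b_xy; heterogeneity of d_i = b_xy(i) - b_xy(top) across
partners rejects the shared-variant model.  The test statistic sums squared
standardized differences, with the null distribution of the correlated sum
approximated by a Satterthwaite-scaled chi-square matched to the first two
moments implied by the eigenvalues of the d-correlation matrix.

Verdict logic: P_HEIDI < 0.05 -> linkage regardless of P_SMR; otherwise
causal_or_pleiotropic iff P_SMR passes the (Bonferroni by default)
multiple-testing threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SMRConfig:
    top_qtl_p_max: float = 5e-8
    heidi_r2_min: float = 0.05
    heidi_r2_max: float = 0.9
    heidi_max_snps: int = 20
    heidi_candidate_p: float = 1.57e-3  # |z| > 3.16 eligibility for HEIDI partners
    p_heidi_pass: float = 0.05
    smr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.heidi_r2_min < self.heidi_r2_max < 1.0):
            raise ValueError("need 0 < r2_min < r2_max < 1")


@dataclass
class SMRResult:
    trait_id: str
    instrument_variant: str
    b_xy: float
    se_xy: float
    T_smr: float
    P_smr: float
    P_heidi: float  # NaN when undefined (< 3 eligible partners)
    n_heidi_snps: int
    verdict: str  # causal_or_pleiotropic | linkage | not_significant | heidi_undefined


def smr_test(b_qtl: float, se_qtl: float, b_gwas: float, se_gwas: float) -> tuple[float, float, float, float]:
    """Single-instrument SMR: returns (b_xy, se_xy, T_SMR, P_SMR)."""
    if b_qtl == 0:
        raise ValueError("b_qtl = 0: instrument invalid")
    z_q = b_qtl / se_qtl
    z_g = b_gwas / se_gwas
    b_xy = b_gwas / b_qtl
    denom = z_q**2 + z_g**2
    T = (z_q**2 * z_g**2) / denom if denom > 0 else 0.0
    P = float(stats.chi2.sf(T, df=1))
    # delta-method standard error of the ratio
    se_xy = abs(b_xy) * np.sqrt((se_gwas / b_gwas) ** 2 + (se_qtl / b_qtl) ** 2) if b_gwas != 0 else abs(
        se_gwas / b_qtl
    )
    return float(b_xy), float(se_xy), float(T), P


def heidi_test(
    qtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: np.ndarray,
    top_index: int,
    cfg: SMRConfig | None = None,
) -> tuple[float, int]:
    """HEIDI heterogeneity test around one instrument.

    ``qtl`` / ``gwas`` are allele-aligned summaries over the same variants
    (columns b, se); ``ld`` is the variant correlation matrix (signed r) and
    ``top_index`` the instrument's row.  Candidate partners need QTL p below
    ``heidi_candidate_p`` and r^2 with the instrument in [r2_min, r2_max],
    capped at ``heidi_max_snps`` by descending QTL significance.  Returns
    (P_HEIDI, n_snps); P_HEIDI is NaN with fewer than 3 eligible partners.
    """
    cfg = cfg or SMRConfig()
    b_q = qtl["b"].to_numpy(float)
    se_q = qtl["se"].to_numpy(float)
    b_g = gwas["b"].to_numpy(float)
    se_g = gwas["se"].to_numpy(float)
    z_q = b_q / se_q
    p_q = 2.0 * stats.norm.sf(np.abs(z_q))

    r_top = ld[top_index]
    r2 = r_top**2
    eligible = (
        (p_q < cfg.heidi_candidate_p)
        & (r2 >= cfg.heidi_r2_min)
        & (r2 <= cfg.heidi_r2_max)
        & (np.arange(len(b_q)) != top_index)
    )
    cand = np.flatnonzero(eligible)
    if len(cand) > cfg.heidi_max_snps:
        cand = cand[np.argsort(p_q[cand], kind="stable")[: cfg.heidi_max_snps]]
    if len(cand) < 3:
        return float("nan"), int(len(cand))

    idx = np.concatenate([[top_index], cand])
    bq, sq, bg, sg = b_q[idx], se_q[idx], b_g[idx], se_g[idx]
    R = ld[np.ix_(idx, idx)]
    bxy = bg / bq

    # delta-method covariance of bxy_i across partners (QTL and GWAS cohorts
    # independent, so the two sampling contributions add).  Second-order
    # ratio-moment terms matter at moderate instrument strength: for
    # X/Y with Y ~ N(B, s^2), E[X/Y] ~= (E X / B)(1 + c^2) and the
    # GWAS-error variance picks up a (1 + 3 c^2) factor, c = s/B = 1/z_qtl.
    cq2 = (sq / bq) ** 2
    bxy = bxy / (1.0 + cq2)  # ratio-bias correction
    a_g = (sg / bq) * np.sqrt(1.0 + 3.0 * cq2)
    a_q = bxy * (sq / bq)
    cov = R * np.outer(a_g, a_g) + R * np.outer(a_q, a_q)
    k = len(cand)
    d = bxy[1:] - bxy[0]
    cov_d = cov[1:, 1:] - cov[1:, [0]] - cov[[0], 1:] + cov[0, 0]
    var_d = np.diag(cov_d).copy()
    # two-sample LD mismatch: each cohort's marginal effects track its own
    # empirical LD with the causal variant, so b_xy(i) carries extra
    # variance ~ bxy^2 (1 - r^2)^2 (1/n_qtl + 1/n_gwas) / r^2 relative to a
    # fixed reference r (taken as the instrument LD under the null)
    n_q = float(qtl["n"].iloc[0]) if "n" in qtl else np.nan
    n_g = float(gwas["n"].iloc[0]) if "n" in gwas else np.nan
    if np.isfinite(n_q) and np.isfinite(n_g):
        r_i = np.clip(np.abs(r_top[cand]), 0.1, 1.0)
        u = np.abs(bxy[0]) * (1.0 - r_i**2) / r_i * np.sqrt(1.0 / n_q + 1.0 / n_g)
        # neighbors share most of their LD-estimation error; approximate the
        # error correlation between partners by their own LD
        cov_d = cov_d + R[1:, 1:] * np.outer(u, u)
        var_d = np.diag(cov_d).copy()
    var_d[var_d <= 0] = np.finfo(float).tiny
    zd = d / np.sqrt(var_d)
    T = float(zd @ zd)

    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    lam = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    lam = lam[lam > 1e-12]
    if lam.sum() <= 0:
        return 1.0, k
    # Satterthwaite: T ~ g * chi2(h) with g = sum(l^2)/sum(l), h = (sum l)^2 / sum(l^2)
    g = (lam**2).sum() / lam.sum()
    h = lam.sum() ** 2 / (lam**2).sum()
    P = float(stats.chi2.sf(T / g, df=h))
    return P, k


def ld_matrix(dosages: np.ndarray) -> np.ndarray:
    """Signed variant correlation matrix from cohort dosages (in-sample
    reference panel)."""
    return np.corrcoef(dosages, rowvar=False)


def smr_thresholds(n_pgenes: int, n_egenes: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni SMR thresholds for the protein and transcript analyses."""
    if n_pgenes <= 0 or n_egenes <= 0:
        raise ValueError("gene counts must be positive")
    return alpha / n_pgenes, alpha / n_egenes


def smr_heidi(
    trait_id: str,
    qtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: np.ndarray,
    n_tested_traits: int = 1,
    cfg: SMRConfig | None = None,
) -> SMRResult:
    """Run SMR + HEIDI for one trait over an allele-aligned variant window.

    The instrument is the most significant QTL variant; it must reach
    ``top_qtl_p_max``.  The verdict applies the Bonferroni-corrected SMR
    threshold (alpha / n_tested_traits) and the HEIDI pass rule.
    """
    cfg = cfg or SMRConfig()
    z_q = (qtl["b"] / qtl["se"]).to_numpy()
    p_q = 2.0 * stats.norm.sf(np.abs(z_q))
    top = int(np.argmin(p_q))
    if p_q[top] > cfg.top_qtl_p_max:
        raise ValueError(f"top QTL p {p_q[top]:.3g} exceeds instrument threshold {cfg.top_qtl_p_max}")
    b_xy, se_xy, T, P_smr = smr_test(
        float(qtl["b"].iloc[top]), float(qtl["se"].iloc[top]),
        float(gwas["b"].iloc[top]), float(gwas["se"].iloc[top]),
    )
    P_heidi, n_snps = heidi_test(qtl, gwas, ld, top, cfg)
    thr = cfg.smr_alpha / max(1, n_tested_traits)
    if np.isnan(P_heidi):
        verdict = "heidi_undefined"
    elif P_heidi < cfg.p_heidi_pass:
        verdict = "linkage"
    elif P_smr < thr:
        verdict = "causal_or_pleiotropic"
    else:
        verdict = "not_significant"
    return SMRResult(
        trait_id=trait_id,
        instrument_variant=str(qtl["variant_id"].iloc[top]) if "variant_id" in qtl else str(top),
        b_xy=b_xy,
        se_xy=se_xy,
        T_smr=T,
        P_smr=P_smr,
        P_heidi=P_heidi,
        n_heidi_snps=n_snps,
        verdict=verdict,
    )
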