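"""Transcript-mediation test for colocalized protein QTLs.

Classifies a pQTL as transcription-dependent or transcription-independent by
conditional mapping: the variant's effect on protein is re-estimated with the
gene's mRNA level as a covariate.  If the transcript mediates the effect, the
conditional p-value collapses.  Significance of the collapse is calibrated by
permuting the mRNA covariate's sample labels (genotype and protein fixed),
which preserves the SNP-protein association under the no-mediation null:

  x      = -log10(conditional p)
  x_r    = same statistic with the mRNA labels permuted, r = 1..R
  z      = (x_obs - mean(x_r)) / sd(x_r)

A mediator is called when z <= -4.26, the one-sided normal quantile at
p = 1e-5 (0.01 Bonferroni-corrected over 1000 tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: one-sided normal quantile at p = 1e-5, the default classification cutoff
Z_THRESHOLD_DEFAULT = -4.26


def z_cutoff(p: float = 1e-5) -> float:
    """Normal quantile giving the classification threshold (-4.26 at 1e-5)."""
    return float(stats.norm.ppf(p))


@dataclass
class MediationConfig:
    n_permutations: int = 1000
    z_threshold: float = Z_THRESHOLD_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.z_threshold >= 0:
            raise ValueError("z_threshold must be negative (signal collapse is one-sided)")


@dataclass
class MediationResult:
    trait_id: str
    variant_id: str
    unconditional_p: float
    conditional_p: float
    null_mean: float
    null_sd: float
    z: float
    classification: str
    flagged: bool = False


def _partial_t_p(r_pg: np.ndarray, r_pm: np.ndarray, r_mg: np.ndarray, n: int):
    """t-test p-value for the dosage term in protein ~ mRNA + dosage,
    expressed through pairwise correlations (n - 3 dof)."""
    denom = np.sqrt(np.maximum((1.0 - r_pm**2) * (1.0 - r_mg**2), 1e-300))
    r_part = (r_pg - r_pm * r_mg) / denom
    r_part = np.clip(r_part, -1.0 + 1e-15, 1.0 - 1e-15)
    t = r_part * np.sqrt((n - 3) / (1.0 - r_part**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 3)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def conditional_scan(
    protein: np.ndarray, mrna: np.ndarray, dosage: np.ndarray
) -> tuple[float, float]:
    """p-value (and slope) of the variant in protein ~ intercept + mRNA + dosage.

    Raises if mRNA is collinear with dosage (|r| > 0.999), where the
    conditional effect is unidentifiable.
    """
    n = len(protein)
    X = np.column_stack([np.ones(n), mrna, dosage])
    r_mg = float(np.corrcoef(mrna, dosage)[0, 1])
    if abs(r_mg) > 0.999:
        raise ValueError("mRNA collinear with dosage; conditional p undefined")
    beta, *_ = np.linalg.lstsq(X, protein, rcond=None)
    resid = protein - X @ beta
    sigma2 = resid @ resid / (n - 3)
    if sigma2 <= 1e-24 * protein.var():
        # numerically perfect fit: the dosage term's t-statistic is 0/0
        # noise; a vanishing coefficient means the mediator explains it all
        if abs(beta[2]) < 1e-8 * max(1.0, abs(beta[1])):
            return 1.0, float(beta[2])
        return float(np.finfo(float).tiny), float(beta[2])
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[2, 2])
    if se == 0:
        return float(np.finfo(float).tiny), float(beta[2])
    t = beta[2] / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df=n - 3), np.finfo(float).tiny, 1.0))
    return p, float(beta[2])


def mediation_test(
    protein: np.ndarray,
    mrna: np.ndarray,
    dosage: np.ndarray,
    cfg: MediationConfig | None = None,
    trait_id: str = "",
    variant_id: str = "",
    rng: np.random.Generator | None = None,
) -> MediationResult:
    """Permutation-null mediation z-score for one protein / mRNA / variant.

    The null permutes only the mRNA covariate; the observed drop statistic
    x = -log10(p_conditional) is standardized against the permutation
    moments.  A degenerate null (sd = 0) yields an independent call with
    ``flagged=True``.
    """
    cfg = cfg or MediationConfig()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = len(protein)

    ps = (protein - protein.mean()) / protein.std()
    ms = (mrna - mrna.mean()) / mrna.std()
    gs = (dosage - dosage.mean()) / dosage.std()
    r_pg = float(ps @ gs / n)
    r_mg = float(ms @ gs / n)
    if abs(r_mg) > 0.999:
        raise ValueError("mRNA collinear with dosage; conditional p undefined")
    r_pm = float(ps @ ms / n)

    # unconditional p from simple regression (n - 2 dof)
    t_u = r_pg * np.sqrt((n - 2) / max(1.0 - r_pg**2, 1e-300))
    p_uncond = float(np.clip(2.0 * stats.t.sf(abs(t_u), df=n - 2), np.finfo(float).tiny, 1.0))

    p_cond = float(_partial_t_p(np.array([r_pg]), np.array([r_pm]), np.array([r_mg]), n)[0])
    x_obs = -np.log10(p_cond)

    R = cfg.n_permutations
    perms = rng.permuted(np.broadcast_to(ms, (R, n)).copy(), axis=1)  # R x n
    r_pm_r = perms @ ps / n
    r_mg_r = perms @ gs / n
    p_r = _partial_t_p(np.full(R, r_pg), r_pm_r, r_mg_r, n)
    x_r = -np.log10(p_r)

    mu, sd = float(x_r.mean()), float(x_r.std(ddof=1))
    if sd == 0:
        logger.info("degenerate permutation null for %s; calling independent", trait_id)
        return MediationResult(trait_id, variant_id, p_uncond, p_cond, mu, 0.0, np.nan, "independent", True)
    z = (x_obs - mu) / sd
    cls = "dependent" if z <= cfg.z_threshold else "independent"
    return MediationResult(trait_id, variant_id, p_uncond, p_cond, mu, sd, float(z), cls, False)


def mediation_summary(
    results: list[MediationResult],
    mrna_values: dict[str, np.ndarray] | None = None,
    protein_values: dict[str, np.ndarray] | None = None,
) -> dict:
    """Counts and percentages per class, plus (optionally) the per-class mean
    Pearson correlation between mRNA and protein levels."""
    n = len(results)
    dep = [r for r in results if r.classification == "dependent"]
    ind = [r for r in results if r.classification == "independent"]
    out = {
        "n": n,
        "n_dependent": len(dep),
        "n_independent": len(ind),
        "pct_dependent": 100.0 * len(dep) / n if n else np.nan,
        "pct_independent": 100.0 * len(ind) / n if n else np.nan,
    }
    if mrna_values and protein_values:
        for name, grp in (("dependent", dep), ("independent", ind)):
            rs = [
                float(np.corrcoef(mrna_values[r.trait_id], protein_values[r.trait_id])[0, 1])
                for r in grp
                if r.trait_id in mrna_values and r.trait_id in protein_values
            ]
            out[f"mean_r_{name}"] = float(np.mean(rs)) if rs else np.nan
    return out
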