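"""Cis and trans QTL mapping with permutation-calibrated significance.

Per trait, all variants in the cis window (TSS +/- 1 Mb by default) are
scanned with simple linear regression on dosage; per-trait multiple testing
over the window is calibrated by permuting sample labels, recording the
minimum nominal p of each permutation, and fitting a Beta(a, b) distribution
to those minima by maximum likelihood.  The beta-adjusted empirical p-value
of the observed top association is the fitted Beta CDF evaluated at the
observed minimum nominal p; genome-wide FDR across traits uses Storey's
q-value.  Trans scans use the conservative Bonferroni threshold
alpha / (n_variants x n_traits).

Sign convention: the reported ``beta`` is oriented to the reference allele
(positive beta = higher expression in the presence of the reference allele);
``slope`` is the raw regression slope on ALT-allele dosage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import GenotypeMatrix, TraitMatrix

logger = logging.getLogger(__name__)


@dataclass
class WindowConfig:
    cis_window: int = 1_000_000
    trans_min_distance: int = 5_000_000
    n_permutations: int = 10_000

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.trans_min_distance <= self.cis_window:
            raise ValueError("trans_min_distance must exceed cis_window")


# ---------------------------------------------------------------------------
# nominal association scan
# ---------------------------------------------------------------------------

def _regress(dosage: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple regression of y on each dosage column.

    Returns (slope, se, t, p) with a t-test on n-2 degrees of freedom.
    """
    n = len(y)
    yc = y - y.mean()
    dc = dosage - dosage.mean(axis=0)
    sxx = np.einsum("ij,ij->j", dc, dc)
    sxy = dc.T @ yc
    slope = sxy / sxx
    rss = yc @ yc - slope * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return slope, se, t, p


def cis_window_mask(trait_row: pd.Series, variants: pd.DataFrame, cis_window: int) -> np.ndarray:
    same = variants["chrom"].to_numpy() == trait_row["chrom"]
    dist = variants["pos"].to_numpy() - int(trait_row["tss"])
    return same & (np.abs(dist) <= cis_window)


def trans_mask(trait_row: pd.Series, variants: pd.DataFrame, min_distance: int) -> np.ndarray:
    other = variants["chrom"].to_numpy() != trait_row["chrom"]
    pos = variants["pos"].to_numpy()
    far = (pos < int(trait_row["gene_start"]) - min_distance) | (
        pos > int(trait_row["gene_end"]) + min_distance
    )
    return other | (~other & far)


def nominal_scan(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    window: WindowConfig | None = None,
    mode: str = "cis",
) -> dict[str, pd.DataFrame]:
    """Per-trait association summaries for every variant in the window.

    Returns ``{trait_id: DataFrame}`` with columns variant_id, A1, A2, freq,
    b (slope on ALT dosage), se, z, p, n, tss_distance.  A trait with no
    variants in its window maps to an empty frame.
    """
    window = window or WindowConfig()
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be 'cis' or 'trans'")
    out: dict[str, pd.DataFrame] = {}
    v = geno.variants
    for i, row in traits.traits.iterrows():
        mask = (
            cis_window_mask(row, v, window.cis_window)
            if mode == "cis"
            else trans_mask(row, v, window.trans_min_distance)
        )
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            out[row["trait_id"]] = pd.DataFrame(
                columns=["variant_id", "A1", "A2", "freq", "b", "se", "z", "p", "n", "tss_distance"]
            )
            continue
        y = traits.values[i]
        slope, se, t, p = _regress(geno.dosages[:, idx], y)
        sub = v.iloc[idx]
        out[row["trait_id"]] = pd.DataFrame(
            {
                "variant_id": sub["id"].to_numpy(),
                "A1": sub["alt"].to_numpy(),
                "A2": sub["ref"].to_numpy(),
                "freq": geno.dosages[:, idx].mean(axis=0) / 2.0,
                "b": slope,
                "se": se,
                "z": np.where(np.isfinite(t), t, np.sign(slope) * 1e308),
                "p": p,
                "n": len(y),
                "tss_distance": sub["pos"].to_numpy() - int(row["tss"]),
            }
        )
    return out


# ---------------------------------------------------------------------------
# permutation pass
# ---------------------------------------------------------------------------

def _fit_beta_mle(pmins: np.ndarray) -> tuple[float, float, bool]:
    """MLE of Beta(a, b) on permutation minimum p-values (support clipped
    away from {0, 1}); returns (a, b, converged)."""
    x = np.clip(pmins, 1e-300, 1.0 - 1e-12)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        ok = np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0
        return float(a), float(b), bool(ok)
    except Exception:
        return np.nan, np.nan, False


def permutation_pass(
    trait_values: np.ndarray,
    nominal: pd.DataFrame,
    dosages: np.ndarray,
    R: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Beta-approximated empirical p for one trait's top cis association.

    Permutes the trait's sample labels R times, rescans the window each time
    and records the minimum nominal p; fits Beta(a, b) to the minima by MLE.
    ``adjusted_p = BetaCDF(min observed nominal p)`` and
    ``direct_empirical_p = (1 + #{perm <= obs}) / (R + 1)``.  The top variant
    is the argmin of nominal p, ties broken by smallest |TSS distance| then
    lexical variant id.  On MLE failure the record falls back to the direct
    empirical p (``converged = False``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(trait_values)
    m = len(nominal)
    if m == 0:
        return {}

    order = np.lexsort(
        (nominal["variant_id"].to_numpy(), np.abs(nominal["tss_distance"].to_numpy()), nominal["p"].to_numpy())
    )
    top = nominal.iloc[order[0]]
    p_obs = float(nominal["p"].min())

    if m == 1:
        # no multiplicity: empirical p equals the nominal p
        return {
            "trait_id": None,
            "variant_id": top["variant_id"],
            "slope": float(top["b"]),
            "beta": -float(top["b"]),
            "se": float(top["se"]),
            "nominal_p": p_obs,
            "adjusted_p": p_obs,
            "direct_empirical_p": p_obs,
            "tss_distance": int(top["tss_distance"]),
            "n_tested_variants": 1,
            "beta_shape1": 1.0,
            "beta_shape2": 1.0,
            "converged": True,
        }

    gs = (dosages - dosages.mean(axis=0)) / dosages.std(axis=0)
    ys = (trait_values - trait_values.mean()) / trait_values.std()
    perms = rng.permuted(np.broadcast_to(ys, (R, n)).copy(), axis=1)
    corr = np.abs(gs.T @ perms.T) / n  # m x R
    rmax = corr.max(axis=0)
    rmax = np.clip(rmax, 0.0, 1.0 - 1e-15)
    tmax = rmax * np.sqrt((n - 2) / (1.0 - rmax**2))
    pmins = np.clip(2.0 * stats.t.sf(tmax, df=n - 2), np.finfo(float).tiny, 1.0)

    direct = (1.0 + np.sum(pmins <= p_obs)) / (R + 1.0)
    a, b, ok = _fit_beta_mle(pmins)
    adjusted = float(stats.beta.cdf(p_obs, a, b)) if ok else direct

    return {
        "trait_id": None,
        "variant_id": top["variant_id"],
        "slope": float(top["b"]),
        "beta": -float(top["b"]),
        "se": float(top["se"]),
        "nominal_p": p_obs,
        "adjusted_p": adjusted,
        "direct_empirical_p": direct,
        "tss_distance": int(top["tss_distance"]),
        "n_tested_variants": m,
        "beta_shape1": a,
        "beta_shape2": b,
        "converged": ok,
        "perm_min_p": pmins,
    }


def map_cis(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    window: WindowConfig | None = None,
    seed: int = 0,
    keep_null: bool = False,
) -> pd.DataFrame:
    """Full cis pass: nominal scan + permutation pass + Storey q-values.

    One row per trait (its top variant).  Each trait gets its own
    permutation stream seeded by (seed, trait index) for reproducibility.
    """
    window = window or WindowConfig()
    scans = nominal_scan(traits, geno, window, mode="cis")
    v = geno.variants
    id_to_col = {vid: j for j, vid in enumerate(v["id"])}
    rows = []
    for i, trow in traits.traits.iterrows():
        tid = trow["trait_id"]
        nom = scans[tid]
        if len(nom) == 0:
            continue
        cols = [id_to_col[x] for x in nom["variant_id"]]
        rec = permutation_pass(
            traits.values[i],
            nom,
            geno.dosages[:, cols],
            R=window.n_permutations,
            rng=np.random.default_rng((seed, i)),
        )
        rec["trait_id"] = tid
        if not keep_null:
            rec.pop("perm_min_p", None)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out["qvalue"] = storey_qvalues(out["adjusted_p"].to_numpy())
    return out


def map_trans(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    window: WindowConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Trans scan of all eligible variant-trait pairs against the Bonferroni
    threshold alpha / (n_variants x n_traits)."""
    window = window or WindowConfig()
    scans = nominal_scan(traits, geno, window, mode="trans")
    thr = trans_threshold(geno.n_variants, traits.n_traits, alpha)
    hits = []
    for tid, nom in scans.items():
        sig = nom.loc[nom["p"] < thr]
        for _, r in sig.iterrows():
            hits.append(
                dict(
                    trait_id=tid,
                    variant_id=r["variant_id"],
                    slope=r["b"],
                    beta=-r["b"],
                    se=r["se"],
                    nominal_p=r["p"],
                    threshold=thr,
                )
            )
    return pd.DataFrame(hits, columns=["trait_id", "variant_id", "slope", "beta", "se", "nominal_p", "threshold"])


#: QTLtools-style permutation-output column order (q-value appended)
QTL_COLUMNS = [
    "phenotype_id", "phenotype_chrom", "phenotype_start", "phenotype_end", "strand",
    "n_variants", "distance", "variant_id", "variant_chrom", "variant_pos", "dof",
    "beta_shape1", "beta_shape2", "nominal_p", "slope", "adjusted_p", "qvalue",
]


def to_qtltools_table(records: pd.DataFrame, traits: TraitMatrix, geno: GenotypeMatrix) -> pd.DataFrame:
    """Arrange per-trait top-variant records in the QTLtools permutation
    output column order, with the q-value column appended."""
    t = traits.traits.set_index("trait_id")
    v = geno.variants.set_index("id")
    rows = []
    for _, r in records.iterrows():
        trow = t.loc[r["trait_id"]]
        vrow = v.loc[r["variant_id"]]
        rows.append(
            {
                "phenotype_id": r["trait_id"],
                "phenotype_chrom": trow["chrom"],
                "phenotype_start": int(trow["gene_start"]),
                "phenotype_end": int(trow["gene_end"]),
                "strand": trow["strand"],
                "n_variants": int(r["n_tested_variants"]),
                "distance": int(r["tss_distance"]),
                "variant_id": r["variant_id"],
                "variant_chrom": vrow["chrom"],
                "variant_pos": int(vrow["pos"]),
                "dof": geno.n_samples - 2,
                "beta_shape1": r["beta_shape1"],
                "beta_shape2": r["beta_shape2"],
                "nominal_p": r["nominal_p"],
                "slope": r["slope"],
                "adjusted_p": r["adjusted_p"],
                "qvalue": r.get("qvalue", np.nan),
            }
        )
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


# ---------------------------------------------------------------------------
# FDR and thresholds
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate with cubic-smoother extrapolation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid; a cubic
    polynomial in lambda is fit to the curve and evaluated at lambda -> 1,
    then clipped to (0, 1].
    """
    p = np.asarray(p, float)
    lambdas = np.arange(0.05, 0.951, 0.05) if lambdas is None else lambdas
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, 1.0))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with fewer than 100 p-values pi0 is fixed at 1
    (equivalent to Benjamini-Hochberg)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 100:
            warnings.warn("fewer than 100 p-values: pi0 fixed at 1 (BH-equivalent)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = pi0 * np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def trans_threshold(n_variants: int, n_traits: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold over all variant x trait pairs."""
    if n_variants <= 0 or n_traits <= 0:
        raise ValueError("variant and trait counts must be positive")
    return alpha / (n_variants * n_traits)


# ---------------------------------------------------------------------------
# annotation summaries
# ---------------------------------------------------------------------------

def annotation_product(exonic_pct: float, nonsyn_within_exonic_pct: float) -> float:
    """Overall non-synonymous percentage = exonic % x (non-syn | exonic) %."""
    return exonic_pct * nonsyn_within_exonic_pct / 100.0


def summarize_annotations(
    records: pd.DataFrame,
    variants: pd.DataFrame,
    q_threshold: float = 0.05,
    tss_window: int = 10_000,
) -> dict:
    """Annotation-class fractions among significant QTLs (q < threshold).

    Reports per-class percentages, the percentage within ``tss_window`` bp of
    the TSS, the overall non-synonymous percentage (exonic fraction times the
    non-synonymous fraction within exonic), and pleiotropic variants
    (associated with more than one trait).
    """
    sig = records.loc[records["qvalue"] < q_threshold] if "qvalue" in records else records
    n = len(sig)
    out: dict = {"n_significant": n, "class_pct": {}, "tss_within_pct": np.nan, "nonsyn_overall_pct": np.nan}
    if n == 0:
        return out
    anno = variants.set_index("id")["anno_class"]
    classes = sig["variant_id"].map(anno)
    for c in anno.unique():
        out["class_pct"][c] = 100.0 * (classes == c).mean()
    exonic = classes.isin(["exonic_nonsyn", "exonic_syn"])
    out["exonic_pct"] = 100.0 * exonic.mean()
    nonsyn_within = (classes[exonic] == "exonic_nonsyn").mean() if exonic.any() else np.nan
    out["nonsyn_within_exonic_pct"] = 100.0 * nonsyn_within
    out["nonsyn_overall_pct"] = annotation_product(out["exonic_pct"], out["nonsyn_within_exonic_pct"])
    out["tss_within_pct"] = 100.0 * (sig["tss_distance"].abs() <= tss_window).mean()
    counts = sig.groupby("variant_id")["trait_id"].nunique()
    out["pleiotropic_variants"] = counts.index[counts > 1].tolist()
    return out
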