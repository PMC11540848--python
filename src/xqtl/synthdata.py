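"""Synthetic cohort generator for the xQTL pipeline.

Generates genotype dosages with block LD, mRNA / protein trait matrices with
hidden confounders and known cis architecture, GWAS summary statistics under
causal / pleiotropic / linkage / null scenarios, and multiplexed isobaric
(TMT-style) PSM reporter-intensity tables.  Every downstream stage of the
pipeline is exercised against these generators, whose ground truth is returned
alongside the data.

Model sketch
------------
* Genotypes: per block, 2n latent haplotype vectors follow an AR(1) Gaussian
  process with correlation ``ld_rho``; each latent value is thresholded at the
  normal quantile of the variant's allele frequency, and the two haplotypes
  are summed to a dosage in {0,1,2}.  Blocks live on separate chromosomes, so
  cross-block LD is exactly zero and Hardy-Weinberg holds by construction.
* mRNA: ``beta * standardized dosage + loadings @ hidden_factors + noise``.
* Protein: transcript-dependent genes inherit the SNP effect through mRNA
  (``b_med * mRNA + noise``); transcript-independent genes get a direct SNP
  effect with no mRNA term.
* GWAS: a phenotype is built in an independently drawn cohort (two-sample
  setting) from the target gene's molecular trait (causal), directly from the
  causal variant (pleiotropy), or from an LD partner (linkage); marginal
  per-variant regressions give b / se / z / p.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANNO_CLASSES = ("exonic_nonsyn", "exonic_syn", "intronic", "intergenic", "regulatory")
# default mixture for the annotation metadata attached to simulated variants
_ANNO_PROBS = (0.05, 0.05, 0.35, 0.40, 0.15)

GWAS_SCENARIOS = ("causal", "pleiotropic", "linkage", "null")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the proteogenomic study the pipeline models: 268 brain
    samples, a standardized cis effect of 0.5 (the "large effect" regime),
    and ~79% of protein traits regulated through their transcript.
    """

    n_samples: int = 268
    n_variants: int = 200
    n_blocks: int = 10
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_effect_beta: float = 0.5
    mediation_fraction: float = 0.79
    n_hidden_factors: int = 5
    noise_sd: float = 1.0
    seed: int = 0
    # secondary knobs (not part of the headline conditions)
    variant_spacing: int = 10_000
    mediation_slope: float = 0.8
    independent_effect_scale: float = 1.5
    # cis effect of the mRNA paired with a transcript-independent protein;
    # 0 mirrors the empirical pattern of a pQTL with no eQTL support
    independent_mrna_beta: float = 0.0
    factor_loading_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_blocks", "n_hidden_factors"):
            if getattr(self, name) < 0 or (name != "n_hidden_factors" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0.01 <= lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.mediation_fraction <= 1.0):
            raise ValueError("mediation_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    ``dosages[i, j]`` is the ALT-allele count of sample ``i`` at variant ``j``
    (VCF-native orientation).  ``variants`` carries id, chrom, pos, ref, alt,
    maf, anno_class and the simulation block index.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples/variants metadata")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_maf(self) -> np.ndarray:
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, sd 1)."""
        d = self.dosages
        return (d - d.mean(axis=0)) / d.std(axis=0)


@dataclass
class TraitMatrix:
    """Traits x samples abundance matrix with per-trait gene coordinates."""

    values: np.ndarray
    traits: pd.DataFrame  # trait_id, gene_id, chrom, tss, gene_start, gene_end, strand
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.traits), len(self.samples)):
            raise ValueError("trait values shape does not match metadata")
        t = self.traits
        if len(t):
            plus = t["strand"] == "+"
            ok_plus = (t.loc[plus, "gene_start"] <= t.loc[plus, "tss"]) & (
                t.loc[plus, "tss"] <= t.loc[plus, "gene_end"]
            )
            minus = ~plus
            ok_minus = (t.loc[minus, "gene_start"] <= t.loc[minus, "tss"]) & (
                t.loc[minus, "tss"] <= t.loc[minus, "gene_end"]
            )
            if not (ok_plus.all() and ok_minus.all()):
                raise ValueError("TSS must lie within [gene_start, gene_end]")
        if len(t) and np.isnan(self.values).all(axis=1).any():
            raise ValueError("trait with all-missing values")

    @property
    def n_traits(self) -> int:
        return self.values.shape[0]

    def subset(self, trait_ids: Sequence[str]) -> "TraitMatrix":
        idx = self.traits.index[self.traits["trait_id"].isin(set(trait_ids))]
        return TraitMatrix(
            self.values[idx.to_numpy()],
            self.traits.loc[idx].reset_index(drop=True),
            list(self.samples),
        )


@dataclass
class GwasSummary:
    """Per-variant marginal association summaries for one GWAS trait.

    ``records`` columns: variant_id, A1 (effect allele), A2, freq, b, se, z,
    p, n.  ``scenario`` tags the generative mechanism of the signal.
    """

    records: pd.DataFrame
    trait_name: str
    scenario: str

    def __post_init__(self) -> None:
        if self.scenario not in GWAS_SCENARIOS:
            raise ValueError(f"scenario must be one of {GWAS_SCENARIOS}, got {self.scenario!r}")
        r = self.records
        if (r["se"] <= 0).any() or (r["n"] <= 0).any():
            raise ValueError("all records need se > 0 and n > 0")
        if not np.allclose(r["z"], r["b"] / r["se"], atol=1e-8):
            raise ValueError("z must equal b/se")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _block_sizes(n_variants: int, n_blocks: int) -> list[int]:
    base, extra = divmod(n_variants, n_blocks)
    return [base + (1 if b < extra else 0) for b in range(n_blocks)]


def _ar1_latent(rng: np.random.Generator, n_rows: int, m: int, rho: float) -> np.ndarray:
    """AR(1) latent Gaussian rows: z_j = rho z_{j-1} + sqrt(1-rho^2) e_j."""
    z = np.empty((n_rows, m))
    e = rng.standard_normal((n_rows, m))
    z[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + c * e[:, j]
    return z


def simulate_genotypes(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw a dosage matrix under HWE with within-block AR(1) LD.

    Each block sits on its own synthetic chromosome; variants are spaced
    ``cfg.variant_spacing`` bp apart starting at position 1.  Constant
    columns (possible at extreme allele frequencies) are redrawn i.i.d.
    binomially so that every variant is polymorphic in-sample.

    Passing ``freqs`` fixes the population allele frequencies (e.g. to draw
    a second cohort from the same variant panel); the frequencies used are
    stored in the variant metadata as ``freq_pop``.
    """
    if cfg.n_samples < 30:
        raise ValueError("n_samples < 30: association analysis downstream is undefined")
    rng = cfg.rng(1) if rng is None else rng

    sizes = _block_sizes(cfg.n_variants, cfg.n_blocks)
    lo, hi = cfg.maf_range
    if freqs is None:
        freqs = rng.uniform(lo, hi, size=cfg.n_variants)
    else:
        freqs = np.asarray(freqs, float)
        if len(freqs) != cfg.n_variants:
            raise ValueError("freqs length must equal n_variants")
    thresholds = stats.norm.ppf(freqs)

    dosage_cols: list[np.ndarray] = []
    meta: dict[str, list] = {
        k: [] for k in ("id", "chrom", "pos", "ref", "alt", "maf", "anno_class", "block", "freq_pop")
    }
    j0 = 0
    for b, m in enumerate(sizes):
        z = _ar1_latent(rng, 2 * cfg.n_samples, m, cfg.ld_rho)
        alleles = (z < thresholds[j0 : j0 + m][None, :]).astype(float)
        dos = alleles[: cfg.n_samples] + alleles[cfg.n_samples :]
        chrom = f"chr{b + 1}"
        for k in range(m):
            col = dos[:, k]
            while col.min() == col.max():  # redraw monomorphic columns
                col = rng.binomial(2, freqs[j0 + k], size=cfg.n_samples).astype(float)
            dos[:, k] = col
            pos = 1 + k * cfg.variant_spacing
            meta["id"].append(f"{chrom}_snp{k + 1}")
            meta["chrom"].append(chrom)
            meta["pos"].append(pos)
            meta["ref"].append("A")
            meta["alt"].append("G")
            af = col.mean() / 2.0
            meta["maf"].append(min(af, 1.0 - af))
            meta["anno_class"].append(ANNO_CLASSES[rng.choice(len(ANNO_CLASSES), p=_ANNO_PROBS)])
            meta["block"].append(b)
            meta["freq_pop"].append(freqs[j0 + k])
        dosage_cols.append(dos)
        j0 += m

    dosages = np.concatenate(dosage_cols, axis=1)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(dosages, pd.DataFrame(meta), samples)


# ---------------------------------------------------------------------------
# molecular traits
# ---------------------------------------------------------------------------

def simulate_traits(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TraitMatrix, TraitMatrix, pd.DataFrame]:
    """Simulate mRNA and protein traits with one causal cis variant per gene.

    One gene per LD block.  A ``mediation_fraction`` of genes are
    transcript-dependent (protein inherits the SNP effect through mRNA);
    the rest carry a direct, larger SNP effect on protein with no mRNA term
    (the empirical direction: SNP effects surviving at the protein level
    without transcript support tend to be larger).

    Returns (mRNA, protein, truth) where the truth table has one row per
    gene: class label, causal variant, and all generative coefficients.
    """
    rng = cfg.rng(2) if rng is None else rng
    n, p = geno.n_samples, geno.n_variants
    n_genes = cfg.n_blocks
    blocks = geno.variants["block"].to_numpy()

    n_dep = int(round(cfg.mediation_fraction * n_genes))
    classes = np.array(["dependent"] * n_dep + ["independent"] * (n_genes - n_dep))
    rng.shuffle(classes)

    factors = rng.standard_normal((cfg.n_hidden_factors, n))
    gs = geno.standardized()

    mrna = np.empty((n_genes, n))
    prot = np.empty((n_genes, n))
    truth_rows = []
    trait_meta = []
    for g in range(n_genes):
        in_block = np.flatnonzero(blocks == g)
        causal = int(in_block[len(in_block) // 2])
        v = geno.variants.iloc[causal]
        tss = int(v["pos"])
        strand = "+" if g % 2 == 0 else "-"
        gene_len = 50_000
        if strand == "+":
            gene_start, gene_end = tss, tss + gene_len
        else:
            gene_start, gene_end = max(1, tss - gene_len), tss
        if abs(int(v["pos"]) - tss) > 1_000_000:
            raise RuntimeError("generator contract violated: causal variant outside cis window")

        lam = rng.normal(0.0, cfg.factor_loading_sd, size=cfg.n_hidden_factors)
        eps_m = rng.normal(0.0, cfg.noise_sd, size=n)
        beta_m = cfg.cis_effect_beta if classes[g] == "dependent" else cfg.independent_mrna_beta
        mrna[g] = beta_m * gs[:, causal] + lam @ factors + eps_m

        eps_p = rng.normal(0.0, cfg.noise_sd, size=n)
        if classes[g] == "dependent":
            b_med = cfg.mediation_slope
            beta_direct = np.nan
            prot[g] = b_med * mrna[g] + eps_p
        else:
            b_med = np.nan
            beta_direct = cfg.independent_effect_scale * cfg.cis_effect_beta
            prot[g] = beta_direct * gs[:, causal] + eps_p

        gene_id = f"gene{g + 1}"
        truth_rows.append(
            dict(
                gene_id=gene_id,
                clazz=classes[g],
                causal_variant=v["id"],
                causal_index=causal,
                beta_mrna=beta_m,
                beta_protein_direct=beta_direct,
                mediation_slope=b_med,
            )
        )
        trait_meta.append(
            dict(
                gene_id=gene_id,
                chrom=v["chrom"],
                tss=tss,
                gene_start=gene_start,
                gene_end=gene_end,
                strand=strand,
            )
        )

    meta = pd.DataFrame(trait_meta)
    mrna_meta = meta.copy()
    mrna_meta.insert(0, "trait_id", [f"{g}_mrna" for g in meta["gene_id"]])
    prot_meta = meta.copy()
    prot_meta.insert(0, "trait_id", [f"{g}_prot" for g in meta["gene_id"]])

    truth = pd.DataFrame(truth_rows).rename(columns={"clazz": "class"})
    samples = list(geno.samples)
    return TraitMatrix(mrna, mrna_meta, samples), TraitMatrix(prot, prot_meta, samples), truth


# ---------------------------------------------------------------------------
# GWAS summaries
# ---------------------------------------------------------------------------

def marginal_gwas(dosages: np.ndarray, phenotype: np.ndarray, variants: pd.DataFrame) -> pd.DataFrame:
    """Per-variant simple regression of phenotype on ALT dosage (b, se, z, p)."""
    n = len(phenotype)
    y = phenotype - phenotype.mean()
    d = dosages - dosages.mean(axis=0)
    sxx = (d * d).sum(axis=0)
    b = (d * y[:, None]).sum(axis=0) / sxx
    resid_ss = (y * y).sum() - b * b * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    z = b / se
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    af = dosages.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "variant_id": variants["id"].to_numpy(),
            "A1": variants["alt"].to_numpy(),
            "A2": variants["ref"].to_numpy(),
            "freq": af,
            "b": b,
            "se": se,
            "z": z,
            "p": p,
            "n": n,
        }
    )


def simulate_gwas(
    geno: GenotypeMatrix,
    truth: pd.DataFrame,
    scenario: str,
    cfg: SimConfig,
    target_gene: str | None = None,
    effect_ratio: float = 0.3,
    pleiotropy_effect: float = 0.3,
    n_gwas: int | None = None,
    independent_cohort: bool = True,
    linkage_offset: int = 2,
    rng: np.random.Generator | None = None,
) -> GwasSummary:
    """GWAS summary statistics under a chosen mechanistic scenario.

    causal       phenotype = effect_ratio * (resimulated target mRNA) + noise,
                 so the SMR ratio b_GWAS/b_QTL targets ``effect_ratio``.
    pleiotropic  phenotype built directly from the causal variant.
    linkage      phenotype built from an LD partner ``linkage_offset`` variants
                 away from the molecular QTL.
    null         pure noise.

    By default the GWAS cohort is an independent draw from the same genotype
    distribution (two-sample setting); pass ``independent_cohort=False`` to
    reuse the QTL cohort.
    """
    if scenario not in GWAS_SCENARIOS:
        raise ValueError(f"scenario must be one of {GWAS_SCENARIOS}, got {scenario!r}")
    rng = cfg.rng(3) if rng is None else rng

    if independent_cohort:
        n2 = n_gwas or cfg.n_samples
        panel_freqs = geno.variants["freq_pop"].to_numpy() if "freq_pop" in geno.variants else None
        cohort = simulate_genotypes(replace(cfg, n_samples=n2), rng=rng, freqs=panel_freqs)
    else:
        cohort = geno
    n2 = cohort.n_samples
    gs = cohort.standardized()

    if target_gene is None:
        with_eqtl = truth.loc[truth["beta_mrna"] != 0]
        row = with_eqtl.iloc[0] if len(with_eqtl) else truth.iloc[0]
    else:
        row = truth.loc[truth["gene_id"] == target_gene].iloc[0]
    causal = int(row["causal_index"])

    if scenario == "null":
        y = rng.standard_normal(n2)
    elif scenario == "causal":
        mrna2 = row["beta_mrna"] * gs[:, causal] + rng.normal(0.0, cfg.noise_sd, size=n2)
        y = effect_ratio * mrna2 + rng.standard_normal(n2)
    elif scenario == "pleiotropic":
        y = pleiotropy_effect * gs[:, causal] + rng.standard_normal(n2)
    else:  # linkage
        block = cohort.variants.iloc[causal]["block"]
        in_block = np.flatnonzero(cohort.variants["block"].to_numpy() == block)
        pos = int(np.flatnonzero(in_block == causal)[0])
        partner = in_block[min(pos + linkage_offset, len(in_block) - 1)]
        if partner == causal:
            partner = in_block[max(pos - linkage_offset, 0)]
        y = pleiotropy_effect * gs[:, partner] + rng.standard_normal(n2)

    records = marginal_gwas(cohort.dosages, y, cohort.variants)
    return GwasSummary(records, trait_name=f"gwas_{scenario}", scenario=scenario)


# ---------------------------------------------------------------------------
# PSM reporter-intensity tables
# ---------------------------------------------------------------------------

def simulate_psm_table(
    n_proteins: int,
    n_batches: int,
    impurity: "np.ndarray | object" = None,
    seed: int = 0,
    n_channels: int = 11,
    psm_per_protein: int = 4,
    base_log2_mean: float = 16.0,
    base_log2_sd: float = 1.5,
    sample_effect_sd: float = 0.5,
    channel_loading_sd: float = 0.1,
    noise_sd: float = 0.05,
    low_intensity_fraction: float = 0.05,
    missing_fraction: float = 0.02,
):
    """Simulate a multi-batch isobaric-labeling PSM table with ground truth.

    Each batch carries ``n_channels - 1`` distinct sample channels plus one
    internal-standard channel equal to the mean of the batch's samples (the
    pooled-reference design).  PSM intensity = protein truth x channel
    loading x lognormal noise, mixed through the label-impurity matrix.
    A ``low_intensity_fraction`` of PSMs are scaled down so they fall below
    the min-1000 / median-5000 quality filters; ``missing_fraction`` of PSMs
    are dropped at random per protein-batch (missing-at-random).

    Returns ``(PSMTable, truth_log2, channel_map)`` where ``truth_log2`` is
    the proteins x samples matrix of true log2 relative abundances and
    ``channel_map`` maps (batch, channel) -> sample label.
    """
    from .tmt_quant import PSMTable  # local import avoids a cycle

    rng = np.random.default_rng((seed, 4))
    n_smp_ch = n_channels - 1
    M = np.eye(n_channels) if impurity is None else np.asarray(getattr(impurity, "matrix", impurity), float)
    if M.shape != (n_channels, n_channels):
        raise ValueError("impurity matrix shape does not match channel count")

    samples = [f"S{b + 1:02d}_{c + 1:02d}" for b in range(n_batches) for c in range(n_smp_ch)]
    base = rng.normal(base_log2_mean, base_log2_sd, size=n_proteins)
    sample_fx = rng.normal(0.0, sample_effect_sd, size=(n_proteins, n_batches * n_smp_ch))
    truth_log2 = pd.DataFrame(
        base[:, None] + sample_fx,
        index=[f"P{i + 1:04d}" for i in range(n_proteins)],
        columns=samples,
    )

    rows, intens = [], []
    channel_labels: dict[str, list[str]] = {}
    cmap_rows = []
    psm_counter = 0
    for b in range(n_batches):
        batch = f"batch{b + 1:02d}"
        b_samples = samples[b * n_smp_ch : (b + 1) * n_smp_ch]
        channel_labels[batch] = b_samples + ["IS"]
        for c, s in enumerate(b_samples):
            cmap_rows.append(dict(batch_id=batch, channel=c, sample=s))
        true_lin = 2.0 ** truth_log2[b_samples].to_numpy()  # proteins x 10
        is_col = true_lin.mean(axis=1, keepdims=True)
        chan_true = np.concatenate([true_lin, is_col], axis=1)  # proteins x 11
        loadings = 2.0 ** rng.normal(0.0, channel_loading_sd, size=n_channels)
        for i in range(n_proteins):
            n_psm = max(1, rng.poisson(psm_per_protein))
            for _ in range(n_psm):
                if rng.random() < missing_fraction:
                    continue
                scale = rng.lognormal(0.0, 0.8)
                if rng.random() < low_intensity_fraction:
                    scale *= 1e-4  # drives the PSM under the intensity filters
                noise = 2.0 ** rng.normal(0.0, noise_sd, size=n_channels)
                t = chan_true[i] * loadings * noise * scale
                obs = M @ t
                psm_counter += 1
                rows.append(
                    dict(
                        psm_id=f"psm{psm_counter:06d}",
                        protein_id=truth_log2.index[i],
                        batch_id=batch,
                        jscore=float(rng.uniform(50, 100)),
                    )
                )
                intens.append(obs)

    psm = PSMTable(pd.DataFrame(rows), np.asarray(intens), channel_labels, is_channel=n_channels - 1)
    return psm, truth_log2, pd.DataFrame(cmap_rows)
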