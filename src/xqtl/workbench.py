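"""I/O dialects, configuration, and the end-to-end pipeline driver.

File dialects
-------------
* Genotypes: VCF v4.2 with a ``DS`` FORMAT field (ALT-dosage), or a plain
  dosage TSV (variant metadata columns + one column per sample).
* Molecular phenotypes: QTLtools-style BED (0-based start, 1-based end,
  ``#chr start end id gid strand`` + one column per sample); the TSS is the
  start on + strand and the end on - strand.
* GWAS summaries: GCTA ".ma" TSV with header ``SNP A1 A2 freq b se p n``.

Coordinates are 1-based inclusive internally (VCF-native); BED conversion
happens at the I/O boundary only.

``run_pipeline`` drives the whole analysis on a simulated cohort:
simulate -> quantify -> correct -> map -> coloc -> mediate -> smr ->
prioritize, writing every intermediate as a file plus a JSON manifest with
parameters, output checksums and elapsed times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colocal, factor_correct, mediation, prioritize, qtl_map, smr_heidi, synthdata, tmt_quant
from .synthdata import GenotypeMatrix, GwasSummary, SimConfig, TraitMatrix

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = geno.variants.copy()
    dos = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [
        c for c in ("id", "chrom", "pos", "ref", "alt", "maf", "anno_class", "block", "freq_pop") if c in df
    ]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if df["id"].duplicated().any():
        raise ValueError("duplicate variant ids in dosage TSV")
    return GenotypeMatrix(df[sample_cols].to_numpy().T, df[meta_cols].reset_index(drop=True), sample_cols)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with dosages in the DS FORMAT field and the
    annotation class in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write('##INFO=<ID=ANNO,Number=1,Type=String,Description="Annotation class">\n')
        for chrom in dict.fromkeys(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples) + "\n")
        for j, v in geno.variants.iterrows():
            ds = "\t".join(f"{x:g}" for x in geno.dosages[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t"
                f"ANNO={v['anno_class']}\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a DS-format VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], {k: [] for k in ("id", "chrom", "pos", "ref", "alt", "maf", "anno_class")}
    for var in vcf:
        ds = np.asarray(var.format("DS"), float).reshape(-1)
        rows.append(ds)
        meta["id"].append(var.ID)
        meta["chrom"].append(var.CHROM)
        meta["pos"].append(var.POS)
        meta["ref"].append(var.REF)
        meta["alt"].append(var.ALT[0])
        af = float(ds.mean() / 2.0)
        meta["maf"].append(min(af, 1.0 - af))
        meta["anno_class"].append(var.INFO.get("ANNO") or "intergenic")
    dosages = np.asarray(rows).T
    ids = meta["id"]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in VCF")
    return GenotypeMatrix(dosages, pd.DataFrame(meta), samples)


# ---------------------------------------------------------------------------
# phenotype BED I/O
# ---------------------------------------------------------------------------

def write_phenotype_bed(traits: TraitMatrix, path: str | Path) -> None:
    t = traits.traits
    cols = {
        "#chr": t["chrom"],
        "start": t["gene_start"].astype(int) - 1,  # 0-based start at the boundary
        "end": t["gene_end"].astype(int),
        "id": t["trait_id"],
        "gid": t["gene_id"],
        "strand": t["strand"],
    }
    vals = pd.DataFrame(traits.values, columns=traits.samples)
    df = pd.concat([pd.DataFrame(cols).reset_index(drop=True), vals], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotype_bed(path: str | Path) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["#chr", "start", "end", "id", "gid", "strand"]
    if list(df.columns[:6]) != required:
        raise ValueError(f"phenotype BED must start with columns {required}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"phenotype BED line {bad[0] + 2}: start >= end (0-based/1-based mix-up?)")
    if df["id"].duplicated().any():
        raise ValueError("duplicate trait ids in phenotype BED")
    gene_start = df["start"].astype(int) + 1
    gene_end = df["end"].astype(int)
    tss = np.where(df["strand"] == "+", gene_start, gene_end)
    meta = pd.DataFrame(
        {
            "trait_id": df["id"],
            "gene_id": df["gid"],
            "chrom": df["#chr"],
            "tss": tss,
            "gene_start": gene_start,
            "gene_end": gene_end,
            "strand": df["strand"],
        }
    )
    sample_cols = [c for c in df.columns if c not in required]
    return TraitMatrix(df[sample_cols].to_numpy(), meta, sample_cols)


# ---------------------------------------------------------------------------
# GWAS .ma I/O
# ---------------------------------------------------------------------------

_MA_HEADER = ["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]


def write_gwas_ma(gwas: GwasSummary, path: str | Path) -> None:
    out = gwas.records.rename(columns={"variant_id": "SNP"})[_MA_HEADER]
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gwas_ma(path: str | Path, trait_name: str = "gwas", scenario: str = "null") -> GwasSummary:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _MA_HEADER:
        raise ValueError(f"GWAS .ma file must have header {_MA_HEADER}, got {list(df.columns)}")
    df = df.rename(columns={"SNP": "variant_id"})
    df["z"] = df["b"] / df["se"]
    return GwasSummary(df, trait_name=trait_name, scenario=scenario)


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

def write_psm_tsv(psm: tmt_quant.PSMTable, path: str | Path, channel_map_path: str | Path) -> None:
    df = psm.df.copy()
    for c in range(psm.n_channels):
        df[f"channel_{c + 1}"] = psm.intensities[:, c]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    rows = [
        dict(batch=b, channel=c + 1, label=lab)
        for b, labels in psm.channel_labels.items()
        for c, lab in enumerate(labels)
    ]
    pd.DataFrame(rows).to_csv(channel_map_path, sep="\t", index=False)


def read_psm_tsv(path: str | Path, channel_map_path: str | Path) -> tmt_quant.PSMTable:
    df = pd.read_csv(path, sep="\t")
    chan_cols = sorted([c for c in df.columns if c.startswith("channel_")], key=lambda c: int(c.split("_")[1]))
    inten = df[chan_cols].to_numpy()
    cmap = pd.read_csv(channel_map_path, sep="\t")
    labels = {b: list(grp.sort_values("channel")["label"]) for b, grp in cmap.groupby("batch")}
    meta = df.drop(columns=chan_cols)
    return tmt_quant.PSMTable(meta, inten, labels, is_channel=len(chan_cols) - 1)


# ---------------------------------------------------------------------------
# pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "xqtl_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_samples=200, n_blocks=50, n_variants=1000))
    n_factors: int | None = None  # default: the generator's hidden-factor count
    n_permutations: int = 2000
    pp4_threshold: float = 0.8
    gwas_scenario: str = "causal"
    gwas_effect_ratio: float = 0.3
    n_psm_proteins: int = 40
    n_psm_batches: int = 4
    stages: tuple[str, ...] = (
        "simulate", "quantify", "correct", "map", "coloc", "mediate", "smr", "prioritize",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full simulated analysis and return the manifest.

    Every stage reads files written by earlier stages where practical, writes
    its outputs under ``cfg.out_dir``, and appends a manifest entry (stage,
    parameters, outputs with checksums, elapsed seconds, status).  A stage
    failure is recorded and downstream stages are skipped.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = replace(cfg.sim, seed=cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stages": []}
    state: dict = {}
    failed = False

    for stage in cfg.stages:
        entry = {"stage": stage, "status": "skipped", "outputs": {}, "params": {}}
        if failed:
            manifest["stages"].append(entry)
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[stage](sim, cfg, out, state)
            entry["params"] = _stage_params(stage, sim, cfg)
            entry["outputs"] = {name: _sha256(p) for name, p in outputs.items()}
            entry["status"] = "ok"
        except Exception as exc:  # record and halt downstream
            logger.exception("stage %s failed", stage)
            entry["status"] = f"failed: {exc}"
            failed = True
        entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_params(stage: str, sim: SimConfig, cfg: PipelineConfig) -> dict:
    if stage == "simulate":
        return asdict(sim)
    if stage == "map":
        return {"n_permutations": cfg.n_permutations, "q_threshold": 0.05}
    if stage == "coloc":
        return {"pp4_threshold": cfg.pp4_threshold}
    if stage == "mediate":
        return {"z_threshold": mediation.Z_THRESHOLD_DEFAULT}
    return {}


def _stage_simulate(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno = synthdata.simulate_genotypes(sim)
    mrna, prot, truth = synthdata.simulate_traits(geno, sim)
    gwas = synthdata.simulate_gwas(geno, truth, cfg.gwas_scenario, sim, effect_ratio=cfg.gwas_effect_ratio)
    psm, psm_truth, _ = synthdata.simulate_psm_table(
        cfg.n_psm_proteins, cfg.n_psm_batches, impurity=tmt_quant.make_impurity(11).matrix, seed=cfg.seed
    )
    state.update(geno=geno, mrna=mrna, prot=prot, truth=truth, gwas=gwas, psm=psm, psm_truth=psm_truth)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "mrna_bed": out / "mrna.bed",
        "protein_bed": out / "protein.bed",
        "gwas_ma": out / "gwas.ma",
        "truth": out / "truth.tsv",
        "psm": out / "psm.tsv",
        "channel_map": out / "psm_channels.tsv",
    }
    write_dosage_tsv(geno, paths["genotypes"])
    write_phenotype_bed(mrna, paths["mrna_bed"])
    write_phenotype_bed(prot, paths["protein_bed"])
    write_gwas_ma(gwas, paths["gwas_ma"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format=_FLOAT_FMT)
    write_psm_tsv(psm, paths["psm"], paths["channel_map"])
    return paths


def _stage_quantify(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    psm = read_psm_tsv(out / "psm.tsv", out / "psm_channels.tsv")
    mat = tmt_quant.quantify(psm, impurity=tmt_quant.make_impurity(11))
    path = out / "protein_matrix.tsv"
    mat.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    # self-evaluation: correlation of recovered vs true IS-centered abundances
    truth = state["psm_truth"]
    shared = mat.index.intersection(truth.index)
    cols = [c for c in mat.columns if c in truth.columns]
    rec = mat.loc[shared, cols].to_numpy()
    tru_lin = 2.0 ** truth.loc[shared, cols].to_numpy()
    n_smp = 10
    tru = np.empty_like(tru_lin)
    for b in range(tru_lin.shape[1] // n_smp):
        sl = slice(b * n_smp, (b + 1) * n_smp)
        tru[:, sl] = np.log2(tru_lin[:, sl] / tru_lin[:, sl].mean(axis=1, keepdims=True))
    ok = ~np.isnan(rec)
    r = float(np.corrcoef(rec[ok], tru[ok])[0, 1])
    (out / "quantify_eval.json").write_text(json.dumps({"pearson_r_vs_truth": r}))
    state["quant_r"] = r
    return {"protein_matrix": path, "quantify_eval": out / "quantify_eval.json"}


def _stage_correct(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    k = cfg.n_factors if cfg.n_factors is not None else sim.n_hidden_factors
    fc = factor_correct.FactorConfig(n_factors=k)
    paths = {}
    for name in ("mrna", "protein"):
        bed = out / f"{name}.bed"
        traits = read_phenotype_bed(bed)
        corrected = factor_correct.correct(traits, fc)
        paths[f"{name}_corrected"] = out / f"{name}.corrected.bed"
        write_phenotype_bed(corrected, paths[f"{name}_corrected"])
        state[f"{name}_corrected"] = corrected
    return paths


def _stage_map(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno = read_dosage_tsv(out / "genotypes.tsv")
    window = qtl_map.WindowConfig(n_permutations=cfg.n_permutations)
    paths = {}
    for name in ("mrna", "protein"):
        traits = read_phenotype_bed(out / f"{name}.corrected.bed")
        cis = qtl_map.map_cis(traits, geno, window, seed=cfg.seed)
        trans = qtl_map.map_trans(traits, geno, window)
        paths[f"{name}_cis"] = out / f"{name}.cis_qtl.tsv"
        paths[f"{name}_trans"] = out / f"{name}.trans_qtl.tsv"
        cis.to_csv(paths[f"{name}_cis"], sep="\t", index=False, float_format=_FLOAT_FMT)
        trans.to_csv(paths[f"{name}_trans"], sep="\t", index=False, float_format=_FLOAT_FMT)
        state[f"{name}_cis"] = cis
        state[f"{name}_traits"] = traits
    state["geno"] = geno
    return paths


def _nominal_for_gene(state: dict, which: str, gene_id: str) -> pd.DataFrame:
    traits: TraitMatrix = state[f"{which}_traits"]
    geno: GenotypeMatrix = state["geno"]
    sel = traits.traits["gene_id"] == gene_id
    sub = TraitMatrix(traits.values[sel.to_numpy()], traits.traits.loc[sel].reset_index(drop=True), traits.samples)
    scans = qtl_map.nominal_scan(sub, geno, qtl_map.WindowConfig(), mode="cis")
    return next(iter(scans.values()))


def _stage_coloc(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    rows = []
    for gene in state["truth"]["gene_id"]:
        a_e = _nominal_for_gene(state, "mrna", gene)
        a_p = _nominal_for_gene(state, "protein", gene)
        if len(a_e) < 2 or len(a_p) < 2:
            continue
        res = colocal.colocalize(a_p, a_e)
        rows.append(dict(gene_id=gene, **res.as_dict()))
    df = pd.DataFrame(rows)
    df["colocalized"] = df["PP4"] > cfg.pp4_threshold
    path = out / "coloc.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    state["coloc"] = df
    return {"coloc": path}


def _stage_mediate(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno: GenotypeMatrix = state["geno"]
    id_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
    prot_cis = state["protein_cis"].set_index("trait_id")
    mrna_t: TraitMatrix = state["mrna_traits"]
    prot_t: TraitMatrix = state["protein_traits"]
    coloc_df = state["coloc"]
    eligible = set(coloc_df.loc[coloc_df["colocalized"], "gene_id"])
    results = []
    rng = np.random.default_rng((cfg.seed, 7))
    for gene in state["truth"]["gene_id"]:
        if eligible and gene not in eligible:
            continue
        pid, mid = f"{gene}_prot", f"{gene}_mrna"
        if pid not in prot_cis.index:
            continue
        variant = prot_cis.loc[pid, "variant_id"]
        g = geno.dosages[:, id_to_col[variant]]
        p_row = prot_t.values[(prot_t.traits["trait_id"] == pid).to_numpy()][0]
        m_row = mrna_t.values[(mrna_t.traits["trait_id"] == mid).to_numpy()][0]
        res = mediation.mediation_test(
            p_row, m_row, g, mediation.MediationConfig(seed=cfg.seed), trait_id=pid, variant_id=variant, rng=rng
        )
        results.append(res)
    df = pd.DataFrame([asdict(r) for r in results])
    path = out / "mediation.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    state["mediation"] = results
    return {"mediation": path}


def _stage_smr(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno: GenotypeMatrix = state["geno"]
    gwas = read_gwas_ma(out / "gwas.ma", scenario=cfg.gwas_scenario)
    rows = []
    scfg = smr_heidi.SMRConfig(top_qtl_p_max=1.0)  # desk-scale instruments
    genes = list(state["truth"]["gene_id"])
    for gene in genes:
        qtl = _nominal_for_gene(state, "mrna", gene)
        q_aligned, g_aligned = colocal.align_alleles(qtl, gwas.records)
        if len(q_aligned) < 2:
            continue
        cols = [list(geno.variants["id"]).index(v) for v in q_aligned["variant_id"]]
        ld = smr_heidi.ld_matrix(geno.dosages[:, cols])
        try:
            res = smr_heidi.smr_heidi(gene, q_aligned, g_aligned, ld, n_tested_traits=len(genes), cfg=scfg)
        except ValueError:
            continue
        rows.append(asdict(res))
    df = pd.DataFrame(rows)
    path = out / "smr.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    state["smr"] = df
    return {"smr": path}


def _stage_prioritize(sim: SimConfig, cfg: PipelineConfig, out: Path, state: dict) -> dict:
    rng = np.random.default_rng((cfg.seed, 8))
    genes = list(state["truth"]["gene_id"])
    p_cis = state["protein_cis"].copy()
    p_cis["gene_id"] = p_cis["trait_id"].str.replace("_prot", "", regex=False)
    e_cis = state["mrna_cis"].copy()
    e_cis["gene_id"] = e_cis["trait_id"].str.replace("_mrna", "", regex=False)
    coloc_df = state["coloc"]

    # synthetic stand-ins for the two externally supplied sources
    disease_score = pd.Series(rng.uniform(0, 100, size=len(genes)), index=genes)
    risk_genes = set(rng.choice(genes, size=max(2, len(genes) // 5), replace=False))
    edges = []
    for _ in range(len(genes) * 3):
        a, b = rng.choice(genes, size=2, replace=False)
        edges.append(dict(gene_a=a, gene_b=b, combined_score=int(rng.integers(150, 1000))))
    net = prioritize.PPINetwork.from_edges(pd.DataFrame(edges))
    conn = prioritize.connectivity_score(net, risk_genes, eligible=set(genes))

    sources = {
        "pqtl": prioritize.ranks_from_scores(p_cis.set_index("gene_id")["nominal_p"]),
        "eqtl": prioritize.ranks_from_scores(e_cis.set_index("gene_id")["nominal_p"]),
        "coloc": prioritize.ranks_from_scores(coloc_df.set_index("gene_id")["PP4"], ascending=False),
        "disease": prioritize.ranks_from_scores(disease_score, ascending=False),
        "ppi": prioritize.ranks_from_scores(conn, ascending=False) if len(conn) else pd.Series(dtype=float),
    }
    sources = {k: v for k, v in sources.items() if len(v)}
    ranked = prioritize.aggregate_and_rank(sources)
    path = out / "prioritized.tsv"
    ranked.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    state["ranked"] = ranked

    # self-evaluation vs generator truth
    truth = state["truth"].set_index("gene_id")
    med = {r.trait_id.replace("_prot", ""): r.classification for r in state.get("mediation", [])}
    eval_rows = {
        "mediation_accuracy": float(
            np.mean([med[g] == truth.loc[g, "class"] for g in med]) if med else np.nan
        ),
        "coloc_pp4_mean": float(coloc_df["PP4"].mean()) if len(coloc_df) else np.nan,
        "quantify_pearson_r": state.get("quant_r", np.nan),
    }
    (out / "evaluation.json").write_text(json.dumps(eval_rows, default=str))
    return {"prioritized": path, "evaluation": out / "evaluation.json"}


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "correct": _stage_correct,
    "map": _stage_map,
    "coloc": _stage_coloc,
    "mediate": _stage_mediate,
    "smr": _stage_smr,
    "prioritize": _stage_prioritize,
}
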