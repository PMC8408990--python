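"""End-to-end orchestration: simulate -> train -> associate -> combine -> fine-map.

Every stage reads and writes the plain TSV formats in :mod:`xtwas.formats`,
so each can also be run standalone on externally produced files. A run is a
pure function of its configuration (including the seed): the manifest records
per-stage row counts and SHA-256 checksums of every artifact, and repeated
runs with the same config produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import associate_gene
from .combine import DEFAULT_BLACKLIST, combine_tissues
from .finemap import finemap_tissue
from .formats import read_table, write_table, write_truth
from .simulate import (ConfigError, ReferencePanel, SimulationConfig,
                       preprocess_expression, simulate_expression,
                       simulate_genotypes, simulate_gwas)
from .train import GeneModel, ModelPerformance, retain_models, select_cis_snps, train_gene

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "train", "assoc", "combine", "finemap")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "xtwas_run"
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 1_000_000
    n_lambda: int = 10
    lambda_min_ratio: float = 1e-3
    n_folds: int = 5
    tol: float = 1e-6
    max_iter: int = 5_000
    alpha: float = 0.05
    rho: float = 0.9
    prior_prob: float = 1e-3
    prior_var: float = 40.0
    max_causal: int = 3
    ridge: float = 0.1
    region_threshold: float = 0.05
    blacklist: tuple = DEFAULT_BLACKLIST

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; valid: {list(ALL_STAGES)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            if "tissue_sample_fracs" in sim and sim["tissue_sample_fracs"] is not None:
                sim["tissue_sample_fracs"] = tuple(sim["tissue_sample_fracs"])
            d["sim"] = SimulationConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "blacklist" in d:
            d["blacklist"] = tuple(tuple(r) for r in d["blacklist"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["blacklist"] = [list(r) for r in self.blacklist]
        return d

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _panel_frames(panel: ReferencePanel):
    dos = pd.DataFrame(panel.dosages,
                       columns=panel.snp_meta["snp_id"].tolist())
    dos.insert(0, "sample_id", panel.sample_ids)
    return dos


def _load_panel(out: Path) -> ReferencePanel:
    dos = read_table(out / "panel_dosages.tsv", "panel")
    snp_meta = read_table(out / "snp_meta.tsv", "snp_meta")
    gene_meta = read_table(out / "gene_meta.tsv", "gene_meta")
    sample_ids = dos["sample_id"].tolist()
    mat = dos[snp_meta["snp_id"].tolist()].to_numpy(dtype=float)
    return ReferencePanel(dosages=mat, snp_meta=snp_meta, gene_meta=gene_meta,
                          sample_ids=sample_ids)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{stage}' stage first"
        )
    return path


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    panel = simulate_genotypes(sim)
    tissue_sets, truth = simulate_expression(panel, sim)
    sumstats = simulate_gwas(panel, truth, sim)

    write_table(_panel_frames(panel), out / "panel_dosages.tsv", "panel")
    write_table(panel.snp_meta, out / "snp_meta.tsv", "snp_meta")
    write_table(panel.gene_meta, out / "gene_meta.tsv", "gene_meta")
    for ts in tissue_sets:
        df = pd.DataFrame(ts.expression, columns=ts.gene_ids)
        df.insert(0, "sample_id", [panel.sample_ids[i] for i in ts.sample_idx])
        write_table(df, out / f"expression_{ts.tissue}.tsv", "expression")
    write_table(sumstats, out / "sumstats.tsv", "sumstats")
    write_truth(truth, out / "truth.json")
    return {"n_snps": panel.n_snps, "n_genes": len(panel.gene_meta),
            "n_tissues": len(tissue_sets)}


def stage_train(cfg: RunConfig, out: Path) -> dict:
    panel = _load_panel(out)
    sim = cfg.sim
    tissues = sim.tissue_names()
    expr, sample_idx = {}, {}
    id_of = {s: i for i, s in enumerate(panel.sample_ids)}
    for t in tissues:
        df = read_table(_require(out / f"expression_{t}.tsv", "simulate"), "expression")
        genes = [c for c in df.columns if c != "sample_id"]
        raw = df[genes].to_numpy(dtype=float)
        covar = np.ones((raw.shape[0], 1))  # intercept-only residualization
        expr[t] = (genes, preprocess_expression(raw, covar))
        sample_idx[t] = np.array([id_of[s] for s in df["sample_id"]])

    w_rows, extra_rows, cov_rows = [], [], []
    all_models: list[GeneModel] = []
    for g_i, grow in panel.gene_meta.iterrows():
        gene = grow["gene"]
        snp_idx = select_cis_snps(int(grow["tss"]), int(grow["tes"]),
                                  panel.snp_meta, window=cfg.window)
        if len(snp_idx) == 0:
            logger.info("gene %s skipped: no cis SNPs", gene)
            continue
        X_list, y_list = [], []
        for t in tissues:
            genes_t, mat = expr[t]
            gcol = genes_t.index(gene)
            X_list.append(panel.dosages[np.ix_(sample_idx[t], snp_idx)])
            y_list.append(mat[:, gcol])
        models = train_gene(gene, tissues, X_list, y_list, panel.snp_meta, snp_idx,
                            seed=cfg.seed + 1000 + g_i, tol=cfg.tol,
                            max_iter=cfg.max_iter, n_lambda=cfg.n_lambda)
        all_models.extend(models)

        sub = panel.dosages[:, snp_idx]
        cov = np.cov(sub, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        ids = panel.snp_meta["snp_id"].to_numpy()[snp_idx]
        for a in range(len(ids)):
            for b in range(a, len(ids)):
                cov_rows.append({"gene": gene, "snp_i": ids[a], "snp_j": ids[b],
                                 "value": cov[a, b]})

    kept, summary = retain_models(all_models)
    logger.info("retention summary:\n%s", summary.to_string(index=False))
    for m in kept:
        extra_rows.append({"gene": m.gene, "tissue": m.tissue,
                           "n_snps": len(m.snp_ids), "r": m.performance.r,
                           "p": m.performance.p, "n_eval": m.performance.n_eval})
        for s, ch, pos, ea, oa, w in zip(m.snp_ids, m.chrom, m.pos,
                                         m.effect_allele, m.other_allele, m.weights):
            w_rows.append({"gene": m.gene, "tissue": m.tissue, "snp_id": s,
                           "chrom": ch, "pos": pos, "effect_allele": ea,
                           "other_allele": oa, "weight": w})
    write_table(pd.DataFrame(w_rows, columns=list(
        {"gene": 0, "tissue": 0, "snp_id": 0, "chrom": 0, "pos": 0,
         "effect_allele": 0, "other_allele": 0, "weight": 0})),
        out / "weights.tsv", "weights")
    write_table(pd.DataFrame(extra_rows, columns=["gene", "tissue", "n_snps",
                                                  "r", "p", "n_eval"]),
                out / "weights_extra.tsv", "weights_extra")
    write_table(pd.DataFrame(cov_rows, columns=["gene", "snp_i", "snp_j", "value"]),
                out / "covariance.tsv", "covariance")
    return {"models_trained": len(all_models), "models_retained": len(kept)}


def load_weight_db(out: Path) -> list[GeneModel]:
    """Rebuild GeneModels from the weights + extra TSVs (round-trips exactly)."""
    wdf = read_table(_require(out / "weights.tsv", "train"), "weights")
    edf = read_table(_require(out / "weights_extra.tsv", "train"), "weights_extra")
    perf = {(r["gene"], r["tissue"]): ModelPerformance(r=r["r"], p=r["p"],
                                                       n_eval=int(r["n_eval"]))
            for _, r in edf.iterrows()}
    models = []
    for (gene, tissue), sub in wdf.groupby(["gene", "tissue"], sort=True):
        models.append(GeneModel(
            gene=gene, tissue=tissue,
            snp_ids=sub["snp_id"].tolist(), chrom=sub["chrom"].tolist(),
            pos=sub["pos"].tolist(), effect_allele=sub["effect_allele"].tolist(),
            other_allele=sub["other_allele"].tolist(),
            weights=sub["weight"].to_numpy(dtype=float),
            performance=perf.get((gene, tissue), ModelPerformance(0.0, 1.0, 0)),
        ))
    return models


def _gene_cov(out: Path) -> dict[str, tuple[list[str], np.ndarray]]:
    cdf = read_table(_require(out / "covariance.tsv", "train"), "covariance")
    result = {}
    for gene, sub in cdf.groupby("gene", sort=True):
        ids = list(dict.fromkeys(sub["snp_i"].tolist() + sub["snp_j"].tolist()))
        pos = {s: i for i, s in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        for _, r in sub.iterrows():
            i, j = pos[r["snp_i"]], pos[r["snp_j"]]
            mat[i, j] = mat[j, i] = r["value"]
        result[gene] = (ids, mat)
    return result


def stage_assoc(cfg: RunConfig, out: Path) -> dict:
    models = load_weight_db(out)
    gwas = read_table(_require(out / "sumstats.tsv", "simulate"), "sumstats")
    covs = _gene_cov(out)
    rows = []
    for m in models:
        if m.gene not in covs:
            logger.info("gene %s/%s skipped: no covariance block", m.gene, m.tissue)
            continue
        ids, sigma = covs[m.gene]
        a = associate_gene(m, gwas, sigma, ids)
        if a is None:
            continue
        rows.append({"gene": a.gene, "tissue": a.tissue, "z_gene": a.z_gene,
                     "p": a.p, "effect": a.effect, "ci_low": a.ci_low,
                     "ci_high": a.ci_high, "sigma_g": a.sigma_g,
                     "n_snps_used": a.n_snps_used})
    df = pd.DataFrame(rows, columns=["gene", "tissue", "z_gene", "p", "effect",
                                     "ci_low", "ci_high", "sigma_g", "n_snps_used"])
    write_table(df, out / "associations.tsv", "associations")
    return {"associations": len(df), "genes_tested": df["gene"].nunique() if len(df) else 0}


def stage_combine(cfg: RunConfig, out: Path) -> dict:
    assoc = read_table(_require(out / "associations.tsv", "assoc"), "associations")
    gene_meta = read_table(_require(out / "gene_meta.tsv", "simulate"), "gene_meta")
    if assoc.empty:
        write_table(pd.DataFrame({c: [] for c in ["gene", "n_tissues", "tissue_ps",
                                                  "t_stat", "p_combined",
                                                  "significant", "excluded_region"]}),
                    out / "combined.tsv", "combined")
        return {"genes_combined": 0, "genes_significant": 0}
    comb = combine_tissues(assoc, gene_meta, alpha=cfg.alpha, blacklist=cfg.blacklist)
    dfw = comb.copy()
    dfw["significant"] = dfw["significant"].astype(int)
    dfw["excluded_region"] = dfw["excluded_region"].astype(int)
    write_table(dfw, out / "combined.tsv", "combined")
    return {"genes_combined": len(comb),
            "genes_significant": int(comb["significant"].sum()),
            "bonferroni_threshold": comb.attrs["bonferroni_threshold"]}


def stage_finemap(cfg: RunConfig, out: Path) -> dict:
    panel = _load_panel(out)
    models = load_weight_db(out)
    assoc = read_table(_require(out / "associations.tsv", "assoc"), "associations")
    gene_chroms = dict(zip(panel.gene_meta["gene"], panel.gene_meta["chrom"].astype(str)))
    snp_ids = panel.snp_meta["snp_id"].tolist()
    sigma = np.cov(panel.dosages, rowvar=False, ddof=1)
    rows = []
    n_credible_genes = set()
    for tissue in sorted({m.tissue for m in models}):
        tmodels = [m for m in models if m.tissue == tissue]
        tassoc = assoc[assoc["tissue"] == tissue]
        if tassoc.empty:
            continue
        res = finemap_tissue(tmodels, tassoc, sigma, snp_ids, gene_chroms,
                             prior_prob=cfg.prior_prob, prior_var=cfg.prior_var,
                             max_causal=cfg.max_causal, ridge=cfg.ridge,
                             rho=cfg.rho, region_threshold=cfg.region_threshold)
        res.insert(2, "tissue", tissue)
        rows.append(res)
        n_credible_genes |= set(res.loc[res["in_credible_set"], "gene"])
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame({c: [] for c in SCHEMA_FINEMAP_COLS}))
    write_table(df, out / "finemap.tsv", "finemap")
    return {"finemap_rows": len(df), "genes_in_credible_sets": len(n_credible_genes)}


SCHEMA_FINEMAP_COLS = ["region", "gene", "tissue", "twas_z", "pip", "in_credible_set"]

_STAGE_FNS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "assoc": stage_assoc,
    "combine": stage_combine,
    "finemap": stage_finemap,
}

_STAGE_OUTPUTS = {
    "simulate": ["panel_dosages.tsv", "snp_meta.tsv", "gene_meta.tsv",
                 "sumstats.tsv", "truth.json"],
    "train": ["weights.tsv", "weights_extra.tsv", "covariance.tsv"],
    "assoc": ["associations.tsv"],
    "combine": ["combined.tsv"],
    "finemap": ["finemap.tsv"],
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and write ``manifest.json``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "config.json")
    manifest: dict = {"version": __version__, "config": cfg.to_dict(),
                      "stages": {}, "checksums": {}}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        counts = _STAGE_FNS[stage](cfg, out)
        manifest["stages"][stage] = counts
        for name in _STAGE_OUTPUTS[stage]:
            p = out / name
            if p.exists():
                manifest["checksums"][name] = _sha256(p)
        if stage == "simulate":
            for t in cfg.sim.tissue_names():
                p = out / f"expression_{t}.tsv"
                manifest["checksums"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
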