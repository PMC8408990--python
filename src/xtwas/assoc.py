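"""Gene-level association from GWAS summary statistics (S-PrediXcan).

Given a gene's SNP weights w, the reference dosage covariance Sigma of those
SNPs, and per-SNP GWAS Z-scores z, the gene-level statistic is

    Z_g = sum_l w_l * (sigma_l / sigma_g) * z_l,   sigma_g^2 = w' Sigma w,

which is N(0, 1) under the null when Sigma matches the GWAS cohort's LD. No
individual-level data are needed. Effect sizes are reported per standard
deviation of predicted expression via se_g = 1 / (sigma_g * sqrt(n)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationResult",
    "TwasAssociation",
    "harmonize",
    "predicted_variance",
    "gene_zscore",
    "effect_and_ci",
    "associate_gene",
    "UNTESTABLE_VARIANCE",
]

UNTESTABLE_VARIANCE = 1e-8
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizationResult:
    snp_ids: list[str]
    weights: np.ndarray
    z: np.ndarray
    n_matched: int
    n_flipped: int
    n_ambiguous: int
    n_unmatched: int


@dataclass
class TwasAssociation:
    gene: str
    tissue: str
    z_gene: float
    p: float
    sigma_g: float
    n_snps_used: int
    effect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def odds_ratio(self) -> float | None:
        return None if self.effect is None else float(np.exp(self.effect))


def harmonize(model, gwas: pd.DataFrame) -> HarmonizationResult | None:
    """Align model weights with GWAS Z-scores on a shared allele frame.

    Match by variant id; when the GWAS effect/other alleles are swapped
    relative to the model the Z-score is negated. Strand-ambiguous pairs
    (A/T, C/G) and ids absent from the GWAS are dropped. Returns ``None``
    (with a logged reason) when no SNP survives.
    """
    gw = gwas.set_index("SNP")
    ids, w, z = [], [], []
    n_match = n_flip = n_amb = n_miss = 0
    for snp, ea, oa, weight in zip(model.snp_ids, model.effect_allele,
                                   model.other_allele, model.weights):
        if {ea, oa} in _AMBIGUOUS:
            n_amb += 1
            continue
        if snp not in gw.index:
            n_miss += 1
            continue
        row = gw.loc[snp]
        a1, a2 = str(row["A1"]), str(row["A2"])
        if (a1, a2) == (ea, oa):
            zz = float(row["Z"])
            n_match += 1
        elif (a1, a2) == (oa, ea):
            zz = -float(row["Z"])
            n_flip += 1
        else:
            n_miss += 1
            continue
        ids.append(snp)
        w.append(float(weight))
        z.append(zz)
    if not ids:
        logger.info("gene %s/%s skipped: no SNP overlap with GWAS "
                    "(%d ambiguous, %d unmatched)", model.gene, model.tissue,
                    n_amb, n_miss)
        return None
    return HarmonizationResult(
        snp_ids=ids, weights=np.array(w), z=np.array(z),
        n_matched=n_match, n_flipped=n_flip, n_ambiguous=n_amb, n_unmatched=n_miss,
    )


def predicted_variance(w: np.ndarray, sigma: np.ndarray) -> float:
    """Variance of predicted expression, sigma_g^2 = w' Sigma w."""
    w = np.asarray(w, dtype=float)
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if sigma.shape != (len(w), len(w)):
        raise ValueError(f"covariance shape {sigma.shape} does not match {len(w)} weights")
    return float(max(w @ sigma @ w, 0.0))


def gene_zscore(w: np.ndarray, sigma: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Gene-level (Z_g, two-sided P, sigma_g) from weights, LD, and SNP Z."""
    var_g = predicted_variance(w, sigma)
    if var_g < UNTESTABLE_VARIANCE:
        raise ValueError(f"untestable gene: predicted-expression variance {var_g:.3g}")
    sigma_g = float(np.sqrt(var_g))
    sig_l = np.sqrt(np.clip(np.diag(np.atleast_2d(sigma)), 0.0, None))
    z_g = float(np.sum(np.asarray(w) * sig_l / sigma_g * np.asarray(z)))
    p = float(2.0 * stats.norm.sf(abs(z_g)))
    return z_g, p, sigma_g


def effect_and_ci(z_g: float, sigma_g: float, n: float | None
                  ) -> tuple[float | None, float | None, float | None]:
    """Log-odds effect per SD of predicted expression, with a 95% CI.

    se_g = 1/(sigma_g sqrt(n)); effect = Z_g * se_g; CI = effect +/- 1.96 se_g.
    Returns (None, None, None) with a warning when n is missing.
    """
    if n is None or not np.isfinite(n) or n <= 0:
        logger.warning("missing GWAS sample size; effect fields omitted")
        return None, None, None
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    se = 1.0 / (sigma_g * np.sqrt(n))
    eff = z_g * se
    return float(eff), float(eff - 1.96 * se), float(eff + 1.96 * se)


def associate_gene(model, gwas: pd.DataFrame, sigma: np.ndarray,
                   sigma_snp_ids: list[str]) -> TwasAssociation | None:
    """Full association for one gene-tissue model against one GWAS.

    ``sigma`` is the reference covariance on the frame ``sigma_snp_ids``;
    harmonized SNPs are looked up in that frame.
    """
    harm = harmonize(model, gwas)
    if harm is None:
        return None
    pos = {s: i for i, s in enumerate(sigma_snp_ids)}
    try:
        idx = [pos[s] for s in harm.snp_ids]
    except KeyError as exc:
        raise ValueError(f"SNP {exc} missing from covariance frame for gene {model.gene}")
    sub = np.atleast_2d(sigma)[np.ix_(idx, idx)]
    var_g = predicted_variance(harm.weights, sub)
    if var_g < UNTESTABLE_VARIANCE:
        logger.info("gene %s/%s untestable: sigma_g^2=%.3g", model.gene, model.tissue, var_g)
        return None
    z_g, p, sigma_g = gene_zscore(harm.weights, sub, harm.z)
    n = float(gwas["N"].iloc[0]) if "N" in gwas.columns and len(gwas) else None
    eff, lo, hi = effect_and_ci(z_g, sigma_g, n)
    return TwasAssociation(
        gene=model.gene, tissue=model.tissue, z_gene=z_g, p=p, sigma_g=sigma_g,
        n_snps_used=len(harm.snp_ids), effect=eff, ci_low=lo, ci_high=hi,
    )
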