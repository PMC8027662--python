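"""Synthetic eQTL study for null calibration of the SMR pipeline.

Emulates a transcriptome-wide MR null experiment end to end: simulate
cis-genotypes under Hardy-Weinberg (optionally with AR(1) linkage
disequilibrium), generate expression from an additive model with a fixed
heritability, scan every SNP, select the top SNP if it reaches genome-wide
significance, attach a null GWAS signal (z drawn standard normal, so the
trait Wald statistic is exactly 1-df chi-square), and compute the SMR,
min-test and conditional-test p-values for each selected gene.

Because the trait side is null by construction, the rejection fraction of
each test at nominal alpha measures its realized size: the conditional
test is calibrated (its statistic really is 1-df chi-square) while SMR is
conservative — its statistic is dominated by both Wald statistics, and the
selected exposure Wald statistic is truncated besides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import (
    SelectionDesign,
    chisq_upper_p,
    min_test,
    smr_statistic,
)
from .selection_sim import qq_points

__all__ = [
    "GeneSimConfig",
    "GeneScanResult",
    "simulate_genotypes",
    "simulate_expression",
    "marginal_scan",
    "select_instrument",
    "run_smr_null_experiment",
    "SMRNullExperimentResult",
]


@dataclass(frozen=True)
class GeneSimConfig:
    """Parameters of one synthetic-eQTL null experiment.

    Defaults follow a moderate-power design: N = 1000 individuals,
    200 cis-SNPs per gene with AR(1) LD 0.5, five causal eQTLs explaining
    h2 = 0.4 of unit-variance expression, genome-wide instrument selection.
    """

    n_individuals: int = 1000
    n_snps: int = 200
    n_causal: int = 5
    h2: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_genes: int = 1000
    p_select: float = 5e-8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.h2 < 1):
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not (-1 < self.ld_rho < 1):
            raise ValueError("ld_rho must lie in (-1, 1)")


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthetic 0/1/2 genotypes under Hardy-Weinberg equilibrium.

    Each SNP gets a minor-allele frequency drawn uniformly from
    ``maf_range``. Two haplotypes per individual are generated from a
    latent AR(1) Gaussian process across SNPs (correlation ``ld_rho``
    between adjacent SNPs) and thresholded at the MAF quantile, so each
    marginal is Bernoulli(MAF) and the genotype is their sum —
    HWE-binomial per SNP with first-order LD along the map.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    thresh = stats.norm.ppf(mafs)
    s = np.sqrt(1.0 - ld_rho**2)
    geno = np.zeros((n_individuals, n_snps), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        latent = rng.standard_normal((n_individuals, n_snps))
        if ld_rho != 0.0:
            for j in range(1, n_snps):
                latent[:, j] = ld_rho * latent[:, j - 1] + s * latent[:, j]
        geno += latent < thresh
    return geno


def simulate_expression(
    genotypes: np.ndarray,
    n_causal: int,
    h2: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict]:
    """Additive expression model with an exactly realized heritability.

    Picks ``n_causal`` SNPs uniformly without replacement, draws their
    effects standard normal, then rescales the realized genetic component
    to sample variance ``h2`` and the residual to sample variance
    ``1 - h2``, so the realized genetic-variance fraction is ``h2``
    exactly (no Monte-Carlo noise in the variance partition) and the
    total variance is 1 up to the genetic-residual sample covariance.

    Returns the expression vector and a record of the causal indices and
    rescaled effects.
    """
    n, m = genotypes.shape
    if n_causal > m:
        raise ValueError("n_causal cannot exceed the number of SNPs")
    if not (0 <= h2 < 1):
        raise ValueError(f"h2 must be in [0, 1), got {h2}")
    if h2 > 0 and n_causal == 0:
        raise ValueError("positive heritability requires at least one causal SNP")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    causal = np.sort(rng.choice(m, size=n_causal, replace=False)) if n_causal else np.array([], dtype=int)
    betas = rng.standard_normal(n_causal)
    genetic = np.zeros(n)
    if n_causal and h2 > 0:
        genetic = genotypes[:, causal].astype(float) @ betas
        gvar = genetic.var()
        if gvar == 0:
            raise ValueError("causal genotypes are constant; cannot impose heritability")
        scale = np.sqrt(h2 / gvar)
        genetic *= scale
        betas = betas * scale
    else:
        betas = np.zeros(n_causal)
    resid = rng.standard_normal(n)
    resid *= np.sqrt((1.0 - h2) / resid.var())
    return genetic + resid, {"causal_idx": causal, "beta": betas}


def marginal_scan(genotypes: np.ndarray, expression: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of expression on genotype.

    Closed-form OLS per column: slope = Sxy/Sxx, residual variance on
    n - 2 df, p from the 1-df chi-square of the Wald statistic (the
    large-sample reference used throughout the pipeline). Constant
    genotype columns are flagged (``ok = False``) and excluded from
    instrument selection rather than raising.
    """
    G = np.asarray(genotypes, dtype=float)
    x = np.asarray(expression, dtype=float)
    n, m = G.shape
    if x.shape != (n,):
        raise ValueError("expression length must match the number of individuals")
    Gc = G - G.mean(axis=0)
    xc = x - x.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = Gc.T @ xc
    ok = sxx > 0
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = sxy[ok] / sxx[ok]
        rss = xc @ xc - beta[ok] * sxy[ok]
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se[ok] = np.sqrt(sigma2 / sxx[ok])
        w = (beta[ok] / se[ok]) ** 2
        p[ok] = stats.chi2.sf(w, df=1)
    return pd.DataFrame(
        {"snp": np.arange(m), "beta": beta, "se": se, "p": p, "n": n, "ok": ok}
    )


def select_instrument(scan: pd.DataFrame, p_select: float = 5e-8) -> int | None:
    """Index of the top SNP if it reaches the selection threshold, else None.

    The top SNP is the one with minimal p among non-degenerate columns;
    exact ties go to the smallest index.
    """
    usable = scan[scan["ok"]]
    if usable.empty:
        return None
    top = int(usable["p"].idxmin())  # idxmin returns the first minimal label
    if scan.loc[top, "p"] < p_select:
        return top
    return None


@dataclass
class GeneScanResult:
    """Per-gene outcome of the scan-select-test pipeline."""

    gene: int
    top_snp: int | None
    w_gx_top: float
    selected: bool
    w_gy: float | None = None
    t_smr: float | None = None
    p_smr: float | None = None
    p_min: float | None = None
    p_conditional: float | None = None


@dataclass
class SMRNullExperimentResult:
    """Null-calibration summary over all simulated genes."""

    config: GeneSimConfig
    genes: pd.DataFrame
    n_selected: int
    rejection: dict[str, dict[float, float]]
    qq_smr: tuple[np.ndarray, np.ndarray] | None
    insufficient_selection: bool = False

    def to_table(self) -> pd.DataFrame:
        return self.genes


def run_smr_null_experiment(
    config: GeneSimConfig,
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> SMRNullExperimentResult:
    """Full null-calibration experiment for SMR and its alternatives.

    For each gene: simulate genotypes and expression, scan, select the top
    SNP at ``p_select``; for selected genes draw a null GWAS z-score
    (standard normal, independent of the eQTL study, so ``W_gy`` is
    exactly 1-df chi-square) and compute SMR, min-test and conditional
    p-values. The summary reports, per test, the fraction of selected
    genes with p below each nominal alpha, plus QQ pairs of the SMR
    statistic against the 1-df chi-square.
    """
    rng = np.random.default_rng(config.seed)
    design = SelectionDesign(config.p_select) if config.p_select < 1 else None
    rows = []
    for gene in range(config.n_genes):
        G = simulate_genotypes(
            config.n_individuals, config.n_snps, config.maf_range, config.ld_rho, rng
        )
        expr, _ = simulate_expression(G, config.n_causal, config.h2, rng)
        scan = marginal_scan(G, expr)
        top = select_instrument(scan, config.p_select)
        if top is None:
            usable = scan[scan["ok"]]
            t = int(usable["p"].idxmin()) if not usable.empty else None
            w_top = float((scan.loc[t, "beta"] / scan.loc[t, "se"]) ** 2) if t is not None else 0.0
            rows.append(GeneScanResult(gene, t, w_top, False))
            continue
        w_gx = float((scan.loc[top, "beta"] / scan.loc[top, "se"]) ** 2)
        z_gwas = rng.standard_normal()
        w_gy = float(z_gwas**2)
        t_smr, p_smr = smr_statistic(w_gx, w_gy)
        _, p_min = min_test(w_gx, w_gy)
        p_cond = chisq_upper_p(w_gy)
        rows.append(
            GeneScanResult(gene, top, w_gx, True, w_gy, t_smr, p_smr, p_min, p_cond)
        )
    genes = pd.DataFrame([vars(r) for r in rows])
    sel = genes[genes["selected"]]
    n_sel = len(sel)
    if n_sel == 0:
        return SMRNullExperimentResult(
            config, genes, 0,
            {k: {a: float("nan") for a in alphas} for k in ("smr", "min", "conditional")},
            None, insufficient_selection=True,
        )
    if design is not None:
        assert (sel["w_gx_top"] >= design.w_threshold - 1e-9).all()
    rejection = {
        "smr": {a: float((sel["p_smr"] < a).mean()) for a in alphas},
        "min": {a: float((sel["p_min"] < a).mean()) for a in alphas},
        "conditional": {a: float((sel["p_conditional"] < a).mean()) for a in alphas},
    }
    qq = qq_points(sel["t_smr"].to_numpy(), stats.chi2(df=1))
    return SMRNullExperimentResult(config, genes, n_sel, rejection, qq)
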