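"""Synthetic GWAS cohorts under a shared-polygenic-factor model.

The generator produces, at desk scale, the two datasets the pipeline
needs: a *discovery* cohort from which marginal single-SNP summary
statistics are computed, and a *target* cohort of disease cases, their
unaffected first-degree relatives, and screened controls, carrying a
battery of smoking phenotypes.

Model sketch
------------
Variants are biallelic SNPs arranged in fixed-size LD blocks. Within a
block, haplotypes are drawn from a Gaussian copula with AR(1) correlation
``within_block_rho`` and thresholded to hit each variant's minor-allele
frequency; blocks are independent, so window-based pruning has real work
to do while between-block scores stay uncorrelated.

A fraction ``prop_causal`` of variants is causal. Causal variants carry a
bivariate-normal pair of effects — one on the (smoking) discovery trait,
one on the disease liability — with correlation ``rg``, the genetic
correlation between the two traits. Each effect vector is scaled so the
genetic variance of its trait equals the configured heritability.

Disease status follows a liability-threshold model: liability = genetic
value + standard-normal environment, standardized to unit variance, with
cases above the ``prevalence`` quantile. Relatives are simulated as full
siblings of cases via shared parental haplotypes (expected genotypic
correlation 1/2), retained only if unaffected; controls are founders
screened to be unaffected. Smoking phenotypes (ever/never, age at
initiation, cigarettes per day, current/former) all load on the same
smoking genetic value through logistic, log-normal and negative-binomial
links.

Discovery summary statistics are produced by actually regressing the
simulated trait on each variant (vectorized OLS, or vectorized
Newton-scored logistic for binary traits), so betas and p-values are
internally consistent.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from .io import DosagePanel, write_dosage_tsv, write_phenotypes, write_summary_stats, write_vcf

__all__ = [
    "SmokingParams", "Demographics", "SimulationConfig", "TrueEffects",
    "liability_threshold", "variant_table", "simulate_effects",
    "simulate_genotypes", "simulate_discovery_sumstats",
    "simulate_discovery_cohort", "simulate_target_cohort",
    "simulate_phenotypes", "generate_fixture_set",
    "marginal_linear_gwas", "marginal_logistic_gwas",
    "DISCOVERY_TRAITS",
]

#: the four smoking phenotypes a discovery scan can target, with their
#: regression model and the subset of the cohort they are defined on
DISCOVERY_TRAITS = {
    "initiation": ("logistic", "all"),        # ever vs never smokers
    "age_initiation": ("linear", "ever"),     # log age at initiation
    "quantity": ("linear", "ever"),           # cigarettes per day
    "cessation": ("logistic", "ever"),        # current vs former
}


@dataclass(frozen=True)
class SmokingParams:
    """Rates and scales for the four smoking phenotypes.

    ``ever_rate`` is the baseline ever-smoker probability;
    ``mean_age_initiation`` / ``sd_log_age_initiation`` parametrize the
    log-normal initiation age; ``mean_cpd`` / ``cpd_dispersion`` the
    negative-binomial cigarettes-per-day; ``current_rate`` the baseline
    probability of being a current (vs former) smoker.
    """

    ever_rate: float = 0.30
    mean_age_initiation: float = 20.0
    sd_log_age_initiation: float = 0.15
    mean_cpd: float = 18.0
    cpd_dispersion: float = 8.0
    current_rate: float = 0.65


@dataclass(frozen=True)
class Demographics:
    """Per-group age/sex/education distributions for the target cohort.

    Defaults mirror the demographic structure of a case/relative/control
    family study of schizophrenia (relatives oldest, controls youngest and
    male-skewed).
    """

    age_mean_sd: dict = field(default_factory=lambda: {
        "HC": (37.2, 14.1), "FR": (56.8, 15.6), "SCZ": (42.9, 13.1)})
    male_frac: dict = field(default_factory=lambda: {
        "HC": 0.66, "FR": 0.32, "SCZ": 0.38})
    education_mean_sd: dict = field(default_factory=lambda: {
        "HC": (16.1, 2.4), "FR": (12.8, 2.1), "SCZ": (12.6, 2.2)})
    onset_mean_sd: tuple = (26.9, 10.6)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; every randomness source derives from
    ``seed``."""

    n_variants: int = 20_000
    block_size: int = 50
    within_block_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    prop_causal: float = 0.1
    h2_discovery: float = 0.5
    h2_liability: float | None = None  # None -> same as h2_discovery
    rg: float = 0.5
    n_discovery: int = 2_000
    n_cases: int = 130
    n_relatives: int = 56
    n_controls: int = 146
    prevalence: float = 0.01
    smoking_params: SmokingParams = field(default_factory=SmokingParams)
    demographics: Demographics = field(default_factory=Demographics)
    #: fraction of summary-stat records emitted with the effect allele set
    #: to REF (weight sign-flipped) / written on the opposite strand, to
    #: exercise allele harmonization downstream
    frac_effect_is_ref: float = 0.2
    frac_opposite_strand: float = 0.1
    #: fraction of target variants assigned sub-0.9 imputation quality
    frac_low_info: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.rg <= 1.0:
            raise ValueError(f"rg must be in [-1, 1], got {self.rg}")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        if not 0.0 < self.prop_causal <= 1.0:
            raise ValueError("prop_causal must be in (0, 1]")
        for name in ("h2_discovery",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.h2_liability is not None and not 0.0 <= self.h2_liability < 1.0:
            raise ValueError("h2_liability must be in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_relatives > self.n_cases:
            raise ValueError("n_relatives must be <= n_cases "
                             "(each relative is attached to one case family)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def h2_liab(self) -> float:
        return self.h2_discovery if self.h2_liability is None else self.h2_liability


@dataclass
class TrueEffects:
    """Per-variant true effect pair: (discovery trait, disease liability)."""

    beta_discovery: np.ndarray
    beta_liability: np.ndarray
    causal: np.ndarray  # bool

    def __post_init__(self):
        noncausal = ~self.causal
        assert np.all(self.beta_discovery[noncausal] == 0.0)
        assert np.all(self.beta_liability[noncausal] == 0.0)


# rng stream ids, fanned out from config.seed via SeedSequence
_S_VARIANTS, _S_EFFECTS, _S_DISCOVERY, _S_PHENO_D, _S_TARGET, _S_PHENO_T = range(6)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def liability_threshold(prevalence: float) -> float:
    """Standard-normal quantile above which liability means disease."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    return float(sps.norm.ppf(1.0 - prevalence))


# ---------------------------------------------------------------------------
# variant map
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant map: id, chromosome, position, ref/alt, maf, info.

    Blocks are laid out contiguously over autosomes 1-22; positions are
    evenly spaced so the panel is sorted by (chromosome, position).
    """
    rng = _rng(config, _S_VARIANTS)
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    ref_idx = rng.integers(0, 4, size=m)
    alt_off = rng.integers(1, 4, size=m)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_off) % 4]

    n_blocks = math.ceil(m / config.block_size)
    blocks_per_chrom = math.ceil(n_blocks / 22)
    block_of = np.arange(m) // config.block_size
    chrom = (block_of // blocks_per_chrom) + 1
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        pos[idx] = 10_000 + 5_000 * np.arange(len(idx))

    info = rng.uniform(0.92, 1.0, size=m)
    low = rng.random(m) < config.frac_low_info
    info[low] = rng.uniform(0.5, 0.9, size=int(low.sum()))

    return pd.DataFrame({
        "variant_id": [f"snp{i:06d}" for i in range(m)],
        "chromosome": chrom.astype(str),
        "position": pos,
        "ref": ref,
        "alt": alt,
        "maf": mafs,
        "info": np.round(info, 4),
        "block": block_of,
    })


# ---------------------------------------------------------------------------
# true effects
# ---------------------------------------------------------------------------

def simulate_effects(config: SimulationConfig,
                     variants: pd.DataFrame | None = None) -> TrueEffects:
    """Draw spike-and-slab bivariate-normal effect pairs.

    Causal variants (an exact ``prop_causal`` fraction) get effects with
    correlation ``rg``; each vector is then scaled so that, under
    Hardy-Weinberg and linkage equilibrium, the genetic variance of its
    trait equals the configured heritability (phenotype construction
    additionally standardizes realized genetic values, see
    :func:`simulate_phenotypes`).
    """
    if variants is None:
        variants = variant_table(config)
    rng = _rng(config, _S_EFFECTS)
    m = config.n_variants
    n_causal = max(1, int(round(config.prop_causal * m)))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    causal = np.zeros(m, dtype=bool)
    causal[causal_idx] = True

    # explicit bivariate construction: works for the degenerate |rg| = 1 case
    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    pairs = np.column_stack([
        z1, config.rg * z1 + math.sqrt(max(0.0, 1.0 - config.rg ** 2)) * z2])
    beta_d = np.zeros(m)
    beta_l = np.zeros(m)
    beta_d[causal_idx] = pairs[:, 0]
    beta_l[causal_idx] = pairs[:, 1]

    p = variants["maf"].to_numpy()
    het = 2.0 * p * (1.0 - p)
    for beta, h2 in ((beta_d, config.h2_discovery), (beta_l, config.h2_liab)):
        raw = float(np.sum(het * beta ** 2))
        if raw > 0 and h2 > 0:
            beta *= math.sqrt(h2 / raw)
        elif h2 == 0:
            beta[:] = 0.0
    return TrueEffects(beta_d, beta_l, causal)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_haplotypes(rng: np.random.Generator, n_hap: int, mafs: np.ndarray,
                     rho: float, block_size: int) -> np.ndarray:
    """AR(1)-Gaussian-copula haplotypes, int8 (n_hap x n_variants)."""
    m = len(mafs)
    out = np.empty((n_hap, m), dtype=np.int8)
    thr = sps.norm.ppf(mafs)
    scale = math.sqrt(1.0 - rho * rho)
    for start in range(0, m, block_size):
        b = min(block_size, m - start)
        z = rng.standard_normal((n_hap, b))
        if rho > 0:
            for j in range(1, b):
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        out[:, start:start + b] = z < thr[start:start + b]
    return out


def _founder_dosages(rng, n, mafs, rho, block_size) -> np.ndarray:
    h = _draw_haplotypes(rng, 2 * n, mafs, rho, block_size)
    return (h[:n] + h[n:]).astype(np.int8)


def _sibling_pair_dosages(rng, n_fam, mafs, rho, block_size):
    """Two full siblings per family from four shared parental haplotypes.

    Transmission is per LD block (each child inherits one whole block
    haplotype from each parent), preserving within-block LD and giving an
    expected genotypic correlation of 1/2 between siblings.
    """
    m = len(mafs)
    hm = [_draw_haplotypes(rng, n_fam, mafs, rho, block_size) for _ in range(2)]
    hf = [_draw_haplotypes(rng, n_fam, mafs, rho, block_size) for _ in range(2)]
    n_blocks = math.ceil(m / block_size)
    kids = []
    for _child in range(2):
        picks_m = rng.integers(0, 2, size=(n_fam, n_blocks))
        picks_f = rng.integers(0, 2, size=(n_fam, n_blocks))
        block_of = np.minimum(np.arange(m) // block_size, n_blocks - 1)
        sel_m = picks_m[:, block_of]  # (n_fam, m) in {0,1}
        sel_f = picks_f[:, block_of]
        dm = np.where(sel_m == 0, hm[0], hm[1])
        df_ = np.where(sel_f == 0, hf[0], hf[1])
        kids.append((dm + df_).astype(np.int8))
    return kids[0], kids[1]


def _panel_from_dosages(variants: pd.DataFrame, sample_prefix: str,
                        dosages: np.ndarray) -> DosagePanel:
    samples = [f"{sample_prefix}{i:05d}" for i in range(dosages.shape[0])]
    meta = variants[["variant_id", "chromosome", "position", "ref", "alt",
                     "info"]].copy()
    return DosagePanel(meta, samples, dosages.astype(float))


def simulate_genotypes(config: SimulationConfig,
                       role: Literal["discovery", "target-founder",
                                     "target-offspring"] = "discovery",
                       n_samples: int | None = None,
                       rng: np.random.Generator | None = None):
    """Simulate a genotype panel for one cohort role.

    ``discovery`` and ``target-founder`` return a :class:`DosagePanel` of
    unrelated individuals. ``target-offspring`` returns a *pair* of panels
    holding full-sibling pairs (one row per family in each), built by
    Mendelian transmission from shared parental haplotypes.
    """
    variants = variant_table(config)
    mafs = variants["maf"].to_numpy()
    if role == "discovery":
        rng = rng or _rng(config, _S_DISCOVERY)
        n = n_samples or config.n_discovery
        d = _founder_dosages(rng, n, mafs, config.within_block_rho,
                             config.block_size)
        return _panel_from_dosages(variants, "D", d)
    if role == "target-founder":
        rng = rng or _rng(config, _S_TARGET)
        n = n_samples or config.n_controls
        d = _founder_dosages(rng, n, mafs, config.within_block_rho,
                             config.block_size)
        return _panel_from_dosages(variants, "T", d)
    if role == "target-offspring":
        rng = rng or _rng(config, _S_TARGET)
        n = n_samples or config.n_cases
        a, b = _sibling_pair_dosages(rng, n, mafs, config.within_block_rho,
                                     config.block_size)
        return (_panel_from_dosages(variants, "SIBA", a),
                _panel_from_dosages(variants, "SIBB", b))
    raise ValueError(f"unknown role {role!r}")


# ---------------------------------------------------------------------------
# marginal GWAS
# ---------------------------------------------------------------------------

def marginal_linear_gwas(X: np.ndarray, y: np.ndarray):
    """Per-variant simple linear regression, vectorized.

    Returns (beta, se, p). Monomorphic variants get beta 0, p 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    xm = X.mean(axis=0)
    xc = X - xm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    mono = sxx <= 1e-12
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.nan)
    p = np.ones(X.shape[1])
    ok = ~mono
    beta[ok] = sxy[ok] / sxx[ok]
    syy = float(yc @ yc)
    rss = syy - beta[ok] * sxy[ok]
    rss = np.maximum(rss, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    p[ok] = 2.0 * sps.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p, mono


def marginal_logistic_gwas(X: np.ndarray, y: np.ndarray, max_iter: int = 30,
                           tol: float = 1e-8, chunk: int = 4_000):
    """Per-variant logistic regression (intercept + dosage), vectorized.

    Newton-Raphson on the 2x2 systems for all variants of a chunk at once;
    returns (logOR, se, p, monomorphic_mask) with Wald p-values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    p = np.ones(m)
    mono = X.std(axis=0) <= 1e-9
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        raise ValueError("binary trait has a single class")
    a0 = logit(ybar)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        Xc = X[:, sl]
        k = Xc.shape[1]
        a = np.full(k, a0)
        b = np.zeros(k)
        for _ in range(max_iter):
            eta = a[None, :] + Xc * b[None, :]
            mu = expit(eta)
            w = mu * (1.0 - mu)
            r = y[:, None] - mu
            g0 = r.sum(axis=0)
            g1 = np.einsum("ij,ij->j", Xc, r)
            h00 = w.sum(axis=0)
            h01 = np.einsum("ij,ij->j", Xc, w)
            h11 = np.einsum("ij,ij,ij->j", Xc, Xc, w)
            det = h00 * h11 - h01 * h01
            det = np.where(det <= 1e-12, np.nan, det)
            da = (h11 * g0 - h01 * g1) / det
            db = (h00 * g1 - h01 * g0) / det
            da = np.nan_to_num(da)
            db = np.nan_to_num(db)
            a += da
            b += db
            if max(np.max(np.abs(da), initial=0), np.max(np.abs(db), initial=0)) < tol:
                break
        eta = a[None, :] + Xc * b[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", Xc, w)
        h11 = np.einsum("ij,ij,ij->j", Xc, Xc, w)
        det = h00 * h11 - h01 * h01
        with np.errstate(divide="ignore", invalid="ignore"):
            var_b = np.where(det > 1e-12, h00 / det, np.nan)
        beta[sl] = b
        se[sl] = np.sqrt(var_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = b / se[sl]
        p[sl] = np.where(np.isfinite(z), 2.0 * sps.norm.sf(np.abs(z)), 1.0)
    beta[mono] = 0.0
    p[mono] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p, mono


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _genetic_values(dosages: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return dosages.astype(float) @ beta


def _reference_moments(config: SimulationConfig, effects: TrueEffects,
                       rng: np.random.Generator, n_ref: int = 1_000):
    """Population mean/sd of both genetic values, from a founder draw."""
    variants = variant_table(config)
    d = _founder_dosages(rng, n_ref, variants["maf"].to_numpy(),
                         config.within_block_rho, config.block_size)
    gd = _genetic_values(d, effects.beta_discovery)
    gl = _genetic_values(d, effects.beta_liability)
    return ((gd.mean(), max(gd.std(), 1e-12)),
            (gl.mean(), max(gl.std(), 1e-12)))


def _standardize(g, moments, h2):
    mu, sd = moments
    return (g - mu) / sd * math.sqrt(h2)


def _smoking_block(rng, z_smoke, ages, params: SmokingParams, h2: float):
    """Smoking phenotypes from the standardized smoking genetic value.

    ``z_smoke`` has variance ``h2``; each trait adds its own environmental
    residual. Higher genetic value means later initiation (and higher
    ever-smoking, quantity, and persistence) — the direction in which the
    disease-liability overlap is configured to act.
    """
    n = len(z_smoke)
    sigma_e = math.sqrt(max(1.0 - h2, 1e-12))
    ever_p = expit(logit(params.ever_rate) + z_smoke + 0.5 * sigma_e
                   * rng.standard_normal(n))
    ever = rng.random(n) < ever_p

    y_init = z_smoke + sigma_e * rng.standard_normal(n)
    age_init = np.exp(np.log(params.mean_age_initiation)
                      + params.sd_log_age_initiation * y_init)
    age_init = np.clip(np.round(age_init), 15, None)
    age_init = np.minimum(age_init, np.maximum(np.round(ages) - 1, 16))

    y_cpd = z_smoke + sigma_e * rng.standard_normal(n)
    mu_cpd = np.exp(np.log(params.mean_cpd) + 0.25 * y_cpd)
    r = params.cpd_dispersion
    cpd = rng.negative_binomial(r, r / (r + mu_cpd)) + 1.0

    cur_p = expit(logit(params.current_rate) + z_smoke + 0.5 * sigma_e
                  * rng.standard_normal(n))
    current = rng.random(n) < cur_p

    age_init = np.where(ever, age_init, np.nan)
    cpd = np.where(ever, cpd, np.nan)
    current = np.where(ever, current.astype(float), np.nan)
    return ever, age_init, cpd, current


def _demographic_block(rng, n, group, demo: Demographics):
    mu, sd = demo.age_mean_sd[group]
    age = np.clip(np.round(rng.normal(mu, sd, size=n)), 18, 90)
    sex = np.where(rng.random(n) < demo.male_frac[group], "M", "F")
    emu, esd = demo.education_mean_sd[group]
    edu = np.clip(np.round(rng.normal(emu, esd, size=n)), 6, 22)
    return age, sex, edu


def simulate_target_cohort(config: SimulationConfig,
                           effects: TrueEffects | None = None,
                           max_batches: int = 400):
    """Full target cohort: cases, unaffected sibling relatives, controls.

    Returns ``(panel, phenotypes, truth)`` where ``truth`` is a DataFrame
    with each individual's true genetic values and liability. Cases are
    ascertained by rejection sampling of sibling-pair families against the
    liability threshold; the attached sibling's environmental residual is
    redrawn (up to a cap) until unaffected, matching a family study that
    recruits *unaffected* first-degree relatives.
    """
    if effects is None:
        effects = simulate_effects(config)
    variants = variant_table(config)
    mafs = variants["maf"].to_numpy()
    rng = _rng(config, _S_TARGET)
    prng = _rng(config, _S_PHENO_T)
    (md, ml) = _reference_moments(config, effects, rng)
    thr = liability_threshold(config.prevalence)
    h2l = config.h2_liab
    sigma_e = math.sqrt(max(1.0 - h2l, 1e-12))

    case_d, rel_d = [], []
    case_g, rel_g = [], []   # (g_discovery, liability) tuples
    n_found = 0
    batch = max(64, min(4096, int(config.n_cases / config.prevalence / 16) + 64))
    for _ in range(max_batches):
        if n_found >= config.n_cases:
            break
        a, b = _sibling_pair_dosages(rng, batch, mafs, config.within_block_rho,
                                     config.block_size)
        gl_a = _standardize(_genetic_values(a, effects.beta_liability), ml, h2l)
        liab_a = gl_a + sigma_e * prng.standard_normal(batch)
        idx = np.where(liab_a > thr)[0]
        if idx.size == 0:
            continue
        gl_b = _standardize(_genetic_values(b[idx], effects.beta_liability), ml, h2l)
        # redraw sibling environment until unaffected (cap 50 tries)
        liab_b = gl_b + sigma_e * prng.standard_normal(idx.size)
        for _try in range(50):
            still = liab_b > thr
            if not still.any():
                break
            liab_b[still] = gl_b[still] + sigma_e * prng.standard_normal(int(still.sum()))
        chosen = np.where(liab_b <= thr)[0][: config.n_cases - n_found]
        if chosen.size:
            take = idx[chosen]
            case_d.append(a[take])
            rel_d.append(b[take])
            case_g.append(np.column_stack([
                _standardize(_genetic_values(a[take], effects.beta_discovery),
                             md, config.h2_discovery),
                liab_a[take]]))
            rel_g.append(np.column_stack([
                _standardize(_genetic_values(b[take], effects.beta_discovery),
                             md, config.h2_discovery),
                liab_b[chosen]]))
            n_found += chosen.size
    if n_found < config.n_cases:
        raise RuntimeError(
            f"could not ascertain {config.n_cases} cases at prevalence "
            f"{config.prevalence} within {max_batches} batches")

    case_dos = np.concatenate(case_d)[: config.n_cases]
    rel_dos = np.concatenate(rel_d)[: config.n_relatives]
    case_gv = np.concatenate(case_g)[: config.n_cases]
    rel_gv = np.concatenate(rel_g)[: config.n_relatives]

    # controls: founders screened to be unaffected
    ctrl_chunks, ctrl_gv = [], []
    n_ctrl = 0
    while n_ctrl < config.n_controls:
        d = _founder_dosages(rng, config.n_controls, mafs,
                             config.within_block_rho, config.block_size)
        gl = _standardize(_genetic_values(d, effects.beta_liability), ml, h2l)
        liab = gl + sigma_e * prng.standard_normal(config.n_controls)
        keep = liab <= thr
        d = d[keep][: config.n_controls - n_ctrl]
        gd = _standardize(_genetic_values(d, effects.beta_discovery), md,
                          config.h2_discovery)
        ctrl_chunks.append(d)
        ctrl_gv.append(np.column_stack([gd, liab[keep][: d.shape[0]]]))
        n_ctrl += d.shape[0]
    ctrl_dos = np.concatenate(ctrl_chunks)[: config.n_controls]
    ctrl_gvals = np.concatenate(ctrl_gv)[: config.n_controls]

    dosages = np.concatenate([ctrl_dos, rel_dos, case_dos])
    groups = (["HC"] * config.n_controls + ["FR"] * config.n_relatives
              + ["SCZ"] * config.n_cases)
    gvals = np.concatenate([ctrl_gvals, rel_gv, case_gv])
    samples = [f"{g}{i:04d}" for i, g in enumerate(groups)]
    meta = variants[["variant_id", "chromosome", "position", "ref", "alt",
                     "info"]].copy()
    panel = DosagePanel(meta, samples, dosages.astype(float))
    truth = pd.DataFrame({"sample_id": samples, "group": groups,
                          "g_discovery": gvals[:, 0], "liability": gvals[:, 1]})
    phenotypes = simulate_phenotypes(panel, effects, config, truth=truth,
                                     rng=prng)
    return panel, phenotypes, truth


def simulate_phenotypes(panel: DosagePanel, effects: TrueEffects,
                        config: SimulationConfig,
                        truth: pd.DataFrame | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Phenotype table for a target panel.

    Disease status and group labels come from ``truth`` when the panel was
    produced by :func:`simulate_target_cohort`; otherwise all individuals
    are labelled by liability drawn here. Smoking variables derive from
    the smoking genetic value through the configured links.
    """
    rng = rng or _rng(config, _S_PHENO_T)
    if truth is None:
        gd = _genetic_values(panel.dosages, effects.beta_discovery)
        gl = _genetic_values(panel.dosages, effects.beta_liability)
        # fall back to in-sample standardization
        zd = (gd - gd.mean()) / max(gd.std(), 1e-12) * math.sqrt(config.h2_discovery)
        zl = (gl - gl.mean()) / max(gl.std(), 1e-12) * math.sqrt(config.h2_liab)
        liab = zl + math.sqrt(max(1 - config.h2_liab, 1e-12)) \
            * rng.standard_normal(panel.n_samples)
        thr = liability_threshold(config.prevalence)
        groups = np.where(liab > thr, "SCZ", "HC")
        truth = pd.DataFrame({"sample_id": panel.samples, "group": groups,
                              "g_discovery": zd, "liability": liab})
    demo = config.demographics
    parts = []
    for group in ("HC", "FR", "SCZ"):
        sub = truth[truth["group"] == group]
        if sub.empty:
            continue
        n = len(sub)
        age, sex, edu = _demographic_block(rng, n, group, demo)
        ever, age_init, cpd, current = _smoking_block(
            rng, sub["g_discovery"].to_numpy(), age,
            config.smoking_params, config.h2_discovery)
        onset = np.full(n, np.nan)
        if group == "SCZ":
            omu, osd = demo.onset_mean_sd
            onset = np.clip(np.round(rng.normal(omu, osd, size=n)), 13, None)
            onset = np.minimum(onset, age)
        parts.append(pd.DataFrame({
            "sample_id": sub["sample_id"].to_numpy(),
            "group": group, "age": age, "sex": sex, "education": edu,
            "ever_smoker": ever.astype(int),
            "age_initiation": age_init, "cpd": cpd,
            "current_smoker": current, "onset_age": onset,
        }))
    out = pd.concat(parts, ignore_index=True)
    order = pd.Index(truth["sample_id"])
    return out.set_index("sample_id").loc[order].reset_index()


# ---------------------------------------------------------------------------
# discovery cohort and summary statistics
# ---------------------------------------------------------------------------

def simulate_discovery_cohort(config: SimulationConfig,
                              effects: TrueEffects | None = None):
    """Discovery panel plus its smoking phenotypes (founders only)."""
    if effects is None:
        effects = simulate_effects(config)
    panel = simulate_genotypes(config, "discovery")
    rng = _rng(config, _S_PHENO_D)
    gd = _genetic_values(panel.dosages, effects.beta_discovery)
    z = (gd - gd.mean()) / max(gd.std(), 1e-12) * math.sqrt(config.h2_discovery)
    ages = np.clip(np.round(rng.normal(45, 12, size=panel.n_samples)), 20, 90)
    ever, age_init, cpd, current = _smoking_block(
        rng, z, ages, config.smoking_params, config.h2_discovery)
    pheno = pd.DataFrame({
        "sample_id": panel.samples, "ever_smoker": ever.astype(int),
        "age_initiation": age_init, "cpd": cpd, "current_smoker": current,
    })
    return panel, pheno, effects


def simulate_discovery_sumstats(panel: DosagePanel, effects: TrueEffects,
                                config: SimulationConfig,
                                trait: str = "age_initiation",
                                phenotypes: pd.DataFrame | None = None,
                                representation_noise: bool = True) -> pd.DataFrame:
    """Marginal single-SNP summary statistics for one smoking trait.

    The trait is generated on (or taken from) the discovery cohort and
    regressed on every variant — OLS for continuous traits, logistic for
    binary ones, so binary weights are log odds ratios. With
    ``representation_noise`` a configured fraction of records is emitted
    with the effect allele set to REF (weight negated) or with both
    alleles complemented, exercising downstream harmonization; the
    encoding is deterministic given the config seed.
    """
    if trait not in DISCOVERY_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; "
                         f"choose from {sorted(DISCOVERY_TRAITS)}")
    model, subset = DISCOVERY_TRAITS[trait]
    if phenotypes is None:
        _, phenotypes, _ = simulate_discovery_cohort(config, effects)
        if len(phenotypes) != panel.n_samples:
            raise ValueError("panel does not match the discovery config")
    pheno = phenotypes.set_index("sample_id").loc[panel.samples]

    if subset == "ever":
        mask = pheno["ever_smoker"].to_numpy() == 1
    else:
        mask = np.ones(panel.n_samples, dtype=bool)
    X = panel.dosages[mask]
    if trait == "initiation":
        y = pheno["ever_smoker"].to_numpy(float)[mask]
    elif trait == "age_initiation":
        y = np.log(pheno["age_initiation"].to_numpy(float)[mask])
    elif trait == "quantity":
        y = pheno["cpd"].to_numpy(float)[mask]
    else:  # cessation: current (1) vs former (0)
        y = pheno["current_smoker"].to_numpy(float)[mask]

    if model == "linear":
        beta, se, p, mono = marginal_linear_gwas(X, y)
    else:
        beta, se, p, mono = marginal_logistic_gwas(X, y)

    variants = variant_table(config)
    eaf = X.mean(axis=0) / 2.0
    out = pd.DataFrame({
        "variant_id": variants["variant_id"],
        "chromosome": variants["chromosome"],
        "position": variants["position"],
        "effect_allele": variants["alt"],
        "other_allele": variants["ref"],
        "weight": beta,
        "p_value": p,
        "eaf": eaf,
        "info": variants["info"],
        "monomorphic": mono,
    })
    if representation_noise:
        out = _apply_representation_noise(out, config)
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _apply_representation_noise(sumstats: pd.DataFrame,
                                config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 99)))
    out = sumstats.copy()
    m = len(out)
    swap = rng.random(m) < config.frac_effect_is_ref
    comp = rng.random(m) < config.frac_opposite_strand
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    w = out["weight"].to_numpy().copy()
    ea[swap], oa[swap], w[swap] = oa[swap].copy(), ea[swap].copy(), -w[swap]
    for arr in (ea, oa):
        arr[comp] = [_COMP[b] for b in arr[comp]]
    out["effect_allele"], out["other_allele"], out["weight"] = ea, oa, w
    return out


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

def generate_fixture_set(config: SimulationConfig, output_dir,
                         traits: Sequence[str] = tuple(DISCOVERY_TRAITS)) -> pd.DataFrame:
    """Write a complete, reproducible fixture set to ``output_dir``.

    One summary-statistics file per requested smoking trait, the target
    dosage panel in both dialects (VCF and dosage-tsv), the phenotype
    table, the config used, and a checksum manifest. Re-running with the
    same config is byte-identical.
    """
    import yaml

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    effects = simulate_effects(config)
    d_panel, d_pheno, _ = simulate_discovery_cohort(config, effects)
    files = []
    for trait in traits:
        ss = simulate_discovery_sumstats(d_panel, effects, config, trait,
                                         phenotypes=d_pheno)
        path = outdir / f"sumstats_{trait}.tsv"
        write_summary_stats(ss.drop(columns=["monomorphic"]), path)
        files.append(path)

    t_panel, t_pheno, truth = simulate_target_cohort(config, effects)
    write_dosage_tsv(t_panel, outdir / "target.dosage.tsv")
    files.append(outdir / "target.dosage.tsv")
    write_vcf(t_panel, outdir / "target.vcf")
    files.append(outdir / "target.vcf")
    write_phenotypes(t_pheno, outdir / "phenotypes.tsv")
    files.append(outdir / "phenotypes.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                 float_format="%.6g")
    files.append(outdir / "truth.tsv")
    cfg = asdict(config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    files.append(outdir / "config.yaml")

    entries = [{"path": f.name,
                "sha256": hashlib.sha256(f.read_bytes()).hexdigest()}
               for f in files]
    manifest = pd.DataFrame(entries)
    manifest.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
    return manifest
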