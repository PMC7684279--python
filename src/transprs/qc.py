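"""Variant QC and allele harmonization.

QC applies, in a fixed order: duplicate-id removal, strand-ambiguous
(A/T, C/G) removal, a chromosome drop list (Y and mitochondrial by
default), an imputation-quality floor, a minor-allele-frequency floor,
and an exact Hardy-Weinberg test (hard genotype calls only). Each
excluded variant is logged once with the first rule it failed, so
stage-count bookkeeping is exact.

Harmonization reconciles each discovery record's effect allele with the
target panel's counted (ALT) allele: a direct match keeps the weight, a
flipped match negates it, and for non-ambiguous SNPs the same two cases
are tried on the complementary strand. Allele sets that cannot be
reconciled become ``excluded(mismatch)`` values rather than exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import DosagePanel

__all__ = [
    "QcThresholds", "is_strand_ambiguous", "hwe_exact_test", "variant_qc",
    "harmonize_alleles", "harmonize", "MATCH_TYPES",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MATCH_TYPES = ("direct", "flipped", "complement-direct",
               "complement-flipped", "excluded")


@dataclass(frozen=True)
class QcThresholds:
    """Variant-level QC cutoffs.

    Defaults: MAF >= 0.01, HWE exact p >= 1e-6, imputation INFO >= 0.9,
    strand-ambiguous SNPs dropped, Y and MT excluded.
    """

    maf_min: float = 0.01
    hwe_alpha: float = 1e-6
    info_min: float = 0.9
    drop_ambiguous: bool = True
    drop_chroms: frozenset = frozenset({"Y", "MT"})

    def __post_init__(self):
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must be in (0, 1)")
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must be in [0, 1]")


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    for a in (a1, a2):
        if a not in _COMP:
            raise ValueError(f"non-ACGT allele: {a!r}")
    return _COMP[a1] == a2


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, heterozygote counts follow the
    distribution P(h) proportional to n! / (nAA! nAa! naa!) * 2^h; the
    p-value sums the probabilities of all heterozygote counts (same
    parity as the minor-allele total) no more probable than the observed
    one. Monomorphic tables have a single attainable configuration and
    p = 1.
    """
    counts = (n_ref_hom, n_het, n_alt_hom)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = int(sum(counts))
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_het = int(n_het)
    rare = int(2 * min(n_ref_hom, n_alt_hom) + n_het)  # minor-allele count
    if rare == 0 or rare == 2 * n:
        return 1.0
    # log-probability of each attainable het count h (h = rare mod 2, ... , rare)
    hs = np.arange(rare % 2, rare + 1, 2)
    hs = hs[(rare - hs) % 2 == 0]
    hom_rare = (rare - hs) // 2
    hom_common = n - hs - hom_rare
    hs = hs[hom_common >= 0]
    hom_rare = (rare - hs) // 2
    hom_common = n - hs - hom_rare
    lg = math.lgamma
    logp = np.array([
        hv * math.log(2) - lg(hv + 1) - lg(hr + 1) - lg(hc + 1)
        for hv, hr, hc in zip(hs, hom_rare, hom_common)
    ])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.where(hs == n_het)[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray):
    d = col[~np.isnan(col)]
    r = np.round(d).astype(int)
    return int(np.sum(r == 0)), int(np.sum(r == 1)), int(np.sum(r == 2))


def variant_qc(panel: DosagePanel, thresholds: QcThresholds | None = None,
               hwe_sample_mask: np.ndarray | None = None):
    """Apply the QC filters; returns ``(kept_ids, exclusion_log)``.

    ``exclusion_log`` is a DataFrame (variant_id, rule, detail) with one
    row per excluded variant, labelled with the first failing rule. The
    HWE test runs only when the panel holds hard genotype calls;
    ``hwe_sample_mask`` optionally restricts it to a founder/control
    subset.
    """
    thr = thresholds or QcThresholds()
    meta = panel.variants
    ids = meta["variant_id"].to_numpy()
    excluded: dict[int, tuple[str, str]] = {}

    dup = pd.Index(ids).duplicated(keep="first")
    for i in np.where(dup)[0]:
        excluded[i] = ("duplicate", "duplicate variant id")

    if thr.drop_ambiguous:
        for i in range(len(meta)):
            if i in excluded:
                continue
            try:
                amb = is_strand_ambiguous(meta["ref"].iat[i], meta["alt"].iat[i])
            except ValueError:
                excluded[i] = ("alleles", "non-ACGT allele")
                continue
            if amb:
                excluded[i] = ("ambiguous",
                               f"{meta['ref'].iat[i]}/{meta['alt'].iat[i]}")

    chroms = meta["chromosome"].astype(str).to_numpy()
    for i in np.where(np.isin(chroms, list(thr.drop_chroms)))[0]:
        excluded.setdefault(int(i), ("chromosome", chroms[i]))

    if "info" in meta.columns:
        info = meta["info"].to_numpy(dtype=float)
        for i in np.where(info < thr.info_min)[0]:
            excluded.setdefault(int(i), ("info", f"INFO={info[i]:.3g}"))

    freqs = panel.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    with np.errstate(invalid="ignore"):
        low = np.where(~(maf >= thr.maf_min))[0]
    for i in low:
        excluded.setdefault(int(i), ("maf", f"MAF={maf[i]:.4g}"))

    if panel.is_hard_calls():
        dos = panel.dosages if hwe_sample_mask is None \
            else panel.dosages[hwe_sample_mask]
        for i in range(panel.n_variants):
            if i in excluded:
                continue
            p = hwe_exact_test(*_genotype_counts(dos[:, i]))
            if p < thr.hwe_alpha:
                excluded[i] = ("hwe", f"p={p:.3g}")

    kept = [ids[i] for i in range(len(ids)) if i not in excluded]
    log = pd.DataFrame(
        [{"variant_id": ids[i], "rule": r, "detail": d}
         for i, (r, d) in sorted(excluded.items())],
        columns=["variant_id", "rule", "detail"])
    return kept, log


def harmonize_alleles(effect_allele: str, other_allele: str,
                      ref: str, alt: str, weight: float):
    """Align one discovery record to the target's counted (ALT) allele.

    Returns ``(match_type, aligned_weight)``; ``aligned_weight`` is None
    for ``excluded`` matches. Complementary-strand matches are attempted
    only for non-ambiguous allele pairs (for A/T and C/G SNPs the two
    strands are indistinguishable).
    """
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    ref, alt = str(ref).upper(), str(alt).upper()
    for a in (ea, oa, ref, alt):
        if a not in _COMP:
            return "excluded", None
    if ea == oa or ref == alt:
        return "excluded", None
    if (ea, oa) == (alt, ref):
        return "direct", float(weight)
    if (ea, oa) == (ref, alt):
        return "flipped", -float(weight)
    if not is_strand_ambiguous(ea, oa) and not is_strand_ambiguous(ref, alt):
        cea, coa = _COMP[ea], _COMP[oa]
        if (cea, coa) == (alt, ref):
            return "complement-direct", float(weight)
        if (cea, coa) == (ref, alt):
            return "complement-flipped", -float(weight)
    return "excluded", None


def harmonize(sumstats: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a summary-statistics table against target variant metadata.

    Joins on ``variant_id`` and applies :func:`harmonize_alleles` per
    record. Returns a DataFrame with ``variant_id, p_value,
    aligned_weight, match_type`` covering the intersection; excluded
    variants carry NaN weights and ``match_type`` ``excluded``.
    """
    tgt = variants.set_index("variant_id")[["ref", "alt"]]
    common = sumstats[sumstats["variant_id"].isin(tgt.index)].copy()
    refs = tgt.loc[common["variant_id"], "ref"].to_numpy()
    alts = tgt.loc[common["variant_id"], "alt"].to_numpy()
    types, weights = [], []
    for ea, oa, r, a, w in zip(common["effect_allele"], common["other_allele"],
                               refs, alts, common["weight"]):
        t, aw = harmonize_alleles(ea, oa, r, a, w)
        types.append(t)
        weights.append(np.nan if aw is None else aw)
    out = pd.DataFrame({
        "variant_id": common["variant_id"].to_numpy(),
        "p_value": common["p_value"].to_numpy(),
        "aligned_weight": weights,
        "match_type": types,
    })
    return out.reset_index(drop=True)
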