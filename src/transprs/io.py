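"""Readers and writers for the file shapes the pipeline touches.

Four formats are supported, all plain text:

* GWAS summary statistics — tab/whitespace-delimited with a header row; a
  column map resolves nonstandard header names. Files may carry effect
  sizes as ``BETA``/``logOR`` (used as-is) or as ``OR`` (natural log is
  taken on read).
* Genotype dosages — either VCF with a per-sample ``DS`` field (falling
  back to hard ``GT`` calls) or a "dosage-tsv" dialect: one variant per
  row, metadata columns then one column per sample, ``NA`` for missing.
* Phenotype tables — tab-delimited, one row per individual (diagnostic
  group, demographics, smoking variables).
* Result tables — tab-delimited with a deterministic column order.

All readers validate against the type invariants (alleles distinct,
p-values in (0, 1], dosages in [0, 2]) and either fail with row numbers
(strict) or skip offending rows with a logged warning (lenient).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("transprs")

VALID_CHROMS = {str(c) for c in range(1, 23)} | {"X", "Y", "MT"}

#: canonical summary-statistic columns, in write order
SUMSTAT_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele",
    "other_allele", "weight", "p_value", "eaf", "info",
]

#: header aliases understood without an explicit column map
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "SNP": "variant_id", "ID": "variant_id", "RSID": "variant_id",
    "MARKERNAME": "variant_id",
    "CHR": "chromosome", "CHROM": "chromosome",
    "BP": "position", "POS": "position",
    "A1": "effect_allele", "EFFECT_ALLELE": "effect_allele",
    "A2": "other_allele", "OTHER_ALLELE": "other_allele",
    "BETA": "weight", "B": "weight", "LOGOR": "weight", "EFFECT": "weight",
    "OR": "odds_ratio",
    "P": "p_value", "PVAL": "p_value", "P_VALUE": "p_value",
    "EAF": "eaf", "FRQ": "eaf", "FREQ": "eaf", "AF": "eaf",
    "INFO": "info", "R2": "info", "DR2": "info",
}

MANDATORY_SUMSTAT = ["variant_id", "chromosome", "position",
                     "effect_allele", "other_allele", "p_value"]

PHENOTYPE_COLUMNS = [
    "sample_id", "group", "age", "sex", "education", "ever_smoker",
    "age_initiation", "cpd", "current_smoker", "onset_age",
]

GROUPS = ("HC", "FR", "SCZ")


class FileFormatError(ValueError):
    """A file violates its declared format or a type invariant."""


def normalize_chromosome(value) -> str:
    """Strip a ``chr`` prefix and map ``M``/``chrM`` to ``MT``."""
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"M", "MT"}:
        return "MT"
    return s.upper() if s.upper() in {"X", "Y"} else s


@dataclass
class DosagePanel:
    """Target-genotype container: variant metadata plus a samples x variants
    dosage matrix counting alternate alleles in [0, 2] (NaN = missing).

    ``variants`` carries at least ``variant_id, chromosome, position, ref,
    alt`` and optionally ``info``.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray  # (n_samples, n_variants), float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < -1e-6) | (self.dosages > 2 + 1e-6)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def is_hard_calls(self) -> bool:
        """True if every non-missing dosage is an integer 0/1/2."""
        d = self.dosages[~np.isnan(self.dosages)]
        return bool(np.all(np.abs(d - np.round(d)) < 1e-9))

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant (missing-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, ids: Sequence[str]) -> "DosagePanel":
        idx = pd.Index(self.variants["variant_id"])
        pos = idx.get_indexer(pd.Index(ids))
        if np.any(pos < 0):
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"variants not in panel: {missing[:5]}")
        return DosagePanel(self.variants.iloc[pos].reset_index(drop=True),
                           list(self.samples), self.dosages[:, pos])

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosagePanel":
        idx = pd.Index(self.samples)
        pos = idx.get_indexer(pd.Index(sample_ids))
        if np.any(pos < 0):
            raise KeyError("samples not in panel")
        return DosagePanel(self.variants.copy(), list(sample_ids),
                           self.dosages[pos, :])


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path, column_map: Mapping[str, str] | None = None,
                       strict: bool = True) -> pd.DataFrame:
    """Read a summary-statistics file into the canonical schema.

    Parameters
    ----------
    path : str or Path
        Tab- or whitespace-delimited file with a header row.
    column_map : mapping, optional
        Extra ``{file header -> canonical name}`` entries layered on top of
        the built-in aliases. A header mapped to ``odds_ratio`` is
        log-transformed into ``weight``.
    strict : bool
        If True, any invalid row aborts with its line number; otherwise
        invalid rows are skipped with a warning.

    Returns
    -------
    DataFrame with columns :data:`SUMSTAT_COLUMNS` (eaf/info may be NaN).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k.upper(): v for k, v in column_map.items()})
    rename = {c: cmap[c.upper()] for c in df.columns if c.upper() in cmap}
    df = df.rename(columns=rename)

    if "weight" not in df.columns and "odds_ratio" in df.columns:
        orv = pd.to_numeric(df["odds_ratio"], errors="coerce")
        if (orv <= 0).any():
            raise FileFormatError(f"{path}: non-positive OR cannot be logged")
        df["weight"] = np.log(orv)
    missing = [c for c in MANDATORY_SUMSTAT + ["weight"] if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing mandatory column(s) {missing}")

    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    for col in ("position",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("weight", "p_value", "eaf", "info"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "info"):
        if col not in df.columns:
            df[col] = np.nan
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask, reason):
        nonlocal bad
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad |= mask

    flag(~df["chromosome"].isin(VALID_CHROMS), "invalid chromosome")
    flag(df["position"].isna() | (df["position"] < 1), "position < 1")
    flag(df["effect_allele"].isin(["", "NAN"]) | df["other_allele"].isin(["", "NAN"]),
         "empty allele")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(df["p_value"].isna() | (df["p_value"] <= 0) | (df["p_value"] > 1),
         "p-value outside (0, 1]")
    flag(~np.isfinite(df["weight"].to_numpy(dtype=float)), "non-finite weight")

    if bad.any():
        # +2: header line plus 1-based counting
        lines = [f"line {i + 2}: {reasons[i]}" for i in df.index[bad][:10]]
        msg = f"{path}: {int(bad.sum())} invalid row(s): " + "; ".join(lines)
        if strict:
            raise FileFormatError(msg)
        logger.warning(msg)
        df = df[~bad]

    df["position"] = df["position"].astype(int)
    return df[SUMSTAT_COLUMNS + [c for c in df.columns if c not in SUMSTAT_COLUMNS
                                 and c != "odds_ratio"]].reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMSTAT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA",
                    float_format="%.6g")


# ---------------------------------------------------------------------------
# dosages
# ---------------------------------------------------------------------------

DOSAGE_TSV_META = ["variant_id", "chromosome", "position", "ref", "alt", "info"]


def read_dosages(path, dialect: str = "dosage-tsv") -> DosagePanel:
    """Read a genotype-dosage panel.

    ``dialect`` is ``"vcf-dosage"`` (VCF exposing a ``DS`` per-sample field,
    falling back to hard GT calls) or ``"dosage-tsv"`` (variants as rows,
    samples as columns, ``NA`` missing). Multi-allelic VCF records are
    skipped with a warning; the counted allele is ALT.
    """
    if dialect == "dosage-tsv":
        return _read_dosage_tsv(path)
    if dialect == "vcf-dosage":
        return _read_vcf_dosage(path)
    raise ValueError(f"unknown dosage dialect: {dialect!r}")


def _read_dosage_tsv(path) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."], dtype={"chromosome": str})
    missing = [c for c in DOSAGE_TSV_META if c not in df.columns and c != "info"]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in DOSAGE_TSV_META]
    if not sample_cols:
        raise FileFormatError(f"{path}: no sample columns")
    meta = df[[c for c in DOSAGE_TSV_META if c in df.columns]].copy()
    if "info" not in meta.columns:
        meta["info"] = np.nan
    meta["chromosome"] = meta["chromosome"].map(normalize_chromosome)
    dos = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    with np.errstate(invalid="ignore"):
        if np.any((dos < -1e-6) | (dos > 2 + 1e-6)):
            raise FileFormatError(f"{path}: dosage outside [0, 2]")
    return DosagePanel(meta, sample_cols, dos)


def _read_vcf_dosage(path) -> DosagePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        try:
            arr = v.format("DS")
        except Exception:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(len(samples))
            ds[ds < -0.5] = np.nan  # cyvcf2 missing sentinel
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            ds = np.where(gt == 3, 2.0, gt)
            ds[gt == 2] = np.nan
        info = v.INFO.get("INFO")
        if info is None:
            info = v.INFO.get("R2", np.nan)
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", normalize_chromosome(v.CHROM),
                     v.POS, v.REF, v.ALT[0], float(info) if info is not None else np.nan))
        cols.append(ds)
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic record(s)", path, n_multi)
    meta = pd.DataFrame(rows, columns=DOSAGE_TSV_META)
    dos = np.asarray(cols, dtype=float).T if cols else np.empty((len(samples), 0))
    with np.errstate(invalid="ignore"):
        if np.any((dos < -1e-6) | (dos > 2 + 1e-6)):
            raise FileFormatError(f"{path}: dosage outside [0, 2]")
    return DosagePanel(meta, samples, dos)


def write_dosage_tsv(panel: DosagePanel, path) -> None:
    meta = panel.variants.copy()
    if "info" not in meta.columns:
        meta["info"] = np.nan
    out = meta[DOSAGE_TSV_META].copy()
    dosages = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    pd.concat([out, dosages], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.4g")


def write_vcf(panel: DosagePanel, path) -> None:
    """Write the panel as an uncompressed VCF with GT and DS fields."""
    hard = panel.is_hard_calls()
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,'
                 'Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        meta = panel.variants
        has_info = "info" in meta.columns
        for j in range(panel.n_variants):
            row = meta.iloc[j]
            info = row["info"] if has_info else np.nan
            info_s = f"INFO={info:.4g}" if np.isfinite(info) else "."
            fields = []
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    gt = gt_map[int(round(d))] if hard else "./."
                    fields.append(f"{gt}:{d:.4g}")
            fh.write(f"{row['chromosome']}\t{int(row['position'])}\t"
                     f"{row['variant_id']}\t{row['ref']}\t{row['alt']}\t.\t"
                     f"PASS\t{info_s}\tGT:DS\t" + "\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, strict: bool = True) -> pd.DataFrame:
    """Read a phenotype table and enforce smoking-field consistency.

    Never-smokers must have ``age_initiation``, ``cpd`` and
    ``current_smoker`` missing; ever-smokers must carry an initiation age.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."])
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask, reason):
        nonlocal bad
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad |= mask

    flag(~df["group"].isin(GROUPS), "group not in {HC, FR, SCZ}")
    never = df["ever_smoker"] == 0
    ever = df["ever_smoker"] == 1
    smoker_only = df[["age_initiation", "cpd", "current_smoker"]].notna().any(axis=1)
    flag(never & smoker_only, "smoker-only field set for never-smoker")
    flag(ever & df["age_initiation"].isna(), "ever-smoker lacks age_initiation")
    if bad.any():
        lines = [f"line {i + 2}: {reasons[i]}" for i in df.index[bad][:10]]
        msg = f"{path}: {int(bad.sum())} invalid row(s): " + "; ".join(lines)
        if strict:
            raise FileFormatError(msg)
        logger.warning(msg)
        df = df[~bad]
    return df[PHENOTYPE_COLUMNS].reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA",
                                 float_format="%.6g")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], output_dir) -> pd.DataFrame:
    """Write one tab-delimited file per result table.

    Returns a manifest DataFrame (name, path, sha256, n_rows). Column order
    within each table is preserved as given, so repeated runs produce
    byte-identical files.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA",
                     float_format="%.8g")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"name": name, "path": str(path),
                        "sha256": digest, "n_rows": len(table)})
    manifest = pd.DataFrame(entries, columns=["name", "path", "sha256", "n_rows"])
    manifest.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
    return manifest
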