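"""P_T-threshold SNP sets and per-individual polygenic scores.

A polygenic score is the raw weighted allele-dosage sum
``score_i = sum_v dosage_iv * aligned_weight_v`` over the variants whose
discovery p-value passes a cutoff; the default grid scans the eight
nested cutoffs 1e-4 ... 1. Missing dosages are mean-imputed per variant
by default; an ``omit`` policy (renormalizing each person's score by the
observed weight mass) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DosagePanel

__all__ = ["DEFAULT_GRID", "ThresholdGrid", "PrsProfile",
           "threshold_select", "score", "prs_profile"]

DEFAULT_GRID = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered p-value cutoffs, strictly increasing, each in (0, 1]."""

    cutoffs: tuple = DEFAULT_GRID

    def __post_init__(self):
        c = tuple(float(x) for x in self.cutoffs)
        if not c or any(not 0 < x <= 1 for x in c):
            raise ValueError("cutoffs must lie in (0, 1]")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        object.__setattr__(self, "cutoffs", c)

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self):
        return len(self.cutoffs)


@dataclass
class PrsProfile:
    """Per-individual scores at each cutoff, plus per-cutoff SNP counts."""

    samples: list
    cutoffs: tuple
    scores: np.ndarray       # (n_samples, n_cutoffs)
    snp_counts: np.ndarray   # (n_cutoffs,)
    standardized: bool = False

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.samples), len(self.cutoffs)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if np.any(np.diff(self.snp_counts) < 0):
            raise ValueError("snp_count must be non-decreasing across cutoffs")

    def column(self, cutoff: float) -> np.ndarray:
        return self.scores[:, self.cutoffs.index(cutoff)]

    def standardize(self) -> "PrsProfile":
        """Z-score each cutoff column (constant columns stay 0)."""
        sd = self.scores.std(axis=0, ddof=0)
        safe = np.where(sd > 0, sd, 1.0)
        z = (self.scores - self.scores.mean(axis=0)) / safe
        z[:, sd == 0] = 0.0
        return PrsProfile(list(self.samples), self.cutoffs, z,
                          self.snp_counts.copy(), standardized=True)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"pt_{c:g}" for c in self.cutoffs])
        df.insert(0, "sample_id", self.samples)
        return df


def threshold_select(harmonized: pd.DataFrame,
                     grid: ThresholdGrid | Sequence[float] = DEFAULT_GRID
                     ) -> dict[float, list]:
    """Nested per-cutoff variant-id sets: {v : p_v <= cutoff}.

    Expects a harmonized table with ``variant_id``, ``p_value`` and
    ``aligned_weight`` columns; excluded (NaN-weight) records never
    enter a set.
    """
    grid = grid if isinstance(grid, ThresholdGrid) else ThresholdGrid(tuple(grid))
    usable = harmonized[harmonized["aligned_weight"].notna()]
    out = {}
    for cutoff in grid:
        out[cutoff] = usable.loc[usable["p_value"] <= cutoff,
                                 "variant_id"].tolist()
    return out


def score(panel: DosagePanel, weights: Mapping[str, float] | pd.Series,
          ids: Sequence[str] | None = None,
          missing_policy: str = "mean") -> np.ndarray:
    """Weighted dosage sum per individual over the given variant set.

    ``missing_policy``: ``"mean"`` imputes each variant's mean dosage into
    its missing entries; ``"omit"`` drops missing terms and rescales each
    individual's score by total |weight| over observed |weight|.
    """
    if missing_policy not in ("mean", "omit"):
        raise ValueError("missing_policy must be 'mean' or 'omit'")
    w = pd.Series(weights, dtype=float)
    if ids is None:
        ids = list(w.index)
    ids = list(ids)
    if not ids:
        return np.zeros(panel.n_samples)
    missing_ids = [i for i in ids if i not in w.index]
    if missing_ids:
        raise KeyError(f"no weight for variant(s): {missing_ids[:5]}")
    sub = panel.subset_variants(ids)  # raises on ids absent from the panel
    wv = w.loc[ids].to_numpy()
    d = sub.dosages
    nan = np.isnan(d)
    if not nan.any():
        return d @ wv
    if missing_policy == "mean":
        col_means = np.nanmean(np.where(nan, np.nan, d), axis=0)
        col_means = np.nan_to_num(col_means)
        filled = np.where(nan, col_means[None, :], d)
        return filled @ wv
    filled = np.where(nan, 0.0, d)
    raw = filled @ wv
    total = np.abs(wv).sum()
    seen = (~nan) @ np.abs(wv)
    scale = np.where(seen > 0, total / np.where(seen > 0, seen, 1.0), 0.0)
    return raw * scale


def prs_profile(panel: DosagePanel, harmonized: pd.DataFrame,
                grid: ThresholdGrid | Sequence[float] = DEFAULT_GRID,
                missing_policy: str = "mean",
                standardized: bool = False) -> PrsProfile:
    """Score every individual at every cutoff of the grid.

    Raw sums are the default; ``standardized=True`` z-scores each cutoff
    column for reporting.
    """
    grid = grid if isinstance(grid, ThresholdGrid) else ThresholdGrid(tuple(grid))
    usable = harmonized[harmonized["aligned_weight"].notna()]
    usable = usable[usable["variant_id"].isin(set(panel.variant_ids))]
    weights = usable.set_index("variant_id")["aligned_weight"]
    sets = threshold_select(usable, grid)
    cols, counts = [], []
    for cutoff in grid:
        ids = sets[cutoff]
        counts.append(len(ids))
        cols.append(score(panel, weights, ids, missing_policy))
    profile = PrsProfile(list(panel.samples), tuple(grid),
                         np.column_stack(cols), np.array(counts, dtype=int))
    return profile.standardize() if standardized else profile
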