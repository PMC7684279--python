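"""Sliding-window LD pruning on dosage data.

The statistic is the squared Pearson correlation of (mean-imputed)
dosages — the standard pruning statistic on imputed data, where
haplotype-phase r² is not available. Within each window of
``window_snps`` consecutive variants the algorithm repeatedly takes the
currently worst pair (largest r² above the threshold) and removes its
lower-priority member (the larger discovery p-value; ties go to the
later position), then slides the window by ``step_snps``. Windows never
span chromosomes. A final verification sweep repeats full passes until
no window contains a violating pair, so the documented post-condition
holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DosagePanel

__all__ = ["PruneConfig", "dosage_r2", "prune_window", "prune_report"]


@dataclass(frozen=True)
class PruneConfig:
    """Pruning parameters: r² ceiling 0.25 in 200-SNP windows stepping 50."""

    r2_max: float = 0.25
    window_snps: int = 200
    step_snps: int = 50
    priority: str = "p-value"  # or "order"

    def __post_init__(self):
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must be in (0, 1]")
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 1 <= self.step_snps <= self.window_snps:
            raise ValueError("step_snps must be in [1, window_snps]")
        if self.priority not in ("p-value", "order"):
            raise ValueError("priority must be 'p-value' or 'order'")


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairwise-complete over non-missing entries; 0 by convention when
    either vector has no variance. Fewer than two complete pairs is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete pairs")
    x, y = x[ok], y[ok]
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0 or sy <= 0:
        return 0.0
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return min(1.0, r * r)


def _impute_columns(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant."""
    if not np.isnan(d).any():
        return np.asarray(d, dtype=float)
    d = np.array(d, dtype=float, copy=True)
    means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    means = np.nan_to_num(means)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise r² of the columns of ``d``; zero-variance columns give 0."""
    x = d - d.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", x, x))
    safe = np.where(norms > 0, norms, 1.0)
    xn = x / safe
    r = xn.T @ xn
    r[norms == 0, :] = 0.0
    r[:, norms == 0] = 0.0
    np.fill_diagonal(r, 0.0)
    return np.clip(r * r, 0.0, 1.0)


def _prune_chrom(dosages: np.ndarray, priorities: np.ndarray,
                 config: PruneConfig) -> np.ndarray:
    """Return a boolean keep-mask over the variants of one chromosome."""
    m = dosages.shape[1]
    keep = np.ones(m, dtype=bool)
    w, step = config.window_snps, config.step_snps

    def drop_worst_pairs(window_idx: np.ndarray) -> bool:
        """One exhaustive removal loop on the kept variants of a window."""
        changed = False
        while True:
            live = window_idx[keep[window_idx]]
            if live.size < 2:
                return changed
            r2 = _r2_matrix(dosages[:, live])
            iu = np.triu_indices(live.size, k=1)
            vals = r2[iu]
            worst = np.argmax(vals)
            if vals[worst] <= config.r2_max:
                return changed
            i, j = live[iu[0][worst]], live[iu[1][worst]]
            # remove the lower-priority member: larger p-value, tie -> later
            if (priorities[i], i) >= (priorities[j], j):
                keep[i] = False
            else:
                keep[j] = False
            changed = True

    starts = list(range(0, max(m - w, 0) + 1, step)) or [0]
    if starts[-1] + w < m:
        starts.append(m - w)
    # repeat full passes until stable so the post-condition holds globally
    for _pass in range(m + 1):
        any_change = False
        for s in starts:
            any_change |= drop_worst_pairs(np.arange(s, min(s + w, m)))
        if not any_change:
            break
    return keep


def prune_window(panel: DosagePanel, config: PruneConfig | None = None,
                 priorities: pd.Series | np.ndarray | None = None) -> list:
    """Greedy sliding-window pruning; returns the kept variant ids.

    ``priorities`` maps variant id (or position in the panel) to the
    discovery p-value used to decide which member of a correlated pair to
    drop; required when ``config.priority == "p-value"``. The panel must
    be sorted by (chromosome, position).
    """
    config = config or PruneConfig()
    meta = panel.variants
    chrom = meta["chromosome"].astype(str).to_numpy()
    pos = meta["position"].to_numpy()
    for c in pd.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            raise ValueError(f"panel is not position-sorted on chromosome {c}")
    # chromosomes must be contiguous
    first_seen = pd.Series(range(len(chrom)), index=chrom).groupby(level=0).min()
    order = first_seen.sort_values().index.to_numpy()
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
    if len(boundaries) != len(order):
        raise ValueError("chromosome blocks are not contiguous; sort the panel")

    m = panel.n_variants
    if config.priority == "p-value":
        if priorities is None:
            raise ValueError("priorities required for p-value priority")
        if isinstance(priorities, pd.Series):
            prio = priorities.reindex(meta["variant_id"]).to_numpy(dtype=float)
        else:
            prio = np.asarray(priorities, dtype=float)
        prio = np.where(np.isfinite(prio), prio, 1.0)
    else:
        prio = np.zeros(m)  # pure order: ties always drop the later variant

    dos = _impute_columns(panel.dosages)
    keep = np.ones(m, dtype=bool)
    for c in order:
        sel = np.where(chrom == c)[0]
        keep[sel] = _prune_chrom(dos[:, sel], prio[sel], config)
    return [meta["variant_id"].iat[i] for i in range(m) if keep[i]]


def prune_report(panel: DosagePanel, kept_ids: Sequence[str]) -> pd.DataFrame:
    """Per-chromosome before/after counts."""
    meta = panel.variants
    kept = meta["variant_id"].isin(set(kept_ids))
    out = (meta.assign(kept=kept)
               .groupby("chromosome", sort=False)
               .agg(n_before=("variant_id", "size"), n_after=("kept", "sum"))
               .reset_index())
    out["n_after"] = out["n_after"].astype(int)
    return out
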