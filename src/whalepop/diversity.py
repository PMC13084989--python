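"""Windowed diversity statistics and Tajima's D.

Per-site nucleotide diversity uses the unbiased pairwise estimator
pi_j = 2 d_j (k_j - d_j) / (k_j (k_j - 1)) over the k_j called haplotypes
with derived/alt count d_j; window pi and Watterson's theta are normalized
by the full window length (10 kb by default), and observed heterozygosity is
averaged over variant sites only.  Genome-wide values are unweighted means
over windows with data; windows without variants are flagged undefined for
H_obs rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeDataset

__all__ = ["WindowStats", "window_stats", "genome_wide_means", "tajimas_d",
           "site_pi"]


@dataclass
class WindowStats:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    n_variant_sites: int
    s: int  # segregating sites
    pi: float  # per bp
    theta_w: float  # per bp
    h_obs: float  # mean per-variant-site heterozygote fraction; NaN if none
    k_modal: int  # modal called-haplotype count


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else np.nan


def site_pi(alt_count: np.ndarray, called_haps: np.ndarray) -> np.ndarray:
    """Per-site pi: mean pairwise difference among called haplotypes."""
    k = called_haps.astype(float)
    d = alt_count.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * d * (k - d) / (k * (k - 1.0))
    pi[k < 2] = np.nan
    return pi


def window_stats(dataset: GenotypeDataset,
                 window_size: int = 10_000) -> list[WindowStats]:
    """Non-overlapping window statistics across every scaffold."""
    h = dataset.haplotypes
    called = (h >= 0).sum(axis=1)
    alt = np.where(h > 0, 1, 0).sum(axis=1)
    seg = (alt > 0) & (alt < called)
    het = dataset.is_het()
    g = dataset.genotypes()
    called_dip = (g >= 0).sum(axis=1)
    n_het = het.sum(axis=1)

    out = []
    for sci, (sc, L) in enumerate(zip(dataset.scaffold_ids,
                                      dataset.scaffold_lengths)):
        idxs = np.where(dataset.site_scaffold == sci)[0]
        pos0 = dataset.positions[idxs] - 1
        for start in range(0, int(L), window_size):
            end = min(start + window_size, int(L))
            lo = np.searchsorted(pos0, start)
            hi = np.searchsorted(pos0, end)
            w = idxs[lo:hi]
            nv = int(len(w))
            if nv == 0:
                out.append(WindowStats(sc, start, end, 0, 0, 0.0, 0.0,
                                       np.nan, 0))
                continue
            s_count = int(seg[w].sum())
            pis = site_pi(alt[w], called[w])
            pi = float(np.nansum(pis)) / window_size
            ks = called[w]
            k_modal = int(np.bincount(ks).argmax())
            a = _harmonic(k_modal)
            theta = (s_count / (a * window_size)
                     if np.isfinite(a) and a > 0 else 0.0)
            with np.errstate(invalid="ignore"):
                hfrac = np.where(called_dip[w] > 0,
                                 n_het[w] / called_dip[w], np.nan)
            h_obs = float(np.nanmean(hfrac)) if np.isfinite(hfrac).any() else np.nan
            out.append(WindowStats(sc, start, end, nv, s_count, pi, theta,
                                   h_obs, k_modal))
    return out


def genome_wide_means(windows: list[WindowStats]) -> dict[str, float]:
    """Unweighted means over windows with data; undefined windows excluded."""
    df = pd.DataFrame([w.__dict__ for w in windows])
    has_var = df["n_variant_sites"] > 0
    return {
        "pi": float(df["pi"].mean()),
        "theta_w": float(df["theta_w"].mean()),
        "h_obs": float(df.loc[has_var, "h_obs"].mean()) if has_var.any()
        else np.nan,
        "n_windows": int(len(df)),
        "n_windows_with_variants": int(has_var.sum()),
    }


def windows_frame(windows: list[WindowStats]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])


def tajimas_d(dataset: GenotypeDataset,
              sites_mask: np.ndarray | None = None) -> float:
    """Tajima's D over a region; sites with any missing call are dropped.

    Returns NaN (flagged undefined) when no segregating site survives.
    """
    h = dataset.haplotypes
    if sites_mask is not None:
        h = h[sites_mask]
    complete = (h >= 0).all(axis=1)
    h = h[complete]
    if h.size == 0:
        return np.nan
    n = h.shape[1]
    alt = (h > 0).sum(axis=1)
    seg = (alt > 0) & (alt < n)
    s = int(seg.sum())
    if s == 0 or n < 3:
        return np.nan
    d = alt[seg].astype(float)
    pi_total = float(np.sum(2.0 * d * (n - d) / (n * (n - 1.0))))

    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    if var <= 0:
        return np.nan
    return float((pi_total - s / a1) / np.sqrt(var))
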