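"""Population-structure tools: LD decay and pruning, WC F_ST, PCA.

r-squared is the squared Pearson correlation of unphased genotype dosages
(composite LD), which is what the usual pruning tools compute; the
Weir & Cockerham (1984) estimator uses the full three-level variance
decomposition (among populations / among individuals / within individuals)
with unequal sample sizes, and the "weighted" genome-wide value is
sum(a) / sum(a + b + c) across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDResult", "ld_decay_and_prune", "weighted_fst", "pca"]


@dataclass
class LDResult:
    pairs: pd.DataFrame  # distance_bp, r2
    decay: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs


def _dosage_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    ok = (gi >= 0) & (gj >= 0)
    if ok.sum() < 2:
        return np.nan
    x, y = gi[ok].astype(float), gj[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return np.nan  # monomorphic in the called subset: undefined
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay_and_prune(genotypes: np.ndarray, positions: np.ndarray,
                       scaffolds: np.ndarray | None = None,
                       r2_threshold: float = 0.2,
                       window_snps: int = 50, step_snps: int = 5,
                       max_pair_distance: int = 500_000,
                       n_bins: int = 25):
    """LD decay curve and PLINK-style window pruning.

    Returns ``(LDResult, retained site indices)``.  Pruning slides a window
    of ``window_snps`` advancing by ``step_snps``; for any within-window pair
    with r2 above the threshold the site with the lower minor-allele
    frequency is dropped (tie: the later position).
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions)
    n_sites = g.shape[0]
    if scaffolds is None:
        scaffolds = np.zeros(n_sites, dtype=int)

    # minor-allele frequencies
    called = g >= 0
    with np.errstate(invalid="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / (2.0 * called.sum(axis=1))
    maf = np.minimum(p, 1 - p)

    keep = np.ones(n_sites, dtype=bool)
    pair_rows = []
    for sc in np.unique(scaffolds):
        idx = np.where(scaffolds == sc)[0]
        m = len(idx)
        start = 0
        while start < m:
            win = idx[start:start + window_snps]
            for a in range(len(win)):
                ia = win[a]
                if not keep[ia]:
                    continue
                for b in range(a + 1, len(win)):
                    ib = win[b]
                    if not keep[ib]:
                        continue
                    d = int(abs(pos[ib] - pos[ia]))
                    if d > max_pair_distance:
                        continue
                    r2 = _dosage_r2(g[ia], g[ib])
                    if np.isnan(r2):
                        continue
                    pair_rows.append((d, r2))
                    if r2 > r2_threshold:
                        if maf[ia] < maf[ib] or (maf[ia] == maf[ib]
                                                 and pos[ia] > pos[ib]):
                            keep[ia] = False
                            break  # site ia gone; stop pairing it
                        keep[ib] = False
            if start + window_snps >= m:
                break
            start += step_snps

    pairs = pd.DataFrame(pair_rows, columns=["distance_bp", "r2"])
    if len(pairs):
        edges = np.linspace(0, max_pair_distance, n_bins + 1)
        which = np.clip(np.digitize(pairs["distance_bp"], edges) - 1,
                        0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            sel = pairs["r2"][which == b]
            rows.append((edges[b], edges[b + 1],
                         float(sel.mean()) if len(sel) else np.nan, len(sel)))
        decay = pd.DataFrame(rows, columns=["bin_start", "bin_end",
                                            "mean_r2", "n_pairs"])
    else:
        decay = pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2",
                                      "n_pairs"])
    return LDResult(pairs=pairs, decay=decay), np.where(keep)[0]


def weighted_fst(genotypes: np.ndarray, labels) -> tuple[float, pd.DataFrame]:
    """Weir-Cockerham weighted F_ST over sites with defined denominators.

    ``genotypes``: (sites, samples) dosages with -1 missing; ``labels``: one
    population label per sample (exactly two populations).  Returns the
    weighted estimate and the per-site a/b/c components.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) != 2:
        raise ValueError("weighted_fst requires exactly two populations")
    g = np.asarray(genotypes, dtype=float)
    masks = [labels == p for p in pops]
    r = 2

    comps = []
    for s in range(g.shape[0]):
        ns, ps, hs = [], [], []
        for m in masks:
            gs = g[s, m]
            gs = gs[gs >= 0]
            ns.append(len(gs))
            if len(gs):
                ps.append(gs.sum() / (2.0 * len(gs)))
                hs.append(np.mean(gs == 1))
            else:
                ps.append(np.nan)
                hs.append(np.nan)
        ns = np.array(ns, dtype=float)
        if np.any(ns < 2):
            comps.append((np.nan, np.nan, np.nan))
            continue
        ps, hs = np.array(ps), np.array(hs)
        nbar = ns.mean()
        nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns * ps).sum() / (r * nbar)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        comps.append((a, b, c))

    comp = pd.DataFrame(comps, columns=["a", "b", "c"])
    denom = comp.sum(axis=1)
    use = np.isfinite(denom) & (denom != 0)
    if not use.any():
        raise ValueError("no site with a defined F_ST denominator")
    est = float(comp.loc[use, "a"].sum() / denom[use].sum())
    return est, comp


def pca(genotypes: np.ndarray, n_components: int = 10):
    """PCA of a dosage matrix with Patterson scaling.

    Missing dosages are imputed to the site mean; each site is centered and
    divided by sqrt(p(1-p)).  Returns (coordinates (samples x PCs),
    explained-variance fractions).  Sign convention: the largest-magnitude
    coordinate of each PC is positive.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    poly = np.nanmax(g, axis=1) != np.nanmin(g, axis=1)
    if not poly.any():
        raise ValueError("PCA requires at least one polymorphic site")
    g = g[poly]
    mean = np.nanmean(g, axis=1, keepdims=True)
    g = np.where(np.isnan(g), mean, g)
    p = mean.ravel() / 2.0
    scale = np.sqrt(p * (1 - p))
    x = (g - mean) / scale[:, None]

    n = x.shape[1]
    cov = (x.T @ x) / x.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    k = min(n_components, n)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for c in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, c]))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
    frac = vals[:k] / vals.sum() if vals.sum() > 0 else np.zeros(k)
    return coords, frac
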