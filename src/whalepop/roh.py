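"""Runs of homozygosity: detection, F_ROH summaries and TMRCA dating.

Three detectors over one sample's ordered biallelic sites on one scaffold:

* ``hmm``        -- two-state (ROH / non-ROH) Viterbi decoding.  Inside an
  ROH a heterozygote is seen only through genotyping error, with a fixed
  phred-30 rate epsilon = 1e-3; outside, the heterozygote probability is the
  Hardy-Weinberg expectation 2p(1-p) from sample allele frequencies.  The
  per-bp state-switch rate tau (default 5e-8) makes the transition
  probability between adjacent sites 1 - exp(-d * tau).
* ``strict_hmm`` -- the same model with epsilon = 0, so any confident
  heterozygote terminates a run (maximal homozygous stretches).
* ``rule``       -- maximal segments containing at most ``max_het_mismatches``
  heterozygous calls (default 2), reported as the longest non-overlapping
  set, greedy by length.

All methods report segments of at least ``min_length_bp`` (10 kb).

A run of genetic length l cM has its most recent common ancestor about
50 / l generations ago, i.e. T_gen = 50 / (L_Mb * r_cM/Mb) for physical
length L at a constant map rate r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeDataset

__all__ = ["ROHSegment", "FrohSummary", "detect_roh", "detect_roh_dataset",
           "froh", "roh_age"]

DEFAULT_EPSILON = 1e-3  # phred-30 genotyping error inside a run
DEFAULT_TAU = 5e-8  # per-bp state-switch rate
_LOG0 = -1e30


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    method: str
    n_het_mismatches: int
    score: float  # Viterbi log-odds for HMM methods, NaN for rule

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def roh_age(length_bp: float, rec_rate_cM_per_Mb: float = 1.0,
            generation_time_years: float = 32.0) -> tuple[float, float]:
    """TMRCA of a run of homozygosity: T_gen = 50 / (L_Mb * r).

    Returns unrounded (generations, years); only the product of length and
    map rate matters.
    """
    if length_bp <= 0 or rec_rate_cM_per_Mb <= 0 or generation_time_years <= 0:
        raise ValueError("length, recombination rate and generation time "
                         "must be positive")
    generations = 50.0 / (length_bp / 1e6 * rec_rate_cM_per_Mb)
    return generations, generations * generation_time_years


def _viterbi(het: np.ndarray, pos: np.ndarray, p_het_pop: np.ndarray,
             epsilon: float, tau: float):
    """Two-state Viterbi; state 1 = ROH.  Returns (path, log-odds score)."""
    m = len(het)
    log_e = np.empty((m, 2))
    with np.errstate(divide="ignore"):
        e_roh_het = np.log(epsilon) if epsilon > 0 else _LOG0
        e_roh_hom = np.log1p(-epsilon)
        p = np.clip(p_het_pop, 1e-12, 1 - 1e-12)
        log_e[:, 0] = np.where(het, np.log(p), np.log1p(-p))
        log_e[:, 1] = np.where(het, e_roh_het, e_roh_hom)

    import math

    log_stay = np.log1p(np.clip(np.expm1(-np.diff(pos).astype(float) * tau),
                                -0.5, None))  # log(1 - t), t capped at 0.5
    log_switch = np.log(np.clip(-np.expm1(-np.diff(pos).astype(float) * tau),
                                1e-300, 0.5))
    e0, e1 = log_e[:, 0], log_e[:, 1]
    d0 = math.log(0.5) + e0[0]
    d1 = math.log(0.5) + e1[0]
    back = np.zeros((m, 2), dtype=np.int8)
    for s in range(1, m):
        st, sw = log_stay[s - 1], log_switch[s - 1]
        a00, a10 = d0 + st, d1 + sw
        a01, a11 = d0 + sw, d1 + st
        if a00 >= a10:
            back[s, 0] = 0
            n0 = a00 + e0[s]
        else:
            back[s, 0] = 1
            n0 = a10 + e0[s]
        if a11 >= a01:
            back[s, 1] = 1
            n1 = a11 + e1[s]
        else:
            back[s, 1] = 0
            n1 = a01 + e1[s]
        d0, d1 = n0, n1
    path = np.empty(m, dtype=np.int8)
    path[-1] = 0 if d0 >= d1 else 1
    for s in range(m - 1, 0, -1):
        path[s - 1] = back[s, path[s]]
    return path, float(d1 - d0)


def _runs(mask: np.ndarray):
    """(start_idx, end_idx_inclusive) of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask) - 1]
    return list(zip(starts, ends))


def detect_roh(genotypes: np.ndarray, positions: np.ndarray,
               p_alt: np.ndarray, method: str = "hmm",
               min_length_bp: int = 10_000,
               epsilon: float = DEFAULT_EPSILON, tau: float = DEFAULT_TAU,
               max_het_mismatches: int = 2,
               sample: str = "", scaffold: str = "") -> list[ROHSegment]:
    """Detect ROH for one sample on one scaffold.

    ``genotypes``: dosages 0/1/2 (-1 missing) at sorted ``positions``
    (1-based); ``p_alt``: per-site sample alt-allele frequency used for the
    non-ROH heterozygote emission.  Missing calls are skipped.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    g = np.asarray(genotypes)
    called = g >= 0
    g, pos = g[called], pos[called]
    p = np.asarray(p_alt, dtype=float)[called]
    if len(g) == 0:
        return []
    het = g == 1
    p_het_pop = 2.0 * p * (1.0 - p)

    segs: list[tuple[int, int, int, float]] = []  # start, end, n_het, score
    if method in ("hmm", "strict_hmm"):
        eps = 0.0 if method == "strict_hmm" else epsilon
        path, score = _viterbi(het, pos, p_het_pop, eps, tau)
        for i0, i1 in _runs(path == 1):
            segs.append((int(pos[i0]) - 1, int(pos[i1]),
                         int(het[i0:i1 + 1].sum()), score))
    elif method == "rule":
        segs = _rule_segments(het, pos, max_het_mismatches)
    else:
        raise ValueError(f"unknown ROH method: {method}")

    out = [ROHSegment(sample=sample, scaffold=scaffold, start=s, end=e,
                      method=method, n_het_mismatches=nh, score=sc)
           for s, e, nh, sc in segs if e - s >= min_length_bp]
    return out


def _rule_segments(het, pos, max_mismatches):
    """Maximal segments with <= max_mismatches hets; longest non-overlapping."""
    m = len(pos)
    het_idx = np.where(het)[0]
    candidates = []
    # candidate windows bounded by the (max_mismatches+1)-th het on each side
    n_het_total = len(het_idx)
    bounds = np.concatenate([[-1], het_idx, [m]])
    k = max_mismatches
    for a in range(n_het_total + 1):
        close = min(a + k + 1, n_het_total + 1)
        lo = bounds[a] + 1  # first site after the previous het
        hi = bounds[close] - 1  # last site before the closing het
        if hi < lo:
            continue
        n_het = int(het[lo:hi + 1].sum())
        candidates.append((int(pos[lo]) - 1, int(pos[hi]), n_het))
    # greedy longest non-overlapping
    candidates.sort(key=lambda c: c[1] - c[0], reverse=True)
    chosen: list[tuple[int, int, int, float]] = []
    for s, e, nh in candidates:
        if all(e <= cs or s >= ce for cs, ce, _, _ in chosen):
            chosen.append((s, e, nh, np.nan))
    chosen.sort()
    return chosen


def detect_roh_dataset(dataset: GenotypeDataset, method: str = "hmm",
                       **kwargs) -> list[ROHSegment]:
    """Run detect_roh for every sample on every scaffold of a dataset."""
    g = dataset.genotypes()
    called = (g >= 0)
    with np.errstate(invalid="ignore"):
        p_alt = np.where(called, g, 0).sum(axis=1) / (2.0 * called.sum(axis=1))
    p_alt = np.nan_to_num(p_alt)
    segs = []
    for sci, sc in enumerate(dataset.scaffold_ids):
        sel = dataset.site_scaffold == sci
        if not sel.any():
            continue
        pos = dataset.positions[sel]
        for i, name in enumerate(dataset.sample_ids):
            segs.extend(detect_roh(g[sel, i], pos, p_alt[sel], method=method,
                                   sample=name, scaffold=sc, **kwargs))
    return segs


@dataclass
class FrohSummary:
    sample: str
    autosomal_length_bp: int
    per_class: dict[str, float]  # class label -> F_ROH
    counts: dict[str, int]
    total_froh: float


DEFAULT_CLASSES = ((0.01e6, 0.1e6), (0.1e6, 1e6), (1e6, np.inf))


def _merge(segments):
    """Union of possibly overlapping segments (per sample+scaffold)."""
    merged = []
    for seg in sorted(segments, key=lambda s: (s.scaffold, s.start)):
        if merged and merged[-1][0] == seg.scaffold \
                and seg.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], seg.end)
        else:
            merged.append([seg.scaffold, seg.start, seg.end])
    return [(sc, s, e) for sc, s, e in merged]


def froh(segments: list[ROHSegment], autosomal_length_bp: int,
         class_bounds=DEFAULT_CLASSES) -> list[FrohSummary]:
    """F_ROH per sample and length class; overlapping calls merged by union."""
    if autosomal_length_bp <= 0:
        raise ValueError("autosomal_length_bp must be > 0")
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    out = []
    for sample, segs in sorted(by_sample.items()):
        merged = _merge(segs)
        lengths = np.array([e - s for _, s, e in merged], dtype=float)
        per_class, counts = {}, {}
        for lo, hi in class_bounds:
            label = (f"[{lo / 1e6:g},{'inf' if np.isinf(hi) else f'{hi / 1e6:g}'})Mb")
            sel = (lengths >= lo) & (lengths < hi)
            per_class[label] = float(lengths[sel].sum()) / autosomal_length_bp
            counts[label] = int(sel.sum())
        out.append(FrohSummary(sample=sample,
                               autosomal_length_bp=autosomal_length_bp,
                               per_class=per_class, counts=counts,
                               total_froh=float(lengths.sum())
                               / autosomal_length_bp))
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.scaffold, s.start, s.end, s.length_bp, s.method,
          s.n_het_mismatches, s.score) for s in segments],
        columns=["sample", "scaffold", "start", "end", "length_bp",
                 "method", "n_het", "score"])
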