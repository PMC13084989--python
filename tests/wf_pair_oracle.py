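"""Backward discrete-generation Wright-Fisher IBD oracle for one pair.

Tracks the ancestral material of two sampled haplotypes through a
random-mating Wright-Fisher population of N diploids: every generation each
carrier chromosome is the product of one meiosis (uniform parent individual,
Poisson crossovers along the genetic map, fair starting phase).  Wherever
material from the two sampled haplotypes lands on the same parent
chromosome, that overlap has coalesced; the overlap interval is recorded
with its age and removed from further tracking.  This realizes, at the
population-process level, exactly the assumptions behind the 2g-per-Morgan
exponential segment model -- so it is the independent end-to-end check of
that approximation, including back-coalescence and edge effects the model
ignores.
"""

import numpy as np

__all__ = ["wf_pair_ibd_segments"]


def wf_pair_ibd_segments(n_diploid: int, length_morgans: float, g_max: int,
                         rng) -> list[tuple[float, int]]:
    """Simulate one haplotype pair; returns [(segment length M, age), ...]."""
    L = float(length_morgans)
    seg_s = np.array([0.0, 0.0])
    seg_e = np.array([L, L])
    carrier = np.array([0, 2], dtype=np.int64)  # two distinct individuals
    origin = np.array([0, 1], dtype=np.int8)
    out: list[tuple[float, int]] = []

    for g in range(1, g_max + 1):
        if len(seg_s) == 0:
            break
        u, inv = np.unique(carrier, return_inverse=True)
        k = len(u)
        parent = rng.integers(n_diploid, size=k)
        phase0 = rng.integers(2, size=k)
        ncross = rng.poisson(L, size=k)
        cpos = rng.uniform(0.0, L, size=int(ncross.sum()))
        cown = np.repeat(np.arange(k), ncross)
        order = np.lexsort((cpos, cown))
        cpos, cown = cpos[order], cown[order]
        offs = np.searchsorted(cown, np.arange(k + 1))
        keys = cown * (L + 1.0) + cpos
        i0 = np.searchsorted(keys, inv * (L + 1.0) + seg_s)
        i1 = np.searchsorted(keys, inv * (L + 1.0) + seg_e)
        parity0 = (phase0[inv] + (i0 - offs[inv])) % 2

        reps = (i1 - i0) + 1
        total = int(reps.sum())
        seg_idx = np.repeat(np.arange(len(seg_s)), reps)
        group_start = np.repeat(np.cumsum(reps) - reps, reps)
        within = np.arange(total) - group_start
        cross_idx = i0[seg_idx] + within
        starts = np.where(within == 0, seg_s[seg_idx],
                          cpos[np.minimum(cross_idx - 1, len(cpos) - 1)]
                          if len(cpos) else seg_s[seg_idx])
        last = within == (reps[seg_idx] - 1)
        ends = np.where(last, seg_e[seg_idx],
                        cpos[np.minimum(cross_idx, max(len(cpos) - 1, 0))]
                        if len(cpos) else seg_e[seg_idx])
        par = (parity0[seg_idx] + within) % 2
        new_carrier = 2 * parent[inv][seg_idx] + par
        new_origin = origin[seg_idx]
        keep = ends > starts
        seg_s, seg_e = starts[keep], ends[keep]
        carrier, origin = new_carrier[keep], new_origin[keep]

        # coalescence: carriers holding material of both origins
        u2, inv2 = np.unique(carrier, return_inverse=True)
        has0 = np.zeros(len(u2), dtype=bool)
        has1 = np.zeros(len(u2), dtype=bool)
        has0[inv2[origin == 0]] = True
        has1[inv2[origin == 1]] = True
        hot = np.where(has0 & has1)[0]
        if len(hot):
            drop = np.zeros(len(seg_s), dtype=bool)
            add_s, add_e, add_c, add_o = [], [], [], []
            for group in hot:
                idx = np.where(inv2 == group)[0]
                ivs0 = _union([(seg_s[i], seg_e[i]) for i in idx
                               if origin[i] == 0])
                ivs1 = _union([(seg_s[i], seg_e[i]) for i in idx
                               if origin[i] == 1])
                coal = _intersect(ivs0, ivs1)
                if not coal:
                    continue
                for lo, hi in coal:
                    out.append((hi - lo, g))
                for i in idx:
                    remainder = _subtract([(seg_s[i], seg_e[i])], coal)
                    if remainder == [(seg_s[i], seg_e[i])]:
                        continue
                    drop[i] = True
                    for lo, hi in remainder:
                        add_s.append(lo)
                        add_e.append(hi)
                        add_c.append(carrier[i])
                        add_o.append(origin[i])
            if drop.any() or add_s:
                seg_s = np.concatenate([seg_s[~drop], add_s])
                seg_e = np.concatenate([seg_e[~drop], add_e])
                carrier = np.concatenate([carrier[~drop],
                                          add_c]).astype(np.int64)
                origin = np.concatenate([origin[~drop],
                                         add_o]).astype(np.int8)
    return out


def _union(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a, b):
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(ivs, cuts):
    out = []
    for s, e in ivs:
        cur = s
        for cs, ce in cuts:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
        if cur < e:
            out.append((cur, e))
    return out
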