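"""KING-robust pairwise kinship and relative exclusion.

The within/between-family robust estimator is

    phi_hat = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

over sites called in both samples: N_Aa,Aa counts double heterozygotes,
N_AA,aa opposite homozygotes, and N_Aa(i) the heterozygous sites of sample i.
First-degree relatives sit near phi = 0.25; the conventional exclusion cutoff
0.177 is the geometric midpoint 2^(-5/2) between first- and second-degree
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["KinshipResult", "king_kinship", "kinship_table",
           "exclude_relatives", "FIRST_DEGREE_THRESHOLD"]

FIRST_DEGREE_THRESHOLD = 0.177


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[int, int]
    phi: float  # NaN when undefined
    n_het_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int
    n_shared_sites: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.phi)


def king_kinship(genotypes: np.ndarray, pair: tuple[int, int]) -> KinshipResult:
    """KING-robust kinship for one sample pair.

    ``genotypes`` is a (sites, samples) dosage matrix with values 0/1/2 and
    -1 for missing.  A zero denominator or no shared called sites yields a
    flagged NaN result rather than an error.
    """
    i, j = pair
    gi, gj = genotypes[:, i], genotypes[:, j]
    shared = (gi >= 0) & (gj >= 0)
    gi, gj = gi[shared], gj[shared]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    n_i, n_j = int(het_i.sum()), int(het_j.sum())
    denom = n_i + n_j
    phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else np.nan
    return KinshipResult(pair=(i, j), phi=phi, n_het_het=n_hh,
                         n_opposite_hom=n_opp, n_het_i=n_i, n_het_j=n_j,
                         n_shared_sites=int(shared.sum()))


def kinship_table(genotypes: np.ndarray,
                  sample_ids: list[str] | None = None) -> pd.DataFrame:
    """All pairwise KING-robust estimates as a tidy table."""
    n = genotypes.shape[1]
    ids = sample_ids or [str(i) for i in range(n)]
    rows = []
    for i, j in combinations(range(n), 2):
        r = king_kinship(genotypes, (i, j))
        rows.append((ids[i], ids[j], r.phi, r.n_het_het, r.n_opposite_hom,
                     r.n_het_i, r.n_het_j, r.n_shared_sites))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi",
                                       "n_het_het", "n_opposite_hom",
                                       "n_het_i", "n_het_j", "n_shared"])


def exclude_relatives(phi_table: pd.DataFrame,
                      threshold: float = FIRST_DEGREE_THRESHOLD,
                      call_rates: dict[str, float] | None = None
                      ) -> tuple[list[str], list[str]]:
    """Greedy removal until no pair exceeds the kinship threshold.

    At each step the individual in the most over-threshold pairs is removed;
    ties break toward the lower call rate, then the lexicographically larger
    ID.  Returns (retained ids, removal log in order).
    """
    samples = sorted(set(phi_table["sample_i"]) | set(phi_table["sample_j"]))
    edges = {(r.sample_i, r.sample_j)
             for r in phi_table.itertuples()
             if np.isfinite(r.phi) and r.phi > threshold}
    removed: list[str] = []
    active = set(samples)
    while True:
        live = [(a, b) for a, b in edges if a in active and b in active]
        if not live:
            break
        deg: dict[str, int] = {}
        for a, b in live:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1

        def sort_key(s):
            cr = call_rates.get(s, 1.0) if call_rates else 1.0
            # most edges first, then lowest call rate, then smallest ID
            return (-deg[s], cr, s)

        victim = sorted(deg, key=sort_key)[0]
        removed.append(victim)
        active.discard(victim)
    return [s for s in samples if s in active], removed
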