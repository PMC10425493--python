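"""Over-representation analysis of a significant-gene list against gene sets.

One hypergeometric upper-tail test per set: k genes of the input list fall in
a set of m background-restricted members, with an input list of n unique genes
drawn from a background of N panel genes.  Sets reaching the minimum overlap
(default 5) form the tested family; their p values are FDR-corrected by
Benjamini-Hochberg into q values.  A set is significant when k >= 5, p < 0.01
and q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deg import adjust_bh
from .io import GeneSetCollection

MIN_OVERLAP = 5
P_THRESHOLD = 0.01
Q_THRESHOLD = 0.05


def hypergeom_p(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    N: background size; m: set size within the background; n: input-list size;
    k: overlap.  Exact tail summation (survival function), stable down to the
    smallest representable p.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("need m <= N and n <= N")
    if not (0 <= k <= min(m, n)):
        raise ValueError("need 0 <= k <= min(m, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def run_ora(deg_genes, collection: GeneSetCollection, background,
            min_overlap: int = MIN_OVERLAP, p_threshold: float = P_THRESHOLD,
            q_threshold: float = Q_THRESHOLD,
            gate_before_fdr: bool = True) -> pd.DataFrame:
    """Hypergeometric ORA of ``deg_genes`` against every set in ``collection``.

    Gene identity is by symbol: callers pass probe-collapsed unique symbols
    (a gene counts as significant if any of its probes is).  Sets are
    intersected with the background before testing and genes outside the
    background are ignored.  With ``gate_before_fdr`` (default) sets below the
    minimum overlap are excluded from the FDR family and get q = NaN; set it
    False to correct across all sets.  Results are sorted by q then p.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    degs = set(deg_genes) & background
    N = len(background)
    n = len(degs)

    rows = []
    for name, members in collection.items():
        mem = set(members) & background
        m = len(mem)
        k = len(mem & degs)
        p = hypergeom_p(k, m, n, N) if m else 1.0
        rows.append((name, k, m, n, N, p))
    res = pd.DataFrame(rows, columns=["set", "k", "m", "n", "N", "p"]).set_index("set")

    eligible = res["k"] >= min_overlap
    res["q"] = np.nan
    family = eligible if gate_before_fdr else pd.Series(True, index=res.index)
    if family.any():
        res.loc[family, "q"] = adjust_bh(res.loc[family, "p"].to_numpy())
    res["significant"] = (
        (res["k"] >= min_overlap)
        & (res["p"] < p_threshold)
        & (res["q"] < q_threshold)
    ).fillna(False)
    return res.sort_values(["q", "p"], na_position="last")
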