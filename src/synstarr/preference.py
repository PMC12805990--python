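"""Position-specific sequence preferences of variant activity.

Links sequence to activity three ways:

* consensus / frequency matrices over a variant subset (e.g. the
  high-activity class), with IUPAC codes at ties;
* a probability-logo statistic per (window position, nucleotide): one-sided
  rank-sum tests of whether variants carrying that base are more (or less)
  active than all others, summarized as a signed height
  ``sign * -log10(min one-sided p)``;
* grouped comparisons of a flanking triplet against named 3-mers (e.g. GGG
  and GTG downstream of the core).

Rank-sum p-values use exact enumeration of group assignments when the
number of assignments is small and a tie-corrected normal approximation
with continuity correction otherwise, so monotone transformations of the
activities leave every statistic unchanged.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .designs import ALPHABET, LibraryDesign, iupac_code

__all__ = [
    "consensus_matrix",
    "position_stats",
    "motif_group_test",
    "rank_sum_test",
]

P_FLOOR = 1e-300
#: use exact enumeration while C(n, n1) is at most this
EXACT_ENUMERATION_LIMIT = 20_000


def consensus_matrix(windows: Sequence[str],
                     design: LibraryDesign) -> tuple[pd.DataFrame, str]:
    """Per-position nucleotide frequencies and the consensus string.

    ``windows`` are realized 10-bp windows from one library; fixed
    positions therefore come out one-hot.  Ties in the arg-max base are
    reported as IUPAC ambiguity codes.
    """
    if len(windows) == 0:
        raise ValueError("empty variant subset")
    arr = np.array([list(w) for w in windows])
    if arr.shape[1] != 10:
        raise ValueError("windows must be 10-mers")
    freq = pd.DataFrame(
        {base: (arr == base).mean(axis=0) for base in ALPHABET},
        index=pd.RangeIndex(10, name="position"))
    consensus = []
    for _, row in freq.iterrows():
        best = row.max()
        consensus.append(iupac_code([b for b in ALPHABET if row[b] == best]))
    return freq, "".join(consensus)


def _exact_ranksum_p(pooled_ranks: np.ndarray, n1: int,
                     observed: float) -> tuple[float, float]:
    """Exact one-sided p-values for the rank-sum of the first group.

    Enumerates all C(n, n1) assignments of the pooled (mid)ranks, so ties
    are handled exactly.  Returns (p_greater, p_less), each including the
    observed outcome (p = P(stat >= obs) resp. P(stat <= obs)).
    """
    from itertools import combinations

    n = len(pooled_ranks)
    tol = 1e-9
    ge = le = total = 0
    for idx in combinations(range(n), n1):
        stat = pooled_ranks[list(idx)].sum()
        total += 1
        if stat >= observed - tol:
            ge += 1
        if stat <= observed + tol:
            le += 1
    return ge / total, le / total


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum p-values for group ``x`` vs group ``y``.

    Returns ``(p_greater, p_less)``: evidence that x-values are larger,
    resp. smaller, than y-values.  Exact by enumeration for small designs
    (at most ``EXACT_ENUMERATION_LIMIT`` group assignments), otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n = len(x), len(x) + len(y)
    if comb(n, n1) <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        observed = ranks[:n1].sum()
        return _exact_ranksum_p(ranks, n1, observed)
    g = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    l = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
    return float(g.pvalue), float(l.pvalue)


def position_stats(windows: Sequence[str], values: Sequence[float],
                   design: LibraryDesign, statistic: str = "ranksum",
                   p_significant: float = 0.01) -> pd.DataFrame:
    """Probability-logo table: per (position, base) activity association.

    For every degenerate window position and base, the activities of
    variants carrying that base are compared against all other variants in
    both directions.  ``height`` is ``-log10(min p)`` signed positive when
    the "greater" direction wins.  Fixed positions carry no statistic; a
    base absent at a position gives a row of NaNs.

    ``statistic`` is ``"ranksum"`` (default) or ``"t"`` (Welch t-test).
    """
    values = np.asarray(values, dtype=float)
    if len(windows) != len(values):
        raise ValueError("windows and values differ in length")
    if len(windows) < 2:
        raise ValueError("need at least two variants")
    if not np.isfinite(values).all():
        raise ValueError("activities must be finite")
    arr = np.array([list(w) for w in windows])

    rows = []
    for pos in design.degenerate_positions:
        col = arr[:, pos]
        for base in ALPHABET:
            mask = col == base
            n_with = int(mask.sum())
            n_without = len(values) - n_with
            if n_with == 0 or n_without == 0:
                rows.append((pos, base, n_with, n_without,
                             np.nan, np.nan, np.nan, False))
                continue
            if statistic == "ranksum":
                p_g, p_l = rank_sum_test(values[mask], values[~mask])
            elif statistic == "t":
                p_g = stats.ttest_ind(values[mask], values[~mask],
                                      equal_var=False,
                                      alternative="greater").pvalue
                p_l = stats.ttest_ind(values[mask], values[~mask],
                                      equal_var=False,
                                      alternative="less").pvalue
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
            p_min = max(min(p_g, p_l), P_FLOOR)
            sign = 1.0 if p_g <= p_l else -1.0
            height = sign * -np.log10(p_min)
            rows.append((pos, base, n_with, n_without, p_g, p_l, height,
                         p_min < p_significant))
    return pd.DataFrame(rows, columns=[
        "position", "base", "n_with", "n_without",
        "p_greater", "p_less", "height", "significant"])


def motif_group_test(windows: Sequence[str], values: Sequence[float],
                     design: LibraryDesign,
                     motifs: Iterable[str] = ("GGG", "GTG"),
                     region: str = "downstream") -> pd.DataFrame:
    """Compare activity between flank-motif groups and all other variants.

    ``region`` selects the upstream (window positions 0-2) or downstream
    (7-9) flanking triplet relative to the ACGT core.  Each motif group is
    tested against the "other" group (flanks matching none of the motifs)
    with a two-sided rank-sum test; group sizes and medians are reported.
    """
    values = np.asarray(values, dtype=float)
    motifs = list(motifs)
    if region == "downstream":
        lo, hi = max(design.core_positions) + 1, 10
    elif region == "upstream":
        lo, hi = 0, min(design.core_positions)
    else:
        raise ValueError(f"unknown region {region!r}")
    flanks = np.array([w[lo:hi] for w in windows])
    other_mask = ~np.isin(flanks, motifs)
    if not other_mask.any():
        raise ValueError("no variants outside the motif groups")
    other = values[other_mask]

    rows = [("other", int(other_mask.sum()), float(np.median(other)),
             0.0, np.nan)]
    for motif in motifs:
        mask = flanks == motif
        if not mask.any():
            raise ValueError(f"no variant carries motif {motif!r} "
                             f"in the {region} flank")
        group = values[mask]
        p_g, p_l = rank_sum_test(group, other)
        p_two = min(1.0, 2.0 * min(p_g, p_l))
        rows.append((motif, int(mask.sum()), float(np.median(group)),
                     float(np.median(group) - np.median(other)), p_two))
    return pd.DataFrame(rows, columns=[
        "group", "n", "median", "median_diff_vs_other", "p_vs_other"])
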