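"""Focal-individual population enrichment test.

Given the IBD segments a single focal individual (e.g. an ancient genome)
shares with a reference panel, test each population for over-representation
of shared segments.  Under the null hypothesis of no association between
population membership and IBD sharing, the number of focal-shared segments
falling in population i follows Binomial(n_i, p) with p = T/N, where n_i is
the population size, T the total number of focal-shared segments and N the
total number of individuals.  The expected count is n_i * p, so expected
counts sum exactly to T.

P-values are one-sided upper tails (the enrichment direction) and are
adjusted for multiple testing with the two-stage Benjamini-Hochberg (TSBH)
procedure, which is robust under the block-positive dependence this design
induces (finding IBD with one population changes p for the others).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .populations import PopulationTable
from .segments import IBDSegment

__all__ = [
    "TSBHResult",
    "focal_segment_counts",
    "binomial_upper_pvalue",
    "tsbh_adjust",
    "enrichment_report",
]


def focal_segment_counts(
    segments: Sequence[IBDSegment],
    focal_id: str,
    population_table: PopulationTable,
    trials: Literal["segments", "individuals"] = "segments",
) -> tuple[dict[str, int], int, int]:
    """Count focal-shared segments per population.

    Returns ``(observed, T, n_ignored)`` where ``observed`` maps every
    population in the table to its count (zeros included), ``T`` is the
    total and ``n_ignored`` the number of input segments not involving the
    focal individual (excluded with a warning count, not an error).

    ``trials="individuals"`` counts distinct sharing partners instead of
    segments.
    """
    if focal_id not in population_table:
        raise KeyError(f"focal individual {focal_id!r} not in population table")
    observed = {pop: 0 for pop in population_table.populations}
    partners: set[str] = set()
    n_ignored = 0
    for seg in segments:
        if focal_id not in seg.samples:
            n_ignored += 1
            continue
        (partner,) = seg.samples - {focal_id}
        if trials == "individuals" and partner in partners:
            continue
        partners.add(partner)
        pop = population_table.get(partner)
        if pop is None:
            raise KeyError(f"sharing partner {partner!r} not in population table")
        observed[pop] += 1
    return observed, sum(observed.values()), n_ignored


def binomial_upper_pvalue(observed: int, n: int, p: float) -> float:
    """P(X >= observed) for X ~ Binomial(n, p); exact upper tail.

    ``observed = 0`` returns 1 (the whole distribution).  An observed count
    above the binomial support n (possible when one partner shares many
    segments) is capped at n with a warning — the tail is then the point
    mass P(X = n).
    """
    if observed < 0:
        raise ValueError(f"observed count {observed} < 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"success probability {p} outside [0, 1]")
    if n < 0:
        raise ValueError(f"trial count {n} < 0")
    if observed > n:
        warnings.warn(
            f"observed count {observed} exceeds binomial support n={n}; capping",
            stacklevel=2,
        )
        observed = n
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, p))


@dataclass(frozen=True)
class TSBHResult:
    p_adjusted: np.ndarray
    reject: np.ndarray
    m0: int
    r1: int
    alpha: float


def _bh_reject_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of BH step-up rejections at the given level."""
    m = len(p_sorted)
    crit = level * np.arange(1, m + 1) / m
    passed = np.nonzero(p_sorted <= crit)[0]
    return int(passed[-1] + 1) if passed.size else 0


def tsbh_adjust(p_values: Sequence[float], alpha: float = 0.05) -> TSBHResult:
    """Two-stage Benjamini-Hochberg adjustment.

    Stage 1 runs BH at level alpha' = alpha/(1+alpha); the number of true
    nulls is estimated as m0 = m - r1 (r1 = stage-1 rejections).  Stage 2
    re-runs BH at the inflated level alpha' * m / m0.  Edge cases: r1 = 0
    rejects nothing (m0 = m); r1 = m rejects everything (m0 = 0).

    Adjusted p-values are the standard BH step-up values scaled by m0/m,
    clipped to [0, 1], monotone in the sorted order; with this definition
    rejection corresponds to p_adjusted <= alpha/(1+alpha).  (Published
    implementations differ by the constant factor (1+alpha) so that
    rejection reads p_adjusted <= alpha; the rejection sets are identical.)
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d array of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    r1 = _bh_reject_count(p_sorted, alpha1)
    if r1 == 0:
        m0, n_reject = m, 0
    elif r1 == m:
        m0, n_reject = 0, m
    else:
        m0 = m - r1
        n_reject = _bh_reject_count(p_sorted, alpha1 * m / m0)
    ranks = np.arange(1, m + 1)
    bh = np.minimum.accumulate((m * p_sorted / ranks)[::-1])[::-1]
    adj_sorted = np.clip(bh * (m0 / m), 0.0, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    reject = np.zeros(m, dtype=bool)
    reject[order[:n_reject]] = True
    return TSBHResult(p_adjusted=p_adj, reject=reject, m0=m0, r1=r1, alpha=alpha)


def enrichment_report(
    segments: Sequence[IBDSegment],
    focal_id: str,
    population_table: PopulationTable,
    alpha: float = 0.05,
    sided: Literal["greater", "two-sided"] = "greater",
    trials: Literal["segments", "individuals"] = "segments",
) -> pd.DataFrame:
    """Per-population enrichment table for one focal individual.

    Columns: population, n, observed, expected, p_raw, p_adj, reject;
    rows sorted by adjusted p-value.  ``expected = n_i * T/N`` so the
    expected column sums exactly to T.  With T = 0 all raw p-values are 1
    and nothing is rejected.
    """
    observed, total, _ = focal_segment_counts(segments, focal_id, population_table, trials)
    sizes = population_table.sizes
    n_total = population_table.n_individuals
    p_null = total / n_total if n_total else 0.0
    pops = population_table.populations
    rows = []
    for pop in pops:
        n_i = sizes[pop]
        obs = observed[pop]
        if total == 0:
            p_raw = 1.0
        else:
            p_raw = binomial_upper_pvalue(obs, n_i, p_null)
            if sided == "two-sided":
                # doubled smaller tail, capped at 1
                lower = float(stats.binom.cdf(min(obs, n_i), n_i, p_null))
                p_raw = min(1.0, 2.0 * min(p_raw, lower))
        rows.append((pop, n_i, obs, n_i * p_null, p_raw))
    df = pd.DataFrame(rows, columns=["population", "n", "observed", "expected", "p_raw"])
    res = tsbh_adjust(df["p_raw"].to_numpy(), alpha)
    df["p_adj"] = res.p_adjusted
    df["reject"] = res.reject if total > 0 else False
    df = df.sort_values(["p_adj", "p_raw", "population"], kind="mergesort").reset_index(drop=True)
    df.attrs["T"] = total
    df.attrs["N"] = n_total
    df.attrs["p_null"] = p_null
    df.attrs["m0"] = res.m0
    df.attrs["alpha"] = alpha
    return df
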