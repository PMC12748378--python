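"""Cohort-level copy-number profiling.

Operates on an *alteration table*: one row per patient with stratum labels
(``site``, ``histology``, ``sample_type``) plus per-gene integer copy-number
calls in GISTIC convention (columns ``cn_<GENE>``, values -2..+2) and
per-gene pathogenic-mutation flags (columns ``mut_<GENE>``, boolean).

A call at or above +2 counts as high-level amplification.  Rates are
reported both exactly (100*k/n) and rounded half-to-even at two decimals,
matching the convention used when presenting cohort frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySubsetError, InputError, UndefinedRateError

logger = logging.getLogger(__name__)

CN_PREFIX = "cn_"
MUT_PREFIX = "mut_"

#: copy-number call at or above which a gene counts as amplified
AMP_CALL_CUTOFF = 2


@dataclass(frozen=True)
class RateResult:
    """Amplification frequency for one stratum."""

    stratum: str
    numerator: int
    denominator: int
    rate_percent: float        # exactly 100 * k / n
    rate_percent_2dp: float    # rounded half-to-even at 2 decimals


@dataclass(frozen=True)
class CoAlterationRow:
    """Frequency of one co-occurring event among anchor-amplified cases."""

    gene: str
    event: str                 # "co-amplified" | "mutated"
    count: int
    frequency_percent: float


def call_amplified(copy_number_call: int, cutoff: int = AMP_CALL_CUTOFF) -> bool:
    """True iff an integer copy-number call is at or above the cutoff."""
    if isinstance(copy_number_call, bool) or not isinstance(
        copy_number_call, (int, np.integer)
    ):
        raise InputError(
            f"copy-number call must be an integer, got {copy_number_call!r}"
        )
    return int(copy_number_call) >= cutoff


def round2_half_even(k: int, n: int) -> float:
    """100*k/n rounded half-to-even at two decimals, via exact decimals."""
    q = (Decimal(100 * k) / Decimal(n)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN
    )
    return float(q)


def amplification_rate(k: int, n: int, stratum: str = "all") -> RateResult:
    """Amplification frequency from a numerator/denominator pair.

    Raises :class:`UndefinedRateError` for ``n == 0`` rather than returning
    a silent zero.
    """
    if n == 0:
        raise UndefinedRateError(f"rate undefined for stratum {stratum!r}: n = 0")
    if not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    return RateResult(
        stratum=stratum,
        numerator=int(k),
        denominator=int(n),
        rate_percent=100.0 * k / n,
        rate_percent_2dp=round2_half_even(k, n),
    )


def _anchor_calls(table: pd.DataFrame, anchor_gene: str) -> pd.Series:
    col = CN_PREFIX + anchor_gene
    if col not in table.columns:
        raise InputError(f"table has no copy-number column for {anchor_gene!r}")
    calls = table[col]
    n_missing = int(calls.isna().sum())
    if n_missing:
        # mirrors excluding cases without complete copy-number profiles
        logger.info(
            "excluding %d patients lacking a %s copy-number call",
            n_missing,
            anchor_gene,
        )
    return calls


def stratified_rates(
    table: pd.DataFrame,
    anchor_gene: str = "CCNE1",
    stratum_key: str = "histology",
    cutoff: int = AMP_CALL_CUTOFF,
) -> tuple[list[RateResult], float | None]:
    """Per-stratum amplification rates plus a between-stratum homogeneity test.

    The test is a chi-square test (no continuity correction) on the
    strata x {amplified, not amplified} contingency table.  For two strata
    with any expected cell below 5, Fisher's exact test is substituted;
    for larger tables with small expected cells a warning is logged but the
    chi-square p is still reported.  A single stratum yields ``p = None``.
    """
    if stratum_key not in table.columns:
        raise InputError(f"stratum key {stratum_key!r} not in table")
    calls = _anchor_calls(table, anchor_gene)
    kept = table.loc[calls.notna()].copy()
    amp = kept[CN_PREFIX + anchor_gene].astype(int) >= cutoff

    results: list[RateResult] = []
    counts: list[tuple[int, int]] = []
    for stratum, idx in sorted(kept.groupby(stratum_key).groups.items()):
        n = len(idx)
        k = int(amp.loc[idx].sum())
        results.append(amplification_rate(k, n, stratum=str(stratum)))
        counts.append((k, n - k))

    if len(results) < 2:
        return results, None

    obs = np.array(counts, dtype=float)
    if obs.sum(axis=0).min() == 0:
        # one column all zero: homogeneity test degenerate, p undefined
        logger.warning("contingency table has an all-zero column; p set to 1")
        return results, 1.0
    expected = stats.contingency.expected_freq(obs)
    if len(results) == 2 and (expected < 5).any():
        _, p = stats.fisher_exact(obs.astype(int))
        return results, float(p)
    if (expected < 5).any():
        logger.warning(
            "expected cell below 5 in a %dx2 table; chi-square approximation "
            "may be inaccurate",
            len(results),
        )
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return results, float(p)


def coalteration_frequencies(
    table: pd.DataFrame,
    anchor_gene: str = "CCNE1",
    cutoff: int = AMP_CALL_CUTOFF,
) -> list[CoAlterationRow]:
    """Co-amplification and co-mutation frequencies among anchor-amplified cases.

    For every non-anchor gene with a copy-number column, the frequency of
    calls at or above the cutoff within the anchor-amplified subset; for
    every gene with a mutation-flag column, the frequency of pathogenic
    mutations in the same subset.  Sorted by descending frequency, ties
    broken lexicographically by gene label.
    """
    calls = _anchor_calls(table, anchor_gene)
    kept = table.loc[calls.notna()]
    amp_mask = kept[CN_PREFIX + anchor_gene].astype(int) >= cutoff
    amped = kept.loc[amp_mask]
    m = len(amped)
    if m == 0:
        raise EmptySubsetError(f"no {anchor_gene}-amplified cases in table")

    rows: list[CoAlterationRow] = []
    for col in kept.columns:
        if col.startswith(CN_PREFIX):
            gene = col[len(CN_PREFIX):]
            if gene == anchor_gene:
                continue
            k = int((amped[col].fillna(-10).astype(int) >= cutoff).sum())
            rows.append(
                CoAlterationRow(gene, "co-amplified", k, 100.0 * k / m)
            )
        elif col.startswith(MUT_PREFIX):
            gene = col[len(MUT_PREFIX):]
            if gene == anchor_gene:
                continue
            k = int(amped[col].fillna(False).astype(bool).sum())
            rows.append(CoAlterationRow(gene, "mutated", k, 100.0 * k / m))

    rows.sort(key=lambda r: (-r.frequency_percent, r.gene))
    return rows


def rates_to_frame(results: list[RateResult]) -> pd.DataFrame:
    """Tabulate RateResults for TSV output."""
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "amplified": [r.numerator for r in results],
            "total": [r.denominator for r in results],
            "rate_percent": [r.rate_percent for r in results],
            "rate_percent_2dp": [r.rate_percent_2dp for r in results],
        }
    )


def coalterations_to_frame(rows: list[CoAlterationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "event": [r.event for r in rows],
            "count": [r.count for r in rows],
            "frequency_percent": [r.frequency_percent for r in rows],
        }
    )
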