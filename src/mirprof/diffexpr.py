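"""Two-library differential expression for count data without replicates.

Normalization is reads-per-million of clean reads. The test statistic is
the exact conditional distribution of one library's count given the
other's (for totals N1, N2 and counts x, y):

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

evaluated via log-gamma. The lower tail C sums p(y'|x) for y' <= y, the
upper tail D for y' >= y, and the reported two-sided p-value is
min(1, 2*min(C, D)). The test runs on raw counts (the factorials require
integers); normalized expression drives the fold change and the
zero/low-expression prefilter (both NE < 1 -> discard; NE 0 -> 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.special import gammaln, logsumexp

MILLION = 1_000_000.0
ZERO_REPLACEMENT = 0.001
MIN_NE = 1.0


def normalize(count: float, total: int) -> float:
    """Reads-per-million: count / total * 1e6."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * MILLION


def prefilter(
    ne_r: float,
    ne_p: float,
    min_ne: float = MIN_NE,
    zero_replacement: float = ZERO_REPLACEMENT,
) -> tuple[float, float] | None:
    """Low-expression/zero handling; None means the miRNA is discarded."""
    if ne_r < 0 or ne_p < 0:
        raise ValueError("NE must be non-negative")
    if ne_r < min_ne and ne_p < min_ne:
        return None
    return (ne_r or zero_replacement, ne_p or zero_replacement)


def fold_change(ne_r: float, ne_p: float) -> tuple[float, float]:
    """(ratio, log2 ratio) of R over P normalized expression."""
    if ne_p <= 0:
        raise ValueError("ne_p must be positive (apply prefilter first)")
    ratio = ne_r / ne_p
    return ratio, math.log2(ratio)


def _log_pmf(y_values, x: int, log_ratio: float, log1p_ratio: float):
    import numpy as np

    y = np.asarray(y_values, dtype=float)
    return (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1p_ratio
    )


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for counts (x in lib 1, y in lib 2).

    Exposed one-sided tails via :func:`ac_tails`.
    """
    lower, upper = ac_tails(x, y, n1, n2)
    return min(1.0, 2.0 * min(lower, upper))


def ac_tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(lower tail C = P(Y <= y | x), upper tail D = P(Y >= y | x))."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if int(x) != x or int(y) != y:
        raise ValueError("counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    ratio = n2 / n1
    log_ratio = math.log(ratio)
    log1p_ratio = math.log1p(ratio)
    import numpy as np

    log_cum = logsumexp(_log_pmf(np.arange(y + 1), x, log_ratio, log1p_ratio))
    log_point = float(_log_pmf([y], x, log_ratio, log1p_ratio)[0])
    lower = min(1.0, math.exp(log_cum))
    # total mass is 1, so D = 1 - C + p(y|x)
    upper = min(1.0, max(0.0, 1.0 - lower + math.exp(log_point)))
    return lower, upper


def classify(ratio: float) -> str:
    """Fold-change class: down (<=0.5), mid (0.5..2], up (>2)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio <= 0.5:
        return "down"
    if ratio > 2.0:
        return "up"
    return "mid"


@dataclass(frozen=True)
class DEResult:
    name: str
    x: int  # raw count, library P
    y: int  # raw count, library R
    ne_r: float
    ne_p: float
    ratio: float | None
    log2_ratio: float | None
    p_value: float | None
    reg_class: str | None
    significant: bool
    specific: str | None = None  # 'R' or 'P' when expressed in one library only


def de_table(
    counts_p: dict[str, int],
    counts_r: dict[str, int],
    total_p: int,
    total_r: int,
    alpha: float = 0.05,
    min_ne: float = MIN_NE,
    zero_replacement: float = ZERO_REPLACEMENT,
    min_abs_log2: float = 1.0,
) -> list[DEResult]:
    """Full DE analysis: normalize -> prefilter -> fold/test -> classify.

    miRNA sets are outer-joined with zero counts. miRNAs expressed in
    exactly one library are flagged specific and carry no p/fold.
    Ordering: descending |log2 ratio| then name; specific rows last.
    """
    names = sorted(set(counts_p) | set(counts_r))
    tested: list[DEResult] = []
    specific: list[DEResult] = []
    for name in names:
        x = int(counts_p.get(name, 0))
        y = int(counts_r.get(name, 0))
        ne_p = normalize(x, total_p)
        ne_r = normalize(y, total_r)
        adjusted = prefilter(ne_r, ne_p, min_ne, zero_replacement)
        if adjusted is None:
            continue
        if (x == 0) != (y == 0):
            specific.append(
                DEResult(
                    name, x, y, ne_r, ne_p,
                    ratio=None, log2_ratio=None, p_value=None,
                    reg_class=None, significant=False,
                    specific="R" if x == 0 else "P",
                )
            )
            continue
        ratio, log2_ratio = fold_change(*adjusted)
        p = ac_pvalue(x, y, total_p, total_r)
        tested.append(
            DEResult(
                name, x, y, ne_r, ne_p,
                ratio=ratio, log2_ratio=log2_ratio, p_value=p,
                reg_class=classify(ratio),
                significant=(p < alpha and abs(log2_ratio) > min_abs_log2),
            )
        )
    tested.sort(key=lambda r: (-abs(r.log2_ratio), r.name))
    specific.sort(key=lambda r: r.name)
    return tested + specific


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame with fixed, documented columns.

    ``ratio`` is always R-NE/P-NE and ``log2_ratio`` its log2; display
    rounding to 2 decimals happens only here, full precision upstream.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "miRNA": r.name,
                "count_P": r.x,
                "count_R": r.y,
                "NE_R": round(r.ne_r, 2),
                "NE_P": round(r.ne_p, 2),
                "ratio": round(r.ratio, 2) if r.ratio is not None else None,
                "log2_ratio": round(r.log2_ratio, 2) if r.log2_ratio is not None else None,
                "p_value": round(r.p_value, 4) if r.p_value is not None else None,
                "reg_class": r.reg_class,
                "significant": r.significant,
                "specific": r.specific,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "miRNA", "count_P", "count_R", "NE_R", "NE_P", "ratio",
            "log2_ratio", "p_value", "reg_class", "significant", "specific",
        ],
    )


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[idx] * m / rank)
        adjusted[idx] = prev
    return adjusted
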