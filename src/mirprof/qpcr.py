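"""Stem-loop RT-qPCR quantification by the 2^-ddCt method.

ddCt = (Ct_miRNA - Ct_ref)_R - (Ct_miRNA - Ct_ref)_P; the baseline
condition therefore evaluates to 1 by construction. Replicates are
aggregated by averaging dCt within condition before ddCt (per-replicate
relative values against the baseline mean dCt are also reported to give
a spread).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

CT_WARN_LO, CT_WARN_HI = 10.0, 40.0


@dataclass(frozen=True)
class QpcrMeasurement:
    mirna: str
    condition: str  # 'P' or 'R'
    replicate: str
    ct_mirna: float
    ct_ref: float

    def __post_init__(self) -> None:
        for value in (self.ct_mirna, self.ct_ref):
            if not math.isfinite(value):
                raise ValueError("Ct values must be finite")
            if not CT_WARN_LO <= value <= CT_WARN_HI:
                logger.warning(
                    "Ct %.2f for %s/%s outside the typical 10-40 range",
                    value, self.mirna, self.condition,
                )


def ddct(
    ct_mirna_r: float,
    ct_ref_r: float,
    ct_mirna_p: float,
    ct_ref_p: float,
) -> float:
    """Relative expression 2^-ddCt of condition R against baseline P."""
    delta_delta = (ct_mirna_r - ct_ref_r) - (ct_mirna_p - ct_ref_p)
    return 2.0 ** (-delta_delta)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"miRNA", "condition", "replicate", "ct_mirna", "ct_ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def summarize_validation(
    ct_table: pd.DataFrame,
    de_ratios: dict[str, float],
    baseline: str = "P",
    test: str = "R",
) -> pd.DataFrame:
    """Per-miRNA relative expression (mean +/- sd) and DE concordance.

    Concordant iff (relative expression > 1) matches (DE ratio > 1);
    'flat' when either side equals 1; 'not compared' when the miRNA is
    missing from either table.
    """
    rows = []
    for mirna, sub in ct_table.groupby("miRNA", sort=True):
        by_cond = {cond: grp for cond, grp in sub.groupby("condition")}
        if baseline not in by_cond or test not in by_cond:
            rows.append(
                {"miRNA": mirna, "mean": None, "sd": None, "concordance": "not compared"}
            )
            continue
        dct = {
            cond: (grp["ct_mirna"] - grp["ct_ref"]).to_numpy()
            for cond, grp in by_cond.items()
        }
        baseline_mean = dct[baseline].mean()
        per_rep = 2.0 ** (-(dct[test] - baseline_mean))
        mean = float(2.0 ** (-(dct[test].mean() - baseline_mean)))
        sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
        if mirna not in de_ratios or de_ratios[mirna] is None:
            concordance = "not compared"
        elif mean == 1.0 or de_ratios[mirna] == 1.0:
            concordance = "flat"
        elif (mean > 1.0) == (de_ratios[mirna] > 1.0):
            concordance = "concordant"
        else:
            concordance = "discordant"
        rows.append({"miRNA": mirna, "mean": mean, "sd": sd, "concordance": concordance})
    return pd.DataFrame(rows, columns=["miRNA", "mean", "sd", "concordance"])
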