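"""Ranking proteins by accumulation in the detergent-insoluble fraction.

For each protein, the per-replicate difference of iBAQ abundances between
mutant and wild-type insoluble fractions (delta-iBAQ) measures how much
more of it aggregates when the quality-control ligase is absent. Proteins
are ranked by mean delta-iBAQ and the top decile is selected. Differences
(not log ratios) are used deliberately: they weight abundant proteins,
which is the point when the aggregating species of interest are highly
expressed ribosomal proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    """Mutant and wild-type replicates do not line up."""


@dataclass
class ProteinAbundance:
    """Per-replicate iBAQ abundances for one protein, paired by replicate id."""

    protein: str
    mutant: dict[str, float]
    wildtype: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mutant) != set(self.wildtype):
            only_m = sorted(set(self.mutant) - set(self.wildtype))
            only_w = sorted(set(self.wildtype) - set(self.mutant))
            raise PairingError(
                f"{self.protein}: unpaired replicates "
                f"(mutant-only {only_m}, wildtype-only {only_w})"
            )
        if not self.mutant:
            raise PairingError(f"{self.protein}: no replicates")


@dataclass
class DeltaIbaqSummary:
    """Mean delta-iBAQ with SEM; rank and decile flag filled by rank_and_select."""

    protein: str
    delta_per_replicate: list[float]
    mean_delta: float
    sem: float
    rank: int | None = None
    top_decile: bool | None = None


def delta_ibaq(abundance: ProteinAbundance) -> DeltaIbaqSummary:
    """Per-replicate mutant-minus-wildtype iBAQ differences and their mean/SEM.

    SEM is the sample standard deviation over sqrt(n); it is 0 (flagged
    in the log) for a single replicate, where no spread is estimable.
    """
    reps = sorted(abundance.mutant)
    deltas = [abundance.mutant[r] - abundance.wildtype[r] for r in reps]
    n = len(deltas)
    mean = float(np.mean(deltas))
    if n == 1:
        logger.info("%s: single replicate, SEM set to 0", abundance.protein)
        sem = 0.0
    else:
        sem = float(np.std(deltas, ddof=1)) / math.sqrt(n)
    return DeltaIbaqSummary(
        protein=abundance.protein,
        delta_per_replicate=deltas,
        mean_delta=mean,
        sem=sem,
    )


def rank_and_select(
    summaries: list[DeltaIbaqSummary], decile: float = 0.10
) -> pd.DataFrame:
    """Rank by descending mean delta-iBAQ and flag the top decile.

    Decile size is ``ceil(decile * n)``; ties in mean_delta that straddle
    the boundary expand the selection (logged) rather than being broken
    arbitrarily. The rank order itself breaks exact ties by protein name
    so output is deterministic.
    """
    if not summaries:
        raise ValueError("rank_and_select: no summaries")
    df = pd.DataFrame(
        {
            "protein": [s.protein for s in summaries],
            "mean_delta": [s.mean_delta for s in summaries],
            "sem": [s.sem for s in summaries],
            "delta_per_replicate": [list(s.delta_per_replicate) for s in summaries],
        }
    )
    df = df.sort_values(
        ["mean_delta", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    k = math.ceil(decile * n)
    cutoff = df["mean_delta"].iloc[k - 1]
    top = df["mean_delta"] > cutoff
    tied = df["mean_delta"] == cutoff
    if int(top.sum() + tied.sum()) > k:
        logger.info(
            "top-decile boundary tie at mean_delta=%s: selecting %d proteins "
            "instead of %d",
            cutoff,
            int(top.sum() + tied.sum()),
            k,
        )
    df["rank"] = np.arange(1, n + 1)
    df["top_decile"] = top | tied
    for s in summaries:
        row = df[df["protein"] == s.protein].iloc[0]
        s.rank = int(row["rank"])
        s.top_decile = bool(row["top_decile"])
    return df


def read_ibaq_table(
    path,
    mutant_cols: dict[str, str],
    wildtype_cols: dict[str, str],
    protein_col: str = "protein",
) -> list[ProteinAbundance]:
    """Read a proteinGroups-style TSV with per-sample iBAQ columns.

    ``mutant_cols`` / ``wildtype_cols`` map replicate id -> column name,
    e.g. ``{"A": "iBAQ tom1_A"}``. Missing or non-numeric iBAQ cells are
    treated as 0 (protein absent from that fraction) and logged.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        protein = str(row[protein_col])

        def grab(cols: dict[str, str]) -> dict[str, float]:
            vals = {}
            for rep, col in cols.items():
                v = pd.to_numeric(row.get(col), errors="coerce")
                if pd.isna(v):
                    logger.warning("%s: missing iBAQ in %s, using 0", protein, col)
                    v = 0.0
                vals[rep] = float(v)
            return vals

        out.append(
            ProteinAbundance(protein=protein, mutant=grab(mutant_cols), wildtype=grab(wildtype_cols))
        )
    return out
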