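"""Aggregation of SILAC mutant/WT ratios for GlyGly-modified lysine sites.

A GlyGly (diGly) remnant on a lysine marks a former ubiquitin conjugate;
the heavy/light SILAC ratio of the modified peptide quantifies how site
occupancy changes between a mutant and wild type. This module turns
per-replicate peptide-level ratios into per-site summaries:

* label-swap replicates are re-oriented to a common mutant/WT convention,
* multiple peptides covering one site within a replicate collapse to the
  median on the log2 scale,
* across replicates the mean log2 ratio, a t-based 95% confidence
  interval, the linear fold change, and a >=2-fold-decrease flag are
  computed,
* sites seen in fewer than ``min_reps`` replicates are filtered, not
  summarized,
* optional protein-level normalization converts ratios to occupancy
  ratios, and category fractions report how decreases distribute over
  ribosomal vs non-ribosomal proteins.

All combination happens on the log2 scale (multiplicative error model,
symmetric treatment of up- and down-regulation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("large", "small", "nonribosomal", "other")


class RatioError(ValueError):
    """A non-positive or otherwise invalid ratio in an input record."""


@dataclass(frozen=True)
class ReplicateRatio:
    """One replicate's mutant/WT ratio for one site (before orientation)."""

    replicate: str
    ratio: float
    swap: bool = False


@dataclass
class GlyGlySiteRecord:
    """Per-replicate measurements for one GlyGly site."""

    protein: str
    position: int
    replicate_ratios: list[ReplicateRatio] = field(default_factory=list)
    category: str = "other"

    def __post_init__(self) -> None:
        reps = [r.replicate for r in self.replicate_ratios]
        if len(reps) != len(set(reps)):
            raise RatioError(
                f"{self.protein} K{self.position}: duplicate replicate ids {reps}"
            )
        for r in self.replicate_ratios:
            if not (r.ratio > 0) or not math.isfinite(r.ratio):
                raise RatioError(
                    f"{self.protein} K{self.position} replicate {r.replicate}: "
                    f"ratio must be positive and finite, got {r.ratio}"
                )


@dataclass(frozen=True)
class SiteSummary:
    """Aggregated occupancy change for one site."""

    protein: str
    position: int
    category: str
    n_reps: int
    mean_log2: float
    ci95_low: float
    ci95_high: float
    fold_change: float
    decreased_2x: bool
    normalized: bool = False
    degenerate_ci: bool = False


def orient_ratio(ratio: float, swap: bool) -> float:
    """Orient one ratio to the mutant/WT convention.

    In a label-swap replicate the heavy/light assignment of the two
    conditions is inverted, so the measured ratio is WT/mutant and must
    be reciprocated.
    """
    if not (ratio > 0) or not math.isfinite(ratio):
        raise RatioError(f"ratio must be positive and finite, got {ratio}")
    return 1.0 / ratio if swap else ratio


def collapse_peptides(measurements: Iterable[ReplicateRatio]) -> float:
    """Collapse several peptide-level measurements of one site within one
    replicate to a single ratio: the median on the log2 scale, back-
    transformed (the geometric median for an odd count)."""
    oriented = [orient_ratio(m.ratio, m.swap) for m in measurements]
    if not oriented:
        raise RatioError("collapse_peptides: no measurements")
    return float(2.0 ** np.median(np.log2(oriented)))


def summarize_site(
    record: GlyGlySiteRecord,
    min_reps: int = 2,
    fold_threshold: float = 0.5,
) -> SiteSummary | None:
    """Summarize one site across replicates; None if under-observed.

    The 95% CI uses the t distribution with ``n_reps - 1`` degrees of
    freedom. With a single replicate (allowed only when ``min_reps=1``)
    the interval is the point estimate +/- infinity and the summary is
    flagged degenerate.
    """
    ratios = [orient_ratio(r.ratio, r.swap) for r in record.replicate_ratios]
    n = len(ratios)
    if n < min_reps:
        return None
    logs = np.log2(ratios)
    mean = float(np.mean(logs))
    degenerate = n == 1
    if degenerate:
        lo, hi = -math.inf, math.inf
    else:
        sem = float(np.std(logs, ddof=1)) / math.sqrt(n)
        tcrit = float(stats.t.ppf(0.975, df=n - 1))
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    fold = 2.0 ** mean
    return SiteSummary(
        protein=record.protein,
        position=record.position,
        category=record.category,
        n_reps=n,
        mean_log2=mean,
        ci95_low=lo,
        ci95_high=hi,
        fold_change=fold,
        decreased_2x=fold <= fold_threshold,
        degenerate_ci=degenerate,
    )


def normalize_by_protein(
    site_ratio: float,
    protein_ratio: float | None,
) -> tuple[float, bool]:
    """Divide a site ratio by its protein-level abundance ratio.

    Converts a raw site ratio into an occupancy ratio: a site can lose
    ubiquitination without the protein itself becoming less abundant,
    and this division separates the two. Returns ``(ratio, normalized)``;
    with no protein entry the raw ratio is passed through and flagged.
    """
    if protein_ratio is None:
        return site_ratio, False
    if not (site_ratio > 0 and protein_ratio > 0):
        raise RatioError(
            f"ratios must be positive: site={site_ratio}, protein={protein_ratio}"
        )
    return site_ratio / protein_ratio, True


def summarize_table(
    records: Sequence[GlyGlySiteRecord],
    min_reps: int = 2,
    protein_ratios: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Summarize many sites into a tidy frame.

    When ``protein_ratios`` is given, each replicate ratio is divided by
    the protein-level mutant/WT ratio before aggregation; sites whose
    protein lacks an entry fall back to unnormalized values and carry
    ``normalized=False``.
    """
    rows = []
    for rec in records:
        pr = None
        if protein_ratios is not None:
            pr = protein_ratios.get(rec.protein)
            if pr is None:
                logger.warning(
                    "no protein-level ratio for %s; leaving site K%d unnormalized",
                    rec.protein,
                    rec.position,
                )
        if pr is not None:
            rec = GlyGlySiteRecord(
                protein=rec.protein,
                position=rec.position,
                category=rec.category,
                replicate_ratios=[
                    ReplicateRatio(
                        r.replicate,
                        normalize_by_protein(orient_ratio(r.ratio, r.swap), pr)[0],
                        swap=False,
                    )
                    for r in rec.replicate_ratios
                ],
            )
        s = summarize_site(rec, min_reps=min_reps)
        if s is None:
            rows.append(
                {
                    "protein": rec.protein,
                    "position": rec.position,
                    "category": rec.category,
                    "n_reps": len(rec.replicate_ratios),
                    "filtered": True,
                }
            )
            continue
        rows.append(
            {
                "protein": s.protein,
                "position": s.position,
                "category": s.category,
                "n_reps": s.n_reps,
                "filtered": False,
                "mean_log2": s.mean_log2,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "fold_change": s.fold_change,
                "decreased_2x": s.decreased_2x,
                "normalized": pr is not None,
            }
        )
    cols = [
        "protein", "position", "category", "n_reps", "filtered",
        "mean_log2", "ci95_low", "ci95_high", "fold_change",
        "decreased_2x", "normalized",
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def report_fractions(summaries: pd.DataFrame) -> pd.DataFrame:
    """Category breakdown of the >=2-fold-decreased site set.

    For each category: how many of the decreased sites belong to it
    (share of decreased) and what fraction of the category's sites
    decreased (within-category rate). Percentages are carried at full
    precision with an integer display column.
    """
    df = summaries[~summaries.get("filtered", False).astype(bool)].copy()
    dec = df[df["decreased_2x"].astype(bool)]
    n_dec = len(dec)
    rows = []
    for cat in sorted(df["category"].dropna().unique()):
        in_cat = df[df["category"] == cat]
        dec_in_cat = dec[dec["category"] == cat]
        share = 100.0 * len(dec_in_cat) / n_dec if n_dec else 0.0
        rate = 100.0 * len(dec_in_cat) / len(in_cat) if len(in_cat) else 0.0
        rows.append(
            {
                "category": cat,
                "n_sites": len(in_cat),
                "n_decreased": len(dec_in_cat),
                "pct_of_decreased": share,
                "pct_of_decreased_display": int(round(share)),
                "pct_category_decreased": rate,
                "pct_category_decreased_display": int(round(rate)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_decreased_total"] = n_dec
    return out


# ---------------------------------------------------------------------------
# table I/O


def read_site_table(
    path,
    *,
    protein_col: str = "protein",
    position_col: str = "position",
    replicate_col: str = "replicate",
    ratio_col: str = "ratio",
    swap_col: str = "swap",
    category_col: str = "category",
) -> list[GlyGlySiteRecord]:
    """Read a long-format GlyGly site table (TSV).

    Expected columns (renameable to accept MaxQuant-style exports):
    protein, position, replicate, ratio, swap (0/1), category. Several
    rows per (site, replicate) are allowed and collapse to the log2
    median.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {protein_col, position_col, replicate_col, ratio_col} - set(df.columns)
    if missing:
        raise RatioError(f"{path}: missing columns {sorted(missing)}")
    records: list[GlyGlySiteRecord] = []
    for (protein, position), grp in df.groupby([protein_col, position_col], sort=True):
        cat = "other"
        if category_col in grp.columns:
            cat = str(grp[category_col].iloc[0])
        reps = []
        for rep, rgrp in grp.groupby(replicate_col, sort=True):
            ms = [
                ReplicateRatio(
                    str(rep),
                    float(row[ratio_col]),
                    bool(row[swap_col]) if swap_col in grp.columns else False,
                )
                for _, row in rgrp.iterrows()
            ]
            reps.append(ReplicateRatio(str(rep), collapse_peptides(ms), swap=False))
        records.append(
            GlyGlySiteRecord(
                protein=str(protein),
                position=int(position),
                replicate_ratios=reps,
                category=cat,
            )
        )
    return records


def read_protein_ratios(path, protein_col: str = "protein", ratio_col: str = "ratio") -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {str(r[protein_col]): float(r[ratio_col]) for _, r in df.iterrows()}
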