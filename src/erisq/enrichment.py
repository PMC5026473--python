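"""Category over-representation testing with BH correction.

Given a selected set of items (e.g. the top decile of delta-iBAQ, or the
>=2-fold-decreased ubiquitination sites), a user-supplied category
annotation, and the background of everything identified in the
experiment, each category gets a one-sided Fisher exact test for
over-representation in the selection, and the p-values are adjusted
across categories by the Benjamini-Hochberg step-up. The background is
always the identified items, never the whole genome: identification
itself is biased, and only the identified universe shares that bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2-table enrichment of one category in a selected set."""

    category: str
    in_set_in_cat: int
    in_set_not_cat: int
    out_set_in_cat: int
    out_set_not_cat: int
    odds_ratio: float
    p: float
    q: float | None = None


def fisher_enrichment(
    selected: Iterable, category_members: Iterable, background: Iterable
) -> EnrichmentResult:
    """One-sided (over-representation) Fisher exact test for one category.

    The p-value is the upper hypergeometric tail P[X >= a] for the
    overlap count a. The odds ratio is the unconditional (a*d)/(b*c),
    infinite when b*c == 0 with a*d > 0.
    """
    bg = set(background)
    sel = set(selected)
    if not sel <= bg:
        extra = sorted(map(str, sel - bg))[:5]
        raise ValueError(f"selected set is not contained in background (e.g. {extra})")
    cat = set(category_members) & bg
    a = len(sel & cat)
    b = len(sel - cat)
    c = len(cat - sel)
    d = len(bg) - a - b - c
    # upper tail of Hypergeom(N=len(bg), K=len(cat), n=len(sel)) at a
    p = float(stats.hypergeom.sf(a - 1, len(bg), len(cat), len(sel)))
    p = min(p, 1.0)
    if b * c == 0:
        odds = math_inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        category="",
        in_set_in_cat=a,
        in_set_not_cat=b,
        out_set_in_cat=c,
        out_set_not_cat=d,
        odds_ratio=odds,
        p=p,
    )


math_inf = float("inf")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich_categories(
    selected: Iterable,
    annotations: Mapping,
    background: Iterable,
) -> pd.DataFrame:
    """Test every category in an item -> category annotation map.

    Returns one row per category sorted by adjusted p (then name), with
    the 2x2 counts, odds ratio, raw p and BH-adjusted q.
    """
    bg = set(background)
    sel = set(selected)
    cats: dict[str, set] = {}
    for item, cat in annotations.items():
        if item in bg:
            cats.setdefault(str(cat), set()).add(item)
    rows = []
    for cat_name in sorted(cats):
        r = fisher_enrichment(sel, cats[cat_name], bg)
        rows.append(
            {
                "category": cat_name,
                "in_set_in_cat": r.in_set_in_cat,
                "in_set_not_cat": r.in_set_not_cat,
                "out_set_in_cat": r.out_set_in_cat,
                "out_set_not_cat": r.out_set_not_cat,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].tolist())
        df = df.sort_values(["q", "p", "category"], kind="mergesort").reset_index(drop=True)
    return df


def read_annotations(path, item_col: str = "item", category_col: str = "category") -> dict[str, str]:
    """Read a two-column item/category annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    return {str(r[item_col]): str(r[category_col]) for _, r in df.iterrows()}
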