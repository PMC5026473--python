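"""SILAC GlyGly ratio aggregation: orientation, collapse, summaries,
normalization, category fractions, and statistical calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erisq.glygly_quant import (
    GlyGlySiteRecord,
    RatioError,
    ReplicateRatio,
    collapse_peptides,
    normalize_by_protein,
    orient_ratio,
    read_site_table,
    report_fractions,
    summarize_site,
    summarize_table,
)
from erisq.synthetic_data import SimConfig, make_glygly_table


def record(ratios, swaps=None, protein="P", position=1, category="other"):
    swaps = swaps or [False] * len(ratios)
    return GlyGlySiteRecord(
        protein=protein,
        position=position,
        category=category,
        replicate_ratios=[
            ReplicateRatio(str(i + 1), r, s) for i, (r, s) in enumerate(zip(ratios, swaps))
        ],
    )


class TestOrientRatio:
    @pytest.mark.parametrize(
        "ratio,swap,expected", [(0.25, False, 0.25), (4.0, True, 0.25), (1.0, True, 1.0)]
    )
    def test_orientation(self, ratio, swap, expected):
        assert orient_ratio(ratio, swap) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_ratio_rejected(self, bad):
        with pytest.raises(RatioError):
            orient_ratio(bad, False)

    @given(st.floats(min_value=1e-6, max_value=1e6), st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_swap_is_an_involution(self, ratio, swap):
        # inverting the ratio and toggling the flag leaves orientation unchanged
        assert orient_ratio(1.0 / ratio, not swap) == pytest.approx(
            orient_ratio(ratio, swap), rel=1e-9
        )


class TestCollapsePeptides:
    def test_singleton(self):
        assert collapse_peptides([ReplicateRatio("1", 0.5)]) == pytest.approx(0.5)

    def test_all_equal_after_orientation(self):
        ms = [ReplicateRatio("1", 0.25), ReplicateRatio("1", 0.25), ReplicateRatio("1", 4.0, swap=True)]
        assert collapse_peptides(ms) == pytest.approx(0.25)

    def test_log2_median_of_three(self):
        ms = [ReplicateRatio("1", r) for r in (0.2, 0.3, 0.8)]
        assert collapse_peptides(ms) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(RatioError):
            collapse_peptides([])


class TestSummarizeSite:
    def test_zero_variance_threefold_site(self):
        s = summarize_site(record([0.25, 0.25, 0.25]))
        assert s.mean_log2 == pytest.approx(-2.0)
        assert s.fold_change == pytest.approx(0.25)
        assert s.decreased_2x
        assert s.ci95_low == pytest.approx(s.ci95_high) == pytest.approx(-2.0)

    def test_null_site_not_decreased(self):
        s = summarize_site(record([1.0, 1.0]))
        assert s.mean_log2 == pytest.approx(0.0)
        assert not s.decreased_2x

    def test_fold_threshold_separates_2p4_from_1p6_fold(self):
        # a 2.4-fold decrease crosses the >=2-fold line; a 1.6-fold one does not
        s24 = summarize_site(record([1 / 2.4] * 3))
        s16 = summarize_site(record([1 / 1.6] * 3))
        assert s24.decreased_2x and not s16.decreased_2x

    def test_under_observed_site_is_filtered(self):
        assert summarize_site(record([0.25]), min_reps=2) is None

    def test_single_replicate_ci_is_degenerate(self):
        s = summarize_site(record([0.25]), min_reps=1)
        assert s.degenerate_ci
        assert s.ci95_low == -math.inf and s.ci95_high == math.inf

    def test_ci_bounds_bracket_the_mean(self):
        s = summarize_site(record([0.2, 0.5, 0.3]))
        assert s.ci95_low <= s.mean_log2 <= s.ci95_high

    def test_duplicate_replicate_ids_rejected(self):
        with pytest.raises(RatioError):
            GlyGlySiteRecord("P", 1, [ReplicateRatio("1", 0.5), ReplicateRatio("1", 0.6)])


def test_label_swap_involution_on_a_full_table():
    """Inverting every ratio and toggling every swap flag is a no-op."""
    cfg = SimConfig(seed=11, n_sites=60)
    table, _ = make_glygly_table(cfg)
    flipped = table.copy()
    flipped["ratio"] = 1.0 / flipped["ratio"]
    flipped["swap"] = 1 - flipped["swap"]

    def summarize(df, tmp_path_factory=None):
        recs = []
        for (prot, pos), grp in df.groupby(["protein", "position"]):
            recs.append(
                GlyGlySiteRecord(
                    protein=prot, position=int(pos), category=grp["category"].iloc[0],
                    replicate_ratios=[
                        ReplicateRatio(str(r["replicate"]), r["ratio"], bool(r["swap"]))
                        for _, r in grp.iterrows()
                    ],
                )
            )
        return summarize_table(recs)

    a, b = summarize(table), summarize(flipped)
    pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-9)


def test_scale_equivariance_shifts_mean_log2_exactly():
    base = record([0.2, 0.5, 0.3])
    c = 3.7
    scaled = record([0.2 * c, 0.5 * c, 0.3 * c])
    s0, s1 = summarize_site(base), summarize_site(scaled)
    assert s1.mean_log2 - s0.mean_log2 == pytest.approx(math.log2(c), rel=1e-12)
    assert (s1.ci95_high - s1.ci95_low) == pytest.approx(s0.ci95_high - s0.ci95_low)


class TestNormalizeByProtein:
    def test_identity_and_arithmetic(self):
        assert normalize_by_protein(0.25, 1.0) == (pytest.approx(0.25), True)
        assert normalize_by_protein(0.25, 0.5) == (pytest.approx(0.5), True)
        assert normalize_by_protein(0.25, None) == (0.25, False)

    def test_uniform_protein_drop_recovered_only_when_normalized(self):
        """If every protein's abundance halves, raw site ratios conflate the
        protein change with occupancy; normalization removes it."""
        cfg = SimConfig(seed=5, n_sites=200, noise_sd_log2=0.05)
        table, truth = make_glygly_table(cfg)
        table = table.copy()
        # protein abundance drops 2-fold uniformly: measured site ratios halve
        oriented = np.where(table["swap"] == 1, 1 / table["ratio"], table["ratio"])
        oriented = oriented * 0.5
        table["ratio"] = np.where(table["swap"] == 1, 1 / oriented, oriented)
        recs = []
        for (prot, pos), grp in table.groupby(["protein", "position"]):
            recs.append(
                GlyGlySiteRecord(
                    protein=prot, position=int(pos), category=grp["category"].iloc[0],
                    replicate_ratios=[
                        ReplicateRatio(str(r["replicate"]), r["ratio"], bool(r["swap"]))
                        for _, r in grp.iterrows()
                    ],
                )
            )
        protein_ratios = {p: 0.5 for p in table["protein"].unique()}
        norm = summarize_table(recs, protein_ratios=protein_ratios)
        raw = summarize_table(recs)
        merged = norm.merge(truth, on=["protein", "position"], suffixes=("", "_t"))
        null_norm = merged[~merged["affected"]]
        assert null_norm["mean_log2"].abs().mean() < 0.1   # planted 0 recovered
        raw_merged = raw.merge(truth, on=["protein", "position"])
        null_raw = raw_merged[~raw_merged["affected"]]
        assert null_raw["mean_log2"].mean() == pytest.approx(-1.0, abs=0.1)


class TestReportFractions:
    @staticmethod
    def _frame(n_dec_ribo, n_dec_non, n_ribo, n_non):
        rows = []
        for i in range(n_ribo):
            rows.append({"protein": f"R{i}", "position": 1, "category": "large",
                         "filtered": False, "decreased_2x": i < n_dec_ribo})
        for i in range(n_non):
            rows.append({"protein": f"N{i}", "position": 1, "category": "nonribosomal",
                         "filtered": False, "decreased_2x": i < n_dec_non})
        return pd.DataFrame(rows)

    def test_published_headline_fractions(self):
        # 141 decreased sites, 51 ribosomal of 101; 36% of decreases ribosomal,
        # >50% of ribosomal sites decreased
        df = self._frame(n_dec_ribo=51, n_dec_non=90, n_ribo=101, n_non=837)
        out = report_fractions(df).set_index("category")
        assert out.attrs["n_decreased_total"] == 141
        ribo = out.loc["large"]
        assert ribo["pct_of_decreased_display"] == 36
        assert ribo["pct_of_decreased"] == pytest.approx(100 * 51 / 141)
        assert ribo["pct_category_decreased"] == pytest.approx(100 * 51 / 101)
        assert ribo["pct_category_decreased"] > 50.0

    def test_empty_decreased_set_yields_zeros(self):
        df = self._frame(0, 0, 5, 5)
        out = report_fractions(df)
        assert (out["pct_of_decreased"] == 0).all()
        assert (out["n_decreased"] == 0).all()


def test_read_site_table_collapses_peptides_and_orients(tmp_path):
    p = tmp_path / "sites.tsv"
    pd.DataFrame(
        {
            "protein": ["P1"] * 4,
            "position": [10] * 4,
            "replicate": ["1", "1", "2", "3"],
            "ratio": [0.2, 0.8, 0.5, 2.0],
            "swap": [0, 0, 0, 1],
            "category": ["large"] * 4,
        }
    ).to_csv(p, sep="\t", index=False)
    (rec,) = read_site_table(p)
    by_rep = {r.replicate: r.ratio for r in rec.replicate_ratios}
    assert by_rep["1"] == pytest.approx(0.4)   # log2 median of 0.2, 0.8
    assert by_rep["3"] == pytest.approx(0.5)   # swap replicate re-oriented
    s = summarize_site(rec)
    assert s.n_reps == 3


def test_ci_coverage_is_calibrated_on_null_sites():
    """Across 1000 null sites the t-based 95% CI covers the true log2 ratio
    (zero) in 95% +/- 2% of cases."""
    cfg = SimConfig(seed=42, n_sites=1000, frac_affected=0.0)
    table, _ = make_glygly_table(cfg)
    covered = 0
    total = 0
    for (prot, pos), grp in table.groupby(["protein", "position"]):
        rec = GlyGlySiteRecord(
            protein=prot, position=int(pos), category="other",
            replicate_ratios=[
                ReplicateRatio(str(r["replicate"]), r["ratio"], bool(r["swap"]))
                for _, r in grp.iterrows()
            ],
        )
        s = summarize_site(rec)
        total += 1
        if s.ci95_low <= 0.0 <= s.ci95_high:
            covered += 1
    assert total == 1000
    assert covered / total == pytest.approx(0.95, abs=0.02)


def test_planted_fourfold_sites_recovered_with_high_sensitivity_low_fpr():
    """Sites planted at a 4-fold occupancy decrease (0.3 log2-units replicate
    noise, 3 replicates) are flagged with sensitivity >= 0.95 and null sites
    stay below a 5% false-positive rate, across 10 seeds."""
    sens, fpr = [], []
    for seed in range(10):
        cfg = SimConfig(seed=seed, n_sites=1000)
        table, truth = make_glygly_table(cfg)
        recs = []
        for (prot, pos), grp in table.groupby(["protein", "position"]):
            recs.append(
                GlyGlySiteRecord(
                    protein=prot, position=int(pos), category=grp["category"].iloc[0],
                    replicate_ratios=[
                        ReplicateRatio(str(r["replicate"]), r["ratio"], bool(r["swap"]))
                        for _, r in grp.iterrows()
                    ],
                )
            )
        out = summarize_table(recs).merge(truth, on=["protein", "position"])
        aff = out[out["affected"]]
        nul = out[~out["affected"]]
        sens.append(aff["decreased_2x"].mean())
        fpr.append(nul["decreased_2x"].mean())
    assert np.mean(sens) >= 0.95
    assert np.mean(fpr) <= 0.05
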