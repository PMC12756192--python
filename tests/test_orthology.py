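"""Orthogroup parsing, LDO/concordance logic, and the conjecture fit/binning."""

import numpy as np
import pandas as pd
import pytest

from conftest import ols_closed_form
from plmsim import (
    ConcordanceRecord,
    OrthologGroup,
    bin_summary,
    classify_relationships,
    concordance,
    concordance_summary,
    find_ldo,
    fit_and_flag_outliers,
    fit_by_category,
    read_ortholog_table,
    write_ortholog_table,
)
from plmsim.synthetic import SyntheticOrthoSpec, gen_ortholog_table


def make_group(na, nb, gid="g"):
    return OrthologGroup(
        group_id=gid,
        species_a="A",
        species_b="B",
        members_a=tuple(f"a{i}" for i in range(na)),
        members_b=tuple(f"b{i}" for i in range(nb)),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "na,nb,expected",
        [
            (1, 1, "one-to-one"),
            (1, 2, "one-to-two"),
            (2, 1, "one-to-two"),
            (1, 3, "one-to-many"),
            (5, 1, "one-to-many"),
            (3, 2, "many-to-many"),
            (2, 2, "many-to-many"),
        ],
    )
    def test_category_from_member_counts(self, na, nb, expected):
        assert classify_relationships(make_group(na, nb)) == expected

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            make_group(0, 2)


class TestTableIO:
    def test_round_trip_preserves_groups(self, tmp_path):
        data = gen_ortholog_table(
            SyntheticOrthoSpec(n_one_to_one=3, n_one_to_two=3, n_many_to_many=2, seed=4)
        )
        path = tmp_path / "orthologs.tsv"
        write_ortholog_table(path, data.groups)
        back = read_ortholog_table(path)
        assert back == data.groups

    def test_one_species_groups_are_filtered(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "group_id\tspecies\tprotein_id\n"
            "g1\tA\ta1\ng1\tB\tb1\n"
            "g2\tA\ta2\ng2\tA\ta3\n"  # single-species group: dropped
        )
        groups = read_ortholog_table(path)
        assert [g.group_id for g in groups] == ["g1"]

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "group_id\tspecies\tprotein_id\n"
            "g1\tA\ta1\ng1\tB\tb1\n"
            "g1\tB\t\n"  # missing protein id
        )
        groups = read_ortholog_table(path)
        assert groups[0].members_b == ("b1",)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("group_id\tspecies\tprotein_id\n")
        with pytest.raises(ValueError):
            read_ortholog_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("group_id\tprotein_id\ng1\ta1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_ortholog_table(path)


class TestLDO:
    def test_highest_identity_wins(self):
        """The less diverged of two co-orthologs (37.85% vs 35.14%) is the LDO."""
        ldo, tied = find_ldo(
            "CDS1_YEAST",
            ["CDS1_HUMAN", "CDS2_HUMAN"],
            {"CDS1_HUMAN": 37.85, "CDS2_HUMAN": 35.14},
        )
        assert ldo == "CDS1_HUMAN"
        assert not tied

    def test_exact_tie_reported(self):
        ldo, tied = find_ldo("s", ["x", "y"], {"x": 50.0, "y": 50.0})
        assert ldo is None
        assert tied

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            find_ldo("s", ["x"], {"x": 50.0})

    def test_missing_identity_reported(self):
        with pytest.raises(KeyError, match="missing identity"):
            find_ldo("s", ["x", "y"], {"x": 50.0})


class TestConcordance:
    def test_agreeing_metrics_are_concordant(self):
        group = make_group(1, 2)
        rec = concordance(group, {"b0": 60.0, "b1": 40.0}, {"b0": 0.9, "b1": 0.7})
        assert rec.status == "concordant"
        assert rec.ldo_id == rec.embedding_top_id == "b0"

    def test_disagreeing_metrics_are_discordant(self):
        """Identity prefers one paralog, embeddings the other (the CDS pattern)."""
        group = make_group(1, 2)
        rec = concordance(group, {"b0": 37.85, "b1": 35.14}, {"b0": 0.80, "b1": 0.85})
        assert rec.status == "discordant"
        assert rec.ldo_id == "b0"
        assert rec.embedding_top_id == "b1"

    def test_tie_in_either_metric_is_tied(self):
        group = make_group(1, 2)
        rec = concordance(group, {"b0": 50.0, "b1": 50.0}, {"b0": 0.9, "b1": 0.7})
        assert rec.status == "tied"

    def test_wrong_category_rejected(self):
        with pytest.raises(ValueError, match="one-to-two"):
            concordance(make_group(1, 3), {}, {})

    def test_summary_fractions(self):
        recs = [
            ConcordanceRecord("g1", "s", "a", "a", "concordant"),
            ConcordanceRecord("g2", "s", "a", "a", "concordant"),
            ConcordanceRecord("g3", "s", "a", "b", "discordant"),
        ]
        summary = concordance_summary(recs)
        assert summary["concordant"] == pytest.approx(2 / 3)
        assert sum(summary.values()) == pytest.approx(1.0)

    def test_all_tied_summary(self):
        recs = [ConcordanceRecord("g1", "s", None, None, "tied")]
        summary = concordance_summary(recs)
        assert summary == {"concordant": 0.0, "discordant": 0.0, "tied": 1.0}

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            concordance_summary([])

    def test_concordant_fraction_tracks_planted_rate(self):
        """discordance_rate 0.3 at low noise: recovered fraction matches the
        planted truth exactly, and the planting is a plausible Binomial(n, 0.3)
        draw (exact binomial test)."""
        from scipy import stats

        from plmsim import concordance_from_records

        n = 300
        data = gen_ortholog_table(
            SyntheticOrthoSpec(n_one_to_two=n, discordance_rate=0.3, noise_sd=0.005, seed=6)
        )
        summary = concordance_summary(concordance_from_records(data.groups, data.records))
        n_planted = int(data.group_truth["planted_discordant"].sum())
        assert summary["discordant"] == pytest.approx(n_planted / n)
        assert stats.binomtest(n_planted, n, 0.3).pvalue > 1e-3


def make_points(rng, n=200, slope=0.005, intercept=0.3, noise=0.01):
    x = rng.uniform(20, 95, size=n)
    y = intercept + slope * x + noise * rng.standard_normal(n)
    return pd.DataFrame(
        {"pair_id": [f"p{i}" for i in range(n)], "identity_pct": x, "similarity": y}
    )


class TestOutlierFit:
    def test_points_on_exact_line_flag_nothing(self):
        df = pd.DataFrame(
            {
                "pair_id": ["a", "b", "c", "d"],
                "identity_pct": [10.0, 20.0, 30.0, 40.0],
                "similarity": [0.1, 0.2, 0.3, 0.4],
            }
        )
        fit = fit_and_flag_outliers(df)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.flagged_ids == ()

    def test_single_ten_sd_offset_point_flagged_alone(self, rng):
        """One point 10 noise-SDs below a noisy line is the only flag."""
        df = make_points(rng, n=200, noise=0.01)
        outlier = pd.DataFrame(
            {"pair_id": ["planted"], "identity_pct": [55.0], "similarity": [0.3 + 0.005 * 55 - 0.1]}
        )
        fit = fit_and_flag_outliers(pd.concat([df, outlier], ignore_index=True))
        assert fit.flagged_ids == ("planted",)

    def test_ols_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            df = make_points(rng, n=int(rng.integers(5, 40)))
            fit = fit_and_flag_outliers(df)
            slope, intercept = ols_closed_form(df["identity_pct"], df["similarity"])
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_residual_sd_uses_n_minus_two(self, rng):
        df = make_points(rng, n=50)
        fit = fit_and_flag_outliers(df)
        resid = df["similarity"] - (fit.slope * df["identity_pct"] + fit.intercept)
        assert fit.residual_sd == pytest.approx(np.sqrt((resid**2).sum() / 48), abs=1e-12)

    def test_flags_invariant_to_identity_shift(self, rng):
        df = make_points(rng, n=100)
        df.loc[0, "similarity"] -= 0.2
        flagged_before = fit_and_flag_outliers(df).flagged_ids
        shifted = df.assign(identity_pct=df["identity_pct"] + 13.0)
        assert fit_and_flag_outliers(shifted).flagged_ids == flagged_before

    def test_too_few_points_rejected(self):
        df = pd.DataFrame(
            {"pair_id": ["a", "b"], "identity_pct": [1.0, 2.0], "similarity": [0.0, 0.1]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            fit_and_flag_outliers(df)

    def test_zero_identity_variance_rejected(self):
        df = pd.DataFrame(
            {"pair_id": list("abc"), "identity_pct": [5.0] * 3, "similarity": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="variance"):
            fit_and_flag_outliers(df)

    def test_fit_by_category_fits_each_separately(self, rng):
        df_a = make_points(rng, n=50).assign(category="one-to-one")
        df_b = make_points(rng, n=50, intercept=0.5).assign(category="many-to-many")
        fits = fit_by_category(pd.concat([df_a, df_b], ignore_index=True))
        assert set(fits) == {"one-to-one", "many-to-many"}
        assert fits["one-to-one"].intercept != fits["many-to-many"].intercept


class TestBinSummary:
    def test_point_lands_in_half_open_bin(self):
        df = pd.DataFrame({"pair_id": ["a"], "identity_pct": [35.0], "similarity": [0.5]})
        out = bin_summary(df, bin_width=10)
        assert (out.loc[0, "bin_lo"], out.loc[0, "bin_hi"]) == (30.0, 40.0)

    def test_identity_100_falls_in_last_bin(self):
        df = pd.DataFrame({"pair_id": ["a"], "identity_pct": [100.0], "similarity": [0.9]})
        out = bin_summary(df, bin_width=10)
        assert (out.loc[0, "bin_lo"], out.loc[0, "bin_hi"]) == (90.0, 100.0)

    def test_uniform_points_spread_over_bins(self, rng):
        """Counts from uniform identities pass a chi-square sanity check."""
        from scipy import stats

        n = 2000
        df = pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "identity_pct": rng.uniform(0, 100, size=n),
                "similarity": rng.uniform(0, 1, size=n),
            }
        )
        out = bin_summary(df, bin_width=10)
        counts = out["count"].to_numpy()
        assert counts.sum() == n
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4

    def test_nonpositive_width_rejected(self):
        df = pd.DataFrame({"pair_id": ["a"], "identity_pct": [1.0], "similarity": [0.1]})
        with pytest.raises(ValueError):
            bin_summary(df, bin_width=0)

    def test_mean_and_median_reported_per_bin(self):
        df = pd.DataFrame(
            {
                "pair_id": ["a", "b", "c"],
                "identity_pct": [31.0, 35.0, 39.0],
                "similarity": [0.2, 0.4, 0.9],
            }
        )
        out = bin_summary(df, bin_width=10)
        assert out.loc[0, "count"] == 3
        assert out.loc[0, "mean_similarity"] == pytest.approx(0.5)
        assert out.loc[0, "median_similarity"] == pytest.approx(0.4)
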