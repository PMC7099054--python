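"""Repertoire statistics: skewness, Gini, hypomutation, usage, motifs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcrpipe import stats
from bcrpipe.stats import (
    clonotype_frequencies,
    clonotype_table,
    gini_index,
    mean_mutations,
    motif_intact_pct,
    mutation_distribution,
    pct_hypomutated,
    skewness,
    v_gene_usage,
)


_BASE = {
    "donor_id": "d",
    "compartment": "blood",
    "isotype": "IgG",
    "duplicate_count": 1,
    "v_call": "IGHV1-2*01",
    "junction_aa": "CARW",
}


def _records(rows):
    if not rows:
        return pd.DataFrame(columns=list(_BASE) + ["sequence_id", "v_mutation_count"])
    return pd.DataFrame([{**_BASE, **row} for row in rows])


def gini_mean_absolute_difference(counts):
    """Independent Gini oracle: half the mean absolute difference divided by
    the mean, G = sum_ij |y_i - y_j| / (2 n^2 ybar)."""
    y = np.asarray(counts, dtype=float)
    n = y.size
    return float(np.abs(y[:, None] - y[None, :]).sum() / (2 * n * n * y.mean()))


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # n=4: G1 = sqrt(12)/2 * m3/m2^1.5 evaluates to exactly 2
        assert skewness([0, 0, 0, 1]) == pytest.approx(2.0)

    def test_sign_flips_under_negation(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, size=50)
        assert skewness(-x) == pytest.approx(-skewness(x))

    def test_degenerate_inputs(self):
        assert skewness([1, 2]) is None
        assert skewness([3, 3, 3, 3]) is None

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        values=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda v: round(v, 2)
            ),
            min_size=3,
            max_size=40,
        )
    )
    def test_matches_pandas_adjusted_fisher_pearson(self, values):
        expected = pd.Series(values).skew()
        result = skewness(values)
        if result is None:
            assert not np.isfinite(expected) or expected == 0.0
        else:
            assert result == pytest.approx(float(expected), abs=1e-9)

    def test_weighted_equals_expanded(self):
        values = [0, 2, 7, 11]
        weights = [3, 1, 2, 5]
        expanded = np.repeat(values, weights)
        assert skewness(values, weights) == pytest.approx(skewness(expanded))


class TestGini:
    def test_equal_counts_give_zero(self):
        assert gini_index([5, 5, 5, 5]) == 0.0

    def test_hand_computed_two_clonotypes(self):
        assert gini_index([1, 9]) == pytest.approx(0.4)

    def test_single_clonotype_is_zero(self):
        assert gini_index([42]) == pytest.approx(0.0)

    def test_empty_is_undefined(self):
        assert gini_index([]) is None

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(1, 100, size=30)
        assert gini_index(y * 7) == pytest.approx(gini_index(y), abs=1e-12)

    def test_transfer_increases_inequality(self):
        y = [10, 10, 10, 10]
        assert gini_index([19, 1, 10, 10]) > gini_index(y)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        counts=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                        max_size=100)
    )
    def test_agrees_with_mean_absolute_difference_oracle(self, counts):
        assert gini_index(counts) == pytest.approx(
            gini_mean_absolute_difference(counts), abs=1e-9
        )


class TestHypomutation:
    def test_strictly_below_threshold(self):
        records = _records(
            [{"sequence_id": str(i), "v_mutation_count": c}
             for i, c in enumerate([0, 1, 4, 5, 6])]
        )
        assert pct_hypomutated(records) == pytest.approx(60.0)

    def test_all_hypermutated_is_zero(self):
        records = _records(
            [{"sequence_id": str(i), "v_mutation_count": c}
             for i, c in enumerate([5, 9, 30])]
        )
        assert pct_hypomutated(records) == 0.0

    def test_threshold_extremes(self):
        records = _records(
            [{"sequence_id": str(i), "v_mutation_count": c}
             for i, c in enumerate([0, 3, 12])]
        )
        assert pct_hypomutated(records, threshold=0) == 0.0
        assert pct_hypomutated(records, threshold=10**6) == 100.0

    def test_read_weighting(self):
        records = _records(
            [
                {"sequence_id": "a", "v_mutation_count": 0, "duplicate_count": 9},
                {"sequence_id": "b", "v_mutation_count": 10, "duplicate_count": 1},
            ]
        )
        assert pct_hypomutated(records) == pytest.approx(90.0)

    def test_empty_selection_undefined(self):
        assert pct_hypomutated(_records([]), isotype="IgG") is None

    def test_simulated_donor_near_preset_target(self, era_sim_small,
                                                era_records_small):
        """Pipeline-recovered hypomutated fraction sits within 3 binomial SE
        (variant-level) of the ERA mixture target."""
        from bcrpipe.simulate import PRESETS

        target = 100 * PRESETS["ERA"].shm_mixture.hypo_mass()
        n = era_sim_small.truth["variant_id"].nunique()
        se = 100 * np.sqrt((target / 100) * (1 - target / 100) / n)
        assert abs(pct_hypomutated(era_records_small) - target) < 3 * se


class TestDistributionsAndClonotypes:
    def test_read_weighted_histogram(self):
        records = _records(
            [
                {"sequence_id": "a", "v_mutation_count": 0, "duplicate_count": 2},
                {"sequence_id": "b", "v_mutation_count": 3},
            ]
        )
        hist = mutation_distribution(records)
        assert hist.to_dict() == {0: 2, 3: 1}

    def test_clone_weighted_uses_mean_per_clonotype(self):
        records = _records(
            [
                {"sequence_id": "a", "v_mutation_count": 2, "junction_aa": "CAAAW"},
                {"sequence_id": "b", "v_mutation_count": 4, "junction_aa": "CAAAW"},
                {"sequence_id": "c", "v_mutation_count": 7, "junction_aa": "CCCCW"},
            ]
        )
        hist = mutation_distribution(records, weighting="clone")
        assert hist.to_dict() == {3.0: 1, 7.0: 1}

    def test_clonotype_table_groups_by_cdr3_and_allele(self):
        records = _records(
            [
                {"sequence_id": "a", "junction_aa": "CAW", "v_mutation_count": 1},
                {"sequence_id": "b", "junction_aa": "CAW", "v_mutation_count": 1,
                 "duplicate_count": 4},
                {"sequence_id": "c", "junction_aa": "CAW", "v_call": "IGHV3-7*01",
                 "v_mutation_count": 1},
            ]
        )
        table = clonotype_table(records)
        assert len(table) == 2
        assert sorted(table["read_count"]) == [1, 5]

    def test_clonotype_frequencies_sum_and_flag(self):
        table = pd.DataFrame(
            {"junction_aa": ["a", "b", "c"], "v_call": ["v"] * 3,
             "read_count": [10, 10, 80]}
        )
        freq = clonotype_frequencies(table)
        assert freq["frequency_pct"].sum() == pytest.approx(100.0)
        assert list(freq["frequency_pct"]) == [10.0, 10.0, 80.0]
        assert list(freq["dominant"]) == [True, True, True]
        singletons = clonotype_frequencies(
            pd.DataFrame(
                {
                    "junction_aa": [f"c{i}" for i in range(300)],
                    "v_call": ["v"] * 300,
                    "read_count": [1] * 300,
                }
            )
        )
        assert not singletons["dominant"].any()
        assert singletons["frequency_pct"].iloc[0] == pytest.approx(100 / 300)

    def test_simulated_dominant_clonotype_flagged(self, era_records_small):
        table = clonotype_table(era_records_small)
        freq = clonotype_frequencies(table)
        assert freq["dominant"].any()


class TestUsageAndMotifs:
    def test_usage_fraction(self):
        rows = [{"sequence_id": str(i), "v_mutation_count": 0} for i in range(975)]
        rows += [
            {"sequence_id": f"x{i}", "v_call": "IGHV4-34*01", "v_mutation_count": 0}
            for i in range(25)
        ]
        assert v_gene_usage(_records(rows), "IGHV4-34") == pytest.approx(2.5)

    def test_absent_gene_is_zero(self):
        records = _records([{"sequence_id": "a", "v_mutation_count": 0}])
        assert v_gene_usage(records, "IGHV7-81") == 0.0

    def test_family_breakdown(self):
        records = _records(
            [
                {"sequence_id": "a", "v_call": "IGHV1-2*01", "v_mutation_count": 2},
                {"sequence_id": "b", "v_call": "IGHV1-18*01", "v_mutation_count": 4},
                {"sequence_id": "c", "v_call": "IGHV3-7*01", "v_mutation_count": 10},
            ]
        )
        breakdown = stats.family_mean_mutations(records)
        assert breakdown["IGHV1"] == pytest.approx(3.0)
        assert breakdown["IGHV3"] == pytest.approx(10.0)

    def test_motif_intact_percentage(self):
        rows = [
            {"sequence_id": str(i), "v_call": "IGHV4-34*01", "v_mutation_count": 0,
             "motif_avy_intact": intact, "motif_nhs_intact": True}
            for i, intact in enumerate([True, True, True, False])
        ]
        records = _records(rows).astype(
            {"motif_avy_intact": "boolean", "motif_nhs_intact": "boolean"}
        )
        assert motif_intact_pct(records, "IgG", "AVY") == pytest.approx(75.0)
        assert motif_intact_pct(records, "IgG", "NHS") == pytest.approx(100.0)

    def test_no_v4_34_reads_undefined(self):
        records = _records(
            [{"sequence_id": "a", "v_mutation_count": 0,
              "motif_avy_intact": pd.NA, "motif_nhs_intact": pd.NA}]
        ).astype({"motif_avy_intact": "boolean", "motif_nhs_intact": "boolean"})
        assert motif_intact_pct(records, "IgG", "AVY") is None

    def test_planted_disruption_rate_recovered(self, reference):
        """Simulated IGHV4-34 reads with forced AVY disruptions at a 50% rate
        come back with roughly half the motifs intact."""
        from bcrpipe.pipeline import process_simulation
        from bcrpipe.simulate import get_preset, simulate_donor

        preset = get_preset(
            "ERA", v4_34_usage=0.5, motif_disruption_rate=0.5, n_reads=1500
        )
        sim = simulate_donor(preset, seed=21, reference=reference)
        records, _ = process_simulation(sim, reference)
        pct = motif_intact_pct(records, "IgG", "AVY")
        # forced disruptions plus occasional random motif hits push intactness
        # below ~55%; random hits alone would stay near 90%+
        assert 30.0 < pct < 60.0


class TestTargetingProfile:
    def test_unmutated_profile_is_zero(self, reference):
        records = _records([])
        profile = stats.mutation_targeting_profile(records, reference)
        assert not profile.any()

    def test_single_position_spike(self, reference):
        allele = reference["IGHV3-23*01"]
        germ = allele.nt_sequence
        mutated = list(germ)
        mutated[50] = "A" if germ[50] != "A" else "C"
        seq = "".join(mutated) + "GCTGATGAA"
        records = _records(
            [
                {
                    "sequence_id": "a",
                    "v_call": allele.allele_name,
                    "v_mutation_count": 1,
                    "sequence": seq,
                    "v_sequence_start": 0,
                    "v_sequence_end": len(germ),
                }
            ]
        )
        profile = stats.mutation_targeting_profile(records, reference)
        assert profile[50] > 0
        assert (np.delete(profile, 50) == 0).all()

    def test_uniform_planting_gives_flat_profile(self, reference,
                                                 era_records_small):
        profile = stats.mutation_targeting_profile(era_records_small, reference)
        inner = profile[:290]
        # uniform planting: no position should dominate
        assert inner.max() < 5 * inner.mean()


class TestSummary:
    def test_summary_fields_populated(self, era_records_small):
        summary = stats.summarize_repertoire(era_records_small, "era", "IgG")
        assert summary.total_reads == 2000
        assert 0 <= summary.gini < 1
        assert 0 <= summary.pct_hypomutated <= 100
        assert summary.mean_mutations > 5
        assert summary.skewness is not None
        assert summary.max_clonotype_freq > 0.5
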