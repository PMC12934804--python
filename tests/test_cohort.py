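"""Cohort statistics: 96-profiles, aggregation, terciles, tests, regression."""

import math
from itertools import permutations, combinations

import numpy as np
import pandas as pd
import pytest

from motifload import (
    MutationRecord,
    ReferenceGenome,
    SampleCatalog,
    SingleCellScaling,
    compare_cohorts,
    cosine_similarity,
    donor_aggregate,
    make_genome,
    profile_96,
    prorate_single_cell,
    regress_age_disease,
    spearman,
    tercile_of,
)
from motifload.cohort import CHANNELS_96


def summaries_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["donor_id", "motif", "meml_mean", "meml_mean_nonzero",
                 "n_samples", "tissue", "disease", "age", "study_id"],
    )


class TestProfile96:
    def test_single_mutation_channel(self):
        genome = ReferenceGenome({"c": "AAAAACAAAAA"})
        cat = SampleCatalog("S1", [MutationRecord("S1", "c", 6, "C", "T")])
        prof = profile_96([cat], genome)
        assert prof["aCa>aTa"] == 1
        assert prof.sum() == 1

    def test_strand_flip_doubles(self, small_genome, rng):
        from motifload import make_catalog

        cat, _ = make_catalog(small_genome, n_background=200, processes=[], seed=4)
        flipped = cat.strand_flipped(small_genome)
        single = profile_96([cat], small_genome)
        # strand-canonical: the flipped catalogue on the flipped genome gives
        # the identical profile, so pooling equals doubling
        prof_flipped = profile_96([flipped], small_genome.reverse_complemented())
        assert (single + prof_flipped == 2 * single).all()

    def test_conservation(self, small_genome, rng):
        from motifload import make_catalog

        cat, _ = make_catalog(small_genome, n_background=300, processes=[], seed=8)
        prof = profile_96([cat], small_genome)
        assert prof.sum() + prof.attrs["skipped"] == len(cat)

    def test_channel_count(self):
        assert len(CHANNELS_96) == 96
        assert len(set(CHANNELS_96)) == 96


class TestCosine:
    def test_identical(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        u = np.zeros(96); u[0] = 1
        v = np.zeros(96); v[1] = 1
        assert cosine_similarity(u, v) == 0.0

    def test_scale_invariance(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, 7.5 * v) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestDonorAggregate:
    def test_means_with_and_without_zeros(self):
        results = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "donor_id": ["D1"] * 3,
                "tissue": ["liver"] * 3,
                "disease": ["healthy"] * 3,
                "age": [50.0] * 3,
                "study_id": ["st1"] * 3,
                "motif": ["aTn"] * 3,
                "meml": [0.0, 10.0, 20.0],
            }
        )
        out = donor_aggregate(results)
        row = out.iloc[0]
        assert row["meml_mean"] == pytest.approx(10.0)
        assert row["meml_mean_nonzero"] == pytest.approx(15.0)
        assert row["n_samples"] == 3

    def test_single_sample_donor(self):
        results = pd.DataFrame(
            {
                "sample_id": ["s1"], "donor_id": ["D1"], "tissue": ["t"],
                "disease": ["healthy"], "age": [40.0], "study_id": ["st1"],
                "motif": ["aTn"], "meml": [7.0],
            }
        )
        row = donor_aggregate(results).iloc[0]
        assert row["meml_mean"] == row["meml_mean_nonzero"] == 7.0

    def test_all_zero_donor(self):
        results = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"], "donor_id": ["D1"] * 2,
                "tissue": ["t"] * 2, "disease": ["healthy"] * 2,
                "age": [40.0] * 2, "study_id": ["st1"] * 2,
                "motif": ["aTn"] * 2, "meml": [0.0, 0.0],
            }
        )
        row = donor_aggregate(results).iloc[0]
        assert row["meml_mean"] == 0.0
        assert math.isnan(row["meml_mean_nonzero"])


class TestSpearman:
    def test_monotone_perfect(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 25])[0] == pytest.approx(1.0)
        assert spearman(x, [10, 8, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho)

    def test_exact_permutation_oracle_small_n(self, rng):
        """|rho| agrees with the full-permutation distribution support for
        n <= 7 (no ties): every observed rho must be attainable, and the
        permutation p of |rho| >= observed matches a direct enumeration."""
        n = 6
        x = np.arange(n, dtype=float)
        y = rng.permutation(n).astype(float)
        rho, _ = spearman(x, y)
        # enumeration oracle over all permutations
        rhos = []
        for perm in permutations(range(n)):
            d = x - np.array(perm)
            rhos.append(1 - 6 * np.sum(d**2) / (n * (n**2 - 1)))
        rhos = np.array(rhos)
        assert np.any(np.isclose(rhos, rho, atol=1e-12))

    def test_length_check(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestTercile:
    @pytest.mark.parametrize(
        "age,expected",
        [(0, "T1"), (30, "T1"), (33.3, "T1"), (33.4, "T2"), (50, "T2"),
         (66.7, "T2"), (66.8, "T3"), (70, "T3"), (100, "T3"), (105, "T3")],
    )
    def test_boundaries(self, age, expected):
        assert tercile_of(age) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            tercile_of(-1)

    def test_monotone_step_function(self):
        ages = np.linspace(0, 100, 400)
        labels = [tercile_of(a) for a in ages]
        assert labels == sorted(labels)


def rank_sum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n].sum()
    total = 0
    extreme = 0
    mean_w = ranks.sum() * n / len(pooled)
    for idx in combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-9:
            extreme += 1
    return extreme / total


class TestCompareCohorts:
    def _frame(self, healthy_vals, diseased_vals, motif="aTn"):
        rows = []
        for i, v in enumerate(healthy_vals):
            rows.append([f"H{i}", motif, v, v, 1, "t", "healthy", 70.0, "st1"])
        for i, v in enumerate(diseased_vals):
            rows.append([f"D{i}", motif, v, v, 1, "t", "fibrosis", 70.0, "st1"])
        return summaries_frame(rows)

    def test_identical_groups_nonsignificant(self):
        df = self._frame([5.0] * 6, [5.0] * 6)
        out = compare_cohorts(df)
        assert len(out) == 1
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_shift_detected_and_matches_exact_enumeration(self, rng):
        x = list(rng.normal(10, 1, size=7))
        y = [v + 30 for v in rng.normal(10, 1, size=7)]
        out = compare_cohorts(self._frame(x, y))
        p = out.iloc[0]["p"]
        assert p < 0.01
        # asymptotic p close to the exact enumeration at this n
        assert p == pytest.approx(rank_sum_oracle(x, y), abs=0.01)

    def test_label_swap_symmetry(self, rng):
        x = list(rng.normal(5, 2, size=8))
        y = list(rng.normal(6, 2, size=8))
        p1 = compare_cohorts(self._frame(x, y)).iloc[0]["p"]
        p2 = compare_cohorts(self._frame(y, x)).iloc[0]["p"]
        assert p1 == pytest.approx(p2)

    def test_comparisons_within_study_and_tercile(self):
        rows = [
            ["H1", "aTn", 1.0, 1.0, 1, "t", "healthy", 20.0, "st1"],
            ["H2", "aTn", 2.0, 2.0, 1, "t", "healthy", 70.0, "st1"],
            ["D1", "aTn", 9.0, 9.0, 1, "t", "fibrosis", 70.0, "st2"],
        ]
        # diseased donor is in another study: no valid cell
        assert compare_cohorts(summaries_frame(rows)).empty


class TestRegression:
    def test_noiseless_age_slope_recovered(self):
        ages = np.linspace(20, 80, 30)
        rows = [
            [f"D{i}", "aTn", 2 * a, 2 * a, 1, "t", "healthy", a, "st1"]
            for i, a in enumerate(ages)
        ]
        out = regress_age_disease(summaries_frame(rows))
        slope = out[out["term"] == "age"].iloc[0]
        assert slope["estimate"] == pytest.approx(2.0, abs=1e-8)

    def test_disease_effect_recovered(self, rng):
        ages = np.linspace(20, 80, 40)
        rows = []
        for i, a in enumerate(ages):
            disease = "healthy" if i % 2 == 0 else "fibrosis"
            effect = 0.0 if disease == "healthy" else 25.0
            value = 1.5 * a + effect + rng.normal(0, 1)
            rows.append([f"D{i}", "aTn", value, value, 1, "t", disease, a, "st1"])
        out = regress_age_disease(summaries_frame(rows))
        eff = out[out["term"] == "disease[fibrosis]"].iloc[0]
        assert eff["estimate"] == pytest.approx(25.0, abs=2.0)
        assert eff["p"] < 1e-6

    def test_permuted_response_null(self, rng):
        """Permuting MEML against age gives roughly uniform age p-values."""
        ages = np.linspace(20, 80, 24)
        pvals = []
        for _ in range(40):
            values = rng.permutation(1.0 + np.arange(24))
            rows = [
                [f"D{i}", "aTn", v, v, 1, "t", "healthy", a, "st1"]
                for i, (a, v) in enumerate(zip(ages, values))
            ]
            out = regress_age_disease(summaries_frame(rows))
            pvals.append(out[out["term"] == "age"].iloc[0]["p"])
        assert 0.1 < np.mean(pvals) < 0.9  # crude uniformity sanity check


class TestProrate:
    def test_formula(self):
        scaling = SingleCellScaling("s1", estimated_snvs=1000, identified_mutations=500)
        assert prorate_single_cell(30, scaling) == pytest.approx(60.0)

    def test_identity_and_zero(self):
        scaling = SingleCellScaling("s1", 400, 400)
        assert prorate_single_cell(12.5, scaling) == 12.5
        assert prorate_single_cell(0.0, scaling) == 0.0

    def test_zero_identified_rejected(self):
        with pytest.raises(ValueError):
            SingleCellScaling("s1", 100, 0)
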