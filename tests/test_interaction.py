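import itertools
from collections import Counter
from math import comb

import numpy as np
import pandas as pd
import pytest

from plasmaclust import (
    ComparisonSpec,
    generate_cohort,
    CohortConfig,
    mannwhitney,
    normalize_volumes,
    permute_membership,
    run_all,
    run_comparison,
)


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        assert mannwhitney([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_complete_separation_matches_exact_enumeration(self):
        # U = 0; with n=m=4 there are C(8,4)=70 orderings and the two-sided
        # exact p is 2 * P(U <= 0) = 2/70
        p = mannwhitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2.0 / comb(8, 4))

    def test_exact_p_matches_full_enumeration_for_small_samples(self, rng):
        a = rng.normal(size=4)
        b = rng.normal(size=3) + 0.5
        observed_u = sum((x > y) for x in a for y in b)
        n_a = len(a)
        pooled = np.concatenate([a, b])
        us = []
        for combo in itertools.combinations(range(7), n_a):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(7) if i not in combo]]
            us.append(sum((x > y) for x in ga for y in gb))
        us = np.asarray(us)
        p_lo = np.mean(us <= observed_u)
        p_hi = np.mean(us >= observed_u)
        expected = min(1.0, 2 * min(p_lo, p_hi))
        assert mannwhitney(a, b) == pytest.approx(expected)

    def test_type_one_error_calibrated(self, rng):
        n_sim = 10_000
        a = rng.normal(size=(n_sim, 12))
        b = rng.normal(size=(n_sim, 12))
        ps = mannwhitney(a, b, axis=-1)
        rate = float((ps < 0.05).mean())
        assert 0.04 < rate < 0.06

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mannwhitney([], [1.0, 2.0])


class TestPermuteMembership:
    def test_preserves_all_cluster_by_diagnosis_cell_counts(self, rng):
        n = 200
        cl = rng.integers(0, 4, n)
        dg = rng.choice(["CN", "MCI", "AD"], n)
        original = Counter(zip(cl, dg))
        for seed in range(50):
            perm = permute_membership(cl, dg, seed=seed)
            assert Counter(zip(perm, dg)) == original

    def test_single_subject_strata_force_identity(self):
        cl = np.array([0, 1, 2])
        dg = np.array(["CN", "MCI", "AD"])  # one subject per stratum
        np.testing.assert_array_equal(permute_membership(cl, dg, seed=0), cl)

    def test_uniform_over_admissible_assignments(self):
        # 6-subject toy: stratum A = subjects 0-3 (clusters 0,0,1,1),
        # stratum B = subjects 4-5 (clusters 0,1).  Admissible label vectors
        # are the distinct within-stratum arrangements: C(4,2) * 2 = 12.
        cl = np.array([0, 0, 1, 1, 0, 1])
        dg = np.array(["A", "A", "A", "A", "B", "B"])
        rng = np.random.default_rng(77)
        counts = Counter()
        n_draws = 12_000
        for _ in range(n_draws):
            counts[tuple(permute_membership(cl, dg, rng=rng))] += 1
        assert len(counts) == 12
        expected = n_draws / 12
        sd = np.sqrt(n_draws * (1 / 12) * (11 / 12))
        for arrangement, count in counts.items():
            assert abs(count - expected) < 4 * sd


class TestRunComparison:
    def test_dominant_observed_p_is_significant(self, rng):
        n = 80
        cl = np.repeat([0, 1], n // 2)
        dg = np.array(["CN", "MCI"] * (n // 2))
        phen = pd.DataFrame({"r": np.where(cl == 0, 0.0, 5.0) + rng.normal(0, .1, n)})
        spec = ComparisonSpec("whole_cluster", 0, "r")
        res = run_comparison(spec, phen, cl, dg, n_perm=99, seed=0)
        assert res.observed_p < res.null_ps.min()
        assert res.significant

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="diagnosis_pair"):
            ComparisonSpec("diagnostic_group", 0, "r")
        with pytest.raises(ValueError, match="scheme"):
            ComparisonSpec("anova", 0, "r")

    def test_empty_group_names_the_comparison(self, rng):
        cl = np.zeros(10, dtype=int)
        dg = np.array(["CN"] * 10)
        phen = pd.DataFrame({"r": rng.normal(size=10)})
        spec = ComparisonSpec("whole_cluster", 0, "r")
        with pytest.raises(ValueError, match="whole_cluster"):
            run_comparison(spec, phen, cl, dg, n_perm=10, seed=0)


@pytest.fixture(scope="module")
def labelled_cohort():
    cfg = CohortConfig(
        n_subjects=180, n_markers=8, n_informative=4, n_clusters=4,
        cluster_proportions=(0.3, 0.25, 0.25, 0.2), n_regions=6,
        n_interaction_regions=2, seed=8)
    cohort = generate_cohort(cfg)
    phen = normalize_volumes(cohort.volumes, cohort.icv)
    return cohort, phen


class TestRunAll:
    def test_whole_cluster_cardinality(self, labelled_cohort):
        cohort, phen = labelled_cohort
        table = run_all(phen, cohort.true_cluster.to_numpy(),
                        cohort.diagnosis.to_numpy(),
                        schemes=("whole_cluster",), n_perm=20, seed=0)
        assert len(table) == 4 * 6  # clusters x regions

    def test_diagnostic_group_cardinality(self, labelled_cohort):
        cohort, phen = labelled_cohort
        table = run_all(phen, cohort.true_cluster.to_numpy(),
                        cohort.diagnosis.to_numpy(),
                        schemes=("diagnostic_group",), n_perm=20, seed=0)
        # clusters x unordered diagnosis pairs x regions, skipped cells kept
        # as rows with a note
        assert len(table) == 4 * 3 * 6

    def test_determinism_of_significant_set(self, labelled_cohort):
        cohort, phen = labelled_cohort
        kwargs = dict(schemes=("diagnostic_interaction",), n_perm=50, seed=4)
        t1 = run_all(phen, cohort.true_cluster.to_numpy(),
                     cohort.diagnosis.to_numpy(), **kwargs)
        t2 = run_all(phen, cohort.true_cluster.to_numpy(),
                     cohort.diagnosis.to_numpy(), **kwargs)
        pd.testing.assert_frame_equal(t1, t2)

    def test_recovers_planted_interaction_regions(self, labelled_cohort):
        cohort, phen = labelled_cohort
        table = run_all(phen, cohort.true_cluster.to_numpy(),
                        cohort.diagnosis.to_numpy(),
                        schemes=("diagnostic_interaction",), n_perm=200, seed=1)
        interacting = table[
            table.phenotype.isin(cohort.interaction_region_ids)
            & (table.diagnosis_or_pair == "AD")]
        others = table[~table.phenotype.isin(cohort.interaction_region_ids)
                       & (table.diagnosis_or_pair == "AD")]
        assert interacting.significant.mean() >= 0.8
        assert others.significant.mean() <= 0.3
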