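import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from isobarrier.core import CompoundTable, ValidationError
from isobarrier.pheromones import (
    AnosimResult,
    anosim,
    bray_curtis_matrix,
    compound_proportions,
    enrichment_screen,
    nmds,
    prefilter_compounds,
)
from isobarrier import synthetic as syn


def _paired_table(andro_amounts, ctrl_amounts, compound="c1"):
    """Five males with paired androconia/hind-wing samples of one compound."""
    rows = []
    for i, (a, c) in enumerate(zip(andro_amounts, ctrl_amounts)):
        rows.append((f"m{i}", "E", "M", "androconia", compound, a))
        rows.append((f"m{i}", "E", "M", "hindwing_control", compound, c))
    return CompoundTable(
        pd.DataFrame(
            rows,
            columns=["individual_id", "taxon", "sex", "region", "compound_id", "amount"],
        )
    )


class TestPrefilter:
    def test_singleton_removed(self, config):
        table = syn.gen_compound_table(config)
        filtered = prefilter_compounds(table, contaminant_list=[])
        singles = [c for c in table.compounds if c.startswith("U")]
        assert singles  # generator injected some
        assert not set(singles) & set(filtered.compounds)

    def test_identity_when_nothing_to_drop(self):
        table = _paired_table([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        filtered = prefilter_compounds(table, contaminant_list=[])
        assert filtered.compounds == table.compounds

    def test_study_counts_53_minus_13(self):
        """53 compounds with 13 flagged/singleton leave 40."""
        rows = []
        for i in range(53):
            comp = f"c{i:02d}"
            n_samples = 1 if 45 <= i < 50 else 6  # 5 singletons
            for j in range(n_samples):
                rows.append((f"m{j}", "E", "M", "androconia", comp, 1.0))
        table = CompoundTable(
            pd.DataFrame(
                rows,
                columns=[
                    "individual_id", "taxon", "sex", "region", "compound_id", "amount",
                ],
            )
        )
        contaminants = [f"c{i:02d}" for i in range(50, 53)] + [
            f"c{i:02d}" for i in range(40, 45)
        ]  # 8 contaminants + 5 singletons = 13 exclusions
        filtered = prefilter_compounds(table, contaminants)
        assert len(table.compounds) == 53
        assert len(filtered.compounds) == 40


class TestEnrichmentScreen:
    def test_identical_regions_not_retained(self):
        table = _paired_table([2, 2, 2, 2, 2], [2, 2, 2, 2, 2])
        res = enrichment_screen(table)
        assert res.retained == []
        assert res.excluded["c1"] == "not_enriched"

    def test_tenfold_enrichment_exact_p(self):
        """n = 5 uniform enrichment: exact one-sided signed-rank p = 1/32."""
        table = _paired_table([10, 20, 30, 40, 50], [1, 2, 3, 4, 5])
        res = enrichment_screen(table)
        assert res.retained == ["c1"]
        p = res.stats.loc[0, "p_signed_rank"]
        assert p == pytest.approx(1 / 32)

    def test_every_compound_has_exactly_one_fate(self, config):
        table = prefilter_compounds(
            syn.gen_compound_table(config), syn.contaminant_compounds(config)
        )
        res = enrichment_screen(table)
        assert set(res.retained) | set(res.excluded) == set(table.compounds)
        assert not set(res.retained) & set(res.excluded)

    def test_synthetic_recovery(self, config):
        table = prefilter_compounds(
            syn.gen_compound_table(config), syn.contaminant_compounds(config)
        )
        res = enrichment_screen(table)
        truth = set(syn.true_pheromones(config))
        retained = set(res.retained)
        non_targets = set(table.compounds) - truth
        assert len(retained & truth) / len(truth) >= 0.9
        assert len(retained - truth) <= max(1, round(0.05 * len(non_targets)))

    def test_scale_invariance(self, config):
        """Rank tests only: multiplying all amounts by 1000 changes nothing."""
        table = prefilter_compounds(
            syn.gen_compound_table(config), syn.contaminant_compounds(config)
        )
        scaled = CompoundTable(table.long.assign(amount=table.long["amount"] * 1000))
        assert enrichment_screen(table).retained == enrichment_screen(scaled).retained

    def test_sample_order_invariance(self, config):
        table = prefilter_compounds(
            syn.gen_compound_table(config), syn.contaminant_compounds(config)
        )
        shuffled = CompoundTable(
            table.long.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        assert enrichment_screen(table).retained == enrichment_screen(shuffled).retained


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        props = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        d = bray_curtis_matrix(props)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_profiles_one(self):
        props = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis_matrix(props).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_worked_case(self):
        # sum|p-q| / sum(p+q) = (0.6 + 0.6) / 2 = 0.6
        props = pd.DataFrame([[0.8, 0.2], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis_matrix(props).loc["a", "b"] == pytest.approx(0.6)

    def test_zero_profile_rejected(self):
        props = pd.DataFrame([[0.0, 0.0], [0.5, 0.5]], index=["a", "b"])
        with pytest.raises(ValidationError):
            bray_curtis_matrix(props)

    def test_matrix_properties(self, config):
        table = prefilter_compounds(
            syn.gen_compound_table(config), syn.contaminant_compounds(config)
        )
        screen = enrichment_screen(table)
        d = bray_curtis_matrix(compound_proportions(table, screen.retained)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestNMDS:
    def test_planar_configuration_near_zero_stress(self, rng):
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = nmds(d, seed=0)
        assert res.stress < 0.01

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        a = nmds(d, seed=3)
        b = nmds(d, seed=3)
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())
        assert a.stress == b.stress

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            nmds(np.array([[0, 1, 2, 3], [0, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]]))

    def test_coordinates_centered(self, rng):
        pts = rng.normal(size=(9, 4))
        res = nmds(squareform(pdist(pts)), seed=1)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_clusters_recovered_from_disjoint_profiles(self):
        cfg = syn.SimulationConfig(seed=77, compound_log_sd=0.2)
        table = prefilter_compounds(
            syn.gen_compound_table(cfg), syn.contaminant_compounds(cfg)
        )
        screen = enrichment_screen(table)
        props = compound_proportions(table, screen.retained)
        d = bray_curtis_matrix(props)
        res = nmds(d, seed=0)
        meta = table.individual_meta().loc[props.index]
        males = meta[meta["sex"] == "M"].index
        coords = res.coordinates.loc[males]
        labels = meta.loc[males, "taxon"]
        # nearest-centroid assignment from the ordination matches taxon labels
        cents = coords.groupby(labels).mean()
        dists = {
            t: np.linalg.norm(coords - cents.loc[t].to_numpy(), axis=1)
            for t in cents.index
        }
        assigned = pd.DataFrame(dists, index=coords.index).idxmin(axis=1)
        assert (assigned == labels).mean() > 0.9


def brute_force_anosim_r(d, labels):
    """Enumerate all label permutations; return observed R and exact p."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) // 2

    def r_for(lab):
        lab = np.asarray(lab)
        between = lab[iu[0]] != lab[iu[1]]
        return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)

    observed = r_for(labels)
    perms = [r_for(p) for p in itertools.permutations(labels)]
    p = sum(r >= observed for r in perms) / len(perms)
    return observed, p


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
        d = squareform(pdist(pts))
        res = anosim(d, ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_small_instance_matches_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        labels = ["a", "a", "a", "b", "b", "b"]
        expected_r, _ = brute_force_anosim_r(d, labels)
        res = anosim(d, labels, n_permutations=999, seed=0)
        assert res.r == pytest.approx(expected_r)

    def test_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        pts = rng.normal(size=(12, 3))
        pts[6:] += 0.8
        d = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        ours = anosim(d, labels, n_permutations=99, seed=0)
        theirs = skbio_anosim(DistanceMatrix(d), labels, permutations=99)
        assert ours.r == pytest.approx(theirs["test statistic"])

    def test_singleton_group_rejected(self, rng):
        d = squareform(pdist(rng.normal(size=(5, 2))))
        with pytest.raises(ValidationError):
            anosim(d, ["a", "a", "a", "a", "b"])

    def test_null_rejection_rate(self):
        """Structureless data: E[R] ~ 0 and rejection rate ~ alpha."""
        rng = np.random.default_rng(42)
        n_reps, n_perm, alpha = 200, 199, 0.05
        rejections, rs = 0, []
        labels = np.array(["a"] * 5 + ["b"] * 5)
        for i in range(n_reps):
            d = squareform(pdist(rng.normal(size=(10, 3))))
            res = anosim(d, labels, n_permutations=n_perm, seed=i)
            rs.append(res.r)
            rejections += res.pvalue <= alpha
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) <= 3 * se
        assert abs(np.mean(rs)) < 0.05
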