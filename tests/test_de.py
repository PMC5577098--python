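import numpy as np
import pytest
from scipy import stats

from pathvote import (
    DEPathway,
    GeneSet,
    GeneSetCollection,
    SimulationConfig,
    map_pathways_to_de,
    screen_de_genes,
    simulate,
)
from pathvote.containers import DataError
from pathvote.de import NoDEPathwayError

from conftest import make_dataset

# Moderated-t oracle: p-values computed with limma 3.58.1 (lmFit + eBayes,
# two-group design) on the fixture produced by _limma_fixture() below.
LIMMA_DF_PRIOR = 2.67054076899
LIMMA_S2_PRIOR = 0.691981753546
LIMMA_P = np.array([
    3.15459065932e-06, 0.395598355777, 0.00647412896509, 4.43535303233e-05,
    0.00545440233721, 0.000968542505732, 2.78215143174e-06, 0.0156327006356,
    0.0683085825207, 4.58784899991e-07, 0.0113045015823, 0.249770406054,
    0.197198373365, 0.446265028536, 0.664368138455, 0.390498196855,
    0.000929776200051, 0.154445655422, 0.814457441751, 0.246440179529,
    0.795004830511, 0.780672327182, 0.0245916812512, 0.414395210467,
    0.145120946395, 0.499357918581, 0.131173594365, 0.976350017664,
    0.0529337179667, 0.0701560350189, 0.35611232728, 0.635173266509,
    0.422565602319, 0.484927349453, 0.59028088672, 0.686550095308,
    0.323764737874, 0.672103187171, 0.80206774921, 0.420175601068,
    0.505373677657, 0.338641140155, 0.353338452432, 0.750334889994,
    0.676641619185, 0.999860699377, 0.0598387263185, 0.0246936327813,
    0.407795275719, 0.382695675239, 0.84509402815, 0.177486403281,
    0.529122105794, 0.999981930632, 0.643274650928, 0.926179200944,
    0.322240886893, 0.698467150547, 0.465519408445, 0.579891332909,
])


def _limma_fixture():
    rng = np.random.default_rng(12345)
    n1, n2, g = 8, 12, 60
    sd = np.exp(rng.normal(0, 0.5, g))
    X = rng.normal(0, 1, (g, n1 + n2)) * sd[:, None]
    X[:10, :n1] += 1.5
    return make_dataset(X, ["pos"] * n1 + ["neg"] * n2)


class TestModeratedT:
    def test_matches_limma_on_heteroscedastic_fixture(self):
        de = screen_de_genes(_limma_fixture(), method="moderated")
        assert de.df_prior == pytest.approx(LIMMA_DF_PRIOR, abs=1e-8)
        assert de.s2_prior == pytest.approx(LIMMA_S2_PRIOR, abs=1e-8)
        np.testing.assert_allclose(de.p_value, LIMMA_P, atol=1e-10)

    def test_constant_gene_never_de(self):
        values = np.vstack([np.ones(10), np.random.default_rng(1).normal(size=10)])
        ds = make_dataset(values, ["pos"] * 5 + ["neg"] * 5)
        for method in ("moderated", "welch"):
            de = screen_de_genes(ds, method=method)
            assert de.p_value[0] == 1.0
            assert not de.is_de[0]

    def test_is_de_matches_alpha_cut(self):
        de = screen_de_genes(_limma_fixture(), alpha=0.05)
        np.testing.assert_array_equal(de.is_de, de.p_value < 0.05)

    def test_welch_agrees_with_scipy(self):
        ds = _limma_fixture()
        de = screen_de_genes(ds, method="welch")
        y = ds.y()
        t, p = stats.ttest_ind(ds.values[:, y], ds.values[:, ~y], axis=1, equal_var=False)
        np.testing.assert_allclose(de.p_value, p, atol=1e-12)

    def test_alpha_monotonicity(self):
        ds = _limma_fixture()
        sets = [set(screen_de_genes(ds, alpha=a).de_genes) for a in (0.01, 0.05, 0.2)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_null_pvalues_uniform(self):
        """Pooled moderated p-values over 50 null datasets pass a KS test."""
        pooled = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_genes=300, n_pathways=5, pathway_size_range=(5, 20),
                n_informative_pathways=0, effect_size=0.0,
                within_pathway_correlation=0.0, n_pos=15, n_neg=15, seed=7000 + seed,
            )
            ds = simulate(cfg)[0]
            pooled.append(screen_de_genes(ds).p_value)
        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01


class TestDEPathwayMapping:
    def _de(self, de_genes, universe):
        p = np.where(np.isin(universe, de_genes), 0.001, 0.9)
        from pathvote.de import DEResult

        return DEResult(
            gene_ids=tuple(universe),
            statistic=np.zeros(len(universe)),
            p_value=p,
            is_de=p < 0.05,
            alpha=0.05,
            method="moderated",
        )

    def test_intersection(self, toy_collection):
        universe = ["g1", "g2", "g3", "g4", "g5", "g6"]
        de = self._de(["g2", "g5"], universe)
        result = map_pathways_to_de(toy_collection, de)
        assert [(dp.pathway_id, dp.feature_genes) for dp in result] == [
            ("pwA", ("g2",)),
            ("pwC", ("g2", "g5")),
        ]

    def test_pathway_without_de_genes_excluded(self, toy_collection):
        universe = ["g1", "g2", "g3", "g4", "g5", "g6"]
        de = self._de(["g1"], universe)
        result = map_pathways_to_de(toy_collection, de)
        assert [dp.pathway_id for dp in result] == ["pwA"]

    def test_saturation_keeps_all_pathways_in_order(self, toy_collection):
        universe = ["g1", "g2", "g3", "g4", "g5", "g6"]
        de = self._de(universe, universe)
        result = map_pathways_to_de(toy_collection, de)
        assert [dp.pathway_id for dp in result] == ["pwA", "pwB", "pwC"]
        assert result[0].feature_genes == ("g1", "g2", "g3")

    def test_no_de_pathway_is_error(self, toy_collection):
        universe = ["g1", "g2", "g3", "g4", "g5", "g6"]
        de = self._de([], universe)
        with pytest.raises(NoDEPathwayError):
            map_pathways_to_de(toy_collection, de)

    def test_feature_genes_limited_to_universe(self):
        coll = GeneSetCollection.from_sets([GeneSet("pw", "p", ("g1", "gX"))])
        universe = ["g1", "g2"]
        de = self._de(["g1", "g2"], universe)
        (dp,) = map_pathways_to_de(coll, de)
        assert dp.feature_genes == ("g1",)

    def test_empty_feature_set_invalid(self):
        with pytest.raises(DataError):
            DEPathway(pathway_id="pw", name="p", feature_genes=(), n_pathway_genes=3)


def test_degenerate_training_rejected():
    # only one negative sample -> rejected before any statistics run
    with pytest.raises(DataError):
        ds = make_dataset(np.zeros((3, 3)), ["pos", "pos", "neg"], sample_ids=["a", "b", "c"])
        screen_de_genes(ds)
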