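import math

import numpy as np
import pytest
from scipy import stats

from cladefill.genome_io import Annotation, GeneModel
from cladefill.hit_scoring import (
    BAD,
    CANDIDATE,
    GOOD,
    HitParseError,
    HmmHit,
    InsufficientHitsError,
    ScoreModel,
    classify_hit,
    filter_candidates,
    fit_score_model,
    parse_hmm_hits,
    pooled_score_model,
    posterior_genuine,
)
from cladefill.intervals import GenomicInterval
from cladefill.skewt import SkewTParams

TBL_HEADER = (
    "# target name        accession  query name           accession  hmmfrom hmm to "
    "alifrom  ali to envfrom  env to  sq len strand   E-value  score  bias  description\n"
)


def tbl(tmp_path, rows):
    path = tmp_path / "hits.tbl"
    path.write_text(TBL_HEADER + "".join(rows))
    return path


def row(target="chr1", alifrom=101, alito=250, strand="+", score=300.0):
    return (
        f"{target} - OG1 - 1 150 {alifrom} {alito} {alifrom} {alito} "
        f"5000 {strand} 1e-20 {score} 0.1 -\n"
    )


class TestParseHits:
    def test_plus_strand_hit_and_adjusted_score(self, tmp_path):
        hits = parse_hmm_hits(tbl(tmp_path, [row()]), "OG1")
        (hit,) = hits
        assert hit.location == GenomicInterval("chr1", 100, 250, "+")
        assert hit.length == 150
        assert hit.adjusted_score == pytest.approx(2.0)

    def test_minus_strand_coordinates_normalised(self, tmp_path):
        hits = parse_hmm_hits(tbl(tmp_path, [row(alifrom=250, alito=101, strand="-")]), "OG1")
        assert hits[0].location == GenomicInterval("chr1", 100, 250, "-")

    def test_empty_file(self, tmp_path):
        assert parse_hmm_hits(tbl(tmp_path, []), "OG1") == []

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tbl"
        path.write_text("chr1 only four fields here\n")
        with pytest.raises(HitParseError, match="line 1"):
            parse_hmm_hits(path, "OG1")


class TestClassify:
    @pytest.fixture()
    def annotation(self):
        ann = Annotation("sp")
        ann.add(GeneModel("in_og", "sp", [GenomicInterval("chr1", 100, 400)]))
        ann.add(GeneModel("other", "sp", [GenomicInterval("chr1", 1000, 1300)]))
        return ann

    @pytest.fixture()
    def og(self):
        from cladefill.orthogroups import Orthogroup

        return Orthogroup("OG1", frozenset({("sp", "in_og"), ("b", "b1")}))

    def hit(self, start, end):
        return HmmHit("OG1", GenomicInterval("chr1", start, end), 100.0)

    def test_overlap_with_own_orthogroup_gene_is_good(self, annotation, og):
        assert classify_hit(self.hit(350, 500), annotation, og) == GOOD

    def test_overlap_with_foreign_gene_only_is_bad(self, annotation, og):
        assert classify_hit(self.hit(1200, 1400), annotation, og) == BAD

    def test_intergenic_hit_is_candidate(self, annotation, og):
        assert classify_hit(self.hit(500, 900), annotation, og) == CANDIDATE


def make_model(good, bad, pg=0.5):
    return ScoreModel(
        species="sp", good_dist=good, bad_dist=bad,
        prior_genuine=pg, prior_mistake=1 - pg, n_good=100, n_bad=100,
    )


class TestFit:
    def test_insufficient_data_signal(self):
        assert fit_score_model([1.0] * 30, [0.5] * 500, min_n=50) is None

    def test_priors_are_class_proportions(self):
        rng = np.random.default_rng(0)
        good = SkewTParams(1.2, 0.3, 2.0, 8.0).rvs(900, rng)
        bad = SkewTParams(0.3, 0.2, 2.0, 8.0).rvs(100, rng)
        model = fit_score_model(good, bad, min_n=50)
        assert model.prior_genuine == pytest.approx(0.9)
        assert model.prior_mistake == pytest.approx(0.1)

    def test_parameter_recovery_and_summary(self):
        rng = np.random.default_rng(77)
        g_true = SkewTParams(1.2, 0.3, 2.0, 8.0)
        b_true = SkewTParams(0.3, 0.2, 2.0, 8.0)
        model = fit_score_model(g_true.rvs(2000, rng), b_true.rvs(2000, rng), min_n=50)
        assert abs(model.good_dist.loc - g_true.loc) / g_true.loc < 0.10
        assert abs(model.bad_dist.loc - b_true.loc) / b_true.loc < 0.10
        assert model.prior_genuine == pytest.approx(0.5)
        assert "P(genuine)" in model.summary()

    def test_pooled_fallback_uses_other_species(self):
        rng = np.random.default_rng(1)
        g = SkewTParams(1.2, 0.3, 2.0, 8.0).rvs(500, rng)
        b = SkewTParams(0.3, 0.2, 2.0, 8.0).rvs(500, rng)
        pool = {"target": ([1.0] * 10, [0.2] * 5), "other": (g, b)}
        model = pooled_score_model(pool, "target", min_n=50)
        assert model.pooled
        assert model.n_good == 500

    def test_pooled_still_insufficient_is_hard_error(self):
        pool = {"a": ([1.0] * 5, [0.2] * 5), "b": ([1.0] * 5, [0.2] * 5)}
        with pytest.raises(InsufficientHitsError, match="species"):
            pooled_score_model(pool, "a", min_n=50)


class TestPosterior:
    def test_equal_densities_and_priors_give_half(self):
        dist = SkewTParams(1.0, 0.5, 1.0, 10.0)
        model = make_model(dist, dist, pg=0.5)
        assert posterior_genuine(1.3, model) == pytest.approx(0.5)

    def test_limit_when_mistake_density_vanishes(self):
        model = make_model(
            SkewTParams(5.0, 0.2, 0.0, 50.0), SkewTParams(0.0, 0.2, 0.0, 50.0)
        )
        assert posterior_genuine(5.0, model) > 0.999999

    def test_complement_sums_to_one(self):
        model = make_model(
            SkewTParams(1.2, 0.3, 2.0, 8.0), SkewTParams(0.3, 0.2, 2.0, 8.0), pg=0.7
        )
        x = np.linspace(-1, 3, 50)
        post = posterior_genuine(x, model)
        swapped = ScoreModel(
            species="sp", good_dist=model.bad_dist, bad_dist=model.good_dist,
            prior_genuine=0.3, prior_mistake=0.7, n_good=1, n_bad=1,
        )
        np.testing.assert_allclose(post + posterior_genuine(x, swapped), 1.0, atol=1e-12)

    def test_grid_equivalence_with_independent_bayes_quotient(self):
        """The posterior matches a from-scratch density-ratio computation."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            gp = SkewTParams(rng.uniform(0.5, 2), rng.uniform(0.1, 0.5),
                             rng.uniform(-3, 3), rng.uniform(3, 20))
            bp = SkewTParams(rng.uniform(-0.5, 0.5), rng.uniform(0.1, 0.5),
                             rng.uniform(-3, 3), rng.uniform(3, 20))
            pg = rng.uniform(0.2, 0.8)
            model = make_model(gp, bp, pg)
            x = np.linspace(-2, 4, 100)

            def density(p, xs):
                z = (xs - p.loc) / p.scale
                w = p.shape * z * np.sqrt((p.df + 1) / (p.df + z**2))
                return 2.0 / p.scale * stats.t.pdf(z, p.df) * stats.t.cdf(w, p.df + 1)

            num = density(gp, x) * pg
            expected = num / (num + density(bp, x) * (1 - pg))
            np.testing.assert_allclose(posterior_genuine(x, model), expected, atol=1e-9)


class TestFilter:
    def separated_model(self):
        return make_model(
            SkewTParams(1.5, 0.2, 0.0, 10.0), SkewTParams(0.3, 0.2, 0.0, 10.0)
        )

    def hit(self, score_per_base, length=100, start=0):
        return HmmHit(
            "OG1", GenomicInterval("chr1", start, start + length),
            score_per_base * length,
        )

    def test_partition_preserves_order_and_members(self):
        hits = [self.hit(s, start=100 * i) for i, s in enumerate([2.0, 0.1, 1.4, 0.5])]
        retained, rejected = filter_candidates(hits, self.separated_model())
        assert retained == [hits[0], hits[2]]
        assert rejected == [hits[1], hits[3]]

    def test_posterior_exactly_half_is_rejected(self):
        dist = SkewTParams(1.0, 0.5, 1.0, 10.0)
        model = make_model(dist, dist, pg=0.5)  # posterior is 1/2 everywhere
        retained, rejected = filter_candidates([self.hit(1.0)], model)
        assert retained == [] and len(rejected) == 1

    def test_retained_set_is_upper_score_interval(self):
        """With well-separated unimodal fits the decision is a threshold rule."""
        model = self.separated_model()
        scores = np.linspace(0.0, 2.5, 200)
        decisions = [posterior_genuine(s, model) > 0.5 for s in scores]
        # once retention starts it never reverts on the grid
        first = decisions.index(True)
        assert all(decisions[first:])
        assert not any(decisions[:first])
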