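import numpy as np
import pandas as pd
import pytest

from g4pause.association import (Anchor, annotate_sites, biotype_summary,
                                 group_by_upstream_g, metaprofile,
                                 random_control_sites, site_abundance,
                                 strand_asymmetry_test, upstream_g_content,
                                 upstream_enrichment_test, variant_overlap)
from g4pause.coverage import EndCoverageTrack
from g4pause.genome_io import (CircularGenome, GeneAnnotation,
                               GenomicInterval, VariantSet)
from g4pause.pausecall import PauseSite


def _site(pos, strand="+", start=None, end=None):
    start = pos if start is None else start
    end = pos + 1 if end is None else end
    return PauseSite(GenomicInterval(start, end, strand), pos, strand, 2,
                     {"a": 5.0})


def _rand_genome(length, seed=0, p=(0.3, 0.2, 0.25, 0.25)):
    rng = np.random.default_rng(seed)
    return CircularGenome("m", "".join(rng.choice(list("ACGT"), p=p,
                                                  size=length)))


class TestMetaprofile:
    def test_constant_track(self):
        tracks = {"+": np.full(500, 2.5), "-": np.full(500, 2.5)}
        prof = metaprofile(tracks, [_site(100), _site(300, "-")], 50, 50)
        np.testing.assert_allclose(prof.mean, 2.5)
        np.testing.assert_allclose(prof.sem, 0.0)
        assert prof.n == 2

    def test_delta_at_summit(self):
        tracks = {"+": np.zeros(500), "-": np.zeros(500)}
        tracks["+"][100] = 1.0
        prof = metaprofile(tracks, [_site(100)], 50, 50)
        assert prof.mean[50] == 1.0 and prof.mean.sum() == 1.0

    def test_minus_strand_orientation(self):
        # spike 10 nt left (reference) of a minus-strand summit is
        # downstream in transcription direction: appears at offset +10
        tracks = {"+": np.zeros(500), "-": np.zeros(500)}
        tracks["-"][90] = 1.0
        prof = metaprofile(tracks, [_site(100, "-")], 50, 50)
        assert prof.mean[50 + 10] == 1.0

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            metaprofile({"+": np.zeros(10), "-": np.zeros(10)}, [])


class TestControls:
    def test_seed_determinism(self):
        g = _rand_genome(300)
        a = random_control_sites(g, 40, exclude=[_site(5)], seed=9)
        b = random_control_sites(g, 40, exclude=[_site(5)], seed=9)
        assert a == b

    def test_exclusion_respected(self):
        g = _rand_genome(300)
        excluded = [_site(p) for p in range(0, 200)]
        controls = random_control_sites(g, 50, exclude=excluded, seed=1)
        assert all(c.position >= 200 for c in controls)

    def test_strand_proportions(self):
        g = _rand_genome(400)
        controls = random_control_sites(g, 100, (0.7, 0.3), seed=2)
        n_plus = sum(1 for c in controls if c.strand == "+")
        assert n_plus == 70

    def test_infeasible_n_rejected(self):
        g = _rand_genome(50)
        with pytest.raises(ValueError):
            random_control_sites(g, 60, seed=0)


class TestUpstreamG:
    def test_plus_strand_window(self):
        seq = "A" * 50 + "G" * 50 + "A" * 50
        g = CircularGenome("m", seq)
        count, frac = upstream_g_content(g, _site(100), k=50)
        assert count == 50 and frac == 1.0
        assert upstream_g_content(g, _site(50), k=50)[0] == 0

    def test_minus_strand_window_is_complemented(self):
        # minus-strand upstream = reference (pos, pos+k], complemented
        seq = "A" * 5 + "C" * 3 + "AA"
        g = CircularGenome("m", seq)
        count, _ = upstream_g_content(g, _site(4, "-"), k=3)
        assert count == 3  # C's at 5..7 read as G on the minus strand

    def test_summit_base_excluded(self):
        g = CircularGenome("m", "G" * 10)
        count, frac = upstream_g_content(g, _site(5), k=4)
        assert count == 4


class TestEnrichment:
    def test_extreme_separation(self):
        g = CircularGenome("m", "G" * 100 + "A" * 100)
        pause = [_site(p) for p in range(60, 100, 2)]    # all-G upstream
        ctrl = [_site(p) for p in range(160, 200, 2)]    # all-A upstream
        res = upstream_enrichment_test(pause, ctrl, g, k=20)
        assert res.pvalue < 1e-6 and res.direction == "pause>control"

    def test_identical_lists_degenerate(self):
        g = CircularGenome("m", "G" * 50)
        sites = [_site(p) for p in range(10, 20)]
        with pytest.warns(UserWarning):
            res = upstream_enrichment_test(sites, sites, g, k=5)
        assert res.pvalue == 1.0

    def test_null_calibration(self):
        # both groups drawn from the same genome at random positions:
        # the rank test should reject at ~5%
        g = _rand_genome(4000, seed=3)
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 400
        for _ in range(reps):
            pos = rng.choice(4000, size=60, replace=False)
            pause = [Anchor(int(p), "+") for p in pos[:30]]
            ctrl = [Anchor(int(p), "+") for p in pos[30:]]
            res = upstream_enrichment_test(pause, ctrl, g, k=50)
            rejections += res.pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.08


class TestStrandAsymmetry:
    def test_paper_scale_split_significant(self):
        res = strand_asymmetry_test(314, 151)
        assert res.pvalue < 0.0001

    def test_even_split_null(self):
        res = strand_asymmetry_test(100, 100)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_closed_form(self):
        res = strand_asymmetry_test(60, 40)
        assert res.statistic == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(0.0455, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            strand_asymmetry_test(0, 0)


class TestGroupByUpstreamG:
    def _tracks(self, values):
        return [EndCoverageTrack("a", values, np.zeros_like(values),
                                 normalization="rpm_total", denominator=1e6)]

    def test_perfect_dependence(self):
        rng = np.random.default_rng(6)
        g = _rand_genome(4000, seed=6)
        sites = [_site(int(p)) for p in rng.choice(4000, 80, replace=False)]
        cov = np.zeros(4000)
        for s in sites:
            cov[s.summit] = upstream_g_content(g, s, 50)[0]  # coverage == G
        table, pairwise, global_test = group_by_upstream_g(
            sites, self._tracks(cov), g, k=50)
        assert global_test.pvalue < 1e-6
        medians = table.groupby("bin", observed=True)["abundance"].median()
        ordered = table.groupby("bin", observed=True)["upstream_g"].median() \
            .sort_values().index
        assert medians[ordered].is_monotonic_increasing

    def test_independent_coverage_not_significant(self):
        rng = np.random.default_rng(7)
        g = _rand_genome(4000, seed=7)
        sites = [_site(int(p)) for p in rng.choice(4000, 80, replace=False)]
        cov = np.zeros(4000)
        for s in sites:
            cov[s.summit] = rng.gamma(5, 2)
        _, pairwise, global_test = group_by_upstream_g(
            sites, self._tracks(cov), g, k=50)
        assert global_test.pvalue > 0.01


class TestVariantOverlap:
    def test_half_open_convention(self):
        sites = [_site(10, start=10, end=12)]
        variants = VariantSet([10, 11, 12], ["a", "b", "c"])
        out = variant_overlap(sites, variants, 100)
        assert out["n_variants_in_sites"] == 2
        assert out["n_sites_with_variant"] == 1

    def test_wrapped_site(self):
        sites = [PauseSite(GenomicInterval(98, 3, "+"), 0, "+", 2, {})]
        out = variant_overlap(sites, VariantSet([1], ["v"]), 100)
        assert out["n_variants_in_sites"] == 1

    def test_empty_variants(self):
        out = variant_overlap([_site(5)], VariantSet([], []), 100)
        assert out["n_variants_in_sites"] == 0
        assert out["pct_variants_per_site"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 500
        sites = []
        for _ in range(30):
            s = int(rng.integers(0, L))
            w = int(rng.integers(1, 20))
            e = (s + w) % L
            sites.append(PauseSite(GenomicInterval(s, e if e else L, "+"),
                                   s, "+", 2, {}))
        vpos = list(rng.choice(L, size=40, replace=False))
        variants = VariantSet([int(v) for v in vpos],
                              [f"v{i}" for i in range(40)])
        out = variant_overlap(sites, variants, L)
        covered = set()
        for s in sites:
            covered |= {int(p) for p in s.interval.positions(L)}
        oracle_vars = sum(1 for v in vpos if int(v) in covered)
        oracle_sites = sum(
            1 for s in sites
            if any(int(v) in {int(p) for p in s.interval.positions(L)}
                   for v in vpos))
        assert out["n_variants_in_sites"] == oracle_vars
        assert out["n_sites_with_variant"] == oracle_sites


class TestAnnotation:
    @pytest.fixture
    def annotation(self):
        return GeneAnnotation([
            (GenomicInterval(100, 200, "+"), "MT-X", "mRNA"),
            (GenomicInterval(300, 370, "-"), "MT-T1", "tRNA"),
        ])

    def test_in_gene_classification(self, annotation):
        df = annotate_sites([_site(150)], annotation, 1000)
        assert df.loc[0, "gene"] == "MT-X" and df.loc[0, "class"] == "body"

    def test_intergenic(self, annotation):
        df = annotate_sites([_site(50)], annotation, 1000)
        assert df.loc[0, "gene"] == "intergenic"

    def test_first_base_is_five_prime(self, annotation):
        df = annotate_sites([_site(100)], annotation, 1000)
        assert df.loc[0, "class"] == "5prime"

    def test_minus_strand_five_prime_is_right_edge(self, annotation):
        df = annotate_sites([_site(369, "-")], annotation, 1000)
        assert df.loc[0, "class"] == "5prime"

    def test_strand_mismatch_is_intergenic(self, annotation):
        df = annotate_sites([_site(150, "-")], annotation, 1000)
        assert df.loc[0, "gene"] == "intergenic"

    def test_biotype_summary(self, annotation):
        df = annotate_sites([_site(150), _site(160), _site(350, "-")],
                            annotation, 1000)
        summary = biotype_summary(df, annotation)
        row = summary.set_index("biotype")
        assert row.loc["mRNA", "genes_with_pause"] == 1
        assert row.loc["tRNA", "genes_with_pause"] == 1
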