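import numpy as np
import pytest

from g4pause.genome_io import base_composition, reverse_complement
from g4pause.g4score import qgrs_find_motifs, scan_genome_motifs
from g4pause.pausecall import PauseSite
from g4pause.genome_io import GenomicInterval
from g4pause.synthetic import (SimulationParams, SyntheticTruth,
                               evaluate_recovery, read_truth, simulate,
                               simulate_genome, write_truth)


class TestGenomeGeneration:
    def test_seed_determinism(self):
        p = SimulationParams(seed=5)
        g1, t1 = simulate_genome(p)
        g2, t2 = simulate_genome(p)
        assert g1.sequence == g2.sequence
        assert [(m.interval, m.strand) for m in t1.motifs] == \
            [(m.interval, m.strand) for m in t2.motifs]

    def test_strand_asymmetric_composition_is_exact(self, default_sim):
        _, genome, _, _ = default_sim
        comp = base_composition(genome.sequence)
        assert round(100 * comp["G"]) == 13
        rc = base_composition(reverse_complement(genome.sequence))
        assert round(100 * rc["G"]) == 31

    def test_motif_count_and_strands(self, default_sim):
        params, _, truth, _ = default_sim
        plus = [m for m in truth.motifs if m.strand == "+"]
        minus = [m for m in truth.motifs if m.strand == "-"]
        assert len(plus) == params.n_g4_plus
        assert len(minus) == params.n_g4_minus

    def test_planted_motifs_recovered_by_scan(self, default_sim):
        _, genome, truth, _ = default_sim
        found = {(m.interval.start, m.interval.end, m.strand)
                 for m in scan_genome_motifs(genome)}
        for m in truth.motifs:
            assert (m.interval.start, m.interval.end, m.strand) in found

    def test_planted_motif_sequence_matches_pattern(self, default_sim):
        _, genome, truth, _ = default_sim
        for m in truth.motifs[:10]:
            pos = m.interval.positions(genome.length)
            seq = "".join(genome.sequence[int(p)] for p in pos)
            if m.strand == "-":
                seq = reverse_complement(seq)
            sub = qgrs_find_motifs(seq)
            assert len(sub) == 1 and sub[0].tract == m.tract

    def test_no_motifs_requested(self):
        p = SimulationParams(n_g4_plus=0, n_g4_minus=0, seed=2)
        _, truth = simulate_genome(p)
        assert truth.motifs == []

    def test_infeasible_placement_rejected(self):
        p = SimulationParams(length=2000, n_g4_plus=20, n_g4_minus=20, seed=0)
        with pytest.raises(ValueError):
            simulate_genome(p)


class TestCoverageGeneration:
    def test_full_determinism(self):
        p = SimulationParams(seed=3)
        g1, t1, tr1 = simulate(p)
        g2, t2, tr2 = simulate(p)
        assert [(x.position, x.strand) for x in t1.pauses] == \
            [(x.position, x.strand) for x in t2.pauses]
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.plus, b.plus)
            np.testing.assert_array_equal(a.minus, b.minus)

    def test_pause_offsets_in_band_downstream(self, default_sim):
        params, genome, truth, _ = default_sim
        L = genome.length
        lo, hi = params.offset_range
        for p in truth.pauses:
            if p.source != "g4":
                continue
            m = truth.motifs[p.motif_index]
            w = m.interval.width(L)
            center = (m.interval.start + w // 2) % L
            if p.strand == "+":
                off = (p.position - center) % L
            else:
                off = (center - p.position) % L
            assert lo <= off <= max(hi, w // 2 + 5)
            # strictly downstream of the motif's 3' end
            tpe = m.three_prime_end
            d3 = (p.position - tpe) % L if p.strand == "+" \
                else (tpe - p.position) % L
            assert 0 < d3 < 100

    def test_pause_positions_unique_per_strand(self, default_sim):
        _, _, truth, _ = default_sim
        keys = [(p.position, p.strand) for p in truth.pauses]
        assert len(keys) == len(set(keys))

    def test_pause_mean_elevation(self):
        # Monte-Carlo check of the generator itself: mean count at pause
        # bases across replicates ~ mu * fold within 3 standard errors
        p = SimulationParams(length=3000, n_g4_plus=2, n_g4_minus=2,
                             n_noise_pauses=0, replicates=60,
                             library_sizes=(1e6,) * 60, pause_prob=1.0,
                             seed=8)
        _, truth, tracks = simulate(p)
        vals = [t.strand(x.strand)[x.position]
                for t in tracks for x in truth.pauses]
        vals = np.array(vals, dtype=float)
        target = p.mu_background * p.pause_fold
        sd = np.sqrt(target + target ** 2 / p.nb_size)
        sem = sd / np.sqrt(vals.size)
        assert abs(vals.mean() - target) < 3 * sem

    def test_null_fold_gives_flat_background(self):
        p = SimulationParams(length=3000, n_g4_plus=2, n_g4_minus=2,
                             pause_fold=1.0 + 1e-9, n_noise_pauses=0,
                             seed=9)
        _, truth, tracks = simulate(p)
        counts = np.concatenate([t.plus for t in tracks])
        assert counts.max() < 30  # no systematically elevated base


class TestTruthIO:
    def test_round_trip(self, tmp_path, default_sim):
        params, _, truth, _ = default_sim
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        assert len(back.motifs) == len(truth.motifs)
        assert [(m.interval.start, m.strand, m.tract, m.loops)
                for m in back.motifs] == \
            [(m.interval.start, m.strand, m.tract, m.loops)
             for m in truth.motifs]
        assert [(p.position, p.strand, p.source) for p in back.pauses] == \
            [(p.position, p.strand, p.source) for p in truth.pauses]

    def test_params_rerun_identical(self, tmp_path, default_sim):
        params, genome, _, _ = default_sim
        write_truth(SyntheticTruth(params=params), tmp_path)
        back = read_truth(tmp_path)
        g2, _ = simulate_genome(back.params,
                                np.random.default_rng(back.params.seed))
        g1, _ = simulate_genome(params, np.random.default_rng(params.seed))
        assert g1.sequence == g2.sequence


class TestRecoveryMetric:
    def _sites(self, positions, strand="+"):
        return [PauseSite(GenomicInterval(p, p + 1, strand), p, strand, 2, {})
                for p in positions]

    def _truth(self, positions, strand="+"):
        t = SyntheticTruth()
        from g4pause.synthetic import PlantedPause
        t.pauses = [PlantedPause(p, strand, "g4") for p in positions]
        return t

    def test_perfect_recovery(self):
        truth = self._truth([10, 50, 90])
        rec = evaluate_recovery(self._sites([10, 50, 90]), truth, 100)
        assert rec["recall"] == 1.0 and rec["precision"] == 1.0

    def test_no_calls_is_na_precision(self):
        rec = evaluate_recovery([], self._truth([10]), 100)
        assert rec["recall"] == 0.0 and np.isnan(rec["precision"])

    def test_tolerance_gate(self):
        truth = self._truth([10, 50])
        rec = evaluate_recovery(self._sites([12, 52]), truth, 100,
                                tolerance=1)
        assert rec["recall"] == 0.0
        rec2 = evaluate_recovery(self._sites([11, 51]), truth, 100,
                                 tolerance=1)
        assert rec2["recall"] == 1.0

    def test_matching_is_one_to_one(self):
        truth = self._truth([10])
        rec = evaluate_recovery(self._sites([10, 11]), truth, 100)
        assert rec["n_matched"] == 1 and rec["precision"] == 0.5

    def test_strand_must_match(self):
        truth = self._truth([10], strand="-")
        rec = evaluate_recovery(self._sites([10], "+"), truth, 100)
        assert rec["recall"] == 0.0
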