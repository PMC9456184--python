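import numpy as np
import pytest

from lncsponge.seqio import MirnaRecord, TranscriptRecord
from lncsponge.simulate import (
    SimulationConfig,
    SpongePlanEntry,
    plant_sponge_sites,
    simulate_mirnas,
)
from lncsponge.targets import (
    TargetParams,
    build_null,
    find_seed_sites,
    hybrid_score,
    predict_targets,
)

from conftest import random_dna
from oracles import seed_scan_oracle

MIRNA = MirnaRecord("mir", "UAGCUUAUCAGACUGAUGUUGA")  # 22 nt


def _perfect_site(mirna: MirnaRecord, with_a1=True) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    site = "".join(comp[c] for c in reversed(mirna.mature_sequence[1:8]))
    return site + ("A" if with_a1 else comp[mirna.mature_sequence[0]])


class TestFindSeedSites:
    def test_no_complement_no_sites(self):
        lnc = TranscriptRecord("l", "A" * 300)
        assert find_seed_sites(MIRNA, lnc) == []

    def test_constructed_8mer(self):
        rng = np.random.default_rng(0)
        left, right = random_dna(rng, 50), random_dna(rng, 50)
        lnc = TranscriptRecord("l", left + _perfect_site(MIRNA) + right)
        sites = [s for s in find_seed_sites(MIRNA, lnc) if s.site_type == "8mer"]
        assert len(sites) >= 1
        assert any(s.start == 50 for s in sites)

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(1)
        mirnas = simulate_mirnas(SimulationConfig(seed=13, n_mirnas=5))
        for mir in mirnas:
            lnc = TranscriptRecord("l", random_dna(rng, 2000))
            got = {(s.start, s.site_type) for s in find_seed_sites(mir, lnc)}
            assert got == seed_scan_oracle(mir.mature_sequence, lnc.sequence)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            find_seed_sites(MirnaRecord("m", "UAGCUAU"), TranscriptRecord("l", "ACGT"))


class TestHybridScore:
    def test_perfect_complement_score(self):
        comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
        window = "".join(comp[c] for c in reversed(MIRNA.mature_sequence))
        # 7 seed positions doubled (+10) and 15 others (+5)
        assert hybrid_score(MIRNA.mature_sequence, window) == 145.0

    def test_no_complementarity_zero(self):
        assert hybrid_score("A" * 22, "A" * 22) == 0.0

    def test_locality(self):
        comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
        window = "".join(comp[c] for c in reversed(MIRNA.mature_sequence))
        assert hybrid_score(MIRNA.mature_sequence, window) == hybrid_score(
            MIRNA.mature_sequence, window
        )
        # content outside the window cannot matter: different flank, same window
        lnc_a = TranscriptRecord("a", "G" * 40 + window + "C" * 40)
        lnc_b = TranscriptRecord("b", "T" * 40 + window + "A" * 40)
        w_a = lnc_a.sequence[40 : 40 + len(window)]
        w_b = lnc_b.sequence[40 : 40 + len(window)]
        assert hybrid_score(MIRNA.mature_sequence, w_a) == hybrid_score(
            MIRNA.mature_sequence, w_b
        )

    def test_guaranteed_seed_scores(self):
        # a bare 7mer-m8 site scores exactly 70 in an otherwise
        # non-complementary context
        site = _perfect_site(MIRNA, with_a1=False)[:7]
        window = site + "A" * 30  # poly-A pairs nothing for this miRNA 3' end
        assert hybrid_score(MIRNA.mature_sequence, window) >= 70.0


class TestPredictTargets:
    def test_planted_sites_all_pass(self):
        cfg = SimulationConfig(seed=3, n_mirnas=3)
        mirnas = simulate_mirnas(cfg)
        rng = np.random.default_rng(4)
        lnc = TranscriptRecord("l", random_dna(rng, 800))
        planted, coords = plant_sponge_sites(
            [lnc], mirnas, [SpongePlanEntry(0, (0,), 4)], seed=5
        )
        sites, counts = predict_targets(mirnas, planted)
        assert counts.loc[mirnas[0].id, "l"] >= 4
        planted_starts = {c[2] for c in coords}
        consensus_starts = {
            s.start for s in sites
            if s.passed_consensus and s.mirna_id == mirnas[0].id
        }
        assert planted_starts <= consensus_starts

    def test_infinite_threshold_no_consensus(self):
        cfg = SimulationConfig(seed=3, n_mirnas=2)
        mirnas = simulate_mirnas(cfg)
        rng = np.random.default_rng(5)
        lnc = TranscriptRecord("l", random_dna(rng, 1500))
        _, counts = predict_targets(
            mirnas, [lnc], TargetParams(min_hybrid_score=float("inf"))
        )
        assert (counts == 0).all().all()

    def test_counts_monotone_in_thresholds(self):
        cfg = SimulationConfig(seed=6, n_mirnas=4)
        mirnas = simulate_mirnas(cfg)
        rng = np.random.default_rng(7)
        lncs = [TranscriptRecord(f"l{i}", random_dna(rng, 1200)) for i in range(3)]
        loose = predict_targets(mirnas, lncs, TargetParams("6mer", 0.0))[1]
        mid = predict_targets(mirnas, lncs, TargetParams("7mer-A1", 70.0))[1]
        strict = predict_targets(mirnas, lncs, TargetParams("8mer", 90.0))[1]
        assert (loose >= mid).all().all()
        assert (mid >= strict).all().all()

    def test_empty_inputs_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            sites, counts = predict_targets([], [])
        assert sites == [] and counts.empty


class TestBuildNull:
    def test_homopolymer_fixed_point(self):
        mirnas = [MirnaRecord("m", "UUUUUUUUUUUUUUUUUUUUUU")]
        lnc = TranscriptRecord("l", "A" * 200)
        _, real = predict_targets(mirnas, [lnc], TargetParams("6mer", 0.0))
        null = build_null([lnc], mirnas, 1, seed=1, params=TargetParams("6mer", 0.0))
        assert (null[0] == real).all().all()

    def test_composition_preserved(self):
        cfg = SimulationConfig(seed=8, n_mirnas=2)
        mirnas = simulate_mirnas(cfg)
        rng = np.random.default_rng(9)
        lnc = TranscriptRecord("l", random_dna(rng, 500))
        from lncsponge.seqio import shuffle_sequence

        shuffled = shuffle_sequence(lnc.sequence, (11 * 1000003 + 0) * 131 + 0)
        assert sorted(shuffled) == sorted(lnc.sequence)

    def test_planted_sponge_beats_null(self):
        cfg = SimulationConfig(seed=10, n_mirnas=3)
        mirnas = simulate_mirnas(cfg)
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            lnc = TranscriptRecord("l", random_dna(rng, 1000))
            planted, _ = plant_sponge_sites(
                [lnc], mirnas, [SpongePlanEntry(0, (0,), 6)], seed=seed
            )
            _, real = predict_targets(mirnas, planted)
            null = build_null(planted, mirnas, 3, seed=seed)
            null_mean = np.mean([m.loc[mirnas[0].id, "l"] for m in null])
            wins += real.loc[mirnas[0].id, "l"] > null_mean
        assert wins == n_seeds
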