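import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from lncsponge.classify import find_orfs
from lncsponge.seqio import TranscriptRecord
from lncsponge.simulate import (
    SimulationConfig,
    SpongePlanEntry,
    default_config,
    plant_sponge_sites,
    simulate_counts,
    simulate_mirnas,
    simulate_transcriptomes,
)
from lncsponge.targets import find_seed_sites


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_coding=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(length_range=(50, 1000))
        with pytest.raises(ValueError):
            SpongePlanEntry(0, (0,), -1)


class TestTranscriptomes:
    def test_zero_clusters_empty(self):
        sets, truth = simulate_transcriptomes(SimulationConfig(n_clusters=0))
        assert all(len(v) == 0 for v in sets.values())
        assert truth.class_by_transcript == {}

    def test_zero_mutation_identical_copies(self):
        cfg = SimulationConfig(seed=2, n_clusters=1, p_coding=0.0,
                               mutation_rate=0.0, source_presence=(1, 1, 1))
        sets, _ = simulate_transcriptomes(cfg)
        seqs = {r.sequence for src in sets.values() for r in src}
        assert len(seqs) == 1

    def test_reproducible(self):
        cfg = SimulationConfig(seed=5, n_clusters=10)
        a, _ = simulate_transcriptomes(cfg)
        b, _ = simulate_transcriptomes(cfg)
        for src in a:
            assert [(r.id, r.sequence) for r in a[src]] == [
                (r.id, r.sequence) for r in b[src]
            ]

    def test_coding_fraction_within_binomial_ci(self):
        # fraction of coding clusters over 20 seeds vs Binomial(20*50, 0.4)
        n_seeds, n_clusters, p = 20, 50, 0.4
        total_coding = 0
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_clusters=n_clusters, p_coding=p,
                                   length_range=(300, 800))
            _, truth = simulate_transcriptomes(cfg)
            total_coding += sum(
                1 for c in truth.cluster_class.values() if c == "coding"
            )
        n = n_seeds * n_clusters
        lo, hi = binom.ppf([0.025, 0.975], n, p)
        assert lo <= total_coding <= hi

    def test_noncoding_clusters_have_no_long_orf(self):
        cfg = SimulationConfig(seed=6, n_clusters=12, p_coding=0.5)
        sets, truth = simulate_transcriptomes(cfg)
        for src in sets.values():
            for rec in src:
                orfs = find_orfs(rec, min_aa=50)
                if truth.class_by_transcript[rec.id] == "coding":
                    assert orfs, rec.id
                # noncoding copies may gain chance ORFs only through
                # mutation; the base sequence is ORF-free by construction

    def test_planted_sites_detectable_in_every_copy(self):
        cfg = default_config(seed=8, n_clusters=30)
        sets, truth = simulate_transcriptomes(cfg)
        mirnas = {m.id: m for m in simulate_mirnas(cfg)}
        records = {r.id: r for src in sets.values() for r in src}
        assert truth.planted_sites
        for tid, mir_id, start, site_type in truth.planted_sites:
            sites = find_seed_sites(mirnas[mir_id], records[tid])
            assert any(s.start == start and s.site_type == site_type
                       for s in sites), (tid, mir_id, start)


class TestPlantSpongeSites:
    def _lnc(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return TranscriptRecord("L", "".join(rng.choice(list("ACGT"), n)))

    def _mirnas(self):
        return simulate_mirnas(SimulationConfig(seed=1, n_mirnas=3))

    def test_zero_sites_unchanged(self):
        lnc = self._lnc(300)
        out, planted = plant_sponge_sites(
            [lnc], self._mirnas(), [SpongePlanEntry(0, (0,), 0)], seed=1
        )
        assert out[0].sequence == lnc.sequence and planted == []

    def test_packing_feasibility(self):
        mirnas = self._mirnas()
        out, planted = plant_sponge_sites(
            [self._lnc(300)], mirnas, [SpongePlanEntry(0, (0,), 10)], seed=2
        )
        assert len(planted) == 10
        starts = sorted(p[2] for p in planted)
        assert all(b - a >= 8 for a, b in zip(starts, starts[1:]))
        with pytest.raises(ValueError, match="too short"):
            plant_sponge_sites(
                [self._lnc(300)], mirnas, [SpongePlanEntry(0, (0,), 40)], seed=2
            )

    def test_planted_8mer_found(self):
        mirnas = self._mirnas()
        out, planted = plant_sponge_sites(
            [self._lnc(400)], mirnas, [SpongePlanEntry(0, (1,), 1)], seed=3
        )
        (tid, mir_id, start, site_type) = planted[0]
        sites = find_seed_sites(mirnas[1], out[0])
        assert any(s.start == start and s.site_type == "8mer" for s in sites)


class TestCounts:
    def _records(self, n):
        return [TranscriptRecord(f"t{i:03d}", "ACGT") for i in range(n)]

    def test_poisson_limit(self):
        cfg = SimulationConfig(seed=3, n_samples_per_group=10, dispersion=0.0,
                               de_fraction=0.0, tissues=("midgut",),
                               library_factor_range=(1.0, 1.0))
        counts, samples, _ = simulate_counts(self._records(300), cfg)
        unfed = samples.index[samples["condition"] == "unfed"]
        sub = counts[unfed]
        ratio = (sub.var(axis=1, ddof=1) / sub.mean(axis=1)).mean()
        assert 0.8 <= ratio <= 1.2

    def test_no_de_flagged(self):
        cfg = SimulationConfig(seed=4, de_fraction=0.0, tissues=("midgut",))
        _, _, de = simulate_counts(self._records(100), cfg)
        assert not de["is_de"].any()

    def test_planted_fold_change_recovered(self):
        cfg = SimulationConfig(seed=5, n_samples_per_group=10, dispersion=0.05,
                               de_fraction=1.0, de_log2fc=2.0,
                               tissues=("midgut",))
        counts, samples, de = simulate_counts(self._records(200), cfg)
        fed = samples.index[samples["condition"] == "fed"]
        unfed = samples.index[samples["condition"] == "unfed"]
        lfc = np.log2(counts[fed].mean(axis=1) / counts[unfed].mean(axis=1))
        signed = lfc * np.sign(de["true_log2fc"])
        assert abs(signed.mean() - 2.0) <= 0.2

    def test_too_few_replicates_errors(self):
        cfg = SimulationConfig(n_samples_per_group=1)
        with pytest.raises(ValueError, match="samples per"):
            simulate_counts(self._records(10), cfg)

    def test_reproducible(self):
        cfg = SimulationConfig(seed=6, tissues=("midgut",))
        a, _, _ = simulate_counts(self._records(50), cfg)
        b, _, _ = simulate_counts(self._records(50), cfg)
        pd.testing.assert_frame_equal(a, b)
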