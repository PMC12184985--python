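import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cutac import coverage as cov
from cutac.genome import HISTONE_SET
from cutac.simulate import (Amplicon, SimulationConfig, load_truth,
                            miniature_genome, simulate_cohort,
                            simulate_spiked_pair, write_cohort)


def config(genome, **kw):
    kw.setdefault("n_pairs", 2)
    kw.setdefault("depth_per_sample", 20_000)
    kw.setdefault("seed", 5)
    return SimulationConfig(genome=genome, **kw)


class TestGenomeConstant:
    def test_miniature_genome_contents(self, genome):
        assert genome.nuclear_length() == 27_000_000
        assert len(genome.ccres) == 2_500
        assert genome.ccres["category"].nunique() == 5
        assert len(genome.gene_sets[HISTONE_SET]) == 64
        assert len(genome.gene_sets["ribosomal_protein"]) == 25
        assert len(genome.analyzed_arms()) == 6
        assert all(g.span is not None for g in genome.genes)

    def test_rebuild_is_identical(self, genome):
        again = miniature_genome()
        pd.testing.assert_frame_equal(again.ccres, genome.ccres)
        assert [g.span for g in again.genes] == \
            [g.span for g in genome.genes]


class TestCohortStructure:
    def test_pairing_and_metadata(self, genome):
        c = simulate_cohort(config(genome))
        assert len(c.samples) == 4
        roles = c.metadata.groupby("pair_id")["role"].apply(set)
        assert all(r == {"tumor", "normal"} for r in roles)
        for fs in c.samples:
            assert fs.total_count == 20_000

    def test_determinism_byte_identical(self, genome, tmp_path):
        def digest(d):
            h = hashlib.sha256()
            for p in sorted((d).iterdir()):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            return h.hexdigest()

        c1 = simulate_cohort(config(genome))
        write_cohort(c1, tmp_path / "a")
        c2 = simulate_cohort(config(genome))
        write_cohort(c2, tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_write_cohort_file_tree(self, genome, tmp_path):
        c = simulate_cohort(config(genome))
        paths = write_cohort(c, tmp_path / "out")
        assert len(paths["fragments"]) == 4
        truth = load_truth(paths["truth"])
        assert truth == c.truth
        meta = pd.read_csv(paths["metadata"], sep="\t")
        assert list(meta.columns) == ["sample_id", "pair_id", "role", "type",
                                      "who_grade", "recurrence_months",
                                      "event"]

    def test_infeasible_mito_fraction_rejected(self, genome):
        with pytest.raises(ValueError):
            simulate_cohort(config(genome, mito_fraction=1.0))


class TestGenerativeStructure:
    def test_null_config_has_no_systematic_ccre_shift(self, genome):
        cfg = config(genome, n_pairs=1, depth_per_sample=100_000,
                     hyper_factor=0.0, arm_cn=None, proliferation=[0.1],
                     gene_program_sd=0.0, ccre_program_sd=0.0,
                     mito_fraction=0.0)
        c = simulate_cohort(cfg)
        t, n = c.pairs()[0]
        m = cov.build_signal_matrix([t, n], genome, "ccre")
        diff = m.values.iloc[0] - m.values.iloc[1]
        # symmetric null: mean T-N over cCREs within sampling noise of zero
        se = diff.std() / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se

    def test_amplicon_raises_local_coverage_ratio(self, genome):
        amp = Amplicon("chr2", 1_000_000, 1_150_000, copy_ratio=8.0)
        cfg = config(genome, n_pairs=1, depth_per_sample=200_000,
                     amplicons=[amp], arm_cn=None)
        c = simulate_cohort(cfg)
        t, n = c.pairs()[0]
        iv = pd.DataFrame([("chr2", 1_000_000, 1_150_000),
                           ("chr2", 2_000_000, 2_150_000)],
                          columns=["chrom", "start", "end"])
        tv = cov.aggregate(cov.coverage(t, genome), iv)
        nv = cov.aggregate(cov.coverage(n, genome), iv)
        ratio_inside = tv[0] / nv[0]
        ratio_outside = tv[1] / nv[1]
        assert ratio_inside / ratio_outside >= 4.0

    def test_mito_fraction_hits_target(self, genome):
        cfg = config(genome, n_pairs=1, depth_per_sample=100_000,
                     mito_fraction=0.3)
        c = simulate_cohort(cfg)
        for fs in c.samples:
            assert cov.mito_fraction(fs, genome) == pytest.approx(0.3,
                                                                  abs=0.01)

    def test_histone_share_increases_with_rho(self, genome):
        lo = config(genome, n_pairs=1, depth_per_sample=100_000,
                    proliferation=[0.2], arm_cn=None, seed=3)
        hi = config(genome, n_pairs=1, depth_per_sample=100_000,
                    proliferation=[0.8], arm_cn=None, seed=3)
        shares = []
        for cfg in (lo, hi):
            c = simulate_cohort(cfg)
            t, _ = c.pairs()[0]
            in_locus = ((t.frags["chrom"] == "chr1")
                        & (t.frags["start"].between(1_000_000, 1_160_000)))
            shares.append(in_locus.mean())
        assert shares[1] > 2.0 * shares[0]

    def test_arm_gain_raises_arm_share(self, genome):
        base = config(genome, n_pairs=1, depth_per_sample=100_000,
                      arm_cn=None, seed=4)
        gained = config(genome, n_pairs=1, depth_per_sample=100_000,
                        arm_cn={"chr3q": 1.8}, seed=4)
        shares = []
        for cfg in (base, gained):
            c = simulate_cohort(cfg)
            t, _ = c.pairs()[0]
            on_arm = ((t.frags["chrom"] == "chr3")
                      & (t.frags["start"] >= 3_000_000))
            shares.append(on_arm.mean())
        assert shares[1] > 1.3 * shares[0]

    def test_rnaseq_tracks_cutac_gene_signal(self, genome):
        cfg = config(genome, n_pairs=3, depth_per_sample=100_000, seed=11)
        c = simulate_cohort(cfg)
        tumors = [fs for fs in c.samples if fs.role == "tumor"]
        m = cov.build_signal_matrix(tumors, genome, "gene_span")
        shared = [gid for gid in m.values.columns if gid in c.rnaseq.index]
        for sid in m.values.index:
            r, _ = spearmanr(m.values.loc[sid, shared],
                             c.rnaseq.loc[shared, sid.replace("_T", "_R")])
            assert r >= 0.7


class TestSpikedPair:
    def test_shared_background_and_extra_mass(self, genome):
        t, n, spikes = simulate_spiked_pair(genome, 50_000, 10, 10.0, seed=2)
        assert len(spikes) == 10
        assert n.total_count == 50_000
        assert t.total_count > n.total_count
        # the normal's fragments are a subset of the tumor's
        t_set = set(map(tuple, t.frags.to_numpy()))
        n_set = set(map(tuple, n.frags.to_numpy()))
        assert n_set <= t_set
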