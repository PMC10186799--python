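"""Mapper, SAM I/O, pileup, coverage QC and variant filtering."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import symbiopop as sp
from symbiopop._seqcodes import encode, revcomp
from symbiopop.errors import ConfigurationError, PipelineError
from symbiopop.mapping import VariantFilters


def _pangenome(seqs: dict) -> sp.PangenomeReference:
    return sp.PangenomeReference([sp.Gene(k, v, "core") for k, v in seqs.items()])


def _random_seq(rng, n) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def toy_pangenome():
    rng = np.random.default_rng(5)
    return _pangenome({f"g{i}": _random_seq(rng, 400) for i in range(3)})


class TestMapReads:
    def test_exact_substring_maps_uniquely(self, toy_pangenome):
        seq = toy_pangenome.gene("g1").sequence[37 : 37 + 100]
        aset = sp.map_reads([("r1", seq)], toy_pangenome)
        assert aset.gene_ids == ["g1"]
        assert aset.starts[0] == 37 and aset.n_mismatches[0] == 0
        assert not aset.reverse[0]

    def test_reverse_complement_read_maps_to_forward_coordinates(self, toy_pangenome):
        seq = toy_pangenome.gene("g1").sequence[37 : 37 + 100]
        aset = sp.map_reads([("r1", revcomp(seq))], toy_pangenome)
        assert aset.gene_ids == ["g1"]
        assert aset.starts[0] == 37 and aset.reverse[0]
        assert aset.seqs[0] == seq  # stored in gene-forward orientation

    def test_read_shared_by_two_genes_is_ambiguous(self):
        rng = np.random.default_rng(6)
        shared = _random_seq(rng, 200)
        pg = _pangenome({
            "a": shared + _random_seq(rng, 200),
            "b": shared + _random_seq(rng, 200),
        })
        aset = sp.map_reads([("r1", shared[:120])], pg)
        assert len(aset) == 0
        assert aset.stats["ambiguous"] == 1

    def test_non_acgt_read_skipped_with_warning(self, toy_pangenome):
        seq = toy_pangenome.gene("g0").sequence[:100]
        with pytest.warns(UserWarning, match="non-ACGT"):
            aset = sp.map_reads([("r1", seq[:50] + "N" + seq[51:])], toy_pangenome)
        assert aset.stats["skipped_non_acgt"] == 1

    def test_too_diverged_read_unmapped(self, toy_pangenome):
        seq = list(toy_pangenome.gene("g0").sequence[:100])
        for i in range(0, 100, 10):  # 10 mismatches > 5% of 100
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        aset = sp.map_reads([("r1", "".join(seq))], toy_pangenome)
        assert len(aset) == 0 and aset.stats["unmapped"] == 1

    def test_empty_pangenome_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.PangenomeReference([])

    def test_agrees_with_bruteforce_hamming_scan(self):
        """Seeded mapper matches an exhaustive all-positions scan on small
        instances. Reads are planted with <= 2 mutations: an 80-bp read has
        four 21-mer seed windows of which a single mutation can spoil at
        most two, so two mutations always leave one window intact and the
        seeded candidate set provably contains the global optimum."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            pg = _pangenome({f"g{i}": _random_seq(rng, 300) for i in range(4)})
            reads = []
            for r in range(30):
                if rng.random() < 0.2:
                    reads.append((f"junk{r}", _random_seq(rng, 80)))
                    continue
                g = pg.genes[rng.integers(0, 4)]
                start = int(rng.integers(0, len(g) - 80 + 1))
                seq = list(g.sequence[start : start + 80])
                for _m in range(rng.integers(0, 3)):
                    i = int(rng.integers(0, 80))
                    seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
                s = "".join(seq)
                reads.append((f"r{r}", revcomp(s) if rng.random() < 0.5 else s))
            got = sp.map_reads(reads, pg, max_mismatch_frac=0.05)
            mapped = {
                rid: (gid, st, mm)
                for rid, gid, st, mm in zip(
                    got.read_ids, got.gene_ids, got.starts, got.n_mismatches
                )
            }
            oracle = self._bruteforce(reads, pg, 0.05)
            assert mapped == oracle

    @staticmethod
    def _bruteforce(reads, pg, max_frac):
        out = {}
        codes = {g.gene_id: encode(g.sequence) for g in pg.genes}
        for rid, seq in reads:
            rc = encode(seq)
            L = rc.size
            best_mm, best = int(max_frac * L) + 1, []
            for gid, gcodes in codes.items():
                for si, ref_read in enumerate((rc, encode(revcomp(seq)))):
                    for start in range(gcodes.size - L + 1):
                        mm = int(np.count_nonzero(gcodes[start : start + L] != ref_read))
                        if mm < best_mm:
                            best_mm, best = mm, [(gid, si, start)]
                        elif mm == best_mm:
                            best.append((gid, si, start))
            if not best or len({g for g, _s, _p in best}) > 1:
                continue
            # mirror mapper tie-break: prefer forward strand, then the lowest
            # start in strand-local coordinates (the mapper scans each strand
            # in its own frame before converting back)
            gid = best[0][0]
            glen = codes[gid].size
            si, local = min(
                (si, (glen - fwd - L) if si else fwd) for _g, si, fwd in best
            )
            start = (glen - local - L) if si else local
            out[rid] = (gid, start, best_mm)
        return out

    def test_simulated_reads_map_to_their_true_gene(self):
        """>= 99% of symbiont reads at 1% error find their origin gene."""
        cfg = sp.study_config(
            n_core_genes=40, n_variant_sites=100, samples_per_group=1,
            lifestyles=("host_associated",), error_rate=0.01,
            host_read_fraction=0.0, seed=23,
        )
        pg, reads, truth = sp.simulate_study(cfg)
        sid = cfg.samples[0].sample_id
        aset = sp.map_reads(reads[sid], pg, max_mismatch_frac=0.05)
        origins = truth.read_origins[sid].set_index("read_id")
        mapped = dict(zip(aset.read_ids, aset.gene_ids))
        correct = sum(
            1 for rid, row in origins.iterrows() if mapped.get(rid) == row.gene_id
        )
        assert correct / len(origins) >= 0.99


class TestSamIO:
    def test_round_trip_preserves_alignments(self, toy_pangenome, tmp_path):
        rng = np.random.default_rng(8)
        reads = []
        for i in range(40):
            g = toy_pangenome.genes[rng.integers(0, 3)]
            start = int(rng.integers(0, len(g) - 90))
            s = g.sequence[start : start + 90]
            reads.append((f"r{i}", revcomp(s) if i % 2 else s))
        aset = sp.map_reads(reads, toy_pangenome)
        path = tmp_path / "t.sam"
        sp.write_sam(aset, toy_pangenome, path)
        back = sp.read_sam(path, toy_pangenome, sample_id=aset.sample_id)
        assert back.read_ids == aset.read_ids
        assert back.gene_ids == aset.gene_ids
        assert np.array_equal(back.starts, aset.starts)
        assert np.array_equal(back.reverse, aset.reverse)
        assert back.seqs == aset.seqs
        assert np.array_equal(back.n_mismatches, aset.n_mismatches)

    def test_sam_pos_is_one_based(self, toy_pangenome, tmp_path):
        g0 = toy_pangenome.gene("g0")
        sam = tmp_path / "m.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            + "".join(f"@SQ\tSN:{g.gene_id}\tLN:{len(g)}\n" for g in toy_pangenome.genes)
            + f"r1\t0\tg0\t1\t60\t50M\t*\t0\t0\t{g0.sequence[:50]}\t*\n"
            + f"r2\t4\t*\t0\t0\t*\t*\t0\t0\t{g0.sequence[:50]}\t*\n"
        )
        aset = sp.read_sam(sam, toy_pangenome)
        assert aset.read_ids == ["r1"]  # unmapped r2 skipped
        assert aset.starts[0] == 0  # SAM POS=1 -> internal 0-based

    def test_unknown_reference_listed(self, toy_pangenome, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:nope\tLN:100\n")
        with pytest.raises(ConfigurationError, match="nope"):
            sp.read_sam(sam, toy_pangenome)


class TestPileup:
    def test_identical_reads_give_unanimous_counts(self, toy_pangenome):
        seq = toy_pangenome.gene("g2").sequence[10:110]
        aset = sp.map_reads([(f"r{i}", seq) for i in range(10)], toy_pangenome)
        ncm, _cov = sp.pileup_counts([aset], toy_pangenome)
        pos_55 = np.flatnonzero((ncm.gene_ids == "g2") & (ncm.positions == 65))[0]
        base = toy_pangenome.gene("g2").sequence[65]
        expected = np.zeros(4)
        expected["ACGT".index(base)] = 10
        assert np.array_equal(ncm.counts[pos_55, 0], expected)

    def test_depth_equals_overlapping_alignments(self, toy_pangenome):
        rng = np.random.default_rng(9)
        reads = []
        for i in range(60):
            g = toy_pangenome.genes[rng.integers(0, 3)]
            start = int(rng.integers(0, len(g) - 70))
            reads.append((f"r{i}", g.sequence[start : start + 70]))
        aset = sp.map_reads(reads, toy_pangenome)
        ncm, _ = sp.pileup_counts([aset], toy_pangenome)
        depth = ncm.depth()[:, 0]
        # conservation: total counts across sites == total aligned bases
        assert depth.sum() == sum(len(s) for s in aset.seqs)
        # spot-check one site against a direct overlap count
        gid, pos = ncm.gene_ids[13], ncm.positions[13]
        overlap = sum(
            1
            for j in range(len(aset))
            if aset.gene_ids[j] == gid and aset.starts[j] <= pos < aset.starts[j] + 70
        )
        assert depth[13] == overlap

    def test_simulated_coverage_near_nominal_depth(self, study_recovery):
        cov = study_recovery["coverage"]
        assert (np.abs(cov.mean_depth - 20.0) / 20.0 < 0.10).all()


class TestSampleQC:
    def _cov(self, depths):
        return pd.DataFrame(
            {"mean_depth": depths, "breadth": [1.0] * len(depths)},
            index=[f"s{i}" for i in range(len(depths))],
        )

    def test_boundary_depth_retained(self):
        qc = sp.sample_qc(self._cov([10.0]), 10.0)
        assert qc.retained == ["s0"]

    def test_low_coverage_sample_flagged(self):
        qc = sp.sample_qc(self._cov([12.0, 5.9]), 10.0)
        assert qc.retained == ["s0"] and qc.low_coverage == ["s1"]

    def test_empty_retained_set_raises(self):
        with pytest.raises(PipelineError, match="min_mean_depth"):
            sp.sample_qc(self._cov([3.9, 5.9]), 10.0)

    def test_raising_threshold_never_adds_samples(self):
        cov = self._cov([5.0, 10.0, 15.0, 25.0])
        prev = set(cov.index)
        for thr in (4, 8, 12, 20):
            cur = set(sp.sample_qc(cov, thr).retained)
            assert cur <= prev
            prev = cur


class TestCallVariants:
    def _ncm(self, counts):
        counts = np.asarray(counts)
        return sp.NucleotideCountMatrix(
            gene_ids=np.array(["g0"] * counts.shape[0], dtype=object),
            positions=np.arange(counts.shape[0]),
            samples=[f"s{i}" for i in range(counts.shape[1])],
            counts=counts,
        )

    def test_monomorphic_site_excluded(self):
        ncm = self._ncm([[[0, 20, 0, 0], [0, 20, 0, 0]]])
        vt = sp.call_variants(ncm, ["s0", "s1"])
        assert vt.n_sites == 0

    def test_alphabetical_tie_break_and_noise_allele(self):
        ncm = self._ncm([[[25, 0, 25, 0], [25, 0, 25, 1]]])
        vt = sp.call_variants(ncm, ["s0", "s1"], VariantFilters(noise_allele_max=2))
        assert vt.n_sites == 1
        assert vt.ref[0] == "A" and vt.alt[0] == "G"  # A=50 G=50 T=1 pooled

    def test_third_allele_above_noise_max_excluded(self):
        ncm = self._ncm([[[25, 0, 25, 2], [25, 0, 25, 2]]])
        vt = sp.call_variants(ncm, ["s0", "s1"], VariantFilters(noise_allele_max=2))
        assert vt.n_sites == 0  # pooled T=4 exceeds noise_allele_max

    def test_empty_result_warns_not_raises(self):
        ncm = self._ncm([[[0, 20, 0, 0], [0, 20, 0, 0]]])
        with pytest.warns(UserWarning, match="no sites"):
            vt = sp.call_variants(ncm, ["s0", "s1"])
        assert vt.n_sites == 0

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 30, size=(120, 3, 4))
        ncm = self._ncm(counts)
        samples = ncm.samples
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prev_depth = None
            for d in (5, 10, 20, 40):
                got = set(sp.call_variants(
                    ncm, samples, VariantFilters(min_site_depth=d)
                ).sites())
                if prev_depth is not None:
                    assert got <= prev_depth
                prev_depth = got
            prev_maf = None
            for m in (0.0, 0.05, 0.2, 0.4):
                got = set(sp.call_variants(
                    ncm, samples, VariantFilters(min_site_depth=5, min_maf=m)
                ).sites())
                if prev_maf is not None:
                    assert got <= prev_maf
                prev_maf = got

    def test_planted_site_recovery(self, study_recovery, variants_recovery):
        """>= 95% of planted polymorphisms recovered, <= 1% spurious calls."""
        planted = set(study_recovery["truth"].variant_sites)
        called = set(variants_recovery.sites())
        assert len(planted & called) / len(planted) >= 0.95
        assert len(called - planted) / len(called) <= 0.01
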