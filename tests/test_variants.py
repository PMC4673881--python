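"""Read trimming, alignment filtering, pileup calling and matrix filters,
each checked against a brute-force oracle where the rule has boundary
structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samgwas import synthgen
from samgwas.variants import (
    MISSING,
    AlignmentRecord,
    GenotypeMatrix,
    PileupSite,
    ReadRecord,
    call_site,
    filter_alignment,
    filter_matrix,
    merge_consensus,
    pileups_from_alignments,
    read_fastq,
    read_sam,
    read_vcf,
    trim_read,
    write_fastq,
    write_sam,
    write_vcf,
)


def mk_read(quals, bases=None):
    bases = bases or "A" * len(quals)
    return ReadRecord(id="r", bases=bases, qualities=list(quals))


def brute_force_trim(quals, q=15, w=10):
    """Independent scanner: iterate end-stripping and full window enumeration
    to a fixed point."""
    quals = list(quals)
    while True:
        before = list(quals)
        while quals and quals[0] < q:
            quals.pop(0)
        while quals and quals[-1] < q:
            quals.pop()
        if len(quals) >= w:
            for start in range(len(quals) - w + 1):
                if sum(quals[start : start + w]) / w < q:
                    quals = quals[:start]
                    break
        if quals == before:
            return quals


class TestTrimRead:
    def test_high_quality_identity(self):
        r = mk_read([40] * 30)
        out = trim_read(r)
        assert out.bases == r.bases and out.qualities == r.qualities

    def test_all_low_quality_empty(self):
        assert len(trim_read(mk_read([10] * 30))) == 0

    def test_three_prime_degradation_stripped(self):
        # 30 good bases then a 20-base q5 run: end stripping removes the run
        r = mk_read([30] * 30 + [5] * 20)
        out = trim_read(r)
        assert len(out) == 30
        assert out.qualities == [30] * 30
        assert out.qualities == brute_force_trim(r.qualities)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        quals = rng.integers(0, 41, rng.integers(1, 80)).tolist()
        out = trim_read(mk_read(quals))
        assert out.qualities == brute_force_trim(quals)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=0, max_size=60))
    def test_idempotent(self, quals):
        if not quals:
            return
        once = trim_read(mk_read(quals))
        twice = trim_read(once)
        assert once.bases == twice.bases and once.qualities == twice.qualities


class TestFilterAlignment:
    def mk(self, length, mismatches, tail, unique=True):
        return AlignmentRecord("r", "chr1", 0, length, mismatches, tail, unique)

    @pytest.mark.parametrize(
        "length,mm,tail,keep",
        [
            (36, 2, 0, True),   # boundary: two or less per 36 bp
            (36, 3, 0, False),  # just over the mismatch bound
            (75, 0, 4, True),   # fewer than five tail bases per 75 bp
            (75, 0, 5, False),  # exactly five is rejected
            (72, 4, 0, True),   # two 36-bp units → 4 allowed
            (72, 5, 0, False),
            (150, 0, 9, True),  # two 75-bp units → tail < 10
            (150, 0, 10, False),
        ],
    )
    def test_boundaries(self, length, mm, tail, keep):
        assert filter_alignment(self.mk(length, mm, tail)) is keep

    def test_non_unique_rejected(self):
        assert not filter_alignment(self.mk(36, 0, 0, unique=False))


class TestCallSite:
    def obs(self, n, base="T", q=20, off_start=10, off_end=10, prefix="r"):
        return [(f"{prefix}{i}", base, q, off_start, off_end) for i in range(n)]

    def test_minimal_passing_alt_call(self):
        pile = PileupSite("chr1", 100, "A", self.obs(5))
        assert call_site(pile) == 2

    def test_four_reads_insufficient(self):
        pile = PileupSite("chr1", 100, "A", self.obs(4, q=40))
        assert call_site(pile) == MISSING

    def test_edge_and_quality_masking(self):
        # 6 ALT reads: 2 within 3 bases of a read end, 1 at q19 → 3 usable
        obs = (
            self.obs(3, q=30)
            + [("e1", "T", 30, 2, 50), ("e2", "T", 30, 50, 1)]
            + [("q1", "T", 19, 10, 10)]
        )
        pile = PileupSite("chr1", 100, "A", obs)
        usable = [o for o in obs if o[3] >= 3 and o[4] >= 3 and o[2] >= 20]
        assert len(usable) == 3  # brute-force refilter
        assert call_site(pile) == MISSING

    def test_com_hom_mirror_rule(self):
        pile = PileupSite("chr1", 100, "A", self.obs(8, base="A", q=30))
        assert call_site(pile) == 0

    def test_mixed_pileup_fails_purity(self):
        obs = self.obs(6, base="T", prefix="a") + self.obs(4, base="A", prefix="b")
        pile = PileupSite("chr1", 100, "A", obs)
        assert call_site(pile) == MISSING  # 0.6 ALT fraction < 0.9 purity


def toy_matrix(calls, source="genomic"):
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(n_sites) * 100,
            "com": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n_ind)], sites=sites, calls=calls, source=source
    )


class TestMergeConsensus:
    def test_agreement_kept(self):
        a = toy_matrix([[0], [2]])
        b = toy_matrix([[0], [2]])
        m = merge_consensus([a, b])
        assert m.calls.tolist() == [[0], [2]]

    def test_conflict_scored_missing(self):
        a = toy_matrix([[0]])
        b = toy_matrix([[2]])
        assert merge_consensus([a, b]).calls[0, 0] == MISSING

    def test_missing_ignored_with_concrete_call(self):
        a = toy_matrix([[MISSING]])
        b = toy_matrix([[2]])
        assert merge_consensus([a, b]).calls[0, 0] == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        runs = [toy_matrix(rng.choice([0, 2, MISSING], size=(6, 10))) for _ in range(3)]
        fwd = merge_consensus(runs).calls
        rev = merge_consensus(runs[::-1]).calls
        np.testing.assert_array_equal(fwd, rev)

    def test_allele_collision_is_error(self):
        a = toy_matrix([[0]])
        b = toy_matrix([[0]])
        b.sites.loc[0, "alt"] = "G"
        with pytest.raises(ValueError, match="collision"):
            merge_consensus([a, b])


class TestFilterMatrix:
    def test_maf_arithmetic_boundary(self):
        # 3 ALT-hom among 400 non-missing → MAF 0.0075 < 0.01 → dropped
        calls = np.zeros((400, 1), dtype=np.int8)
        calls[:3, 0] = 2
        assert filter_matrix(toy_matrix(calls)).n_sites == 0
        calls[3, 0] = 2  # 4/400 = 0.01 → kept
        assert filter_matrix(toy_matrix(calls)).n_sites == 1

    def test_missingness_strictly_over_60(self):
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[:5, :] = 2  # keep MAF safe
        calls[5:66, 0] = MISSING  # 61% missing → dropped
        calls[5:65, 1] = MISSING  # 60% missing → kept
        m = filter_matrix(toy_matrix(calls))
        assert m.n_sites == 1 and m.sites.loc[0, "pos"] == 100

    def test_brute_force_recount(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 2, MISSING], size=(50, 40), p=[0.75, 0.1, 0.15])
        m = toy_matrix(calls)
        log = {}
        kept = filter_matrix(m, log=log)
        survivors = 0
        for j in range(40):
            col = calls[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            p_alt = (obs == 2).mean()
            maf = min(p_alt, 1 - p_alt)
            miss = (col == MISSING).mean()
            if maf >= 0.01 and miss <= 0.60:
                survivors += 1
        assert kept.n_sites == survivors == log["n_kept"]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 2, MISSING], size=(30, 25), p=[0.8, 0.08, 0.12])
        once = filter_matrix(toy_matrix(calls))
        twice = filter_matrix(once)
        np.testing.assert_array_equal(once.calls, twice.calls)


class TestRoundTrips:
    def test_reads_to_matrix_roundtrip(self):
        """Error-free reads at depth 10 reconstruct the generating genotype."""
        rng = np.random.default_rng(3)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        sites = [(150, "T" if ref[150] != "T" else "C"), (400, "G" if ref[400] != "G" else "A")]
        _, alns = synthgen.gen_reads(ref, sites, depth=10, seed=5)
        kept = [a for a in alns if filter_alignment(a)]
        piles = pileups_from_alignments(kept, {"chr1": ref})
        assert call_site(piles[("chr1", 150)]) == 2
        assert call_site(piles[("chr1", 400)]) == 2
        assert call_site(piles[("chr1", 300)]) == 0  # non-variant site is COM

    def test_fastq_roundtrip(self, tmp_path):
        reads = [mk_read([2, 20, 40], bases="ACG"), mk_read([0, 40, 33], bases="TTT")]
        write_fastq(reads, tmp_path / "x.fastq")
        back = read_fastq(tmp_path / "x.fastq")
        assert [r.bases for r in back] == ["ACG", "TTT"]
        assert [r.qualities for r in back] == [[2, 20, 40], [0, 40, 33]]

    def test_sam_roundtrip(self, tmp_path):
        ref = {"chr1": "ACGT" * 30}
        alns = [
            AlignmentRecord("r1", "chr1", 4, 8, 1, 0, True, bases="CGTACGTA", qualities=[30] * 8)
        ]
        write_sam(alns, ref, tmp_path / "x.sam")
        back = read_sam(tmp_path / "x.sam")
        a = back[0]
        assert (a.read_id, a.chrom, a.pos, a.mismatches, a.unique) == ("r1", "chr1", 4, 1, True)
        assert a.bases == "CGTACGTA" and a.qualities == [30] * 8

    def test_vcf_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 2, MISSING], size=(8, 12))
        m = toy_matrix(calls)
        write_vcf(m, tmp_path / "x.vcf")
        back = read_vcf(tmp_path / "x.vcf")
        assert back.individuals == m.individuals
        np.testing.assert_array_equal(back.calls, m.calls)
        pd.testing.assert_frame_equal(back.sites, m.sites)
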