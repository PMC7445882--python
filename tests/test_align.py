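"""Banded aligner vs full DP oracle; strand pileups; SAM import."""

import random

import numpy as np
import pytest

import oracles
from nanoverify import dna
from nanoverify.align import (
    Alignment,
    BandError,
    StrandPileup,
    align_read,
    build_pileup,
    identify_target,
    import_sam,
    read_pileup_tsv,
)
from nanoverify.simulate import ErrorModel, simulate_reads


def _mutate(target, rng, n_ops):
    read = list(target)
    for _ in range(n_ops):
        op = rng.choice("sid")
        p = rng.randrange(len(read)) if read else 0
        if op == "s" and read:
            read[p] = rng.choice("ACGT")
        elif op == "i":
            read.insert(p, rng.choice("ACGT"))
        elif op == "d" and len(read) > 1:
            del read[p]
    return "".join(read)


class TestAlignRead:
    def test_identity_alignment(self):
        t = "ACGTACGTACGTACGT"
        a = align_read(t, t)
        assert a.score == 2 * len(t)
        assert a.pairs == [(i, i) for i in range(len(t))]

    def test_single_deletion_located(self):
        target = "ACGTTGCATGCAGTACCATG"
        read = target[:9] + target[10:]  # drop position 9
        a = align_read(read, target)
        gaps = [(t, r) for t, r in a.pairs if r is None]
        assert gaps == [(9, None)]
        assert not [p for p in a.pairs if p[0] is None]

    def test_banded_equals_full_dp_oracle(self):
        rng = random.Random(17)
        for k in range(50):
            n = rng.randint(5, 200)
            target = "".join(rng.choice("ACGT") for _ in range(n))
            if k % 4 == 0:
                read = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 200)))
            else:
                read = _mutate(target, rng, rng.randint(0, 15))
            band = abs(len(read) - len(target)) + 30
            a = align_read(read, target, band_width=band)
            assert a.score == oracles.gotoh_semiglobal_score(read, target), (read, target)

    def test_traceback_score_consistency(self):
        rng = random.Random(23)
        for _ in range(30):
            n = rng.randint(10, 150)
            target = "".join(rng.choice("ACGT") for _ in range(n))
            read = _mutate(target, rng, rng.randint(0, 12))
            a = align_read(read, target)
            s, gap_run = 0, None
            for t, r in a.pairs:
                if t is not None and r is not None:
                    s += 2 if read[r] == target[t] else -3
                    gap_run = None
                else:
                    kind = "del" if r is None else "ins"
                    if gap_run != kind:
                        s -= 4
                        gap_run = kind
                    s -= 2
            assert s == a.score
            tpos = [t for t, _ in a.pairs if t is not None]
            assert tpos == sorted(set(tpos))  # strictly increasing

    def test_narrow_band_bounded_by_optimum(self):
        # path wanders 40 diagonals off-centre (insertion then deletion of
        # equal size): a narrow band returns its within-band optimum, never
        # more than the full-matrix optimum; a sufficient band recovers it
        rng = random.Random(3)
        target = "".join(rng.choice("ACGT") for _ in range(200))
        extra = "".join(rng.choice("ACGT") for _ in range(40))
        read = target[:60] + extra + target[60:120] + target[160:]
        full = oracles.gotoh_semiglobal_score(read, target)
        narrow = align_read(read, target, band_width=8)
        assert narrow.score <= full
        wide = align_read(read, target, band_width=41)
        assert wide.score == full

    def test_deterministic(self):
        rng = random.Random(5)
        target = "".join(rng.choice("ACGT") for _ in range(120))
        read = _mutate(target, rng, 8)
        a1 = align_read(read, target)
        a2 = align_read(read, target)
        assert a1.pairs == a2.pairs and a1.score == a2.score

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_read("", "ACGT")
        with pytest.raises(ValueError):
            align_read("ACGT", "")


class TestIdentifyTarget:
    def test_picks_true_target(self):
        rng = np.random.default_rng(6)
        targets = {f"t{i}": dna.random_dna(rng, 150) for i in range(3)}
        model = ErrorModel(0.07, 0.015, 0.015, seed=6)
        reads = simulate_reads(targets["t1"], 1, 1, model)
        for r in reads:
            tid, margin = identify_target(r.sequence, targets)
            assert tid == "t1" and margin > 0

    def test_single_target_margin_infinite(self):
        tid, margin = identify_target("ACGTACGT", {"only": "ACGTACGTAA"})
        assert tid == "only" and margin == float("inf")

    def test_identical_targets_ambiguous(self):
        t = "ACGTACGTACGTACGT"
        tid, margin = identify_target(t, {"a": t, "b": t})
        assert margin == 0


class TestBuildPileup:
    def test_perfect_forward_read(self):
        t = "ACGTACGT"
        a = align_read(t, t)
        pile = build_pileup([(a, t)], t)
        for i, base in enumerate(t):
            assert pile.counts[i, 0, dna.SYMBOL_INDEX[base]] == 1
            assert pile.counts[i].sum() == 1
        assert pile.max_depth() == 1

    def test_counts_conservation(self):
        rng = random.Random(9)
        t = "".join(rng.choice("ACGT") for _ in range(100))
        alns = []
        expected = 0
        for _ in range(10):
            read = _mutate(t, rng, 6)
            a = align_read(read, t)
            alns.append((a, read))
            expected += sum(1 for tp, _ in a.pairs if tp is not None)
        pile = build_pileup(alns, t)
        assert pile.counts.sum() == expected

    def test_strand_separation_and_order_invariance(self):
        rng = random.Random(11)
        t = "".join(rng.choice("ACGT") for _ in range(80))
        alns = []
        for i in range(8):
            read = _mutate(t, rng, 4)
            strand = "forward" if i % 2 == 0 else "reverse"
            alns.append((align_read(read, t, strand=strand), read))
        p1 = build_pileup(alns, t)
        p2 = build_pileup(list(reversed(alns)), t)
        assert (p1.counts == p2.counts).all()
        n_fwd_alns = sum(1 for a, _ in alns if a.strand == "forward")
        # forward columns only ever touched by forward alignments
        assert p1.depths()[:, 0].max() <= n_fwd_alns

    def test_systematic_site_counts(self):
        template = dna.random_dna(np.random.default_rng(12), 90)
        pos = 45
        alt = next(b for b in "ACGT" if b != template[pos])
        from nanoverify.simulate import SystematicErrorSite

        site = SystematicErrorSite(pos, "forward", alt, rate=0.9)
        model = ErrorModel(0.0, 0.0, 0.0, seed=12)
        reads = simulate_reads(template, 30, 30, model, sites=[site])
        alns = []
        n_fired = 0
        for r in reads:
            strand = r.id.rsplit("strand=", 1)[-1]
            seq = r.sequence if strand == "forward" else dna.revcomp(r.sequence)
            if strand == "forward" and seq[pos] == alt:
                n_fired += 1
            alns.append((align_read(seq, template, strand=strand), seq))
        pile = build_pileup(alns, template)
        ai = dna.SYMBOL_INDEX[alt]
        assert pile.counts[pos, 0, ai] == n_fired
        assert n_fired >= 20  # rate 0.9 of 30
        assert pile.counts[pos, 1, ai] == 0

    def test_out_of_range_alignment_rejected(self):
        a = Alignment("r", "t", "forward", [(5, 0)], 0)
        pile = StrandPileup("t", 3)
        with pytest.raises(ValueError):
            pile.add_alignment(a, "ACGT")

    def test_tsv_roundtrip(self, tmp_path):
        rng = random.Random(13)
        t = "".join(rng.choice("ACGT") for _ in range(40))
        alns = [(align_read(_mutate(t, rng, 3), t), None) for _ in range(4)]
        alns = [(a, r if r else _mutate(t, rng, 0)) for a, r in alns]
        pile = build_pileup([(align_read(t, t), t)], t)
        path = tmp_path / "pile.tsv"
        pile.write_tsv(path, t)
        back, ref = read_pileup_tsv(path)
        assert (back.counts == pile.counts).all()
        assert ref == t


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:tgt\tLN:20\n"
TGT = "ACGTACGTACGTACGTACGT"


class TestImportSam:
    def test_handwritten_sam_exact_counts(self, tmp_path):
        # read1: 20M forward, one mismatch at pos 5 (C->G)
        r1 = TGT[:5] + "G" + TGT[6:]
        # read2: 8M2D10M forward: deletion of positions 8-9
        r2 = TGT[:8] + TGT[10:]
        # read3: reverse strand (FLAG 16), 20M perfect
        sam = SAM_HEADER
        sam += f"r1\t0\ttgt\t1\t60\t20M\t*\t0\t0\t{r1}\t*\n"
        sam += f"r2\t0\ttgt\t1\t60\t8M2D10M\t*\t0\t0\t{r2}\t*\n"
        sam += f"r3\t16\ttgt\t1\t60\t20M\t*\t0\t0\t{TGT}\t*\n"
        path = tmp_path / "three.sam"
        path.write_text(sam)
        pile = import_sam(path, TGT)
        # manual CIGAR walk expectations: r3 (reverse) covers every position
        for i, b in enumerate(TGT):
            assert pile.counts[i, 1, dna.SYMBOL_INDEX[b]] == 1
        assert pile.counts[5, 0, dna.SYMBOL_INDEX["G"]] == 1  # r1 mismatch
        assert pile.counts[5, 0, dna.SYMBOL_INDEX[TGT[5]]] == 1  # r2 ref base
        assert pile.counts[8, 0, dna.SYMBOL_INDEX[dna.DEL]] == 1
        assert pile.counts[9, 0, dna.SYMBOL_INDEX[dna.DEL]] == 1
        assert pile.counts[8, 0, dna.SYMBOL_INDEX[TGT[8]]] == 1  # from r1
        assert pile.counts.sum() == 60  # 20 + 20 + 20 columns incl. deletions

    def test_empty_sam(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text(SAM_HEADER)
        pile = import_sam(path, TGT)
        assert pile.counts.sum() == 0

    def test_unmapped_read_skipped(self, tmp_path):
        path = tmp_path / "unmapped.sam"
        path.write_text(SAM_HEADER + f"u1\t4\t*\t0\t0\t*\t*\t0\t0\t{TGT}\t*\n")
        pile = import_sam(path, TGT)
        assert pile.counts.sum() == 0

    def test_matches_internal_pileup(self, tmp_path):
        # same three alignments built internally give identical counts
        r1 = TGT[:5] + "G" + TGT[6:]
        r2 = TGT[:8] + TGT[10:]
        alns = [
            (align_read(r1, TGT, read_id="r1"), r1),
            (align_read(r2, TGT, read_id="r2"), r2),
            (align_read(TGT, TGT, read_id="r3", strand="reverse"), TGT),
        ]
        internal = build_pileup(alns, TGT)
        sam = SAM_HEADER
        sam += f"r1\t0\ttgt\t1\t60\t20M\t*\t0\t0\t{r1}\t*\n"
        sam += f"r2\t0\ttgt\t1\t60\t8M2D10M\t*\t0\t0\t{r2}\t*\n"
        sam += f"r3\t16\ttgt\t1\t60\t20M\t*\t0\t0\t{TGT}\t*\n"
        path = tmp_path / "same.sam"
        path.write_text(sam)
        external = import_sam(path, TGT)
        assert (internal.counts == external.counts).all()
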