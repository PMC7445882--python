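"""Banded semi-global alignment and strand-separated pileups.

The aligner is a Gotoh affine-gap dynamic program restricted to a
diagonal band, with free end gaps on the read side (leading/trailing
target may be skipped at no cost).  Rows are vectorised with numpy; the
within-row horizontal-gap recurrence is replaced by an exact running-max
formulation over gap-open sources, which is valid because re-opening a
gap out of a just-closed gap is always dominated by extending it.

All scores are integers so traceback can rely on exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from . import dna

NEG = -(1 << 40)  # -infinity sentinel that survives a few additions


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 4  # positive penalties; gap of length L costs open + ext*L
    gap_extend: int = 2


DEFAULT_SCORING = Scoring()
DEFAULT_BAND = 64


class BandError(RuntimeError):
    """The band could not connect the alignment endpoints."""


@dataclass
class Alignment:
    read_id: str
    target_id: str
    strand: str  # forward | reverse
    pairs: list[tuple[int | None, int | None]]  # (target_pos, read_pos); None = gap
    score: int

    def aligned_columns(self) -> int:
        return sum(1 for t, r in self.pairs if t is not None)


def _band_matrices(read: np.ndarray, target: np.ndarray, w: int, sc: Scoring):
    """Fill banded H/E/F/HnoE matrices; returns them plus band geometry."""
    m, n = len(read), len(target)
    dlo = min(0, n - m) - w
    dhi = max(0, n - m) + w
    W = dhi - dlo + 1
    open_, ext = sc.gap_open, sc.gap_extend

    H = np.full((m + 1, W), NEG, dtype=np.int64)
    E = np.full((m + 1, W), NEG, dtype=np.int64)
    F = np.full((m + 1, W), NEG, dtype=np.int64)
    HN = np.full((m + 1, W), NEG, dtype=np.int64)  # max(diag, F): E-chain sources

    o_idx = np.arange(W)
    j0 = dlo + o_idx  # j at row 0
    H[0][(j0 >= 0) & (j0 <= n)] = 0

    pad = np.array([NEG], dtype=np.int64)
    for i in range(1, m + 1):
        j = i + dlo + o_idx
        in_band = (j >= 0) & (j <= n)
        has_diag = j >= 1  # D and E consume a target base
        jc = np.clip(j - 1, 0, n - 1)
        sub = np.where(target[jc] == read[i - 1], sc.match, sc.mismatch)
        D = H[i - 1] + sub
        D[~has_diag] = NEG
        Hprev_s = np.concatenate([H[i - 1, 1:], pad])
        Fprev_s = np.concatenate([F[i - 1, 1:], pad])
        Fi = np.maximum(Fprev_s, Hprev_s - open_) - ext
        Fi[~in_band] = NEG
        hn = np.maximum(D, Fi)
        hn[~in_band] = NEG
        c = np.maximum.accumulate(hn + ext * o_idx)
        Ei = np.concatenate([pad, c[:-1]]) - open_ - ext * o_idx
        Ei[~(in_band & has_diag)] = NEG
        Hi = np.maximum(hn, Ei)
        H[i], E[i], F[i], HN[i] = Hi, Ei, Fi, hn
    return H, E, F, HN, dlo, W


def _traceback(H, E, F, HN, dlo, W, read, target, sc: Scoring):
    """Walk back from the best last-row cell; returns (pairs, score, touched_edge)."""
    m, n = len(read), len(target)
    open_, ext = sc.gap_open, sc.gap_extend
    last = H[m].copy()
    j_last = m + dlo + np.arange(W)
    last[(j_last < 0) | (j_last > n)] = NEG
    o = int(np.argmax(last))
    score = int(last[o])
    if score <= NEG // 2:
        raise BandError("no path through the band")

    pairs: list[tuple[int | None, int | None]] = []
    touched = False
    i, state = m, "H"
    while i > 0:
        j = i + dlo + o
        if 0 < i < m and (o == 0 or o == W - 1) and 0 < j < n:
            touched = True
        if state == "H":
            if H[i][o] == E[i][o] and E[i][o] > NEG // 2 and H[i][o] != HN[i][o]:
                state = "E"
                continue
            sub = sc.match if target[j - 1] == read[i - 1] else sc.mismatch
            if j >= 1 and H[i][o] == H[i - 1][o] + sub:
                pairs.append((j - 1, i - 1))
                i -= 1
                continue
            if H[i][o] == E[i][o]:
                state = "E"
                continue
            state = "F"
            continue
        if state == "E":
            pairs.append((j - 1, None))  # deletion in read: target base unmatched
            if E[i][o] == E[i][o - 1] - ext:
                o -= 1
                continue
            # gap opened from the non-E cell value to the left
            o -= 1
            state = "HN"
            continue
        if state == "HN":
            j = i + dlo + o
            sub = sc.match if j >= 1 and target[j - 1] == read[i - 1] else None
            if sub is not None and HN[i][o] == H[i - 1][o] + sub:
                pairs.append((j - 1, i - 1))
                i -= 1
                state = "H"
                continue
            state = "F"
            continue
        # state == "F": insertion in read (read base with no target)
        pairs.append((None, i - 1))
        if F[i][o] == F[i - 1][o + 1] - ext:
            i -= 1
            o += 1
            continue
        i -= 1
        o += 1
        state = "H"
    pairs.reverse()
    return pairs, score, touched


def align_read(
    read_seq: str,
    target: str,
    band_width: int = DEFAULT_BAND,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    target_id: str = "target",
    strand: str = "forward",
) -> Alignment:
    """Banded semi-global alignment of a read against a target.

    The band is doubled automatically (up to 4x) when the optimal path
    touches the band edge or no path connects the endpoints; a still
    disconnected band raises :class:`BandError`.
    """
    if not read_seq or not target:
        raise ValueError("read and target must be non-empty")
    rv = dna.seq_to_array(dna.validate_dna(read_seq, "read"))
    tv = dna.seq_to_array(dna.validate_dna(target, "target"))
    w = band_width
    last_exc: BandError | None = None
    for attempt in range(3):  # w, 2w, 4w
        try:
            H, E, F, HN, dlo, W = _band_matrices(rv, tv, w, scoring)
            pairs, score, touched = _traceback(H, E, F, HN, dlo, W, rv, tv, scoring)
        except BandError as exc:
            last_exc = exc
            w *= 2
            continue
        if touched and attempt < 2:
            w *= 2
            continue
        return Alignment(read_id, target_id, strand, pairs, score)
    raise BandError(f"band width {band_width} (doubled to {w}) cannot connect endpoints: {last_exc}")


def identify_target(
    read_seq: str,
    targets: dict[str, str],
    band_width: int = DEFAULT_BAND,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[str, float]:
    """Best-scoring target over both read orientations, with score margin.

    Returns ``(target_id, margin)``; margin is ``inf`` for a single
    target and 0 marks an ambiguous identification.
    """
    if not targets:
        raise ValueError("need at least one target")
    scores: dict[str, int] = {}
    for tid, tseq in targets.items():
        best = NEG
        for seq in (read_seq, dna.revcomp(read_seq)):
            try:
                best = max(best, align_read(seq, tseq, band_width, scoring).score)
            except BandError:
                continue
        scores[tid] = best
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        return ranked[0][0], float("inf")
    return ranked[0][0], float(ranked[0][1] - ranked[1][1])


# --- pileup ------------------------------------------------------------------

STRANDS = ("forward", "reverse")


@dataclass
class StrandPileup:
    """Per-position, per-strand counts of A/C/G/T/deletion plus insertions."""

    target_id: str
    length: int
    counts: np.ndarray = None  # shape (length, 2, 5); strand 0=fwd 1=rev
    insertions: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    # insertions keyed by (preceding target position, inserted sequence) -> [fwd, rev]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.length, 2, 5), dtype=np.int64)

    def depth(self, pos: int, strand: int) -> int:
        return int(self.counts[pos, strand].sum())

    def depths(self) -> np.ndarray:
        """(length, 2) per-strand depths."""
        return self.counts.sum(axis=2)

    def max_depth(self) -> int:
        if self.length == 0:
            return 0
        return int(self.depths().sum(axis=1).max())

    def add_alignment(self, aln: Alignment, read_seq: str) -> None:
        s = 0 if aln.strand == "forward" else 1
        ins_run: list[str] = []
        last_t = None
        for t, r in aln.pairs:
            if t is None:
                ins_run.append(read_seq[r])
                continue
            if not 0 <= t < self.length:
                raise ValueError(f"alignment position {t} outside target of length {self.length}")
            if ins_run:
                key = (last_t if last_t is not None else -1, "".join(ins_run))
                self.insertions.setdefault(key, np.zeros(2, dtype=np.int64))[s] += 1
                ins_run = []
            if r is None:
                self.counts[t, s, dna.SYMBOL_INDEX[dna.DEL]] += 1
            else:
                b = read_seq[r]
                if b in dna.SYMBOL_INDEX:
                    self.counts[t, s, dna.SYMBOL_INDEX[b]] += 1
            last_t = t
        if ins_run:
            key = (last_t if last_t is not None else -1, "".join(ins_run))
            self.insertions.setdefault(key, np.zeros(2, dtype=np.int64))[s] += 1

    def to_frame(self, target: str | None = None) -> pd.DataFrame:
        cols = {}
        cols["pos"] = np.arange(self.length)
        cols["ref"] = list(target) if target else ["N"] * self.length
        for si, tag in ((0, "f"), (1, "r")):
            for b in dna.SYMBOLS:
                name = ("DEL" if b == dna.DEL else b) + f"_{tag}"
                cols[name] = self.counts[:, si, dna.SYMBOL_INDEX[b]]
        return pd.DataFrame(cols)

    def write_tsv(self, path, target: str | None = None) -> None:
        self.to_frame(target).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path, target_id: str = "target") -> tuple[StrandPileup, str]:
    df = pd.read_csv(path, sep="\t")
    pile = StrandPileup(target_id=target_id, length=len(df))
    for si, tag in ((0, "f"), (1, "r")):
        for b in dna.SYMBOLS:
            name = ("DEL" if b == dna.DEL else b) + f"_{tag}"
            pile.counts[:, si, dna.SYMBOL_INDEX[b]] = df[name].to_numpy()
    ref = "".join(df["ref"].astype(str))
    return pile, ref


def build_pileup(
    alignments: list[tuple[Alignment, str]],
    target: str,
    target_id: str = "target",
) -> StrandPileup:
    """Accumulate (alignment, oriented read sequence) pairs into a pileup."""
    pile = StrandPileup(target_id=target_id, length=len(target))
    for aln, seq in alignments:
        pile.add_alignment(aln, seq)
    return pile


def import_sam(sam_path, target: str, target_id: str | None = None) -> StrandPileup:
    """Build a pileup from an external SAM alignment via a CIGAR walk.

    FLAG bit 16 sets the strand; unmapped, secondary and supplementary
    records are skipped, as are records with missing sequence or CIGAR
    (counted as warnings on the returned pileup's ``n_skipped``).
    """
    pile = StrandPileup(target_id=target_id or "target", length=len(target))
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        if target_id is None and sam.references:
            pile.target_id = sam.references[0]
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None or rec.query_sequence is None:
                n_skipped += 1
                continue
            strand = "reverse" if rec.is_reverse else "forward"
            pairs: list[tuple[int | None, int | None]] = []
            qpos, tpos = 0, rec.reference_start
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    pairs.extend((tpos + k, qpos + k) for k in range(ln))
                    qpos += ln
                    tpos += ln
                elif op == 1:  # I
                    pairs.extend((None, qpos + k) for k in range(ln))
                    qpos += ln
                elif op == 2:  # D
                    pairs.extend((tpos + k, None) for k in range(ln))
                    tpos += ln
                elif op in (4,):  # soft clip
                    qpos += ln
                elif op in (3,):  # N: skip region
                    tpos += ln
                # H/P consume nothing
            aln = Alignment(rec.query_name, pile.target_id, strand, pairs, 0)
            pile.add_alignment(aln, rec.query_sequence.upper())
    pile.n_skipped = n_skipped  # type: ignore[attr-defined]
    return pile
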