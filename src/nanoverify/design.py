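"""Barcoded-primer design.

Candidate barcodes are drawn at random, scored for secondary-structure
propensity, ranked, filtered for mutual edit distance and assembled onto
universal binding sites.  Forward barcodes index plates, reverse
barcodes index wells, so ``n_forward x n_reverse`` primer pairs address
every well of every plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dna
from ._edit import levenshtein_batch

MIN_BARCODE_LENGTH = 8

WELL_ROWS = "ABCDEFGH"
WELL_COLS = 12


@dataclass(frozen=True)
class Barcode:
    """A short index sequence with a structure score (higher = less structure)."""

    sequence: str
    delta_g_score: float
    role: str = "unassigned"  # forward | reverse | unassigned

    def __post_init__(self) -> None:
        dna.validate_dna(self.sequence, "barcode")
        if not np.isfinite(self.delta_g_score):
            raise ValueError("delta_g_score must be finite")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair addressing one well of one plate."""

    plate_index: int  # 1-based
    well_label: str  # A1..H12
    fwd_barcode: str
    rev_barcode: str
    forward_primer: str  # fwd barcode + forward binding site
    reverse_primer: str  # rev barcode + reverse binding site

    @property
    def sample_id(self) -> str:
        return f"plate{self.plate_index}_{self.well_label}"


def well_labels(n: int) -> list[str]:
    """Row-major 96-well labels A1..H12, truncated to the first ``n``."""
    if n > len(WELL_ROWS) * WELL_COLS:
        raise ValueError(f"cannot label {n} wells on a 96-well plate")
    labels = [f"{r}{c}" for r in WELL_ROWS for c in range(1, WELL_COLS + 1)]
    return labels[:n]


def generate_candidates(
    n: int,
    length: int = 24,
    seed: int = 0,
    gc_min: float = 0.30,
    gc_max: float = 0.70,
) -> list[Barcode]:
    """Generate ``n`` distinct random barcodes of ``length`` nt.

    Candidates are uniform random DNA filtered to ``gc_min..gc_max`` GC
    content; generation is deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < MIN_BARCODE_LENGTH:
        raise ValueError(
            f"barcode length {length} < {MIN_BARCODE_LENGTH}: too short for "
            "error-tolerant matching"
        )
    if n > 4**length:
        raise ValueError(f"cannot produce {n} distinct {length}-mers (only {4**length} exist)")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[Barcode] = []
    attempts = 0
    max_attempts = 10_000 + 400 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not generate {n} distinct candidates after {attempts} draws "
                f"(got {len(out)}); relax the GC bounds or shorten the request"
            )
        seq = dna.random_dna(rng, length)
        if seq in seen:
            continue
        if not (gc_min <= dna.gc_fraction(seq) <= gc_max):
            continue
        seen.add(seq)
        out.append(Barcode(seq, score_structure(seq)))
    return out


def _stems(sequence: str, min_stem: int = 4) -> list[tuple[int, int, int]]:
    """Maximal intramolecular self-complementary stems of length >= min_stem.

    A stem pairs ``sequence[i:i+k]`` with the reverse complement of
    ``sequence[j:j+k]`` (``i <= j``); returned as ``(i, j, k)`` tuples,
    maximal in the sense that no further complementary base pair extends
    the run on either side.
    """
    s = sequence
    L = len(s)
    comp = dict(zip("ACGT", "TGCA"))
    pair = [[comp[a] == b for b in s] for a in s]  # pair[x][y]: x can base-pair y

    stems: list[tuple[int, int, int]] = []
    # anti-diagonal runs in the pairing matrix: x increases while y decreases
    for x0 in range(L):
        for y0 in range(L - 1, x0 - 1, -1):
            # start of a run only if the previous anti-diagonal cell is absent/false
            if x0 > 0 and y0 < L - 1 and pair[x0 - 1][y0 + 1]:
                continue
            if not pair[x0][y0]:
                continue
            k = 0
            while x0 + k < L and y0 - k >= 0 and x0 + k <= y0 - k and pair[x0 + k][y0 - k]:
                k += 1
            if k >= min_stem:
                i = x0
                j = y0 - k + 1
                stems.append((i, j, k))
    return stems


def score_structure(sequence: str, min_stem: int = 4, terminal_penalty: float = 3.0) -> float:
    """Secondary-structure propensity proxy (0 = none, more negative = worse).

    Score is ``-sum(2k)`` over maximal self-complementary stems of length
    ``k >= min_stem``, minus ``terminal_penalty`` per stem that involves a
    terminal base (a stem at either molecule end leaves a recessed,
    extension-prone terminus).  Symmetric under reverse complement.
    """
    s = dna.validate_dna(sequence)
    score = 0.0
    L = len(s)
    for i, j, k in _stems(s, min_stem=min_stem):
        score -= 2.0 * k
        if i == 0 or j + k == L:
            score -= terminal_penalty
    return score


def rank_candidates(candidates: list[Barcode]) -> list[Barcode]:
    """Descending structure score, ties broken lexicographically by sequence."""
    return sorted(candidates, key=lambda b: (-b.delta_g_score, b.sequence))


def rank_and_select(
    candidates: list[Barcode],
    n_forward: int,
    n_reverse: int,
    min_pairwise_edit: int = 8,
) -> tuple[list[Barcode], list[Barcode]]:
    """Select disjoint forward/reverse barcode sets from ranked candidates.

    Walks the ranking greedily, keeping a candidate only if its edit
    distance to every already-selected barcode is >= ``min_pairwise_edit``.
    Reverse barcodes are filled first (best-ranked), then forward.
    """
    ranked = rank_candidates(candidates)
    selected: list[Barcode] = []
    sequences: list[str] = []
    need = n_forward + n_reverse
    for cand in ranked:
        if len(selected) == need:
            break
        if sequences:
            d = levenshtein_batch(cand.sequence, sequences)
            if int(d.min()) < min_pairwise_edit:
                continue
        selected.append(cand)
        sequences.append(cand.sequence)
    if len(selected) < need:
        raise ValueError(
            f"only {len(selected)} of {need} barcodes survive the pairwise "
            f"edit-distance filter (>= {min_pairwise_edit}); supply more candidates"
        )
    reverse = [Barcode(b.sequence, b.delta_g_score, "reverse") for b in selected[:n_reverse]]
    forward = [
        Barcode(b.sequence, b.delta_g_score, "forward")
        for b in selected[n_reverse : n_reverse + n_forward]
    ]
    return forward, reverse


def allocate_pairs(
    forward: list[Barcode],
    reverse: list[Barcode],
    binding_fwd: str,
    binding_rev: str,
) -> list[PrimerPair]:
    """Cross every forward (plate) barcode with every reverse (well) barcode.

    Primer sequence is barcode followed by the universal binding site.
    """
    if not binding_fwd or not binding_rev:
        raise ValueError("binding sites must be non-empty")
    binding_fwd = dna.validate_dna(binding_fwd, "binding_fwd")
    binding_rev = dna.validate_dna(binding_rev, "binding_rev")
    labels = well_labels(len(reverse))
    pairs = []
    for p, fwd in enumerate(forward, start=1):
        for label, rev in zip(labels, reverse):
            pairs.append(
                PrimerPair(
                    plate_index=p,
                    well_label=label,
                    fwd_barcode=fwd.sequence,
                    rev_barcode=rev.sequence,
                    forward_primer=fwd.sequence + binding_fwd,
                    reverse_primer=rev.sequence + binding_rev,
                )
            )
    return pairs


# --- serialization -----------------------------------------------------------

PRIMER_SHEET_COLUMNS = [
    "plate",
    "well",
    "fwd_barcode",
    "rev_barcode",
    "fwd_primer",
    "rev_primer",
]


def pairs_to_frame(pairs: list[PrimerPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.plate_index, p.well_label, p.fwd_barcode, p.rev_barcode, p.forward_primer, p.reverse_primer)
            for p in pairs
        ],
        columns=PRIMER_SHEET_COLUMNS,
    )


def write_primer_sheet(pairs: list[PrimerPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_primer_sheet(path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype={"plate": int})
    missing = set(PRIMER_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"primer sheet missing columns: {sorted(missing)}")
    return [
        PrimerPair(
            plate_index=int(r.plate),
            well_label=str(r.well),
            fwd_barcode=str(r.fwd_barcode),
            rev_barcode=str(r.rev_barcode),
            forward_primer=str(r.fwd_primer),
            reverse_primer=str(r.rev_primer),
        )
        for r in df.itertuples(index=False)
    ]


def write_primer_fasta(pairs: list[PrimerPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.sample_id}_F\n{p.forward_primer}\n")
            fh.write(f">{p.sample_id}_R\n{p.reverse_primer}\n")
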