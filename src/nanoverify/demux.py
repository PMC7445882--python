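"""Error-tolerant dual-barcode demultiplexing.

Each read is tested in both orientations: the plate (forward) barcode is
matched by infix edit distance inside a 5' terminal window and the well
(reverse) barcode — as its reverse complement — inside a 3' window.  A
read is assigned to the (plate, well) with the smallest combined
distance, provided both individual distances pass ``max_dist`` and the
runner-up pair is at least ``min_margin`` worse; anything else is
unassigned.  Ambiguity never guesses: ties go to the unassigned bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna
from ._edit import infix_distance_batch, infix_locate
from .design import PrimerPair
from .simulate import Read, write_fastq

DEFAULT_WINDOW = 60
DEFAULT_MAX_DIST = 6  # floor(24 / 4) for the default 24-mers
DEFAULT_MIN_MARGIN = 2
MIN_INSERT = 50  # reads shorter than both primers + this are unassignable


@dataclass(frozen=True)
class DemuxParams:
    max_dist: int = DEFAULT_MAX_DIST
    window: int = DEFAULT_WINDOW
    min_margin: int = DEFAULT_MIN_MARGIN


@dataclass
class DemuxAssignment:
    read_id: str
    plate_index: int | None
    well_label: str | None
    orientation: str  # forward | reverse | unassigned
    fwd_edit_distance: int
    rev_edit_distance: int

    @property
    def assigned(self) -> bool:
        return self.plate_index is not None

    @property
    def sample_id(self) -> str | None:
        if not self.assigned:
            return None
        return f"plate{self.plate_index}_{self.well_label}"


def locate_barcode(
    read_seq: str, barcode: str, window: int, end: str = "five_prime"
) -> tuple[int, int]:
    """Best infix placement of ``barcode`` in a terminal window of the read.

    Returns ``(best_edit_distance, offset)`` where offset is 0-based in
    read coordinates (start of the matched segment).  A window longer
    than the read is truncated, not an error.
    """
    if window < len(barcode):
        raise ValueError("window must be at least the barcode length")
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be five_prime or three_prime")
    window = min(window, len(read_seq))
    if end == "five_prime":
        text = read_seq[:window]
        dist, start, _ = infix_locate(barcode, text)
        return dist, start
    text = read_seq[len(read_seq) - window :]
    dist, start, _ = infix_locate(barcode, text)
    return dist, start + len(read_seq) - window


@dataclass
class _BarcodePanel:
    """Pre-extracted barcode arrays for batch matching."""

    pairs: list[PrimerPair]
    fwd_barcodes: list[str]  # unique plate barcodes
    rev_barcodes_rc: list[str]  # unique well barcodes, reverse-complemented
    fwd_index: list[int]  # per pair: index into fwd_barcodes
    rev_index: list[int]
    min_length: int


def build_panel(barcode_map: list[PrimerPair]) -> _BarcodePanel:
    if not barcode_map:
        raise ValueError("barcode map is empty")
    fwd, rev = [], []
    fwd_pos, rev_pos = {}, {}
    fwd_index, rev_index = [], []
    for p in barcode_map:
        if p.fwd_barcode not in fwd_pos:
            fwd_pos[p.fwd_barcode] = len(fwd)
            fwd.append(p.fwd_barcode)
        if p.rev_barcode not in rev_pos:
            rev_pos[p.rev_barcode] = len(rev)
            rev.append(dna.revcomp(p.rev_barcode))
        fwd_index.append(fwd_pos[p.fwd_barcode])
        rev_index.append(rev_pos[p.rev_barcode])
    min_len = min(len(p.forward_primer) + len(p.reverse_primer) for p in barcode_map) + MIN_INSERT
    return _BarcodePanel(
        pairs=list(barcode_map),
        fwd_barcodes=fwd,
        rev_barcodes_rc=rev,
        fwd_index=fwd_index,
        rev_index=rev_index,
        min_length=min_len,
    )


def _orientation_distances(
    seq: str, panel: _BarcodePanel, window: int
) -> tuple[np.ndarray, np.ndarray]:
    w = min(window, len(seq))
    head, tail = seq[:w], seq[len(seq) - w :]
    d_fwd = infix_distance_batch(panel.fwd_barcodes, head)
    d_rev = infix_distance_batch(panel.rev_barcodes_rc, tail)
    return d_fwd, d_rev


def classify_read(
    read: Read,
    barcode_map: list[PrimerPair] | _BarcodePanel,
    max_dist: int = DEFAULT_MAX_DIST,
    window: int = DEFAULT_WINDOW,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> DemuxAssignment:
    """Assign a read to a (plate, well) or leave it unassigned."""
    panel = barcode_map if isinstance(barcode_map, _BarcodePanel) else build_panel(barcode_map)
    unassigned = DemuxAssignment(read.id, None, None, "unassigned", -1, -1)
    if len(read.sequence) < panel.min_length:
        return unassigned

    candidates: list[tuple[int, int, int, str, PrimerPair]] = []
    for orientation, seq in (
        ("forward", read.sequence),
        ("reverse", dna.revcomp(read.sequence)),
    ):
        d_fwd, d_rev = _orientation_distances(seq, panel, window)
        for i, pair in enumerate(panel.pairs):
            df = int(d_fwd[panel.fwd_index[i]])
            dr = int(d_rev[panel.rev_index[i]])
            candidates.append((df + dr, df, dr, orientation, pair))

    candidates.sort(key=lambda c: c[0])
    best = candidates[0]
    runner_up = next((c for c in candidates[1:] if c[4] is not best[4]), None)
    total, df, dr, orientation, pair = best
    if df > max_dist or dr > max_dist:
        return unassigned
    if runner_up is not None and runner_up[0] - total < min_margin:
        return unassigned
    return DemuxAssignment(read.id, pair.plate_index, pair.well_label, orientation, df, dr)


def trim_primers(oriented_seq: str, pair: PrimerPair, window: int = DEFAULT_WINDOW) -> str:
    """Cut located primer copies off a forward-oriented read.

    The full forward primer is located in the 5' window and the reverse
    complement of the reverse primer in the 3' window; a terminus whose
    primer cannot be found at <= 40% edit distance is left untouched.
    """
    seq = oriented_seq
    fwd = pair.forward_primer
    w = min(max(window, 2 * len(fwd)), len(seq))
    dist, _, end = infix_locate(fwd, seq[:w])
    if dist <= 0.4 * len(fwd):
        seq = seq[end:]
    rev_rc = dna.revcomp(pair.reverse_primer)
    w = min(max(window, 2 * len(rev_rc)), len(seq))
    dist, start, _ = infix_locate(rev_rc, seq[len(seq) - w :])
    if dist <= 0.4 * len(rev_rc):
        seq = seq[: len(seq) - w + start]
    return seq


@dataclass
class DemuxResult:
    bins: dict[str, list[Read]]  # sample_id -> reads (oriented as read, not flipped)
    unassigned: list[Read]
    assignments: dict[str, DemuxAssignment]
    n_malformed: int = 0
    malformed_lines: list[int] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.bins.values()) + len(self.unassigned)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for sample, reads in sorted(self.bins.items()):
            n_fwd = sum(1 for r in reads if self.assignments[r.id].orientation == "forward")
            rows.append((sample, len(reads), n_fwd, len(reads) - n_fwd))
        rows.append(("unassigned", len(self.unassigned), 0, 0))
        return pd.DataFrame(rows, columns=["sample", "n_reads", "n_fwd", "n_rev"])


def _parse_fastq_lenient(path) -> tuple[list[Read], list[int]]:
    """4-line FASTQ parser that skips malformed records, noting line numbers."""
    reads: list[Read] = []
    bad: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        chunk = lines[i : i + 4]
        if (
            len(chunk) < 4
            or not chunk[0].startswith("@")
            or not chunk[2].startswith("+")
            or len(chunk[1]) != len(chunk[3])
            or not chunk[1]
        ):
            bad.append(i + 1)  # 1-based line number of the offending record
            i += 1
            # resync on the next plausible header
            while i < len(lines) and not lines[i].startswith("@"):
                i += 1
            continue
        reads.append(Read(id=chunk[0][1:].split()[0], sequence=chunk[1].upper(), quality=chunk[3]))
        i += 4
    return reads, bad


def demux_batch(
    fastq_path,
    barcode_map: list[PrimerPair],
    params: DemuxParams = DemuxParams(),
) -> DemuxResult:
    """Partition a FASTQ into per-sample bins plus an unassigned bin."""
    reads, bad = _parse_fastq_lenient(fastq_path)
    panel = build_panel(barcode_map)
    bins: dict[str, list[Read]] = {}
    unassigned: list[Read] = []
    assignments: dict[str, DemuxAssignment] = {}
    for read in reads:
        a = classify_read(read, panel, params.max_dist, params.window, params.min_margin)
        assignments[read.id] = a
        if a.assigned:
            read.sample_id = a.sample_id
            read.orientation = a.orientation
            bins.setdefault(a.sample_id, []).append(read)
        else:
            unassigned.append(read)
    return DemuxResult(bins, unassigned, assignments, len(bad), bad)


def write_demux_output(result: DemuxResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, reads in result.bins.items():
        write_fastq(reads, out / f"{sample}.fastq")
    write_fastq(result.unassigned, out / "unassigned.fastq")
    result.report_frame().to_csv(out / "demux_report.tsv", sep="\t", index=False)
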