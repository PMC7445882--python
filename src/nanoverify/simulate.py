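"""Nanopore-like amplicon read simulation.

Generates full-length amplicon passes with i.i.d. substitution/indel
noise, strand-restricted systematic error sites and true variants, plus
a ground-truth sidecar for test harnesses.  Reverse-strand reads are
emitted as reverse complements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dna
from .design import PrimerPair

MAX_TOTAL_ERROR = 0.3  # sanity bound around the realistic per-base error range


@dataclass(frozen=True)
class ErrorModel:
    """Flat per-base error rates for read simulation."""

    sub_rate: float = 0.07
    ins_rate: float = 0.015
    del_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.total_rate > MAX_TOTAL_ERROR:
            raise ValueError(f"total error rate {self.total_rate:.3f} exceeds {MAX_TOTAL_ERROR}")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass(frozen=True)
class SystematicErrorSite:
    """A strand-specific recurrent miscall at one template position."""

    position: int  # 0-based coordinate on the simulated sequence
    strand: str  # forward | reverse
    alt_base: str  # A/C/G/T or '-' for deletion
    rate: float

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError("strand must be forward or reverse")
        if self.alt_base not in dna.SYMBOLS:
            raise ValueError("alt_base must be one of A/C/G/T/-")
        if not 0.0 < self.rate <= 1.0:
            raise ValueError("rate must be in (0, 1]")


@dataclass(frozen=True)
class TrueVariant:
    """A genuine template change, present on both strands."""

    position: int
    alt_base: str  # A/C/G/T or '-'

    def __post_init__(self) -> None:
        if self.alt_base not in dna.SYMBOLS:
            raise ValueError("alt_base must be one of A/C/G/T/-")


@dataclass
class Read:
    id: str
    sequence: str
    quality: str = ""
    # populated by demultiplexing
    sample_id: str | None = None
    orientation: str | None = None


def build_amplicon(template: str, pair: PrimerPair) -> str:
    """PCR product: forward primer + template + revcomp(reverse primer)."""
    if not template:
        raise ValueError("template must be non-empty")
    return pair.forward_primer + template + dna.revcomp(pair.reverse_primer)


def phred_char(error_rate: float) -> str:
    """Single Phred+33 quality character for a per-base error rate."""
    if error_rate <= 0:
        q = 40
    else:
        q = int(round(-10.0 * math.log10(error_rate)))
    return chr(33 + max(0, min(q, 40)))


def _check_positions(length: int, sites, variants) -> None:
    for s in sites:
        if not 0 <= s.position < length:
            raise ValueError(f"systematic site position {s.position} outside template")
    for v in variants:
        if not 0 <= v.position < length:
            raise ValueError(f"variant position {v.position} outside template")
    by_pos = {}
    for v in variants:
        if v.position in by_pos:
            raise ValueError(f"duplicate variant at position {v.position}")
        by_pos[v.position] = v


def simulate_reads(
    amplicon: str,
    n_fwd: int,
    n_rev: int,
    model: ErrorModel,
    sites: list[SystematicErrorSite] = (),
    variants: list[TrueVariant] = (),
    read_prefix: str = "sim",
) -> list[Read]:
    """Simulate ``n_fwd`` forward and ``n_rev`` reverse full-length passes.

    True variants mutate the template for every read; systematic sites
    fire at their rate on their strand only; random errors are applied
    i.i.d. per base afterwards.  Read ids encode the ground-truth strand
    (``..._strand=forward``).  Deterministic for a fixed model seed.
    """
    amplicon = dna.validate_dna(amplicon, "amplicon")
    if n_fwd < 0 or n_rev < 0:
        raise ValueError("read counts must be >= 0")
    _check_positions(len(amplicon), sites, variants)
    for v in variants:
        if amplicon[v.position] == v.alt_base:
            raise ValueError(f"variant at {v.position} equals the template base")
    for s in sites:
        if amplicon[s.position] == s.alt_base:
            raise ValueError(f"systematic site at {s.position} equals the template base")

    rng = np.random.default_rng(model.seed)
    qual_char = phred_char(model.total_rate)
    mutated = list(amplicon)
    for v in variants:
        mutated[v.position] = v.alt_base  # '-' marks deletion, dropped later

    reads: list[Read] = []
    strands = ["forward"] * n_fwd + ["reverse"] * n_rev
    for idx, strand in enumerate(strands):
        bases = list(mutated)
        for s in sites:
            if s.strand == strand and rng.random() < s.rate:
                bases[s.position] = s.alt_base
        out: list[str] = []
        for b in bases:
            if b == dna.DEL:
                continue
            r = rng.random()
            if r < model.del_rate:
                continue
            if r < model.del_rate + model.sub_rate:
                choices = [x for x in dna.BASES if x != b]
                out.append(choices[rng.integers(0, 3)])
            else:
                out.append(b)
            if rng.random() < model.ins_rate:
                out.append(dna.BASES[rng.integers(0, 4)])
        seq = "".join(out)
        if strand == "reverse":
            seq = dna.revcomp(seq)
        read_id = f"{read_prefix}_{idx:05d}_strand={strand}"
        reads.append(Read(id=read_id, sequence=seq, quality=qual_char * len(seq)))
    return reads


# --- FASTQ / ground-truth IO -------------------------------------------------


def write_fastq(reads: list[Read], path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": [ord(c) - 33 for c in r.quality]},
        )
        for r in reads
    ]
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return reads


@dataclass
class GroundTruth:
    """Sidecar truth for a simulated FASTQ: who each read is and what was planted."""

    sample_of_read: dict[str, str] = field(default_factory=dict)
    strand_of_read: dict[str, str] = field(default_factory=dict)
    variants: dict[str, list[TrueVariant]] = field(default_factory=dict)
    sites: dict[str, list[SystematicErrorSite]] = field(default_factory=dict)

    def add_sample(self, sample_id, reads, variants, sites) -> None:
        for r in reads:
            self.sample_of_read[r.id] = sample_id
            self.strand_of_read[r.id] = r.id.rsplit("strand=", 1)[-1]
        self.variants[sample_id] = list(variants)
        self.sites[sample_id] = list(sites)

    def to_json(self, path) -> None:
        payload = {
            "sample_of_read": self.sample_of_read,
            "strand_of_read": self.strand_of_read,
            "variants": {
                k: [v.__dict__ for v in vs] for k, vs in self.variants.items()
            },
            "sites": {k: [s.__dict__ for s in ss] for k, ss in self.sites.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gt = cls()
        gt.sample_of_read = payload["sample_of_read"]
        gt.strand_of_read = payload["strand_of_read"]
        gt.variants = {
            k: [TrueVariant(**v) for v in vs] for k, vs in payload["variants"].items()
        }
        gt.sites = {
            k: [SystematicErrorSite(**s) for s in ss] for k, ss in payload["sites"].items()
        }
        return gt
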