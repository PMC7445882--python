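import numpy as np
import pytest

from nanoverify import dna
from nanoverify.align import align_read, build_pileup
from nanoverify.design import allocate_pairs, generate_candidates, rank_and_select
from nanoverify.simulate import simulate_reads

BINDING_FWD = "ATGACCATGATTACGGATTCACTG"
BINDING_REV = "CAGGAAACAGCTATGACCATGATT"


@pytest.fixture(scope="session")
def barcode_sets():
    """6 forward + 96 reverse designed barcodes (seed 7, pairwise edit >= 8)."""
    cands = generate_candidates(500, 24, seed=7)
    return rank_and_select(cands, 6, 96, min_pairwise_edit=8)


@pytest.fixture(scope="session")
def primer_pairs(barcode_sets):
    fwd, rev = barcode_sets
    return allocate_pairs(fwd, rev, BINDING_FWD, BINDING_REV)


@pytest.fixture(scope="session")
def small_primer_map(primer_pairs):
    """Four wells spanning two plates and two well positions."""
    wanted = {(1, "A1"), (1, "A2"), (2, "A1"), (2, "A2")}
    return [p for p in primer_pairs if (p.plate_index, p.well_label) in wanted]


def make_template(seed: int, length: int) -> str:
    return dna.random_dna(np.random.default_rng(seed), length)


def simulate_pileup(template, n_fwd, n_rev, model, sites=(), variants=(), band=64):
    """simulate -> strand-aware align -> pileup, using read-id ground truth."""
    reads = simulate_reads(template, n_fwd, n_rev, model, sites, variants)
    alignments = []
    for r in reads:
        strand = r.id.rsplit("strand=", 1)[-1]
        seq = r.sequence if strand == "forward" else dna.revcomp(r.sequence)
        aln = align_read(seq, template, band_width=band, read_id=r.id, strand=strand)
        alignments.append((aln, seq))
    return build_pileup(alignments, template)
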