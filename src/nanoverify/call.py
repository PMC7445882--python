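"""Strand-concordant Bayesian SNV calling.

Forward and reverse reads are modelled separately.  For each strand the
likelihood of every base hypothesis is binomial in the number of
supporting reads — correct reads with probability ``1 - e``, the error
mass ``e`` split uniformly over the four other symbols — so deeper
strands carry proportionally more weight.  A variant is reported only
when the two strands agree on the same non-reference base and the
combined posterior clears a confidence threshold; at discordant
(strand-biased) positions the template base is retained, which is what
separates genuine variants from single-strand systematic miscalls.

Deletions participate as a fifth symbol; insertions are handled by a
separate per-strand concordance rule outside the binomial model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import dna
from .align import StrandPileup

N_SYMBOLS = len(dna.SYMBOLS)  # A C G T -

STATUS_SNV = "SNV"
STATUS_REFERENCE = "REFERENCE"
STATUS_STRAND_BIASED = "STRAND_BIASED"
STATUS_LOW_DEPTH = "LOW_DEPTH"


@dataclass(frozen=True)
class CallParams:
    error_rate: float = 0.10  # midpoint of the realistic 5-15% per-base range
    tau: float = 0.99  # combined posterior threshold for reporting an SNV
    min_depth_per_strand: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if not 0.5 < self.tau < 1.0:
            raise ValueError("tau must be in (0.5, 1)")
        if self.min_depth_per_strand < 1:
            raise ValueError("min_depth_per_strand must be >= 1")


@dataclass
class StrandPosterior:
    position: int
    strand: str
    probs: dict[str, float]
    depth: int

    @property
    def best(self) -> str:
        return max(self.probs, key=lambda b: self.probs[b])

    def has_unique_argmax(self) -> bool:
        top = max(self.probs.values())
        return sum(1 for v in self.probs.values() if v == top) == 1


@dataclass
class VariantCall:
    position: int  # 0-based
    ref_base: str
    called_base: str
    posterior: float  # combined across strands
    fwd_posterior: float
    rev_posterior: float
    status: str
    flag: str | None = None


@dataclass
class IndelRecord:
    """A merged indel: deletion run over reference positions, or an insertion."""

    kind: str  # deletion | insertion
    position: int  # first deleted position, or position preceding an insertion
    length: int
    sequence: str  # deleted reference bases or inserted bases


def _as_count_vector(counts) -> np.ndarray:
    if isinstance(counts, np.ndarray):
        v = counts.astype(float)
        if v.shape != (N_SYMBOLS,):
            raise ValueError(f"count vector must have shape ({N_SYMBOLS},)")
        return v
    v = np.zeros(N_SYMBOLS)
    for b, k in counts.items():
        v[dna.SYMBOL_INDEX[b]] = k
    return v


def strand_likelihood(counts, error_rate: float, base_hypothesis: str) -> float:
    """Per-strand binomial log-likelihood of one base hypothesis.

    ``log L(b) = k_b log(1-e) + (n - k_b) log(e/4)`` with ``n`` the strand
    depth; the multinomial coefficient is hypothesis-independent and
    omitted.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    v = _as_count_vector(counts)
    if (v < 0).any():
        raise ValueError("counts must be non-negative")
    n = v.sum()
    k = v[dna.SYMBOL_INDEX[base_hypothesis]]
    return k * math.log1p(-error_rate) + (n - k) * math.log(error_rate / 4.0)


def _log_likelihoods(v: np.ndarray, e: float) -> np.ndarray:
    n = v.sum()
    return v * math.log1p(-e) + (n - v) * math.log(e / 4.0)


def strand_posterior(
    counts,
    error_rate: float,
    prior: dict[str, float] | None = None,
    position: int = 0,
    strand: str = "forward",
) -> StrandPosterior:
    """Normalized posterior over the five symbols for one strand."""
    v = _as_count_vector(counts)
    if prior is None:
        logp = np.zeros(N_SYMBOLS)
    else:
        pv = np.array([prior.get(b, 0.0) for b in dna.SYMBOLS], dtype=float)
        if pv.sum() <= 0:
            raise ValueError("prior must have positive mass")
        if (pv < 0).any():
            raise ValueError("prior probabilities must be non-negative")
        pv = pv / pv.sum()
        with np.errstate(divide="ignore"):
            logp = np.log(pv)
    ll = logp + _log_likelihoods(v, error_rate)
    ll -= ll.max()
    p = np.exp(ll)
    p /= p.sum()
    return StrandPosterior(
        position=position,
        strand=strand,
        probs={b: float(p[i]) for i, b in enumerate(dna.SYMBOLS)},
        depth=int(v.sum()),
    )


def call_position(
    fwd_counts,
    rev_counts,
    ref_base: str,
    params: CallParams = CallParams(),
    position: int = 0,
) -> VariantCall:
    """Strand-concordant call at one reference position.

    Low depth on either strand retains the reference; disagreement of
    the per-strand argmax bases (including within-strand ties) is
    treated as strand bias and retains the reference; agreement on a
    non-reference base becomes an SNV only if the combined posterior
    reaches ``tau``.
    """
    e = params.error_rate
    fwd = strand_posterior(fwd_counts, e, position=position, strand="forward")
    rev = strand_posterior(rev_counts, e, position=position, strand="reverse")

    if fwd.depth < params.min_depth_per_strand or rev.depth < params.min_depth_per_strand:
        return VariantCall(position, ref_base, ref_base, 1.0, 0.0, 0.0, STATUS_LOW_DEPTH)

    b_f, b_r = fwd.best, rev.best
    discordant = (
        b_f != b_r or not fwd.has_unique_argmax() or not rev.has_unique_argmax()
    )
    if discordant:
        return VariantCall(
            position,
            ref_base,
            ref_base,
            1.0,
            fwd.probs[b_f],
            rev.probs[b_r],
            STATUS_STRAND_BIASED,
        )

    b = b_f
    combined = np.array([fwd.probs[s] * rev.probs[s] for s in dna.SYMBOLS])
    total = combined.sum()
    if total <= 0:
        post = 1.0 / N_SYMBOLS
    else:
        post = float(combined[dna.SYMBOL_INDEX[b]] / total)

    if b == ref_base:
        return VariantCall(position, ref_base, b, post, fwd.probs[b], rev.probs[b], STATUS_REFERENCE)
    if post >= params.tau:
        return VariantCall(position, ref_base, b, post, fwd.probs[b], rev.probs[b], STATUS_SNV)
    return VariantCall(
        position,
        ref_base,
        ref_base,
        post,
        fwd.probs[b],
        rev.probs[b],
        STATUS_REFERENCE,
        flag="low_confidence_alt",
    )


@dataclass
class SampleCalls:
    calls: list[VariantCall]
    indels: list[IndelRecord] = field(default_factory=list)

    def snvs(self) -> list[VariantCall]:
        return [c for c in self.calls if c.status == STATUS_SNV and c.called_base != dna.DEL]

    def deletion_calls(self) -> list[VariantCall]:
        return [c for c in self.calls if c.status == STATUS_SNV and c.called_base == dna.DEL]


def _merge_deletions(calls: list[VariantCall], target: str) -> list[IndelRecord]:
    out: list[IndelRecord] = []
    run_start = None
    prev = None
    for c in calls:
        if c.status == STATUS_SNV and c.called_base == dna.DEL:
            if run_start is None or c.position != prev + 1:
                if run_start is not None:
                    out.append(
                        IndelRecord("deletion", run_start, prev - run_start + 1, target[run_start : prev + 1])
                    )
                run_start = c.position
            prev = c.position
        else:
            if run_start is not None:
                out.append(
                    IndelRecord("deletion", run_start, prev - run_start + 1, target[run_start : prev + 1])
                )
                run_start = None
    if run_start is not None:
        out.append(IndelRecord("deletion", run_start, prev - run_start + 1, target[run_start : prev + 1]))
    return out


def _concordant_insertions(pileup: StrandPileup, min_fraction: float = 0.5) -> list[IndelRecord]:
    depths = pileup.depths()
    by_pos: dict[int, dict[str, np.ndarray]] = {}
    for (pos, seq), cnt in pileup.insertions.items():
        by_pos.setdefault(pos, {})[seq] = cnt
    out = []
    for pos, seqs in sorted(by_pos.items()):
        total = np.zeros(2)
        for cnt in seqs.values():
            total += cnt
        if pos < 0 or pos >= pileup.length:
            continue
        df, dr = depths[pos]
        if df == 0 or dr == 0:
            continue
        if total[0] >= min_fraction * df and total[1] >= min_fraction * dr:
            best_seq = max(seqs.items(), key=lambda kv: kv[1].sum())[0]
            out.append(IndelRecord("insertion", pos, len(best_seq), best_seq))
    return out


def call_sample(
    pileup: StrandPileup,
    target: str,
    params: CallParams = CallParams(),
) -> SampleCalls:
    """Call every position of a target from its strand pileup."""
    if pileup.length != len(target):
        raise ValueError(f"pileup length {pileup.length} != target length {len(target)}")
    calls = [
        call_position(pileup.counts[i, 0], pileup.counts[i, 1], target[i], params, position=i)
        for i in range(len(target))
    ]
    indels = _merge_deletions(calls, target)
    indels.extend(_concordant_insertions(pileup))
    return SampleCalls(calls=calls, indels=indels)


def naive_pooled_consensus(pileup: StrandPileup, target: str) -> list[int]:
    """Positions where a strand-pooled majority vote contradicts the target.

    The vulnerable baseline the strand-concordant caller is compared
    against: counts from both strands are merged and the plurality
    symbol wins outright.
    """
    pooled = pileup.counts.sum(axis=1)  # (length, 5)
    miscalls = []
    for i in range(pileup.length):
        if pooled[i].sum() == 0:
            continue
        best = int(np.argmax(pooled[i]))
        ref_idx = dna.SYMBOL_INDEX[target[i]]
        if best != ref_idx and pooled[i][best] > pooled[i][ref_idx]:
            miscalls.append(i)
    return miscalls
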