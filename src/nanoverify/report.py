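"""Per-sample reporting: VCF emission, summary table, cost utility and
the end-to-end pipeline (demux -> align -> call -> summarize)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dna
from .align import DEFAULT_BAND, StrandPileup, align_read, build_pileup, identify_target
from .call import CallParams, SampleCalls, call_sample
from .demux import DemuxParams, demux_batch, trim_primers, write_demux_output
from .design import PrimerPair
from .simulate import Read

SUMMARY_COLUMNS = [
    "sample",
    "target",
    "identity",
    "n_mutations",
    "n_indels",
    "coverage",
    "max_depth",
    "n_fwd",
    "n_rev",
    "status",
]


@dataclass
class SampleSummary:
    sample_id: str
    target_id: str
    identity: float
    n_mutations: int
    n_indels: int
    coverage: float
    max_depth: int
    n_reads_fwd: int
    n_reads_rev: int
    status: str = "OK"

    def as_row(self) -> list:
        return [
            self.sample_id,
            self.target_id,
            f"{self.identity:.6f}",
            self.n_mutations,
            self.n_indels,
            f"{self.coverage:.6f}",
            self.max_depth,
            self.n_reads_fwd,
            self.n_reads_rev,
            self.status,
        ]


def summarize(
    sample_calls: SampleCalls,
    pileup: StrandPileup,
    target: str,
    sample_id: str = "sample",
    target_id: str = "target",
    n_reads_fwd: int | None = None,
    n_reads_rev: int | None = None,
) -> SampleSummary:
    """Condense calls + pileup into the per-sample verification metrics.

    identity = (L - SNV positions - indel-affected positions) / L; an
    insertion counts as one affected position.  Positions lacking
    coverage on either strand lower ``coverage`` but not identity (both
    numbers are reported).
    """
    L = len(target)
    snvs = sample_calls.snvs()
    n_mut = len(snvs)
    indel_positions = sum(
        rec.length if rec.kind == "deletion" else 1 for rec in sample_calls.indels
    )
    identity = (L - n_mut - indel_positions) / L if L else 1.0
    identity = min(1.0, max(0.0, identity))
    depths = pileup.depths()
    coverage = float(((depths[:, 0] >= 1) & (depths[:, 1] >= 1)).mean()) if L else 0.0
    if n_reads_fwd is None:
        n_reads_fwd = int(depths[:, 0].max()) if L else 0
    if n_reads_rev is None:
        n_reads_rev = int(depths[:, 1].max()) if L else 0
    return SampleSummary(
        sample_id=sample_id,
        target_id=target_id,
        identity=identity,
        n_mutations=n_mut,
        n_indels=len(sample_calls.indels),
        coverage=coverage,
        max_depth=pileup.max_depth(),
        n_reads_fwd=n_reads_fwd,
        n_reads_rev=n_reads_rev,
    )


def cost_per_kb(cost_per_sample: float, amplicon_length_kb: float) -> float:
    """Per-kilobase cost, rounded to 2 decimals (unit-agnostic)."""
    if amplicon_length_kb <= 0:
        raise ValueError("amplicon length must be positive")
    return round(cost_per_sample / amplicon_length_kb, 2)


# --- VCF ---------------------------------------------------------------------


def write_vcf(
    sample_calls: SampleCalls,
    target: str,
    sample_id: str,
    path,
    target_id: str = "target",
    pileup: StrandPileup | None = None,
) -> None:
    """Minimal VCFv4.2 with SNV and merged indel records (1-based POS)."""
    depths = pileup.depths() if pileup is not None else None
    n_biased = sum(1 for c in sample_calls.calls if c.status == "STRAND_BIASED")
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={target_id}",
        f"##contig=<ID={target_id},length={len(target)}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth (fwd+rev)">',
        '##INFO=<ID=SB,Number=1,Type=Integer,Description="Count of strand-biased positions in this sample">',
        '##INFO=<ID=PP,Number=1,Type=Float,Description="Combined strand-concordant posterior">',
        f"##sample={sample_id}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]

    def dp(pos: int) -> int:
        if depths is None:
            return 0
        return int(depths[pos].sum())

    records: list[tuple[int, str]] = []
    for c in sample_calls.snvs():
        info = f"DP={dp(c.position)};SB={n_biased};PP={c.posterior:.6f}"
        records.append(
            (
                c.position + 1,
                f"{target_id}\t{c.position + 1}\t.\t{c.ref_base}\t{c.called_base}\t.\tPASS\t{info}",
            )
        )
    for rec in sample_calls.indels:
        if rec.kind == "deletion":
            if rec.position > 0:
                pos = rec.position  # anchor base before the run (1-based = pos)
                ref = target[rec.position - 1 : rec.position + rec.length]
                alt = target[rec.position - 1]
            else:
                # deletion at target start: anchor on the following base
                pos = 1
                ref = target[: rec.length + 1]
                alt = target[rec.length]
            info = f"DP={dp(rec.position)};SB={n_biased}"
            records.append((pos, f"{target_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}"))
        else:
            anchor = target[rec.position]
            pos = rec.position + 1
            info = f"DP={dp(rec.position)};SB={n_biased}"
            records.append(
                (pos, f"{target_id}\t{pos}\t.\t{anchor}\t{anchor}{rec.sequence}\t.\tPASS\t{info}")
            )
    records.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, line in records:
            fh.write(line + "\n")


# --- pipeline ----------------------------------------------------------------


@dataclass
class PipelineConfig:
    error_rate: float = 0.10
    tau: float = 0.99
    min_depth_per_strand: int = 5
    max_dist: int = 6
    window: int = 60
    min_margin: int = 2
    band_width: int = DEFAULT_BAND
    seed: int = 0
    identify: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def call_params(self) -> CallParams:
        return CallParams(self.error_rate, self.tau, self.min_depth_per_strand)

    def demux_params(self) -> DemuxParams:
        return DemuxParams(self.max_dist, self.window, self.min_margin)


@dataclass
class SampleResult:
    summary: SampleSummary
    calls: SampleCalls | None = None
    pileup: StrandPileup | None = None
    target: str = ""


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult] = field(default_factory=dict)
    demux_report: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = [self.samples[k].summary.as_row() for k in sorted(self.samples)]
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _oriented_reads(reads: list[Read]) -> list[tuple[Read, str]]:
    out = []
    for r in reads:
        seq = r.sequence if r.orientation == "forward" else dna.revcomp(r.sequence)
        out.append((r, seq))
    return out


def process_sample(
    reads: list[Read],
    pair: PrimerPair,
    target: str,
    target_id: str,
    config: PipelineConfig,
) -> SampleResult:
    """Align one demultiplexed read set and call/summarize it."""
    alignments = []
    n_fwd = n_rev = 0
    for read, oriented in _oriented_reads(reads):
        trimmed = trim_primers(oriented, pair, window=config.window)
        if not trimmed:
            continue
        strand = read.orientation or "forward"
        aln = align_read(
            trimmed,
            target,
            band_width=config.band_width,
            read_id=read.id,
            target_id=target_id,
            strand=strand,
        )
        alignments.append((aln, trimmed))
        if strand == "forward":
            n_fwd += 1
        else:
            n_rev += 1
    pileup = build_pileup(alignments, target, target_id)
    calls = call_sample(pileup, target, config.call_params())
    summary = summarize(
        calls,
        pileup,
        target,
        sample_id=pair.sample_id,
        target_id=target_id,
        n_reads_fwd=n_fwd,
        n_reads_rev=n_rev,
    )
    return SampleResult(summary=summary, calls=calls, pileup=pileup, target=target)


def _choose_target(
    reads: list[Read], pair: PrimerPair, targets: dict[str, str], config: PipelineConfig
) -> str:
    """Identification mode: majority vote of per-read best targets."""
    votes: dict[str, int] = {}
    for read, oriented in _oriented_reads(reads):
        trimmed = trim_primers(oriented, pair, window=config.window)
        if not trimmed:
            continue
        tid, _ = identify_target(trimmed, targets, band_width=config.band_width)
        votes[tid] = votes.get(tid, 0) + 1
    if not votes:
        return sorted(targets)[0]
    return max(sorted(votes), key=lambda t: votes[t])


def run_pipeline(
    fastq_path,
    barcode_map: list[PrimerPair],
    targets: dict[str, str],
    config: PipelineConfig = PipelineConfig(),
    sample_targets: dict[str, str] | None = None,
    outdir=None,
) -> PipelineResult:
    """demux -> per-sample align -> call -> summarize.

    ``sample_targets`` maps sample_id to target_id (verification mode);
    with ``config.identify`` the target is chosen per sample by scoring
    reads against every target.  Every barcode pair in the map gets a
    summary row; samples without reads are flagged NO_READS.
    """
    targets = {tid: dna.validate_dna(seq, tid) for tid, seq in targets.items()}
    demux = demux_batch(fastq_path, barcode_map, config.demux_params())
    result = PipelineResult(demux_report=demux.report_frame())
    pairs_by_sample = {p.sample_id: p for p in barcode_map}

    for sample_id in sorted(pairs_by_sample):
        pair = pairs_by_sample[sample_id]
        reads = demux.bins.get(sample_id, [])
        if not reads:
            result.samples[sample_id] = SampleResult(
                summary=SampleSummary(sample_id, "", 0.0, 0, 0, 0.0, 0, 0, 0, status="NO_READS")
            )
            continue
        if config.identify:
            target_id = _choose_target(reads, pair, targets, config)
        elif sample_targets and sample_id in sample_targets:
            target_id = sample_targets[sample_id]
        elif len(targets) == 1:
            target_id = next(iter(targets))
        else:
            raise ValueError(
                f"no target mapping for sample {sample_id}; provide sample_targets or identify=True"
            )
        result.samples[sample_id] = process_sample(
            reads, pair, targets[target_id], target_id, config
        )

    result.manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "n_reads": demux.n_reads,
        "n_unassigned": len(demux.unassigned),
        "n_malformed": demux.n_malformed,
        "targets": sorted(targets),
        "samples": sorted(pairs_by_sample),
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_demux_output(demux, out / "demux")
        for sample_id, sres in result.samples.items():
            if sres.calls is None:
                continue
            write_vcf(
                sres.calls,
                sres.target,
                sample_id,
                out / f"{sample_id}.vcf",
                target_id=sres.summary.target_id,
                pileup=sres.pileup,
            )
        result.summary_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=1, sort_keys=True)
    return result
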