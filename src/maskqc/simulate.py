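"""Seeded simulator of a resequencing experiment with planted homozygous SNPs.

The generator emulates the statistical structure of a 76-cycle single-end
Illumina run over a small genome at ~22-fold coverage:

* a uniform-random reference sequence;
* a sample genome carrying ``n_snps`` planted homozygous substitutions —
  by default restricted to G→A / C→T, the canonical transitions induced by
  EMS (ethyl methanesulfonate) mutagenesis;
* fixed-length reads from uniformly random positions and strands, whose
  per-cycle PHRED scores decay linearly (with Gaussian noise) from
  ``q_high`` at the first cycle to ``q_low`` at the last, reproducing the
  low-quality 3' tails that masking and trimming act on;
* base-call errors coupled to the emitted score: each base is miscalled
  with probability ``10^(-q/10)``, substituting uniformly among the other
  three bases (a sequencer emits concrete calls, never 'N').

Everything is driven by a single seeded PRNG stream, so one
(seed, config) pair fully determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import SimulationError
from .fastq_io import FastqRecord

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
# With A=0, C=1, G=2, T=3 the complement is 3 - code.

QUAL_MIN, QUAL_MAX = 2, 41  # emitted score clamp (Illumina 1.8+ range)


class Snp(NamedTuple):
    """A planted homozygous substitution (0-based reference position)."""

    position: int
    ref_base: str
    alt_base: str


class Placement(NamedTuple):
    """True origin of one read: 0-based start of its reference window."""

    read_id: str
    start: int
    strand: str  # '+' or '-'


@dataclass
class SimTruth:
    """Ground truth emitted alongside the reads."""

    snps: list[Snp]
    placements: list[Placement]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a desk-scale version of a 76-cycle single-end run:
    100 kb reference, 100 planted EMS-like SNPs, 22-fold coverage, and a
    quality profile decaying from Q38 to Q12 with SD 3 — enough 3'-end decay
    that roughly the last fifth of each read falls below Q20.
    """

    seed: int = 0
    ref_length: int = 100_000
    n_snps: int = 100
    read_length: int = 76
    mean_coverage: float = 22.0
    q_high: float = 38.0
    q_low: float = 12.0
    q_sd: float = 3.0
    ems_bias: bool = True

    def __post_init__(self) -> None:
        if self.ref_length < self.read_length:
            raise SimulationError("ref_length must be >= read_length")
        if self.n_snps >= self.ref_length:
            raise SimulationError("n_snps must be < ref_length")
        if self.q_low > self.q_high:
            raise SimulationError("q_low must be <= q_high")
        if self.mean_coverage <= 0:
            raise SimulationError("mean_coverage must be positive")
        if self.read_length < 1 or self.q_sd < 0:
            raise SimulationError("invalid read_length or q_sd")

    @property
    def n_reads(self) -> int:
        return round(self.mean_coverage * self.ref_length / self.read_length)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_reference(seed: int | np.random.Generator, length: int) -> str:
    """An i.i.d. uniform A/C/G/T sequence, deterministic under the seed."""
    if length < 1:
        raise SimulationError("reference length must be >= 1")
    rng = _rng(seed)
    codes = rng.integers(0, 4, size=length)
    return "".join(BASES[c] for c in codes)


def plant_snps(
    ref: str,
    n: int,
    seed: int | np.random.Generator,
    ems_bias: bool = True,
) -> tuple[str, list[Snp]]:
    """Substitute ``n`` distinct positions of ``ref``; return genome and truth.

    With ``ems_bias`` every planted SNP is a G→A or C→T transition (EMS
    chemistry); otherwise positions are unrestricted and the alternative
    base is drawn uniformly among the three non-reference bases.
    """
    rng = _rng(seed)
    if ems_bias:
        eligible = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        eligible = np.flatnonzero((eligible == ord("G")) | (eligible == ord("C")))
    else:
        eligible = np.arange(len(ref))
    if n > len(eligible):
        raise SimulationError(
            f"cannot plant {n} SNPs: only {len(eligible)} eligible positions"
        )
    positions = np.sort(rng.choice(eligible, size=n, replace=False))
    genome = list(ref)
    snps: list[Snp] = []
    for pos in positions:
        ref_base = ref[pos]
        if ems_bias:
            alt = "A" if ref_base == "G" else "T"
        else:
            others = [b for b in BASES if b != ref_base]
            alt = others[rng.integers(0, 3)]
        genome[pos] = alt
        snps.append(Snp(int(pos), ref_base, alt))
    return "".join(genome), snps


def cycle_mean_quality(cycle: int, config: SimConfig) -> float:
    """Mean PHRED score at a cycle: linear from q_high (cycle 0) to q_low (last)."""
    if not 0 <= cycle < config.read_length:
        raise SimulationError(f"cycle {cycle} outside read of length {config.read_length}")
    if config.read_length == 1:
        return config.q_high
    frac = cycle / (config.read_length - 1)
    return config.q_high + (config.q_low - config.q_high) * frac


def cycle_quality(
    cycle: int, config: SimConfig, seed: int | np.random.Generator
) -> int:
    """One emitted PHRED score at a cycle: Normal(mean, q_sd), rounded, clamped."""
    rng = _rng(seed)
    q = rng.normal(cycle_mean_quality(cycle, config), config.q_sd)
    return int(np.clip(np.rint(q), QUAL_MIN, QUAL_MAX))


def simulate_reads(
    sample_genome: str,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[FastqRecord], list[Placement]]:
    """Draw reads from the sample genome under the quality-coupled error model.

    Read count is ``round(mean_coverage * ref_length / read_length)``; start
    positions and strands are uniform; minus-strand reads are emitted as the
    reverse complement of their window with the quality vector applying in
    read orientation (cycle 0 = first sequenced base).
    """
    rng = _rng(config.seed if seed is None else seed)
    genome = np.frombuffer(sample_genome.encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_TO_CODE.items():
        code[ord(b)] = i
    genome_codes = code[genome]
    if (genome_codes < 0).any():
        raise SimulationError("sample genome contains non-ACGT characters")

    L = config.read_length
    G = len(sample_genome)
    n = config.n_reads
    starts = rng.integers(0, G - L + 1, size=n)
    minus = rng.integers(0, 2, size=n).astype(bool)

    means = np.array([cycle_mean_quality(c, config) for c in range(L)])
    quals = rng.normal(means, config.q_sd, size=(n, L))
    quals = np.clip(np.rint(quals), QUAL_MIN, QUAL_MAX).astype(np.int8)

    windows = genome_codes[starts[:, None] + np.arange(L)]
    true_codes = windows.copy()
    true_codes[minus] = 3 - windows[minus][:, ::-1]  # reverse complement

    perr = 10.0 ** (-quals / 10.0)
    miscall = rng.random((n, L)) < perr
    shift = rng.integers(1, 4, size=(n, L))
    called = np.where(miscall, (true_codes + shift) % 4, true_codes)

    base_chars = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    records: list[FastqRecord] = []
    placements: list[Placement] = []
    width = len(str(max(n - 1, 0)))
    for i in range(n):
        read_id = f"read_{i:0{width}d}"
        seq = base_chars[called[i]].tobytes().decode("ascii")
        records.append(FastqRecord(read_id, seq, quals[i].tolist()))
        placements.append(Placement(read_id, int(starts[i]), "-" if minus[i] else "+"))
    return records, placements


@dataclass
class SimDataset:
    """A complete simulated experiment: reference, sample, truth and reads."""

    config: SimConfig
    reference: str
    sample_genome: str
    truth: SimTruth
    reads: list[FastqRecord] = field(repr=False)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator from one seed: reference → SNPs → reads."""
    rng = np.random.default_rng(config.seed)
    ref = simulate_reference(rng, config.ref_length)
    sample, snps = plant_snps(ref, config.n_snps, rng, config.ems_bias)
    reads, placements = simulate_reads(sample, config, rng)
    return SimDataset(config, ref, sample, SimTruth(snps, placements), reads)


# --- plain-text truth/reference I/O -----------------------------------------

def write_fasta(sequence: str, path: str | Path, name: str = "ref") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    """First sequence of a FASTA file (the simulator writes exactly one)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_truth_vcf(snps: Sequence[Snp], path: str | Path, chrom: str = "ref") -> None:
    """Minimal VCF (CHROM/POS/REF/ALT, 1-based positions) for the planted SNPs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in snps:
            fh.write(f"{chrom}\t{snp.position + 1}\t.\t{snp.ref_base}\t{snp.alt_base}\t.\t.\t.\n")


def read_truth_vcf(path: str | Path) -> list[Snp]:
    snps = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            snps.append(Snp(int(fields[1]) - 1, fields[3], fields[4]))
    return snps


def write_placements_tsv(placements: Sequence[Placement], path: str | Path) -> None:
    """read_id / 0-based start / strand, tab-separated with a header line."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tstrand\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.start}\t{p.strand}\n")


def read_placements_tsv(path: str | Path) -> list[Placement]:
    placements = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise SimulationError(f"{path}: missing placements header")
        for line in fh:
            read_id, start, strand = line.rstrip("\n").split("\t")
            placements.append(Placement(read_id, int(start), strand))
    return placements
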