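"""The two quality-control operators compared in this package.

*Masking* replaces every base call whose PHRED score falls below a cutoff
with an undetermined base ('N'), leaving read length, read count and the
quality string untouched.

*Dynamic trimming* (SolexaQA-style) keeps only the longest contiguous run
of bases whose scores pass the same cutoff and discards the read entirely
when that run is shorter than a minimum length (default 25 bases).

Both operators use one boundary convention: a base is retained iff its
score is >= the cutoff (Q20 <-> error probability <= 1%). Ties between
equally long runs are broken toward the 5' end, where Illumina quality is
typically better.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Iterator, Literal, Optional

from .fastq_io import FastqRecord

Mode = Literal["mask", "trim", "none"]


@dataclass(frozen=True)
class MaskPolicy:
    """Masking parameters: cutoff score and the character written over failures."""

    min_q: int = 20
    mask_char: str = "N"

    def __post_init__(self) -> None:
        if self.min_q < 0:
            raise ValueError("min_q must be >= 0")
        if self.mask_char not in ("N", "n"):
            raise ValueError("mask_char must be 'N' or 'n'")


@dataclass(frozen=True)
class TrimPolicy:
    """Trimming parameters: cutoff score and minimum kept length."""

    min_q: int = 20
    min_len: int = 25

    def __post_init__(self) -> None:
        if self.min_q < 0:
            raise ValueError("min_q must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class TrimResult:
    """The kept interval [kept_start, kept_end) in original-read coordinates."""

    kept_start: int
    kept_end: int
    discarded: bool

    @property
    def kept_length(self) -> int:
        return self.kept_end - self.kept_start


@dataclass
class PreprocessSummary:
    """Read/base accounting across a processed stream."""

    reads_in: int = 0
    reads_out: int = 0
    reads_discarded: int = 0
    bases_in: int = 0
    bases_out: int = 0
    bases_masked: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def mask_read(rec: FastqRecord, policy: MaskPolicy = MaskPolicy()) -> FastqRecord:
    """Return a copy of ``rec`` with every base scoring below the cutoff masked.

    Qualities, length and identifier are unchanged, so masking is idempotent:
    the set of failing positions cannot change on a second pass.
    """
    seq = "".join(
        policy.mask_char if q < policy.min_q else b
        for b, q in zip(rec.sequence, rec.qualities)
    )
    return FastqRecord(rec.read_id, seq, list(rec.qualities), rec.description)


def longest_passing_run(qualities: list[int], min_q: int) -> tuple[int, int]:
    """Longest contiguous run of scores >= min_q as [start, end); 5'-most on ties.

    Returns (0, 0) when no base passes.
    """
    best_start, best_end = 0, 0
    run_start: Optional[int] = None
    for i, q in enumerate(qualities):
        if q >= min_q:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_end - best_start:
                best_start, best_end = run_start, i
            run_start = None
    if run_start is not None and len(qualities) - run_start > best_end - best_start:
        best_start, best_end = run_start, len(qualities)
    return best_start, best_end


def trim_read(
    rec: FastqRecord, policy: TrimPolicy = TrimPolicy()
) -> tuple[TrimResult, Optional[FastqRecord]]:
    """Trim ``rec`` to its longest all-passing run; discard if it is too short.

    Returns the kept interval (in original-read coordinates) and the trimmed
    record, or ``None`` when the read is discarded.
    """
    start, end = longest_passing_run(rec.qualities, policy.min_q)
    if end - start < policy.min_len:
        return TrimResult(start, start, discarded=True), None
    result = TrimResult(start, end, discarded=False)
    trimmed = FastqRecord(
        rec.read_id,
        rec.sequence[start:end],
        list(rec.qualities[start:end]),
        rec.description,
    )
    return result, trimmed


def process_stream(
    records: Iterable[FastqRecord],
    mode: Mode,
    mask_policy: MaskPolicy | None = None,
    trim_policy: TrimPolicy | None = None,
) -> tuple[Iterator[FastqRecord], PreprocessSummary]:
    """Apply one operator to a record stream, with summary accounting.

    Returns a lazy iterator of surviving records and the summary object,
    which is filled in as the iterator is consumed (complete once the
    iterator is exhausted). ``mode='none'`` is the identity.
    """
    if mode not in ("mask", "trim", "none"):
        raise ValueError(f"unknown mode: {mode!r}")
    mask_policy = mask_policy or MaskPolicy()
    trim_policy = trim_policy or TrimPolicy()
    summary = PreprocessSummary()

    def gen() -> Iterator[FastqRecord]:
        for rec in records:
            summary.reads_in += 1
            summary.bases_in += len(rec)
            if mode == "mask":
                out = mask_read(rec, mask_policy)
                summary.bases_masked += sum(
                    1 for q in rec.qualities if q < mask_policy.min_q
                )
            elif mode == "trim":
                _, out = trim_read(rec, trim_policy)
                if out is None:
                    summary.reads_discarded += 1
                    continue
            else:
                out = rec
            summary.reads_out += 1
            summary.bases_out += len(out)
            yield out

    return gen(), summary
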