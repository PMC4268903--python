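"""FASTQ reading and writing with explicit PHRED-encoding handling.

The strict 4-line FASTQ dialect is the only one accepted: each record is
exactly ``@id [description]`` / sequence / ``+`` / quality. Wrapped
(multi-line) records are rejected rather than silently joined, because
sequencer output is 4-line and streaming is simpler and safer that way.
Gzip input is detected from the file's magic bytes, not its name.

PHRED scores relate to the base-call error probability by ``p = 10^(-Q/10)``;
Q20 corresponds to a 1% chance that the base call is wrong.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import EncodingError, FastqParseError, QualityRangeError

logger = logging.getLogger(__name__)

#: Highest PHRED score storable in a FastqRecord (ASCII '~' under Phred+33).
MAX_PHRED = 93

_STANDARD_BASES = frozenset("ACGTNacgtn")

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class QualityEncoding:
    """An ASCII quality-character encoding: score = ord(char) - ascii_offset."""

    name: str
    ascii_offset: int

    @property
    def max_q(self) -> int:
        """Largest score representable with printable ASCII (up to '~', 126)."""
        return 126 - self.ascii_offset


PHRED33 = QualityEncoding("phred33", 33)
PHRED64 = QualityEncoding("phred64", 64)


@dataclass
class FastqRecord:
    """A single sequencing read: identifier, bases, per-base PHRED scores."""

    read_id: str
    sequence: str
    qualities: list[int]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.read_id or any(ch.isspace() for ch in self.read_id):
            raise ValueError(f"invalid read id: {self.read_id!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        for q in self.qualities:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(
                    f"read {self.read_id}: PHRED score {q} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ParseSummary:
    """Counts accumulated while reading a FASTQ stream."""

    records: int = 0
    bases: int = 0
    non_standard_bases: int = 0  # characters outside {A,C,G,T,N} (any case)


@dataclass
class EncodingGuess:
    """Result of encoding autodetection; ``ambiguous`` means both dialects fit."""

    encoding: QualityEncoding
    ambiguous: bool = False


def q_to_perr(q: float) -> float:
    """Error probability for a PHRED score: ``10^(-q/10)`` (Q20 -> 0.01)."""
    if q < 0:
        raise ValueError(f"PHRED score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def perr_to_q(p: float) -> float:
    """PHRED value (real-valued) for an error probability: ``-10*log10(p)``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def decode_quality(qual_string: str, enc: QualityEncoding = PHRED33) -> list[int]:
    """Decode an ASCII quality string to integer PHRED scores."""
    offset = enc.ascii_offset
    scores = []
    for i, ch in enumerate(qual_string):
        q = ord(ch) - offset
        if q < 0:
            raise EncodingError(
                f"quality character {ch!r} (ASCII {ord(ch)}) at position {i} "
                f"is below the {enc.name} offset {offset}"
            )
        scores.append(q)
    return scores


def encode_quality(qualities: Iterable[int], enc: QualityEncoding = PHRED33) -> str:
    """Encode integer PHRED scores as an ASCII quality string."""
    chars = []
    for i, q in enumerate(qualities):
        if not 0 <= q <= enc.max_q:
            raise QualityRangeError(
                f"PHRED score {q} at position {i} not representable in "
                f"{enc.name} (range 0..{enc.max_q})"
            )
        chars.append(chr(q + enc.ascii_offset))
    return "".join(chars)


def detect_encoding(sample: Iterable[str]) -> EncodingGuess:
    """Guess the quality encoding from a sample of quality strings.

    Any ASCII code below 59 forces Phred+33 (such characters are impossible
    under Phred+64). If every code is >= 64 and at least one exceeds 74 the
    sample looks like Phred+64. Otherwise both dialects fit; Phred+33 is
    returned with the ambiguous flag set.
    """
    lo, hi = 0x110000, -1
    seen = False
    for s in sample:
        for ch in s:
            code = ord(ch)
            seen = True
            if code < lo:
                lo = code
            if code > hi:
                hi = code
    if not seen:
        raise ValueError("cannot detect encoding from an empty sample")
    if lo < 59:
        return EncodingGuess(PHRED33)
    if lo >= 64 and hi > 74:
        return EncodingGuess(PHRED64)
    logger.warning(
        "quality codes in [%d, %d] fit both Phred+33 and Phred+64; "
        "assuming Phred+33", lo, hi,
    )
    return EncodingGuess(PHRED33, ambiguous=True)


def _open_maybe_gzip(source: str | Path | IO[bytes]) -> IO[bytes]:
    """Open a path or binary stream, transparently ungzipping by magic bytes."""
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    else:
        raw = source
    if hasattr(raw, "peek"):
        head = raw.peek(2)[:2]
        buffered = raw
    elif raw.seekable():
        pos = raw.tell()
        head = raw.read(2)
        raw.seek(pos)
        buffered = raw
    else:
        # wrapping takes ownership: only safe for streams we cannot rewind
        buffered = io.BufferedReader(raw)  # type: ignore[arg-type]
        head = buffered.peek(2)[:2]
    if head == GZIP_MAGIC:
        return gzip.open(buffered, "rb")  # type: ignore[return-value]
    return buffered


def read_fastq(
    source: str | Path | IO[bytes],
    encoding: QualityEncoding = PHRED33,
    summary: ParseSummary | None = None,
) -> Iterator[FastqRecord]:
    """Stream FastqRecords from a 4-line FASTQ file (plain or gzipped).

    Records are yielded lazily in file order; memory use is independent of
    file size. Malformed input raises :class:`FastqParseError` with the
    offending 1-based line number. Bases outside {A,C,G,T,N} are passed
    through unmodified but counted in ``summary`` when one is supplied.
    """
    stream = _open_maybe_gzip(source)
    close = isinstance(source, (str, Path))
    try:
        line_no = 0
        while True:
            header = stream.readline()
            if not header:
                return
            line_no += 1
            header_s = header.decode("ascii", errors="replace").rstrip("\n")
            if not header_s.startswith("@"):
                raise FastqParseError(
                    f"expected '@' header, got {header_s[:30]!r}", line_no
                )
            name = header_s[1:]
            if not name:
                raise FastqParseError("empty read id", line_no)
            read_id, _, description = name.partition(" ")

            seq_line = stream.readline()
            if not seq_line:
                raise FastqParseError("truncated record: missing sequence", line_no + 1)
            line_no += 1
            sequence = seq_line.decode("ascii", errors="replace").rstrip("\n")

            plus_line = stream.readline()
            if not plus_line:
                raise FastqParseError("truncated record: missing '+' separator", line_no + 1)
            line_no += 1
            if not plus_line.decode("ascii", errors="replace").startswith("+"):
                raise FastqParseError(
                    "expected '+' separator (wrapped multi-line FASTQ is not supported)",
                    line_no,
                )

            qual_line = stream.readline()
            if not qual_line:
                raise FastqParseError("truncated record: missing quality line", line_no + 1)
            line_no += 1
            qual_string = qual_line.decode("ascii", errors="replace").rstrip("\n")

            if len(sequence) != len(qual_string):
                raise FastqParseError(
                    f"read {read_id}: sequence length {len(sequence)} != "
                    f"quality length {len(qual_string)}",
                    line_no,
                )
            try:
                qualities = decode_quality(qual_string, encoding)
            except EncodingError as exc:
                raise FastqParseError(str(exc), line_no) from exc

            if summary is not None:
                summary.records += 1
                summary.bases += len(sequence)
                summary.non_standard_bases += sum(
                    1 for ch in sequence if ch not in _STANDARD_BASES
                )
            yield FastqRecord(read_id, sequence, qualities, description)
    finally:
        if close:
            stream.close()


def sniff_encoding(
    source: str | Path, max_records: int = 1000
) -> EncodingGuess:
    """Detect the quality encoding of a FASTQ file from its first records."""
    quals: list[str] = []
    with _open_maybe_gzip(source) as stream:
        for i, line in enumerate(stream):
            if i % 4 == 3:
                quals.append(line.decode("ascii", errors="replace").rstrip("\n"))
                if len(quals) >= max_records:
                    break
    if not quals:
        raise FastqParseError("no records found while detecting encoding")
    return detect_encoding(quals)


def write_fastq(
    records: Iterable[FastqRecord],
    sink: str | Path | IO[bytes],
    encoding: QualityEncoding = PHRED33,
    compress: bool | None = None,
) -> int:
    """Write records as 4-line FASTQ; returns the number written.

    ``compress`` defaults to gzipping when the sink is a path ending in
    ``.gz``. Scores outside the encoding's representable range raise
    :class:`QualityRangeError`.
    """
    if isinstance(sink, (str, Path)):
        if compress is None:
            compress = str(sink).endswith(".gz")
        raw: IO[bytes] = open(sink, "wb")
        close_raw = True
    else:
        raw = sink
        close_raw = False
        compress = bool(compress)
    # mtime=0 and an empty embedded filename keep gzip output byte-deterministic.
    stream = (
        gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
        if compress
        else raw
    )
    count = 0
    try:
        for rec in records:
            header = f"@{rec.read_id}"
            if rec.description:
                header += f" {rec.description}"
            qual = encode_quality(rec.qualities, encoding)
            stream.write(
                f"{header}\n{rec.sequence}\n+\n{qual}\n".encode("ascii")
            )
            count += 1
    finally:
        if compress:
            stream.close()  # flush gzip trailer without closing a caller's stream
        if close_raw:
            raw.close()
    return count
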