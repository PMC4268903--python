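"""End-to-end comparison of preprocessing methods on simulated data.

Alignment is bypassed: each read's true placement is known from the
simulator, so reads are piled up directly on the reference and a naive
caller declares a homozygous SNP wherever a non-reference base dominates a
sufficiently deep column. This isolates the effect of preprocessing on
calling from aligner behaviour, which is deliberately not modelled.

The comparison runs one simulated read set through three arms — no quality
control, dynamic trimming, masking — and scores each call set against the
planted SNPs. Assessed negatives are all non-SNP reference positions, a
much larger denominator than a Sanger-assayed candidate panel, so only the
ordering of false-positive counts and their pairwise Fisher tests are
comparable across arms, not the absolute rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .contingency_stats import (
    ConfusionCounts,
    Table2x2,
    TestResult,
    fisher_exact,
    fn_rate,
    fp_rate,
)
from .errors import EvaluationError
from .fastq_io import FastqRecord
from .preprocess import (
    MaskPolicy,
    PreprocessSummary,
    TrimPolicy,
    TrimResult,
    mask_read,
    trim_read,
)
from .simulate import BASES, Placement, SimConfig, Snp, simulate_dataset

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = -1
_CODE[ord("n")] = -1

DEFAULT_MIN_DEPTH = 3
DEFAULT_HOM_FRAC = 0.8


@dataclass(frozen=True)
class PileupColumn:
    """Base tally at one reference position; 'N' calls carry no weight."""

    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def pileup(
    records: Iterable[FastqRecord],
    placements: Mapping[str, Placement],
    ref_length: int,
    read_length: int,
    trim_results: Mapping[str, TrimResult] | None = None,
) -> np.ndarray:
    """Tally aligned base calls per reference position.

    Returns an (ref_length, 4) array of counts over A/C/G/T in that order.
    Records are in read orientation (as sequenced); minus-strand reads
    contribute the complement of each call at mirrored offsets. A trimmed
    record maps its base i to original-read coordinate ``kept_start + i``
    before the strand arithmetic, using ``read_length`` as the pre-trim
    length. Masked ('N'/'n') bases are skipped, so every surviving
    determined base contributes exactly one count.
    """
    counts = np.zeros((ref_length, 4), dtype=np.int64)
    for rec in records:
        placement = placements.get(rec.read_id)
        if placement is None:
            raise EvaluationError(f"no placement for read {rec.read_id}")
        offset = 0
        if trim_results is not None and rec.read_id in trim_results:
            offset = trim_results[rec.read_id].kept_start
        codes = _CODE[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        i_orig = offset + np.arange(len(codes))
        if placement.strand == "+":
            positions = placement.start + i_orig
            aligned = codes
        else:
            positions = placement.start + (read_length - 1) - i_orig
            aligned = np.where(codes >= 0, 3 - codes, codes)
        keep = aligned >= 0
        positions = positions[keep]
        if positions.size and (positions.min() < 0 or positions.max() >= ref_length):
            raise EvaluationError(
                f"read {rec.read_id}: aligned positions outside reference"
            )
        np.add.at(counts, (positions, aligned[keep]), 1)
    return counts


def pileup_columns(counts: np.ndarray) -> Iterable[PileupColumn]:
    """Non-empty columns of a pileup array as PileupColumn objects."""
    for pos in np.flatnonzero(counts.sum(axis=1)):
        yield PileupColumn(
            int(pos), {b: int(counts[pos, i]) for i, b in enumerate(BASES)}
        )


def call_snps(
    counts: np.ndarray,
    ref: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
) -> dict[int, str]:
    """Naive homozygous-SNP caller over a pileup.

    A position is called with alternative base b iff depth >= ``min_depth``,
    b differs from the reference base, and b accounts for at least
    ``hom_frac`` of the column's determined calls. At most one call per
    position: the most frequent alternative, ties broken alphabetically.
    """
    ref_codes = _CODE[np.frombuffer(ref.encode("ascii"), dtype=np.uint8)]
    if len(ref_codes) != len(counts):
        raise EvaluationError("reference length does not match pileup")
    depth = counts.sum(axis=1)
    alt_counts = counts.copy()
    idx = np.arange(len(counts))
    valid_ref = ref_codes >= 0
    alt_counts[idx[valid_ref], ref_codes[valid_ref]] = -1
    best = alt_counts.argmax(axis=1)  # first max -> alphabetical tie-break
    best_n = alt_counts[idx, best]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, best_n / np.maximum(depth, 1), 0.0)
    called = (depth >= min_depth) & (best_n > 0) & (frac >= hom_frac) & valid_ref
    return {int(p): BASES[best[p]] for p in np.flatnonzero(called)}


@dataclass
class MethodResult:
    """One arm of the comparison: preprocessing accounting plus call scoring."""

    method: str
    summary: PreprocessSummary
    confusion: ConfusionCounts
    fp_rate: float
    fn_rate: float
    calls: dict[int, str] = field(repr=False)
    snp_depths: list[int] = field(repr=False)  # pileup depth at each planted SNP

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "summary": self.summary.as_dict(),
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
        }


@dataclass
class EvalReport:
    """Three-arm comparison report with pairwise Fisher tests on FP counts."""

    n_snps: int
    n_negatives: int
    snp_positions: list[int]
    results: dict[str, MethodResult]
    fisher_mask_vs_none: TestResult
    fisher_trim_vs_none: TestResult

    def as_dict(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "n_negatives": self.n_negatives,
            "methods": {m: r.as_dict() for m, r in self.results.items()},
            "fisher_fp": {
                "mask_vs_none": self.fisher_mask_vs_none.as_dict(),
                "trim_vs_none": self.fisher_trim_vs_none.as_dict(),
            },
        }


def evaluate_method(
    reads: Sequence[FastqRecord],
    placements: Mapping[str, Placement],
    ref: str,
    snps: Sequence[Snp],
    method: str,
    read_length: int,
    mask_policy: MaskPolicy | None = None,
    trim_policy: TrimPolicy | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
) -> MethodResult:
    """Run one preprocessing arm through pileup, calling and scoring."""
    if method not in ("none", "mask", "trim"):
        raise ValueError(f"unknown method: {method!r}")
    mask_policy = mask_policy or MaskPolicy()
    trim_policy = trim_policy or TrimPolicy()

    summary = PreprocessSummary()
    processed: list[FastqRecord] = []
    trim_results: dict[str, TrimResult] = {}
    for rec in reads:
        summary.reads_in += 1
        summary.bases_in += len(rec)
        out: Optional[FastqRecord]
        if method == "mask":
            out = mask_read(rec, mask_policy)
            summary.bases_masked += sum(
                1 for q in rec.qualities if q < mask_policy.min_q
            )
        elif method == "trim":
            tr, out = trim_read(rec, trim_policy)
            if out is None:
                summary.reads_discarded += 1
                continue
            trim_results[rec.read_id] = tr
        else:
            out = rec
        summary.reads_out += 1
        summary.bases_out += len(out)
        processed.append(out)

    counts = pileup(
        processed, placements, len(ref), read_length,
        trim_results if method == "trim" else None,
    )
    calls = call_snps(counts, ref, min_depth, hom_frac)

    snp_positions = {s.position for s in snps}
    called_positions = set(calls)
    tp = len(called_positions & snp_positions)
    fp = len(called_positions - snp_positions)
    fn = len(snp_positions) - tp
    tn = (len(ref) - len(snp_positions)) - fp
    confusion = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    depth = counts.sum(axis=1)
    return MethodResult(
        method=method,
        summary=summary,
        confusion=confusion,
        fp_rate=fp_rate(confusion),
        fn_rate=fn_rate(confusion),
        calls=calls,
        snp_depths=[int(depth[s.position]) for s in snps],
    )


def compare_methods(
    config: SimConfig,
    mask_policy: MaskPolicy | None = None,
    trim_policy: TrimPolicy | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
) -> EvalReport:
    """Simulate one dataset and run it through none / trim / mask arms.

    The identical read set feeds all three arms; the Fisher tests put the
    no-quality-control arm in row 1 and ask, one-sided, whether it has an
    excess of false positives over the preprocessed arm.
    """
    ds = simulate_dataset(config)
    placements = {p.read_id: p for p in ds.truth.placements}
    results = {
        method: evaluate_method(
            ds.reads, placements, ds.reference, ds.truth.snps, method,
            config.read_length, mask_policy, trim_policy, min_depth, hom_frac,
        )
        for method in ("none", "trim", "mask")
    }

    def fp_table(a: MethodResult, b: MethodResult) -> Table2x2:
        return Table2x2(
            a.confusion.fp, a.confusion.tn, b.confusion.fp, b.confusion.tn
        )

    return EvalReport(
        n_snps=config.n_snps,
        n_negatives=config.ref_length - config.n_snps,
        snp_positions=[s.position for s in ds.truth.snps],
        results=results,
        fisher_mask_vs_none=fisher_exact(
            fp_table(results["none"], results["mask"]), "greater"
        ),
        fisher_trim_vs_none=fisher_exact(
            fp_table(results["none"], results["trim"]), "greater"
        ),
    )
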