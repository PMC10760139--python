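"""Read k-mer counting, coverage estimation and k-mer classification.

Canonical k-mer counts from the sequenced sample anchor the sampling:
the count histogram yields the k-mer coverage ``c`` (the expected count
of a k-mer present on both haplotypes of a diploid sample; heterozygous
k-mers peak near ``c/2``), and each presence-matrix k-mer is classified
as absent, heterozygous, homozygous or frequent by comparing its count
against fractions of ``c``.  Singleton counts are discarded on loading,
and only k-mers used in the presence matrices are retained for sampling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .kmer_index import canonical_codes, decode_kmer, encode_kmer, kmer_codes

__all__ = [
    "KmerCounts",
    "ReadProfile",
    "ClassificationThresholds",
    "CoverageEstimationError",
    "count_read_kmers",
    "estimate_coverage",
    "classify_kmer",
    "ABSENT",
    "HETEROZYGOUS",
    "HOMOZYGOUS",
    "FREQUENT",
]

ABSENT = "absent"
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
FREQUENT = "frequent"

_CLASS_ORDER = (ABSENT, HETEROZYGOUS, HOMOZYGOUS, FREQUENT)


class CoverageEstimationError(RuntimeError):
    """Coverage could not be estimated; the user must provide a value."""


@dataclass(frozen=True)
class ClassificationThresholds:
    """Count/coverage ratio bands separating the four k-mer classes.

    A k-mer with count ``n`` and coverage ``c`` is absent when
    ``n/c < absent_below``, heterozygous up to ``het_below`` (band centred
    on 0.5), homozygous up to ``hom_below`` (band centred on 1), and
    frequent beyond.
    """

    absent_below: float = 0.25
    het_below: float = 0.75
    hom_below: float = 1.75

    def __post_init__(self) -> None:
        if not 0 < self.absent_below < self.het_below < self.hom_below:
            raise ValueError("thresholds must be increasing and positive")


@dataclass
class KmerCounts:
    """Strand-combined canonical k-mer counts (singletons removed)."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def get(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def restrict(self, kmers: Iterable[str]) -> "KmerCounts":
        """Counts restricted to the k-mers used in presence matrices."""
        keep = {km: self.counts[km] for km in kmers if km in self.counts}
        return KmerCounts(self.k, keep)

    # -- TSV interchange ----------------------------------------------

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "KmerCounts":
        counts: dict[str, int] = {}
        with _open_text(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#k="):
                        k = int(line[3:])
                    continue
                try:
                    kmer, value = line.split("\t")
                    count = int(value)
                except ValueError as exc:
                    raise ValueError(f"malformed counts line {lineno}: {line!r}") from exc
                counts[kmer] = count
        if k is None:
            if not counts:
                raise ValueError("cannot infer k from an empty counts file")
            k = len(next(iter(counts)))
        bad = next((km for km in counts if len(km) != k), None)
        if bad is not None:
            raise ValueError(f"k-mer {bad!r} does not match k={k}")
        counts = {km: c for km, c in counts.items() if c >= 2}
        return cls(k, counts)


def _open_text(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_records(path) -> Iterator[tuple[str, str]]:
    """(name, sequence) records from FASTA or FASTQ (optionally gzipped)."""
    with _open_text(path, "rt") as fh:
        first = fh.read(1)
        if not first:
            raise ValueError("empty read file")
        fh.seek(0)
        if first == ">":
            from Bio import SeqIO

            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)
        elif first == "@":
            record_no = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                record_no += 1
                seq = fh.readline().rstrip("\n")
                plus = fh.readline()
                qual = fh.readline().rstrip("\n")
                if (
                    not header.startswith("@")
                    or not plus.startswith("+")
                    or not qual
                    or len(qual) != len(seq)
                ):
                    raise ValueError(f"malformed FASTQ record {record_no}")
                yield header[1:].split()[0], seq
        else:
            raise ValueError("unrecognized read format (expected FASTA or FASTQ)")


def count_read_kmers(reads, k: int, keep_singletons: bool = False) -> KmerCounts:
    """Count canonical k-mers in reads.

    ``reads`` is a file path (FASTA/FASTQ, optionally gzipped) or an
    iterable of sequence strings.  Every length-k window containing only
    ACGT contributes one count to its canonical k-mer; windows with other
    bases contribute nothing.  k-mers seen exactly once are dropped on
    finalize unless ``keep_singletons`` is set.
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        seqs: Iterable[str] = (seq for _, seq in _read_records(reads))
    else:
        seqs = iter(reads)

    total: dict[int, int] = {}
    chunk: list[str] = []
    chunk_len = 0

    def flush() -> None:
        nonlocal chunk, chunk_len
        if not chunk:
            return
        joined = "N".join(chunk)
        codes, valid = kmer_codes(joined, k)
        if len(codes):
            can = canonical_codes(codes, k)[valid]
            values, counts = np.unique(can, return_counts=True)
            for code, n in zip(values.tolist(), counts.tolist()):
                total[code] = total.get(code, 0) + n
        chunk = []
        chunk_len = 0

    for seq in seqs:
        chunk.append(seq)
        chunk_len += len(seq)
        if chunk_len >= 4_000_000:
            flush()
    flush()

    minimum = 1 if keep_singletons else 2
    counts = {
        decode_kmer(code, k): n for code, n in total.items() if n >= minimum
    }
    return KmerCounts(k, counts)


# ---------------------------------------------------------------------------
# Coverage estimation
# ---------------------------------------------------------------------------


def estimate_coverage(
    counts: KmerCounts,
    secondary_window: float = 0.25,
    secondary_min_fraction: float = 0.5,
) -> float:
    """Estimate k-mer coverage from the count histogram.

    The histogram mode (lightly smoothed with a +-1 moving average to
    stabilise ties between neighbouring Poisson bins) is used outright
    when it lies strictly above the median of the stored counts.
    Otherwise a secondary peak is sought within ``+-secondary_window`` of
    twice the primary mode: it must lie above the median, be a local
    histogram maximum, and carry at least ``secondary_min_fraction`` of
    the primary peak's mass; if found, it is the estimate (the primary
    peak was the heterozygous one).  Failing that, a mode within the
    peak's own width of the median — ``max(2, 0.1 * median)`` count bins —
    is still accepted as a single straddling coverage peak.  If all
    attempts fail a :class:`CoverageEstimationError` is raised and the
    user must provide an estimate.
    """
    if len(counts) == 0:
        raise CoverageEstimationError("no k-mer counts to estimate coverage from")
    values = np.fromiter(counts.counts.values(), dtype=np.int64, count=len(counts))
    hist = np.bincount(values)
    if np.count_nonzero(hist) < 2:
        raise CoverageEstimationError(
            "degenerate count histogram (a single distinct count value)"
        )
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    mode = int(np.argmax(smooth))
    median = float(np.median(values))

    def refined_mode() -> float:
        # Refine back to the raw histogram around the smoothed peak.
        lo = max(mode - 1, 0)
        return float(lo + int(np.argmax(hist[lo : mode + 2])))

    if mode > median:
        return refined_mode()

    lo = int(np.floor(2 * mode * (1 - secondary_window)))
    hi = int(np.ceil(2 * mode * (1 + secondary_window)))
    lo = max(lo, int(np.floor(median)) + 1)
    hi = min(hi, len(hist) - 1)
    best = None
    for v in range(lo, hi + 1):
        if v <= median:
            continue
        left = smooth[v - 1] if v - 1 >= 0 else 0
        right = smooth[v + 1] if v + 1 < len(smooth) else 0
        if smooth[v] < left or smooth[v] < right:
            continue  # not a local maximum of the smoothed histogram
        if best is None or smooth[v] > smooth[best]:
            best = v
    if best is not None and smooth[best] >= secondary_min_fraction * smooth[mode]:
        return float(best)

    if mode >= median - max(2.0, 0.1 * median):
        return refined_mode()
    raise CoverageEstimationError(
        "could not find a coverage peak above the median; "
        "provide the k-mer coverage explicitly"
    )


def classify_kmer(
    count: int, coverage: float, thresholds: ClassificationThresholds | None = None
) -> str:
    """Classify one k-mer count as absent/heterozygous/homozygous/frequent."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    t = thresholds or ClassificationThresholds()
    ratio = count / coverage
    if ratio < t.absent_below:
        return ABSENT
    if ratio < t.het_below:
        return HETEROZYGOUS
    if ratio < t.hom_below:
        return HOMOZYGOUS
    return FREQUENT


@dataclass
class ReadProfile:
    """Counts, estimated coverage, and per-matrix-k-mer classes."""

    counts: KmerCounts
    coverage: float
    classes: dict[str, str]
    thresholds: ClassificationThresholds

    @classmethod
    def build(
        cls,
        counts: KmerCounts,
        matrix_kmers: Iterable[str],
        coverage: float | None = None,
        thresholds: ClassificationThresholds | None = None,
    ) -> "ReadProfile":
        """Profile the reads against the k-mers used in presence matrices.

        Counts are restricted to the matrix k-mers; coverage is estimated
        from the restricted counts unless supplied.  Every matrix k-mer
        receives exactly one class (missing counts classify as absent).
        """
        matrix_kmers = list(matrix_kmers)
        restricted = counts.restrict(matrix_kmers)
        if coverage is None:
            coverage = estimate_coverage(restricted)
        thresholds = thresholds or ClassificationThresholds()
        classes = {
            km: classify_kmer(restricted.get(km), coverage, thresholds)
            for km in matrix_kmers
        }
        return cls(restricted, float(coverage), classes, thresholds)

    def class_tally(self) -> dict[str, int]:
        tally = {c: 0 for c in _CLASS_ORDER}
        for c in self.classes.values():
            tally[c] += 1
        return tally
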