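"""Read-to-library mapping with post-alignment filtering.

Amplicon reads from the sorted populations are mapped back to the designed
element library: reads are linker- and quality-trimmed, locally aligned
(Smith-Waterman, affine gaps) against every element oligo on both strands,
reduced to one best alignment per read, and passed through three filters —
at most 3 mismatches, at most 3 gap columns, and a mapped length no more
than 10 nt short of the maximum possible — before per-element counting.

The scoring scheme is BLASTN-like (match +2, mismatch -3, gap existence 5,
gap extension 2). ``evalue_proxy`` is ``exp(-score) * search_space`` — a
deterministic ranking proxy mirroring how an E-value orders hits, not a
calibrated Karlin-Altschul E-value.

For whole-sample mapping a 16-mer index shortlists candidate elements per
read; the shortlisted alignments are produced by the same kernel as the
exhaustive reference path and are exact, not approximate, for every
candidate actually aligned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._sw import encode, sw_align
from .library_design import LibraryElement, reverse_complement

DEFAULT_MIN_PHRED = 25.75
QUALITY_WINDOW = 4
MIN_LINKER_OVERLAP = 8


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring; penalty fields are non-negative magnitudes."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5  # gap existence cost
    gap_extend: int = 2  # per-base gap cost

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative magnitudes")

    @property
    def default_floor(self) -> int:
        """Minimum reportable score: a 20 bp exact match."""
        return 20 * self.match


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    element_id: str
    strand: str  # '+' or '-'
    score: int
    mismatches: int
    gaps: int  # gap columns: total inserted + deleted bases
    mapped_length: int  # bp of the element covered by the alignment
    read_length: int  # trimmed read length (sets the max possible mapping)
    evalue_proxy: float


def evalue_proxy(score: float, library_total_bp: int, read_bp: int) -> float:
    """Ranking proxy ~ exp(-score) * search space; underflows to 0 for
    large scores, which is harmless for ordering (score dominates ties)."""
    with np.errstate(under="ignore"):
        return float(np.exp(-float(score)) * (library_total_bp * read_bp))


# ---------------------------------------------------------------------------
# trimming


def remove_linker(sequence: str, linker: str) -> str:
    """Strip the shared linker from the read start.

    Exact full-linker prefixes are removed; otherwise the longest overlap of
    a linker suffix with the read prefix (>= 8 bp) is removed, covering
    reads that start inside the linker.
    """
    if not linker:
        return sequence
    if sequence.startswith(linker):
        return sequence[len(linker):]
    for k in range(min(len(linker), len(sequence)) - 1, MIN_LINKER_OVERLAP - 1, -1):
        if linker[-k:] == sequence[:k]:
            return sequence[k:]
    return sequence


def quality_trim_length(qualities: np.ndarray, min_phred: float = DEFAULT_MIN_PHRED) -> int:
    """Length to keep under the sliding-window quality rule.

    A 4-base window ends at each position (shorter at the 5' start); the
    read is truncated before the first position whose window mean drops to
    or below ``min_phred``.
    """
    q = np.asarray(qualities, dtype=float)
    n = q.shape[0]
    if n == 0:
        return 0
    c = np.concatenate(([0.0], np.cumsum(q)))
    starts = np.maximum(np.arange(n) - (QUALITY_WINDOW - 1), 0)
    means = (c[np.arange(1, n + 1)] - c[starts]) / (np.arange(n) + 1 - starts)
    bad = np.flatnonzero(means <= min_phred)
    return int(bad[0]) if bad.size else n


def trim_read(read: Read, linker: str, min_phred: float = DEFAULT_MIN_PHRED) -> Read:
    """Remove the linker prefix, then quality-trim the 3' end."""
    seq = remove_linker(read.sequence, linker)
    offset = len(read.sequence) - len(seq)
    qual = read.qualities[offset:]
    keep = quality_trim_length(qual, min_phred)
    return Read(read.id, seq[:keep], qual[:keep])


# ---------------------------------------------------------------------------
# alignment


def _align_pair(
    read: Read,
    q_fwd: np.ndarray,
    q_rev: np.ndarray,
    element: LibraryElement,
    r_codes: np.ndarray,
    scheme: ScoringScheme,
    library_total_bp: int,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Align a read (both strands) against one element oligo."""
    out = []
    for strand, q in (("+", q_fwd), ("-", q_rev)):
        score, mm, gaps, _, _, r0, r1 = sw_align(
            q, r_codes, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
        )
        out.append(
            AlignmentRecord(
                read_id=read.id,
                element_id=element.id,
                strand=strand,
                score=int(score),
                mismatches=int(mm),
                gaps=int(gaps),
                mapped_length=int(r1 - r0),
                read_length=len(read),
                evalue_proxy=evalue_proxy(score, library_total_bp, len(read)),
            )
        )
    return out[0], out[1]


class LibraryAligner:
    """Aligns reads against a library of element oligos.

    ``align_read`` is the exhaustive reference path (every element, both
    strands). ``align_read_indexed`` shortlists candidate (element, strand)
    pairs via a 16-mer exact-match index and aligns only those with the
    identical kernel; reads sharing no 16-mer with any oligo return no
    records.
    """

    def __init__(
        self,
        library: Sequence[LibraryElement],
        scheme: ScoringScheme | None = None,
        k: int = 16,
    ):
        self.library = list(library)
        self.scheme = scheme or ScoringScheme()
        self.k = k
        self._oligos = [el.oligo_sequence or el.core_sequence for el in self.library]
        self._codes = [encode(s) for s in self._oligos]
        self.library_total_bp = sum(len(s) for s in self._oligos)
        self._index: dict[str, set[tuple[int, str]]] = {}
        for i, oligo in enumerate(self._oligos):
            for start in range(len(oligo) - k + 1):
                self._index.setdefault(oligo[start : start + k], set()).add((i, "+"))
            rc = reverse_complement(oligo)
            for start in range(len(rc) - k + 1):
                self._index.setdefault(rc[start : start + k], set()).add((i, "-"))

    def _candidates(self, sequence: str, step: int = 8) -> list[tuple[int, str]]:
        """Shortlist (element, strand) pairs by sampled 16-mer votes.

        Shared cloning flanks make flank k-mers hit every element; the true
        source element dominates the vote via its core k-mers, so only
        candidates with at least half the best vote are aligned.
        """
        votes: Counter = Counter()
        for p in range(0, max(len(sequence) - self.k, 0) + 1, step):
            for hit in self._index.get(sequence[p : p + self.k], ()):
                votes[hit] += 1
        if not votes:
            return []
        best = max(votes.values())
        floor = max(1, best // 2)
        return sorted(h for h, v in votes.items() if v >= floor)

    def align_read(
        self, read: Read, min_score: int | None = None
    ) -> list[AlignmentRecord]:
        """Exhaustive local alignment against every element, both strands."""
        if len(read) == 0:
            raise ValueError("cannot align an empty read")
        floor = self.scheme.default_floor if min_score is None else min_score
        q_fwd = encode(read.sequence)
        q_rev = encode(reverse_complement(read.sequence))
        records = []
        for el, codes in zip(self.library, self._codes):
            fwd, rev = _align_pair(
                read, q_fwd, q_rev, el, codes, self.scheme, self.library_total_bp
            )
            best = fwd if fwd.score >= rev.score else rev
            if best.score >= floor:
                records.append(best)
        return records

    def align_read_indexed(
        self, read: Read, min_score: int | None = None
    ) -> list[AlignmentRecord]:
        """Seeded alignment: only elements sharing a 16-mer with the read."""
        if len(read) == 0:
            raise ValueError("cannot align an empty read")
        floor = self.scheme.default_floor if min_score is None else min_score
        cands = self._candidates(read.sequence)
        if not cands:
            return []
        q_cache: dict[str, np.ndarray] = {}
        records = []
        for i, strand in cands:
            if strand not in q_cache:
                q_cache[strand] = (
                    encode(read.sequence)
                    if strand == "+"
                    else encode(reverse_complement(read.sequence))
                )
            el = self.library[i]
            score, mm, gaps, _, _, r0, r1 = sw_align(
                q_cache[strand],
                self._codes[i],
                self.scheme.match,
                self.scheme.mismatch,
                self.scheme.gap_open,
                self.scheme.gap_extend,
            )
            if score >= floor:
                records.append(
                    AlignmentRecord(
                        read_id=read.id,
                        element_id=el.id,
                        strand=strand,
                        score=int(score),
                        mismatches=int(mm),
                        gaps=int(gaps),
                        mapped_length=int(r1 - r0),
                        read_length=len(read),
                        evalue_proxy=evalue_proxy(
                            score, self.library_total_bp, len(read)
                        ),
                    )
                )
        return records


def align_read(
    read: Read,
    library: Sequence[LibraryElement],
    scheme: ScoringScheme | None = None,
    min_score: int | None = None,
) -> list[AlignmentRecord]:
    """One-shot exhaustive alignment (builds a throwaway aligner)."""
    return LibraryAligner(library, scheme).align_read(read, min_score)


# ---------------------------------------------------------------------------
# post-alignment processing


def deduplicate(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep exactly one alignment per read: highest score, then lowest
    e-value proxy, then lexicographically smallest element id."""
    best: dict[str, AlignmentRecord] = {}
    for rec in records:
        cur = best.get(rec.read_id)
        if cur is None or (
            (-rec.score, rec.evalue_proxy, rec.element_id)
            < (-cur.score, cur.evalue_proxy, cur.element_id)
        ):
            best[rec.read_id] = rec
    return list(best.values())


def apply_filters(
    records: Iterable[AlignmentRecord],
    library: Sequence[LibraryElement],
    max_mismatches: int = 3,
    max_gaps: int = 3,
    length_slack: int = 10,
    log: Counter | None = None,
) -> list[AlignmentRecord]:
    """Apply the three post-alignment filters.

    A record survives iff mismatches <= ``max_mismatches`` and gap columns
    <= ``max_gaps`` and mapped length >= max_possible - ``length_slack``,
    where max_possible = min(trimmed read length, element oligo length).
    Per-rule rejection counts accumulate into ``log`` when given.
    """
    oligo_len = {el.id: len(el.oligo_sequence or el.core_sequence) for el in library}
    kept = []
    log = log if log is not None else Counter()
    for rec in records:
        if rec.element_id not in oligo_len:
            raise KeyError(f"alignment references unknown element {rec.element_id!r}")
        max_possible = min(rec.read_length, oligo_len[rec.element_id])
        if rec.mismatches > max_mismatches:
            log["mismatches"] += 1
        elif rec.gaps > max_gaps:
            log["gaps"] += 1
        elif rec.mapped_length < max_possible - length_slack:
            log["mapped_length"] += 1
        else:
            kept.append(rec)
            continue
    log["kept"] += len(kept)
    return kept


def count_elements(
    records: Iterable[AlignmentRecord],
    library: Sequence[LibraryElement],
    sample_name: str = "counts",
) -> pd.Series:
    """Per-element read counts (0 for unobserved elements)."""
    ids = [el.id for el in library]
    counts = Counter(rec.element_id for rec in records)
    return pd.Series(
        [counts.get(i, 0) for i in ids],
        index=pd.Index(ids, name="element_id"),
        name=sample_name,
        dtype=np.int64,
    )


# ---------------------------------------------------------------------------
# whole-sample pipeline


@dataclass
class MappingResult:
    counts: pd.Series
    alignments: list[AlignmentRecord]
    log: Counter = field(default_factory=Counter)

    def alignment_table(self) -> pd.DataFrame:
        """BLAST outfmt-6-like tabular view of the kept alignments."""
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "element_id": r.element_id,
                    "strand": r.strand,
                    "score": r.score,
                    "mismatches": r.mismatches,
                    "gaps": r.gaps,
                    "mapped_length": r.mapped_length,
                    "evalue_proxy": r.evalue_proxy,
                }
                for r in self.alignments
            ]
        )


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a FASTQ file into Read objects (Phred+33 qualities)."""
    reads = []
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            reads.append(
                Read(
                    rid.split()[0],
                    seq.upper(),
                    np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
                    - 33,
                )
            )
    return reads


def map_reads(
    reads: Iterable[Read],
    library: Sequence[LibraryElement],
    linker: str = "",
    min_phred: float = DEFAULT_MIN_PHRED,
    scheme: ScoringScheme | None = None,
    max_mismatches: int = 3,
    max_gaps: int = 3,
    length_slack: int = 10,
    sample_name: str = "counts",
    aligner: LibraryAligner | None = None,
) -> MappingResult:
    """Trim, align (seeded), deduplicate, filter and count a read set."""
    aligner = aligner or LibraryAligner(library, scheme)
    log: Counter = Counter()
    per_read_best: list[AlignmentRecord] = []
    for read in reads:
        log["reads_in"] += 1
        trimmed = trim_read(read, linker, min_phred)
        if len(trimmed) == 0:
            log["empty_after_trim"] += 1
            continue
        records = aligner.align_read_indexed(trimmed)
        if not records:
            log["unaligned"] += 1
            continue
        per_read_best.extend(deduplicate(records))
    filtered = apply_filters(
        per_read_best, library, max_mismatches, max_gaps, length_slack, log
    )
    return MappingResult(
        counts=count_elements(filtered, library, sample_name),
        alignments=filtered,
        log=log,
    )


def map_fastq(path: str | Path, library: Sequence[LibraryElement], **kwargs) -> MappingResult:
    return map_reads(read_fastq(path), library, **kwargs)
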