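"""Design of a pooled barrier-element screening library.

A sort-seq screen of chromatin barrier elements starts from a designed
oligo pool: candidate elements (CTCF-binding sequences ranked by predicted
affinity, MIR retrotransposons with genomic coordinates, and random DNA
controls) are selected under per-category quotas, trimmed to a uniform core
length, and wrapped in cloning flanks to form fixed-length oligos. This
module implements the selection, filtering and assembly rules plus the
coverage-planning arithmetic used to size transformations and transfections.

Conventions
-----------
* Genomic coordinates are 0-based, half-open (BED).
* Distance from an element to a lamina-associated-domain (LAD) boundary is
  the gap in bp between the element interval and the nearest LAD start/end
  coordinate on the same chromosome; an element spanning a boundary has
  distance 0. Elements strictly inside a LAD get the distance to the nearer
  edge.
* Sequences containing an Esp3I (BsmBI) recognition site on either strand
  are unusable for Golden Gate cloning and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

logger = logging.getLogger(__name__)

ESP3I_SITE = "CGTCTC"
ESP3I_SITE_RC = "GAGACG"

_STRANDS = {"+", "-", "."}
_CATEGORIES = {"CTCF", "MIR", "RANDOM"}

#: Per-category element quotas of the screening library (1000 elements).
DEFAULT_QUOTAS: dict[str, int] = {
    "CTCF-High": 450,
    "CTCF-Low": 50,
    "MIR-LAD_bound": 30,
    "MIR-random": 420,
    "RANDOM": 50,
}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to_point(self, pos: int) -> int:
        """Gap in bp from this interval to a point coordinate (0 if inside)."""
        return max(pos - self.end, self.start - pos, 0)


@dataclass(frozen=True)
class CandidateElement:
    """One pre-selection candidate: a scored, optionally localized sequence."""

    id: str
    category: str
    affinity_score: float
    sequence: str
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"candidate {self.id}: empty sequence")
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"candidate {self.id}: category {self.category!r} not in {_CATEGORIES}"
            )


@dataclass(frozen=True)
class LibrarySpec:
    """Composition and assembly rules for the screening library."""

    quotas: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    core_length: int = 250
    flank_total: int = 50
    lad_proximity_bp: int = 5000
    excluded_sites: tuple[str, ...] = (ESP3I_SITE, ESP3I_SITE_RC)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.quotas.values()):
            raise ValueError("quota counts must be >= 0")
        if self.core_length <= 0:
            raise ValueError("core_length must be positive")
        if self.flank_total % 2 != 0:
            raise ValueError("flank_total must be even (split across two sides)")

    @property
    def library_size(self) -> int:
        return sum(self.quotas.values())

    @property
    def oligo_length(self) -> int:
        return self.core_length + self.flank_total


@dataclass(frozen=True)
class LibraryElement:
    """One designed library member: core sequence plus cloning flanks."""

    id: str
    category_label: str
    core_sequence: str
    oligo_sequence: str = ""
    origin: GenomicInterval | None = None


class LibrarySizeError(ValueError):
    """Requested more elements than a category can supply."""


class GenerationError(RuntimeError):
    """Rejection sampling failed to produce an admissible sequence."""


# ---------------------------------------------------------------------------
# selection


def rank_select(
    candidates: Sequence[CandidateElement],
    category: str,
    k: int,
    from_top: bool = True,
) -> list[CandidateElement]:
    """Select the ``k`` highest- (or lowest-) scoring candidates of a category.

    Ordering is by affinity score, descending when ``from_top`` else
    ascending, with ties broken by lexicographic id so the selection is
    deterministic regardless of input order.
    """
    pool = [c for c in candidates if c.category == category]
    if k > len(pool):
        raise LibrarySizeError(
            f"requested {k} elements of category {category!r} "
            f"but only {len(pool)} are available"
        )
    if from_top:
        pool.sort(key=lambda c: (-c.affinity_score, c.id))
    else:
        pool.sort(key=lambda c: (c.affinity_score, c.id))
    return pool[:k]


def lad_proximity_filter(
    elements: Sequence[CandidateElement],
    lads: Sequence[GenomicInterval],
    max_dist: int = 5000,
) -> tuple[list[CandidateElement], list[CandidateElement]]:
    """Partition elements by distance to the nearest LAD boundary.

    An element is *near* iff the gap between its interval and any LAD start
    or end coordinate on the same chromosome is strictly below ``max_dist``.
    Returns ``(near, far)``; elements on chromosomes without any LAD are far.
    """
    boundaries: dict[str, list[int]] = {}
    for lad in lads:
        boundaries.setdefault(lad.chrom, []).extend((lad.start, lad.end))

    near: list[CandidateElement] = []
    far: list[CandidateElement] = []
    for el in elements:
        if el.interval is None:
            raise ValueError(f"element {el.id} has no genomic interval")
        pts = boundaries.get(el.interval.chrom, [])
        if pts and min(el.interval.distance_to_point(p) for p in pts) < max_dist:
            near.append(el)
        else:
            far.append(el)
    return near, far


def contains_excluded_site(seq: str, excluded_sites: Iterable[str]) -> bool:
    """True if any excluded motif occurs in ``seq`` on the given strand.

    Callers wanting both-strand exclusion pass both the motif and its
    reverse complement (the default Esp3I site list already does).
    """
    u = seq.upper()
    return any(site in u for site in excluded_sites)


def generate_random_elements(
    n: int,
    length: int = 250,
    excluded_sites: Iterable[str] = (ESP3I_SITE, ESP3I_SITE_RC),
    seed: int = 0,
    max_attempts: int = 10_000,
    id_prefix: str = "RND",
) -> list[CandidateElement]:
    """Generate ``n`` uniform random DNA sequences free of excluded sites.

    Sequences are rejection-sampled: a draw containing any excluded site is
    discarded and redrawn, up to ``max_attempts`` per sequence.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    sites = tuple(excluded_sites)
    bases = np.array(list("ACGT"))
    out: list[CandidateElement] = []
    for i in range(n):
        for _ in range(max_attempts):
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            if not contains_excluded_site(seq, sites):
                out.append(
                    CandidateElement(
                        id=f"{id_prefix}{i + 1:03d}",
                        category="RANDOM",
                        affinity_score=0.0,
                        sequence=seq,
                    )
                )
                break
        else:
            raise GenerationError(
                f"could not generate an admissible {length} bp sequence in "
                f"{max_attempts} attempts; exclusion rules too restrictive"
            )
    return out


# ---------------------------------------------------------------------------
# assembly


def adjust_length(element: CandidateElement, core_length: int = 250) -> CandidateElement:
    """Trim a candidate to the centered ``core_length`` window.

    When the excess is odd the extra base is kept on the 5' side (i.e. one
    base less is trimmed from the 5' end than from the 3' end). Candidates
    shorter than ``core_length`` are rejected.
    """
    excess = len(element.sequence) - core_length
    if excess < 0:
        raise ValueError(
            f"element {element.id}: sequence length {len(element.sequence)} "
            f"is below core length {core_length}"
        )
    left = excess // 2
    trimmed = element.sequence[left : left + core_length]
    new_interval = element.interval
    if new_interval is not None and excess > 0:
        new_interval = GenomicInterval(
            new_interval.chrom,
            new_interval.start + left,
            new_interval.start + left + core_length,
            new_interval.strand,
        )
    return replace(element, sequence=trimmed, interval=new_interval)


def assemble_oligo(
    element: LibraryElement, left_flank: str, right_flank: str, flank_total: int = 50
) -> LibraryElement:
    """Attach cloning flanks around the core sequence."""
    if len(left_flank) + len(right_flank) != flank_total:
        raise ValueError(
            f"flank lengths {len(left_flank)} + {len(right_flank)} do not sum "
            f"to flank_total {flank_total}"
        )
    oligo = left_flank + element.core_sequence + right_flank
    return replace(element, oligo_sequence=oligo)


def default_flanks(flank_total: int = 50, seed: int = 20) -> tuple[str, str]:
    """Esp3I-free cloning flanks, split evenly across the two sides."""
    half = flank_total // 2
    flanks = generate_random_elements(2, max(half, 1), seed=seed, id_prefix="FLK")
    return flanks[0].sequence[:half], flanks[1].sequence[: flank_total - half]


def assemble_library(
    ctcf_candidates: Sequence[CandidateElement],
    mir_candidates: Sequence[CandidateElement],
    lads: Sequence[GenomicInterval],
    spec: LibrarySpec | None = None,
    left_flank: str | None = None,
    right_flank: str | None = None,
    seed: int = 0,
) -> list[LibraryElement]:
    """Assemble the full screening library under the composition rules.

    CTCF candidates are rank-selected from the top ("CTCF-High" quota) and
    bottom ("CTCF-Low") of the affinity ranking. MIR candidates are split by
    LAD-boundary proximity: every near-boundary MIR is eligible for the
    "MIR-LAD_bound" quota (selected by id for determinism) and the
    "MIR-random" quota is sampled from the remaining far MIRs. Random
    control sequences are generated fresh. All cores are centered-trimmed
    to ``spec.core_length``; candidates that are too short, or whose oligo
    would carry an excluded site, are dropped with a warning and replaced by
    the next eligible candidate where the quota allows.
    """
    spec = spec or LibrarySpec()
    if left_flank is None or right_flank is None:
        lf, rf = default_flanks(spec.flank_total, seed=seed + 1)
        left_flank = left_flank if left_flank is not None else lf
        right_flank = right_flank if right_flank is not None else rf

    rng = np.random.default_rng(seed)
    library: list[LibraryElement] = []

    def admit(pool: Sequence[CandidateElement], label: str, quota: int) -> None:
        taken = 0
        for cand in pool:
            if taken == quota:
                break
            if len(cand.sequence) < spec.core_length:
                logger.warning(
                    "dropping %s (%s): length %d < core %d",
                    cand.id, label, len(cand.sequence), spec.core_length,
                )
                continue
            core = adjust_length(cand, spec.core_length)
            el = assemble_oligo(
                LibraryElement(
                    id=cand.id,
                    category_label=label,
                    core_sequence=core.sequence,
                    origin=core.interval,
                ),
                left_flank,
                right_flank,
                spec.flank_total,
            )
            if contains_excluded_site(el.oligo_sequence, spec.excluded_sites):
                logger.warning("dropping %s (%s): excluded site in oligo", cand.id, label)
                continue
            library.append(el)
            taken += 1
        if taken < quota:
            raise LibrarySizeError(
                f"category {label!r}: only {taken} admissible elements for quota {quota}"
            )

    quotas = dict(spec.quotas)
    n_high = quotas.get("CTCF-High", 0)
    n_low = quotas.get("CTCF-Low", 0)
    if n_high:
        # over-select so excluded-site/short drops can be back-filled
        top = rank_select(ctcf_candidates, "CTCF", len(
            [c for c in ctcf_candidates if c.category == "CTCF"]), from_top=True)
        admit(top, "CTCF-High", n_high)
    if n_low:
        taken_ids = {el.id for el in library}
        bottom = [
            c
            for c in rank_select(
                ctcf_candidates,
                "CTCF",
                len([c for c in ctcf_candidates if c.category == "CTCF"]),
                from_top=False,
            )
            if c.id not in taken_ids
        ]
        admit(bottom, "CTCF-Low", n_low)

    n_bound = quotas.get("MIR-LAD_bound", 0)
    n_mir_rand = quotas.get("MIR-random", 0)
    if n_bound or n_mir_rand:
        near, far = lad_proximity_filter(mir_candidates, lads, spec.lad_proximity_bp)
        near = sorted(near, key=lambda c: c.id)
        admit(near, "MIR-LAD_bound", n_bound)
        far = sorted(far, key=lambda c: c.id)
        order = rng.permutation(len(far))
        admit([far[i] for i in order], "MIR-random", n_mir_rand)

    n_random = quotas.get("RANDOM", 0)
    if n_random:
        # generate a surplus; exclusion inside the random cores is already
        # guaranteed, flank junctions are re-checked by admit()
        randoms = generate_random_elements(
            n_random + 10,
            spec.core_length,
            spec.excluded_sites,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        admit(randoms, "RANDOM", n_random)

    return library


# ---------------------------------------------------------------------------
# coverage arithmetic


def fold_coverage(cfu: float, library_size: int) -> float:
    """Fold coverage of a library by ``cfu`` colony-forming units."""
    if library_size == 0:
        raise ZeroDivisionError("library_size must be positive")
    return cfu / library_size


def expected_clones(
    n_transfections: int, cells_per_transfection: int, integration_efficiency: float
) -> int:
    """Expected stable clone count from pooled transfections.

    The product of transfection count, cells per transfection and absolute
    integration efficiency, rounded to the nearest integer.
    """
    if min(n_transfections, cells_per_transfection) < 0:
        raise ValueError("counts must be >= 0")
    if not 0.0 <= integration_efficiency <= 1.0:
        raise ValueError("integration_efficiency must be in [0, 1]")
    return round(n_transfections * cells_per_transfection * integration_efficiency)


# ---------------------------------------------------------------------------
# I/O


def read_candidate_table(path: str | Path) -> list[CandidateElement]:
    """Read a candidate TSV: id, category, score, chrom, start, end, strand, sequence.

    Coordinate columns may be empty (e.g. random sequences without a genomic
    origin).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": "string"})
    out = []
    for row in df.itertuples(index=False):
        interval = None
        if pd.notna(row.chrom) and pd.notna(row.start) and pd.notna(row.end):
            strand = row.strand if pd.notna(row.strand) else "."
            interval = GenomicInterval(str(row.chrom), int(row.start), int(row.end), strand)
        out.append(
            CandidateElement(
                id=str(row.id),
                category=str(row.category),
                affinity_score=float(row.score),
                sequence=str(row.sequence),
                interval=interval,
            )
        )
    return out


def write_candidate_table(candidates: Sequence[CandidateElement], path: str | Path) -> None:
    rows = []
    for c in candidates:
        iv = c.interval
        rows.append(
            {
                "id": c.id,
                "category": c.category,
                "score": c.affinity_score,
                "chrom": iv.chrom if iv else None,
                "start": iv.start if iv else None,
                "end": iv.end if iv else None,
                "strand": iv.strand if iv else None,
                "sequence": c.sequence,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_library_fasta(
    library: Sequence[LibraryElement], path: str | Path, oligo: bool = False
) -> None:
    """Write core (default) or full-oligo sequences as FASTA."""
    records = [
        SeqRecord(
            Seq(el.oligo_sequence if oligo else el.core_sequence),
            id=el.id,
            description=el.category_label,
        )
        for el in library
    ]
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(path: str | Path, oligo: bool = True) -> list[LibraryElement]:
    """Read library sequences back from FASTA (category label from description)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        label = rec.description.split(maxsplit=1)[1] if " " in rec.description else ""
        out.append(
            LibraryElement(
                id=rec.id,
                category_label=label,
                core_sequence="" if oligo else seq,
                oligo_sequence=seq if oligo else "",
            )
        )
    return out


def write_manifest(library: Sequence[LibraryElement], path: str | Path) -> None:
    rows = []
    for el in library:
        iv = el.origin
        rows.append(
            {
                "id": el.id,
                "category_label": el.category_label,
                "chrom": iv.chrom if iv else None,
                "start": iv.start if iv else None,
                "end": iv.end if iv else None,
                "core_length": len(el.core_sequence),
                "oligo_length": len(el.oligo_sequence),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
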