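"""Synthetic sort-seq screen generator.

Emulates a pooled barrier-element screen read out by FACS sorting and
amplicon sequencing: a reporter integrated at a lamina-associated domain
(LAD) silences over time unless a flanking element protects it. Each
library element is given a latent *barrier strength* ``b`` in [0, 1] that
controls two superposed silencing processes observed in such reporters:

* all-or-none shutdown — each cell switches OFF with per-day hazard
  ``lambda = lambda_max * (1 - b)``, joining the autofluorescent
  (EGFP-negative) population;
* graded decay — cells still ON lose intensity exponentially at rate
  ``k = k_max * (1 - b)`` per day, producing the dimming EGFP-positive
  population.

Cells are sorted into intensity gates, and per-gate element abundances are
turned into sequencing reads with PCR jitter, substitution/indel errors and
synthetic qualities. A ground-truth manifest records the latent parameters
and realized gate frequencies so downstream inference can be scored.

The generator also emits the plasmid-library (pDNA) baseline: element
weights drawn once per pool (gamma-distributed, optionally with dropout)
and sampled twice as technical replicates, mirroring how forward and
reverse reads of a single pDNA sample are treated as replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import (
    CandidateElement,
    GenomicInterval,
    LibraryElement,
    reverse_complement,
)

GATE_LABELS = ("Negative", "Low", "Medium", "High")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# candidate resources (inputs to library design)

#: CTCF core consensus used to plant binding sites in synthetic candidates.
CTCF_CONSENSUS = "CCACCAGGTGGCGC"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant(seq: str, motif: str, pos: int) -> str:
    return seq[:pos] + motif + seq[pos + len(motif):]


def generate_candidate_resources(
    n_ctcf: int = 600,
    n_mir: int = 600,
    n_mir_near_lad: int = 40,
    seed: int = 0,
    candidate_length_range: tuple[int, int] = (250, 320),
) -> dict:
    """Synthesize the upstream inputs of library design.

    Produces scored CTCF-binding candidates (a consensus site planted at the
    candidate center, degraded in proportion to the affinity rank so
    high-scoring candidates carry near-consensus sites), MIR candidates with
    genomic intervals (of which ``n_mir_near_lad`` sit within 5 kb of a LAD
    boundary) enriched for E-box (CANNTG) and G-tract (GGGG) motifs, and
    the LAD interval list itself.

    Returns ``{"ctcf": [...], "mir": [...], "lads": [...]}``.
    """
    rng = np.random.default_rng(seed)
    lads = []
    chrom_cursor: dict[str, int] = {}
    for i in range(20):
        chrom = f"chr{i % 5 + 1}"
        start = chrom_cursor.get(chrom, 10_000_000) + int(rng.integers(200_000, 2_000_000))
        length = int(rng.integers(100_000, 1_000_000))
        lads.append(GenomicInterval(chrom, start, start + length))
        chrom_cursor[chrom] = start + length

    ctcf = []
    for i in range(n_ctcf):
        length = int(rng.integers(*candidate_length_range))
        seq = _random_seq(rng, length)
        # degrade the planted consensus as the score drops
        score = float(n_ctcf - i) + float(rng.random())
        n_mut = int(round((i / max(n_ctcf - 1, 1)) * 6))
        motif = list(CTCF_CONSENSUS)
        for p in rng.choice(len(motif), size=n_mut, replace=False):
            motif[p] = str(rng.choice([b for b in "ACGT" if b != motif[p]]))
        seq = _plant(seq, "".join(motif), (length - len(motif)) // 2)
        ctcf.append(
            CandidateElement(id=f"CTCF{i + 1:04d}", category="CTCF",
                             affinity_score=score, sequence=seq)
        )

    mir = []
    for i in range(n_mir):
        length = int(rng.integers(*candidate_length_range))
        seq = _random_seq(rng, length)
        for _ in range(int(rng.poisson(3))):
            pos = int(rng.integers(0, length - 6))
            seq = _plant(seq, "CA" + _random_seq(rng, 2) + "TG", pos)
        for _ in range(int(rng.poisson(3))):
            pos = int(rng.integers(0, length - 4))
            seq = _plant(seq, "GGGG", pos)
        near = i < n_mir_near_lad
        lad = lads[int(rng.integers(len(lads)))]
        if near:
            boundary = lad.start if rng.random() < 0.5 else lad.end
            start = boundary + int(rng.integers(-4000, 4000))
        else:
            start = lad.start + int(rng.integers(20_000, max(len(lad) - 20_000, 21_000)))
        start = max(start, 0)
        mir.append(
            CandidateElement(
                id=f"MIR{i + 1:04d}",
                category="MIR",
                affinity_score=0.0,
                sequence=seq,
                interval=GenomicInterval(lad.chrom, start, start + length),
            )
        )
    return {"ctcf": ctcf, "mir": mir, "lads": lads}


@dataclass(frozen=True)
class ElementPhenotype:
    """Latent silencing phenotype of one library element."""

    element_id: str
    barrier_strength: float  # b in [0, 1]; 1 = full protection
    silencing_hazard: float  # lambda, per day
    decay_rate: float  # k, per day
    baseline_intensity: float  # I0, arbitrary fluorescence units

    def __post_init__(self) -> None:
        if not 0.0 <= self.barrier_strength <= 1.0:
            raise ValueError("barrier_strength must be in [0, 1]")
        if self.silencing_hazard < 0 or self.decay_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")

    def off_probability(self, day: float) -> float:
        """Closed-form probability a cell has switched OFF by ``day``."""
        return 1.0 - float(np.exp(-self.silencing_hazard * day))


@dataclass(frozen=True)
class SortGate:
    label: str
    lower: float
    upper: float  # np.inf for the top gate

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError(f"gate {self.label}: upper must exceed lower")


@dataclass(frozen=True)
class ScreenSample:
    """Descriptor of one sequencing sample of the screen."""

    population_label: str  # gate label or "pDNA"
    day: int
    replicate: int
    read_count_target: int = 100_000

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.population_label}_d{self.day}_r{self.replicate}"


@dataclass(frozen=True)
class SequencingConfig:
    """Amplicon sequencing emulation parameters (MiSeq-like 2x250)."""

    read_length: int = 250
    substitution_rate: float = 0.001
    insertion_rate: float = 0.0001
    deletion_rate: float = 0.0001
    linker: str = "ACACGACGCTCTTCCGATCT"
    mean_phred: int = 36
    phred_jitter: int = 2
    pcr_noise_sigma: float = 0.05  # ln-scale lognormal amplification jitter
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


# ---------------------------------------------------------------------------
# phenotype scenarios

#: All-or-none hazard of the unprotected reporter: ~36% of cells have
#: discretely switched OFF by day 15. Silencing is modelled as mostly
#: graded: the remaining ON cells of an unprotected reporter decay below
#: the autofluorescence boundary (see DEFAULT_K_MAX), so a bare reporter
#: still reads as essentially fully EGFP-negative at two weeks while a
#: distinct dim EGFP-positive population emerges at intermediate times.
DEFAULT_LAMBDA_MAX = 0.03
#: Intensity decay of unprotected ON cells; at day 15 an element with
#: partial protection (b ~ 0.55-0.85) has its ON cells spread across the
#: Low/Medium gates, while only well-protected elements (b > ~0.85) remain
#: above the High gate.
DEFAULT_K_MAX = 0.6
DEFAULT_I0 = 10_000.0
#: ln-scale sigma of multiplicative cell-to-cell expression noise.
DEFAULT_CELL_NOISE_SIGMA = 0.3
#: Autofluorescence (OFF-cell) lognormal: median and ln-scale sigma.
DEFAULT_AUTOFLUOR_MEDIAN = 30.0
DEFAULT_AUTOFLUOR_SIGMA = 0.4


def phenotype_from_strength(
    element_id: str,
    b: float,
    lambda_max: float = DEFAULT_LAMBDA_MAX,
    k_max: float = DEFAULT_K_MAX,
    baseline_intensity: float = DEFAULT_I0,
) -> ElementPhenotype:
    """Map a barrier strength to the two silencing rates."""
    return ElementPhenotype(
        element_id=element_id,
        barrier_strength=b,
        silencing_hazard=lambda_max * (1.0 - b),
        decay_rate=k_max * (1.0 - b),
        baseline_intensity=baseline_intensity,
    )


def generate_phenotypes(
    element_ids: Sequence[str],
    n_strong: int = 50,
    n_null: int = 50,
    seed: int = 0,
    strong_b_range: tuple[float, float] = (0.9, 1.0),
    background_b_range: tuple[float, float] = (0.55, 0.85),
    background_beta: tuple[float, float] = (3.0, 2.0),
    lambda_max: float = DEFAULT_LAMBDA_MAX,
    k_max: float = DEFAULT_K_MAX,
    baseline_intensity: float = DEFAULT_I0,
    strong_ids: Sequence[str] | None = None,
    null_ids: Sequence[str] | None = None,
) -> list[ElementPhenotype]:
    """Assign barrier strengths across a library.

    ``n_strong`` ids become strong barriers (b uniform in
    ``strong_b_range``) and ``n_null`` become inert controls (b = 0);
    the designation is a seeded shuffle unless explicit ``strong_ids`` /
    ``null_ids`` are given (e.g. making the library's random-sequence
    controls the nulls). The remainder — the bulk of the library, which
    was designed from candidates predicted to be at least partially
    functional — draw b from a Beta distribution rescaled into
    ``background_b_range``: partial protection, below the strong range,
    so their day-15 ON-cell intensities populate the intermediate sorter
    gates.
    """
    if n_strong + n_null > len(element_ids):
        raise ValueError("n_strong + n_null exceeds library size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(element_ids))
    lo, hi = background_b_range
    b = lo + (hi - lo) * rng.beta(*background_beta, size=len(element_ids))
    index_of = {eid: i for i, eid in enumerate(element_ids)}
    if strong_ids is not None:
        strong_idx = np.array([index_of[i] for i in strong_ids])
        n_strong = strong_idx.size
    else:
        strong_idx = order[:n_strong]
    b[strong_idx] = rng.uniform(*strong_b_range, size=n_strong)
    if null_ids is not None:
        null_idx = np.array([index_of[i] for i in null_ids])
        if np.intersect1d(strong_idx, null_idx).size:
            raise ValueError("strong_ids and null_ids overlap")
    else:
        null_idx = np.array(
            [i for i in order if i not in set(strong_idx.tolist())][:n_null]
        )
    b[null_idx] = 0.0
    return [
        phenotype_from_strength(eid, float(bi), lambda_max, k_max, baseline_intensity)
        for eid, bi in zip(element_ids, b)
    ]


def default_gates(
    autofluor_boundary: float = 150.0, top_intensity: float = DEFAULT_I0
) -> list[SortGate]:
    """Negative gate up to the autofluorescence boundary, then log-spaced
    tertiles of the positive range up to ``top_intensity``; High is open."""
    r = (top_intensity / autofluor_boundary) ** (1.0 / 3.0)
    b1 = autofluor_boundary
    return [
        SortGate("Negative", 0.0, b1),
        SortGate("Low", b1, b1 * r),
        SortGate("Medium", b1 * r, b1 * r * r),
        SortGate("High", b1 * r * r, np.inf),
    ]


def validate_gates(gates: Sequence[SortGate]) -> None:
    """Gates must tile [0, inf) contiguously in order."""
    if not gates:
        raise ValueError("no gates supplied")
    if gates[0].lower != 0.0:
        raise ValueError("first gate must start at 0")
    for a, b in zip(gates, gates[1:]):
        if b.lower != a.upper:
            raise ValueError(f"gates {a.label}/{b.label} overlap or leave a gap")
    if not np.isinf(gates[-1].upper):
        raise ValueError("last gate must be open-ended")


# ---------------------------------------------------------------------------
# cell-level simulation


def simulate_population(
    phenotypes: Sequence[ElementPhenotype],
    cells_per_element: int,
    day: float,
    seed: int = 0,
    cell_noise_sigma: float = DEFAULT_CELL_NOISE_SIGMA,
    autofluor_median: float = DEFAULT_AUTOFLUOR_MEDIAN,
    autofluor_sigma: float = DEFAULT_AUTOFLUOR_SIGMA,
    element_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate per-cell reporter intensities at a given day.

    Each cell is OFF with probability ``1 - exp(-lambda * day)`` (intensity
    drawn from the autofluorescence lognormal); otherwise ON at
    ``I0 * exp(-k * day)`` times multiplicative lognormal noise. With
    ``element_weights``, cell counts per element are scaled (clone-number
    imbalance inherited from the plasmid pool).

    Returns a DataFrame with columns ``element_id``, ``intensity``, ``on``.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    if cells_per_element <= 0:
        raise ValueError("cells_per_element must be positive")
    rng = np.random.default_rng(seed)

    n_el = len(phenotypes)
    if element_weights is None:
        n_cells = np.full(n_el, cells_per_element, dtype=np.int64)
    else:
        w = np.asarray(element_weights, dtype=float)
        if w.shape != (n_el,):
            raise ValueError("element_weights must match phenotype count")
        scale = w / w.mean() if w.mean() > 0 else w
        n_cells = np.round(scale * cells_per_element).astype(np.int64)

    ids = np.repeat([p.element_id for p in phenotypes], n_cells)
    lam = np.repeat([p.silencing_hazard for p in phenotypes], n_cells)
    k = np.repeat([p.decay_rate for p in phenotypes], n_cells)
    i0 = np.repeat([p.baseline_intensity for p in phenotypes], n_cells)

    total = ids.shape[0]
    off = rng.random(total) < (1.0 - np.exp(-lam * day))
    intensity = np.empty(total)
    n_off = int(off.sum())
    intensity[off] = autofluor_median * np.exp(
        rng.normal(0.0, autofluor_sigma, size=n_off)
    )
    on = ~off
    intensity[on] = (
        i0[on]
        * np.exp(-k[on] * day)
        * np.exp(rng.normal(0.0, cell_noise_sigma, size=total - n_off))
    )
    return pd.DataFrame({"element_id": ids, "intensity": intensity, "on": on})


def apply_gates(
    cells: pd.DataFrame, gates: Sequence[SortGate]
) -> dict[str, pd.DataFrame]:
    """Assign each cell to exactly one gate by intensity ([lower, upper))."""
    validate_gates(gates)
    edges = [g.lower for g in gates] + [np.inf]
    idx = np.searchsorted(edges, cells["intensity"].to_numpy(), side="right") - 1
    return {
        g.label: cells.iloc[np.flatnonzero(idx == i)] for i, g in enumerate(gates)
    }


def gate_count_matrix(
    gated: Mapping[str, pd.DataFrame], element_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-element cell counts per gate (elements x gates, 0-filled)."""
    cols = {}
    for label, df in gated.items():
        cols[label] = df["element_id"].value_counts().reindex(element_ids, fill_value=0)
    out = pd.DataFrame(cols, index=pd.Index(element_ids, name="element_id"))
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# sequencing


class SimulationError(RuntimeError):
    pass


def _sample_read_counts(
    weights: np.ndarray, n_reads: int, pcr_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read counts with per-element lognormal PCR jitter."""
    w = np.asarray(weights, dtype=float).copy()
    if w.sum() <= 0:
        raise SimulationError("empty population: no template to sequence")
    if pcr_sigma > 0:
        w *= np.exp(rng.normal(0.0, pcr_sigma, size=w.shape))
    return rng.multinomial(n_reads, w / w.sum())


def _mutate(seq: str, cfg: SequencingConfig, rng: np.random.Generator) -> str:
    """Apply substitution/insertion/deletion errors to one read sequence."""
    if cfg.substitution_rate == 0 and cfg.insertion_rate == 0 and cfg.deletion_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.shape[0]
    sub = rng.random(n) < cfg.substitution_rate
    if sub.any():
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.flatnonzero(sub):
            choices = codes[codes != arr[i]]
            arr[i] = rng.choice(choices)
    if cfg.insertion_rate > 0 or cfg.deletion_rate > 0:
        ins = rng.random(n) < cfg.insertion_rate
        dele = rng.random(n) < cfg.deletion_rate
        if ins.any() or dele.any():
            out = bytearray()
            codes = b"ACGT"
            for i in range(n):
                if ins[i]:
                    out.append(codes[rng.integers(0, 4)])
                if not dele[i]:
                    out.append(arr[i])
            return out.decode("ascii")
    return arr.tobytes().decode("ascii")


def _quality_string(length: int, cfg: SequencingConfig, rng: np.random.Generator) -> str:
    q = np.clip(
        np.round(rng.normal(cfg.mean_phred, cfg.phred_jitter, size=length)), 2, 40
    ).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _emit_reads(
    counts: np.ndarray,
    library: Sequence[LibraryElement],
    sample: ScreenSample,
    cfg: SequencingConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Build (read_id, sequence, quality) triples for given per-element counts.

    Each read is the linker followed by a contiguous window of the element
    oligo (either strand), with sequencing errors applied to the insert.
    The true element id is recorded in the read name after a ``#`` so
    simulations can be scored; the mapper never parses it.
    """
    reads: list[tuple[str, str, str]] = []
    serial = 0
    for el, c in zip(library, counts):
        if c == 0:
            continue
        oligo = el.oligo_sequence or el.core_sequence
        max_start = max(len(oligo) - cfg.read_length, 0)
        starts = rng.integers(0, max_start + 1, size=c)
        strands = rng.random(c) < 0.5
        for s, minus in zip(starts, strands):
            insert = oligo[s : s + cfg.read_length]
            if minus:
                insert = reverse_complement(insert)
            insert = _mutate(insert, cfg, rng)
            seq = cfg.linker + insert
            serial += 1
            rid = f"{sample.name}:{serial}#{el.id}"
            reads.append((rid, seq, _quality_string(len(seq), cfg, rng)))
    return reads


def reads_from_population(
    gated_cells: pd.DataFrame,
    library: Sequence[LibraryElement],
    sample: ScreenSample,
    cfg: SequencingConfig,
    seed: int | None = None,
) -> list[tuple[str, str, str]]:
    """Sequence one sorted population: multinomial element sampling with PCR
    jitter, then error-bearing reads. Raises SimulationError on empty gates."""
    if sample.read_count_target <= 0:
        raise ValueError("read_count_target must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = [el.id for el in library]
    freq = (
        gated_cells["element_id"].value_counts().reindex(ids, fill_value=0).to_numpy()
    )
    counts = _sample_read_counts(
        freq.astype(float), sample.read_count_target, cfg.pcr_noise_sigma, rng
    )
    return _emit_reads(counts, library, sample, cfg, rng)


def pdna_weights(
    n_elements: int,
    dropout_fraction: float = 0.015,
    dispersion: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Element weights of the plasmid pool.

    Weights are gamma with shape ``1 / dispersion`` (squared coefficient of
    variation ~= dispersion); a ``dropout_fraction`` of elements get zero
    weight, emulating members lost during synthesis/cloning.
    """
    if not 0.0 <= dropout_fraction < 1.0:
        raise ValueError("dropout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if dispersion <= 0:
        w = np.ones(n_elements)
    else:
        shape = 1.0 / dispersion
        w = rng.gamma(shape, 1.0 / shape, size=n_elements)
    n_drop = int(round(dropout_fraction * n_elements))
    if n_drop:
        w[rng.choice(n_elements, size=n_drop, replace=False)] = 0.0
    return w


def simulate_pdna(
    library: Sequence[LibraryElement],
    cfg: SequencingConfig,
    dropout_fraction: float = 0.015,
    dispersion: float = 0.01,
    read_count_target: int = 100_000,
    day: int = 0,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> tuple[list[list[tuple[str, str, str]]], np.ndarray, pd.DataFrame]:
    """Sequence the plasmid pool as two technical replicates.

    Returns (reads per replicate, pool weights, counts DataFrame with one
    column per technical replicate).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if weights is None:
        weights = pdna_weights(
            len(library), dropout_fraction, dispersion, seed=int(rng.integers(2**31))
        )
    ids = [el.id for el in library]
    all_reads = []
    counts = {}
    for rep in (1, 2):
        sample = ScreenSample("pDNA", day, rep, read_count_target)
        c = _sample_read_counts(weights, read_count_target, cfg.pcr_noise_sigma, rng)
        counts[sample.name] = c
        all_reads.append(_emit_reads(c, library, sample, cfg, rng))
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="element_id"))
    return all_reads, weights, counts_df


# ---------------------------------------------------------------------------
# whole-screen orchestration


@dataclass
class ScreenResult:
    """Counts, sample sheet and ground truth of one simulated screen."""

    counts: pd.DataFrame  # elements x samples (read counts)
    sample_sheet: pd.DataFrame  # sample, population, day, replicate, role
    ground_truth: pd.DataFrame
    reads: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


def simulate_screen(
    library: Sequence[LibraryElement],
    phenotypes: Sequence[ElementPhenotype],
    days: Sequence[int] = (15,),
    replicates: int = 2,
    cells_per_element: int = 1000,
    reads_per_sample: int = 100_000,
    gates: Sequence[SortGate] | None = None,
    cfg: SequencingConfig | None = None,
    dropout_fraction: float = 0.015,
    dispersion: float = 0.01,
    seed: int = 0,
    emit_fastq: bool = False,
) -> ScreenResult:
    """Run the full synthetic screen.

    For each day and biological replicate an independent cell population is
    simulated (clone numbers inherit the plasmid-pool weights), sorted into
    gates, and sequenced to ``reads_per_sample`` reads per gate. The pDNA
    pool is sequenced as two technical replicates. With ``emit_fastq`` the
    per-sample reads are kept; otherwise only counts are stored (the counts
    are always derived from the same multinomial draw that would have
    produced the reads).
    """
    gates = list(gates) if gates is not None else default_gates()
    validate_gates(gates)
    cfg = cfg or SequencingConfig(read_length=250)
    rng = np.random.default_rng(seed)
    ids = [el.id for el in library]
    id_to_pheno = {p.element_id: p for p in phenotypes}
    ordered_phenos = [id_to_pheno[i] for i in ids]

    weights = pdna_weights(
        len(library), dropout_fraction, dispersion, seed=int(rng.integers(2**31))
    )

    counts: dict[str, np.ndarray] = {}
    sheet_rows = []
    reads: dict[str, list] = {}
    gate_freq_sum = pd.DataFrame(0.0, index=pd.Index(ids, name="element_id"),
                                 columns=[g.label for g in gates])
    n_pops = 0

    for day in days:
        for rep in range(1, replicates + 1):
            pop = simulate_population(
                ordered_phenos,
                cells_per_element,
                day,
                seed=int(rng.integers(2**31)),
                element_weights=weights,
            )
            gated = apply_gates(pop, gates)
            gmat = gate_count_matrix(gated, ids)
            totals = gmat.sum(axis=1).replace(0, 1)
            gate_freq_sum += gmat.div(totals, axis=0)
            n_pops += 1
            for gate in gates:
                sample = ScreenSample(gate.label, day, rep, reads_per_sample)
                c = _sample_read_counts(
                    gmat[gate.label].to_numpy().astype(float),
                    reads_per_sample,
                    cfg.pcr_noise_sigma,
                    rng,
                )
                counts[sample.name] = c
                sheet_rows.append(
                    {
                        "sample": sample.name,
                        "population": gate.label,
                        "day": day,
                        "replicate": rep,
                        "role": "sorted",
                    }
                )
                if emit_fastq:
                    reads[sample.name] = _emit_reads(c, library, sample, cfg, rng)

    pdna_reads, weights, pdna_counts = simulate_pdna(
        library,
        cfg,
        read_count_target=reads_per_sample,
        seed=int(rng.integers(2**31)),
        weights=weights,
    )
    for i, col in enumerate(pdna_counts.columns):
        counts[col] = pdna_counts[col].to_numpy()
        sheet_rows.append(
            {
                "sample": col,
                "population": "pDNA",
                "day": 0,
                "replicate": i + 1,
                "role": "pdna",
            }
        )
        if emit_fastq:
            reads[col] = pdna_reads[i]

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="element_id"))
    truth = ground_truth_frame(ordered_phenos, gate_freq_sum / max(n_pops, 1), weights)
    return ScreenResult(
        counts=counts_df,
        sample_sheet=pd.DataFrame(sheet_rows),
        ground_truth=truth,
        reads=reads,
    )


def ground_truth_frame(
    phenotypes: Sequence[ElementPhenotype],
    gate_frequencies: pd.DataFrame | None = None,
    pool_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate latent parameters (and realized gate frequencies if given)."""
    df = pd.DataFrame(
        {
            "element_id": [p.element_id for p in phenotypes],
            "barrier_strength": [p.barrier_strength for p in phenotypes],
            "silencing_hazard": [p.silencing_hazard for p in phenotypes],
            "decay_rate": [p.decay_rate for p in phenotypes],
            "baseline_intensity": [p.baseline_intensity for p in phenotypes],
        }
    ).set_index("element_id")
    if pool_weights is not None:
        df["pool_weight"] = np.asarray(pool_weights, dtype=float)
    if gate_frequencies is not None:
        df = df.join(gate_frequencies.add_prefix("freq_"))
    return df


def write_ground_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def true_element_of_read(read_id: str) -> str:
    """Recover the ground-truth element id tagged in a simulated read name."""
    return read_id.rsplit("#", 1)[1]
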