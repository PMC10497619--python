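"""Sequence features of library elements: GC content, degenerate motif
counts and information-content logos.

Barrier activity has been linked to binding of boundary-associated factors;
the screen compares two degenerate motifs across enrichment-defined element
sets: the USF E-box ``CANNTG`` and the VEZF1 G-tract ``GGGG``. Motif
occurrences are counted at every (overlapping) start position matching the
IUPAC pattern; overlap counting matters for run-like patterns (``GGGGG``
contains two ``GGGG`` starts). By default patterns are counted on the given
strand only, with an opt-in for both strands that suppresses double
counting of reverse-complement-palindromic patterns such as ``CANNTG``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import t_test_two_tailed

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

USF_MOTIF_PATTERN = "CANNTG"
VEZF1_MOTIF_PATTERN = "GGGG"


@dataclass(frozen=True)
class DegenerateMotif:
    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC symbols in pattern: {bad}")

    def reverse_complement(self) -> "DegenerateMotif":
        return DegenerateMotif(
            self.pattern.upper().translate(_COMPLEMENT)[::-1], self.name
        )

    def is_palindromic(self) -> bool:
        """True if the pattern equals its own reverse complement (e.g. CANNTG)."""
        return self.pattern.upper() == self.reverse_complement().pattern


USF_MOTIF = DegenerateMotif(USF_MOTIF_PATTERN, "USF")
VEZF1_MOTIF = DegenerateMotif(VEZF1_MOTIF_PATTERN, "VEZF1")


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern.upper():
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_motif(
    sequence: str, motif: DegenerateMotif, both_strands: bool = False
) -> int:
    """Number of overlapping start positions matching the IUPAC pattern.

    With ``both_strands`` the reverse-complement pattern is also scanned on
    the same sequence, except for palindromic patterns where the two scans
    are identical and would double-count every site.
    """
    seq = sequence.upper()
    n = len(re.findall(_pattern_regex(motif.pattern), seq))
    if both_strands and not motif.is_palindromic():
        n += len(re.findall(_pattern_regex(motif.reverse_complement().pattern), seq))
    return n


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases; NaN if none (flagged undefined)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


# ---------------------------------------------------------------------------
# position frequency matrices and logos

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    freqs: np.ndarray  # (length, 4) per-position base frequencies, ACGT order
    n_sequences: int

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not np.allclose(self.freqs.sum(axis=1), 1.0):
            raise ValueError("per-position frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def build_pfm(sequences: Sequence[str]) -> PositionFrequencyMatrix:
    """Column-wise base frequencies of equal-length sequences.

    Ambiguous IUPAC bases contribute fractionally to each compatible base
    (an N adds 1/4 to all four).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be equal length")
    counts = np.zeros((length, 4))
    for s in sequences:
        for i, c in enumerate(s.upper()):
            bases = IUPAC.get(c)
            if bases is None:
                raise ValueError(f"invalid base {c!r}")
            w = 1.0 / len(bases)
            for b in bases:
                counts[i, _BASE_INDEX[b]] += w
    return PositionFrequencyMatrix(counts / len(sequences), len(sequences))


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b f log2 f.

    0 * log 0 is taken as 0; no small-sample correction is applied. Values
    lie in [0, 2], with 2 bits at an invariant position.
    """
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + plogp.sum(axis=1)


# ---------------------------------------------------------------------------
# set comparisons

#: Box statistics as plotted for feature comparisons: whiskers min..max,
#: box 25th..75th percentile (linear interpolation), middle line median.
_SUMMARY_FIELDS = ("n", "min", "q1", "median", "q3", "max", "mean")


def summary_stats(values: Sequence[float]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
        "mean": float(v.mean()),
    }


def compare_feature_across_sets(
    feature_values: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Welch t-tests and box statistics across element sets.

    Returns (pairwise p-value table, per-set summary table). Each set needs
    at least two values for the test to be defined.
    """
    labels = list(feature_values)
    for lab in labels:
        if len(feature_values[lab]) < 2:
            raise ValueError(f"set {lab!r} needs >= 2 values")
    stats_rows = {lab: summary_stats(feature_values[lab]) for lab in labels}
    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pairs.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "p_value": t_test_two_tailed(feature_values[a], feature_values[b]),
                }
            )
    return pd.DataFrame(pairs), pd.DataFrame(stats_rows).T.rename_axis("set")


def top_enriched_subset(
    results: pd.DataFrame, population: str, n: int = 50
) -> list[str]:
    """Ids of the ``n`` most-enriched elements (by fold change) of one
    population — e.g. restricting a crowded EGFP-negative hit list to its
    top 50 before feature comparison."""
    sub = results[results["population"] == population]
    return list(sub.sort_values("fold_change", ascending=False)["element_id"].head(n))
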