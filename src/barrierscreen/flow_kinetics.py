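"""Flow-cytometry normalization and silencing kinetics.

Reporter silencing is followed over days by flow cytometry. Day-to-day
instrument drift is compensated with standard fluorescent beads run in
every session: the sample mean EGFP on day n is multiplied by the ratio of
bead mean EGFP on day n to bead mean EGFP on day 1 (the first post-removal
measurement is the reference). Note the multiplier direction follows the
published formula verbatim; scaling a sample *up* when the beads read
brighter looks inverted as a drift correction, but fidelity to the printed
formula wins and fold changes between conditions are unaffected (the bead
factor cancels).

Silencing kinetics are summarized two ways: the EGFP-positive fraction
(all-or-none silencing) and an exponential fit to the population mean
fluorescence intensity, I(t) = I0 * exp(-k t), via ordinary least squares
on log MFI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FlowSample:
    """One flow-cytometry measurement of one sample on one day."""

    sample_id: str
    day: int
    mfi: float
    beads_mfi: float
    egfp_pos_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.mfi <= 0 or self.beads_mfi <= 0:
            raise ValueError("mfi and beads_mfi must be positive")
        if not np.isnan(self.egfp_pos_fraction) and not (
            0.0 <= self.egfp_pos_fraction <= 1.0
        ):
            raise ValueError("egfp_pos_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DecayFit:
    i0_hat: float
    k_hat: float
    residual_sse: float  # on the log scale

    def __post_init__(self) -> None:
        if self.i0_hat <= 0:
            raise ValueError("fitted I0 must be positive")
        if not np.isfinite(self.k_hat):
            raise ValueError("fitted decay rate must be finite")

    def predict(self, day: np.ndarray | float) -> np.ndarray | float:
        return self.i0_hat * np.exp(-self.k_hat * np.asarray(day, dtype=float))


def bead_adjust(sample: FlowSample, beads_day1: float) -> float:
    """Bead-normalized MFI: mfi * beads_mfi(day n) / beads_mfi(day 1)."""
    if beads_day1 <= 0:
        raise ValueError("reference bead intensity must be positive")
    return sample.mfi * sample.beads_mfi / beads_day1


def bead_adjust_series(samples: Sequence[FlowSample]) -> pd.DataFrame:
    """Bead-adjust a time series, using its day-1 (or earliest) bead value
    as the reference. Returns day, raw and adjusted MFI per sample."""
    if not samples:
        raise ValueError("empty series")
    by_day = sorted(samples, key=lambda s: s.day)
    day1 = next((s for s in by_day if s.day == 1), by_day[0])
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in by_day],
            "day": [s.day for s in by_day],
            "mfi": [s.mfi for s in by_day],
            "adjusted_mfi": [bead_adjust(s, day1.beads_mfi) for s in by_day],
        }
    )


def mfi_fold_change(
    treated: Sequence[FlowSample], control: Sequence[FlowSample], day: int
) -> float:
    """Ratio of bead-adjusted MFIs (treated / control) at one day.

    Replicate measurements on the requested day are averaged per series.
    The bead reference is each series' own day-1 measurement, so a common
    rescaling of bead values leaves the ratio unchanged.
    """
    out = []
    for series in (treated, control):
        adj = bead_adjust_series(series)
        vals = adj.loc[adj["day"] == day, "adjusted_mfi"]
        if vals.empty:
            raise ValueError(f"series has no measurement on day {day}")
        out.append(float(vals.mean()))
    return out[0] / out[1]


def fit_exponential_decay(samples: Sequence[FlowSample]) -> DecayFit:
    """Least-squares exponential decay fit of MFI over days.

    Fits ln(MFI) = ln(I0) - k * day by ordinary least squares; needs at
    least three distinct days and positive MFIs throughout.
    """
    days = np.array([s.day for s in samples], dtype=float)
    mfi = np.array([s.mfi for s in samples], dtype=float)
    if np.unique(days).size < 3:
        raise ValueError("need measurements on at least 3 distinct days")
    if (mfi <= 0).any():
        raise ValueError("all MFIs must be positive for a log-scale fit")
    y = np.log(mfi)
    slope, intercept = np.polyfit(days, y, 1)
    resid = y - (slope * days + intercept)
    return DecayFit(
        i0_hat=float(np.exp(intercept)),
        k_hat=float(-slope),
        residual_sse=float((resid**2).sum()),
    )


def percent_positive(intensities: Sequence[float], threshold: float) -> float:
    """Fraction of cells at or above the autofluorescence threshold."""
    v = np.asarray(intensities, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity vector")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float((v >= threshold).mean())


def read_flow_table(path) -> list[FlowSample]:
    """Read a flow summary TSV: sample_id, day, mfi, beads_mfi
    [, egfp_pos_fraction]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FlowSample(
                sample_id=str(row.sample_id),
                day=int(row.day),
                mfi=float(row.mfi),
                beads_mfi=float(row.beads_mfi),
                egfp_pos_fraction=float(getattr(row, "egfp_pos_fraction", float("nan"))),
            )
        )
    return out
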