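"""qPCR validation arithmetic: standard curves, primer gates, E^dCt.

Efficiency is the per-cycle amplification factor (2 = perfect doubling),
estimated from the least-squares slope of mean Ct against log10 relative
concentration.  Primer sets pass with an efficiency between 1.93 and 2.07
and a standard-curve correlation coefficient below -0.98.  Relative
abundance against a calibrator transcript is ``N_rel = E_bar ** dCt`` with
``dCt = Ct_calibrator - Ct_target`` and ``E_bar`` the arithmetic mean of the
passing efficiencies; matched tag counts are normalised to the calibrator's
count for side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EFFICIENCY_MIN = 1.93
EFFICIENCY_MAX = 2.07
CORRELATION_MAX = -0.98


class QpcrError(ValueError):
    pass


@dataclass
class DilutionSeries:
    """Standard-curve points: (log10 relative concentration, replicate Cts)."""

    points: list[tuple[float, list[float]]]
    min_points: int = 4  # protocol floor: at least four distinct dilutions

    def __post_init__(self):
        distinct = {x for x, _ in self.points}
        if len(distinct) < self.min_points:
            raise QpcrError(
                f"need >= {self.min_points} distinct dilution points, got {len(distinct)}"
            )
        for x, cts in self.points:
            if not cts:
                raise QpcrError(f"dilution point {x} has no Ct replicates")

    def mean_cts(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p[0] for p in self.points], dtype=float)
        y = np.array([fmean(p[1]) for p in self.points], dtype=float)
        return x, y


@dataclass(frozen=True)
class PrimerQC:
    efficiency: float
    slope: float
    correlation: float
    passed: bool


@dataclass(frozen=True)
class RelativeAbundance:
    transcript: str
    mean_ct: float
    delta_ct: float
    n_rel: float


def efficiency_from_curve(series: DilutionSeries) -> PrimerQC:
    """Fit mean Ct vs log10 concentration; E = 10 ** (-1 / slope).

    The correlation coefficient is Pearson's r of the same points; the gate
    passes iff 1.93 <= E <= 2.07 and r < -0.98.
    """
    x, y = series.mean_cts()
    if np.ptp(x) == 0:
        raise QpcrError("zero spread in dilution concentrations")
    slope, _intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise QpcrError("flat standard curve: slope is zero")
    efficiency = float(10.0 ** (-1.0 / slope))
    r = float(np.corrcoef(x, y)[0, 1])
    passed = EFFICIENCY_MIN <= efficiency <= EFFICIENCY_MAX and r < CORRELATION_MAX
    return PrimerQC(efficiency, float(slope), r, passed)


def relative_abundance(
    mean_ct: Mapping[str, float],
    calibrator: str,
    efficiencies: Mapping[str, PrimerQC] | Mapping[str, float] | Sequence[float],
    require_pass: bool = True,
) -> list[RelativeAbundance]:
    """N_rel per transcript relative to *calibrator* via E_bar ** dCt.

    *efficiencies* may be PrimerQC objects (gated), plain efficiency values,
    or a bare sequence; E_bar is their arithmetic mean.  The calibrator's
    N_rel is exactly 1.
    """
    if calibrator not in mean_ct:
        raise QpcrError(f"calibrator {calibrator!r} missing from Ct table")
    if isinstance(efficiencies, Mapping):
        values = []
        for name, eff in efficiencies.items():
            if isinstance(eff, PrimerQC):
                if require_pass and not eff.passed:
                    raise QpcrError(f"primer set for {name!r} failed QC")
                values.append(eff.efficiency)
            else:
                values.append(float(eff))
    else:
        values = [float(e) for e in efficiencies]
    if not values:
        raise QpcrError("no efficiencies supplied")
    e_bar = fmean(values)
    if e_bar <= 0:
        raise QpcrError(f"mean efficiency must be positive, got {e_bar}")
    ct_cal = mean_ct[calibrator]
    out = []
    for transcript, ct in mean_ct.items():
        d_ct = ct_cal - ct
        out.append(RelativeAbundance(transcript, ct, d_ct, float(e_bar ** d_ct)))
    return out


def tag_relative(counts: Mapping[str, float], calibrator: str) -> dict[str, float]:
    """Tag counts normalised to the calibrator's count."""
    if calibrator not in counts:
        raise QpcrError(f"calibrator {calibrator!r} missing from counts")
    cal = counts[calibrator]
    if cal <= 0:
        raise QpcrError(f"calibrator count must be positive, got {cal}")
    return {t: c / cal for t, c in counts.items()}


def comparison_table(
    abundances: Sequence[RelativeAbundance], tag_rel: Mapping[str, float]
) -> pd.DataFrame:
    """qPCR and tag-count relative abundances side by side."""
    rows = [
        {
            "transcript": a.transcript,
            "mean_ct": a.mean_ct,
            "delta_ct": a.delta_ct,
            "n_rel_qpcr": a.n_rel,
            "n_rel_tags": tag_rel.get(a.transcript),
        }
        for a in abundances
    ]
    return pd.DataFrame(rows)


def read_ct_csv(path) -> dict[str, float]:
    """CSV: transcript, then one column per replicate Ct; returns mean Ct."""
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        cts = [float(v) for v in row[1:] if not pd.isna(v)]
        if not cts:
            raise QpcrError(f"{row[0]}: no Ct replicates")
        out[str(row[0])] = fmean(cts)
    return out


def read_curves_csv(path) -> dict[str, DilutionSeries]:
    """CSV: transcript, log10_dilution, ct (one replicate per row)."""
    df = pd.read_csv(path)
    required = {"transcript", "log10_dilution", "ct"}
    if not required.issubset(df.columns):
        raise QpcrError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    series: dict[str, DilutionSeries] = {}
    for transcript, grp in df.groupby("transcript"):
        points = [
            (float(x), [float(v) for v in sub["ct"]])
            for x, sub in grp.groupby("log10_dilution")
        ]
        series[str(transcript)] = DilutionSeries(points)
    return series
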