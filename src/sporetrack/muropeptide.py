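"""Muropeptide chromatogram quantification.

Quantifies UPLC absorbance traces (204 nm detection) of muramidase-
digested peptidoglycan the way muropeptide analyses are conventionally
reported: each species' abundance is the *relative area* of its peak
within the sample, and whole-sample peptidoglycan amounts are compared
through total (baseline-subtracted) chromatogram area normalized to
initial biomass.

Species identities are user-supplied retention-time windows — peak
assignment from chemistry is outside this package's scope. Labels use
the conventional shorthand (M4 = monomeric MurNAc-tetrapeptide,
D44 = crosslinked tetrapeptide dimer, T444 = trimer; an ``Anh`` suffix
marks 1,6-anhydro-MurNAc forms, the signature products of lytic
transglycosylases). The anhydro fraction of total muropeptide area is
the headline readout: vegetative-cell profiles are dominated by M4/D44
with a small anhydro fraction, spore profiles by anhydro species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sp_signal

__all__ = [
    "Chromatogram",
    "detect_and_integrate_peaks",
    "assign_labels",
    "relative_abundances",
    "anhydro_fraction",
    "total_pg_comparison",
]

PEAK_COLUMNS = ["species_label", "start_min", "apex_min", "end_min",
                "area", "relative_area", "is_anhydro"]


@dataclass
class Chromatogram:
    """A uniformly sampled absorbance trace.

    ``biomass_norm`` is the per-sample scale factor (same initial
    biomass across samples) used by :func:`total_pg_comparison`.
    """

    time: np.ndarray            # min, strictly increasing, uniform
    signal: np.ndarray          # absorbance (arbitrary detector units)
    sample_id: str = "sample"
    biomass_norm: float = 1.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be equal-length 1D arrays")
        if self.time.size < 3:
            raise ValueError("chromatogram too short")
        dt = np.diff(self.time)
        if not (dt > 0).all():
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time must be uniformly sampled")
        if self.biomass_norm <= 0:
            raise ValueError("biomass_norm must be > 0")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None,
                 biomass_norm: float = 1.0) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(time=df.iloc[:, 0].to_numpy(),
                   signal=df.iloc[:, 1].to_numpy(),
                   sample_id=sample_id or str(path),
                   biomass_norm=biomass_norm)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "absorbance": self.signal}
                     ).to_csv(path, index=False)


def rolling_baseline(chrom: Chromatogram, window_min: float = 1.0,
                     smooth_min: float = 0.05) -> np.ndarray:
    """Baseline by grey-scale opening (rolling minimum then maximum).

    A 1-min structuring element passes linear drift through unchanged
    while suppressing peaks much narrower than the window. The signal
    is pre-smoothed over ``smooth_min`` so the minimum filter tracks
    the local mean rather than the noise floor, which would bias the
    baseline low by a few noise standard deviations.
    """
    s = chrom.signal
    k = int(round(smooth_min / chrom.sampling_interval))
    if k > 1:
        s = ndimage.uniform_filter1d(s, size=k, mode="nearest")
    n = max(3, int(round(window_min / chrom.sampling_interval)) | 1)
    lo = ndimage.minimum_filter1d(s, size=n, mode="nearest")
    return ndimage.maximum_filter1d(lo, size=n, mode="nearest")


def detect_and_integrate_peaks(
    chrom: Chromatogram,
    min_prominence: float = 0.01,
    baseline_window_min: float = 1.0,
    boundary_height_frac: float = 0.005,
) -> pd.DataFrame:
    """Detect peaks, assign boundaries, and integrate areas.

    The baseline is subtracted first. Peak apexes come from local-maxima
    prominence; each peak's boundaries extend outward to the valley
    shared with the neighbouring peak or to where the subtracted signal
    falls below ``boundary_height_frac`` of the apex height. Areas are
    trapezoidal integrals of the baseline-subtracted signal, so
    overlapping neighbours are split at the valley (no deconvolution).

    Returns an unlabelled peak table (``species_label`` None).
    """
    sub = chrom.signal - rolling_baseline(chrom, baseline_window_min)
    apexes, _ = sp_signal.find_peaks(sub, prominence=min_prominence)
    rows = []
    dt = chrom.sampling_interval
    for idx, apex in enumerate(apexes):
        height = sub[apex]
        floor = boundary_height_frac * height
        lo_lim = apexes[idx - 1] if idx > 0 else 0
        hi_lim = apexes[idx + 1] if idx + 1 < len(apexes) else sub.size - 1
        # left boundary: valley with the previous peak, or noise floor
        left = apex
        while left > lo_lim and sub[left - 1] > floor:
            left -= 1
        if idx > 0 and left <= lo_lim:
            left = lo_lim + int(np.argmin(sub[lo_lim:apex + 1]))
        right = apex
        while right < hi_lim and sub[right + 1] > floor:
            right += 1
        if idx + 1 < len(apexes) and right >= hi_lim:
            right = apex + int(np.argmin(sub[apex:hi_lim + 1]))
        area = float(np.trapezoid(sub[left:right + 1], dx=dt))
        rows.append((None, chrom.time[left], chrom.time[apex],
                     chrom.time[right], max(area, 0.0), np.nan, False))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def assign_labels(
    peak_table: pd.DataFrame,
    reference_windows: Mapping[str, tuple[float, float]],
    anhydro_marker: str = "anh",
) -> pd.DataFrame:
    """Label peaks by the retention-time window containing their apex.

    Windows must not overlap. Peaks whose apex falls in no window are
    labelled ``"unknown"``. ``is_anhydro`` is set when the label
    contains the anhydro marker (case-insensitive).
    """
    items = sorted(reference_windows.items(), key=lambda kv: kv[1][0])
    for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
        if b0 < a1:
            raise ValueError(f"windows {la!r} and {lb!r} overlap")
    out = peak_table.copy()
    labels = []
    for apex in out["apex_min"]:
        label = "unknown"
        for name, (lo, hi) in items:
            if lo <= apex <= hi:
                label = name
                break
        labels.append(label)
    out["species_label"] = labels
    out["is_anhydro"] = [anhydro_marker in s.lower() for s in labels]
    return out


def relative_abundances(peak_table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``relative_area`` = area / total area over the sample."""
    if len(peak_table) == 0:
        raise ValueError("peak table is empty")
    total = float(peak_table["area"].sum())
    if total <= 0:
        raise ValueError("total peak area is zero")
    out = peak_table.copy()
    out["relative_area"] = out["area"] / total
    return out


def anhydro_fraction(peak_table: pd.DataFrame) -> float:
    """Summed relative area of anhydro-labelled peaks."""
    t = peak_table
    if t["relative_area"].isna().any():
        t = relative_abundances(t)
    return float(t.loc[t["is_anhydro"], "relative_area"].sum())


def total_pg_comparison(
    chromatograms: Sequence[Chromatogram],
    reference_sample: str | None = None,
    baseline_window_min: float = 1.0,
) -> pd.DataFrame:
    """Relative total peptidoglycan amounts across samples.

    For each chromatogram the total baseline-subtracted area is divided
    by its ``biomass_norm``; replicates sharing a ``sample_id`` are
    averaged. Ratios are reported against ``reference_sample`` (default:
    the first sample seen).

    Returns one row per sample: (sample_id, n_replicates,
    mean_total_area, sd_total_area, ratio_to_reference).
    """
    if len(chromatograms) < 2:
        raise ValueError("need at least two chromatograms to compare")
    totals: dict[str, list[float]] = {}
    order: list[str] = []
    for c in chromatograms:
        sub = c.signal - rolling_baseline(c, baseline_window_min)
        area = float(np.trapezoid(sub, dx=c.sampling_interval)) / c.biomass_norm
        totals.setdefault(c.sample_id, []).append(area)
        if c.sample_id not in order:
            order.append(c.sample_id)
    if reference_sample is None:
        reference_sample = order[0]
    if reference_sample not in totals:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    ref = float(np.mean(totals[reference_sample]))
    rows = [(s, len(v), float(np.mean(v)),
             float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             float(np.mean(v)) / ref)
            for s, v in ((s, totals[s]) for s in order)]
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_replicates", "mean_total_area",
        "sd_total_area", "ratio_to_reference"])
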