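"""Group-level diurnal respiration-rate summaries.

Per-animal RR series are aggregated into a herd-level view: each animal
contributes its mean valid RR per 10-min bin, and the group median with
an interquartile band (25th–75th percentile across animals) is reported
per bin.  A 6-h centered rolling median smooths the group series enough
to expose the diurnal cycle — low rates at night, high rates around
early afternoon — while suppressing transient artifacts.

Bins are anchored at t = 0 (midnight of the series' first day);
quantiles use linear interpolation between order statistics, which
matters for small herds (the band for five animals is the 2nd/4th
order-statistic blend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from rrsonic.audio_io import RRSeries


@dataclass(frozen=True)
class GroupSeries:
    """Binned group RR: median with IQR band and contributor counts.

    ``timestamps`` are bin centers (seconds); bins with no contributing
    animal are gaps (NaN quantiles, ``n_animals = 0``).  Wherever at
    least one animal contributes, ``q25 <= group_median <= q75``.
    """

    timestamps: np.ndarray
    group_median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_animals: np.ndarray
    interval: float  # s, bin width

    def __post_init__(self) -> None:
        for name in ("timestamps", "group_median", "q25", "q75"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        object.__setattr__(self, "n_animals", np.asarray(self.n_animals, dtype=np.int64))
        n = self.timestamps.size
        if not all(
            getattr(self, f).size == n for f in ("group_median", "q25", "q75", "n_animals")
        ):
            raise ValueError("GroupSeries arrays must have equal length")
        present = self.n_animals >= 1
        if np.any(present & ~((self.q25 <= self.group_median) & (self.group_median <= self.q75))):
            raise ValueError("q25 <= median <= q75 violated on a populated bin")

    def __len__(self) -> int:
        return self.timestamps.size


def group_series(
    series_by_animal: Mapping[str, RRSeries], interval: float = 600.0
) -> GroupSeries:
    """Aggregate per-animal RR series into binned group statistics.

    Per bin of ``interval`` seconds (anchored at t = 0), each animal
    contributes the mean of its valid estimates falling in the bin; the
    group median and 25th/75th percentiles are taken across contributing
    animals.  Bins where no animal contributes are gaps.  The result is
    invariant under permutation of the animals.
    """
    if not series_by_animal:
        raise ValueError("need at least one animal series")
    if interval <= 0:
        raise ValueError("interval must be positive")

    lo = min(s.timestamps[0] for s in series_by_animal.values() if len(s))
    hi = max(s.timestamps[-1] for s in series_by_animal.values() if len(s))
    first_bin = int(math.floor(lo / interval))
    last_bin = int(math.floor(hi / interval))
    n_bins = last_bin - first_bin + 1

    # per-animal bin means of valid estimates
    per_animal = np.full((len(series_by_animal), n_bins), np.nan)
    for row, key in enumerate(sorted(series_by_animal)):
        s = series_by_animal[key]
        if not len(s):
            continue
        bins = np.floor(s.timestamps / interval).astype(int) - first_bin
        for b in range(n_bins):
            vals = s.rr[(bins == b) & s.valid]
            if vals.size:
                per_animal[row, b] = np.mean(vals)

    n_animals = np.sum(~np.isnan(per_animal), axis=0)
    med = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = per_animal[~np.isnan(per_animal[:, b]), b]
        if vals.size:
            med[b] = np.median(vals)
            q25[b], q75[b] = np.percentile(vals, [25, 75])  # linear interpolation
    centers = (np.arange(first_bin, last_bin + 1) + 0.5) * interval
    return GroupSeries(
        timestamps=centers, group_median=med, q25=q25, q75=q75,
        n_animals=n_animals, interval=interval,
    )


def rolling_median_hours(group: GroupSeries, window_h: float = 6.0) -> GroupSeries:
    """Centered rolling median of a group series over ``window_h`` hours.

    Gap bins are skipped inside the window; an output bin is itself a
    gap when fewer than half of the window's bins are populated.  The
    median, q25 and q75 tracks are smoothed identically, so the band
    ordering is preserved.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    half = window_h * 3600.0 / 2.0
    n = len(group)
    med = np.full(n, np.nan)
    q25 = np.full(n, np.nan)
    q75 = np.full(n, np.nan)
    n_animals = np.zeros(n, dtype=np.int64)
    ts = group.timestamps
    present = group.n_animals >= 1
    for i in range(n):
        in_win = np.abs(ts - ts[i]) <= half + 1e-9
        used = in_win & present
        if np.sum(used) >= 0.5 * np.sum(in_win) and np.any(used):
            med[i] = np.median(group.group_median[used])
            q25[i] = np.median(group.q25[used])
            q75[i] = np.median(group.q75[used])
            n_animals[i] = int(np.max(group.n_animals[used]))
    return GroupSeries(
        timestamps=ts.copy(), group_median=med, q25=q25, q75=q75,
        n_animals=n_animals, interval=group.interval,
    )
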