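"""Agreement between algorithm RR estimates and manual annotations.

Manual annotation marks each audible exhalation on the audio timeline
(Audacity label track, one ``'b'`` per breath).  This module turns such
a track into a reference RR series, pairs it with the algorithm output
on a common report grid, and computes the standard paired-comparison
statistics: MAE, RMSE, bias (estimate − reference), SD of the error,
Pearson r and R².

Reference construction mirrors the estimate path deliberately:
instantaneous rates ``60 / inter-breath-interval`` are placed on the
report grid and then summarized with the *same* rolling median as the
estimates, so both sides receive identical smoothing and the comparison
measures the algorithm, not asymmetric post-processing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from rrsonic.audio_io import LabelTrack, RRSeries
from rrsonic.pipeline import PipelineConfig, summarize_median

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised when two RR series are not on the same report grid."""


class InsufficientDataError(ValueError):
    """Raised when too few paired observations exist for a statistic."""


@dataclass(frozen=True)
class AgreementMetrics:
    """Paired-comparison statistics between estimates and reference.

    ``bias`` is signed (estimate − reference); ``sd_error`` uses the
    sample (n−1) convention, so ``rmse² = bias² + sd_error²·(n−1)/n``.
    ``r2`` is the squared Pearson correlation; both are NaN when either
    series is constant (correlation undefined).
    """

    n: int
    mae: float
    rmse: float
    bias: float
    sd_error: float
    r: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "bias": self.bias,
            "sd_error": self.sd_error,
            "r": self.r,
            "r2": self.r2,
        }


def annotations_to_rr(track: LabelTrack, cfg: PipelineConfig | None = None) -> RRSeries:
    """Reference RR series from an exhalation label track.

    Each pair of consecutive event *starts* defines an inter-breath
    interval; its instantaneous rate ``60/interval`` sits at the interval
    midpoint.  Rates outside the ``[rr_min, rr_max]`` acceptance range
    are excluded as annotation artifacts (logged).  Each interval is
    assigned to the nearest slot of the uniform ``report_hop`` grid
    (slot value = median of its intervals), then summarized with the
    same rolling median applied to algorithm estimates.

    Fewer than two events yield an empty series (logged), not an error.
    """
    cfg = cfg or PipelineConfig()
    starts = track.starts()
    if starts.size < 2:
        logger.info("%s: %d event(s), cannot form an interval; empty reference", track.source, starts.size)
        empty = np.empty(0)
        return RRSeries(timestamps=empty, rr=empty, valid=empty.astype(bool))

    intervals = np.diff(starts)
    inst_rr = 60.0 / intervals
    mids = (starts[:-1] + starts[1:]) / 2.0
    in_range = (inst_rr >= cfg.rr_min) & (inst_rr <= cfg.rr_max)
    n_out = int(np.sum(~in_range))
    if n_out:
        logger.info(
            "%s: excluded %d interval(s) implying rates outside [%g, %g] bpm",
            track.source, n_out, cfg.rr_min, cfg.rr_max,
        )

    n_grid = int(math.floor(starts[-1] / cfg.report_hop)) + 1
    timestamps = np.arange(n_grid) * cfg.report_hop
    rr = np.full(n_grid, np.nan)
    valid = np.zeros(n_grid, dtype=bool)
    n_src = np.zeros(n_grid, dtype=np.int64)
    # each interval feeds the grid slot nearest its midpoint; the slot
    # value is the median of its intervals — the exact mirror of how
    # pipeline candidates are bucketed, so both sides see the same
    # temporal treatment
    # half-up rounding: exact-half midpoints go to the later slot instead
    # of alternating under round-half-to-even
    slot = np.floor(mids / cfg.report_hop + 0.5).astype(int)
    for i in range(n_grid):
        sel = (slot == i) & in_range
        if np.any(sel):
            rr[i] = np.median(inst_rr[sel])
            valid[i] = True
            n_src[i] = int(np.sum(sel))
    grid = RRSeries(timestamps=timestamps, rr=rr, valid=valid, n_candidates=n_src)
    return summarize_median(grid, cfg)


def pair_series(
    estimates: RRSeries, reference: RRSeries, *, tol: float = 1e-6
) -> list[tuple[float, float]]:
    """Pair two RR series sharing a report grid.

    The series must have the same grid spacing (hop); their timestamp
    ranges may differ.  A pair is kept for every common timestamp where
    *both* series are valid.
    """
    if len(estimates) > 1 and len(reference) > 1:
        if not np.isclose(estimates.hop, reference.hop, rtol=0, atol=tol):
            raise AlignmentError(
                f"series grids differ: hop {estimates.hop} s vs {reference.hop} s"
            )
        offset = (reference.timestamps[0] - estimates.timestamps[0]) % estimates.hop
        if min(offset, estimates.hop - offset) > tol:
            raise AlignmentError("series grids are offset against each other")
    ref_lookup = {
        round(t / tol): (r, v)
        for t, r, v in zip(reference.timestamps, reference.rr, reference.valid)
    }
    pairs: list[tuple[float, float]] = []
    for t, r, v in zip(estimates.timestamps, estimates.rr, estimates.valid):
        if not v:
            continue
        hit = ref_lookup.get(round(t / tol))
        if hit is not None and hit[1]:
            pairs.append((float(r), float(hit[0])))
    logger.info("paired %d observations (%d est, %d ref points)", len(pairs), len(estimates), len(reference))
    return pairs


def agreement_metrics(pairs: Sequence[tuple[float, float]]) -> AgreementMetrics:
    """Error and correlation statistics over paired (estimate, reference).

    MAE = mean |e|, RMSE = sqrt(mean e²), bias = mean e, sd_error =
    sample SD of e, with e = estimate − reference; r is the Pearson
    correlation and R² its square.  Constant series make the correlation
    undefined, reported as NaN; the error moments are still computed.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError(f"need >= 2 pairs, got {0 if arr.ndim != 2 else arr.shape[0]}")
    est, ref = arr[:, 0], arr[:, 1]
    err = est - ref
    n = err.size
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sd_error = float(np.std(err, ddof=1))
    if n >= 3 and np.std(est) > 0 and np.std(ref) > 0:
        r = float(stats.pearsonr(est, ref).statistic)
    else:
        r = float("nan")
    return AgreementMetrics(n=n, mae=mae, rmse=rmse, bias=bias, sd_error=sd_error, r=r, r2=r * r)
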