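"""Standard end-to-end validation run on synthetic data.

Ties the pieces together: generate the standard benchmark recordings,
extract RR with the default pipeline, build references from the
generated label tracks exactly as one would from manual annotation, and
pool the paired 10-min rolling-median values into one set of agreement
metrics.  Recordings are processed one at a time so memory stays flat.
"""

from __future__ import annotations

import logging

from rrsonic.agreement import AgreementMetrics, agreement_metrics, annotations_to_rr, pair_series
from rrsonic.pipeline import PipelineConfig, extract_rr, summarize_median
from rrsonic.synth_data import benchmark_specs, generate_breath_audio

logger = logging.getLogger(__name__)


def benchmark_agreement(
    seed: int, cfg: PipelineConfig | None = None
) -> tuple[AgreementMetrics, list[tuple[float, float]]]:
    """Pooled agreement of pipeline output vs label-derived reference.

    Runs the full standard benchmark (10 x 20-min recordings spanning
    20-100 bpm) and returns the pooled metrics together with the paired
    (estimate, reference) rolling-median values.
    """
    cfg = cfg or PipelineConfig()
    pairs: list[tuple[float, float]] = []
    for k, spec in enumerate(benchmark_specs(seed)):
        audio, track, _ = generate_breath_audio(spec)
        estimates = summarize_median(extract_rr(audio, cfg), cfg)
        reference = annotations_to_rr(track, cfg)
        new = pair_series(estimates, reference)
        logger.info("benchmark recording %d: %d pairs", k, len(new))
        pairs.extend(new)
    return agreement_metrics(pairs), pairs
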