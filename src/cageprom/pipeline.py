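"""End-to-end assembly of the per-promoter property table.

Two entry points:

* :func:`promoter_properties` - the real pipeline: promoters called from a
  tag landscape, an expression matrix, a genome and an identity track.
* :func:`synthetic_property_table` - the matrix-level path for planted
  cohorts: expression counts, window sequences and initiation-profile
  spreads are synthesized directly from the ground truth (same metric
  functions, no positional landscape), which keeps planted-network
  studies at thousands of promoters fast.

The nine analyzed properties are: TSS spread (``iqr``), CpG
observed/expected (``cpg_oe``), G+C percentage (``gc_pct``), best TATA
score (``tata_score``), upstream identity (``identity_pct``), expression
breadth (``entropy_100``), average, maximum and germ-cell-average tpm.
``sd`` and ``tag_count`` are carried along.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cage_io import IdentityTrack, PositionCountMatrix, SampleSpec, TagLandscape
from .expression_metrics import ExpressionMatrix, specificity_table, summarize_expression
from .promoter_calling import (
    Promoter,
    collect_promoters,
    filter_by_annotation,
    find_local_maxima,
    tss_spread,
)
from .sequence_features import (
    cpg_oe,
    extract_window,
    gc_percent,
    identity_upstream,
    tata_best_score,
)
from .synthetic_data import (
    CohortConfig,
    PromoterTruth,
    _streams,
    expression_counts,
    generate_cohort,
    initiation_profile,
    make_tata_pcm,
    promoter_window_sequence,
    true_ppm,
)

PROPERTY_COLUMNS = [
    "iqr",
    "cpg_oe",
    "gc_pct",
    "tata_score",
    "identity_pct",
    "entropy_100",
    "avg_tpm",
    "max_tpm",
    "germ_avg_tpm",
]


def call_promoters(
    landscape: TagLandscape, tss_bed: pd.DataFrame, d: int = 50
) -> list[Promoter]:
    """Local maxima -> annotation filter -> fixed-window tag collection."""
    anchors = find_local_maxima(landscape, d)
    anchors = filter_by_annotation(anchors, tss_bed, d)
    return collect_promoters(anchors, landscape, d)


def promoter_properties(
    promoters: Sequence[Promoter],
    samples: Sequence[SampleSpec],
    genome: Mapping[str, str],
    pcm: PositionCountMatrix,
    identity_track: IdentityTrack | None = None,
    n: int = 100,
    seed: int = 0,
    min_total: int = 100,
    background: str = "uniform",
    w: int = 100,
) -> pd.DataFrame:
    """Per-promoter property table from called promoters.

    Promoters below ``min_total`` tags get NaN expression breadth (their
    fixed-depth entropy is undefined); missing values stay missing rather
    than being zero-filled.
    """
    matrix = ExpressionMatrix.from_promoters(promoters, samples)
    spec = specificity_table(matrix, n=n, seed=seed, min_total=min_total)
    summ = summarize_expression(matrix)
    rows = []
    for i, p in enumerate(promoters):
        window = extract_window(genome, p.contig, p.anchor, p.strand, w)
        spread = tss_spread(p) if p.tag_count > 0 else None
        rows.append(
            {
                "promoter": matrix.promoter_ids[i],
                "iqr": spread.iqr if spread else np.nan,
                "sd": spread.sd if spread else np.nan,
                "cpg_oe": cpg_oe(window),
                "gc_pct": gc_percent(window),
                "tata_score": tata_best_score(window, pcm, background).score,
                "identity_pct": (
                    identity_upstream(identity_track, p.contig, p.anchor, p.strand)
                    if identity_track is not None
                    else np.nan
                ),
            }
        )
    props = pd.DataFrame(rows)
    props = props.merge(
        spec[["promoter", "entropy_100", "tag_count"]], on="promoter"
    ).merge(summ[["promoter", "avg_tpm", "max_tpm", "germ_avg_tpm"]], on="promoter")
    return props


def synthetic_property_table(
    config: CohortConfig,
    seed: int | None = None,
    n: int = 100,
    min_total: int = 100,
    spread_tags: int = 1000,
    background: str = "uniform",
) -> tuple[pd.DataFrame, list[PromoterTruth], ExpressionMatrix]:
    """Property table for a planted cohort, computed at matrix level.

    Expression counts are Poisson draws from the planted per-sample ppm;
    window sequences come from the same sampler the landscape renderer
    uses; TSS spread is measured on up to ``spread_tags`` initiation
    positions drawn from the promoter's true profile (a capped multiset,
    since spread statistics stabilize long before thousands of tags).
    """
    seed = config.seed if seed is None else seed
    samples, truths = generate_cohort(config)
    rng_expr, rng_seq, rng_spread = _streams(seed + 1_000_003, 3)
    ppm = true_ppm(truths, samples, config, rng_expr)
    counts = expression_counts(ppm, samples, rng_expr)
    matrix = ExpressionMatrix(
        counts=counts,
        library_sizes=np.array([s.library_size for s in samples]),
        sample_ids=[s.sample_id for s in samples],
        promoter_ids=[f"p{i}" for i in range(len(truths))],
        is_germ=np.array([s.is_germ for s in samples]),
    )
    spec = specificity_table(matrix, n=n, seed=seed, min_total=min_total)
    summ = summarize_expression(matrix)
    pcm = make_tata_pcm()
    d = config.d
    profiles = {
        shape: initiation_profile(shape, d, config) for shape in ("narrow", "broad")
    }
    offsets = np.arange(-d, d + 1)
    rows = []
    for i, t in enumerate(truths):
        win = promoter_window_sequence(t, pcm, rng_seq)
        total = int(counts[i].sum())
        if total > 0:
            m = min(total, spread_tags)
            weights = rng_spread.multinomial(m, profiles[t.shape])
            spread = tss_spread(positions=offsets, weights=weights)
            iqr, sd = spread.iqr, spread.sd
        else:
            iqr = sd = np.nan
        rows.append(
            {
                "promoter": f"p{i}",
                "iqr": iqr,
                "sd": sd,
                "cpg_oe": cpg_oe(win),
                "gc_pct": gc_percent(win),
                "tata_score": tata_best_score(win, pcm, background).score,
                "identity_pct": t.identity_pct,
            }
        )
    props = pd.DataFrame(rows)
    props = props.merge(
        spec[["promoter", "entropy_100", "tag_count"]], on="promoter"
    ).merge(summ[["promoter", "avg_tpm", "max_tpm", "germ_avg_tpm"]], on="promoter")
    return props, truths, matrix
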