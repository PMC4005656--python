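"""Promoter definition from a CAGE tag landscape.

A promoter is anchored at a locally maximal CAGE start site near an
annotated TSS, and collects every tag starting within ``d`` bases of the
anchor.  Fixing the collection window avoids the classic artifact of
distance-based tag clustering, which produces wider clusters at higher
sequencing depth; ``distance_cluster`` is kept as the baseline that
demonstrates the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cage_io import TagLandscape

__all__ = [
    "Anchor",
    "Promoter",
    "SpreadStats",
    "find_local_maxima",
    "filter_by_annotation",
    "collect_promoters",
    "tss_spread",
    "weighted_quantile",
    "distance_cluster",
    "Cluster",
    "depth_artifact_experiment",
]

Anchor = tuple[str, int, str]  # (contig, 0-based position, strand)


@dataclass
class Promoter:
    """Tags collected in a fixed +/- d window around a locally maximal site.

    ``offsets`` holds per-base tag counts over genomic positions
    ``[anchor - d, anchor + d]`` (length 2d+1, genomic order), summed over
    samples.  ``per_sample_counts`` is x_gt, the tag count per sample.
    """

    contig: str
    anchor: int
    strand: str
    d: int
    offsets: np.ndarray
    per_sample_counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.per_sample_counts = np.asarray(self.per_sample_counts, dtype=np.int64)
        if self.offsets.shape != (2 * self.d + 1,):
            raise ValueError("offsets must have length 2d+1")
        if self.offsets.sum() != self.per_sample_counts.sum():
            raise ValueError("offset total and per-sample total disagree")

    @property
    def tag_count(self) -> int:
        return int(self.offsets.sum())


@dataclass(frozen=True)
class SpreadStats:
    """TSS spread of one promoter: IQR and SD of tag start coordinates."""

    iqr: float
    sd: float


def _is_five_prime_of(a: int, b: int, strand: str) -> bool:
    """True when position a is strictly 5' of b on the given strand."""
    return a < b if strand == "+" else a > b


def find_local_maxima(landscape: TagLandscape, d: int) -> list[Anchor]:
    """Locally maximal CAGE start sites, pooled over samples.

    A site is returned when its pooled count is strictly greater than the
    count of every non-tied site within +/- d on the same strand.  Among
    sites tied for the maximum within +/- d of each other, only the 5'-most
    (strand-aware) is returned.  Zero-count sites are never returned.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    anchors: list[Anchor] = []
    for contig, strand in landscape.keys():
        pos, cnt = landscape.pooled(contig, strand)
        keep = cnt > 0
        pos, cnt = pos[keep], cnt[keep]
        n = len(pos)
        lo = np.searchsorted(pos, pos - d, side="left")
        hi = np.searchsorted(pos, pos + d, side="right")
        for i in range(n):
            window = slice(lo[i], hi[i])
            wc = cnt[window]
            wp = pos[window]
            if (wc > cnt[i]).any():
                continue
            tied = wp[(wc == cnt[i]) & (wp != pos[i])]
            if any(_is_five_prime_of(int(t), int(pos[i]), strand) for t in tied):
                continue
            anchors.append((contig, int(pos[i]), strand))
    return sorted(anchors)


def tss_positions_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Annotated TSS positions from a BED frame: start for +, end-1 for -."""
    tss = bed.copy()
    tss["pos"] = np.where(tss["strand"] == "+", tss["start"], tss["end"] - 1)
    return tss[["contig", "pos", "strand"]]


def filter_by_annotation(
    anchors: Sequence[Anchor], tss_bed: pd.DataFrame, d: int
) -> list[Anchor]:
    """Keep anchors within d bases of a same-strand annotated TSS (inclusive)."""
    tss = tss_positions_from_bed(tss_bed)
    by_key: dict[tuple[str, str], np.ndarray] = {
        (str(c), str(s)): np.sort(sub["pos"].to_numpy(np.int64))
        for (c, s), sub in tss.groupby(["contig", "strand"])
    }
    kept = []
    for contig, pos, strand in anchors:
        sites = by_key.get((contig, strand))
        if sites is None or not len(sites):
            continue
        i = np.searchsorted(sites, pos)
        nearest = min(
            (abs(int(sites[j]) - pos) for j in (i - 1, i) if 0 <= j < len(sites)),
            default=None,
        )
        if nearest is not None and nearest <= d:
            kept.append((contig, pos, strand))
    return kept


def collect_promoters(
    anchors: Sequence[Anchor], landscape: TagLandscape, d: int
) -> list[Promoter]:
    """Collect tags starting within +/- d of each anchor into promoters.

    Every tag position within d of at least one anchor contributes to
    exactly one promoter: the nearest anchor, with ties broken toward the
    anchor 5' of the site (strand-aware), so no tag is double-counted even
    when anchors are 51..2d bases apart.
    """
    promoters: list[Promoter] = []
    anchors_by_key: dict[tuple[str, str], list[int]] = {}
    for contig, pos, strand in anchors:
        anchors_by_key.setdefault((contig, strand), []).append(pos)

    for (contig, strand), apos_list in sorted(anchors_by_key.items()):
        apos = np.array(sorted(apos_list), dtype=np.int64)
        pos, _ = landscape.pooled(contig, strand)
        if not len(pos):
            assigned = {int(a): np.array([], dtype=np.int64) for a in apos}
        else:
            i = np.searchsorted(apos, pos)
            left = np.clip(i - 1, 0, len(apos) - 1)
            right = np.clip(i, 0, len(apos) - 1)
            dl = np.abs(pos - apos[left])
            dr = np.abs(pos - apos[right])
            # nearest anchor; exact tie -> anchor 5' of the site
            if strand == "+":
                choose_left = (dl < dr) | ((dl == dr) & (apos[left] < pos))
            else:
                choose_left = dl < dr  # on '-', larger coordinate is 5'
                tie = dl == dr
                choose_left = choose_left | (tie & (apos[left] > pos))
            nearest = np.where(choose_left, left, right)
            dist = np.abs(pos - apos[nearest])
            in_window = dist <= d
            assigned = {
                int(a): pos[in_window & (nearest == j)]
                for j, a in enumerate(apos)
            }
        wide_all = landscape.sample_counts_at(contig, strand, pos)
        for a in apos:
            mine = assigned[int(a)]
            offsets = np.zeros(2 * d + 1, dtype=np.int64)
            per_sample = np.zeros(len(landscape.sample_ids), dtype=np.int64)
            if len(mine):
                wide = wide_all.loc[wide_all.index.isin(mine)]
                site_totals = wide.sum(axis=1)
                for p, c in site_totals.items():
                    offsets[int(p) - (int(a) - d)] = int(c)
                per_sample = wide.sum(axis=0).to_numpy(np.int64)
            promoters.append(
                Promoter(
                    contig=contig,
                    anchor=int(a),
                    strand=strand,
                    d=d,
                    offsets=offsets,
                    per_sample_counts=per_sample,
                    sample_ids=list(landscape.sample_ids),
                )
            )
    return promoters


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Type-7 (linear-interpolation) quantile of an integer-weighted multiset.

    Equivalent to ``np.quantile(np.repeat(values, weights), q)`` without
    expanding the multiset.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=np.int64)
    if (weights < 0).any():
        raise ValueError("negative weights")
    mask = weights > 0
    values, weights = values[mask], weights[mask]
    if not len(values):
        raise ValueError("empty multiset")
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cw = np.cumsum(weights)
    n = int(cw[-1])
    h = (n - 1) * q

    def elem(k: int) -> float:
        return float(values[np.searchsorted(cw, k + 1, side="left")])

    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    vlo = elem(lo)
    return vlo + (h - lo) * (elem(hi) - vlo)


def tss_spread(promoter: Promoter | None = None, *,
               positions: np.ndarray | None = None,
               weights: np.ndarray | None = None) -> SpreadStats:
    """IQR and SD of tag start coordinates within one promoter.

    Statistics are computed on the multiset of start coordinates weighted
    by tag counts; IQR is Q3 - Q1 with linear interpolation (type 7).
    Either a :class:`Promoter` or explicit positions/weights may be given.
    """
    if promoter is not None:
        positions = np.arange(
            promoter.anchor - promoter.d, promoter.anchor + promoter.d + 1
        )
        weights = promoter.offsets
    positions = np.asarray(positions, dtype=float)
    weights = np.asarray(weights, dtype=np.int64)
    total = int(weights.sum())
    if total < 1:
        raise ValueError("spread undefined for a promoter with zero tags")
    q1 = weighted_quantile(positions, weights, 0.25)
    q3 = weighted_quantile(positions, weights, 0.75)
    mean = float(np.average(positions, weights=weights))
    var = float(np.average((positions - mean) ** 2, weights=weights))
    return SpreadStats(iqr=q3 - q1, sd=float(np.sqrt(var)))


@dataclass(frozen=True)
class Cluster:
    """A single-linkage cluster of tag start sites."""

    contig: str
    strand: str
    start: int  # 5'-agnostic genomic min
    end: int    # genomic max, inclusive
    n_sites: int
    tag_count: int

    @property
    def width(self) -> int:
        return self.end - self.start


def distance_cluster(
    landscape: TagLandscape | None = None,
    gap: int = 20,
    *,
    positions: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    contig: str = "chr1",
    strand: str = "+",
) -> list[Cluster]:
    """Single-linkage clustering of nonzero tag sites with spacing <= gap.

    This is the naive promoter definition whose cluster widths grow with
    sequencing depth; it exists as a baseline, not as the recommended caller.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    jobs: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    if landscape is not None:
        for c, s in landscape.keys():
            p, n = landscape.pooled(c, s)
            jobs.append((c, s, p, n))
    else:
        p = np.asarray(positions, dtype=np.int64)
        n = np.asarray(counts, dtype=np.int64) if counts is not None else np.ones_like(p)
        order = np.argsort(p)
        jobs.append((contig, strand, p[order], n[order]))
    clusters: list[Cluster] = []
    for c, s, p, n in jobs:
        keep = n > 0
        p, n = p[keep], n[keep]
        if not len(p):
            continue
        breaks = np.where(np.diff(p) > gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(p) - 1]])
        for i0, i1 in zip(starts, ends):
            clusters.append(
                Cluster(
                    contig=c,
                    strand=s,
                    start=int(p[i0]),
                    end=int(p[i1]),
                    n_sites=int(i1 - i0 + 1),
                    tag_count=int(n[i0 : i1 + 1].sum()),
                )
            )
    return clusters


def depth_artifact_experiment(
    profile: np.ndarray,
    depths: Sequence[int] = (100, 10_000),
    n_reps: int = 100,
    gap: int = 20,
    d: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample one fixed initiation profile at several depths and compare
    distance-cluster width with fixed-window IQR.

    ``profile`` gives per-base initiation probabilities over offsets centered
    on 0 (odd length).  For each replicate and depth, tags are drawn
    multinomially; we record the mean width of distance-based clusters and
    the IQR of tags within the fixed +/- d window around the profile mode.
    Cluster width grows with depth (the artifact) while the fixed-window IQR
    is depth-stable in expectation.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) % 2 != 1:
        raise ValueError("profile length must be odd (centered on the anchor)")
    profile = profile / profile.sum()
    half = len(profile) // 2
    offsets = np.arange(-half, half + 1)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        for rep in range(n_reps):
            counts = rng.multinomial(depth, profile)
            nz = counts > 0
            clusters = distance_cluster(
                positions=offsets[nz], counts=counts[nz], gap=gap
            )
            mean_width = float(np.mean([c.width for c in clusters]))
            window = np.abs(offsets) <= d
            stats = tss_spread(positions=offsets[window], weights=counts[window])
            rows.append(
                {
                    "depth": depth,
                    "rep": rep,
                    "n_clusters": len(clusters),
                    "mean_cluster_width": mean_width,
                    "fixed_window_iqr": stats.iqr,
                    "fixed_window_sd": stats.sd,
                }
            )
    return pd.DataFrame(rows)
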