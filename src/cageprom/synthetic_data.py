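"""Synthetic FANTOM5-like CAGE cohorts with known ground truth.

The generator emulates the structure of a deep multi-sample CAGE atlas:
hundreds of libraries with heterogeneous sizes, promoters spanning two CpG
classes and two TSS-spread classes, and expression breadth that is
independent of maximum expression level.  Every downstream stage of the
package can therefore be tested against planted truth without any
download.

Ground-truth structure (the planted correlation network)
--------------------------------------------------------
Per promoter, the structural model draws:

* breadth fraction ``f`` (fraction of samples where the promoter is on)
  and maximum level ``M`` (ppm) **independently** - the planted version of
  the finding that expression breadth is independent of maximum level;
* germ-line activity ``g``, a noisy companion of ``f``, which decides how
  many germ-cell samples are active;
* a CpG latent driven by true germ-line expression (level x activity),
  emulating the methylation/mutation mechanism: active germ-line
  promoters keep their CpGs.  The latent also pushes %G+C up;
* a TATA box planted preferentially in GC-poor promoters;
* a narrow initiation profile made more likely by a TATA box and by a
  high maximum level; a broad flat-topped profile otherwise;
* upstream cross-species identity increasing with maximum level.

Expression in an active sample is ``M`` for the promoter's top sample and
``damping * M * lognormal`` (bounded above by ``damping * M``) elsewhere,
so the true maximum is exactly ``M`` no matter how many samples are
active: breadth cannot leak into measured maximum expression.  Tag totals
are Poisson around ppm * N_t / 1e6 and tag positions are multinomial draws
from the initiation profile.

``PLANTED_DIRECT_EDGES`` lists the property pairs coupled directly by this
model, with signs; every other significant pairwise association in a
generated cohort is an indirect consequence and should be removed by the
network reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cage_io import (
    BED_COLUMNS,
    IdentityTrack,
    PositionCountMatrix,
    SampleSpec,
    TagLandscape,
    write_bed,
    write_ctss,
    write_fasta,
    write_identity_bed,
    write_metadata,
    write_pcm,
)

__all__ = [
    "CohortConfig",
    "PromoterTruth",
    "SyntheticDataset",
    "ConfigError",
    "GenerationError",
    "PLANTED_DIRECT_EDGES",
    "generate_cohort",
    "true_ppm",
    "expression_counts",
    "initiation_profile",
    "make_tata_pcm",
    "render_landscape",
    "write_dataset",
    "generate_bias_counts",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class GenerationError(ValueError):
    """Generation preconditions violated (e.g. overlapping anchors)."""


#: Property pairs directly coupled by the structural model, with signs.
#: Everything else significant in a generated cohort is indirect.
PLANTED_DIRECT_EDGES: tuple[tuple[str, str, int], ...] = (
    ("avg_tpm", "germ_avg_tpm", +1),   # average includes the germ samples
    ("avg_tpm", "max_tpm", +1),        # avg is bounded by max and max/T
    ("avg_tpm", "entropy_100", +1),    # breadth raises average, not max
    ("cpg_oe", "germ_avg_tpm", +1),    # germ-line activity preserves CpGs
    ("cpg_oe", "gc_pct", +1),          # CpG depletion also depletes G+C
    ("gc_pct", "tata_score", -1),      # TATA boxes favored in GC-poor DNA
    ("iqr", "tata_score", -1),         # TATA boxes sharpen initiation
    ("iqr", "max_tpm", -1),            # strong promoters initiate sharply
    ("identity_pct", "max_tpm", +1),   # strong promoters evolve slowly
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the tests:
    120 samples and 2000 promoters, library sizes lognormal around one
    million mapped tags, ten percent germ-cell samples.
    """

    n_samples: int = 120
    n_promoters: int = 2000
    seed: int = 0
    germ_fraction: float = 0.1
    library_size_median: float = 1_000_000.0
    library_size_sigma: float = 0.8
    noise_sigma: float = 0.5            # per-sample lognormal expression noise
    max_level_log_mean: float = math.log(250.0)  # median max level, ppm
    max_level_sigma: float = 1.0
    min_breadth: float = 0.1
    germ_coupling_noise: float = 0.45   # sd linking germ propensity to breadth
    nonpeak_damping: float = 0.7        # non-top active samples sit below max
    cpg_latent_noise: float = 0.75
    gc_latent_noise: float = 0.35
    identity_noise: float = 22.0
    narrow_decay: float = 0.55          # geometric decay of the narrow profile
    broad_plateau: int = 41             # flat-top width of the broad profile
    d: int = 50
    anchor_spacing: int = 1000
    contig_size: int = 500              # promoters per synthetic contig
    replicate_groups: int = 0           # extra duplicated-ontology sample pairs

    def validate(self) -> None:
        for name in ("germ_fraction", "min_breadth"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.nonpeak_damping <= 1.0):
            raise ConfigError("nonpeak_damping must lie in (0, 1]")
        if not (0.0 < self.narrow_decay < 1.0):
            raise ConfigError("narrow_decay must lie in (0, 1)")
        if self.n_samples < 4 or self.n_promoters < 1:
            raise ConfigError("cohort too small")
        if self.anchor_spacing <= 4 * self.d:
            raise ConfigError("anchor_spacing must exceed 4d")
        if self.replicate_groups < 0:
            raise ConfigError("replicate_groups must be >= 0")


@dataclass(frozen=True)
class PromoterTruth:
    """Planted truth for one promoter."""

    contig: str
    anchor: int
    strand: str
    breadth_fraction: float
    max_level: float                    # ppm, the true maximum over samples
    active_samples: frozenset[str]
    peak_sample: str
    shape: str                          # narrow | broad
    cpg_class: str                      # high | low
    cpg_oe_target: float
    gc_target: float
    has_tata: bool
    identity_pct: float
    germ_active_fraction: float         # realized fraction of germ samples on


@dataclass
class SyntheticDataset:
    """A fully rendered cohort: landscape plus all companion files."""

    config: CohortConfig
    samples: list[SampleSpec]
    truths: list[PromoterTruth]
    landscape: TagLandscape
    genome: dict[str, str]
    tss_bed: pd.DataFrame
    identity_track: IdentityTrack
    pcm: PositionCountMatrix


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _make_samples(config: CohortConfig, rng: np.random.Generator) -> list[SampleSpec]:
    T = config.n_samples
    sizes = np.round(
        config.library_size_median
        * np.exp(config.library_size_sigma * rng.standard_normal(T))
    ).astype(np.int64)
    sizes = np.maximum(sizes, 10_000)
    n_germ = max(2, int(round(config.germ_fraction * T)))
    germ_idx = set(rng.choice(T, size=n_germ, replace=False).tolist())
    samples = []
    for i in range(T):
        terms = {f"cell_type_{i:04d}", "sample"}
        if i in germ_idx:
            terms.add("germ_cell")
        samples.append(
            SampleSpec(
                sample_id=f"s{i:04d}",
                library_size=int(sizes[i]),
                ontology_terms=frozenset(terms),
                is_germ=i in germ_idx,
            )
        )
    # optional replicate pairs: duplicate the ontology of the first
    # replicate_groups non-germ samples onto fresh appended samples
    for r in range(config.replicate_groups):
        donor = samples[r]
        samples.append(
            SampleSpec(
                sample_id=f"s{T + r:04d}rep",
                library_size=int(
                    max(
                        10_000,
                        round(
                            config.library_size_median
                            * math.exp(
                                config.library_size_sigma * rng.standard_normal()
                            )
                        ),
                    )
                ),
                ontology_terms=donor.ontology_terms,
                is_germ=donor.is_germ,
            )
        )
    return samples


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SampleSpec], list[PromoterTruth]]:
    """Draw the cohort: sample specs and per-promoter planted truths.

    Deterministic for a fixed ``config.seed``.  Breadth fractions are
    drawn independently of maximum levels; CpG class is coupled to
    germ-cell activity; at least two germ-cell samples are present.
    """
    config.validate()
    rng_samples, rng_truths = _streams(config.seed, 4)[:2]
    samples = _make_samples(config, rng_samples)
    T = config.n_samples  # planted truths ignore appended replicate samples
    core = samples[:T]
    germ_ids = [s.sample_id for s in core if s.is_germ]
    nong_ids = [s.sample_id for s in core if not s.is_germ]
    n_germ = len(germ_ids)
    G = config.n_promoters
    rng = rng_truths

    f = config.min_breadth + (1.0 - config.min_breadth) * rng.uniform(size=G)
    M = np.exp(
        config.max_level_log_mean + config.max_level_sigma * rng.standard_normal(G)
    )
    g_prop = np.clip(f + config.germ_coupling_noise * rng.standard_normal(G), 0.02, 1.0)

    contigs = [
        f"chr{1 + i // config.contig_size}" for i in range(G)
    ]
    strands = np.where(rng.uniform(size=G) < 0.5, "+", "-")
    offsets_in_contig = [
        (i % config.contig_size) * config.anchor_spacing + config.anchor_spacing // 2
        for i in range(G)
    ]

    # first pass: activity, then cohort-level latents that need ranks
    k_active = np.maximum(1, np.round(f * T).astype(int))
    n_act_germ = np.zeros(G, dtype=int)
    active_sets: list[frozenset[str]] = []
    peaks: list[str] = []
    for i in range(G):
        kg = int(rng.binomial(n_germ, g_prop[i]))
        kg = min(kg, k_active[i], n_germ)
        kg = max(kg, k_active[i] - len(nong_ids))
        act = list(rng.choice(germ_ids, size=kg, replace=False)) if kg else []
        act += list(rng.choice(nong_ids, size=k_active[i] - kg, replace=False))
        n_act_germ[i] = kg
        active_sets.append(frozenset(act))
        peaks.append(act[int(rng.integers(len(act)))])

    germ_truth = M * (n_act_germ / max(n_germ, 1))
    cpg_latent = np.log(germ_truth + 1e-3) + 2.0 * config.cpg_latent_noise * (
        rng.standard_normal(G)
    )
    q = stats_rankdata(cpg_latent) / G  # ecdf in (0, 1]
    high = q > 0.5
    # bimodal target with a valley around 0.5, mirroring the CpG histogram
    cpg_target = np.where(high, 0.70 + 0.6 * (q - 0.5), 0.10 + 0.4 * q)
    gc_target = 0.35 + 0.28 * np.clip(
        q + config.gc_latent_noise * rng.standard_normal(G), 0.0, 1.0
    )
    p_tata = _sigmoid(0.4 - 18.0 * (gc_target - 0.47))
    has_tata = rng.uniform(size=G) < p_tata
    zM = (np.log(M) - config.max_level_log_mean) / config.max_level_sigma
    p_narrow = _sigmoid(-1.4 + 3.0 * has_tata + 1.4 * zM)
    narrow = rng.uniform(size=G) < p_narrow
    identity = np.clip(
        45.0 + 14.0 * zM + config.identity_noise * rng.standard_normal(G), 0.0, 100.0
    )

    truths = []
    for i in range(G):
        truths.append(
            PromoterTruth(
                contig=contigs[i],
                anchor=int(offsets_in_contig[i]),
                strand=str(strands[i]),
                breadth_fraction=float(f[i]),
                max_level=float(M[i]),
                active_samples=active_sets[i],
                peak_sample=peaks[i],
                shape="narrow" if narrow[i] else "broad",
                cpg_class="high" if high[i] else "low",
                cpg_oe_target=float(cpg_target[i]),
                gc_target=float(gc_target[i]),
                has_tata=bool(has_tata[i]),
                identity_pct=float(identity[i]),
                germ_active_fraction=float(n_act_germ[i] / max(n_germ, 1)),
            )
        )
    return samples, truths


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties averaged."""
    return rankdata(x)


def true_ppm(
    truths: Sequence[PromoterTruth],
    samples: Sequence[SampleSpec],
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """True per-sample expression (ppm) for every promoter.

    Inactive samples are 0.  The promoter's top active sample sits exactly
    at ``max_level``; every other active sample is
    ``damping * max_level * exp(sigma * (z - z_max))`` so that the true
    maximum is independent of how many samples are active.
    """
    sample_index = {s.sample_id: j for j, s in enumerate(samples)}
    ppm = np.zeros((len(truths), len(samples)))
    for i, t in enumerate(truths):
        rest = sorted(t.active_samples - {t.peak_sample})
        ppm[i, sample_index[t.peak_sample]] = t.max_level
        if rest:
            z = config.noise_sigma * rng.standard_normal(len(rest))
            lv = config.nonpeak_damping * t.max_level * np.exp(z - z.max())
            ppm[i, [sample_index[a] for a in rest]] = lv
    return ppm


def expression_counts(
    ppm: np.ndarray, samples: Sequence[SampleSpec], rng: np.random.Generator
) -> np.ndarray:
    """Poisson tag counts around ppm * N_t / 1e6."""
    N = np.array([s.library_size for s in samples], dtype=float)
    return rng.poisson(ppm * N / 1e6).astype(np.int64)


def initiation_profile(shape: str, d: int, config: CohortConfig | None = None) -> np.ndarray:
    """Per-base initiation probabilities over offsets -d..+d (5' to 3').

    Narrow promoters decay geometrically from a single modal base (IQR
    about 2 at the default decay); broad promoters have a flat-topped
    plateau (IQR about 20 at the default width 41), with faint geometric
    shoulders in both shapes so deep sampling reveals rare distal starts.
    """
    config = config or CohortConfig()
    offsets = np.arange(-d, d + 1)
    if shape == "narrow":
        p = config.narrow_decay ** np.abs(offsets)
    elif shape == "broad":
        half = config.broad_plateau // 2
        p = np.where(np.abs(offsets) <= half, 1.0, 0.6 ** (np.abs(offsets) - half))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return p / p.sum()


def make_tata_pcm() -> PositionCountMatrix:
    """A synthetic TATA-box position count matrix (TBP-like, length 13).

    This is a constructed stand-in with the canonical TATAWAWR core and
    weakly constrained flanks, not a copy of any database matrix; scores
    from it are only used as ranks downstream.
    """
    # columns: counts for A, C, G, T
    counts = np.array(
        [
            [90, 110, 120, 80],     # weak flank
            [70, 80, 60, 190],      # t
            [8, 6, 6, 380],         # T
            [380, 6, 6, 8],         # A
            [30, 5, 5, 360],        # T
            [370, 5, 5, 20],        # A
            [270, 10, 10, 110],     # A/t (W)
            [340, 10, 20, 30],      # A
            [160, 40, 120, 80],     # a/g (R)
            [110, 90, 130, 70],     # weak
            [90, 110, 130, 70],     # weak
            [80, 120, 130, 70],     # weak GC-leaning flank
            [90, 110, 120, 80],     # weak
        ]
    )
    return PositionCountMatrix(name="TATA_synthetic", counts=counts)


_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def _markov_window(
    gc: float, cpg_oe_target: float, length: int, rng: np.random.Generator
) -> str:
    """Sample a sequence with given G+C fraction and CpG observed/expected.

    First-order chain: bases are drawn iid at frequencies (A and T equal,
    C and G equal at gc/2) except that the probability of G after a C is
    scaled so the expected CG dinucleotide frequency is
    cpg_oe_target * (gc/2)^2.
    """
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    q_cg = min(cpg_oe_target * gc / 2.0, 0.9)
    after_c = base_p.copy()
    after_c[2] = 0.0
    after_c = after_c / after_c.sum() * (1.0 - q_cg)
    after_c[2] = q_cg
    seq = np.empty(length, dtype=np.int8)
    u = rng.uniform(size=length)
    cum_base = np.cumsum(base_p)
    cum_after_c = np.cumsum(after_c)
    seq[0] = np.searchsorted(cum_base, u[0])
    for i in range(1, length):
        cum = cum_after_c if seq[i - 1] == 1 else cum_base
        seq[i] = np.searchsorted(cum, u[i])
    return _BASE_ARR[seq].tobytes().decode()


def _plant_tata(seq: str, pcm: PositionCountMatrix, w: int,
                rng: np.random.Generator) -> str:
    """Place a strong motif instance upstream of the window center.

    The motif start sits 31 bases 5' of the anchor (window index w - 31),
    the canonical core-promoter position; each motif base is drawn from
    the corresponding count column.
    """
    start = w - 31
    letters = []
    for k in range(pcm.length):
        sharp = pcm.counts[k].astype(float) ** 2  # strong sites: near-consensus
        p = sharp / sharp.sum()
        letters.append("ACGT"[rng.choice(4, p=p)])
    return seq[:start] + "".join(letters) + seq[start + pcm.length :]


def promoter_window_sequence(
    truth: PromoterTruth,
    pcm: PositionCountMatrix,
    rng: np.random.Generator,
    w: int = 100,
) -> str:
    """Coding-strand window sequence (length 2w+1) honoring the truth."""
    seq = _markov_window(truth.gc_target, truth.cpg_oe_target, 2 * w + 1, rng)
    if truth.has_tata:
        seq = _plant_tata(seq, pcm, w, rng)
    return seq


def render_landscape(
    truths: Sequence[PromoterTruth],
    samples: Sequence[SampleSpec],
    config: CohortConfig,
    seed: int | None = None,
    w: int = 100,
) -> SyntheticDataset:
    """Render the cohort into a tag landscape plus companion files.

    Produces per-sample tag counts at each base (multinomial positions
    from each promoter's initiation profile, Poisson totals), a genome
    FASTA honoring each promoter's CpG class and TATA status, a TSS BED at
    the true anchors, an identity track covering the 100 bases upstream of
    each anchor, and the sample metadata.  Anchors closer than 4d on one
    contig raise :class:`GenerationError`.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng_expr, rng_pos, rng_seq, rng_bg = _streams(seed + 1, 4)
    d = config.d
    pcm = make_tata_pcm()

    by_contig: dict[str, list[PromoterTruth]] = {}
    for t in truths:
        by_contig.setdefault(t.contig, []).append(t)
    for contig, ts in by_contig.items():
        pos = sorted(t.anchor for t in ts)
        if any(b - a <= 4 * d for a, b in zip(pos, pos[1:])):
            raise GenerationError(f"anchors closer than 4d on {contig}")

    # genome background at 40% G+C, then overwrite promoter windows
    genome: dict[str, str] = {}
    for contig, ts in sorted(by_contig.items()):
        size = max(t.anchor for t in ts) + 4 * d + w + 10
        bg = _BASE_ARR[
            rng_bg.choice(4, size=size, p=[0.30, 0.20, 0.20, 0.30])
        ].tobytes().decode()
        arr = list(bg)
        for t in sorted(ts, key=lambda t: t.anchor):
            win = promoter_window_sequence(t, pcm, rng_seq, w)
            if t.strand == "-":
                win = win.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            lo = t.anchor - w
            if lo < 0 or t.anchor + w + 1 > size:
                raise GenerationError("genome too short for promoter window")
            arr[lo : t.anchor + w + 1] = list(win)
        genome[contig] = "".join(arr)

    ppm = true_ppm(truths, samples, config, rng_expr)
    counts = expression_counts(ppm, samples, rng_expr)

    records: list[tuple[str, int, str, str, int]] = []
    profiles = {
        "narrow": initiation_profile("narrow", d, config),
        "broad": initiation_profile("broad", d, config),
    }
    for i, t in enumerate(truths):
        profile = profiles[t.shape]
        row = counts[i]
        active = np.where(row > 0)[0]
        if not len(active):
            continue
        draws = rng_pos.multinomial(row[active], profile)
        sign = 1 if t.strand == "+" else -1
        for a_j, dr in zip(active, draws):
            nz = np.where(dr > 0)[0]
            for k in nz:
                pos = t.anchor + sign * (k - d)
                records.append(
                    (t.contig, int(pos), t.strand, samples[a_j].sample_id, int(dr[k]))
                )
    landscape = TagLandscape.from_records(records, [s.sample_id for s in samples])

    tss_rows = [
        (t.contig, t.anchor, t.anchor + 1, f"tss_{i}", 0.0, t.strand)
        for i, t in enumerate(truths)
    ]
    tss_bed = pd.DataFrame(tss_rows, columns=BED_COLUMNS)

    ident_rows = []
    for t in truths:
        if t.strand == "+":
            lo, hi = t.anchor - 100, t.anchor
        else:
            lo, hi = t.anchor + 1, t.anchor + 101
        ident_rows.append((t.contig, lo, hi, t.identity_pct))
    identity = IdentityTrack(
        pd.DataFrame(ident_rows, columns=["contig", "start", "end", "score"])
    )

    return SyntheticDataset(
        config=config,
        samples=list(samples),
        truths=list(truths),
        landscape=landscape,
        genome=genome,
        tss_bed=tss_bed,
        identity_track=identity,
        pcm=pcm,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every external file of a rendered cohort; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctss_paths = write_ctss(dataset.landscape, outdir / "ctss")
    paths = {"ctss_dir": outdir / "ctss"}
    paths["metadata"] = outdir / "samples.tsv"
    write_metadata(dataset.samples, paths["metadata"])
    paths["genome"] = outdir / "genome.fa"
    write_fasta(dataset.genome, paths["genome"])
    paths["tss_bed"] = outdir / "tss.bed"
    write_bed(dataset.tss_bed, paths["tss_bed"])
    paths["identity"] = outdir / "identity.bed"
    write_identity_bed(dataset.identity_track, paths["identity"])
    paths["pcm"] = outdir / "tata_synthetic.pfm"
    write_pcm(dataset.pcm, paths["pcm"])
    paths.update({f"ctss:{k}": v for k, v in ctss_paths.items()})
    return paths


def generate_bias_counts(
    n_promoters: int = 200,
    n_samples: int = 120,
    tags_per_promoter: int = 150_000,
    library_size_median: float = 1_000_000.0,
    library_size_sigma: float = 0.8,
    noise_sigma: float = 0.5,
    seed: int = 0,
):
    """A cohort of broad, deeply sampled promoters for the depth-bias
    demonstration.

    Every promoter is active in all samples with lognormal level noise;
    each promoter's total tag count is exact, so all promoters pass the
    eligibility threshold of the bias experiment.  Returns an
    :class:`~cageprom.expression_metrics.ExpressionMatrix`.
    """
    from .expression_metrics import ExpressionMatrix

    rng_n, rng_x = _streams(seed, 2)
    N = np.maximum(
        np.round(
            library_size_median
            * np.exp(library_size_sigma * rng_n.standard_normal(n_samples))
        ).astype(np.int64),
        10_000,
    )
    counts = np.zeros((n_promoters, n_samples), dtype=np.int64)
    for g in range(n_promoters):
        levels = np.exp(noise_sigma * rng_x.standard_normal(n_samples))
        p = levels * N
        counts[g] = rng_x.multinomial(tags_per_promoter, p / p.sum())
    return ExpressionMatrix(
        counts=counts,
        library_sizes=N,
        sample_ids=[f"s{i:04d}" for i in range(n_samples)],
        promoter_ids=[f"b{i}" for i in range(n_promoters)],
        is_germ=np.zeros(n_samples, dtype=bool),
    )
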