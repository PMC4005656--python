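"""Readers, writers and replicate pooling for CAGE-style inputs.

All coordinates are 0-based, half-open internally.  A CTSS position is the
5'-most genomic base of a tag on its own strand.  The formats handled here:

* CTSS TSV, one file per sample: ``contig  position  strand  count``.
* Sample metadata TSV: ``sample_id  library_size  ontology_terms  is_germ``
  with ontology terms joined by ``;``.
* 6-column BED (0-based half-open, strand column used).
* FASTA (case-insensitive; non-ACGT letters become ``N``).
* JASPAR position count matrices (4 base rows, with or without brackets).
* Per-base identity tracks as BED with a score column in [0, 100], or
  axt-style pairwise alignment blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CageIOError",
    "SampleSpec",
    "TagLandscape",
    "PositionCountMatrix",
    "IdentityTrack",
    "read_ctss",
    "write_ctss",
    "read_metadata",
    "write_metadata",
    "pool_replicates",
    "read_pcm",
    "write_pcm",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_identity_bed",
    "write_identity_bed",
    "read_axt",
]

STRANDS = ("+", "-")
BASES = "ACGT"


class CageIOError(ValueError):
    """Raised when an input file does not parse or violates an invariant."""


@dataclass(frozen=True)
class SampleSpec:
    """One CAGE library: id, mapped-tag count N_t, ontology terms, germ flag."""

    sample_id: str
    library_size: int
    ontology_terms: frozenset[str] = frozenset()
    is_germ: bool = False

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise CageIOError(
                f"sample {self.sample_id!r}: library_size must be >= 1, "
                f"got {self.library_size}"
            )


class TagLandscape:
    """Per-base, per-strand, per-sample tag counts.

    Backed by a long-format DataFrame with columns
    ``contig, pos, strand, sample_id, count`` plus a fixed sample order.
    Counts are non-negative integers; strands are kept separate.
    """

    COLUMNS = ["contig", "pos", "strand", "sample_id", "count"]

    def __init__(self, df: pd.DataFrame, sample_ids: Sequence[str]):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise CageIOError(f"landscape frame missing columns: {sorted(missing)}")
        bad = set(df["sample_id"]) - set(sample_ids)
        if bad:
            raise CageIOError(f"landscape has unknown sample ids: {sorted(bad)}")
        if len(df) and (df["count"] < 0).any():
            raise CageIOError("negative tag count in landscape")
        self.df = df[self.COLUMNS].reset_index(drop=True)
        self.sample_ids = list(sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagLandscape):
            return NotImplemented
        if self.sample_ids != other.sample_ids:
            return False
        key = ["contig", "strand", "pos", "sample_id"]
        a = self.df.sort_values(key).reset_index(drop=True)
        b = other.df.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    def totals(self) -> pd.Series:
        """Total tag count per sample, in sample order (zeros included)."""
        t = self.df.groupby("sample_id")["count"].sum()
        return t.reindex(self.sample_ids, fill_value=0)

    def total(self, sample_id: str) -> int:
        return int(self.totals().get(sample_id, 0))

    def keys(self) -> list[tuple[str, str]]:
        if not len(self.df):
            return []
        pairs = self.df[["contig", "strand"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def pooled(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions and counts on (contig, strand), summed over samples."""
        sub = self.df[(self.df["contig"] == contig) & (self.df["strand"] == strand)]
        g = sub.groupby("pos")["count"].sum().sort_index()
        return g.index.to_numpy(dtype=np.int64), g.to_numpy(dtype=np.int64)

    def sample_counts_at(
        self, contig: str, strand: str, positions: np.ndarray
    ) -> pd.DataFrame:
        """Wide table (position x sample) of counts at the given positions."""
        sub = self.df[
            (self.df["contig"] == contig)
            & (self.df["strand"] == strand)
            & (self.df["pos"].isin(positions))
        ]
        wide = sub.pivot_table(
            index="pos", columns="sample_id", values="count", aggfunc="sum", fill_value=0
        )
        return wide.reindex(columns=self.sample_ids, fill_value=0)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str, str, int]], sample_ids: Sequence[str]
    ) -> "TagLandscape":
        df = pd.DataFrame(list(records), columns=cls.COLUMNS)
        return cls(df, sample_ids)


def _parse_ctss_file(path: Path, sample_id: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CageIOError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            contig, pos_s, strand, count_s = parts
            if strand not in STRANDS:
                raise CageIOError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise CageIOError(f"{path}:{lineno}: non-integer field") from exc
            if pos < 0:
                raise CageIOError(f"{path}:{lineno}: negative position {pos}")
            if count < 0:
                raise CageIOError(f"{path}:{lineno}: negative count {count}")
            rows.append((contig, pos, strand, sample_id, count))
    return pd.DataFrame(rows, columns=TagLandscape.COLUMNS)


def read_ctss(
    paths: Mapping[str, str | Path],
    samples: Sequence[SampleSpec],
    contig_lengths: Mapping[str, int] | None = None,
) -> TagLandscape:
    """Read one CTSS file per sample into a :class:`TagLandscape`.

    ``paths`` maps sample_id -> file path; every id must appear in ``samples``.
    If ``contig_lengths`` is given, positions are checked against it.
    """
    sample_ids = [s.sample_id for s in samples]
    unknown = set(paths) - set(sample_ids)
    if unknown:
        raise CageIOError(f"CTSS files for unknown samples: {sorted(unknown)}")
    frames = []
    for sid in sample_ids:
        if sid not in paths:
            continue
        frames.append(_parse_ctss_file(Path(paths[sid]), sid))
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TagLandscape.COLUMNS)
    )
    if contig_lengths is not None and len(df):
        for contig, sub in df.groupby("contig"):
            if contig not in contig_lengths:
                raise CageIOError(f"unknown contig {contig!r} in CTSS input")
            if (sub["pos"] >= contig_lengths[contig]).any():
                raise CageIOError(f"position outside contig {contig!r}")
    return TagLandscape(df, sample_ids)


def write_ctss(landscape: TagLandscape, outdir: str | Path) -> dict[str, Path]:
    """Write one ``<sample_id>.ctss.tsv`` per sample; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    by_sample = dict(tuple(landscape.df.groupby("sample_id")))
    for sid in landscape.sample_ids:
        path = outdir / f"{sid}.ctss.tsv"
        sub = by_sample.get(sid)
        with open(path, "w") as fh:
            if sub is not None:
                sub = sub.sort_values(["contig", "strand", "pos"])
                for row in sub.itertuples(index=False):
                    fh.write(f"{row.contig}\t{row.pos}\t{row.strand}\t{row.count}\n")
        paths[sid] = path
    return paths


def read_metadata(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "library_size", "ontology_terms", "is_germ"}
    missing = required - set(df.columns)
    if missing:
        raise CageIOError(f"{path}: metadata missing columns {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        terms = frozenset(
            t for t in str(row.ontology_terms).split(";") if t and t != "nan"
        )
        specs.append(
            SampleSpec(
                sample_id=row.sample_id,
                library_size=int(row.library_size),
                ontology_terms=terms,
                is_germ=str(row.is_germ).lower() in ("1", "true", "yes"),
            )
        )
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise CageIOError(f"{path}: duplicate sample ids")
    return specs


def write_metadata(samples: Sequence[SampleSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlibrary_size\tontology_terms\tis_germ\n")
        for s in samples:
            terms = ";".join(sorted(s.ontology_terms))
            fh.write(f"{s.sample_id}\t{s.library_size}\t{terms}\t{int(s.is_germ)}\n")


def pool_replicates(
    landscape: TagLandscape, samples: Sequence[SampleSpec]
) -> tuple[TagLandscape, list[SampleSpec]]:
    """Pool samples whose ontology term sets are identical.

    Replicates are detected by exact set equality of their "is_a" terms
    (no ontology-graph reasoning).  Pooled counts are summed per position,
    the pooled library size is the sum of the members' sizes, and the germ
    flag is true if any member is germ.  Samples without replicates pass
    through unchanged.  Total tag count across the cohort is conserved.
    """
    groups: dict[frozenset[str], list[SampleSpec]] = {}
    order: list[frozenset[str]] = []
    for s in samples:
        key = s.ontology_terms
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)

    pooled_specs: list[SampleSpec] = []
    rename: dict[str, str] = {}
    for key in order:
        members = groups[key]
        if len(members) == 1:
            pooled_specs.append(members[0])
            rename[members[0].sample_id] = members[0].sample_id
        else:
            new_id = "+".join(m.sample_id for m in members)
            pooled_specs.append(
                SampleSpec(
                    sample_id=new_id,
                    library_size=sum(m.library_size for m in members),
                    ontology_terms=key,
                    is_germ=any(m.is_germ for m in members),
                )
            )
            for m in members:
                rename[m.sample_id] = new_id

    df = landscape.df.copy()
    if len(df):
        df["sample_id"] = df["sample_id"].map(rename)
        df = (
            df.groupby(["contig", "pos", "strand", "sample_id"], as_index=False)["count"]
            .sum()
        )
    pooled = TagLandscape(df, [s.sample_id for s in pooled_specs])
    return pooled, pooled_specs


@dataclass
class PositionCountMatrix:
    """A JASPAR-style position count matrix: counts[k, x] for bases ACGT."""

    name: str
    counts: np.ndarray  # shape (K, 4), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise CageIOError("PCM counts must have shape (K, 4)")
        if (self.counts < 0).any():
            raise CageIOError("PCM counts must be non-negative")
        if (self.counts.sum(axis=1) <= 0).any():
            raise CageIOError("every PCM column must have a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


_PCM_ROW = re.compile(r"^([ACGTacgt])\s*[:|]?\s*\[?\s*([\d\s.]+?)\s*\]?\s*$")


def read_pcm(path: str | Path) -> PositionCountMatrix:
    """Read a JASPAR-format PCM (4 base rows, optionally bracketed)."""
    name = Path(str(path)).stem
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            m = _PCM_ROW.match(line)
            if not m:
                raise CageIOError(f"{path}: unparseable PCM row: {line!r}")
            base = m.group(1).upper()
            rows[base] = [int(float(v)) for v in m.group(2).split()]
    if set(rows) != set(BASES):
        raise CageIOError(f"{path}: PCM must have exactly rows A, C, G, T")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise CageIOError(f"{path}: PCM rows have unequal lengths")
    counts = np.column_stack([rows[b] for b in BASES])
    return PositionCountMatrix(name=name, counts=counts)


def write_pcm(pcm: PositionCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pcm.name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(str(int(v)) for v in pcm.counts[:, i])
            fh.write(f"{base} [ {vals} ]\n")


_NON_ACGT = re.compile(r"[^ACGT]")


def clean_sequence(seq: str) -> str:
    """Uppercase and replace every non-ACGT letter with N."""
    return _NON_ACGT.sub("N", seq.upper())


def read_fasta(path: str | Path) -> dict[str, str]:
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = clean_sequence(str(rec.seq))
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at 60; kept for signature stability


BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED file (0-based, half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=BED_COLUMNS,
        dtype={"contig": str, "start": np.int64, "end": np.int64,
               "name": str, "score": float, "strand": str},
    )
    if len(df):
        if not df["strand"].isin(STRANDS).all():
            raise CageIOError(f"{path}: BED strand column must be + or -")
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            raise CageIOError(f"{path}: invalid BED intervals")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


class IdentityTrack:
    """Per-base cross-species identity in [0, 100] as genomic intervals.

    Bases not covered by any interval are treated as unaligned (0% identity),
    matching the convention that unaligned bases count in the denominator.
    """

    def __init__(self, intervals: pd.DataFrame):
        # columns: contig, start, end, score
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for contig, sub in intervals.groupby("contig"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            scores = sub["score"].to_numpy(float)
            if (scores < 0).any() or (scores > 100).any():
                raise CageIOError("identity scores must lie in [0, 100]")
            if (starts[1:] < ends[:-1]).any():
                raise CageIOError(f"overlapping identity intervals on {contig}")
            self._by_contig[str(contig)] = (starts, ends, scores)
        self.intervals = intervals.reset_index(drop=True)

    def mean_identity(self, contig: str, start: int, end: int) -> float:
        """Mean per-base identity over [start, end); uncovered bases score 0."""
        if end <= start:
            raise CageIOError("empty span for identity lookup")
        if contig not in self._by_contig:
            return 0.0
        starts, ends, scores = self._by_contig[contig]
        total = 0.0
        for s, e, sc in zip(starts, ends, scores):
            lo = max(s, start)
            hi = min(e, end)
            if hi > lo:
                total += sc * (hi - lo)
        return total / (end - start)


def read_identity_bed(path: str | Path) -> IdentityTrack:
    df = read_bed(path)
    return IdentityTrack(df[["contig", "start", "end", "score"]])


def write_identity_bed(track: IdentityTrack, path: str | Path) -> None:
    df = track.intervals.copy()
    df["name"] = "identity"
    df["strand"] = "+"
    write_bed(df, path)


def read_axt(path: str | Path) -> IdentityTrack:
    """Build a per-base identity track from axt-style alignment blocks.

    Each block is a header line
    ``idx primary_contig start end secondary_contig start end strand score``
    (1-based inclusive primary coordinates, as in UCSC axt) followed by the
    primary and secondary aligned sequences.  Per primary base, identity is
    100 when the aligned secondary base matches (case-insensitive), else 0;
    gap columns in the primary sequence consume no primary base.
    """
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        header = lines[i].split()
        if len(header) < 7:
            raise CageIOError(f"{path}: bad axt header: {lines[i]!r}")
        contig = header[1]
        start = int(header[2]) - 1  # axt is 1-based inclusive
        if i + 2 >= len(lines):
            raise CageIOError(f"{path}: truncated axt block")
        primary = lines[i + 1].upper()
        secondary = lines[i + 2].upper()
        if len(primary) != len(secondary):
            raise CageIOError(f"{path}: axt sequences differ in length")
        pos = start
        for p, s in zip(primary, secondary):
            if p == "-":
                continue
            ident = 100.0 if (p == s and p in BASES) else 0.0
            rows.append((contig, pos, pos + 1, ident))
            pos += 1
        i += 3
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "score"])
    # merge adjacent equal-score single-base intervals for compactness
    if len(df):
        merged = []
        for (contig,), sub in df.groupby(["contig"]):
            sub = sub.sort_values("start")
            cur = None
            for row in sub.itertuples(index=False):
                if (
                    cur is not None
                    and row.start == cur[2]
                    and row.score == cur[3]
                ):
                    cur[2] = row.end
                else:
                    if cur is not None:
                        merged.append(tuple(cur))
                    cur = [contig, row.start, row.end, row.score]
            if cur is not None:
                merged.append(tuple(cur))
        df = pd.DataFrame(merged, columns=["contig", "start", "end", "score"])
    return IdentityTrack(df)
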