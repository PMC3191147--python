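"""Mapping of observed 17-bp tag reads and per-site count matrices.

Quality-aware short-read mappers grade placements by mapping quality, and
MMSDK analyses conventionally keep two tiers: quality > 0 (MQ0, low
confidence — an ambiguously placed read is put at one of the equally best
positions at random and earns quality zero) and quality > 20 (MQ20, high
confidence).  Base qualities are not part of this package's inputs, so the
tiers are modelled directly on the virtual library: an exact match to a genome-unique virtual
tag is *high* confidence; any other resolvable placement (exact match to a
duplicated tag, or a single/randomly chosen best hit at Hamming distance 1)
is *low* confidence; everything else is unmapped.  Reads are matched in both
orientations; a hit in both orientations is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome_assets import reverse_complement
from .virtual_library import TAG_LENGTH, TagLibrary, VirtualTag

logger = logging.getLogger(__name__)

TIER_HIGH = "high"
TIER_LOW = "low"
TIER_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class TagRead:
    read_id: str
    sequence: str  # length 17 over {A,C,G,T,N}
    library_id: str


@dataclass
class ReadStats:
    n_accepted: int = 0
    n_rejected_short: int = 0
    n_truncated: int = 0


@dataclass(frozen=True)
class TagAssignment:
    read_id: str
    library_id: str
    mlu_site_id: str | None
    tier: str
    mismatches: int


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            return "plain"
    return "empty"


def read_tag_sequences(
    path: str | Path, library_id: str
) -> tuple[list[TagRead], ReadStats]:
    """Read 17-bp tag reads from FASTA, FASTQ or one-sequence-per-line text.

    Longer reads are truncated to their first 17 bases (counted); shorter
    ones are rejected (counted).
    """
    path = Path(path)
    fmt = _sniff_format(path)
    stats = ReadStats()
    reads: list[TagRead] = []

    def add(read_id: str, seq: str) -> None:
        seq = seq.upper()
        if len(seq) < TAG_LENGTH:
            stats.n_rejected_short += 1
            return
        if len(seq) > TAG_LENGTH:
            stats.n_truncated += 1
            seq = seq[:TAG_LENGTH]
        stats.n_accepted += 1
        reads.append(TagRead(read_id, seq, library_id))

    if fmt == "empty":
        logger.warning("no reads found in %s", path)
    elif fmt in ("fasta", "fastq"):
        for rec in SeqIO.parse(str(path), fmt):
            add(rec.id, str(rec.seq))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if line:
                    add(f"{library_id}.{i}", line)
    if stats.n_truncated:
        logger.info("%s: truncated %d reads to 17 bp", path, stats.n_truncated)
    return reads, stats


class TagIndex:
    """Exact-match index over all virtual tags (unique + duplicated)."""

    def __init__(self, library: TagLibrary):
        self.lookup: dict[str, list[VirtualTag]] = {}
        for tag in list(library.mappable) + list(library.ambiguous):
            self.lookup.setdefault(tag.sequence, []).append(tag)

    def exact_hits(self, seq: str) -> list[VirtualTag]:
        hits = list(self.lookup.get(seq, ()))
        rc = reverse_complement(seq)
        if rc != seq:
            hits += self.lookup.get(rc, ())
        return hits

    def one_mismatch_hits(self, seq: str) -> list[VirtualTag]:
        hits: list[VirtualTag] = []
        seen: set[int] = set()
        for query in (seq, reverse_complement(seq)):
            for i in range(TAG_LENGTH):
                orig = query[i]
                for base in "ACGT":
                    if base == orig:
                        continue
                    variant = query[:i] + base + query[i + 1 :]
                    for tag in self.lookup.get(variant, ()):
                        if id(tag) not in seen:
                            seen.add(id(tag))
                            hits.append(tag)
        return hits


def map_tags(
    reads: Sequence[TagRead],
    library: TagLibrary,
    seed: int = 0,
    max_mismatches: int = 1,
) -> list[TagAssignment]:
    """Assign reads to MluI sites with high/low/unmapped tiers.

    Exact single hit on a unique tag -> high (0 mismatches).  Exact hit on a
    duplicated tag, multiple exact hits, or a Hamming-distance-1 hit -> low;
    ambiguous candidates are resolved uniformly at random with the seeded
    generator (same seed, same reads => identical assignments).  Reads with
    an N, or >= 2 mismatches from every virtual tag, are unmapped.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    index = TagIndex(library)
    rng = np.random.default_rng(seed)
    out: list[TagAssignment] = []
    for read in reads:
        if "N" in read.sequence:
            out.append(TagAssignment(read.read_id, read.library_id, None,
                                     TIER_UNMAPPED, 0))
            continue
        hits = index.exact_hits(read.sequence)
        mismatches = 0
        if not hits and max_mismatches >= 1:
            hits = index.one_mismatch_hits(read.sequence)
            mismatches = 1
        if not hits:
            out.append(TagAssignment(read.read_id, read.library_id, None,
                                     TIER_UNMAPPED, 0))
            continue
        if len(hits) == 1 and mismatches == 0 and hits[0].unique:
            tier = TIER_HIGH
            target = hits[0]
        else:
            tier = TIER_LOW
            target = hits[0] if len(hits) == 1 else hits[int(rng.integers(len(hits)))]
        out.append(TagAssignment(read.read_id, read.library_id,
                                 target.mlu_site_id, tier, mismatches))
    return out


@dataclass
class TagCountMatrix:
    """Raw per-site, per-library tag counts for one confidence tier.

    ``counts`` is a sites x libraries DataFrame; ``library_totals`` holds the
    total mapped tags per library at this tier (all sites, so normalization
    is insensitive to row filtering).
    """

    counts: pd.DataFrame
    library_totals: pd.Series
    tier: str

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, site_ids: Sequence[str]) -> "TagCountMatrix":
        return TagCountMatrix(self.counts.loc[list(site_ids)],
                              self.library_totals, self.tier)

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"#{header}\n")
            self.counts.to_csv(fh, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path: str | Path, tier: str,
                 library_totals: pd.Series | None = None) -> "TagCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="site_id", comment="#")
        totals = (library_totals if library_totals is not None
                  else counts.sum(axis=0))
        return cls(counts, totals, tier)


def build_count_matrix(
    assignments: Sequence[TagAssignment],
    tier: str,
    site_ids: Sequence[str] | None = None,
    library_ids: Sequence[str] | None = None,
) -> TagCountMatrix:
    """Aggregate assignments into a per-site count matrix.

    ``tier="high"`` counts only high-tier assignments (MQ20 analog);
    ``tier="low"`` counts high + low (MQ0 analog: the inclusive set with
    mapping quality above zero).  A site's (up to two) tags are aggregated.
    """
    if tier not in (TIER_HIGH, TIER_LOW):
        raise ValueError(f"tier must be 'high' or 'low', got {tier!r}")
    accepted = {TIER_HIGH} if tier == TIER_HIGH else {TIER_HIGH, TIER_LOW}
    libs_seen = sorted({a.library_id for a in assignments})
    if library_ids is None:
        library_ids = libs_seen
    else:
        unknown = set(libs_seen) - set(library_ids)
        if unknown:
            raise ValueError(f"assignments reference unknown libraries: "
                             f"{sorted(unknown)}")
    mapped = [a for a in assignments if a.tier in accepted]
    sites_seen = sorted({a.mlu_site_id for a in mapped})
    if site_ids is None:
        site_ids = sites_seen
    site_idx = {s: i for i, s in enumerate(site_ids)}
    lib_idx = {l: i for i, l in enumerate(library_ids)}
    arr = np.zeros((len(site_ids), len(library_ids)), dtype=int)
    totals = np.zeros(len(library_ids), dtype=int)
    for a in mapped:
        totals[lib_idx[a.library_id]] += 1
        si = site_idx.get(a.mlu_site_id)
        if si is not None:
            arr[si, lib_idx[a.library_id]] += 1
    counts = pd.DataFrame(arr, index=list(site_ids), columns=list(library_ids))
    return TagCountMatrix(counts, pd.Series(totals, index=list(library_ids)),
                          tier)


def count_empty_sites(matrix: TagCountMatrix) -> tuple[int, float]:
    """Empty sites (zero in every library) and mappable-site percentage.

    The matrix must cover the full site universe of interest (empty rows
    included).  The percentage is rounded to one decimal, the way the
    library summaries print it.
    """
    from .summaries import percent

    n_sites = len(matrix.counts)
    if n_sites == 0:
        raise ValueError("empty count matrix")
    n_empty = int((matrix.counts.sum(axis=1) == 0).sum())
    return n_empty, percent(n_sites - n_empty, n_sites)


def mapping_summary(
    assignments: Sequence[TagAssignment], stats: dict[str, ReadStats]
) -> pd.DataFrame:
    """Per-library mapping summary (accepted / high / low / unmapped)."""
    rows = {}
    for lib, st in stats.items():
        rows[lib] = {"accepted": st.n_accepted, "rejected_short":
                     st.n_rejected_short, "mapped_high": 0, "mapped_low": 0,
                     "unmapped": 0}
    for a in assignments:
        key = {"high": "mapped_high", "low": "mapped_low",
               "unmapped": "unmapped"}[a.tier]
        rows.setdefault(a.library_id, {"accepted": 0, "rejected_short": 0,
                                       "mapped_high": 0, "mapped_low": 0,
                                       "unmapped": 0})[key] += 1
    return pd.DataFrame(rows).T.sort_index()
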