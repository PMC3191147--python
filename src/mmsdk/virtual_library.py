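"""Virtual MluI/NlaIII tag library construction.

The assay digests genomic DNA with the methylation-sensitive mapping enzyme
MluI (ACGCGT, cuts only unmethylated sites), fragments with the anchoring
enzyme NlaIII (CATG) and releases a 17-bp tag adjacent to the NlaIII site
with the type IIS tagging enzyme MmeI.  Assuming every site is unmethylated,
the same digestion can be simulated on the reference genome; the resulting
17-mers form the *virtual tag library* used as the mapping reference.

Conventions (frozen):

* A fragment runs from an MluI site to the nearest NlaIII site on each side.
  The left fragment is ``[nla.start, mlu.start + 6)`` and the right fragment
  ``[mlu.start, nla.start + 4)`` — each fragment carries the full MluI motif
  on its MluI side and the full CATG on its NlaIII side.
* When two adjacent MluI sites have no NlaIII motif between them, their two
  facing fragments are replaced by one shared ``mlu_mlu`` fragment carrying
  no NlaIII end and therefore no tag; it is excluded from the mappable
  reference.  Each such NlaIII-free interval hence reduces the naive
  two-fragments-per-site count by exactly two:
  ``mappable = 2 * n_sites - 2 * n_nla_free_intervals`` (minus any
  chromosome-end losses, which are logged and reported separately).
* The virtual tag is the 17 bases immediately interior to the CATG motif,
  read from the CATG boundary toward the MluI end; for right-side fragments
  this read direction is the minus strand and the tag is stored
  reverse-complemented with ``strand="-"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_assets import (
    GenomeSequence,
    IntervalAnnotation,
    genome_dict,
    reverse_complement,
)

logger = logging.getLogger(__name__)

MLUI_MOTIF = "ACGCGT"
NLAIII_MOTIF = "CATG"
TAG_LENGTH = 17

# Both motifs are reverse-complement palindromes, so a plus-strand scan is
# exhaustive.  Guard the assumption at import time.
assert reverse_complement(MLUI_MOTIF) == MLUI_MOTIF
assert reverse_complement(NLAIII_MOTIF) == NLAIII_MOTIF


@dataclass(frozen=True)
class RestrictionSite:
    chrom_id: str
    start: int  # 0-based position of the motif's first base
    enzyme: str  # "MluI" | "NlaIII"
    motif: str

    @property
    def end(self) -> int:
        return self.start + len(self.motif)

    @property
    def site_id(self) -> str:
        return f"{self.chrom_id}:{self.start}"


@dataclass(frozen=True)
class VirtualFragment:
    fragment_id: str
    chrom_id: str
    start: int
    end: int
    mlu_site_ids: tuple[str, ...]  # 1 site, or 2 for mlu_mlu
    side: str  # "left" | "right" | "mlu_mlu"
    has_nla_end: bool


@dataclass(frozen=True)
class VirtualTag:
    tag_id: str
    sequence: str
    fragment_id: str
    mlu_site_id: str
    strand: str  # "+" | "-"
    unique: bool = True


@dataclass(frozen=True)
class CGIRegion:
    """CpG island: GC > 0.5, observed/expected CpG > 0.6, length > 500 bp."""

    chrom_id: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float


@dataclass(frozen=True)
class SiteAnnotation:
    mlu_site_id: str
    in_cgi_promoter: bool
    repeat_class: str | None
    nearest_gene: str | None
    distance_to_gene: int | None


class TagLibrary(NamedTuple):
    """Mappable (unique) virtual tags plus the ambiguous side list."""

    mappable: list[VirtualTag]
    ambiguous: list[VirtualTag]


@dataclass
class DigestionSummary:
    """Accounting of one in-silico digestion."""

    n_mlu_sites: int = 0
    n_nla_free_intervals: int = 0
    n_end_losses: int = 0
    n_fragments_mappable: int = 0
    n_fragments_total: int = 0
    dropped_short: int = 0
    dropped_n: int = 0


def find_sites(seq: GenomeSequence, motif: str) -> list[RestrictionSite]:
    """All exact plus-strand occurrences of ``motif``, overlapping included.

    N never matches a motif base.  For reverse-complement-palindromic motifs
    (the MluI and NlaIII recognition sequences) the plus-strand scan covers
    both strands.
    """
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    enzyme = {MLUI_MOTIF: "MluI", NLAIII_MOTIF: "NlaIII"}.get(motif, motif)
    sites = []
    pos = seq.sequence.find(motif)
    while pos != -1:
        sites.append(RestrictionSite(seq.chrom_id, pos, enzyme, motif))
        pos = seq.sequence.find(motif, pos + 1)
    return sites


def mappable_fragment_count(n_mlu_sites: int, n_nla_free_intervals: int) -> int:
    """Size of the mappable virtual library under the frozen counting rule.

    Every MluI site contributes one fragment per side; an adjacent-MluI
    interval with no internal NlaIII site collapses the two facing fragments
    into one untagged shared fragment that is dropped from the mappable
    reference, removing exactly two fragments.
    """
    if n_mlu_sites < 0 or n_nla_free_intervals < 0:
        raise ValueError("counts must be nonnegative")
    return 2 * n_mlu_sites - 2 * n_nla_free_intervals


def _check_sorted(sites: Sequence[RestrictionSite]) -> None:
    keys = [(s.chrom_id, s.start) for s in sites]
    if keys != sorted(keys):
        raise ValueError("restriction sites must be sorted by (chrom, start)")


def build_virtual_fragments(
    genome: Iterable[GenomeSequence],
    mlu_sites: Sequence[RestrictionSite],
    nla_sites: Sequence[RestrictionSite],
    summary: DigestionSummary | None = None,
) -> list[VirtualFragment]:
    """Derive MluI-anchored virtual fragments from sorted site lists.

    Per MluI site: a left fragment back to the nearest upstream CATG and a
    right fragment forward to the nearest downstream CATG.  Adjacent MluI
    sites with no CATG between them share a single ``mlu_mlu`` fragment.  A
    missing CATG before the chromosome start / after its end yields no
    fragment on that side (counted as an end loss).
    """
    _check_sorted(mlu_sites)
    _check_sorted(nla_sites)
    chroms = genome_dict(genome)
    nla_by_chrom: dict[str, np.ndarray] = {}
    for s in nla_sites:
        nla_by_chrom.setdefault(s.chrom_id, []).append(s.start)  # type: ignore[attr-defined]
    nla_by_chrom = {c: np.asarray(v) for c, v in nla_by_chrom.items()}

    mlu_by_chrom: dict[str, list[RestrictionSite]] = {}
    for s in mlu_sites:
        mlu_by_chrom.setdefault(s.chrom_id, []).append(s)

    fragments: list[VirtualFragment] = []
    summary = summary if summary is not None else DigestionSummary()
    summary.n_mlu_sites += len(mlu_sites)

    for chrom_id, sites in mlu_by_chrom.items():
        if chrom_id not in chroms:
            raise ValueError(f"sites reference unknown chromosome {chrom_id!r}")
        chrom_len = len(chroms[chrom_id])
        nla = nla_by_chrom.get(chrom_id, np.empty(0, dtype=int))
        starts = np.array([s.start for s in sites])
        # index of first NlaIII at or after each MluI start; motifs cannot
        # overlap, so strict before/after comparisons on starts suffice
        right_idx = np.searchsorted(nla, starts, side="left")

        for i, site in enumerate(sites):
            sid = site.site_id
            # shared fragment with the previous MluI site?
            prev = sites[i - 1] if i > 0 else None
            left_nla_idx = right_idx[i] - 1
            has_left_nla = left_nla_idx >= 0
            left_nla = int(nla[left_nla_idx]) if has_left_nla else None

            if prev is not None and (left_nla is None or left_nla < prev.start):
                # no CATG between prev and this site: one shared fragment
                summary.n_nla_free_intervals += 1
                fragments.append(
                    VirtualFragment(
                        fragment_id=f"{chrom_id}:{prev.start}-{site.end}:mlu_mlu",
                        chrom_id=chrom_id,
                        start=prev.start,
                        end=site.end,
                        mlu_site_ids=(prev.site_id, sid),
                        side="mlu_mlu",
                        has_nla_end=False,
                    )
                )
            elif left_nla is not None:
                fragments.append(
                    VirtualFragment(
                        fragment_id=f"{chrom_id}:{left_nla}-{site.end}:left",
                        chrom_id=chrom_id,
                        start=left_nla,
                        end=site.end,
                        mlu_site_ids=(sid,),
                        side="left",
                        has_nla_end=True,
                    )
                )
            else:
                summary.n_end_losses += 1

            # right fragment, unless the next MluI shares an NlaIII-free
            # interval with this one (handled by the next iteration's branch)
            nxt = sites[i + 1] if i + 1 < len(sites) else None
            ri = right_idx[i]
            has_right_nla = ri < len(nla)
            right_nla = int(nla[ri]) if has_right_nla else None
            if nxt is not None and (right_nla is None or right_nla > nxt.start):
                continue  # shared mlu_mlu fragment emitted at i+1
            if right_nla is not None:
                end = right_nla + len(NLAIII_MOTIF)
                if end > chrom_len:
                    raise AssertionError("fragment beyond chromosome end")
                fragments.append(
                    VirtualFragment(
                        fragment_id=f"{chrom_id}:{site.start}-{end}:right",
                        chrom_id=chrom_id,
                        start=site.start,
                        end=end,
                        mlu_site_ids=(sid,),
                        side="right",
                        has_nla_end=True,
                    )
                )
            else:
                summary.n_end_losses += 1

    summary.n_fragments_total += len(fragments)
    summary.n_fragments_mappable += sum(f.has_nla_end for f in fragments)
    return fragments


def extract_virtual_tags(
    fragments: Iterable[VirtualFragment],
    genome: Iterable[GenomeSequence],
    summary: DigestionSummary | None = None,
) -> list[VirtualTag]:
    """17-bp virtual tags interior to each fragment's CATG end.

    Left fragments read the plus strand from ``nla.start + 4``; right
    fragments read the 17 bases ending at ``nla.start`` on the minus strand
    (stored reverse-complemented).  Fragments with interior < 17 bases or an
    N inside the 17-mer yield no tag; ``mlu_mlu`` fragments never do.
    """
    chroms = genome_dict(genome)
    tags: list[VirtualTag] = []
    summary = summary if summary is not None else DigestionSummary()
    for frag in fragments:
        if not frag.has_nla_end:
            continue
        seq = chroms[frag.chrom_id].sequence
        if frag.side == "left":
            # fragment = [nla.start, mlu.start + 6)
            interior = (frag.end - len(MLUI_MOTIF)) - (frag.start + len(NLAIII_MOTIF))
            tag_seq = seq[frag.start + 4 : frag.start + 4 + TAG_LENGTH]
            strand = "+"
        elif frag.side == "right":
            # fragment = [mlu.start, nla.start + 4)
            nla_start = frag.end - len(NLAIII_MOTIF)
            interior = nla_start - (frag.start + len(MLUI_MOTIF))
            tag_seq = reverse_complement(seq[nla_start - TAG_LENGTH : nla_start])
            strand = "-"
        else:  # pragma: no cover - defensive
            continue
        if interior < TAG_LENGTH:
            summary.dropped_short += 1
            logger.debug("fragment %s interior %d < 17: no tag",
                         frag.fragment_id, interior)
            continue
        if "N" in tag_seq:
            summary.dropped_n += 1
            logger.debug("fragment %s tag contains N: dropped", frag.fragment_id)
            continue
        tags.append(
            VirtualTag(
                tag_id=f"{frag.fragment_id}:tag",
                sequence=tag_seq,
                fragment_id=frag.fragment_id,
                mlu_site_id=frag.mlu_site_ids[0],
                strand=strand,
            )
        )
    return tags


def filter_unique_tags(tags: Sequence[VirtualTag]) -> TagLibrary:
    """Split tags into genome-unique (mappable) and duplicated 17-mers.

    All copies of a duplicated 17-mer are removed from the mappable library
    (unambiguous mapping requires uniqueness) but kept in a side list so the
    low-confidence mapper can still assign reads to them ambiguously.
    """
    counts = Counter(t.sequence for t in tags)
    mappable = [replace(t, unique=True) for t in tags if counts[t.sequence] == 1]
    ambiguous = [replace(t, unique=False) for t in tags if counts[t.sequence] > 1]
    return TagLibrary(mappable, ambiguous)


_BASE_CODES = {"A": 65, "C": 67, "G": 71, "T": 84, "N": 78}


def _obs_exp_cpg(n_cpg: int, n_c: int, n_g: int, length: int) -> float:
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cpg * length / (n_c * n_g)


def predict_cgi_promoters(
    genome: Iterable[GenomeSequence], window: int = 501
) -> list[CGIRegion]:
    """Predict CpG islands with a sliding window of 501 bp, step 1.

    A window passes when GC fraction > 0.5, observed/expected CpG ratio
    ``(#CpG * L) / (#C * #G)`` > 0.6, and it contains no N.  Overlapping or
    adjacent passing windows are merged and the merged region is re-tested on
    its full extent; regions failing the re-test are discarded.
    """
    regions: list[CGIRegion] = []
    for chrom in genome:
        L = len(chrom)
        if L < window:
            continue
        arr = np.frombuffer(chrom.sequence.encode("ascii"), dtype=np.uint8)
        is_c = arr == _BASE_CODES["C"]
        is_g = arr == _BASE_CODES["G"]
        is_n = arr == _BASE_CODES["N"]
        cpg = np.zeros(L, dtype=bool)
        cpg[:-1] = is_c[:-1] & is_g[1:]

        def wsum(x: np.ndarray, w: int) -> np.ndarray:
            cs = np.concatenate(([0], np.cumsum(x)))
            return cs[w:] - cs[:-w]

        c_w = wsum(is_c, window)
        g_w = wsum(is_g, window)
        n_w = wsum(is_n, window)
        # CpG starts fully inside the window: positions [i, i + window - 1)
        cpg_w = wsum(cpg, window - 1)[: L - window + 1]
        cpg_w = cpg_w[: len(c_w)]

        gc_ok = (c_w + g_w) / window > 0.5
        denom = (c_w * g_w).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where(denom > 0, cpg_w * window / denom, 0.0)
        passing = gc_ok & (obs_exp > 0.6) & (n_w == 0)
        starts = np.flatnonzero(passing)
        if starts.size == 0:
            continue
        # merge runs of passing windows that overlap or touch
        breaks = np.flatnonzero(np.diff(starts) > window)
        run_bounds = np.concatenate(([0], breaks + 1, [starts.size]))
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            r_start = int(starts[a])
            r_end = int(starts[b - 1]) + window
            length = r_end - r_start
            n_c = int(is_c[r_start:r_end].sum())
            n_g = int(is_g[r_start:r_end].sum())
            n_cpg = int(cpg[r_start : r_end - 1].sum())
            gc = (n_c + n_g) / length
            oe = _obs_exp_cpg(n_cpg, n_c, n_g, length)
            if length > 500 and gc > 0.5 and oe > 0.6:
                regions.append(CGIRegion(chrom.chrom_id, r_start, r_end, gc, oe))
            else:
                logger.debug(
                    "merged CGI candidate %s:%d-%d failed re-test "
                    "(gc=%.3f oe=%.3f)", chrom.chrom_id, r_start, r_end, gc, oe
                )
    regions.sort(key=lambda r: (r.chrom_id, r.start))
    return regions


def annotate_sites(
    mlu_sites: Sequence[RestrictionSite],
    cgis: Sequence[CGIRegion],
    repeats: Sequence[IntervalAnnotation],
    genes: Sequence[IntervalAnnotation],
) -> list[SiteAnnotation]:
    """Annotate each MluI site with CGI-promoter, repeat and nearest-gene status.

    CGI membership is >= 1 bp overlap of the 6-bp motif interval.  Repeat
    ties go to the largest overlap, then first interval by coordinate.  The
    nearest gene minimises interval distance (0 when overlapping; ties go to
    the smaller gene start).
    """
    cgi_trees: dict[str, IntervalTree] = {}
    for r in cgis:
        cgi_trees.setdefault(r.chrom_id, IntervalTree()).addi(r.start, r.end)
    rep_trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        rep_trees.setdefault(iv.chrom_id, IntervalTree()).addi(
            iv.start, iv.end, iv.label
        )
    genes_by_chrom: dict[str, list[IntervalAnnotation]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom_id, []).append(g)
    gene_arrays = {}
    for chrom_id, gl in genes_by_chrom.items():
        gl.sort(key=lambda g: (g.start, g.end))
        gene_arrays[chrom_id] = (
            np.array([g.start for g in gl]),
            np.array([g.end for g in gl]),
            gl,
        )

    out: list[SiteAnnotation] = []
    for site in mlu_sites:
        s, e = site.start, site.end
        in_cgi = bool(
            site.chrom_id in cgi_trees and cgi_trees[site.chrom_id].overlap(s, e)
        )
        repeat_class: str | None = None
        tree = rep_trees.get(site.chrom_id)
        if tree is not None:
            hits = tree.overlap(s, e)
            if hits:
                best = sorted(
                    hits,
                    key=lambda iv: (-(min(e, iv.end) - max(s, iv.begin)),
                                    iv.begin, iv.end),
                )
                if len(best) > 1:
                    logger.debug("site %s overlaps %d repeat intervals; "
                                 "keeping %s", site.site_id, len(best),
                                 best[0].data)
                repeat_class = best[0].data

        nearest_gene: str | None = None
        distance: int | None = None
        ga = gene_arrays.get(site.chrom_id)
        if ga is not None:
            gstarts, gends, gl = ga
            d = np.maximum(0, np.maximum(gstarts - e, s - gends))
            idx = int(np.argmin(d))  # first occurrence = smallest gene start
            nearest_gene = gl[idx].label
            distance = int(d[idx])
        out.append(
            SiteAnnotation(site.site_id, in_cgi, repeat_class, nearest_gene,
                           distance)
        )
    return out


def write_library_tsv(
    tags: Sequence[VirtualTag],
    annotations: Sequence[SiteAnnotation],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Export the tag library with per-site annotations as TSV."""
    ann = {a.mlu_site_id: a for a in annotations}
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write(
            "tag_id\tsequence\tchrom\tmlu_site_start\tside\tstrand\tunique\t"
            "in_cgi_promoter\trepeat_class\tnearest_gene\n"
        )
        for t in tags:
            chrom, start = t.mlu_site_id.rsplit(":", 1)
            a = ann.get(t.mlu_site_id)
            fh.write(
                "\t".join(
                    [
                        t.tag_id,
                        t.sequence,
                        chrom,
                        start,
                        t.fragment_id.split(":")[-1],
                        t.strand,
                        str(t.unique),
                        str(a.in_cgi_promoter) if a else "NA",
                        (a.repeat_class or "NA") if a else "NA",
                        (a.nearest_gene or "NA") if a else "NA",
                    ]
                )
                + "\n"
            )


def build_library(
    genome: Sequence[GenomeSequence],
) -> tuple[list[RestrictionSite], list[VirtualFragment], TagLibrary,
           DigestionSummary]:
    """Convenience: full digestion of a genome into the mappable tag library."""
    summary = DigestionSummary()
    mlu, nla = [], []
    for chrom in genome:
        mlu.extend(find_sites(chrom, MLUI_MOTIF))
        nla.extend(find_sites(chrom, NLAIII_MOTIF))
    mlu.sort(key=lambda s: (s.chrom_id, s.start))
    nla.sort(key=lambda s: (s.chrom_id, s.start))
    fragments = build_virtual_fragments(genome, mlu, nla, summary)
    tags = extract_virtual_tags(fragments, genome, summary)
    library = filter_unique_tags(tags)
    return mlu, fragments, library, summary
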