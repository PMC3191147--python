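"""Synthetic genomes, methylomes and tag reads with known ground truth.

The generator emulates the study design the pipeline was built for: a small
multi-chromosome genome carrying planted MluI (ACGCGT) sites flanked by
NlaIII (CATG) sites, CpG-island blocks around a fraction of the MluI sites,
repeat and gene interval annotations, and eight tag libraries — two tissues
x (2 cloned + 2 control) animals — whose per-site tag counts are Poisson
draws of ``depth x unmethylation probability``.  A configurable fraction of
sites receives a multiplicative clone effect on the unmethylation
probability (multiplier < 1 reproduces the direction reported for cloned
animals: fewer tags, i.e. more methylation, in clones).

Truth is defined *post hoc* by scanning the emitted genome: accidental
motifs arising from the random background become real sites of the virtual
library, so the truth tables always describe the genome as written, not as
intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_assets import GenomeSequence, IntervalAnnotation
from .virtual_library import (
    MLUI_MOTIF,
    NLAIII_MOTIF,
    TagLibrary,
    build_library,
    find_sites,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults emulate the cohort the pipeline targets: two tissues, two
    cloned and two control animals per tissue (eight libraries), a modest
    clone effect on a tenth of the sites, and tag depths comparable to a
    lane of tag sequencing spread over the site set.
    """

    n_chroms: int = 2
    chrom_length: int = 120_000
    n_mlu_sites: int = 60  # planted per chromosome; background may add more
    gc_background: float = 0.42
    cgi_fraction: float = 0.3  # fraction of planted sites inside a CGI block
    cgi_length: int = 800
    cgi_gc: float = 0.65
    cgi_obs_exp: float = 0.8
    repeat_fraction: float = 0.2
    repeat_classes: tuple[str, ...] = (
        "SINE/tRNA-Glu", "LINE/L1", "SINE/MIR", "LTR/ERVL")
    repeat_length: int = 400
    gene_fraction: float = 0.5
    gene_length: int = 2000
    tissues: tuple[str, ...] = ("muscle", "liver")
    n_clone_replicates: int = 2
    n_control_replicates: int = 2
    site_unmeth_prob_range: tuple[float, float] = (0.15, 0.5)
    tissue_effect_fraction: float = 0.2
    tissue_effect_multiplier: float = 1.5
    clone_effect_fraction: float = 0.1
    clone_effect_multiplier: float = 1 / 3
    depth: float = 50.0
    read_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.gc_background < 1 or not 0 < self.cgi_gc < 1:
            raise ValueError("GC fractions must be in (0, 1)")
        for frac in (self.cgi_fraction, self.repeat_fraction,
                     self.gene_fraction, self.tissue_effect_fraction,
                     self.clone_effect_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.clone_effect_multiplier <= 0 or self.depth <= 0:
            raise ValueError("multiplier and depth must be positive")
        spacing = self.chrom_length // (self.n_mlu_sites + 1)
        if spacing < 2 * self.cgi_length:
            raise ValueError(
                "planted motifs denser than the spacing the CGI blocks and "
                "NlaIII flanks need; reduce n_mlu_sites or enlarge the "
                "chromosome")

    @property
    def library_design(self) -> list[tuple[str, str, str]]:
        """(library_id, tissue, group) for every library."""
        design = []
        for tissue in self.tissues:
            for i in range(self.n_clone_replicates):
                design.append((f"{tissue}_clone{i + 1}", tissue, "clone"))
            for i in range(self.n_control_replicates):
                design.append((f"{tissue}_control{i + 1}", tissue, "control"))
        return design


@dataclass
class SimulationTruth:
    genome: list[GenomeSequence]
    planted_mlu_positions: dict[str, list[int]]
    site_ids: list[str] = field(default_factory=list)  # realized, post-hoc
    cgi_intervals: list[IntervalAnnotation] = field(default_factory=list)
    repeat_intervals: list[IntervalAnnotation] = field(default_factory=list)
    gene_intervals: list[IntervalAnnotation] = field(default_factory=list)
    unmeth_probs: pd.DataFrame | None = None  # sites x libraries
    diff_sites: dict[str, set[str]] = field(default_factory=dict)  # per tissue


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _cgi_block(rng: np.random.Generator, length: int, gc: float,
               obs_exp: float) -> np.ndarray:
    """GC-rich block whose observed/expected CpG ratio is tuned by swapping
    surplus CG dinucleotides to GC (GC content unchanged)."""
    block = _random_bases(rng, length, gc)
    n_c = int((block == b"C").sum())
    n_g = int((block == b"G").sum())
    target = int(round(obs_exp * n_c * n_g / length))
    is_cg = (block[:-1] == b"C") & (block[1:] == b"G")
    cg_pos = np.flatnonzero(is_cg)
    surplus = len(cg_pos) - target
    if surplus > 0:
        flip = rng.choice(cg_pos, size=surplus, replace=False)
        block[flip], block[flip + 1] = b"G", b"C"
    return block


def simulate_genome(config: SimulationConfig) -> SimulationTruth:
    """Emit a genome with planted MluI/NlaIII sites, CGI blocks and interval
    annotations; realized truth is filled in by scanning the result."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    mlu_arr = np.frombuffer(MLUI_MOTIF.encode(), dtype="S1")
    nla_arr = np.frombuffer(NLAIII_MOTIF.encode(), dtype="S1")

    genome: list[GenomeSequence] = []
    truth = SimulationTruth(genome=genome, planted_mlu_positions={})
    gene_counter = 0

    for ci in range(config.n_chroms):
        chrom_id = f"chr{ci + 1}"
        L = config.chrom_length
        arr = _random_bases(rng, L, config.gc_background)
        spacing = L // (config.n_mlu_sites + 1)
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1,
                              size=config.n_mlu_sites)
        positions = [(k + 1) * spacing + int(jitter[k])
                     for k in range(config.n_mlu_sites)]

        n_cgi = int(round(config.cgi_fraction * len(positions)))
        cgi_sites = set(rng.choice(len(positions), size=n_cgi,
                                   replace=False).tolist())
        n_rep = int(round(config.repeat_fraction * len(positions)))
        rep_sites = rng.choice(len(positions), size=n_rep,
                               replace=False).tolist()
        n_gene = int(round(config.gene_fraction * len(positions)))
        gene_sites = set(rng.choice(len(positions), size=n_gene,
                                    replace=False).tolist())

        # CGI blocks first, motifs afterwards so they survive the overwrite
        half = config.cgi_length // 2
        for k in sorted(cgi_sites):
            pos = positions[k]
            start = max(0, pos - half)
            end = min(L, start + config.cgi_length)
            arr[start:end] = _cgi_block(rng, end - start, config.cgi_gc,
                                        config.cgi_obs_exp)
            truth.cgi_intervals.append(
                IntervalAnnotation(chrom_id, start, end, "planted_cgi"))

        max_flank = max(26, min(1200, spacing // 3))
        for pos in positions:
            arr[pos:pos + 6] = mlu_arr
            dl = int(rng.integers(25, max_flank))
            dr = int(rng.integers(25, max_flank))
            left = pos - dl - 4
            right = pos + 6 + dr
            if left >= 0:
                arr[left:left + 4] = nla_arr
            if right + 4 <= L:
                arr[right:right + 4] = nla_arr

        for idx, k in enumerate(rep_sites):
            pos = positions[k]
            cls = config.repeat_classes[idx % len(config.repeat_classes)]
            off = int(rng.integers(10, config.repeat_length - 10))
            start = max(0, pos + 3 - off)
            end = min(L, start + config.repeat_length)
            truth.repeat_intervals.append(
                IntervalAnnotation(chrom_id, start, end, cls))

        for k in sorted(gene_sites):
            pos = positions[k]
            gene_counter += 1
            off = int(rng.integers(200, 1500))
            start = min(L - 2, pos + 6 + off)
            end = min(L, start + config.gene_length)
            truth.gene_intervals.append(
                IntervalAnnotation(chrom_id, start, end,
                                   f"GENE{gene_counter:04d}"))

        genome.append(GenomeSequence(chrom_id, arr.tobytes().decode("ascii")))
        truth.planted_mlu_positions[chrom_id] = positions

    # realized truth: scan what was actually written
    truth.site_ids = [
        s.site_id for chrom in genome for s in find_sites(chrom, MLUI_MOTIF)
    ]
    return truth


def simulate_methylomes(truth: SimulationTruth,
                        config: SimulationConfig) -> pd.DataFrame:
    """Per-site, per-library unmethylation probabilities.

    A per-site baseline (uniform over ``site_unmeth_prob_range``) is
    modified multiplicatively by the tissue effect on a tissue-specific
    subset and by the clone effect on the differential subset in clone
    libraries; replicates share probabilities (noise enters only through
    count sampling).  Fills ``truth.diff_sites`` per tissue.
    """
    rng = np.random.default_rng([config.seed, 2])
    sites = truth.site_ids
    n = len(sites)
    lo, hi = config.site_unmeth_prob_range
    base = rng.uniform(lo, hi, size=n)

    probs = {}
    truth.diff_sites = {}
    for tissue in config.tissues:
        p_tissue = base.copy()
        n_t = int(round(config.tissue_effect_fraction * n))
        t_idx = rng.choice(n, size=n_t, replace=False)
        p_tissue[t_idx] *= config.tissue_effect_multiplier
        n_d = int(round(config.clone_effect_fraction * n))
        d_idx = rng.choice(n, size=n_d, replace=False)
        truth.diff_sites[tissue] = {sites[i] for i in d_idx}
        p_clone = p_tissue.copy()
        p_clone[d_idx] *= config.clone_effect_multiplier
        for lib_id, lib_tissue, group in config.library_design:
            if lib_tissue != tissue:
                continue
            p = p_clone if group == "clone" else p_tissue
            probs[lib_id] = np.clip(p, 0.0, 1.0)
    df = pd.DataFrame(probs, index=sites)
    truth.unmeth_probs = df
    return df


def _apply_read_errors(reads: np.ndarray, rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on an (n_reads, 17) byte array."""
    if rate <= 0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        # shift each erroneous base by 1-3 positions in the ACGT alphabet
        codes = np.searchsorted(_BASES, reads[mask])
        shift = rng.integers(1, 4, size=n_err)
        reads[mask] = _BASES[(codes + shift) % 4]
    return reads


def simulate_tag_reads(
    truth: SimulationTruth,
    probs: pd.DataFrame,
    config: SimulationConfig,
    library: TagLibrary,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Poisson tag reads per library plus the true per-site count matrix.

    For site s and library l the true count is Poisson(depth *
    unmeth_prob[s, l]); reads are the site's virtual tag sequences (split
    uniformly when a site has two tags) with optional per-base substitution
    errors, shuffled within each library.
    """
    rng = np.random.default_rng([config.seed, 3])
    tags_by_site: dict[str, list[str]] = {}
    for tag in list(library.mappable) + list(library.ambiguous):
        tags_by_site.setdefault(tag.mlu_site_id, []).append(tag.sequence)

    sites = list(probs.index)
    reads_per_lib: dict[str, list[str]] = {}
    true_counts = pd.DataFrame(0, index=sites, columns=list(probs.columns))
    for lib_id in probs.columns:
        lam = config.depth * probs[lib_id].to_numpy()
        counts = rng.poisson(lam)
        seqs: list[str] = []
        for site, c in zip(sites, counts):
            if c == 0:
                continue
            site_tags = tags_by_site.get(site)
            if not site_tags:
                continue  # site has no mappable tag: sequencing sees nothing
            true_counts.loc[site, lib_id] = int(c)
            if len(site_tags) == 1:
                seqs.extend([site_tags[0]] * int(c))
            else:
                split = rng.multinomial(int(c),
                                        [1 / len(site_tags)] * len(site_tags))
                for t, k in zip(site_tags, split):
                    seqs.extend([t] * int(k))
        if seqs:
            arr = np.frombuffer("".join(seqs).encode(), dtype="S1").copy()
            arr = arr.reshape(len(seqs), -1)
            arr = _apply_read_errors(arr, config.read_error_rate, rng)
            order = rng.permutation(len(seqs))
            seqs = ["".join(row) for row in
                    arr[order].astype("U1")]
        reads_per_lib[lib_id] = seqs
    return reads_per_lib, true_counts


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: SimulationTruth
    library: TagLibrary
    reads: dict[str, list[str]]
    true_counts: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full simulation: genome -> virtual library -> methylomes -> reads."""
    truth = simulate_genome(config)
    _, _, library, _ = build_library(truth.genome)
    probs = simulate_methylomes(truth, config)
    reads, true_counts = simulate_tag_reads(truth, probs, config, library)
    return SimulatedDataset(config, truth, library, reads, true_counts)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write genome FASTA, annotation BEDs, per-library tag FASTA and truth
    TSVs — plain-text artifacts consumed by the pipeline without special
    casing."""
    from .genome_assets import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom in dataset.truth.genome:
            fh.write(f">{chrom.chrom_id}\n")
            seq = chrom.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_bed(dataset.truth.repeat_intervals, outdir / "repeats.bed")
    write_bed(dataset.truth.gene_intervals, outdir / "genes.bed")
    write_bed(dataset.truth.cgi_intervals, outdir / "cgi_truth.bed")
    for lib_id, seqs in dataset.reads.items():
        with open(outdir / f"tags_{lib_id}.fa", "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{lib_id}.{i}\n{s}\n")
    dataset.true_counts.to_csv(outdir / "true_counts.tsv", sep="\t",
                               index_label="site_id")
    rows = []
    for tissue, sites in dataset.truth.diff_sites.items():
        for s in sorted(sites):
            rows.append({"tissue": tissue, "site_id": s})
    pd.DataFrame(rows, columns=["tissue", "site_id"]).to_csv(
        outdir / "diff_sites_truth.tsv", sep="\t", index=False)
    if dataset.truth.unmeth_probs is not None:
        dataset.truth.unmeth_probs.to_csv(outdir / "unmeth_probs.tsv",
                                          sep="\t", index_label="site_id")
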