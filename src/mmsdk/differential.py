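"""Differential methylation between clone and control groups.

Per-site significance uses the exact conditional test for comparing two
Poisson totals: with pooled group counts x1, x2 and pooled library totals
N1, N2, under equal per-tag rates x1 | (x1 + x2 = T) ~ Binomial(T,
N1/(N1+N2)); the two-sided p-value doubles the smaller inclusive tail.
Because tag counts report *unmethylated* MluI sites, a significantly lower
tag count in clones means *higher* methylation in clones — all directions
here are in tag-count space and must be inverted for methylation readings.

Repeat classes are compared with a Wilcoxon rank-sum test on pooled
normalized low-confidence values; bisulfite validation tables use Fisher's
exact test.  Multiple testing is controlled by Benjamini-Hochberg FDR, per
tissue for sites and across repeat classes within a tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filtering_normalization import NormalizedMatrix
from .tag_processing import TagCountMatrix
from .virtual_library import SiteAnnotation

logger = logging.getLogger(__name__)

GROUP_CLONE = "clone"
GROUP_CONTROL = "control"


def poisson_sa_test(x1: int, N1: float, x2: int, N2: float) -> float:
    """Exact conditional two-sided test of equal Poisson rates.

    ``x1`` of ``N1`` total tags versus ``x2`` of ``N2``; p = min(1,
    2 * min(P(X <= x1), P(X >= x1))) with X ~ Binomial(x1 + x2,
    N1 / (N1 + N2)).  T = 0 returns 1.
    """
    if min(x1, x2) < 0 or N1 <= 0 or N2 <= 0:
        raise ValueError("counts must be nonnegative and totals positive")
    T = x1 + x2
    if T == 0:
        return 1.0
    pi = N1 / (N1 + N2)
    lower = stats.binom.cdf(x1, T, pi)
    upper = stats.binom.sf(x1 - 1, T, pi)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _poisson_sa_vec(x1: np.ndarray, N1: float, x2: np.ndarray,
                    N2: float) -> np.ndarray:
    T = x1 + x2
    pi = N1 / (N1 + N2)
    lower = stats.binom.cdf(x1, T, pi)
    upper = stats.binom.sf(x1 - 1, T, pi)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(T == 0, 1.0, p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DifferentialResult:
    mlu_site_id: str
    x_clone: int
    x_control: int
    n_clone: float
    n_control: float
    p_value: float
    fdr_p: float
    direction: str  # tag-count space: "higher_in_clone" etc.
    significant: bool
    in_cgi_promoter: bool
    nearest_gene: str | None


def run_differential(
    matrix: TagCountMatrix,
    groups: Mapping[str, str],
    annotations: Sequence[SiteAnnotation],
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-site clone-vs-control scan on a filtered high-confidence matrix.

    Counts and library totals are pooled (summed) within each group; FDR is
    adjusted across all tested sites; significance is called at
    ``fdr_p < alpha``.
    """
    clone_libs = [l for l in matrix.library_ids if groups.get(l) == GROUP_CLONE]
    control_libs = [l for l in matrix.library_ids
                    if groups.get(l) == GROUP_CONTROL]
    unknown = [l for l in matrix.library_ids if l not in groups]
    if unknown:
        raise ValueError(f"libraries without group label: {unknown}")
    if not clone_libs or not control_libs:
        raise ValueError("need >= 1 library in each group")
    N1 = float(matrix.library_totals[clone_libs].sum())
    N2 = float(matrix.library_totals[control_libs].sum())
    if N1 <= 0 or N2 <= 0:
        raise ValueError("a group has zero total mapped tags")
    x1 = matrix.counts[clone_libs].sum(axis=1).to_numpy()
    x2 = matrix.counts[control_libs].sum(axis=1).to_numpy()
    p = _poisson_sa_vec(x1, N1, x2, N2)
    fdr = bh_fdr(p)
    ann = {a.mlu_site_id: a for a in annotations}
    out = []
    for site, xc, xk, pv, fv in zip(matrix.site_ids, x1, x2, p, fdr):
        r1, r2 = xc / N1, xk / N2
        direction = ("higher_in_clone" if r1 > r2
                     else "higher_in_control" if r2 > r1 else "equal")
        a = ann.get(site)
        out.append(DifferentialResult(
            site, int(xc), int(xk), N1, N2, float(pv), float(fv), direction,
            bool(fv < alpha),
            a.in_cgi_promoter if a else False,
            a.nearest_gene if a else None,
        ))
    return out


def differential_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        chrom, pos = r.mlu_site_id.rsplit(":", 1)
        rows.append({
            "site_id": r.mlu_site_id, "chrom": chrom, "pos": int(pos),
            "x_clone": r.x_clone, "x_control": r.x_control,
            "N_clone": r.n_clone, "N_control": r.n_control,
            "p_value": r.p_value, "fdr_p": r.fdr_p,
            "direction": r.direction, "significant": r.significant,
            "in_cgi_promoter": r.in_cgi_promoter,
            "nearest_gene": r.nearest_gene or "NA",
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatClassResult:
    repeat_class: str
    n_sites: int
    mean_clone: float
    mean_control: float
    p_value: float
    fdr_p: float


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum; exact when small and tie-free, else
    normal approximation with tie and continuity corrections."""
    exact = len(a) + len(b) < 20 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def repeat_class_test(
    norm_low: NormalizedMatrix,
    repeat_partition: Mapping[str, TagCountMatrix],
    groups: Mapping[str, str],
) -> list[RepeatClassResult]:
    """Per-repeat-class Wilcoxon rank-sum on pooled normalized values.

    For each class the normalized values of all member sites in all clone
    libraries form one sample and likewise for controls (n_sites x
    n_libraries values each); BH adjustment runs across the tested classes.
    Classes with fewer than 2 sites are skipped with a warning.
    """
    clone_libs = [l for l in norm_low.library_ids
                  if groups.get(l) == GROUP_CLONE]
    control_libs = [l for l in norm_low.library_ids
                    if groups.get(l) == GROUP_CONTROL]
    if not clone_libs or not control_libs:
        raise ValueError("need >= 1 library in each group")
    rows = []
    for cls, sub in sorted(repeat_partition.items(),
                           key=lambda kv: -len(kv[1].counts)):
        sites = [s for s in sub.site_ids if s in norm_low.values.index]
        if len(sites) < 2:
            logger.warning("repeat class %r has < 2 sites; skipped", cls)
            continue
        vals = norm_low.values.loc[sites]
        a = vals[clone_libs].to_numpy(float).ravel()
        b = vals[control_libs].to_numpy(float).ravel()
        rows.append((cls, len(sites), float(a.mean()), float(b.mean()),
                     _rank_sum_p(a, b)))
    if not rows:
        return []
    fdr = bh_fdr([r[4] for r in rows])
    return [RepeatClassResult(cls, n, mc, mk, p, float(q))
            for (cls, n, mc, mk, p), q in zip(rows, fdr)]


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of nonnegative counts."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def annotate_neighbor_genes(
    results: Sequence[DifferentialResult],
) -> tuple[pd.DataFrame, int]:
    """Group significant sites by nearest gene.

    Returns a (gene, n_sites, site_ids) table plus the number of significant
    sites that carry no gene annotation.
    """
    by_gene: dict[str, list[str]] = {}
    unannotated = 0
    for r in results:
        if not r.significant:
            continue
        if r.nearest_gene is None:
            unannotated += 1
        else:
            by_gene.setdefault(r.nearest_gene, []).append(r.mlu_site_id)
    rows = [{"gene": g, "n_sites": len(sites), "site_ids": ",".join(sites)}
            for g, sites in sorted(by_gene.items(),
                                   key=lambda kv: (-len(kv[1]), kv[0]))]
    return pd.DataFrame(rows, columns=["gene", "n_sites", "site_ids"]), unannotated


@dataclass(frozen=True)
class CrossCompareReport:
    n_meth: int
    n_deg: int
    overlap: tuple[str, ...]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)


def cross_compare(meth_genes: Sequence[str],
                  deg_genes: Sequence[str]) -> CrossCompareReport:
    """Case-sensitive intersection of methylation-neighbor and DEG gene lists."""
    overlap = sorted(set(meth_genes) & set(deg_genes))
    return CrossCompareReport(len(set(meth_genes)), len(set(deg_genes)),
                              tuple(overlap))
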