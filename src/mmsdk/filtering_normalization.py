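"""Two-step tag filtering, library-size normalization, repeat partitioning.

Unique (non-repeat) sites are filtered on the high-confidence counts in two
steps: keep sites whose mean count across libraries is >= 5; of the rest,
keep those whose sample standard deviation across libraries is >= 5 (a site
that is silent in most libraries but strongly covered in one is biologically
interesting and survives via the spread branch).  Repeat sites are analysed
on low-confidence (inclusive-tier) counts without this filter.

Normalization divides each site's count by the library's total mapped tag
count at the matching tier (all mapped tags, not only surviving sites, so
filtering and normalization commute) and multiplies by a readability scale,
counts per million by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tag_processing import TagCountMatrix
from .virtual_library import SiteAnnotation


@dataclass
class NormalizedMatrix:
    """Scaled per-site tag rates: ``scale * count / library_total``."""

    values: pd.DataFrame
    scale: float
    tier: str

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"#{header}\n")
            self.values.to_csv(fh, sep="\t", index_label="site_id",
                               float_format="%.6g")


def partition_by_repeat(
    matrix: TagCountMatrix, annotations: Sequence[SiteAnnotation]
) -> tuple[dict[str, TagCountMatrix], TagCountMatrix]:
    """Split sites into per-repeat-class matrices and a unique-site matrix.

    Partitions are disjoint and exhaustive; a matrix site without an
    annotation is an error.
    """
    ann = {a.mlu_site_id: a for a in annotations}
    missing = [s for s in matrix.site_ids if s not in ann]
    if missing:
        raise ValueError(f"sites missing annotation: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    by_class: dict[str, list[str]] = {}
    unique_sites: list[str] = []
    for site in matrix.site_ids:
        cls = ann[site].repeat_class
        if cls is None:
            unique_sites.append(site)
        else:
            by_class.setdefault(cls, []).append(site)
    repeat_matrices = {cls: matrix.subset(sites)
                       for cls, sites in by_class.items()}
    return repeat_matrices, matrix.subset(unique_sites)


def filter_tags(
    matrix: TagCountMatrix, mean_thresh: float = 5.0, sd_thresh: float = 5.0
) -> TagCountMatrix:
    """Two-step site filter on counts across libraries.

    Keep a site iff mean >= ``mean_thresh`` OR (mean < ``mean_thresh`` AND
    sample SD (n-1 denominator) >= ``sd_thresh``).  Site order is preserved;
    the filter is idempotent and invariant to library column order.
    """
    if len(matrix.library_ids) < 2:
        raise ValueError("filtering needs >= 2 libraries (SD undefined)")
    means = matrix.counts.mean(axis=1)
    sds = matrix.counts.std(axis=1, ddof=1)
    keep = (means >= mean_thresh) | (sds >= sd_thresh)
    return TagCountMatrix(matrix.counts.loc[keep], matrix.library_totals,
                          matrix.tier)


def filter_report(
    matrix: TagCountMatrix, mean_thresh: float = 5.0, sd_thresh: float = 5.0
) -> pd.DataFrame:
    """Per-site filter diagnostics: mean, sd, kept flag and surviving branch."""
    means = matrix.counts.mean(axis=1)
    sds = matrix.counts.std(axis=1, ddof=1)
    branch = np.where(means >= mean_thresh, "mean",
                      np.where(sds >= sd_thresh, "sd", "removed"))
    return pd.DataFrame({"mean": means, "sd": sds,
                         "kept": branch != "removed", "branch": branch})


def normalize(matrix: TagCountMatrix, scale: float = 1e6) -> NormalizedMatrix:
    """Library-size normalization against the tier-matched totals."""
    totals = matrix.library_totals.reindex(matrix.library_ids)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total mapped tags for library "
                         f"{zero.index[0]!r}")
    values = matrix.counts * (scale / totals)
    return NormalizedMatrix(values, scale, matrix.tier)
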