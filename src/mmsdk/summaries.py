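"""Small shared reporting helpers used by library and pipeline summaries."""

from __future__ import annotations


def percent(part: float, total: float, decimals: int = 1) -> float:
    """``100 * part / total`` rounded to ``decimals`` places.

    Single code path for every percentage the summaries print (CGI-promoter
    site fraction, repeat fraction, mappable-site fraction, significant-site
    fraction, ...), so all reports round identically.
    """
    if total == 0:
        raise ValueError("total must be nonzero")
    return round(100.0 * part / total, decimals)
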