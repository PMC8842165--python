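"""Small shared reporting helpers."""

from __future__ import annotations


def round_percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """Percentage with round-half-to-even, as printed in screen summaries.

    Returns 0.0 for a zero denominator (callers flag that case).
    ``digits=0`` yields an integer-valued float (e.g. 209/224 -> 93.0).
    """
    if denominator == 0:
        return 0.0
    value = round(100.0 * numerator / denominator, digits)
    return float(value)


def significance_stars(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
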