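"""Published summary counts from the red-winged fairy-wren field study.

The long-term *Malurus elegans* study (Smithbrook Nature Reserve, Western
Australia; genotyped cohorts 2008-2014) that this pipeline is modelled on
reports its headline incidence figures as raw counts.  They are kept here
as reference inputs so reports and tests can recompute the published
percentages by exact integer arithmetic rather than hard-coding rounded
values.
"""

from __future__ import annotations

#: raw incidence counts (numerator, denominator)
STUDY_COUNTS: dict[str, tuple[int, int]] = {
    # social pairings between close kin (k >~ 0.125)
    "close_kin_pairs": (53, 310),
    # social pairings between first-order relatives (k ~ 0.25)
    "first_order_pairs": (24, 310),
    # offspring inbred at the half-sib level or higher (f >~ 0.125)
    "inbred_offspring": (106, 1458),
    # offspring from first-order matings (f ~ 0.25)
    "first_order_offspring": (14, 1458),
    # broods containing at least one inbred offspring
    "broods_with_inbred": (68, 680),
    # broods from first-order matings
    "broods_first_order": (8, 680),
    # first-order inbred offspring that were sired extra-pair
    "first_order_inbred_epo": (7, 14),
    # birds recruiting to a breeding position that did so within 3 years
    "recruited_within_3y": (103, 143),
}

#: published rate summaries that are direct proportions of sampled offspring
STUDY_RATES: dict[str, float] = {
    "epp_offspring": 0.58,  # offspring sired extra-pair
    "broods_with_epo": 0.67,  # broods containing >= 1 EPO
    "nest_predation": 0.70,  # approximate whole-brood predation rate
}


def ratio_percent(name: str, decimals: int = 0) -> float:
    """The published percentage for a named count ratio, by exact division."""
    num, den = STUDY_COUNTS[name]
    return round(100.0 * num / den, decimals)


def summary_ratios(decimals: int = 0) -> dict[str, float]:
    """All count-based percentages, computed from the raw counts."""
    return {name: ratio_percent(name, decimals) for name in STUDY_COUNTS}
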