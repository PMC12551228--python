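"""Published sample statistics of the public RatsPain dataset
(github.com/xhzongyuan/RatsPain).

These are the dataset card's per-rat image counts for the high-confidence
subset (images whose two-stage rater aggregation produced a label). They
drive split-arithmetic checks and the synthetic generator's default class
imbalance; the images themselves are never required.
"""

from __future__ import annotations

# subject -> (no pain, moderate pain, severe pain) image counts,
# high-confidence subset
HIGH_CONFIDENCE_COUNTS: dict[str, tuple[int, int, int]] = {
    "Rat1": (56, 163, 2),
    "Rat2": (102, 108, 0),
    "Rat3": (148, 50, 0),
    "Rat4": (138, 92, 0),
    "Rat5": (63, 116, 3),
    "Rat6": (34, 62, 1),
}

LOW_CONFIDENCE_TOTAL = 157  # images left unlabelled by the aggregation


def high_confidence_total() -> int:
    return sum(sum(v) for v in HIGH_CONFIDENCE_COUNTS.values())


def overall_total() -> int:
    return high_confidence_total() + LOW_CONFIDENCE_TOTAL


def per_label_totals() -> dict[str, int]:
    no = sum(v[0] for v in HIGH_CONFIDENCE_COUNTS.values())
    moderate = sum(v[1] for v in HIGH_CONFIDENCE_COUNTS.values())
    severe = sum(v[2] for v in HIGH_CONFIDENCE_COUNTS.values())
    return {"No": no, "Moderate": moderate, "Severe": severe}


def binary_counts() -> dict[str, tuple[int, int]]:
    """Per-subject (no-pain, pain) counts after merging moderate and severe."""
    return {s: (no, mod + sev) for s, (no, mod, sev) in HIGH_CONFIDENCE_COUNTS.items()}
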