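"""Two-stage grimace-scale label aggregation.

Each image is scored on four facial action units (AUs) — orbital tightening,
ear changes, nose/cheek flattening, whisker change — by five raters on the
0/1/2 scale, with an explicit "uncertain" vote allowed. An AU whose five
first-stage votes contain at least four identical numeric scores is high
confidence and that score is its label. Otherwise three further raters score
it, and the AU is accepted only if some numeric score appears at least five
times among all eight votes; otherwise it is rejected.

An image receives a label — the rounded mean of its accepted AU scores —
only when at least three of its four AUs were accepted; images with fewer
accepted AUs form the low-confidence subset and carry no label.

Rounding of the mean is half-up by default (0.5 → 1), the conservative
direction for pain detection; banker's rounding is available via a flag.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections import Counter
from typing import Optional, Sequence, Union

import pandas as pd

from .exceptions import SchemaError

UNCERTAIN = "uncertain"
Vote = Union[int, str]

STAGE1_RATERS = 5
STAGE1_QUORUM = 4
STAGE2_RATERS = 3
STAGE2_QUORUM = 5
MIN_ACCEPTED_AUS = 3


class AUId(str, enum.Enum):
    ORBITAL = "orbital"
    EARS = "ears"
    NOSE_CHEEK = "nose_cheek"
    WHISKERS = "whiskers"


def _check_vote(v: Vote) -> Vote:
    if v == UNCERTAIN or v == "U":
        return UNCERTAIN
    if isinstance(v, bool) or v not in (0, 1, 2):
        raise SchemaError(f"vote must be 0, 1, 2 or 'uncertain', got {v!r}")
    return int(v)


def stage1_consensus(scores: Sequence[Vote]) -> tuple[str, Optional[int]]:
    """First-stage rule: >=4 of 5 identical numeric votes give high confidence."""
    votes = [_check_vote(v) for v in scores]
    if len(votes) != STAGE1_RATERS:
        raise SchemaError(f"stage 1 needs exactly {STAGE1_RATERS} votes, got {len(votes)}")
    counts = Counter(v for v in votes if v != UNCERTAIN)
    for score, n in counts.most_common():
        if n >= STAGE1_QUORUM:
            return "high_confidence", score
    # >=4 identical "uncertain" votes also fail to form a numeric consensus
    return "needs_stage2", None


def stage2_accept(all_scores: Sequence[Vote]) -> tuple[str, Optional[int]]:
    """Second-stage rule over all 8 votes: accept iff some score appears >=5 times."""
    votes = [_check_vote(v) for v in all_scores]
    if len(votes) != STAGE1_RATERS + STAGE2_RATERS:
        raise SchemaError(
            f"stage 2 needs exactly {STAGE1_RATERS + STAGE2_RATERS} votes, got {len(votes)}")
    counts = Counter(v for v in votes if v != UNCERTAIN)
    for score, n in counts.most_common():
        if n >= STAGE2_QUORUM:
            return "accepted_stage2", score
    return "rejected", None


def image_level_label(accepted_scores: Sequence[int],
                      rounding: str = "half_up") -> Optional[int]:
    """Rounded mean of accepted AU scores; absent with fewer than 3 accepted AUs."""
    for s in accepted_scores:
        if s not in (0, 1, 2):
            raise SchemaError(f"AU consensus score must be 0, 1 or 2, got {s!r}")
    if len(accepted_scores) < MIN_ACCEPTED_AUS:
        return None
    mean = sum(accepted_scores) / len(accepted_scores)
    if rounding == "half_up":
        return int(math.floor(mean + 0.5))
    if rounding == "banker":
        return int(round(mean))
    raise SchemaError(f"unknown rounding mode {rounding!r}")


@dataclasses.dataclass
class AUAnnotation:
    au_id: AUId
    stage1_scores: list
    stage2_scores: Optional[list]
    status: str                      # high_confidence | accepted_stage2 | rejected
    consensus_score: Optional[int]


@dataclasses.dataclass
class ImageAnnotation:
    image_id: str
    subject_id: str
    au_annotations: list
    image_label: Optional[int]
    subset: str                      # high_confidence | low_confidence


def aggregate_au(au_id: AUId, stage1: Sequence[Vote],
                 stage2: Optional[Sequence[Vote]] = None) -> AUAnnotation:
    """Run the two-stage scheme for one AU.

    `stage2` holds the three additional votes and is consulted only when the
    first stage fails to reach consensus; it must be present in that case.
    """
    status, score = stage1_consensus(stage1)
    if status == "high_confidence":
        return AUAnnotation(au_id, list(stage1), None, status, score)
    if stage2 is None:
        raise SchemaError(
            f"AU {au_id.value}: stage 1 had no consensus but no stage-2 votes given")
    status, score = stage2_accept(list(stage1) + list(stage2))
    return AUAnnotation(au_id, list(stage1), list(stage2), status, score)


def aggregate_image(image_id: str, subject_id: str,
                    au_votes: dict, rounding: str = "half_up") -> ImageAnnotation:
    """`au_votes` maps AUId -> (stage1 votes, stage2 votes or None)."""
    aus = [aggregate_au(au, s1, s2) for au, (s1, s2) in sorted(
        au_votes.items(), key=lambda kv: kv[0].value)]
    accepted = [a.consensus_score for a in aus if a.consensus_score is not None]
    label = image_level_label(accepted, rounding=rounding)
    subset = "high_confidence" if label is not None else "low_confidence"
    return ImageAnnotation(image_id, subject_id, aus, label, subset)


def annotate_table(votes: pd.DataFrame, rounding: str = "half_up") -> pd.DataFrame:
    """Aggregate a long-format vote table into image-level labels.

    Input columns: image_id, subject_id, au_id, rater_id, stage (1 or 2),
    score (0/1/2/U). Output columns: image_id, subject_id, image_label
    (nullable), subset.
    """
    required = {"image_id", "subject_id", "au_id", "rater_id", "stage", "score"}
    if not required.issubset(votes.columns):
        raise SchemaError(f"vote table missing columns {sorted(required - set(votes.columns))}")
    rows = []
    for (image_id, subject_id), group in votes.groupby(["image_id", "subject_id"], sort=True):
        au_votes = {}
        for au_name, au_group in group.groupby("au_id"):
            au = AUId(au_name)
            s1 = au_group.loc[au_group["stage"] == 1].sort_values("rater_id")["score"].tolist()
            s2_rows = au_group.loc[au_group["stage"] == 2].sort_values("rater_id")["score"].tolist()
            au_votes[au] = (s1, s2_rows if s2_rows else None)
        ann = aggregate_image(str(image_id), str(subject_id), au_votes, rounding=rounding)
        rows.append({"image_id": ann.image_id, "subject_id": ann.subject_id,
                     "image_label": ann.image_label, "subset": ann.subset})
    return pd.DataFrame(rows)


LABEL_NAMES = {0: "No", 1: "Moderate", 2: "Severe"}


def dataset_statistics(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-subject × pain-level count table over labelled (high-confidence) images.

    Input needs columns subject_id and image_label; unlabelled rows are
    ignored. The returned frame has one row per subject plus a Total row,
    columns No / Moderate / Severe / Total.
    """
    cols = list(LABEL_NAMES.values())
    labelled = annotations.dropna(subset=["image_label"]) if len(annotations) else annotations
    if len(labelled) == 0:
        return pd.DataFrame(columns=cols + ["Total"]).rename_axis("subject_id")
    bad = set(labelled["image_label"].astype(int)) - set(LABEL_NAMES)
    if bad:
        raise SchemaError(f"labels outside 0/1/2: {sorted(bad)}")
    table = (labelled.assign(level=labelled["image_label"].astype(int).map(LABEL_NAMES))
             .pivot_table(index="subject_id", columns="level", aggfunc="size", fill_value=0)
             .reindex(columns=cols, fill_value=0))
    table.columns.name = None
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
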