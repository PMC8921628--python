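"""Prevalence-based training labels from multi-database occurrence tables.

The positive ("deleterious" / functionally abnormal) training set is the
shared dataset: protein variants observed at least once in *every* one of
several independent cancer mutation databases.  Because the databases come
from disjoint studies and technologies, joint recurrence is strong evidence
of genuine positive selection.  The negative set exploits the saturation of
the gene's mutational landscape: variants never observed, or observed only
once, across the whole corpus are taken as functionally normal.

Labels live at the protein-variant level; occurrence counts of distinct
cDNA events producing the same amino-acid change are summed before
thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["variant", "dataset_id", "count"]


def _validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCC_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table lacks columns {missing}")
    if (occ["count"] < 0).any():
        raise ValueError("occurrence counts must be non-negative")
    if occ.duplicated(subset=["variant", "dataset_id"]).any():
        raise ValueError("(variant, dataset_id) pairs must be unique")
    return occ


def build_positive_set(occ: pd.DataFrame, dataset_ids: list[str]) -> set[str]:
    """Variants present (count ≥ 1) in every one of `dataset_ids`.

    Requires at least two datasets — a single database cannot define a
    shared dataset.
    """
    _validate_occurrences(occ)
    if len(dataset_ids) < 2:
        raise ValueError("a shared dataset needs at least two databases")
    known = set(occ["dataset_id"].unique())
    unknown = [d for d in dataset_ids if d not in known]
    if unknown:
        raise ValueError(f"unknown dataset id(s): {unknown}")
    present = occ[occ["count"] >= 1]
    sets = [
        set(present.loc[present["dataset_id"] == d, "variant"])
        for d in dataset_ids
    ]
    return set.intersection(*sets)


def build_negative_set(
    occ: pd.DataFrame,
    space_keys: set[str],
    max_total_count: int = 1,
    per_dataset: bool = False,
) -> tuple[set[str], set[str]]:
    """Missense variants absent or nearly absent from the cancer corpus.

    Returns ``(absent, singleton)`` partitions: variants of the enumerated
    space with total count 0, and those with total count in
    ``[1, max_total_count]``.  By default counts are summed over the whole
    corpus (aggregate rule); ``per_dataset=True`` instead requires the
    maximum per-database count to stay within the threshold.
    """
    _validate_occurrences(occ)
    occ = occ[occ["variant"].isin(space_keys)]
    agg = occ.groupby("variant")["count"].max() if per_dataset else occ.groupby("variant")["count"].sum()
    observed = agg[agg > 0]
    absent = space_keys - set(observed.index)
    singleton = set(observed[observed <= max_total_count].index)
    return absent, singleton


@dataclass
class LabeledCohort:
    """Training labels plus hold-out bookkeeping over a variant space.

    positives are deleterious (D), negatives non-deleterious (ND); holdout
    members are removed from the training pools but retain their original
    label for later experimental validation.
    """

    positives: set[str]
    negatives: set[str]
    holdout: dict[str, str] = field(default_factory=dict)  # variant -> D/ND/NA
    unlabeled: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"labeling contradiction: {len(overlap)} variants in both sets"
            )

    @property
    def n_labeled(self) -> int:
        return len(self.positives) + len(self.negatives)

    def labels(self) -> pd.Series:
        lab = {v: "D" for v in self.positives}
        lab.update({v: "ND" for v in self.negatives})
        return pd.Series(lab, name="label")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(v, "D", "positive") for v in sorted(self.positives)]
            + [(v, "ND", "negative") for v in sorted(self.negatives)]
            + [(v, lab, "holdout") for v, lab in sorted(self.holdout.items())]
            + [(v, "", "unlabeled") for v in sorted(self.unlabeled)]
        )
        return pd.DataFrame(rows, columns=["variant", "label", "provenance"])


def assemble_cohort(
    pos: set[str],
    neg: set[str],
    holdout: set[str],
    space_keys: set[str],
) -> LabeledCohort:
    """Remove hold-outs from the training pools and account for the rest.

    Hold-out variants keep their original label (D for positives, ND for
    negatives, NA when drawn from the unlabeled pool).
    """
    if pos & neg:
        raise ValueError("positive and negative sets overlap")
    held = {}
    for v in holdout:
        if v in pos:
            held[v] = "D"
        elif v in neg:
            held[v] = "ND"
        else:
            held[v] = "NA"
            logger.info("holdout variant %s was unlabeled", v)
    pos_kept = pos - holdout
    neg_kept = neg - holdout
    unlabeled = space_keys - pos_kept - neg_kept - set(held)
    logger.info(
        "cohort: positives %d->%d, negatives %d->%d, holdout %d",
        len(pos), len(pos_kept), len(neg), len(neg_kept), len(held),
    )
    return LabeledCohort(pos_kept, neg_kept, held, unlabeled)
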