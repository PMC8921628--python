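"""External validation harnesses for a trained functionality classifier.

Four independent lines of validation, each consuming model predictions
(variant → D/ND) plus an external table:

* ClinVar-style comparison — curate a 5-tier annotation table, map
  P/LP → D and B/LB → ND, and score the model on the non-VUS records;
  VUS records are reported separately split by predicted class.
* Familial-cancer (LFS-style) cohorts — deleterious-enriched variant
  lists; accuracy is the fraction predicted D after removing known
  founder variants and misidentified SNPs from the denominator.
* Population frequency tables — gnomAD-style lists partitioned by
  predicted class.
* Survival stratification — tumor samples partitioned into
  no-mutation / missense-ND / missense-D / truncating categories, then
  compared by Kaplan–Meier curves, pairwise proportional-hazards score
  tests and a multivariable Cox fit with tumor type as covariate.

Threshold adapters turn competing in-silico scores (numeric cutoffs,
category vocabularies, uncertain bands) into the same D/ND/uncertain
vocabulary for side-by-side comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from mvprof.metrics import ConfusionMatrix, ValidationReport, confusion

logger = logging.getLogger(__name__)

TIERS = ("P", "LP", "VUS", "LB", "B")
TIER_TO_CLASS = {"P": "D", "LP": "D", "B": "ND", "LB": "ND"}

# MAF-style Variant_Classification vocabulary (matched case-insensitively)
TRUNCATING_CLASSES = frozenset(
    {
        "frame_shift_del", "frame_shift_ins", "nonsense_mutation",
        "splice_region", "splice_site",
    }
)
MISSENSE_CLASSES = frozenset({"missense_mutation"})
OTHER_KNOWN_CLASSES = frozenset(
    {
        "in_frame_del", "in_frame_ins", "silent", "nonstop_mutation",
        "translation_start_site", "3'utr", "5'utr", "intron", "rna",
    }
)

DEFAULT_TUMOR_TYPE_EXCLUSIONS = ("PCPG", "TGCT", "DLBC")

SURVIVAL_CATEGORIES = (
    "no_mutation", "missense_ND", "missense_D", "truncating", "excluded",
)


# ---------------------------------------------------------------------------
# ClinVar-style harness
# ---------------------------------------------------------------------------

def _validate_clinvar(raw: pd.DataFrame) -> pd.DataFrame:
    required = {"variant", "tier", "record_id", "variant_class"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    bad = set(raw["tier"].dropna()) - set(TIERS) - {""}
    if bad:
        raise ValueError(f"unknown tier label(s): {sorted(bad)}")
    return raw


def curate_clinvar(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Curate a raw 5-tier annotation table to one record per variant.

    Steps, with accounting: (1) same-variant records with discordant or
    absent labels collapse to a single VUS record; (2) indel-derived
    records are dropped; (3) exact same-label duplicate records are
    dropped.  Returns (curated table, accounting dict); idempotent.
    """
    _validate_clinvar(raw)
    if raw.empty:
        raise ValueError("annotation table is empty")
    df = raw.copy()
    df["tier"] = df["tier"].fillna("").astype(str)
    accounting = {"input": len(df)}

    # conflict collapse first, so its arithmetic is separate from the
    # duplicate accounting
    collapsed_rows = []
    n_conflict_removed = 0
    for variant, grp in df.groupby("variant", sort=False):
        labels = set(grp["tier"])
        if len(labels) > 1 or labels == {""}:
            keep = grp.iloc[[0]].copy()
            keep["tier"] = "VUS"
            collapsed_rows.append(keep)
            n_conflict_removed += len(grp) - 1
        else:
            collapsed_rows.append(grp)
    df = pd.concat(collapsed_rows, ignore_index=True)
    accounting["conflict_collapsed"] = n_conflict_removed

    is_indel = df["variant_class"] == "indel_derived"
    accounting["indel_removed"] = int(is_indel.sum())
    df = df[~is_indel]

    dup = df.duplicated(subset=["variant", "tier"], keep="first")
    accounting["duplicate_removed"] = int(dup.sum())
    df = df[~dup].reset_index(drop=True)

    accounting["retained"] = len(df)
    return df, accounting


def compare_clinvar(
    curated: pd.DataFrame, preds: pd.Series
) -> ValidationReport:
    """Score model predictions against curated non-VUS annotations.

    P/LP map to D, B/LB to ND; VUS records are excluded from the
    confusion matrix but reported split by predicted class.  Variants
    without a prediction are listed, excluded and warned about.
    """
    _validate_clinvar(curated)
    non_vus = curated[curated["tier"].isin(TIER_TO_CLASS)]
    uncovered = sorted(set(non_vus["variant"]) - set(preds.index))
    if uncovered:
        logger.warning("%d annotated variants lack predictions", len(uncovered))
        non_vus = non_vus[~non_vus["variant"].isin(uncovered)]

    vus = curated[curated["tier"] == "VUS"]
    vus_covered = vus[vus["variant"].isin(preds.index)]
    vus_split = (
        preds.reindex(vus_covered["variant"]).value_counts().to_dict()
        if len(vus_covered)
        else {}
    )

    if non_vus.empty:
        return ValidationReport(
            cm=None,
            details={
                "n_vus": len(vus),
                "vus_predicted_D": int(vus_split.get("D", 0)),
                "vus_predicted_ND": int(vus_split.get("ND", 0)),
                "uncovered": uncovered,
            },
        )
    truth = [TIER_TO_CLASS[t] for t in non_vus["tier"]]
    pred = list(preds.reindex(non_vus["variant"]))
    cm = confusion(truth, pred)
    return ValidationReport.from_confusion(
        cm,
        n_non_vus=len(non_vus),
        n_vus=len(vus),
        vus_predicted_D=int(vus_split.get("D", 0)),
        vus_predicted_ND=int(vus_split.get("ND", 0)),
        uncovered=uncovered,
    )


# ---------------------------------------------------------------------------
# LFS-style cohort harness
# ---------------------------------------------------------------------------

def lfs_validate(
    cohort_variants: Sequence[str],
    preds: pd.Series,
    excluded_snps: Sequence[str] = (),
    excluded_founders: Sequence[str] = (),
) -> ValidationReport:
    """Accuracy on a deleterious-enriched familial cohort.

    Distinct variants only (family records collapsing to one variant count
    once); founder variants and misidentified SNPs leave the denominator;
    a variant counts correct when predicted D.  Accuracy is printed to one
    decimal, the convention for cohort accuracies.
    """
    distinct = sorted(set(cohort_variants))
    for v in list(excluded_snps) + list(excluded_founders):
        if v not in distinct:
            logger.warning("exclusion list names absent variant %s", v)
    removed = set(excluded_snps) | set(excluded_founders)
    remaining = [v for v in distinct if v not in removed]
    covered = [v for v in remaining if v in preds.index]
    if len(covered) < len(remaining):
        logger.warning(
            "%d cohort variants lack predictions", len(remaining) - len(covered)
        )
    correct = sum(1 for v in covered if preds[v] == "D")
    n = len(covered)
    cm = ConfusionMatrix(tp=correct, tn=0, fp=0, fn=n - correct) if n else None
    return ValidationReport(
        cm=cm,
        accuracy=round(100.0 * correct / n, 1) if n else None,
        sensitivity=round(100.0 * correct / n, 1) if n else None,
        details={
            "n_distinct": len(distinct),
            "n_excluded": len(set(distinct) & removed),
            "n_evaluated": n,
            "n_predicted_deleterious": correct,
        },
    )


# ---------------------------------------------------------------------------
# Population-table harness
# ---------------------------------------------------------------------------

def summarize_population(
    pop_table: pd.DataFrame, preds: pd.Series
) -> tuple[dict[str, int], pd.DataFrame]:
    """Partition a population (gnomAD-style) variant table by predicted
    class; every listed variant must carry a prediction."""
    if "variant" not in pop_table.columns:
        raise ValueError("population table needs a 'variant' column")
    missing = sorted(set(pop_table["variant"]) - set(preds.index))
    if missing:
        raise ValueError(f"population variants lack predictions: {missing[:5]}")
    joined = pop_table.copy()
    joined["class"] = preds.reindex(pop_table["variant"]).to_numpy()
    counts = {
        "D": int((joined["class"] == "D").sum()),
        "ND": int((joined["class"] == "ND").sum()),
    }
    return counts, joined


# ---------------------------------------------------------------------------
# Survival harness
# ---------------------------------------------------------------------------

def categorize_survival(
    cohort: pd.DataFrame,
    preds: pd.Series,
    truncating_classes: frozenset[str] = TRUNCATING_CLASSES,
) -> pd.DataFrame:
    """Assign each sample a mutational-status category.

    Input has one row per sample with columns patient_id, sample_id,
    ``variants`` (list of (variant_key, variant_class) tuples; empty for
    wild-type samples), time, event, tumor_type.  Rules: samples carrying
    more than one mutation are excluded; patients contributing more than
    one sample are excluded; single missense samples are classed by the
    model's prediction; the stated truncating classes form their own
    category; any other non-missense class is excluded.
    """
    required = {"patient_id", "sample_id", "variants", "time", "event", "tumor_type"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"survival cohort lacks columns {sorted(missing)}")
    if (cohort["time"] < 0).any():
        raise ValueError("survival times must be non-negative")

    df = cohort.copy()
    multi_patient = df["patient_id"].value_counts()
    bad_patients = set(multi_patient[multi_patient > 1].index)

    categories = []
    for _, row in df.iterrows():
        variants = row["variants"] or []
        if row["patient_id"] in bad_patients:
            categories.append("excluded")
        elif len(variants) > 1:
            categories.append("excluded")
        elif len(variants) == 0:
            categories.append("no_mutation")
        else:
            key, vclass = variants[0]
            vclass_n = str(vclass).strip().lower()
            if vclass_n in truncating_classes:
                categories.append("truncating")
            elif vclass_n in MISSENSE_CLASSES:
                pred = preds.get(key)
                if pred == "D":
                    categories.append("missense_D")
                elif pred == "ND":
                    categories.append("missense_ND")
                else:
                    logger.warning("missense variant %s lacks a prediction", key)
                    categories.append("excluded")
            else:
                if vclass_n not in OTHER_KNOWN_CLASSES:
                    logger.warning("unknown variant class %r; sample excluded", vclass)
                categories.append("excluded")
    df["category"] = categories
    return df


@dataclass
class SurvivalAnalysis:
    """Kaplan–Meier curves, pairwise score tests and a multivariable fit."""

    km_curves: dict[str, pd.DataFrame]
    pairwise_p: dict[tuple[str, str], float | None]
    multivariable: pd.DataFrame | None
    category_counts: dict[str, int]
    excluded_tumor_types: tuple[str, ...]


def survival_analyze(
    categorized: pd.DataFrame,
    exclude_tumor_types: Sequence[str] = DEFAULT_TUMOR_TYPE_EXCLUSIONS,
    multivariable: bool = True,
) -> SurvivalAnalysis:
    """Compare survival across mutational-status categories.

    The configured tumor-type exclusion list is applied first.  Pairwise
    comparisons use the score (log-rank) test of a two-group proportional-
    hazards model; a pair where either category has zero events is marked
    undefined (None).  The multivariable Cox fit uses the category (ND as
    reference) and tumor-type dummies, on mutated missense samples plus
    the other categories present.
    """
    df = categorized[categorized["category"] != "excluded"].copy()
    df = df[~df["tumor_type"].isin(set(exclude_tumor_types))]
    cats = [c for c in SURVIVAL_CATEGORIES[:4] if (df["category"] == c).any()]
    with_events = [c for c in cats if df.loc[df["category"] == c, "event"].sum() > 0]
    if len(with_events) < 2:
        raise ValueError("need >=2 categories with events")

    km: dict[str, pd.DataFrame] = {}
    for c in cats:
        sub = df[df["category"] == c]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=c)
        km[c] = kmf.survival_function_

    pairwise: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            sa = df[df["category"] == a]
            sb = df[df["category"] == b]
            if sa["event"].sum() == 0 or sb["event"].sum() == 0:
                pairwise[(a, b)] = None
                continue
            res = logrank_test(
                sa["time"], sb["time"], sa["event"], sb["event"]
            )
            pairwise[(a, b)] = float(res.p_value)

    multi = None
    if multivariable:
        sub = df[df["category"].isin(["missense_D", "missense_ND"])].copy()
        if sub["category"].nunique() == 2 and sub["event"].sum() > 0:
            design = pd.DataFrame(
                {
                    "time": sub["time"].to_numpy(),
                    "event": sub["event"].to_numpy(),
                    "pred_D": (sub["category"] == "missense_D").astype(int).to_numpy(),
                }
            )
            if sub["tumor_type"].nunique() > 1:
                dummies = pd.get_dummies(
                    sub["tumor_type"], prefix="type", drop_first=True
                ).astype(int)
                design = pd.concat(
                    [design, dummies.reset_index(drop=True)], axis=1
                )
            cph = CoxPHFitter(penalizer=1e-4)
            cph.fit(design, duration_col="time", event_col="event")
            multi = cph.summary
    counts = df["category"].value_counts().to_dict()
    counts["excluded"] = int((categorized["category"] == "excluded").sum())
    return SurvivalAnalysis(
        km_curves=km,
        pairwise_p=pairwise,
        multivariable=multi,
        category_counts=counts,
        excluded_tumor_types=tuple(exclude_tumor_types),
    )


def fit_two_group_hazard_ratio(
    categorized: pd.DataFrame, group_a: str, group_b: str
) -> float:
    """Hazard ratio of group_a vs group_b from a two-group Cox fit."""
    df = categorized[categorized["category"].isin([group_a, group_b])]
    design = pd.DataFrame(
        {
            "time": df["time"].to_numpy(),
            "event": df["event"].to_numpy(),
            "is_a": (df["category"] == group_a).astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["is_a"]))


# ---------------------------------------------------------------------------
# In-silico score threshold adapters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdRule:
    """Adapter mapping a competing score to D/ND/uncertain.

    Modes: ``numeric_cutoff`` (cutoff + direction), ``category_map``
    (label → class, total over the score's vocabulary) and
    ``cutoff_with_uncertain_band`` (scores strictly inside (lower, upper)
    are uncertain).
    """

    score: str
    mode: Literal["numeric_cutoff", "category_map", "cutoff_with_uncertain_band"]
    cutoff: float | None = None
    lower: float | None = None
    upper: float | None = None
    higher_is_deleterious: bool = True
    category_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode == "numeric_cutoff" and (
            self.cutoff is None or not np.isfinite(self.cutoff)
        ):
            raise ValueError("numeric_cutoff mode needs a finite cutoff")
        if self.mode == "cutoff_with_uncertain_band":
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise ValueError("uncertain band needs lower <= upper")
        if self.mode == "category_map" and not self.category_map:
            raise ValueError("category_map mode needs a mapping")


def classify_by_threshold(
    scores: pd.Series, rule: ThresholdRule
) -> pd.Series:
    """Apply a threshold rule; missing scores become 'uncertain'."""

    def one(v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "uncertain"
        if rule.mode == "numeric_cutoff":
            hit = v >= rule.cutoff if rule.higher_is_deleterious else v <= rule.cutoff
            return "D" if hit else "ND"
        if rule.mode == "cutoff_with_uncertain_band":
            if rule.lower < v < rule.upper:
                return "uncertain"
            hit = v >= rule.upper if rule.higher_is_deleterious else v <= rule.lower
            return "D" if hit else "ND"
        mapped = rule.category_map.get(str(v))
        if mapped is None:
            raise ValueError(
                f"category {v!r} missing from the map for {rule.score}"
            )
        return mapped

    return scores.map(one)


def default_tool_rules() -> dict[str, ThresholdRule]:
    """Published cutoffs for the compared in-silico tools."""
    return {
        "polyphen": ThresholdRule(
            "polyphen", "category_map",
            category_map={
                "probably damaging": "D", "possibly damaging": "D", "benign": "ND",
            },
        ),
        "mutationassessor": ThresholdRule(
            "mutationassessor", "category_map",
            category_map={
                "high": "D", "medium": "D", "low": "ND", "neutral": "ND",
            },
        ),
        "revel_b": ThresholdRule("revel_b", "numeric_cutoff", cutoff=0.5),
        "revel_c": ThresholdRule("revel_c", "numeric_cutoff", cutoff=0.7),
        "chasm": ThresholdRule("chasm", "numeric_cutoff", cutoff=0.768),
        "chasm_gene_truthset": ThresholdRule(
            "chasm_gene_truthset", "numeric_cutoff", cutoff=0.892
        ),
    }
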