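"""Per-variant prevalence statistics flagging SNP-like outliers.

Tumor-level records (which variants co-occur in each sample, and whether
the sample is germline or somatic) support two descriptive statistics:

* the germline-to-somatic (GVS) ratio — the variant's relative frequency
  among germline records divided by its relative frequency among somatic
  records.  Values far above 1 flag likely constitutional polymorphisms
  misfiled as somatic calls.  The ratio of relative frequencies with an
  additive pseudocount is an interpretation adopted here, documented as
  such.
* the multiple-mutation frequency (MMF) — the fraction of tumors carrying
  the variant in which it co-occurs with at least one other variant of the
  same gene.  High values flag passengers and low-frequency SNPs that ride
  along with a true driver.

Frequency rankings order variants by occurrence count (descending, stable
tie order by key) with log2 counts for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TumorRecord:
    """One tumor sample and the gene variants it carries."""

    sample_id: str
    origin: str  # "somatic" | "germline"
    variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.origin not in ("somatic", "germline"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if len(self.variants) == 0:
            raise ValueError("a tumor record must carry >=1 variant")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variants must be unique within a record")


def gvs_ratio(
    records: Sequence[TumorRecord], variant: str, pseudocount: float = 0.5
) -> float:
    """Germline-to-somatic relative-frequency ratio with pseudocount.

    ((g_v + a)/(G + a)) / ((s_v + a)/(S + a)) where g_v, s_v count the
    variant's germline/somatic records and G, S the corpus totals.  With
    a > 0 the ratio is always finite and positive.
    """
    g_total = sum(1 for r in records if r.origin == "germline")
    s_total = sum(1 for r in records if r.origin == "somatic")
    if pseudocount <= 0 and (g_total == 0 or s_total == 0):
        raise ValueError("corpus must contain both germline and somatic records")
    g_v = sum(1 for r in records if r.origin == "germline" and variant in r.variants)
    s_v = sum(1 for r in records if r.origin == "somatic" and variant in r.variants)
    a = pseudocount
    return ((g_v + a) / (g_total + a)) / ((s_v + a) / (s_total + a))


def mmf(records: Sequence[TumorRecord], variant: str) -> float | None:
    """Fraction of the variant's tumors where it co-occurs with another
    variant; None when the variant is never observed."""
    carrying = [r for r in records if variant in r.variants]
    if not carrying:
        return None
    multi = sum(1 for r in carrying if len(r.variants) > 1)
    return multi / len(carrying)


def frequency_ranking(occ: pd.DataFrame) -> pd.DataFrame:
    """Descending occurrence-count ranking with stable key tie order.

    Input is an occurrence table (variant, dataset_id, count); counts are
    summed per variant.  log2_count is NaN for zero counts (undefined).
    """
    if (occ["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    totals = occ.groupby("variant")["count"].sum().reset_index()
    totals = totals.sort_values(
        by=["count", "variant"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    totals["log2_count"] = [
        math.log2(c) if c > 0 else np.nan for c in totals["count"]
    ]
    totals["rank"] = np.arange(1, len(totals) + 1)
    return totals
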