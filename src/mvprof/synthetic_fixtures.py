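"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real inputs —
multi-database occurrence tables with a planted shared (positive) set and
absent/singleton (negative) sets, bimodal functional-assay scores driven
by a latent functionality class, weaker-signal computational scores,
domain-restricted missingness, a tumor corpus with the canonical
91/7/2% single/double/multi-variant composition, and survival cohorts
with category-dependent hazards — while recording full ground truth so
every stage is testable without downloads.

All randomness flows from the single seed in :class:`FixtureConfig`;
fixtures are byte-identical across runs for a fixed configuration.

Score model
-----------
Each variant carries a latent loss-of-function degree
``z ~ N(separation_sd · 1[deleterious], latent_sd²)``.  Functional assay
readouts are affine in z plus per-assay noise (transactivation drops as z
grows; screen readouts rise); the average and median transactivation
readouts are derived from the eight promoter readouts, as in real assay
tables.  Computational scores see z through a weaker weight and more
noise.  The default separation (3.4 latent sd) puts the generating
mixture's Bayes-optimal accuracy, under the labeled cohort's ~22/78 class
imbalance, at ≈96.5% — the mid-90s regime typical of well-powered
functional classification; see docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mvprof.feature_table import FeatureMatrix, default_feature_specs
from mvprof.prevalence_stats import TumorRecord
from mvprof.variant_space import CodingSequence, VariantSpace, enumerate_snvs

SENSE_CODONS = None  # filled lazily


def _sense_codons() -> list[str]:
    global SENSE_CODONS
    if SENSE_CODONS is None:
        from mvprof.variant_space import BASES, _codon_map

        table = _codon_map(1)
        SENSE_CODONS = sorted(
            c for c, aa in table.items() if aa != "*" and c != "ATG"
        )
    return SENSE_CODONS


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the synthetic study.

    Defaults mirror the real study's set sizes (a 394-codon ORF; 290
    shared-dataset positives; 693 absent + 323 singleton negatives; 7 + 5
    hold-outs plus 29 unlabeled hold-outs completing the 41 kept for
    experimental validation) so accounting tests read naturally.
    """

    seed: int = 0
    n_codons: int = 394
    n_datasets: int = 4
    csd_size: int = 290
    n_absent: int = 693
    n_singleton: int = 323
    holdout_positive: int = 7
    holdout_negative: int = 5
    holdout_unlabeled: int = 29
    p_unlabeled_deleterious: float = 0.5
    # score model
    separation_sd: float = 3.4
    latent_sd: float = 1.0
    functional_noise_sd: float = 0.5
    computational_weight: float = 0.5
    computational_noise_sd: float = 1.0
    contamination: float = 0.0
    # missingness
    domain_codon_range: tuple[int, int] = (94, 312)
    random_missing_rate: float = 0.02
    # tumor corpus
    n_tumors: int = 20000
    tumor_fractions: tuple[float, float, float] = (0.91, 0.07, 0.02)
    germline_fraction: float = 0.1
    # survival
    n_samples: int = 2000
    category_sizes: dict | None = None
    hazard_ratios: dict | None = None
    baseline_hazard: float = 0.01
    censoring_hazard: float = 0.01

    def __post_init__(self) -> None:
        if abs(sum(self.tumor_fractions) - 1.0) > 1e-9:
            raise ValueError("tumor composition fractions must sum to 1")
        for name in ("latent_sd", "functional_noise_sd", "computational_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated study with its ground-truth manifest."""

    space: VariantSpace
    occurrences: pd.DataFrame
    features: FeatureMatrix
    truth: pd.DataFrame  # variant, latent_class (D/ND), provenance
    holdout: set[str]
    dataset_ids: list[str]

    @property
    def planted(self) -> dict[str, set[str]]:
        out = {}
        for prov in ("csd", "absent", "singleton", "unlabeled"):
            out[prov] = set(
                self.truth.loc[self.truth["provenance"] == prov, "variant"]
            )
        return out


def random_orf(rng: np.random.Generator, n_codons: int) -> CodingSequence:
    """A random ORF: ATG + (n-2) random sense codons + a stop codon."""
    if n_codons < 3:
        raise ValueError("an ORF needs at least 3 codons")
    body = rng.choice(_sense_codons(), size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    bases = "ATG" + "".join(body) + stop
    return CodingSequence(id=f"synthetic_orf_{n_codons}", bases=bases)


def _codon_of(key: str) -> int:
    return int("".join(ch for ch in key if ch.isdigit()))


def generate_cohort(cfg: FixtureConfig) -> SyntheticCohort:
    """Generate the occurrence table, feature matrix and truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    cds = random_orf(rng, cfg.n_codons)
    space = enumerate_snvs(cds)
    keys = sorted(v.key for v in space.protein_missense)
    n_planted = cfg.csd_size + cfg.n_absent + cfg.n_singleton
    if n_planted + cfg.holdout_unlabeled > len(keys):
        raise ValueError(
            f"planted sets ({n_planted}+{cfg.holdout_unlabeled} holdout) "
            f"exceed the {len(keys)}-variant space"
        )
    keys_arr = np.array(keys)
    rng.shuffle(keys_arr)
    csd = list(keys_arr[: cfg.csd_size])
    absent = list(keys_arr[cfg.csd_size : cfg.csd_size + cfg.n_absent])
    singleton = list(keys_arr[cfg.csd_size + cfg.n_absent : n_planted])
    unlabeled = list(keys_arr[n_planted:])

    # latent functionality: planted positives are deleterious, planted
    # negatives functional, the remainder mixed
    latent = {}
    for v in csd:
        latent[v] = "D"
    for v in absent + singleton:
        latent[v] = "ND"
    for v in unlabeled:
        latent[v] = "D" if rng.random() < cfg.p_unlabeled_deleterious else "ND"

    dataset_ids = [f"db{i + 1}" for i in range(cfg.n_datasets)]
    rows = []
    for v in csd:
        intensity = rng.lognormal(mean=0.5, sigma=1.0)
        for d in dataset_ids:
            rows.append((v, d, 1 + rng.poisson(intensity)))
    for v in singleton:
        d = dataset_ids[rng.integers(cfg.n_datasets)]
        rows.append((v, d, 1))
    for v in unlabeled:
        # observed more than once but never in every database
        k = int(rng.integers(1, cfg.n_datasets))  # 1..n_datasets-1 databases
        chosen = rng.choice(cfg.n_datasets, size=k, replace=False)
        intensity = rng.lognormal(mean=0.0, sigma=1.0)
        counts = 1 + rng.poisson(intensity, size=k)
        if k == 1 and counts[0] < 2:
            counts[0] = 2
        for d_idx, c in zip(chosen, counts):
            rows.append((v, dataset_ids[d_idx], int(c)))
    occurrences = pd.DataFrame(rows, columns=["variant", "dataset_id", "count"])

    # hold-outs for experimental validation
    holdout = set(
        list(rng.choice(csd, size=cfg.holdout_positive, replace=False))
        + list(
            rng.choice(
                absent + singleton, size=cfg.holdout_negative, replace=False
            )
        )
        + list(
            rng.choice(unlabeled, size=cfg.holdout_unlabeled, replace=False)
        )
    )

    features = _generate_features(rng, keys, latent, cfg)

    truth = pd.DataFrame(
        {
            "variant": keys,
            "latent_class": [latent[v] for v in keys],
            "provenance": [
                "csd" if v in set(csd)
                else "absent" if v in set(absent)
                else "singleton" if v in set(singleton)
                else "unlabeled"
                for v in keys
            ],
            "holdout": [v in holdout for v in keys],
        }
    )
    return SyntheticCohort(
        space=space,
        occurrences=occurrences,
        features=features,
        truth=truth,
        holdout=holdout,
        dataset_ids=dataset_ids,
    )


def _generate_features(
    rng: np.random.Generator,
    keys: Sequence[str],
    latent: dict[str, str],
    cfg: FixtureConfig,
) -> FeatureMatrix:
    specs = default_feature_specs()
    n = len(keys)
    is_d = np.array([latent[v] == "D" for v in keys])
    if cfg.contamination > 0:
        flip = rng.random(n) < cfg.contamination
        z_class = np.where(flip, ~is_d, is_d)
    else:
        z_class = is_d
    z = cfg.separation_sd * z_class.astype(float) + rng.normal(
        0.0, cfg.latent_sd, size=n
    )

    cols: dict[str, np.ndarray] = {}
    promoter_cols = []
    for spec in specs:
        if spec.name.startswith("trans_") and spec.name not in (
            "trans_avg", "trans_median",
        ):
            # transactivation in % of wild type: drops with loss of function
            vals = 100.0 - 25.0 * z + rng.normal(
                0.0, 25.0 * cfg.functional_noise_sd, size=n
            )
            cols[spec.name] = vals
            promoter_cols.append(spec.name)
    promoters = np.column_stack([cols[c] for c in promoter_cols])
    cols["trans_avg"] = promoters.mean(axis=1)
    cols["trans_median"] = np.median(promoters, axis=1)
    for name, sign in (
        ("cell_cycle_arrest", -1.0),  # arrest function lost with z
        ("dominant_negative", +1.0),
        ("lof_screen", +1.0),
        ("etoposide_response", -1.0),
    ):
        cols[name] = sign * z + rng.normal(
            0.0, cfg.functional_noise_sd, size=n
        )
    for spec in specs:
        if spec.group == "computational":
            cols[spec.name] = cfg.computational_weight * z + rng.normal(
                0.0, cfg.computational_noise_sd, size=n
            )

    values = pd.DataFrame(
        {s.name: cols[s.name] for s in specs}, index=list(keys)
    )

    # domain-restricted missingness: the cell-cycle-arrest screen covers
    # only a codon interval (emulating a DNA-binding-domain-only assay)
    codons = np.array([_codon_of(v) for v in keys])
    lo, hi = cfg.domain_codon_range
    outside = (codons < lo) | (codons > hi)
    values.loc[outside, "cell_cycle_arrest"] = np.nan
    if cfg.random_missing_rate > 0:
        comp = [s.name for s in specs if s.group == "computational"]
        drop = rng.random((n, len(comp))) < cfg.random_missing_rate
        arr = values[comp].to_numpy()
        arr[drop] = np.nan
        values[comp] = arr
    return FeatureMatrix(values, specs)


def generate_tumor_corpus(
    cfg: FixtureConfig, variant_pool: Sequence[str] | None = None
) -> list[TumorRecord]:
    """Tumor records with the configured 1/2/3-variant composition."""
    rng = np.random.default_rng(cfg.seed + 1)
    if variant_pool is None:
        variant_pool = [f"V{i}" for i in range(200)]
    pool = np.asarray(variant_pool)
    sizes = rng.choice([1, 2, 3], size=cfg.n_tumors, p=list(cfg.tumor_fractions))
    origins = np.where(
        rng.random(cfg.n_tumors) < cfg.germline_fraction, "germline", "somatic"
    )
    records = []
    for i in range(cfg.n_tumors):
        chosen = rng.choice(pool, size=sizes[i], replace=False)
        records.append(
            TumorRecord(f"T{i:06d}", str(origins[i]), tuple(chosen))
        )
    return records


DEFAULT_HAZARD_RATIOS = {
    "no_mutation": 0.7,
    "missense_ND": 1.0,
    "missense_D": 2.0,
    "truncating": 2.0,
}

# proportions of the four categories in a pan-cancer somatic corpus
DEFAULT_CATEGORY_PROPORTIONS = {
    "no_mutation": 0.677,
    "missense_ND": 0.006,
    "missense_D": 0.206,
    "truncating": 0.111,
}

TUMOR_TYPES = ("BRCA", "LUAD", "COAD", "OV", "HNSC", "UCEC")


def generate_survival_cohort(
    cfg: FixtureConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Survival cohort with exponential event times scaled per category.

    Returns (cohort frame, prediction series) — the predictions map the
    synthetic missense variant keys to the class the generator intends,
    so categorization recovers the ground-truth category exactly.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    hr = dict(DEFAULT_HAZARD_RATIOS)
    if cfg.hazard_ratios:
        hr.update(cfg.hazard_ratios)
    if any(v <= 0 for v in hr.values()):
        raise ValueError("hazard ratios must be positive")
    if cfg.category_sizes:
        sizes = dict(cfg.category_sizes)
    else:
        sizes = {
            c: int(round(p * cfg.n_samples))
            for c, p in DEFAULT_CATEGORY_PROPORTIONS.items()
        }

    rows = []
    preds = {}
    i = 0
    for cat, n_cat in sizes.items():
        if cat not in DEFAULT_HAZARD_RATIOS:
            raise ValueError(f"unknown survival category {cat!r}")
        lam = cfg.baseline_hazard * hr[cat]
        t_event = rng.exponential(1.0 / lam, size=n_cat)
        if cfg.censoring_hazard > 0:
            t_cens = rng.exponential(1.0 / cfg.censoring_hazard, size=n_cat)
        else:
            t_cens = np.full(n_cat, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        types = rng.choice(TUMOR_TYPES, size=n_cat)
        for j in range(n_cat):
            if cat == "no_mutation":
                variants = []
            elif cat == "truncating":
                variants = [(f"trunc_{i}", "Nonsense_Mutation")]
            else:
                key = f"mis_{i}"
                variants = [(key, "Missense_Mutation")]
                preds[key] = "D" if cat == "missense_D" else "ND"
            rows.append(
                {
                    "patient_id": f"P{i:06d}",
                    "sample_id": f"S{i:06d}",
                    "variants": variants,
                    "time": float(time[j]),
                    "event": int(event[j]),
                    "tumor_type": str(types[j]),
                    "true_category": cat,
                }
            )
            i += 1
    cohort = pd.DataFrame(rows)
    if cohort["event"].sum() == 0:
        raise ValueError("censoring removed every event; nothing to analyze")
    return cohort, pd.Series(preds, dtype=object)
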