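"""Readers and writers for the pipeline's table formats.

TSV with a header row is the canonical dialect (CSV accepted on read),
UTF-8 throughout; HGVS strings are never locale-formatted.  FASTA carries
the CDS, YAML the configs and feature specs, JSON the metrics blocks and
run manifests.  MAF-style column names (``Tumor_Sample_Barcode``,
``Variant_Classification``, ``HGVSp_Short``) are recognized by the
survival reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from mvprof.feature_table import FeatureMatrix, FeatureSpec
from mvprof.variant_space import CodingSequence, VariantSpace, protein_key


def read_cds_fasta(path: str | Path, **kwargs) -> CodingSequence:
    """Read the first record of a FASTA file as a coding sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rec = records[0]
    return CodingSequence(id=rec.id, bases=str(rec.seq).upper(), **kwargs)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def space_to_frame(space: VariantSpace) -> pd.DataFrame:
    """The enumerated space as a table (one row per substitution event)."""
    rows = [
        {
            "hgvs_c": e.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "codon": v.codon_number,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "consequence": v.consequence,
        }
        for e, v in space.snvs
    ]
    return pd.DataFrame(rows)


def write_space(space: VariantSpace, path: str | Path) -> None:
    space_to_frame(space).to_csv(path, sep="\t", index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = {"variant", "dataset_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: occurrence table lacks {sorted(missing)}")
    return df


def write_occurrences(occ: pd.DataFrame, path: str | Path) -> None:
    occ.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path: str | Path, specs: list[FeatureSpec]
) -> FeatureMatrix:
    """Feature TSV/CSV with a ``variant`` index column."""
    df = _read_table(path)
    if "variant" not in df.columns:
        raise ValueError(f"{path}: feature table needs a 'variant' column")
    df = df.set_index("variant")
    names = [s.name for s in specs]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {missing}")
    return FeatureMatrix(df[names], specs)


def write_feature_table(m: FeatureMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "variant", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_feature_specs(path: str | Path) -> list[FeatureSpec]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [
        FeatureSpec(
            name=d["name"],
            group=d["group"],
            source=d.get("source", ""),
            higher_is_deleterious=d.get("higher_is_deleterious"),
        )
        for d in raw
    ]


def write_feature_specs(specs: Sequence[FeatureSpec], path: str | Path) -> None:
    data = [
        {
            "name": s.name,
            "group": s.group,
            "source": s.source,
            "higher_is_deleterious": s.higher_is_deleterious,
        }
        for s in specs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_labels(path: str | Path) -> pd.Series:
    df = _read_table(path)
    if not {"variant", "label"} <= set(df.columns):
        raise ValueError(f"{path}: labels need 'variant' and 'label' columns")
    df = df[df["label"].isin(["D", "ND"])]
    return df.set_index("variant")["label"]


def read_predictions(path: str | Path) -> pd.Series:
    df = _read_table(path)
    if not {"variant", "class"} <= set(df.columns):
        raise ValueError(f"{path}: predictions need 'variant' and 'class'")
    return df.set_index("variant")["class"]


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """MAF-like mutation rows + survival columns → one row per sample.

    Recognized column aliases: sample_id/Tumor_Sample_Barcode,
    variant_class/Variant_Classification, variant/HGVSp_Short.  Samples
    with an empty variant_class contribute a no-mutation row.
    """
    df = _read_table(path)
    alias = {
        "Tumor_Sample_Barcode": "sample_id",
        "Variant_Classification": "variant_class",
        "HGVSp_Short": "variant",
    }
    df = df.rename(columns={k: v for k, v in alias.items() if k in df.columns})
    required = {"sample_id", "patient_id", "time", "event", "tumor_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: survival table lacks {sorted(missing)}")
    rows = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        variants = []
        for _, r in grp.iterrows():
            vc = r.get("variant_class")
            if isinstance(vc, str) and vc.strip():
                raw_key = str(r.get("variant", ""))
                key = protein_key(raw_key) or raw_key
                variants.append((key, vc))
        rows.append(
            {
                "patient_id": first["patient_id"],
                "sample_id": sample_id,
                "variants": variants,
                "time": float(first["time"]),
                "event": int(first["event"]),
                "tumor_type": first["tumor_type"],
            }
        )
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (inputs, seeds, chosen parameters)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
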