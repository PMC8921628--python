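"""Enumeration of the single-nucleotide substitution space of an ORF.

Every coding position of a CDS can mutate to three alternative bases, so an
ORF of L nucleotides sustains exactly 3L substitution events.  Each event is
translated in place (only the affected codon changes), classified by
consequence, and deduplicated at the protein level: several cDNA events may
produce the same amino-acid change.  For a typical tumor-suppressor ORF of
394 codons (393 residues + stop) this yields 3546 events.

Conventions (configurable where noted):

* codon-1 (initiator) non-synonymous changes count as missense protein
  variants, flagged ``start_codon=True``;
* substitutions inside the stop codon are classified ``stop_loss`` /
  ``stop_retained`` and are excluded from the missense protein space;
* coordinates are 1-based CDS positions, matching HGVS ``c.`` numbering;
* amino acids use one-letter codes with ``*`` for stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable, IUPACData

BASES = ("A", "C", "G", "T")

AA_3TO1 = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}
AA_3TO1["TER"] = "*"
AA_1TO3 = {v: k for k, v in IUPACData.protein_letters_3to1.items()}
AA_1TO3["*"] = "Ter"

CONSEQUENCES = ("synonymous", "missense", "nonsense", "stop_loss", "stop_retained")


def _codon_map(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence (ORF) given 5'→3' on the coding strand."""

    id: str
    bases: str
    codon_table: int = 1
    require_start: bool = False
    require_stop: bool = False

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if len(bases) == 0 or len(bases) % 3 != 0:
            raise ValueError(
                f"CDS length {len(bases)} is not a positive multiple of 3"
            )
        bad = set(bases) - set(BASES)
        if bad:
            raise ValueError(f"CDS contains non-ACGT bases: {sorted(bad)}")
        codons = self.codons()
        table = CodonTable.unambiguous_dna_by_id[self.codon_table]
        if self.require_start and codons[0] not in table.start_codons:
            raise ValueError(f"first codon {codons[0]} is not a start codon")
        if self.require_stop and codons[-1] not in table.stop_codons:
            raise ValueError(f"last codon {codons[-1]} is not a stop codon")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        return len(self.bases) // 3

    def codons(self) -> list[str]:
        return [self.bases[i : i + 3] for i in range(0, len(self.bases), 3)]


@dataclass(frozen=True)
class SnvEvent:
    """A single-nucleotide substitution within a CDS (1-based coordinates)."""

    cds_position: int
    ref_base: str
    alt_base: str
    codon_index: int
    ref_codon: str
    alt_codon: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        phase = (self.cds_position - 1) % 3
        if self.ref_codon and self.ref_codon[phase] != self.ref_base:
            raise ValueError("ref_codon inconsistent with ref_base at phase")
        if self.codon_index != (self.cds_position + 2) // 3:
            raise ValueError("codon_index inconsistent with cds_position")

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.cds_position}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class ProteinVariant:
    """An amino-acid substitution, with its consequence class."""

    ref_aa: str
    codon_number: int
    alt_aa: str
    consequence: str
    start_codon: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        c = self.consequence
        ref, alt = self.ref_aa, self.alt_aa
        ok = {
            "synonymous": ref == alt and ref != "*",
            "stop_retained": ref == "*" and alt == "*",
            "missense": ref != "*" and alt != "*" and ref != alt,
            "nonsense": ref != "*" and alt == "*",
            "stop_loss": ref == "*" and alt != "*",
        }[c]
        if not ok:
            raise ValueError(
                f"consequence {c} inconsistent with {ref}{self.codon_number}{alt}"
            )

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.codon_number}{self.alt_aa}"

    @property
    def key(self) -> str:
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


@dataclass(frozen=True)
class UnsupportedVariant:
    """Marker for HGVS notation outside the simple-substitution grammar.

    ClinVar-style tables contain indels, splice and intronic records; those
    are flagged rather than raising so curation can drop them with
    accounting.
    """

    text: str
    reason: str = "unsupported variant class"


@dataclass
class VariantSpace:
    """The complete substitution space of one CDS."""

    cds: CodingSequence
    snvs: list[tuple[SnvEvent, ProteinVariant]] = field(default_factory=list)
    include_start_codon_missense: bool = True

    @property
    def cdna_missense(self) -> list[tuple[SnvEvent, ProteinVariant]]:
        return [
            (e, v)
            for e, v in self.snvs
            if v.consequence == "missense"
            and (self.include_start_codon_missense or not v.start_codon)
        ]

    @property
    def protein_missense(self) -> list[ProteinVariant]:
        seen: dict[tuple[str, int, str], ProteinVariant] = {}
        for _, v in self.cdna_missense:
            seen.setdefault((v.ref_aa, v.codon_number, v.alt_aa), v)
        return list(seen.values())

    @property
    def index(self) -> dict[str, list[SnvEvent]]:
        out: dict[str, list[SnvEvent]] = {}
        for e, v in self.cdna_missense:
            out.setdefault(v.hgvs_p, []).append(e)
        return out

    def consequence_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONSEQUENCES}
        for _, v in self.snvs:
            counts[v.consequence] += 1
        return counts


def classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == "*":
        return "stop_retained" if alt_aa == "*" else "stop_loss"
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


def enumerate_snvs(
    cds: CodingSequence, include_start_codon_missense: bool = True
) -> VariantSpace:
    """Enumerate all 3L substitution events of a CDS with consequences.

    Parameters
    ----------
    cds:
        The validated coding sequence.
    include_start_codon_missense:
        When True (default), non-synonymous changes in codon 1 count as
        missense protein variants (flagged ``start_codon``); when False
        the events are still enumerated but dropped from the missense
        views.
    """
    table = _codon_map(cds.codon_table)
    space = VariantSpace(
        cds=cds, include_start_codon_missense=include_start_codon_missense
    )
    codons = cds.codons()
    for pos in range(1, len(cds.bases) + 1):
        ci = (pos + 2) // 3  # 1-based codon index
        phase = (pos - 1) % 3
        ref_codon = codons[ci - 1]
        ref_base = ref_codon[phase]
        ref_aa = table[ref_codon]
        for alt in BASES:
            if alt == ref_base:
                continue
            alt_codon = ref_codon[:phase] + alt + ref_codon[phase + 1 :]
            alt_aa = table[alt_codon]
            event = SnvEvent(pos, ref_base, alt, ci, ref_codon, alt_codon)
            variant = ProteinVariant(
                ref_aa, ci, alt_aa, classify(ref_aa, alt_aa),
                start_codon=(ci == 1),
            )
            space.snvs.append((event, variant))
    return space


def format_hgvs(
    event: SnvEvent,
    variant: ProteinVariant,
    transcript: str | None = None,
    protein: str | None = None,
) -> tuple[str, str]:
    """Format an (event, variant) pair as HGVS c. and p. strings.

    Prefixes with ``<accession>:`` when accessions are given, e.g.
    ``NM_000546:c.743G>A`` / ``NP_000537:p.R248Q``.
    """
    table = _codon_map(1)
    if table[event.alt_codon] != variant.alt_aa or table[event.ref_codon] != variant.ref_aa:
        raise ValueError(
            f"event {event.hgvs_c} does not produce variant {variant.hgvs_p}"
        )
    hgvs_c = event.hgvs_c
    hgvs_p = variant.hgvs_p
    if transcript:
        hgvs_c = f"{transcript}:{hgvs_c}"
    if protein:
        hgvs_p = f"{protein}:{hgvs_p}"
    return hgvs_c, hgvs_p


_C_RE = re.compile(r"^(?:[A-Za-z0-9_.]+:)?c\.(\d+)([ACGT])>([ACGT])$")
_P1_RE = re.compile(r"^(?:[A-Za-z0-9_.]+:)?p\.\(?([A-Z*])(\d+)([A-Z*])\)?$")
_P3_RE = re.compile(
    r"^(?:[A-Za-z0-9_.]+:)?p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)\)?$"
)


def parse_hgvs(text: str) -> SnvEvent | ProteinVariant | UnsupportedVariant:
    """Parse a simple-substitution HGVS string.

    Supports ``c.NNNX>Y`` and ``p.XnY`` (one- or three-letter amino-acid
    codes, optional accession prefix).  Anything else — indels, splice,
    intronic offsets — returns an :class:`UnsupportedVariant` marker so
    table readers can drop such records with accounting instead of
    crashing.
    """
    text = text.strip()
    m = _C_RE.match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if ref == alt:
            return UnsupportedVariant(text, "ref equals alt")
        ci = (pos + 2) // 3
        # codon context unknown from the string alone
        return SnvEvent(pos, ref, alt, ci, "", "")
    m = _P3_RE.match(text)
    if m:
        ref3, num, alt3 = m.groups()
        ref = AA_3TO1.get(ref3.upper())
        alt = "*" if alt3 == "*" else AA_3TO1.get(alt3.upper())
        if ref is None or alt is None:
            return UnsupportedVariant(text, "unknown amino-acid code")
        return ProteinVariant(ref, int(num), alt, classify(ref, alt))
    m = _P1_RE.match(text)
    if m:
        ref, num, alt = m.group(1), int(m.group(2)), m.group(3)
        return ProteinVariant(ref, num, alt, classify(ref, alt))
    return UnsupportedVariant(text)


def protein_key(text: str) -> str | None:
    """Normalize an HGVS p. string to a bare ``R175H``-style key.

    Returns None for unparseable or non-substitution notation.
    """
    parsed = parse_hgvs(text)
    if isinstance(parsed, ProteinVariant):
        return parsed.key
    return None
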