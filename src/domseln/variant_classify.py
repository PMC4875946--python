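"""Variant -> codon mapping, effect/region/MAF classification, fixed divergences,
and the region x effect x frequency-class counts table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .data_model_io import (
    DOMAIN,
    STOP_CODONS,
    UNASSIGNED,
    CodingSequence,
    RegionPartition,
    Variant,
    reverse_complement,
)

logger = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

RARE = "rare"
LOW = "low"
COMMON = "common"
FIXED = "fixed"

MAF_CLASSES = (RARE, LOW, COMMON)
ALL_CLASSES = (RARE, LOW, COMMON, FIXED)
REGIONS = (DOMAIN, UNASSIGNED)
EFFECTS = (NONSYNONYMOUS, SYNONYMOUS)

#: MAF boundaries: rare < RARE_MAX; RARE_MAX <= low <= LOW_MAX; common > LOW_MAX
RARE_MAX = 0.005
LOW_MAX = 0.05

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for a stop."""
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"not a codon: {codon!r}") from None


def classify_effect(ref_codon: str, offset_in_codon: int, alt_base: str) -> str:
    """Effect of substituting ``alt_base`` at position ``offset_in_codon`` (1..3).

    Synonymous iff the encoded amino acid is unchanged under the standard
    code; changes creating a stop codon count as non-synonymous.  The
    reference codon must be a sense codon (terminal stops are excluded
    upstream of classification).
    """
    ref_codon = ref_codon.upper()
    alt_base = alt_base.upper()
    if ref_codon in STOP_CODONS:
        raise ValueError(f"reference codon {ref_codon} is a stop codon")
    if offset_in_codon not in (1, 2, 3):
        raise ValueError(f"offset_in_codon must be 1..3, got {offset_in_codon}")
    if ref_codon[offset_in_codon - 1] == alt_base:
        raise ValueError("alt base equals the reference base at this offset")
    alt_codon = (
        ref_codon[: offset_in_codon - 1] + alt_base + ref_codon[offset_in_codon:]
    )
    return (
        SYNONYMOUS
        if translate_codon(alt_codon) == translate_codon(ref_codon)
        else NONSYNONYMOUS
    )


def maf_class(maf: float) -> str:
    """Frequency class: rare (<0.5%), low (0.5%..5% inclusive), common (>5%)."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf} (monomorphic sites excluded)")
    if maf < RARE_MAX:
        return RARE
    if maf <= LOW_MAX:
        return LOW
    return COMMON


def assign_region(aa_position: int, partition: RegionPartition) -> str:
    """Region label of the codon holding the variant."""
    return partition.region_of(aa_position)


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: Variant
    gene_id: str
    cds_pos: int
    codon_index: int
    offset_in_codon: int
    ref_codon: str
    alt_codon: str
    effect: str
    region: str
    maf_class: str
    is_nonsense: bool = False


@dataclass(frozen=True)
class DivergenceRecord:
    gene_id: str
    cds_pos: int
    ancestral_base: str
    derived_base: str
    effect: str
    region: str


def classify_variants(
    coding_sequences: Sequence[CodingSequence],
    partitions: Mapping[str, RegionPartition],
    variants: Iterable[Variant],
) -> tuple[list[ClassifiedVariant], dict[str, int]]:
    """Map variants onto CDSs and classify each; returns (records, QC counters).

    Variants outside any CDS classification window are skipped; variants whose
    VCF ref base disagrees with the extracted CDS base are skipped and counted
    under ``ref_mismatch``.  Each SNP in a multi-SNP codon is classified
    independently against the reference codon.
    """
    index: dict[tuple[str, int], tuple[CodingSequence, int]] = {}
    for cds in coding_sequences:
        for i in range(3 * cds.aa_len):  # terminal stop excluded
            index[cds.genomic_map[i]] = (cds, i + 1)

    out: list[ClassifiedVariant] = []
    qc = {"classified": 0, "outside_cds": 0, "ref_mismatch": 0, "monomorphic": 0}
    for v in variants:
        hit = index.get((v.chrom, v.pos))
        if hit is None:
            qc["outside_cds"] += 1
            continue
        cds, cds_pos = hit
        ref, alt = v.ref, v.alt
        if cds.strand == "-":
            ref = reverse_complement(ref)
            alt = reverse_complement(alt)
        if cds.nt_seq[cds_pos - 1].upper() != ref:
            qc["ref_mismatch"] += 1
            continue
        if v.maf == 0:
            qc["monomorphic"] += 1
            continue
        codon_index = (cds_pos - 1) // 3 + 1
        offset = (cds_pos - 1) % 3 + 1
        ref_codon = cds.codon(codon_index).upper()
        alt_codon = ref_codon[: offset - 1] + alt + ref_codon[offset:]
        effect = classify_effect(ref_codon, offset, alt)
        out.append(
            ClassifiedVariant(
                variant=v,
                gene_id=cds.gene_id,
                cds_pos=cds_pos,
                codon_index=codon_index,
                offset_in_codon=offset,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                effect=effect,
                region=assign_region(codon_index, partitions[cds.gene_id]),
                maf_class=maf_class(v.maf),
                is_nonsense=translate_codon(alt_codon) == "*",
            )
        )
        qc["classified"] += 1
    return out, qc


def call_fixed_divergence(
    cds: CodingSequence,
    ancestral_cds: str,
    polymorphic_positions: frozenset[int] | set[int],
    partition: RegionPartition | None = None,
    confidence_mask: Sequence[bool] | None = None,
) -> list[DivergenceRecord]:
    """Fixed human-derived changes against an aligned ancestral CDS.

    ``ancestral_cds`` is position-aligned with ``cds.nt_seq``; low-confidence
    ancestral calls are lower-case (or flagged False in ``confidence_mask``).
    A divergence is called where the bases differ, the ancestral call is
    high-confidence, and the 1-based CDS position is not polymorphic.  The
    effect substitutes the human base into the ancestral codon context; codons
    with several divergent sites are classified one-at-a-time left to right.
    """
    if len(ancestral_cds) != len(cds.nt_seq):
        raise ValueError(
            f"{cds.gene_id}: ancestral length {len(ancestral_cds)} != CDS length "
            f"{len(cds.nt_seq)}"
        )
    if confidence_mask is None:
        confidence_mask = [c.isupper() and c != "N" for c in ancestral_cds]
    poly = set(polymorphic_positions)
    human = cds.nt_seq.upper()
    anc = ancestral_cds.upper()

    records: list[DivergenceRecord] = []
    n_stop_context = 0
    for i in range(3 * cds.aa_len):  # terminal stop excluded
        if human[i] == anc[i] or anc[i] not in "ACGT":
            continue
        if not confidence_mask[i]:
            continue
        if (i + 1) in poly:
            continue
        codon_index = i // 3 + 1
        offset = i % 3 + 1
        anc_codon = anc[3 * (codon_index - 1) : 3 * codon_index]
        if anc_codon in STOP_CODONS:
            n_stop_context += 1
            continue
        effect = classify_effect(anc_codon, offset, human[i])
        records.append(
            DivergenceRecord(
                gene_id=cds.gene_id,
                cds_pos=i + 1,
                ancestral_base=anc[i],
                derived_base=human[i],
                effect=effect,
                region=partition.region_of(codon_index) if partition else UNASSIGNED,
            )
        )
    if n_stop_context:
        logger.warning(
            "%s: skipped %d divergences in ancestral stop-codon context",
            cds.gene_id,
            n_stop_context,
        )
    return records


@dataclass
class CountsTable:
    """Counts by region x effect x class; classes rare/low/common plus fixed.

    Pn/Ps are the polymorphic-class sums, Dn/Ds the fixed cells.
    """

    cells: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {
            (r, e, c): 0 for r in REGIONS for e in EFFECTS for c in ALL_CLASSES
        }
        for key, val in self.cells.items():
            if key not in full:
                raise KeyError(f"unknown cell {key}")
            if val < 0:
                raise ValueError(f"negative count in cell {key}")
            full[key] = int(val)
        self.cells = full

    def __getitem__(self, key: tuple[str, str, str]) -> int:
        return self.cells[key]

    def pn(self, region: str) -> int:
        return sum(self.cells[(region, NONSYNONYMOUS, c)] for c in MAF_CLASSES)

    def ps(self, region: str) -> int:
        return sum(self.cells[(region, SYNONYMOUS, c)] for c in MAF_CLASSES)

    def dn(self, region: str) -> int:
        return self.cells[(region, NONSYNONYMOUS, FIXED)]

    def ds(self, region: str) -> int:
        return self.cells[(region, SYNONYMOUS, FIXED)]

    def total_polymorphisms(self, effect: str | None = None) -> int:
        effects = EFFECTS if effect is None else (effect,)
        return sum(
            self.cells[(r, e, c)] for r in REGIONS for e in effects for c in MAF_CLASSES
        )

    def total_divergences(self) -> int:
        return sum(self.cells[(r, e, FIXED)] for r in REGIONS for e in EFFECTS)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "effect": e, "freq_class": c, "count": self.cells[(r, e, c)]}
            for r in REGIONS
            for e in EFFECTS
            for c in ALL_CLASSES
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            f"{r}|{e}|{c}": self.cells[(r, e, c)]
            for r in REGIONS
            for e in EFFECTS
            for c in ALL_CLASSES
        }

    @classmethod
    def from_json_dict(cls, d: Mapping[str, int]) -> "CountsTable":
        cells = {}
        for key, val in d.items():
            r, e, c = key.split("|")
            cells[(r, e, c)] = int(val)
        return cls(cells)


def tabulate(
    classified_variants: Iterable[ClassifiedVariant],
    divergence_records: Iterable[DivergenceRecord] = (),
) -> CountsTable:
    """Cross-tabulate classified polymorphisms and divergences."""
    cells: dict[tuple[str, str, str], int] = {}
    for cv in classified_variants:
        key = (cv.region, cv.effect, cv.maf_class)
        cells[key] = cells.get(key, 0) + 1
    for dr in divergence_records:
        key = (dr.region, dr.effect, FIXED)
        cells[key] = cells.get(key, 0) + 1
    return CountsTable(cells)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def classified_variants_frame(records: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": cv.variant.chrom,
                "pos": cv.variant.pos,
                "ref": cv.variant.ref,
                "alt": cv.variant.alt,
                "gene_id": cv.gene_id,
                "cds_pos": cv.cds_pos,
                "codon_index": cv.codon_index,
                "offset_in_codon": cv.offset_in_codon,
                "ref_codon": cv.ref_codon,
                "alt_codon": cv.alt_codon,
                "effect": cv.effect,
                "region": cv.region,
                "maf_class": cv.maf_class,
                "maf": cv.variant.maf,
                "is_nonsense": cv.is_nonsense,
            }
            for cv in records
        ]
    )


def divergence_frame(records: Iterable[DivergenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": dr.gene_id,
                "cds_pos": dr.cds_pos,
                "ancestral_base": dr.ancestral_base,
                "derived_base": dr.derived_base,
                "effect": dr.effect,
                "region": dr.region,
            }
            for dr in records
        ]
    )
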