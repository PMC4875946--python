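"""Core domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions (fixed here, converted nowhere else):

* genomic and amino-acid coordinates are 1-based inclusive (GFF/VCF style);
* internal CDS offsets are 0-based half-open and exist only inside
  :class:`CodingSequence` methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DOMAIN = "domain"
UNASSIGNED = "unassigned"

#: default E-value threshold applied when reading domain hits
DEFAULT_EVALUE_THRESHOLD = 1e-3

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ParseError(ValueError):
    """A malformed record in one of the consumed file formats."""


class InternalStopError(ValueError):
    """A CDS translates with a stop codon before its final codon."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A principal transcript's CDS structure on the genome."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    phase_of_first_cds: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.phase_of_first_cds not in {0, 1, 2}:
            raise ValueError(f"phase must be 0/1/2, got {self.phase_of_first_cds}")
        ivals = tuple(sorted(tuple(iv) for iv in self.cds_intervals))
        if not ivals:
            raise ValueError(f"{self.transcript_id}: no CDS intervals")
        prev_end = 0
        for start, end in ivals:
            if start < 1 or end < start:
                raise ValueError(
                    f"{self.transcript_id}: bad interval ({start}, {end})"
                )
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
            prev_end = end
        object.__setattr__(self, "cds_intervals", ivals)
        if self.coding_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.coding_length} "
                "not a multiple of 3"
            )

    @property
    def total_span(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def coding_length(self) -> int:
        """Length after trimming the leading phase bases."""
        return self.total_span - self.phase_of_first_cds


@dataclass(frozen=True)
class CodingSequence:
    """Spliced, strand-corrected CDS with a CDS-position -> genome map."""

    gene_id: str
    nt_seq: str
    aa_len: int
    genomic_map: tuple[tuple[str, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.nt_seq) != len(self.genomic_map):
            raise ValueError("nt_seq and genomic_map length mismatch")
        if len(self.nt_seq) not in (3 * self.aa_len, 3 * (self.aa_len + 1)):
            raise ValueError(
                f"{self.gene_id}: nt length {len(self.nt_seq)} inconsistent "
                f"with aa_len {self.aa_len}"
            )

    @property
    def has_terminal_stop(self) -> bool:
        return len(self.nt_seq) == 3 * (self.aa_len + 1)

    @property
    def coding_nt(self) -> str:
        """The classification window: codons 1..aa_len (terminal stop excluded)."""
        return self.nt_seq[: 3 * self.aa_len]

    @property
    def protein_seq(self) -> str:
        return str(Seq(self.coding_nt).translate())

    def codon(self, codon_index: int) -> str:
        """Codon by 1-based index in 1..aa_len."""
        if not 1 <= codon_index <= self.aa_len:
            raise IndexError(f"codon index {codon_index} outside 1..{self.aa_len}")
        i = 3 * (codon_index - 1)
        return self.nt_seq[i : i + 3]

    def cds_pos_of(self, chrom: str, genomic_pos: int) -> int | None:
        """1-based CDS position of a genomic coordinate, or None if outside."""
        try:
            return self.genomic_map.index((chrom, genomic_pos)) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class DomainHit:
    """One pfam_scan-style alignment of a domain model on a protein."""

    protein_id: str
    accession: str
    ali_start: int
    ali_end: int
    e_value: float

    def __post_init__(self) -> None:
        if not 1 <= self.ali_start <= self.ali_end:
            raise ValueError(
                f"{self.protein_id}/{self.accession}: bad alignment coordinates "
                f"({self.ali_start}, {self.ali_end})"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class Segment:
    aa_start: int
    aa_end: int
    label: str
    accessions: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint domain/unassigned segments exactly tiling 1..aa_len."""

    protein_id: str
    aa_len: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        expect_next = 1
        prev_label = None
        for seg in self.segments:
            if seg.aa_start != expect_next:
                raise ValueError(f"{self.protein_id}: segments do not tile 1..aa_len")
            if seg.label == prev_label:
                raise ValueError(f"{self.protein_id}: adjacent segments share a label")
            expect_next = seg.aa_end + 1
            prev_label = seg.label
        if expect_next != self.aa_len + 1:
            raise ValueError(f"{self.protein_id}: segments do not cover 1..{self.aa_len}")

    def region_of(self, aa_position: int) -> str:
        if not 1 <= aa_position <= self.aa_len:
            raise ValueError(
                f"{self.protein_id}: position {aa_position} outside 1..{self.aa_len}"
            )
        for seg in self.segments:
            if seg.aa_start <= aa_position <= seg.aa_end:
                return seg.label
        raise AssertionError("unreachable: partition tiles the protein")

    def residues_in(self, label: str) -> int:
        return sum(s.length for s in self.segments if s.label == label)

    def nt_window(self, segment: Segment) -> tuple[int, int]:
        """CDS nucleotide window (1-based inclusive) of an amino-acid segment."""
        return 3 * (segment.aa_start - 1) + 1, 3 * segment.aa_end


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with population allele counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_number: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if not 0 <= self.alt_count <= self.allele_number:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_count {self.alt_count} outside "
                f"0..{self.allele_number}"
            )

    @property
    def aaf(self) -> float:
        return self.alt_count / self.allele_number

    @property
    def maf(self) -> float:
        return min(self.aaf, 1.0 - self.aaf)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}`` preserving case."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models (GFF3 / GTF)
# ---------------------------------------------------------------------------


def _feature_attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            value = feature.attributes[name][0]
            # strip GFF3 "transcript:" style prefixes
            return value.split(":")[-1]
    return None


def read_gene_models(gff_source: str | Path) -> list[GeneModel]:
    """Read CDS features from GFF3/GTF, one :class:`GeneModel` per transcript.

    Transcripts violating the model invariants (e.g. CDS length not a
    multiple of 3) are skipped with a logged reason.
    """
    db = gffutils.create_db(
        str(gff_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        tid = _feature_attr(feat, "transcript_id", "Parent")
        if tid is None:
            raise ParseError(f"CDS feature at {feat.seqid}:{feat.start} lacks a transcript id")
        gid = _feature_attr(feat, "gene_id", "gene") or tid
        if feat.start > feat.end or feat.start < 1:
            raise ParseError(
                f"malformed coordinates for CDS at {feat.seqid}:{feat.start}-{feat.end}"
            )
        entry = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "cds": []}
        )
        phase = 0 if feat.frame in (None, ".") else int(feat.frame)
        entry["cds"].append((feat.start, feat.end, phase))

    models: list[GeneModel] = []
    for tid, entry in grouped.items():
        ivals = sorted(entry["cds"])
        # the first CDS in transcription order carries the relevant phase
        first = ivals[-1] if entry["strand"] == "-" else ivals[0]
        try:
            models.append(
                GeneModel(
                    gene_id=entry["gene_id"],
                    transcript_id=tid,
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    cds_intervals=tuple((s, e) for s, e, _ in ivals),
                    phase_of_first_cds=first[2],
                )
            )
        except ValueError as exc:
            logger.warning("skipping transcript %s: %s", tid, exc)
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 CDS features (the dialect read_gene_models consumes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            intervals = list(m.cds_intervals)
            first = intervals[-1] if m.strand == "-" else intervals[0]
            for start, end in intervals:
                phase = m.phase_of_first_cds if (start, end) == first else 0
                attrs = (
                    f"ID=CDS:{m.transcript_id}.{start};Parent=transcript:{m.transcript_id};"
                    f"gene_id={m.gene_id};transcript_id={m.transcript_id}"
                )
                fh.write(
                    f"{m.chrom}\tdomseln\tCDS\t{start}\t{end}\t.\t{m.strand}\t{phase}\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(
    genome: Mapping[str, str] | str | Path,
    gene_model: GeneModel,
    *,
    allow_internal_stop: bool = False,
) -> CodingSequence:
    """Splice and strand-correct a CDS, building the CDS->genome coordinate map.

    ``genome`` may be a ``{chrom: sequence}`` mapping or a FASTA path.
    Raises :class:`InternalStopError` on a pre-terminal stop codon unless
    ``allow_internal_stop`` (used when extracting ancestral sequences).
    """
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    if gene_model.chrom not in genome:
        raise KeyError(f"chromosome {gene_model.chrom!r} absent from genome")
    contig = genome[gene_model.chrom]

    pieces: list[str] = []
    coords: list[tuple[str, int]] = []
    for start, end in gene_model.cds_intervals:
        if end > len(contig):
            raise ValueError(
                f"{gene_model.transcript_id}: interval ({start}, {end}) exceeds "
                f"contig {gene_model.chrom} length {len(contig)}"
            )
        pieces.append(contig[start - 1 : end])
        coords.extend((gene_model.chrom, p) for p in range(start, end + 1))
    seq = "".join(pieces)
    if gene_model.strand == "-":
        seq = reverse_complement(seq)
        coords.reverse()
    phase = gene_model.phase_of_first_cds
    if phase:
        seq = seq[phase:]
        coords = coords[phase:]

    ncodons = len(seq) // 3
    upper = seq.upper()
    internal = [
        i + 1
        for i in range(ncodons - 1)
        if upper[3 * i : 3 * i + 3] in STOP_CODONS
    ]
    if internal and not allow_internal_stop:
        raise InternalStopError(
            f"{gene_model.transcript_id}: internal stop codon at codon {internal[0]}"
        )
    terminal_stop = upper[3 * (ncodons - 1) : 3 * ncodons] in STOP_CODONS
    aa_len = ncodons - 1 if terminal_stop else ncodons
    return CodingSequence(
        gene_id=gene_model.gene_id,
        nt_seq=seq,
        aa_len=aa_len,
        genomic_map=tuple(coords),
        strand=gene_model.strand,
    )


# ---------------------------------------------------------------------------
# domain hits and partitions
# ---------------------------------------------------------------------------

_DOMAIN_TSV_COLUMNS = ["protein_id", "ali_start", "ali_end", "accession", "e_value"]


def read_domain_hits(
    tsv_source: str | Path,
    e_value_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[DomainHit]:
    """Read a pfam_scan-style TSV, applying the E-value filter at read time."""
    df = pd.read_csv(tsv_source, sep="\t", dtype={"protein_id": str, "accession": str})
    missing = set(_DOMAIN_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"domain TSV missing columns: {sorted(missing)}")
    hits = []
    n_filtered = 0
    for row in df.itertuples(index=False):
        if row.e_value > e_value_threshold:
            n_filtered += 1
            continue
        hits.append(
            DomainHit(
                protein_id=row.protein_id,
                accession=row.accession,
                ali_start=int(row.ali_start),
                ali_end=int(row.ali_end),
                e_value=float(row.e_value),
            )
        )
    if n_filtered:
        logger.info("filtered %d domain hits above E=%g", n_filtered, e_value_threshold)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.protein_id, h.ali_start, h.ali_end, h.accession, h.e_value) for h in hits],
        columns=_DOMAIN_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def build_partition(hits: Iterable[DomainHit], protein_id: str, aa_len: int) -> RegionPartition:
    """Merge a protein's hit intervals into a domain/unassigned tiling of 1..aa_len."""
    mine = [h for h in hits if h.protein_id == protein_id]
    for h in mine:
        if h.ali_end > aa_len:
            raise ValueError(
                f"hit {h.accession} on {protein_id} ends at {h.ali_end} "
                f"> protein length {aa_len}"
            )
    merged: list[list] = []  # [start, end, {accessions}]
    for h in sorted(mine, key=lambda h: (h.ali_start, h.ali_end)):
        if merged and h.ali_start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], h.ali_end)
            merged[-1][2].add(h.accession)
        else:
            merged.append([h.ali_start, h.ali_end, {h.accession}])

    segments: list[Segment] = []
    cursor = 1
    for start, end, accs in merged:
        if start > cursor:
            segments.append(Segment(cursor, start - 1, UNASSIGNED))
        segments.append(Segment(start, end, DOMAIN, tuple(sorted(accs))))
        cursor = end + 1
    if cursor <= aa_len:
        segments.append(Segment(cursor, aa_len, UNASSIGNED))
    return RegionPartition(protein_id=protein_id, aa_len=aa_len, segments=tuple(segments))


# ---------------------------------------------------------------------------
# variants (VCF)
# ---------------------------------------------------------------------------

_NUCS = {"A", "C", "G", "T"}


def read_variants(vcf_source: str | Path) -> list[Variant]:
    """Read biallelic SNVs from a VCF; multi-allelic SNVs are split per alt allele.

    Allele counts come from AC/AN when present, otherwise from genotypes.
    Non-SNV alleles and records without usable counts are skipped (counted in
    the log).
    """
    variants: list[Variant] = []
    n_skipped_type = 0
    n_skipped_counts = 0
    with pysam.VariantFile(str(vcf_source)) as vf:
        for rec in vf:
            ref = rec.ref.upper() if rec.ref else ""
            if ref not in _NUCS or not rec.alts:
                n_skipped_type += 1
                continue
            an, acs = _allele_counts(rec)
            if an is None:
                n_skipped_counts += 1
                continue
            for alt, ac in zip(rec.alts, acs):
                alt = alt.upper()
                if alt not in _NUCS:
                    n_skipped_type += 1
                    continue
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        allele_number=an,
                        alt_count=ac,
                    )
                )
    if n_skipped_type:
        logger.info("skipped %d non-SNV alleles/records", n_skipped_type)
    if n_skipped_counts:
        logger.warning("skipped %d records lacking AC/AN and genotypes", n_skipped_counts)
    return variants


def _allele_counts(rec) -> tuple[int | None, list[int]]:
    info = rec.info
    if "AN" in info and "AC" in info:
        ac = info["AC"]
        acs = list(ac) if isinstance(ac, tuple) else [int(ac)]
        return int(info["AN"]), [int(a) for a in acs]
    if rec.samples:
        an = 0
        counts = [0] * len(rec.alts)
        for sample in rec.samples.values():
            for allele in sample.get("GT", ()):
                if allele is None:
                    continue
                an += 1
                if allele >= 1:
                    counts[allele - 1] += 1
        if an > 0:
            return an, counts
    return None, []


def write_variants(variants: Sequence[Variant], path: str | Path) -> None:
    """Write variants as an uncompressed VCF with AC/AN INFO fields."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">')
    header.add_line('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">')
    chrom_max: dict[str, int] = {}
    for v in variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    for chrom, mx in sorted(chrom_max.items()):
        header.add_line(f"##contig=<ID={chrom},length={mx + 1000}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref, v.alt),
            )
            rec.info["AC"] = (v.alt_count,)
            rec.info["AN"] = v.allele_number
            out.write(rec)
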