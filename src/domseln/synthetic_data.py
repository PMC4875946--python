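"""Synthetic proteomes, domain annotations, population variants, and ancestral
sequences with known ground truth, plus direct SFS simulation for the DFE stage.

Every simulator is a pure function of its inputs and the seed.  Selection in
the variant simulator acts by *thinning* non-synonymous candidates with a
region-specific acceptance probability, so density-test ground truth is the
acceptance-probability ratio; frequency-level selection is exercised
separately through :func:`simulate_sfs_pair`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import (
    DOMAIN,
    STOP_CODONS,
    CodingSequence,
    DomainHit,
    GeneModel,
    RegionPartition,
    Variant,
    build_partition,
    extract_cds,
    reverse_complement,
    write_domain_hits,
    write_fasta,
    write_gene_models,
    write_variants,
)
from .selection_dfe import QuadratureGrid, SFSPair, fold_spectrum, gamma_mixed_sfs
from .variant_classify import classify_effect, maf_class, translate_codon

_NUCS = "ACGT"
_SENSE_CODONS = sorted(
    b1 + b2 + b3
    for b1 in _NUCS
    for b2 in _NUCS
    for b3 in _NUCS
    if b1 + b2 + b3 not in STOP_CODONS
)
_STOPS = sorted(STOP_CODONS)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 100
    aa_len_range: tuple[int, int] = (60, 240)
    domain_fraction: float = 0.44
    sample_size: int = 2000  # chromosomes
    theta: float = 0.02  # per-site candidate mutation intensity
    accept_nonsyn_domain: float = 1.0
    accept_nonsyn_unassigned: float = 1.0
    divergence_rate: float = 0.01
    ancestral_mask_fraction: float = 0.05
    minus_strand_fraction: float = 0.3
    two_exon_fraction: float = 0.3
    n_accessions: int = 40
    spacer_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 2 <= self.aa_len_range[0] <= self.aa_len_range[1]:
            raise ValueError("aa_len_range must satisfy 2 <= min <= max")
        if not 0 <= self.domain_fraction <= 1:
            raise ValueError("domain_fraction must be in [0, 1]")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        for name in ("theta", "divergence_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("accept_nonsyn_domain", "accept_nonsyn_unassigned"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("ancestral_mask_fraction", "minus_strand_fraction", "two_exon_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthTable:
    """Per-record ground truth plus the generating configuration."""

    records: pd.DataFrame
    config: SimConfig


@dataclass
class Proteome:
    genome: dict[str, str]
    gene_models: list[GeneModel]
    domain_hits: list[DomainHit]
    coding: dict[str, CodingSequence]
    partitions: dict[str, RegionPartition]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gene_models": outdir / "genes.gff3",
            "domain_hits": outdir / "domains.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gene_models(self.gene_models, paths["gene_models"])
        write_domain_hits(self.domain_hits, paths["domain_hits"])
        return paths


def _random_orf(rng: np.random.Generator, aa_len: int) -> str:
    """Start codon + random sense codons + one stop codon."""
    internal = rng.choice(_SENSE_CODONS, size=aa_len - 1)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(internal) + stop


def _domain_hits_for_gene(
    rng: np.random.Generator, gene_id: str, aa_len: int, config: SimConfig
) -> list[DomainHit]:
    target = int(round(config.domain_fraction * aa_len))
    if target < 1:
        return []
    target = min(target, aa_len)
    n_blocks = 2 if (target >= 20 and rng.random() < 0.5) else 1
    block_lens = [target // n_blocks] * n_blocks
    block_lens[0] += target - sum(block_lens)
    hits: list[DomainHit] = []
    cursor = 1
    free = aa_len - target
    for blen in block_lens:
        gap = int(rng.integers(0, free + 1)) if free > 0 else 0
        free -= gap
        start = cursor + gap
        end = start + blen - 1
        acc = f"PF{int(rng.integers(1, config.n_accessions + 1)):05d}"
        e_value = float(10 ** rng.uniform(-12, -4))
        hits.append(DomainHit(gene_id, acc, start, end, e_value))
        if blen >= 10 and rng.random() < 0.2:
            # an overlapping second hit exercising interval merging downstream
            mid = start + blen // 2
            acc2 = f"PF{int(rng.integers(1, config.n_accessions + 1)):05d}"
            hits.append(DomainHit(gene_id, acc2, max(start, mid - 3), end, e_value))
        cursor = end + 1
    return hits


def generate_proteome(config: SimConfig) -> Proteome:
    """Generate a genome FASTA, gene models, and domain hits with known structure.

    ORFs have a start codon, a terminal stop, and no internal stops; a
    configurable fraction of genes sits on the minus strand and/or is split
    across two exons.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 1  # next free 1-based genomic position
    models: list[GeneModel] = []
    hits: list[DomainHit] = []

    def spacer() -> None:
        nonlocal cursor
        s = "".join(rng.choice(list(_NUCS), size=config.spacer_len))
        genome_parts.append(s)
        cursor += config.spacer_len

    for g in range(config.n_genes):
        spacer()
        gene_id = f"g{g + 1:04d}"
        aa_len = int(rng.integers(config.aa_len_range[0], config.aa_len_range[1] + 1))
        orf = _random_orf(rng, aa_len)
        minus = rng.random() < config.minus_strand_fraction
        genomic_seq = reverse_complement(orf) if minus else orf
        two_exon = rng.random() < config.two_exon_fraction and len(orf) >= 30

        if two_exon:
            cut = int(rng.integers(10, len(orf) - 10))
            if minus:
                # transcription right-to-left: second genomic piece is exon 1
                piece1, piece2 = genomic_seq[: len(orf) - cut], genomic_seq[len(orf) - cut :]
            else:
                piece1, piece2 = genomic_seq[:cut], genomic_seq[cut:]
            intron = "".join(rng.choice(list(_NUCS), size=20))
            start1 = cursor
            end1 = start1 + len(piece1) - 1
            start2 = end1 + len(intron) + 1
            end2 = start2 + len(piece2) - 1
            genome_parts.extend([piece1, intron, piece2])
            cursor = end2 + 1
            intervals = ((start1, end1), (start2, end2))
        else:
            start = cursor
            end = start + len(genomic_seq) - 1
            genome_parts.append(genomic_seq)
            cursor = end + 1
            intervals = ((start, end),)

        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=chrom,
                strand="-" if minus else "+",
                cds_intervals=intervals,
            )
        )
        hits.extend(_domain_hits_for_gene(rng, gene_id, aa_len, config))
    spacer()

    genome = {chrom: "".join(genome_parts)}
    coding = {m.gene_id: extract_cds(genome, m) for m in models}
    partitions = {
        m.gene_id: build_partition(hits, m.gene_id, coding[m.gene_id].aa_len)
        for m in models
    }
    return Proteome(genome, models, hits, coding, partitions)


def realized_domain_fraction(proteome: Proteome) -> float:
    dom = sum(p.residues_in(DOMAIN) for p in proteome.partitions.values())
    total = sum(p.aa_len for p in proteome.partitions.values())
    return dom / total


def _draw_allele_count(rng: np.random.Generator, n: int) -> int:
    """Alt-allele count from the 1/i-weighted distribution over 1..n-1."""
    weights = 1.0 / np.arange(1, n)
    return int(rng.choice(np.arange(1, n), p=weights / weights.sum()))


def simulate_variants(
    proteome: Proteome, config: SimConfig
) -> tuple[list[Variant], TruthTable]:
    """Place candidate mutations uniformly over coding sites and thin
    non-synonymous candidates by the region-specific acceptance probability.

    Retained variants get allele counts from a 1/i-weighted distribution over
    1..n-1, populating all three MAF classes; at most one variant is emitted
    per CDS position.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.sample_size
    accept = {DOMAIN: config.accept_nonsyn_domain}
    variants: list[Variant] = []
    truth_rows: list[dict] = []

    for gene_id in sorted(proteome.coding):
        cds = proteome.coding[gene_id]
        partition = proteome.partitions[gene_id]
        L = 3 * cds.aa_len
        n_candidates = rng.poisson(config.theta * L)
        if n_candidates == 0:
            continue
        positions = rng.integers(1, L + 1, size=n_candidates)
        seen: set[int] = set()
        for cds_pos in positions:
            cds_pos = int(cds_pos)
            if cds_pos in seen:
                continue
            seen.add(cds_pos)
            codon_index = (cds_pos - 1) // 3 + 1
            offset = (cds_pos - 1) % 3 + 1
            ref_codon = cds.codon(codon_index).upper()
            ref_base = ref_codon[offset - 1]
            alt_base = str(rng.choice([b for b in _NUCS if b != ref_base]))
            alt_codon = ref_codon[: offset - 1] + alt_base + ref_codon[offset:]
            effect = (
                "synonymous"
                if translate_codon(alt_codon) == translate_codon(ref_codon)
                else "nonsynonymous"
            )
            region = partition.region_of(codon_index)
            if effect == "nonsynonymous":
                p_accept = accept.get(region, config.accept_nonsyn_unassigned)
                if rng.random() > p_accept:
                    continue
            ac = _draw_allele_count(rng, n)
            chrom, pos = cds.genomic_map[cds_pos - 1]
            ref_plus, alt_plus = ref_base, alt_base
            if cds.strand == "-":
                ref_plus = reverse_complement(ref_base)
                alt_plus = reverse_complement(alt_base)
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref_plus,
                    alt=alt_plus,
                    allele_number=n,
                    alt_count=ac,
                )
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "gene_id": gene_id,
                    "cds_pos": cds_pos,
                    "codon_index": codon_index,
                    "effect": effect,
                    "region": region,
                    "maf_class": maf_class(min(ac, n - ac) / n),
                }
            )
    truth = TruthTable(pd.DataFrame(truth_rows), config)
    return variants, truth


def simulate_ancestor(
    proteome: Proteome,
    config: SimConfig,
    polymorphic: set[tuple[str, int]] | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Ancestral genome differing from the reference at Poisson-many coding
    sites, none polymorphic, with a lower-case low-confidence mask.

    At most one difference is introduced per codon, and differences that would
    put an internal stop into the ancestral CDS are skipped, so every emitted
    difference is classifiable in its ancestral codon context.
    """
    rng = np.random.default_rng(config.seed + 2)
    polymorphic = polymorphic or set()
    ancestral = {chrom: list(seq) for chrom, seq in proteome.genome.items()}
    truth_rows: list[dict] = []

    for gene_id in sorted(proteome.coding):
        cds = proteome.coding[gene_id]
        partition = proteome.partitions[gene_id]
        L = 3 * cds.aa_len
        n_div = rng.poisson(config.divergence_rate * L)
        if n_div == 0:
            continue
        touched_codons: set[int] = set()
        candidates = rng.permutation(np.arange(1, L + 1))
        placed = 0
        for cds_pos in candidates:
            if placed >= n_div:
                break
            cds_pos = int(cds_pos)
            chrom, pos = cds.genomic_map[cds_pos - 1]
            if (chrom, pos) in polymorphic:
                continue
            codon_index = (cds_pos - 1) // 3 + 1
            if codon_index in touched_codons:
                continue
            offset = (cds_pos - 1) % 3 + 1
            ref_codon = cds.codon(codon_index).upper()
            human_base = ref_codon[offset - 1]
            anc_base = str(rng.choice([b for b in _NUCS if b != human_base]))
            anc_codon = ref_codon[: offset - 1] + anc_base + ref_codon[offset:]
            if anc_codon in STOP_CODONS:
                continue
            touched_codons.add(codon_index)
            placed += 1
            # human-derived change: human base substituted into ancestral context
            effect = classify_effect(anc_codon, offset, human_base)
            anc_plus = anc_base if cds.strand == "+" else reverse_complement(anc_base)
            ancestral[chrom][pos - 1] = anc_plus
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "gene_id": gene_id,
                    "cds_pos": cds_pos,
                    "ancestral_base": anc_base,
                    "derived_base": human_base,
                    "effect": effect,
                    "region": partition.region_of(codon_index),
                }
            )

    # low-confidence mask: lower-case a random fraction of every contig
    masked_positions: dict[str, np.ndarray] = {}
    for chrom, chars in ancestral.items():
        k = int(round(config.ancestral_mask_fraction * len(chars)))
        idx = rng.choice(len(chars), size=k, replace=False) if k else np.array([], dtype=int)
        for i in idx:
            chars[i] = chars[i].lower()
        masked_positions[chrom] = np.sort(idx)

    truth = pd.DataFrame(truth_rows)
    if not truth.empty:
        truth["masked"] = [
            int(pos - 1) in set(masked_positions[chrom])
            for chrom, pos in zip(truth["chrom"], truth["pos"])
        ]
    ancestral_seqs = {chrom: "".join(chars) for chrom, chars in ancestral.items()}
    return ancestral_seqs, TruthTable(truth, config)


def simulate_sfs_pair(
    beta: float,
    s_mean: float,
    theta_sel: float,
    theta_neu: float,
    r: np.ndarray | None,
    n: int,
    L_sites: float = 1.0,
    seed: int = 0,
    folded: bool = True,
    grid: QuadratureGrid | None = None,
) -> SFSPair:
    """Poisson-sampled paired spectra under the gamma-DFE model.

    Class means: neutral theta_neu * L * r_i / i; selected
    theta_sel * L * r_i * Hbar_i with Hbar the gamma-mixed sojourn integral.
    ``r`` has one distortion per *observed* class (post-folding) and defaults
    to all ones.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    grid = grid or QuadratureGrid(n=n)
    idx = np.arange(1, n)
    neu = theta_neu * L_sites / idx
    sel = theta_sel * L_sites * gamma_mixed_sfs(beta, s_mean, grid)
    if folded:
        neu = fold_spectrum(neu, n)
        sel = fold_spectrum(sel, n)
    if r is None:
        r = np.ones_like(neu)
    r = np.asarray(r, dtype=float)
    if r.shape != neu.shape:
        raise ValueError(f"r must have {neu.shape[0]} entries")
    rng = np.random.default_rng(seed)
    return SFSPair(
        n=n,
        folded=folded,
        neutral_counts=rng.poisson(neu * r).astype(float),
        selected_counts=rng.poisson(sel * r).astype(float),
    )


def write_bundle(
    proteome: Proteome,
    variants: list[Variant],
    ancestral: dict[str, str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a full synthetic input bundle in the pipeline's file dialects."""
    outdir = Path(outdir)
    paths = proteome.write(outdir)
    paths["variants"] = outdir / "variants.vcf"
    write_variants(variants, paths["variants"])
    paths["ancestral"] = outdir / "ancestral.fa"
    write_fasta(ancestral, paths["ancestral"])
    return paths
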