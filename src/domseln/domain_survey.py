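"""Domains devoid of SNPs, the randomization null for their excess, domain
length comparisons, and protein-length vs SNP-count correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats

from .data_model_io import DomainHit
from .variant_classify import ClassifiedVariant, EFFECTS, MAF_CLASSES


@dataclass(frozen=True)
class DomainOccurrence:
    accession: str
    occurrence: int
    mean_length: float
    has_snp: bool


def domain_occurrences(
    domain_hits: Iterable[DomainHit],
    classified_variants: Iterable[ClassifiedVariant],
) -> list[DomainOccurrence]:
    """Per-accession occurrence counts and SNP status across all hit instances.

    An accession carries a SNP iff any variant's codon falls inside any of its
    hit instances on any protein.
    """
    snp_positions: dict[str, set[int]] = {}
    for cv in classified_variants:
        snp_positions.setdefault(cv.gene_id, set()).add(cv.codon_index)

    by_acc: dict[str, dict] = {}
    for hit in domain_hits:
        entry = by_acc.setdefault(hit.accession, {"lengths": [], "has_snp": False})
        entry["lengths"].append(hit.length)
        positions = snp_positions.get(hit.protein_id)
        if positions and any(hit.ali_start <= p <= hit.ali_end for p in positions):
            entry["has_snp"] = True
    return [
        DomainOccurrence(
            accession=acc,
            occurrence=len(entry["lengths"]),
            mean_length=float(np.mean(entry["lengths"])),
            has_snp=entry["has_snp"],
        )
        for acc, entry in sorted(by_acc.items())
    ]


def zero_snp_domains(
    domain_hits: Iterable[DomainHit],
    classified_variants: Iterable[ClassifiedVariant],
) -> list[DomainOccurrence]:
    """The accessions whose every hit instance is SNP-free."""
    return [d for d in domain_occurrences(domain_hits, classified_variants) if not d.has_snp]


@dataclass(frozen=True)
class RandomizationResult:
    n_snps: int
    n_reps: int
    observed_zero_count: int
    observed_mean_occurrence: float
    replicate_zero_counts: np.ndarray
    replicate_mean_occurrences: np.ndarray
    p_count: float
    p_occurrence: float
    p_count_corrected: float
    p_occurrence_corrected: float
    seed: int


def randomization_test(
    protein_lengths: Mapping[str, int],
    domain_hits: Sequence[DomainHit],
    n_snps: int,
    observed_zero_count: int,
    observed_mean_occurrence: float,
    n_reps: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation null: scatter N SNPs uniformly over all protein residues.

    Each replicate draws N residue positions independently (pooled-uniform
    over the concatenated proteome) and recomputes the number of SNP-free
    domain accessions and their mean occurrence.  p_count is the fraction of
    replicates with zero-SNP count >= observed (ties included, no +1
    correction); a +1/(n+1)-corrected variant is reported alongside.
    """
    if not protein_lengths:
        raise ValueError("empty proteome")
    if n_snps < 0 or n_reps < 1:
        raise ValueError("need n_snps >= 0 and n_reps >= 1")
    proteins = sorted(protein_lengths)
    offsets = {}
    total = 0
    for pid in proteins:
        offsets[pid] = total
        total += protein_lengths[pid]

    # sparse residue -> accession coverage matrix (total x n_accessions)
    accessions = sorted({h.accession for h in domain_hits})
    acc_index = {a: i for i, a in enumerate(accessions)}
    n_acc = len(accessions)
    rows, cols = [], []
    occurrence = np.zeros(n_acc, dtype=np.int64)
    for h in domain_hits:
        if h.protein_id not in offsets:
            raise KeyError(f"hit on unknown protein {h.protein_id}")
        base = offsets[h.protein_id]
        rows.extend(range(base + h.ali_start - 1, base + h.ali_end))
        cols.extend([acc_index[h.accession]] * h.length)
        occurrence[acc_index[h.accession]] += 1
    cover = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(total, n_acc)
    )

    rng = np.random.default_rng(seed)
    if n_snps > 0 and n_acc > 0:
        positions = rng.integers(0, total, size=(n_reps, n_snps))
        placement = scipy.sparse.csr_matrix(
            (
                np.ones(n_reps * n_snps),
                (np.repeat(np.arange(n_reps), n_snps), positions.ravel()),
            ),
            shape=(n_reps, total),
        )
        hit_counts = (placement @ cover).toarray()
        zero_mask = hit_counts == 0
    else:
        zero_mask = np.ones((n_reps, n_acc), dtype=bool)
    zero_counts = zero_mask.sum(axis=1).astype(np.int64)
    with np.errstate(invalid="ignore"):
        mean_occ = np.where(
            zero_counts > 0, (zero_mask @ occurrence) / zero_counts, np.nan
        )

    p_count = float(np.mean(zero_counts >= observed_zero_count))
    with np.errstate(invalid="ignore"):
        occ_ge = np.nan_to_num(mean_occ, nan=-np.inf) >= observed_mean_occurrence
    p_occurrence = float(np.mean(occ_ge))
    return RandomizationResult(
        n_snps=n_snps,
        n_reps=n_reps,
        observed_zero_count=observed_zero_count,
        observed_mean_occurrence=observed_mean_occurrence,
        replicate_zero_counts=zero_counts,
        replicate_mean_occurrences=mean_occ,
        p_count=p_count,
        p_occurrence=p_occurrence,
        p_count_corrected=float((np.sum(zero_counts >= observed_zero_count) + 1) / (n_reps + 1)),
        p_occurrence_corrected=float((occ_ge.sum() + 1) / (n_reps + 1)),
        seed=seed,
    )


def length_comparison(
    lengths_with_snp: Sequence[float], lengths_without: Sequence[float]
) -> tuple[float, float, float, float]:
    """(median_with, median_without, U, two-sided p) by Mann-Whitney rank-sum.

    Exact p for small tie-free samples, tie-corrected normal approximation
    otherwise (scipy's default policy).
    """
    if len(lengths_with_snp) == 0 or len(lengths_without) == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.mannwhitneyu(
        lengths_with_snp, lengths_without, alternative="two-sided"
    )
    return (
        float(np.median(lengths_with_snp)),
        float(np.median(lengths_without)),
        float(res.statistic),
        float(res.pvalue),
    )


def length_snp_correlation(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho/p between protein (CDS) length and SNP counts.

    ``per_gene`` needs a ``cds_length`` column plus one ``{effect}_{maf_class}``
    count column per cell of the effect x frequency-class layout.  A constant
    count column yields NaN rho with a flag instead of an error.
    """
    if len(per_gene) < 3:
        raise ValueError("need at least 3 genes")
    rows = []
    for effect in EFFECTS:
        for cls in MAF_CLASSES:
            col = f"{effect}_{cls}"
            if col not in per_gene.columns:
                continue
            y = per_gene[col].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(per_gene["cds_length"].to_numpy()) == 0:
                rows.append(
                    {"effect": effect, "maf_class": cls, "rho": np.nan,
                     "p_value": np.nan, "constant_input": True}
                )
                continue
            rho, p = scipy.stats.spearmanr(per_gene["cds_length"], y)
            rows.append(
                {"effect": effect, "maf_class": cls, "rho": float(rho),
                 "p_value": float(p), "constant_input": False}
            )
    return pd.DataFrame(rows)


def occurrence_frame(occurrences: Iterable[DomainOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": d.accession,
                "occurrence": d.occurrence,
                "mean_length": d.mean_length,
                "has_snp": d.has_snp,
            }
            for d in occurrences
        ]
    )
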