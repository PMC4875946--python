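"""Fractional synonymous / non-synonymous site counting and density odds-ratio tests.

Site counting is unweighted Nei-Gojobori: at each codon position the fraction
of the three possible single-base changes that are synonymous contributes to
the synonymous site total, the remainder to the non-synonymous total, so each
counted codon contributes exactly 3 sites.  Mutations to stop codons count as
non-synonymous opportunity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import scipy.stats

from .data_model_io import DOMAIN, STOP_CODONS, UNASSIGNED, CodingSequence, RegionPartition
from .variant_classify import SYNONYMOUS, classify_effect

_NUCS = "ACGT"


def _enumerate_codon_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    for offset in (1, 2, 3):
        ref_base = codon[offset - 1]
        n_syn = sum(
            1
            for alt in _NUCS
            if alt != ref_base and classify_effect(codon, offset, alt) == SYNONYMOUS
        )
        syn += n_syn / 3.0
    return syn, 3.0 - syn


_SITE_TABLE: dict[str, tuple[float, float]] = {}
for _b1 in _NUCS:
    for _b2 in _NUCS:
        for _b3 in _NUCS:
            _codon = _b1 + _b2 + _b3
            if _codon not in STOP_CODONS:
                _SITE_TABLE[_codon] = _enumerate_codon_sites(_codon)


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous sites, non-synonymous sites) of a sense codon; sums to 3."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    try:
        return _SITE_TABLE[codon]
    except KeyError:
        raise ValueError(f"not a codon: {codon!r}") from None


@dataclass
class SiteCounts:
    """Per-region fractional site totals."""

    syn_sites: dict[str, float]
    nonsyn_sites: dict[str, float]

    def syn(self, region: str) -> float:
        return self.syn_sites.get(region, 0.0)

    def nonsyn(self, region: str) -> float:
        return self.nonsyn_sites.get(region, 0.0)

    def __iadd__(self, other: "SiteCounts") -> "SiteCounts":
        for region, val in other.syn_sites.items():
            self.syn_sites[region] = self.syn_sites.get(region, 0.0) + val
        for region, val in other.nonsyn_sites.items():
            self.nonsyn_sites[region] = self.nonsyn_sites.get(region, 0.0) + val
        return self

    @classmethod
    def zero(cls) -> "SiteCounts":
        return cls({DOMAIN: 0.0, UNASSIGNED: 0.0}, {DOMAIN: 0.0, UNASSIGNED: 0.0})


def region_site_counts(cds: CodingSequence, partition: RegionPartition) -> SiteCounts:
    """Sum codon site counts over codons grouped by region; terminal stop excluded."""
    counts = SiteCounts.zero()
    seq = cds.nt_seq.upper()
    for codon_index in range(1, cds.aa_len + 1):
        codon = seq[3 * (codon_index - 1) : 3 * codon_index]
        syn, nonsyn = codon_site_counts(codon)
        region = partition.region_of(codon_index)
        counts.syn_sites[region] = counts.syn_sites.get(region, 0.0) + syn
        counts.nonsyn_sites[region] = counts.nonsyn_sites.get(region, 0.0) + nonsyn
    return counts


def total_site_counts(
    coding_sequences: Iterable[CodingSequence],
    partitions: Mapping[str, RegionPartition],
) -> SiteCounts:
    total = SiteCounts.zero()
    for cds in coding_sequences:
        total += region_site_counts(cds, partitions[cds.gene_id])
    return total


@dataclass(frozen=True)
class DensityResult:
    """2x2 density comparison: SNPs per site, domain vs unassigned."""

    effect: str
    snp_dom: int
    snp_un: int
    sites_dom: float
    sites_un: float
    odds_ratio: float
    odds_ratio_cmle: float
    p_value: float


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def density_test(
    snp_count_dom: int,
    snp_count_un: int,
    sites_dom: float,
    sites_un: float,
    effect: str = "",
) -> DensityResult:
    """Fisher's exact test on [SNPs, sites - SNPs] for domain vs unassigned.

    The reported density ratio is the sample odds ratio (a*d)/(b*c); the
    conditional-MLE odds ratio is exposed alongside.  Fractional site totals
    are rounded half-up for the exact test.
    """
    if sites_dom <= 0 or sites_un <= 0:
        raise ValueError("site totals must be positive")
    a = int(snp_count_dom)
    c = int(snp_count_un)
    b = _round_half_up(sites_dom) - a
    d = _round_half_up(sites_un) - c
    if b < 0 or d < 0:
        raise ValueError("SNP count exceeds site count")
    table = [[a, b], [c, d]]
    sample_or = (a * d) / (b * c) if b > 0 and c > 0 else float("inf")
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    cmle = scipy.stats.contingency.odds_ratio(table, kind="conditional").statistic
    return DensityResult(
        effect=effect,
        snp_dom=a,
        snp_un=c,
        sites_dom=sites_dom,
        sites_un=sites_un,
        odds_ratio=sample_or,
        odds_ratio_cmle=float(cmle),
        p_value=float(p),
    )
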