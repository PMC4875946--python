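"""Confounder controls: amino-acid composition chi-square tests and
codon-usage-bias filtering via Wright's effective number of codons (ENC)."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .data_model_io import DOMAIN, STOP_CODONS, UNASSIGNED, CodingSequence, RegionPartition
from .variant_classify import translate_codon

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

COMPOSITION_ALPHA = 0.05
ENC_CUTOFF = 50.0

# synonymous-family partition of the standard code used by Wright's ENC:
# 9 two-fold, 1 three-fold (Ile), 5 four-fold, 3 six-fold (Leu, Ser, Arg)
_FAMILIES: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _c = _b1 + _b2 + _b3
            if _c not in STOP_CODONS:
                _FAMILIES.setdefault(translate_codon(_c), []).append(_c)

#: degeneracy class -> (number of families, amino acids)
FAMILY_DEGENERACY: dict[int, list[str]] = {}
for _aa, _codons in _FAMILIES.items():
    FAMILY_DEGENERACY.setdefault(len(_codons), []).append(_aa)
# sanity: {1: [M, W], 2: 9 aas, 3: [I], 4: 5 aas, 6: [L, S, R]}


@dataclass(frozen=True)
class CompositionTest:
    protein_id: str
    counts: pd.DataFrame  # 2 x (<=20) table, rows domain/unassigned
    chi2_statistic: float
    dof: int
    p_value: float
    keep: bool


@dataclass(frozen=True)
class EncResult:
    gene_id: str
    enc: float
    unbiased: bool
    flagged: bool = False  # too few usable families to evaluate the formula


def aa_composition_test(
    protein_seq: str, partition: RegionPartition, alpha: float = COMPOSITION_ALPHA
) -> CompositionTest:
    """Pearson chi-square on the 2 x 20 region-by-amino-acid count table.

    Amino acids absent from both regions are dropped; ``keep`` is True when
    the compositions are not significantly different (p >= alpha).
    """
    if len(protein_seq) != partition.aa_len:
        raise ValueError(
            f"{partition.protein_id}: protein length {len(protein_seq)} != "
            f"partition length {partition.aa_len}"
        )
    counts = {DOMAIN: Counter(), UNASSIGNED: Counter()}
    for seg in partition.segments:
        counts[seg.label].update(protein_seq[seg.aa_start - 1 : seg.aa_end])
    if not counts[DOMAIN] or not counts[UNASSIGNED]:
        raise ValueError(f"{partition.protein_id}: a region has zero residues")
    table = pd.DataFrame(
        [[counts[r].get(aa, 0) for aa in AMINO_ACIDS] for r in (DOMAIN, UNASSIGNED)],
        index=[DOMAIN, UNASSIGNED],
        columns=list(AMINO_ACIDS),
    )
    table = table.loc[:, table.sum(axis=0) > 0]
    stat, p, dof, expected = scipy.stats.chi2_contingency(table.values, correction=False)
    if (expected < 5).any():
        logger.warning(
            "%s: %d expected cells < 5 in the composition table",
            partition.protein_id,
            int((expected < 5).sum()),
        )
    return CompositionTest(
        protein_id=partition.protein_id,
        counts=table,
        chi2_statistic=float(stat),
        dof=int(dof),
        p_value=float(p),
        keep=bool(p >= alpha),
    )


def _family_homozygosity(codon_counts: Counter, codons: list[str]) -> float | None:
    """F-hat = (n * sum p_i^2 - 1) / (n - 1); None when n <= 1 codon observed."""
    n = sum(codon_counts.get(c, 0) for c in codons)
    if n <= 1:
        return None
    p = np.array([codon_counts.get(c, 0) / n for c in codons])
    return float((n * (p**2).sum() - 1) / (n - 1))


def enc(cds: CodingSequence | str, gene_id: str | None = None) -> EncResult:
    """Wright's effective number of codons with CodonW's conventions.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 over the mean homozygosity of each
    degeneracy class; families with <= 1 codon observed are excluded; a
    missing degeneracy-3 class is imputed as (F2 + F4)/2; values above 61
    are capped.  The stop codon is excluded.
    """
    if isinstance(cds, CodingSequence):
        seq = cds.coding_nt.upper()
        gene_id = gene_id or cds.gene_id
    else:
        seq = cds.upper()
        gene_id = gene_id or ""
    if len(seq) < 3:
        raise ValueError("need at least one codon")
    codon_counts: Counter = Counter(
        seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)
    )
    for stop in STOP_CODONS:
        codon_counts.pop(stop, None)

    f_bar: dict[int, float | None] = {}
    for degeneracy, aas in FAMILY_DEGENERACY.items():
        if degeneracy == 1:
            continue
        fs = [
            f
            for aa in aas
            if (f := _family_homozygosity(codon_counts, _FAMILIES[aa])) is not None
        ]
        f_bar[degeneracy] = float(np.mean(fs)) if fs else None

    if f_bar[3] is None and f_bar[2] is not None and f_bar[4] is not None:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0

    weights = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    if any(f_bar[k] is None for k in weights):
        return EncResult(gene_id=gene_id, enc=float("nan"), unbiased=False, flagged=True)

    value = 2.0
    for k, w in weights.items():
        value += w / f_bar[k] if f_bar[k] > 0 else float("inf")
    value = min(value, 61.0)
    return EncResult(gene_id=gene_id, enc=value, unbiased=value > ENC_CUTOFF)


def filter_genes(
    tests: Iterable[CompositionTest] | None = None,
    enc_results: Iterable[EncResult] | None = None,
    mode: str = "composition",
    alpha: float = COMPOSITION_ALPHA,
    enc_cutoff: float = ENC_CUTOFF,
) -> set[str]:
    """Gene/protein ids passing one of the confounder filters.

    ``composition``: keep iff the chi-square p-value >= alpha.
    ``codon``: keep iff ENC > enc_cutoff (ENC <= cutoff means biased usage).
    The two filters are applied independently, never jointly.
    """
    if mode == "composition":
        if tests is None:
            raise ValueError("composition mode needs composition tests")
        return {t.protein_id for t in tests if t.p_value >= alpha}
    if mode == "codon":
        if enc_results is None:
            raise ValueError("codon mode needs ENC results")
        return {
            r.gene_id for r in enc_results if not r.flagged and r.enc > enc_cutoff
        }
    raise ValueError(f"unknown filter mode {mode!r}")


def composition_frame(tests: Iterable[CompositionTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": t.protein_id,
                "chi2": t.chi2_statistic,
                "dof": t.dof,
                "p_value": t.p_value,
                "keep": t.keep,
            }
            for t in tests
        ]
    )


def enc_frame(results: Iterable[EncResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "enc": r.enc, "unbiased": r.unbiased, "flagged": r.flagged}
            for r in results
        ]
    )
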