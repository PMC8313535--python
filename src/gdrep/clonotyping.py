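"""Amino-acid-level clonotype definition and convergent-recombination detection.

A clonotype is the equivalence class of chains sharing locus, V gene, J gene
and CDR3 amino-acid sequence. Distinct CDR3 nucleotide sequences within one
clonotype are tracked as a variant partition; two or more variants mark
convergent recombination.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .errors import ConsistencyError
from .io import ChainRecord, PairedCell

log = logging.getLogger(__name__)

_NT_ALPHABET = frozenset("ACGT")


def strip_allele(call: str) -> str:
    """TRGV7*02 -> TRGV7; calls without an allele suffix pass through."""
    return call.split("*", 1)[0]


@dataclass(frozen=True, slots=True, order=True)
class ClonotypeKey:
    locus: str
    v_gene: str
    j_gene: str
    cdr3_aa: str


@dataclass(frozen=True, slots=True, order=True)
class PairedClonotypeKey:
    gamma_key: ClonotypeKey
    delta_key: ClonotypeKey

    def __post_init__(self) -> None:
        if self.gamma_key.locus != "TRG" or self.delta_key.locus != "TRD":
            raise ValueError("paired key needs a TRG gamma_key and a TRD delta_key")


@dataclass(frozen=True, slots=True)
class Clonotype:
    key: ClonotypeKey
    cell_ids: frozenset
    size: int
    nt_variants: Mapping[str, int]


@dataclass(frozen=True, slots=True)
class ConvergenceReport:
    key: ClonotypeKey
    n_nt_variants: int
    dominant_variant_fraction: float
    is_convergent: bool


def make_clonotype_key(chain: ChainRecord, allele_level: bool = False) -> ClonotypeKey:
    """Build the clonotype key for one chain.

    Gene-level by default (allele suffixes stripped); ``allele_level=True``
    keeps the verbatim calls for sensitivity analyses.
    """
    if not chain.cdr3_aa:
        raise ValueError(f"chain {chain.contig_id!r} has empty cdr3_aa")
    v = chain.v_call if allele_level else strip_allele(chain.v_call)
    j = chain.j_call if allele_level else strip_allele(chain.j_call)
    return ClonotypeKey(locus=chain.locus, v_gene=v, j_gene=j, cdr3_aa=chain.cdr3_aa.upper())


def group_clonotypes(
    cells: Sequence[PairedCell], locus: str, allele_level: bool = False
) -> list[Clonotype]:
    """Partition cells carrying a chain of ``locus`` into clonotypes.

    Output is sorted by descending size, then by key, so it is invariant
    under shuffling of the input cell order.
    """
    if locus not in ("TRG", "TRD"):
        raise ValueError(f"unknown locus {locus!r}")
    acc: dict[ClonotypeKey, tuple[set, Counter]] = {}
    for cell in cells:
        chain = cell.gamma if locus == "TRG" else cell.delta
        if chain is None:
            continue
        key = make_clonotype_key(chain, allele_level=allele_level)
        ids, variants = acc.setdefault(key, (set(), Counter()))
        ids.add(cell.cell_id)
        variants[chain.cdr3_nt] += 1
    out = [
        Clonotype(key=k, cell_ids=frozenset(ids), size=len(ids), nt_variants=dict(variants))
        for k, (ids, variants) in acc.items()
    ]
    out.sort(key=lambda c: (-c.size, c.key))
    return out


def group_paired_clonotypes(
    cells: Sequence[PairedCell], allele_level: bool = False
) -> dict[PairedClonotypeKey, int]:
    """Partition fully paired cells by their (gamma key, delta key) pair.

    Cells missing either chain are excluded; the excluded count is logged.
    """
    sizes: dict[PairedClonotypeKey, int] = {}
    n_excluded = 0
    for cell in cells:
        if not cell.is_paired:
            n_excluded += 1
            continue
        pk = PairedClonotypeKey(
            gamma_key=make_clonotype_key(cell.gamma, allele_level=allele_level),
            delta_key=make_clonotype_key(cell.delta, allele_level=allele_level),
        )
        sizes[pk] = sizes.get(pk, 0) + 1
    if n_excluded:
        log.info("group_paired_clonotypes: excluded %d cells missing one chain", n_excluded)
    return sizes


def translate_cdr3(nt: str) -> str:
    """Standard-code translation of a CDR3 nucleotide junction.

    The junction of a productive chain is in-frame and stop-free, so a bad
    length, a non-ACGT character, or a stop codon is an error.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"CDR3 length {len(nt)} not divisible by 3")
    if not nt or set(nt) - _NT_ALPHABET:
        raise ValueError(f"CDR3 contains characters outside ACGT: {nt!r}")
    aa = str(Seq(nt).translate())
    if "*" in aa:
        raise ValueError(f"CDR3 {nt!r} contains a stop codon")
    return aa


def detect_convergent_recombination(clonotype: Clonotype) -> ConvergenceReport:
    """Report the nucleotide-variant structure of one clonotype.

    Raises
    ------
    ConsistencyError
        If any nucleotide variant does not translate to the clonotype's
        CDR3 amino-acid sequence.
    """
    if not clonotype.nt_variants:
        raise ValueError("clonotype has no nucleotide variants")
    for nt in clonotype.nt_variants:
        if translate_cdr3(nt) != clonotype.key.cdr3_aa:
            raise ConsistencyError(
                f"variant {nt!r} translates to {translate_cdr3(nt)!r}, "
                f"not {clonotype.key.cdr3_aa!r}"
            )
    total = sum(clonotype.nt_variants.values())
    dominant = max(clonotype.nt_variants.values()) / total
    n_var = len(clonotype.nt_variants)
    return ConvergenceReport(
        key=clonotype.key,
        n_nt_variants=n_var,
        dominant_variant_fraction=dominant,
        is_convergent=n_var >= 2,
    )


def clonotype_table(
    clonotypes: Sequence[Clonotype],
    per_sample_sizes: Optional[Mapping[ClonotypeKey, Mapping[str, int]]] = None,
):
    """Tabulate clonotypes (one row each) for TSV export."""
    import pandas as pd

    sample_ids = sorted({s for m in (per_sample_sizes or {}).values() for s in m})
    rows = []
    for c in clonotypes:
        rep = detect_convergent_recombination(c)
        row = {
            "locus": c.key.locus,
            "v_gene": c.key.v_gene,
            "j_gene": c.key.j_gene,
            "cdr3_aa": c.key.cdr3_aa,
            "size": c.size,
            "n_nt_variants": rep.n_nt_variants,
            "dominant_variant_fraction": rep.dominant_variant_fraction,
        }
        for s in sample_ids:
            row[f"size_{s}"] = (per_sample_sizes or {}).get(c.key, {}).get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
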