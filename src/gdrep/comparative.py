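"""Gene-usage tables and tests, clonotype sharing, and top-clone tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .clonotyping import make_clonotype_key, strip_allele
from .io import PairedCell

log = logging.getLogger(__name__)

SEGMENTS = ("duodenum", "jejunum", "ileum")


@dataclass(frozen=True, slots=True)
class UsageTable:
    """Gene x sample counts with column-normalized proportions."""

    counts: pd.DataFrame
    proportions: pd.DataFrame  # NaN columns for empty samples


@dataclass(frozen=True, slots=True)
class UsageTestResult:
    chi2: float
    df: int
    p_value: float
    expected_counts: np.ndarray


@dataclass(frozen=True, slots=True)
class OverlapResult:
    shared: frozenset
    n_shared: int
    fraction_union: float
    fraction_a: float
    fraction_b: float


def _gene_label(chain, level: str) -> str:
    v = strip_allele(chain.v_call)
    j = strip_allele(chain.j_call)
    if level == "V":
        return v
    if level == "J":
        return j
    if level == "VJ":
        return f"{v}/{j}"
    raise ValueError(f"unknown usage level {level!r}")


def gene_usage(cells: Sequence[PairedCell], locus: str, level: str = "V") -> UsageTable:
    """Count gene usage per sample over resolved chains of one locus.

    The table is dense: a gene absent from a sample appears with count 0.
    Samples with no chains get NaN proportions (flagged via a warning).
    """
    if locus not in ("TRG", "TRD"):
        raise ValueError(f"unknown locus {locus!r}")
    tallies: dict[str, dict[str, int]] = {}
    samples: list[str] = []
    for cell in cells:
        if cell.sample_id not in samples:
            samples.append(cell.sample_id)
        chain = cell.gamma if locus == "TRG" else cell.delta
        if chain is None:
            continue
        gene = _gene_label(chain, level)
        tallies.setdefault(gene, {})
        tallies[gene][cell.sample_id] = tallies[gene].get(cell.sample_id, 0) + 1
    genes = sorted(tallies)
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    for gene, per_sample in tallies.items():
        for sample, c in per_sample.items():
            counts.loc[gene, sample] = c
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        log.warning("gene_usage: sample(s) %s have no %s chains; proportions undefined", empty, locus)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = counts / totals.replace(0, np.nan)
    return UsageTable(counts=counts, proportions=proportions)


def usage_chisq(
    counts_a: "pd.Series | Sequence[int]",
    counts_b: "pd.Series | Sequence[int]",
    min_expected: float = 1.0,
) -> UsageTestResult:
    """Pearson chi-squared on a 2 x G gene-count contingency table.

    No continuity correction. Genes whose expected count falls below
    ``min_expected`` are pooled into a single "other" category (warned).
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the same gene index")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each sample needs a positive total count")
    nonzero = (a + b) > 0
    a, b = a[nonzero], b[nonzero]
    table = np.vstack([a, b])
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    low = expected.min(axis=0) < min_expected
    if low.any() and (~low).sum() >= 1:
        log.warning("usage_chisq: pooling %d low-expectation gene(s) into 'other'", int(low.sum()))
        pooled_a = np.concatenate([a[~low], [a[low].sum()]])
        pooled_b = np.concatenate([b[~low], [b[low].sum()]])
        table = np.vstack([pooled_a, pooled_b])
    if table.shape[1] < 2:
        raise ValueError("need at least two gene categories after pooling")
    chi2, p, df, exp = stats.chi2_contingency(table, correction=False)
    return UsageTestResult(chi2=float(chi2), df=int(df), p_value=float(p), expected_counts=exp)


def clonotype_overlap(set_a: Set, set_b: Set) -> OverlapResult:
    """Shared clonotype keys between two repertoires, with three denominators."""
    shared = frozenset(set_a) & frozenset(set_b)
    union = len(set_a | set_b)
    return OverlapResult(
        shared=frozenset(shared),
        n_shared=len(shared),
        fraction_union=len(shared) / union if union else 0.0,
        fraction_a=len(shared) / len(set_a) if set_a else 0.0,
        fraction_b=len(shared) / len(set_b) if set_b else 0.0,
    )


def cross_segment_sharing(keys_by_segment: Mapping[str, Set]) -> dict[str, int]:
    """Seven-region Venn partition of clonotype keys across the three segments."""
    missing = [s for s in SEGMENTS if s not in keys_by_segment]
    if missing or set(keys_by_segment) != set(SEGMENTS):
        raise ValueError(
            f"need exactly the segments {SEGMENTS}; missing {missing}, "
            f"got {sorted(keys_by_segment)}"
        )
    duo = set(keys_by_segment["duodenum"])
    jej = set(keys_by_segment["jejunum"])
    ile = set(keys_by_segment["ileum"])
    all_three = duo & jej & ile
    return {
        "duodenum_only": len(duo - jej - ile),
        "jejunum_only": len(jej - duo - ile),
        "ileum_only": len(ile - duo - jej),
        "duodenum_jejunum": len((duo & jej) - ile),
        "duodenum_ileum": len((duo & ile) - jej),
        "jejunum_ileum": len((jej & ile) - duo),
        "all_three": len(all_three),
    }


def top_clone_table(
    sizes_by_sample: Mapping[str, Mapping],
    focal_sample: str,
    k: int,
    comparator_samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Top-k clonotypes of the focal sample with per-sample sizes and presence.

    ``sizes_by_sample`` maps sample_id -> {clonotype key -> size}. Rows are
    sorted by focal size descending, ties broken by cdr3_aa lexicographic
    order. Absence in a sample is explicit (size 0, present False).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if focal_sample not in sizes_by_sample:
        raise KeyError(f"focal sample {focal_sample!r} not found")
    focal = sizes_by_sample[focal_sample]
    if comparator_samples is None:
        comparator_samples = [s for s in sizes_by_sample if s != focal_sample]
    if k > len(focal):
        log.warning("top_clone_table: k=%d exceeds %d clonotypes; returning all", k, len(focal))
    ranked = sorted(focal.items(), key=lambda kv: (-kv[1], kv[0].cdr3_aa))[:k]
    rows = []
    for rank, (key, size) in enumerate(ranked, start=1):
        row = {
            "rank": rank,
            "locus": key.locus,
            "v_gene": key.v_gene,
            "j_gene": key.j_gene,
            "cdr3_aa": key.cdr3_aa,
            f"size_{focal_sample}": size,
        }
        for s in comparator_samples:
            other = sizes_by_sample.get(s, {})
            row[f"size_{s}"] = other.get(key, 0)
            row[f"present_{s}"] = key in other
        rows.append(row)
    return pd.DataFrame(rows)


def clonotype_key_sets(cells: Sequence[PairedCell], locus: str) -> set:
    """Distinct clonotype keys of one locus over a cell list (convenience)."""
    keys = set()
    for cell in cells:
        chain = cell.gamma if locus == "TRG" else cell.delta
        if chain is not None:
            keys.add(make_clonotype_key(chain))
    return keys
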