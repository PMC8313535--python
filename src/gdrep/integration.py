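"""Join clonotypes with per-cell transcriptome cluster labels.

Cluster labels come from any external clustering tool; this module only
quantifies how clonotypes and gamma/delta pairings distribute across them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .clonotyping import ClonotypeKey, PairedClonotypeKey, make_clonotype_key
from .comparative import UsageTestResult, usage_chisq, _gene_label
from .io import PairedCell

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True, slots=True)
class ClusterAssignment:
    cell_id: str
    cluster_label: str
    embedding_xy: Optional[tuple[float, float]] = None


@dataclass(frozen=True, slots=True)
class AnnotatedCell:
    cell: PairedCell
    cluster_label: str  # UNASSIGNED when no label was provided

    @property
    def is_assigned(self) -> bool:
        return self.cluster_label != UNASSIGNED


@dataclass(frozen=True, slots=True)
class ClusterDistribution:
    subject: Union[ClonotypeKey, PairedClonotypeKey]
    counts: Mapping[str, int]  # assigned cells per cluster
    proportions: Mapping[str, float]
    n_cells: int  # assigned cells carrying the subject
    n_unassigned: int


def attach_clusters(
    cells: Sequence[PairedCell], assignments: Sequence[ClusterAssignment]
) -> list[AnnotatedCell]:
    """Left-join cluster labels onto cells; unlabeled cells become 'unassigned'."""
    labels: dict[str, str] = {}
    for a in assignments:
        if a.cell_id in labels:
            raise ValueError(f"duplicate barcode {a.cell_id!r} in cluster assignments")
        labels[a.cell_id] = a.cluster_label
    out = [AnnotatedCell(cell=c, cluster_label=labels.get(c.cell_id, UNASSIGNED)) for c in cells]
    n_assigned = sum(1 for c in out if c.is_assigned)
    log.info("attach_clusters: %d/%d cells labeled", n_assigned, len(out))
    return out


def _carries(cell: PairedCell, key: Union[ClonotypeKey, PairedClonotypeKey]) -> bool:
    if isinstance(key, PairedClonotypeKey):
        return (
            cell.is_paired
            and make_clonotype_key(cell.gamma) == key.gamma_key
            and make_clonotype_key(cell.delta) == key.delta_key
        )
    chain = cell.gamma if key.locus == "TRG" else cell.delta
    return chain is not None and make_clonotype_key(chain) == key


def clonotype_cluster_distribution(
    annotated: Sequence[AnnotatedCell], key: Union[ClonotypeKey, PairedClonotypeKey]
) -> ClusterDistribution:
    """Per-cluster counts and proportions of cells carrying one clonotype.

    Proportions are over assigned cells only; unassigned carriers are
    counted separately, never silently dropped.
    """
    counts: dict[str, int] = {}
    n_unassigned = 0
    for ac in annotated:
        if not _carries(ac.cell, key):
            continue
        if ac.is_assigned:
            counts[ac.cluster_label] = counts.get(ac.cluster_label, 0) + 1
        else:
            n_unassigned += 1
    n_cells = sum(counts.values())
    proportions = {c: v / n_cells for c, v in counts.items()} if n_cells else {}
    return ClusterDistribution(
        subject=key,
        counts=counts,
        proportions=proportions,
        n_cells=n_cells,
        n_unassigned=n_unassigned,
    )


def pairing_cluster_profiles(
    annotated: Sequence[AnnotatedCell], gamma_key: ClonotypeKey
) -> dict[ClonotypeKey, ClusterDistribution]:
    """One cluster distribution per delta partner of a focal gamma clonotype.

    Ordered by pair size (assigned + unassigned carriers) descending.
    Unpaired cells carrying the gamma key are excluded and logged.
    """
    if gamma_key.locus != "TRG":
        raise ValueError("focal key must be a TRG clonotype")
    by_delta: dict[ClonotypeKey, list[AnnotatedCell]] = {}
    n_unpaired = 0
    for ac in annotated:
        chain = ac.cell.gamma
        if chain is None or make_clonotype_key(chain) != gamma_key:
            continue
        if not ac.cell.is_paired:
            n_unpaired += 1
            continue
        by_delta.setdefault(make_clonotype_key(ac.cell.delta), []).append(ac)
    if n_unpaired:
        log.info("pairing_cluster_profiles: %d unpaired cells carry the focal key", n_unpaired)
    profiles = {}
    order = sorted(by_delta.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    for delta_key, group in order:
        pk = PairedClonotypeKey(gamma_key=gamma_key, delta_key=delta_key)
        profiles[delta_key] = clonotype_cluster_distribution(group, pk)
    return profiles


def cluster_usage_shift(
    cells_a: Sequence[AnnotatedCell],
    cells_b: Sequence[AnnotatedCell],
    cluster: str,
    locus: str,
    level: str = "V",
) -> UsageTestResult:
    """Chi-squared V-gene usage comparison restricted to one cluster."""

    def _counts(cells: Sequence[AnnotatedCell], side: str) -> dict[str, int]:
        present = any(ac.cluster_label == cluster for ac in cells)
        if not present:
            raise ValueError(f"cluster {cluster!r} absent from sample {side}")
        tally: dict[str, int] = {}
        for ac in cells:
            if ac.cluster_label != cluster:
                continue
            chain = ac.cell.gamma if locus == "TRG" else ac.cell.delta
            if chain is None:
                continue
            gene = _gene_label(chain, level)
            tally[gene] = tally.get(gene, 0) + 1
        if sum(tally.values()) < 2:
            raise ValueError(f"cluster {cluster!r} has fewer than 2 {locus} chains in sample {side}")
        return tally

    tally_a = _counts(cells_a, "a")
    tally_b = _counts(cells_b, "b")
    genes = sorted(set(tally_a) | set(tally_b))
    return usage_chisq(
        [tally_a.get(g, 0) for g in genes],
        [tally_b.get(g, 0) for g in genes],
    )
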