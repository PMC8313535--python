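"""Chain-table input/output, productive filtering, and per-cell chain resolution.

Supports two on-disk dialects:

* ``airr`` — AIRR Rearrangement TSV (MiAIRR column names).
* ``tenx`` — 10x-style ``filtered_contig_annotations`` CSV.

Both dialects are normalized into :class:`ChainRecord`, the package-wide
in-memory representation of one annotated V(D)J chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import FormatError, LocusError

log = logging.getLogger(__name__)

VALID_LOCI = ("TRG", "TRD")
_V_PREFIX = {"TRGV": "TRG", "TRDV": "TRD"}

#: Optional sample-metadata columns carried through both dialects verbatim.
META_COLUMNS = ("sample_id", "genotype", "segment")

# Fixed field -> column maps for each dialect. Unknown extra columns in the
# input are ignored (logged at debug level).
_AIRR_MAP = {
    "cell_id": "cell_id",
    "locus": "locus",
    "v_call": "v_call",
    "j_call": "j_call",
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "productive": "productive",
    "umi_count": "duplicate_count",
    "contig_id": "sequence_id",
}
_TENX_MAP = {
    "cell_id": "barcode",
    "locus": "chain",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "cdr3_nt": "cdr3_nt",
    "cdr3_aa": "cdr3",
    "productive": "productive",
    "umi_count": "umis",
    "contig_id": "contig_id",
}
_DIALECTS = {"airr": (_AIRR_MAP, "\t"), "tenx": (_TENX_MAP, ",")}

_TRUE_TOKENS = {"t", "true", "1", "yes"}
_FALSE_TOKENS = {"f", "false", "0", "no"}


@dataclass(frozen=True, slots=True)
class ChainRecord:
    """One annotated V(D)J chain tied to a cell barcode and a sample."""

    cell_id: str
    locus: str
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    productive: Optional[bool]
    umi_count: int
    contig_id: str
    sample_id: str = ""
    genotype: str = ""
    segment: str = ""

    def __post_init__(self) -> None:
        if self.umi_count < 0:
            raise ValueError(f"umi_count must be >= 0, got {self.umi_count}")
        if self.locus not in VALID_LOCI:
            raise LocusError(f"unsupported locus {self.locus!r}")


@dataclass(frozen=True, slots=True)
class PairedCell:
    """A barcode with at most one resolved gamma and one delta chain."""

    cell_id: str
    sample_id: str
    gamma: Optional[ChainRecord]
    delta: Optional[ChainRecord]
    multi_chain_flag: bool = False

    def __post_init__(self) -> None:
        if self.gamma is None and self.delta is None:
            raise ValueError("PairedCell needs at least one chain")
        if self.gamma is not None and self.gamma.locus != "TRG":
            raise ValueError("gamma slot must hold a TRG chain")
        if self.delta is not None and self.delta.locus != "TRD":
            raise ValueError("delta slot must hold a TRD chain")

    @property
    def is_paired(self) -> bool:
        return self.gamma is not None and self.delta is not None


@dataclass(frozen=True, slots=True)
class AssemblySummary:
    """Per-run counts of sequenced cells, productive chains, and pairing."""

    n_cells: int
    n_productive_gamma: int
    n_productive_delta: int
    n_paired: int
    paired_fraction: Optional[float]  # percent, 1 decimal; None when n_cells == 0

    @classmethod
    def from_counts(
        cls,
        n_cells: int,
        n_productive_gamma: int,
        n_productive_delta: int,
        n_paired: int,
    ) -> "AssemblySummary":
        frac = round(100.0 * n_paired / n_cells, 1) if n_cells > 0 else None
        return cls(n_cells, n_productive_gamma, n_productive_delta, n_paired, frac)


def locus_from_v_call(v_call: str) -> str:
    prefix = v_call[:4].upper()
    try:
        return _V_PREFIX[prefix]
    except KeyError:
        raise LocusError(f"cannot determine locus from v_call {v_call!r}") from None


def _parse_productive(token: str) -> Optional[bool]:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    if t in ("", "none", "na", "nan"):
        return None
    raise FormatError(f"unparseable productive flag {token!r}")


def read_rearrangements(path, dialect: str) -> list[ChainRecord]:
    """Read a chain table and normalize it into :class:`ChainRecord` objects.

    Parameters
    ----------
    path:
        TSV (airr) or CSV (tenx) file path.
    dialect:
        ``"airr"`` or ``"tenx"``.

    Raises
    ------
    FormatError
        If a required column for the dialect is missing.
    LocusError
        If any row carries a V call from an unsupported locus; the message
        names the offending row index.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    colmap, sep = _DIALECTS[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [col for col in colmap.values() if col not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for dialect {dialect!r}")
    known = set(colmap.values()) | set(META_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.debug("%s: ignoring extra columns %s", path, extra)

    records: list[ChainRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        v_call = row_d[colmap["v_call"]]
        try:
            locus = locus_from_v_call(v_call)
        except LocusError as exc:
            raise LocusError(f"{path} row {idx}: {exc}") from None
        stated = row_d[colmap["locus"]].strip()
        if stated and stated != locus:
            raise LocusError(
                f"{path} row {idx}: locus column says {stated!r} but v_call "
                f"{v_call!r} implies {locus!r}"
            )
        umi_raw = row_d[colmap["umi_count"]].strip()
        records.append(
            ChainRecord(
                cell_id=row_d[colmap["cell_id"]],
                locus=locus,
                v_call=v_call,
                j_call=row_d[colmap["j_call"]],
                cdr3_nt=row_d[colmap["cdr3_nt"]],
                cdr3_aa=row_d[colmap["cdr3_aa"]],
                productive=_parse_productive(row_d[colmap["productive"]]),
                umi_count=int(umi_raw) if umi_raw else 0,
                contig_id=row_d[colmap["contig_id"]],
                sample_id=row_d.get("sample_id", ""),
                genotype=row_d.get("genotype", ""),
                segment=row_d.get("segment", ""),
            )
        )
    return records


def write_rearrangements(records: Sequence[ChainRecord], path, dialect: str) -> None:
    """Write records so that :func:`read_rearrangements` round-trips exactly."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    colmap, sep = _DIALECTS[dialect]
    if dialect == "airr":
        fmt_bool = lambda b: "" if b is None else ("T" if b else "F")  # noqa: E731
    else:
        fmt_bool = lambda b: "None" if b is None else str(b)  # noqa: E731
    columns = list(colmap.values()) + list(META_COLUMNS)
    rows = []
    for r in records:
        rows.append(
            {
                colmap["cell_id"]: r.cell_id,
                colmap["locus"]: r.locus,
                colmap["v_call"]: r.v_call,
                colmap["j_call"]: r.j_call,
                colmap["cdr3_nt"]: r.cdr3_nt,
                colmap["cdr3_aa"]: r.cdr3_aa,
                colmap["productive"]: fmt_bool(r.productive),
                colmap["umi_count"]: r.umi_count,
                colmap["contig_id"]: r.contig_id,
                "sample_id": r.sample_id,
                "genotype": r.genotype,
                "segment": r.segment,
            }
        )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)


def attach_metadata(records: Iterable[ChainRecord], metadata: pd.DataFrame) -> list[ChainRecord]:
    """Fill genotype/segment from a sample-metadata table keyed by sample_id."""
    required = {"sample_id", "genotype", "segment"}
    if not required.issubset(metadata.columns):
        raise FormatError(f"metadata table needs columns {sorted(required)}")
    lookup = metadata.set_index("sample_id")[["genotype", "segment"]].to_dict("index")
    out = []
    for r in records:
        meta = lookup.get(r.sample_id)
        if meta is None:
            out.append(r)
        else:
            out.append(replace(r, genotype=meta["genotype"], segment=meta["segment"]))
    return out


def filter_productive(records: Sequence[ChainRecord]) -> list[ChainRecord]:
    """Keep exactly the productive records, preserving input order.

    Raises
    ------
    FormatError
        If any record lacks a productive annotation; productivity is never
        inferred from sequence here.
    """
    for i, r in enumerate(records):
        if r.productive is None:
            raise FormatError(
                f"record {i} (contig {r.contig_id!r}) has no productive flag; "
                "annotate productivity upstream before filtering"
            )
    kept = [r for r in records if r.productive]
    if records and not kept:
        log.warning("filter_productive: no productive records among %d inputs", len(records))
    return kept


def _resolve(chains: list[ChainRecord]) -> Optional[ChainRecord]:
    # top UMI, ties broken by lexicographically smallest contig_id
    if not chains:
        return None
    return min(chains, key=lambda r: (-r.umi_count, r.contig_id))


def pair_cells(records: Sequence[ChainRecord], policy: str = "top_umi") -> list[PairedCell]:
    """Collapse productive chains into one :class:`PairedCell` per barcode.

    Barcodes with more than one chain of a locus keep the top-UMI chain
    (deterministic contig_id tie-break) and are flagged via
    ``multi_chain_flag`` so downstream analyses can exclude them.
    """
    if policy != "top_umi":
        raise ValueError(f"unknown pairing policy {policy!r}")
    by_barcode: dict[str, list[ChainRecord]] = {}
    for r in records:
        by_barcode.setdefault(r.cell_id, []).append(r)
    cells = []
    for cell_id, chains in by_barcode.items():
        gammas = [c for c in chains if c.locus == "TRG"]
        deltas = [c for c in chains if c.locus == "TRD"]
        cells.append(
            PairedCell(
                cell_id=cell_id,
                sample_id=chains[0].sample_id,
                gamma=_resolve(gammas),
                delta=_resolve(deltas),
                multi_chain_flag=len(gammas) > 1 or len(deltas) > 1,
            )
        )
    return cells


def assembly_summary(cells: Sequence[PairedCell], total_cells: Optional[int] = None) -> AssemblySummary:
    """Summarize chain recovery and pairing over resolved cells.

    ``total_cells`` overrides the denominator when the number of sequenced
    cells exceeds the number of cells with at least one productive chain
    (cells with no recovered chain cannot appear in ``cells``).
    """
    n_cells = len(cells) if total_cells is None else total_cells
    n_gamma = sum(1 for c in cells if c.gamma is not None)
    n_delta = sum(1 for c in cells if c.delta is not None)
    n_paired = sum(1 for c in cells if c.is_paired)
    return AssemblySummary.from_counts(n_cells, n_gamma, n_delta, n_paired)
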