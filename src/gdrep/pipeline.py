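"""End-to-end orchestration: chain tables in, reproducible report bundle out."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .clonotyping import (
    clonotype_table,
    detect_convergent_recombination,
    group_clonotypes,
    group_paired_clonotypes,
)
from .comparative import (
    SEGMENTS,
    clonotype_overlap,
    cross_segment_sharing,
    gene_usage,
    top_clone_table,
    usage_chisq,
)
from .diversity import (
    AbundanceVector,
    RarefactionSpec,
    bootstrap_diversity,
    compare_diversity_at_point,
    d50,
)
from .errors import PipelineError
from .integration import ClusterAssignment, attach_clusters, clonotype_cluster_distribution, pairing_cluster_profiles
from .io import (
    PairedCell,
    assembly_summary,
    attach_metadata,
    filter_productive,
    pair_cells,
    read_rearrangements,
)

log = logging.getLogger(__name__)

LOCI = ("TRG", "TRD")


@dataclass
class PipelineConfig:
    inputs: list[dict]  # each: {"path": ..., "dialect": "airr"|"tenx"}
    out_dir: str
    metadata_path: Optional[str] = None
    cluster_path: Optional[str] = None
    loci: Sequence[str] = LOCI
    m: int = 3500
    B: int = 50
    seed: int = 0
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "out_dir": str(self.out_dir),
            "metadata_path": self.metadata_path,
            "cluster_path": self.cluster_path,
            "loci": list(self.loci),
            "m": self.m,
            "B": self.B,
            "seed": self.seed,
            "top_k": self.top_k,
        }


def read_cluster_csv(path) -> list[ClusterAssignment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "cell_id" not in df.columns or "cluster_label" not in df.columns:
        raise PipelineError("cluster CSV needs columns cell_id, cluster_label")
    out = []
    for row in df.itertuples(index=False):
        xy = None
        if "x" in df.columns and "y" in df.columns:
            d = dict(zip(df.columns, row))
            if d["x"] and d["y"]:
                xy = (float(d["x"]), float(d["y"]))
        out.append(ClusterAssignment(cell_id=row.cell_id, cluster_label=row.cluster_label, embedding_xy=xy))
    return out


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _key_str(key) -> str:
    return f"{key.v_gene}/{key.j_gene}/{key.cdr3_aa}"


def _paired_key_str(pk) -> str:
    return f"{_key_str(pk.gamma_key)}|{_key_str(pk.delta_key)}"


class _Stage:
    """Context manager that rewrites stage failures as PipelineError."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("pipeline stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _abundances(cells_by_sample: dict[str, list[PairedCell]], locus: str) -> dict[str, AbundanceVector]:
    out = {}
    for sample, cells in cells_by_sample.items():
        if locus == "paired":
            sizes = list(group_paired_clonotypes(cells).values())
        else:
            sizes = [c.size for c in group_clonotypes(cells, locus)]
        if sizes:
            out[sample] = AbundanceVector(sizes)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis stage and write a deterministic report bundle.

    Reports are first written to a staging directory and moved into
    ``config.out_dir`` only on success, so a failed run leaves no partial
    outputs behind. Returns the output directory path.
    """
    out_dir = Path(config.out_dir)
    staging = Path(tempfile.mkdtemp(prefix=".gdrep-staging-", dir=out_dir.parent if out_dir.parent.exists() else None))
    try:
        _run_stages(config, staging)
        out_dir.mkdir(parents=True, exist_ok=True)
        for item in sorted(staging.iterdir()):
            target = out_dir / item.name
            if target.exists():
                if target.is_dir():
                    shutil.rmtree(target)
                else:
                    target.unlink()
            shutil.move(str(item), str(target))
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return out_dir


def _run_stages(config: PipelineConfig, out: Path) -> None:
    with _Stage("read"):
        records = []
        for inp in config.inputs:
            records.extend(read_rearrangements(inp["path"], inp["dialect"]))
        if config.metadata_path:
            records = attach_metadata(records, pd.read_csv(config.metadata_path, dtype=str))

    with _Stage("filter_productive"):
        records = filter_productive(records)

    with _Stage("pair_cells"):
        cells = pair_cells(records)
        cells_by_sample: dict[str, list[PairedCell]] = {}
        for c in cells:
            cells_by_sample.setdefault(c.sample_id, []).append(c)

    with _Stage("assembly_summary"):
        summary = assembly_summary(cells)
        _dump_json(
            {
                "n_cells": summary.n_cells,
                "n_productive_gamma": summary.n_productive_gamma,
                "n_productive_delta": summary.n_productive_delta,
                "n_paired": summary.n_paired,
                "paired_fraction": summary.paired_fraction,
            },
            out / "assembly_summary.json",
        )

    with _Stage("clonotyping"):
        clonotypes_by_locus = {}
        for locus in LOCI:
            clonos = group_clonotypes(cells, locus)
            clonotypes_by_locus[locus] = clonos
            per_sample = {}
            for sample, sample_cells in sorted(cells_by_sample.items()):
                for c in group_clonotypes(sample_cells, locus):
                    per_sample.setdefault(c.key, {})[sample] = c.size
            clonotype_table(clonos, per_sample).to_csv(
                out / f"clonotypes_{locus}.tsv", sep="\t", index=False
            )

    with _Stage("diversity"):
        rows = []
        comparisons = []
        for locus in list(config.loci) + ["paired"]:
            ab = _abundances(cells_by_sample, locus)
            for sample in sorted(ab):
                x = ab[sample]
                if x.n < config.m:
                    raise PipelineError(
                        f"stage 'diversity' failed: interpolation point m={config.m} exceeds "
                        f"n={x.n} for sample {sample!r} ({locus}); lower m or drop the sample"
                    )
                for q in (0, 1):
                    spec = RarefactionSpec(q=q, m=config.m, B=config.B, seed=config.seed)
                    est = bootstrap_diversity(x, spec)
                    rows.append(
                        {
                            "sample": sample, "locus": locus, "q": q, "m": config.m,
                            "estimate": est.estimate, "ci_low": est.ci_low,
                            "ci_high": est.ci_high, "B": config.B, "seed": config.seed,
                        }
                    )
                res = d50(x)
                rows.append(
                    {
                        "sample": sample, "locus": locus, "q": "d50", "m": x.n,
                        "estimate": res.normalized, "ci_low": res.k, "ci_high": res.k,
                        "B": 0, "seed": config.seed,
                    }
                )
            # genotype comparison per segment at the fixed point, q=1
            by_segment: dict[str, dict[str, str]] = {}
            for sample in ab:
                genotype, _, segment = sample.partition("_")
                by_segment.setdefault(segment, {})[genotype] = sample
            for segment in sorted(by_segment):
                pair = by_segment[segment]
                if {"KO", "WT"} <= set(pair):
                    spec = RarefactionSpec(q=1, m=config.m, B=config.B, seed=config.seed)
                    cmp_res = compare_diversity_at_point(
                        ab[pair["KO"]], ab[pair["WT"]], spec, labels=(pair["KO"], pair["WT"])
                    )
                    comparisons.append(
                        {
                            "locus": locus, "segment": segment,
                            "sample_a": pair["KO"], "sample_b": pair["WT"],
                            "mean_a": cmp_res.mean_a, "mean_b": cmp_res.mean_b,
                            "t_statistic": cmp_res.t_statistic, "p_value": cmp_res.p_value,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
        _dump_json(comparisons, out / "diversity_comparisons.json")

    with _Stage("usage"):
        tests = []
        for locus in config.loci:
            for level in ("V", "J", "VJ"):
                table = gene_usage(cells, locus, level)
                table.counts.to_csv(out / f"usage_{locus}_{level}.tsv", sep="\t")
            table = gene_usage(cells, locus, "V")
            by_segment = {}
            for sample in table.counts.columns:
                genotype, _, segment = sample.partition("_")
                by_segment.setdefault(segment, {})[genotype] = sample
            for segment in sorted(by_segment):
                pair = by_segment[segment]
                if {"KO", "WT"} <= set(pair):
                    res = usage_chisq(table.counts[pair["KO"]], table.counts[pair["WT"]])
                    tests.append(
                        {
                            "locus": locus, "segment": segment, "level": "V",
                            "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
                        }
                    )
        _dump_json(tests, out / "usage_tests.json")

    with _Stage("sharing"):
        sharing = {}
        keys_by_sample = {
            locus: {
                sample: {c.key for c in group_clonotypes(sample_cells, locus)}
                for sample, sample_cells in cells_by_sample.items()
            }
            for locus in LOCI
        }
        keys_by_sample["paired"] = {
            sample: set(group_paired_clonotypes(sample_cells))
            for sample, sample_cells in cells_by_sample.items()
        }
        for locus, per_sample in keys_by_sample.items():
            by_segment: dict[str, dict[str, str]] = {}
            for sample in per_sample:
                genotype, _, segment = sample.partition("_")
                by_segment.setdefault(segment, {})[genotype] = sample
            overlaps = {}
            for segment in sorted(by_segment):
                pair = by_segment[segment]
                if {"KO", "WT"} <= set(pair):
                    res = clonotype_overlap(per_sample[pair["KO"]], per_sample[pair["WT"]])
                    overlaps[segment] = {
                        "n_shared": res.n_shared,
                        "fraction_union": res.fraction_union,
                        "fraction_a": res.fraction_a,
                        "fraction_b": res.fraction_b,
                    }
            cross = {}
            for genotype in ("KO", "WT"):
                keys_by_segment = {
                    seg: per_sample[f"{genotype}_{seg}"]
                    for seg in SEGMENTS
                    if f"{genotype}_{seg}" in per_sample
                }
                if set(keys_by_segment) == set(SEGMENTS):
                    cross[genotype] = cross_segment_sharing(keys_by_segment)
            sharing[locus] = {"genotype_overlap_by_segment": overlaps, "cross_segment": cross}
        _dump_json(sharing, out / "sharing.json")

    with _Stage("top_clones"):
        for locus in LOCI:
            sizes_by_sample = {
                sample: {c.key: c.size for c in group_clonotypes(sample_cells, locus)}
                for sample, sample_cells in sorted(cells_by_sample.items())
            }
            sizes_by_sample = {s: m for s, m in sizes_by_sample.items() if m}
            if not sizes_by_sample:
                continue
            focal = max(sizes_by_sample, key=lambda s: sum(sizes_by_sample[s].values()))
            top_clone_table(sizes_by_sample, focal, config.top_k).to_csv(
                out / f"top_clones_{locus}.tsv", sep="\t", index=False
            )

    with _Stage("convergence"):
        frames = []
        for locus in LOCI:
            rows = []
            for c in clonotypes_by_locus[locus]:
                rep = detect_convergent_recombination(c)
                rows.append(
                    {
                        "locus": locus, "v_gene": c.key.v_gene, "j_gene": c.key.j_gene,
                        "cdr3_aa": c.key.cdr3_aa, "size": c.size,
                        "n_nt_variants": rep.n_nt_variants,
                        "dominant_variant_fraction": rep.dominant_variant_fraction,
                        "is_convergent": rep.is_convergent,
                    }
                )
            frames.append(pd.DataFrame(rows))
        pd.concat(frames, ignore_index=True).to_csv(out / "convergence.tsv", sep="\t", index=False)

    if config.cluster_path:
        with _Stage("integration"):
            assignments = read_cluster_csv(config.cluster_path)
            annotated = attach_clusters(cells, assignments)
            gamma_clonos = clonotypes_by_locus["TRG"]
            result = {"top_gamma_distributions": [], "pairing_profiles": {}}
            for c in gamma_clonos[:5]:
                dist = clonotype_cluster_distribution(annotated, c.key)
                result["top_gamma_distributions"].append(
                    {
                        "key": _key_str(c.key),
                        "n_cells": dist.n_cells,
                        "n_unassigned": dist.n_unassigned,
                        "proportions": dict(sorted(dist.proportions.items())),
                    }
                )
            if gamma_clonos:
                profiles = pairing_cluster_profiles(annotated, gamma_clonos[0].key)
                result["pairing_profiles"] = {
                    _key_str(dk): {
                        "n_cells": dist.n_cells,
                        "proportions": dict(sorted(dist.proportions.items())),
                    }
                    for dk, dist in profiles.items()
                }
            _dump_json(result, out / "integration.json")
    else:
        _dump_json({"status": "skipped", "reason": "no cluster path configured"}, out / "integration.json")

    with _Stage("manifest"):
        cfg = config.to_dict()
        cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
        import numpy
        import scipy

        _dump_json(
            {
                "config": cfg,
                "config_sha256": cfg_hash,
                "seed": config.seed,
                "versions": {
                    "gdrep": __version__,
                    "numpy": numpy.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pd.__version__,
                },
            },
            out / "manifest.json",
        )
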