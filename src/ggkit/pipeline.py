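"""End-to-end orchestration: load or simulate, QC, identity, diversity,
AMOVA and tree building, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .amova import amova_one_way, variance_partition_report
from .diversity_stats import locus_statistics, summarize
from .errors import ConfigError, GgkitError
from .genotype_io import (
    GenotypeMatrix,
    SampleMeta,
    read_genotype_table,
    read_locus_metadata,
    read_sample_metadata,
    write_reports,
)
from .identity_matching import (
    distance_histogram,
    match_report,
    pairwise_distances,
    plot_histogram,
    redundancy_groups,
)
from .marker_qc import QcThresholds, filter_panel
from .nj_phylogeny import bootstrap_support
from .synthetic_cohort import CohortSpec, build_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full-pipeline configuration; exactly one of input paths / cohort."""

    out_dir: str
    genotypes_path: str | None = None
    meta_path: str | None = None
    loci_path: str | None = None
    cohort: CohortSpec | None = None
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    min_gap_width: int = 50
    fallback_threshold: int = 10
    n_permutations: int = 999
    bootstrap_reps: int = 100
    seed: int = 0
    plot: bool = False

    def __post_init__(self) -> None:
        has_paths = self.genotypes_path is not None
        has_cohort = self.cohort is not None
        if has_paths == has_cohort:
            raise ConfigError(
                "exactly one of genotypes_path / cohort must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            c = dict(raw["cohort"])
            for key in ("maf_range", "parent_pair"):
                if key in c:
                    c[key] = tuple(c[key])
            if "clone_group_sizes" in c:
                c["clone_group_sizes"] = tuple(c["clone_group_sizes"])
            if "mutant_spec" in c:
                c["mutant_spec"] = tuple(tuple(x) for x in c["mutant_spec"])
            raw["cohort"] = CohortSpec(**c)
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = QcThresholds(**raw["thresholds"])
        return cls(**raw)


@dataclass
class RunResult:
    out_dir: str
    files: list[str]
    manifest: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GgkitError as exc:
                raise GgkitError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order and write reports plus a run manifest.

    Reruns with an identical config (including seed) reproduce identical
    output bytes.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"ggkit_version": __version__, "seed": config.seed, "inputs": {}}
    results: dict[str, object] = {}

    # -- stage: input -------------------------------------------------------
    if config.cohort is not None:
        logger.info("simulating cohort: %d samples x %d loci",
                    config.cohort.n_samples, config.cohort.n_loci)
        cohort = _stage("simulate")(build_cohort)(config.cohort)
        matrix, metas = cohort.matrix, cohort.metas
        results["truth"] = cohort.truth
        manifest["inputs"]["cohort_spec"] = asdict(config.cohort)
    else:
        matrix, metas = _stage("load")(read_genotype_table)(config.genotypes_path)
        manifest["inputs"]["genotypes"] = _sha256(config.genotypes_path)
        if config.meta_path:
            metas = read_sample_metadata(config.meta_path)
            manifest["inputs"]["meta"] = _sha256(config.meta_path)
            meta_ids = {m.sample_id for m in metas}
            missing = [s for s in matrix.sample_ids if s not in meta_ids]
            if missing:
                raise ConfigError(
                    f"metadata lacks sample ids present in genotypes: {missing[:5]}"
                )
    loci_meta = None
    if config.loci_path:
        loci_meta = read_locus_metadata(config.loci_path)
        manifest["inputs"]["loci"] = _sha256(config.loci_path)

    # -- stage: panel QC ----------------------------------------------------
    qc_report, filtered = _stage("qc")(filter_panel)(
        matrix, loci_meta, config.thresholds
    )
    results["qc_report"] = qc_report
    manifest["qc"] = {"n_input": qc_report.n_input, "n_retained": qc_report.n_retained}
    logger.info("panel QC: retained %d/%d loci", qc_report.n_retained, qc_report.n_input)
    if qc_report.n_retained == 0:
        raise GgkitError("stage 'qc': no locus survived panel filters")

    # -- stage: identity ----------------------------------------------------
    pairs = _stage("identity")(pairwise_distances)(filtered)
    gap = distance_histogram(pairs, config.min_gap_width, config.fallback_threshold)
    groups = redundancy_groups(pairs, gap.intra_threshold)
    groups_df, homonymy_df = match_report(groups, metas)
    results["pairs"] = pairs
    results["histogram"] = gap
    results["groups"] = groups
    results["group_labels"] = groups_df
    results["homonymy_flags"] = homonymy_df
    manifest["identity"] = {
        "n_pairs": pairs.n_pairs,
        "intra_threshold": gap.intra_threshold,
        "is_bimodal": gap.is_bimodal,
        "n_groups": len(groups.groups),
        "n_unique_genotypes": len(groups.unique_genotypes),
    }
    logger.info("identity: %d pairs, threshold %d, %d redundancy groups",
                pairs.n_pairs, gap.intra_threshold, len(groups.groups))
    if config.plot:
        plot_histogram(gap, os.path.join(config.out_dir, "histogram.png"))

    # -- stage: diversity ---------------------------------------------------
    meta_by_id = {m.sample_id: m for m in metas}
    unique_cult = [
        s for s in groups.unique_genotypes
        if meta_by_id.get(s) is None or meta_by_id[s].category != "wild"
    ]
    wild = [s for s in matrix.sample_ids
            if meta_by_id.get(s) is not None and meta_by_id[s].category == "wild"]
    stats_cult = _stage("diversity")(locus_statistics)(filtered, unique_cult)
    results["diversity_cultivated"] = stats_cult
    results["diversity_cultivated_summary"] = summarize(stats_cult)
    if wild:
        stats_wild = locus_statistics(filtered, wild)
        results["diversity_wild"] = stats_wild
        results["diversity_wild_summary"] = summarize(stats_wild)

    # -- stage: AMOVA -------------------------------------------------------
    labels = {m.sample_id: (m.group_label or "all") for m in metas}
    n_labels = len({labels.get(s, "all") for s in matrix.sample_ids})
    if n_labels >= 2 and pairs.defined.all():
        amova = _stage("amova")(amova_one_way)(
            pairs,
            {s: labels.get(s, "all") for s in matrix.sample_ids},
            config.n_permutations,
            config.seed,
        )
        results["amova"] = amova
        results["amova_partition"] = variance_partition_report(amova)
        manifest["amova"] = {"phi_st": amova.phi_st, "perm_p": amova.perm_p}
    else:
        logger.info("AMOVA skipped (needs >= 2 group labels and complete distances)")

    # -- stage: tree --------------------------------------------------------
    tree, n_discarded = _stage("tree")(bootstrap_support)(
        filtered, config.bootstrap_reps, config.seed
    )
    results["tree"] = tree
    manifest["tree"] = {
        "bootstrap_reps": config.bootstrap_reps,
        "replicates_discarded": n_discarded,
    }

    files = write_reports(results, config.out_dir)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(manifest_path)
    return RunResult(config.out_dir, sorted(files), manifest)
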