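"""End-to-end orchestration: ingest -> groups -> filter -> DE -> score -> survive.

``run_all`` executes the stages in order, collects a reproducibility manifest
(configuration, seed, per-stage record counts) and writes plain-text outputs:
the DE table, the signature, the score table, per-group Kaplan-Meier step
tables, a canonical summary JSON, and the manifest. Given the same inputs,
configuration, and seed, two runs produce byte-identical summary files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import dge as dge_mod
from .cohort import Cohort, assign_vascular_groups, read_cohort
from .errors import PipelineStageError, VascsigError
from .filtering import KeywordSet, cpm, keyword_filter, low_expression_exclusion
from .scoring import assign_expected_groups, score_samples
from .simulate import SyntheticConfig, simulate_cohort
from .survival import logrank_test, km_estimate, null_calibration, optimize_cutoff

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis parameters with their standard defaults."""

    counts_path: str | None = None
    clinical_path: str | None = None
    annotation_path: str | None = None
    rcbv_threshold: float = 7.0
    rcbv_threshold_inclusive: bool = False
    keywords_path: str | None = None
    min_median_cpm: float = 0.2
    alpha: float = 0.01
    contrast: str = dge_mod.CONTRAST_HV
    include_age: bool = True
    center: str = "median"
    cutoff: int | str = "auto"  # integer or "auto"
    min_group_frac: float = 0.1
    n_permutations: int = 0
    seed: int = 0
    out_dir: str | None = None
    simulate: dict | None = None  # SyntheticConfig overrides; None = read files

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise VascsigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        return None if math.isnan(float(x)) else float(x)
    return x


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    manifest["stages"].append(
        {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
    )
    logger.info("stage %s done: %s", name, counts)


def run_all(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run the whole analysis; returns a result bundle (and writes out_dir).

    The bundle holds the cohort, DE table, signature, score table,
    stratification, survival results, the manifest, and the summary dict.
    """
    manifest: dict = {"config": _jsonable(config.to_dict()), "stages": []}
    bundle: dict = {"manifest": manifest}

    # --- ingest -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if cohort is None:
            if config.simulate is not None:
                sim_cfg = SyntheticConfig.from_dict(
                    {**config.simulate, "seed": config.seed}
                )
                counts, annotation, clinical, truth = simulate_cohort(sim_cfg)
                from .cohort import build_cohort

                cohort = build_cohort(counts, clinical, annotation)
                bundle["truth"] = truth
            else:
                if not (
                    config.counts_path
                    and config.clinical_path
                    and config.annotation_path
                ):
                    raise VascsigError(
                        "either input paths or a simulate block are required"
                    )
                cohort = read_cohort(
                    config.counts_path, config.clinical_path, config.annotation_path
                )
    except VascsigError as exc:
        raise PipelineStageError("ingest", str(exc)) from exc
    bundle["cohort"] = cohort
    _stage(
        manifest,
        "ingest",
        t0,
        n_samples=cohort.n_samples,
        n_genes=cohort.counts.n_genes,
    )

    # --- vascular groups --------------------------------------------------
    t0 = time.perf_counter()
    try:
        assign_vascular_groups(
            cohort,
            threshold=config.rcbv_threshold,
            inclusive=config.rcbv_threshold_inclusive,
        )
    except VascsigError as exc:
        raise PipelineStageError("groups", str(exc)) from exc
    group_sizes = {g: len(v) for g, v in cohort.patients_by_group().items()}
    _stage(manifest, "groups", t0, **group_sizes)

    # --- gene filtering ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        keywords = (
            KeywordSet.from_file(config.keywords_path)
            if config.keywords_path
            else KeywordSet()
        )
        kw_genes = keyword_filter(cohort.annotation, keywords)
        expr_cpm = cpm(cohort.counts.subset_genes(kw_genes))
        retained = low_expression_exclusion(expr_cpm, config.min_median_cpm)
    except VascsigError as exc:
        raise PipelineStageError("filter", str(exc)) from exc
    bundle["retained_genes"] = retained
    _stage(
        manifest,
        "filter",
        t0,
        genes_in=cohort.counts.n_genes,
        genes_after_keyword=len(kw_genes),
        genes_after_cpm=len(retained),
    )

    # --- differential expression -----------------------------------------
    t0 = time.perf_counter()
    try:
        de_table, signature = dge_mod.run_dge(
            cohort,
            contrast=config.contrast,
            alpha=config.alpha,
            gene_ids=retained,
            include_age=config.include_age,
        )
    except VascsigError as exc:
        raise PipelineStageError("dge", str(exc)) from exc
    bundle["de_table"] = de_table
    bundle["signature"] = signature
    _stage(
        manifest,
        "dge",
        t0,
        genes_in=len(retained),
        n_significant=int(de_table["significant"].sum()),
        signature_size=len(signature),
    )

    # --- scoring ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if len(signature) == 0:
            raise VascsigError("empty signature; nothing to score")
        expr_all = dge_mod.log2cpm(cohort.counts.subset_genes(retained))
        scores = score_samples(expr_all, signature, center=config.center)
    except VascsigError as exc:
        raise PipelineStageError("score", str(exc)) from exc
    bundle["scores"] = scores
    _stage(
        manifest,
        "score",
        t0,
        n_samples=len(scores.sample_ids),
        score_min=int(scores.scores.min()),
        score_max=int(scores.scores.max()),
    )

    # --- survival stratification -----------------------------------------
    t0 = time.perf_counter()
    by_id = {p.patient_id: p for p in cohort.patients}
    times = np.array([by_id[s].os_days for s in scores.sample_ids])
    events = np.array([by_id[s].event for s in scores.sample_ids])
    n_valid = int(sum(by_id[s].survival_valid for s in scores.sample_ids))
    try:
        if config.cutoff == "auto":
            cut_res = optimize_cutoff(
                scores.scores, times, events, min_group_frac=config.min_group_frac
            )
            cutoff = cut_res.chosen_cutoff
        else:
            cutoff = int(config.cutoff)
            high = scores.scores > cutoff
            lr = logrank_test(
                times[high], events[high], times[~high], events[~high]
            )
            from .survival import CutoffResult

            cut_res = CutoffResult(
                chosen_cutoff=cutoff,
                p_value=lr.p_value,
                statistic=lr.statistic,
                group_sizes=(int(high.sum()), int((~high).sum())),
                median_survival_per_group=(
                    km_estimate(times[high], events[high]).median_survival,
                    km_estimate(times[~high], events[~high]).median_survival,
                ),
                all_candidate_p={cutoff: lr.p_value},
            )
        strata = assign_expected_groups(scores, cutoff, config.contrast)
        calib = None
        if config.n_permutations:
            calib = null_calibration(
                scores.scores,
                times,
                events,
                n_permutations=config.n_permutations,
                min_group_frac=config.min_group_frac,
                seed=config.seed,
            )
        km_curves = {}
        labels = np.array(strata.expected_group)
        for lab in sorted(set(labels)):
            mask = labels == lab
            km_curves[lab] = km_estimate(times[mask], events[mask])
    except VascsigError as exc:
        raise PipelineStageError("survive", str(exc)) from exc
    bundle["stratification"] = strata
    bundle["cutoff_result"] = cut_res
    bundle["km_curves"] = km_curves
    bundle["calibration"] = calib
    _stage(
        manifest,
        "survive",
        t0,
        n_valid_survival=n_valid,
        cutoff=int(cut_res.chosen_cutoff),
        n_high=cut_res.group_sizes[0],
        n_low=cut_res.group_sizes[1],
    )

    # --- summary ----------------------------------------------------------
    label_counts = {
        lab: int((np.array(strata.expected_group) == lab).sum())
        for lab in sorted(set(strata.expected_group))
    }
    summary = {
        "seed": config.seed,
        "contrast": config.contrast,
        "vascular_group_sizes": group_sizes,
        "genes_initial": cohort.counts.n_genes,
        "genes_after_keyword": len(kw_genes),
        "genes_after_cpm": len(retained),
        "signature_size": len(signature),
        "score_cutoff": int(cut_res.chosen_cutoff),
        "expected_group_sizes": label_counts,
        "logrank_statistic": cut_res.statistic,
        "logrank_p": cut_res.p_value,
        "median_survival_days": {
            "high_score": cut_res.median_survival_per_group[0],
            "low_score": cut_res.median_survival_per_group[1],
        },
        "permutation_adjusted_p": calib.adjusted_p if calib else None,
        "n_valid_survival": n_valid,
    }
    bundle["summary"] = _jsonable(summary)

    if config.out_dir:
        _write_outputs(Path(config.out_dir), bundle)
    return bundle


def _write_outputs(out: Path, bundle: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["de_table"].to_csv(out / "de_table.tsv", sep="\t", index=False)
    bundle["de_table"][["gene_id", "logFC", "neg_log10_q"]].to_csv(
        out / "volcano.tsv", sep="\t", index=False
    )
    bundle["signature"].to_dataframe().to_csv(
        out / "signature.tsv", sep="\t", index=False
    )
    scores = bundle["scores"]
    strata = bundle["stratification"]
    score_df = scores.to_series().to_frame()
    score_df["expected_group"] = strata.expected_group
    score_df.index.name = "patient_id"
    score_df.to_csv(out / "scores.tsv", sep="\t")
    for lab, curve in bundle["km_curves"].items():
        curve.to_dataframe().to_csv(out / f"km_{lab}.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(bundle["manifest"]), fh, indent=2, sort_keys=True)
        fh.write("\n")
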