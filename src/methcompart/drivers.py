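"""Integrated driver scoring and the end-to-end pipeline.

The evidence for a TF driving tumour-specific expression is combined as

    S = log10(F) * (-log10 p)

where F is the fold enrichment of the TF's binding sites in
tumour-specific open chromatin and p the rank-sum p-value for systematic
overexpression of its target genes.  Activator candidates require
F > 1.5 and p < 1e-4 (RNA-polymerase studies excluded by a configurable
name list); repressor candidates require significant depletion from
tumour-specific open chromatin, significant enrichment in tumour-specific
closed chromatin, and systematic target down-regulation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core_genomics import GenomeLayout, PeakSet, read_bed, read_layout
from .compartments import (
    CompartmentProfile,
    MethylationMatrix,
    infer_compartments,
    write_profile,
)
from .differential import DifferentialCompartments, compare_profiles, strict_subset, write_differential
from .tf_enrichment import EnrichmentResult, enrich_studies, results_to_frame
from .expression import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetTestResult,
    ModeratedStats,
    map_targets,
    moderated_t,
    test_target_sets,
)

logger = logging.getLogger("methcompart")

DEFAULT_F_MIN = 1.5
DEFAULT_P_MAX = 1e-4
DEFAULT_ADJ_P_MAX = 0.05
DEFAULT_POLYMERASE_NAMES = frozenset({"POLR2A", "RNAP2", "RNAPII", "POL2"})


@dataclass(frozen=True)
class DriverScore:
    study_id: str
    tf: str
    f_tso: float
    p_up: float
    score: float                       # S = log10(F) * (-log10 p); NaN if undefined
    f_tsc: float | None = None
    p_down: float | None = None
    adj_p_tso: float | None = None
    adj_p_tsc: float | None = None
    activator: bool = False
    repressor: bool = False
    flagged: bool = False              # F zero/infinite: score undefined


def integrated_score(f: float, p: float) -> float:
    """S = log10(F) * (-log10 p).  Requires finite positive F and p in (0, 1]."""
    if not (0 < f < math.inf):
        raise ValueError("F must be positive and finite")
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    return math.log10(f) * (-math.log10(p))


def score_drivers(open_results: Sequence[EnrichmentResult],
                  closed_results: Sequence[EnrichmentResult],
                  up_tests: Sequence[GeneSetTestResult],
                  down_tests: Sequence[GeneSetTestResult]) -> list[DriverScore]:
    """Assemble one DriverScore per study from the enrichment and
    expression evidence (flags are set separately by the selectors)."""
    closed_by_id = {r.study_id: r for r in closed_results}
    up_by_id = {t.study_id: t for t in up_tests}
    down_by_id = {t.study_id: t for t in down_tests}
    out = []
    for r in open_results:
        up = up_by_id.get(r.study_id)
        if up is None:
            continue
        down = down_by_id.get(r.study_id)
        closed = closed_by_id.get(r.study_id)
        flagged = not (0 < r.fold_enrichment < math.inf)
        score = float("nan") if flagged else integrated_score(r.fold_enrichment, up.p_value)
        out.append(DriverScore(
            study_id=r.study_id, tf=r.tf, f_tso=r.fold_enrichment,
            p_up=up.p_value, score=score,
            f_tsc=closed.fold_enrichment if closed else None,
            p_down=down.p_value if down else None,
            adj_p_tso=r.adj_p_value,
            adj_p_tsc=closed.adj_p_value if closed else None,
            flagged=flagged))
    return out


def select_activators(scores: Iterable[DriverScore],
                      f_min: float = DEFAULT_F_MIN,
                      p_max: float = DEFAULT_P_MAX,
                      exclude_tfs: Iterable[str] = DEFAULT_POLYMERASE_NAMES,
                      ) -> list[DriverScore]:
    """TFs enriched toward tumour-specific open chromatin (F > f_min) whose
    targets are systematically overexpressed (p < p_max), ranked by the
    integrated score.  Exclusions (RNA polymerase studies by default) are
    a name list, not hard-coded."""
    if f_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    exclude = {t.upper() for t in exclude_tfs}
    chosen = [replace_flags(s, activator=True) for s in scores
              if s.tf.upper() not in exclude
              and s.f_tso > f_min and s.p_up < p_max]
    return sorted(chosen, key=lambda s: (-(s.score if math.isfinite(s.score) else math.inf),
                                         s.study_id))


def select_repressors(scores: Iterable[DriverScore],
                      p_max: float = DEFAULT_P_MAX,
                      adj_p_max: float = DEFAULT_ADJ_P_MAX) -> list[DriverScore]:
    """TFs significantly depleted from tumour-specific open chromatin
    (F_TSO < 1), significantly enriched in tumour-specific closed
    chromatin (F_TSC > 1), with systematically down-regulated targets.
    "Significant" means BH-adjusted chi-squared p below ``adj_p_max``."""
    chosen = []
    for s in scores:
        if s.f_tsc is None or s.p_down is None:
            continue
        if (s.f_tso < 1 and s.adj_p_tso is not None and s.adj_p_tso < adj_p_max
                and s.f_tsc > 1 and s.adj_p_tsc is not None and s.adj_p_tsc < adj_p_max
                and s.p_down < p_max):
            chosen.append(replace_flags(s, repressor=True))
    return sorted(chosen, key=lambda s: (s.p_down, s.study_id))


def replace_flags(s: DriverScore, activator: bool | None = None,
                  repressor: bool | None = None) -> DriverScore:
    from dataclasses import replace
    kwargs = {}
    if activator is not None:
        kwargs["activator"] = activator
    if repressor is not None:
        kwargs["repressor"] = repressor
    return replace(s, **kwargs)


def scores_to_frame(scores: Sequence[DriverScore],
                    activators: Sequence[DriverScore] = (),
                    repressors: Sequence[DriverScore] = ()) -> pd.DataFrame:
    act = {s.study_id for s in activators}
    rep = {s.study_id for s in repressors}
    rows = []
    for s in sorted(scores, key=lambda x: -(x.score if math.isfinite(x.score) else -math.inf)):
        rows.append({
            "study_id": s.study_id, "tf": s.tf,
            "F_tso": s.f_tso,
            "log10F_tso": math.log10(s.f_tso) if 0 < s.f_tso < math.inf else float("nan"),
            "p_up": s.p_up, "neg_log10_p_up": -math.log10(s.p_up),
            "score": s.score,
            "F_tsc": s.f_tsc, "p_down": s.p_down,
            "activator": s.study_id in act, "repressor": s.study_id in rep,
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs.  Either ``simulate`` is true (inputs are
    generated from ``seed``) or every input path must be supplied."""

    simulate: bool = False
    seed: int = 0
    layout_path: str | None = None
    meth_tumour_path: str | None = None
    meth_normal_path: str | None = None
    peaks_dir: str | None = None
    annotation_path: str | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    theta: float = 0.1
    strict_delta: float | None = None
    tss_cutoff: int = 1000
    f_min: float = DEFAULT_F_MIN
    p_max: float = DEFAULT_P_MAX
    exclude_tfs: tuple[str, ...] = tuple(sorted(DEFAULT_POLYMERASE_NAMES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {})
        kwargs = {**raw, **thresholds}
        if "exclude_tfs" in kwargs:
            kwargs["exclude_tfs"] = tuple(kwargs["exclude_tfs"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulate:
            return
        required = ["layout_path", "meth_tumour_path", "meth_normal_path",
                    "peaks_dir", "annotation_path", "expression_path",
                    "groups_path"]
        missing = [f for f in required if getattr(self, f) is None]
        if missing:
            raise ValueError(f"missing pipeline input(s): {', '.join(missing)}")


@dataclass
class PipelineResult:
    tumour_profile: CompartmentProfile
    normal_profile: CompartmentProfile
    differential: DifferentialCompartments
    open_results: list[EnrichmentResult]
    closed_results: list[EnrichmentResult]
    targets: dict[str, set[str]]
    moderated: ModeratedStats
    up_tests: list[GeneSetTestResult]
    down_tests: list[GeneSetTestResult]
    scores: list[DriverScore]
    activators: list[DriverScore]
    repressors: list[DriverScore]
    provenance: dict


def _load_inputs(config: PipelineConfig):
    from .compartments import MethylationMatrix
    from .core_genomics import read_table
    from .expression import GeneAnnotation, ExpressionMatrix
    if config.simulate:
        from .synthetic import simulate_scenario
        sc = simulate_scenario(config.seed)
        return (sc.truth.layout, sc.meth_tumour, sc.meth_normal,
                list(sc.studies), sc.annotation, sc.expression)
    layout = read_layout(config.layout_path)
    meth_t = MethylationMatrix.from_frame(read_table(config.meth_tumour_path), "tumour")
    meth_n = MethylationMatrix.from_frame(read_table(config.meth_normal_path), "normal")
    studies = []
    for bed in sorted(Path(config.peaks_dir).glob("*.bed")):
        tf = bed.stem.split("_")[0]
        studies.append(read_bed(bed, study_id=bed.stem, tf=tf, layout=layout))
    annotation = GeneAnnotation.from_frame(read_table(config.annotation_path))
    groups = read_table(config.groups_path)["group"].to_dict()
    expr = ExpressionMatrix(values=read_table(config.expression_path), groups=groups)
    return layout, meth_t, meth_n, studies, annotation, expr


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the whole analysis: compartment inference for both cohorts,
    differential windows, TF enrichment, target mapping, moderated t,
    gene-set tests, and driver scoring.  With ``outdir`` the eight result
    tables plus a provenance block are written; reruns with the same
    config produce identical tables."""
    config.validate()
    layout, meth_t, meth_n, studies, annotation, expr = _load_inputs(config)
    logger.info("inferring compartments (%d windows, %d studies)",
                layout.n_windows, len(studies))

    tumour = infer_compartments(meth_t, layout, theta=config.theta)
    normal = infer_compartments(meth_n, layout, theta=config.theta)
    diff = compare_profiles(tumour, normal, config.theta)
    if config.strict_delta is not None:
        diff = strict_subset(diff, config.strict_delta)
    logger.info("differential windows: %d TSO, %d TSC", len(diff.tso), len(diff.tsc))

    open_results = enrich_studies(studies, diff.tso, layout)
    closed_results = enrich_studies(studies, diff.tsc, layout)

    targets = {s.study_id: map_targets(s, annotation, config.tss_cutoff)
               for s in studies}
    moderated = moderated_t(expr)
    up_tests = test_target_sets(moderated, targets, alternative="up")
    down_tests = test_target_sets(moderated, targets, alternative="down")

    scores = score_drivers(open_results, closed_results, up_tests, down_tests)
    activators = select_activators(scores, config.f_min, config.p_max,
                                   config.exclude_tfs)
    repressors = select_repressors(scores, config.p_max)

    provenance = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "simulate": config.simulate,
        "theta": config.theta,
        "strict_delta": config.strict_delta,
        "tss_cutoff": config.tss_cutoff,
        "f_min": config.f_min,
        "p_max": config.p_max,
        "normalization": tumour.normalization,
        "orientation_covariate": tumour.orientation_covariate,
        "n_windows": layout.n_windows,
        "n_tso": len(diff.tso),
        "n_tsc": len(diff.tsc),
    }
    result = PipelineResult(
        tumour_profile=tumour, normal_profile=normal, differential=diff,
        open_results=open_results, closed_results=closed_results,
        targets=targets, moderated=moderated, up_tests=up_tests,
        down_tests=down_tests, scores=scores, activators=activators,
        repressors=repressors, provenance=provenance)
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_profile(result.tumour_profile, outdir / "profile_tumour.tsv")
    write_profile(result.normal_profile, outdir / "profile_normal.tsv")
    write_differential(result.differential, outdir / "differential.tsv")
    results_to_frame(result.open_results, result.closed_results) \
        .to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [(sid, g) for sid, genes in result.targets.items() for g in sorted(genes)],
        columns=["study_id", "gene_id"],
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    result.moderated.table.to_csv(outdir / "moderated_t.tsv", sep="\t",
                                  float_format="%.6g")
    pd.DataFrame([t.__dict__ for t in result.up_tests + result.down_tests]) \
        .to_csv(outdir / "set_tests.tsv", sep="\t", index=False, float_format="%.6g")
    scores_to_frame(result.scores, result.activators, result.repressors) \
        .to_csv(outdir / "driver_scores.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
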