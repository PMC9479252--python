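"""End-to-end orchestration: peaks + profile -> calls -> atlas -> summaries.

Per experiment the stages run in method order: peak–gene association,
promoter and enhancer target sets (or a combined set under method 3), the
direction-specific PAGE gate with score sweep, and EPFP calling.  Calls from
all experiments of a TF are then combined, the replication filter applied,
and the TF characterised.  Every stage consumes and produces plain tables,
so stages are independently runnable and all outputs are reproducible from
(config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .annotation_io import GeneModel, PeakSet
from .atlas_assembly import (ATLAS_COLUMNS, apply_support_filter,
                             combine_calls)
from .enrichment_page import (DIRECTIONS, ExpressionProfile, PAGE_QUARTER)
from .epfp_calling import (CALL_COLUMNS, CONTROL_FC, EPFP_MAX, FC_MIN,
                           call_regulated_targets)
from .set_overlap import similarity_matrix
from .target_scoring import associate_peaks, build_target_set
from .tf_characterization import TFSummary, summarize_tf, summary_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All fixed thresholds of the method in one place."""

    method: int = 1               # target scoring method (1, 2 or 3)
    fc_min: float = FC_MIN        # candidate linear fold threshold
    control_fc: float = CONTROL_FC
    epfp_max: float = EPFP_MAX
    page_quarter: float = PAGE_QUARTER
    subset_moments: bool = True   # PAGE moments within the tested quarter
    rank_window: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ValueError("method must be 1, 2 or 3")
        if not 0 < self.page_quarter <= 1:
            raise ValueError("page_quarter must be in (0, 1]")


@dataclass
class ExperimentResult:
    """Per-experiment candidate tables and gate decisions."""

    experiment_id: str
    candidates: pd.DataFrame       # all EPFP-scored candidates, with `called`
    enrichment: pd.DataFrame       # one row per (region, direction) gate
    bound_genes: frozenset = frozenset()  # all peak-associated genes

    @property
    def calls(self) -> pd.DataFrame:
        if len(self.candidates) == 0:
            return self.candidates
        return self.candidates[self.candidates["called"]]


def run_experiment(genes: GeneModel, peakset: PeakSet,
                   profile: ExpressionProfile,
                   config: RunConfig | None = None) -> ExperimentResult:
    """Run association, enrichment gating and EPFP calling for one
    ChIP-seq experiment against one induction profile."""
    config = config or RunConfig()
    assocs = associate_peaks(peakset, genes)
    region_modes = ["combined"] if config.method == 3 else ["promoter",
                                                            "enhancer"]
    cand_tables, enr_rows = [], []
    for region_mode in region_modes:
        ts = build_target_set(assocs, config.method, region_mode,
                              tf_id=peakset.tf_id,
                              experiment_id=peakset.experiment_id)
        for direction in DIRECTIONS:
            cand = call_regulated_targets(
                profile, ts, direction, epfp_max=config.epfp_max,
                fc_min=config.fc_min, control_fc=config.control_fc,
                quarter=config.page_quarter,
                subset_moments=config.subset_moments)
            enr = cand.attrs["enrichment"]
            enr_rows.append({"tf": peakset.tf_id,
                             "experiment": peakset.experiment_id,
                             "region": region_mode, "direction": direction,
                             "z": enr.z, "p": enr.p, "n_set": enr.n_set,
                             "best_threshold": enr.best_threshold,
                             "significant": enr.significant,
                             "n_targets": len(ts)})
            if len(cand):
                cand_tables.append(cand)
    candidates = (pd.concat(cand_tables, ignore_index=True) if cand_tables
                  else pd.DataFrame(columns=CALL_COLUMNS))
    return ExperimentResult(experiment_id=peakset.experiment_id,
                            candidates=candidates,
                            enrichment=pd.DataFrame(enr_rows),
                            bound_genes=frozenset(assocs["gene"]))


@dataclass
class StudyResult:
    """Atlas entries plus per-experiment results for one TF."""

    tf_id: str
    experiments: list[ExperimentResult]
    atlas: pd.DataFrame
    summary: TFSummary | None = None
    similarity: pd.DataFrame | None = field(default=None, repr=False)


def run_atlas(experiments: list[ExperimentResult], tf_id: str,
              profile: ExpressionProfile,
              experiment_meta: dict[str, str] | None = None,
              universe_size: int | None = None) -> StudyResult:
    """Combine per-experiment calls into the TF's atlas entries and summary.

    The replication filter drops single-experiment entries unless only one
    experiment yielded calls for this TF.  When both an up and a down set
    survive, their signed hypergeometric similarity matrix is attached.
    """
    all_calls = [e.calls for e in experiments if len(e.calls)]
    n_successful = sum(1 for e in experiments if len(e.calls))
    if n_successful == 0:
        logger.warning("no experiment yielded calls for %s", tf_id)
        atlas = pd.DataFrame(columns=ATLAS_COLUMNS)
    else:
        atlas = combine_calls(pd.concat(all_calls, ignore_index=True),
                              experiment_meta)
        atlas = apply_support_filter(atlas, n_successful)
    summary = summarize_tf(atlas, profile, tf_id)
    sim = None
    sets = [(tf_id, d, frozenset(atlas.loc[atlas["direction"] == d, "gene"]))
            for d in DIRECTIONS
            if (atlas["direction"] == d).any()]
    if len(sets) >= 2:
        sim = similarity_matrix(sets, universe_size or len(profile))
    return StudyResult(tf_id=tf_id, experiments=experiments, atlas=atlas,
                       summary=summary, similarity=sim)


def run_study(genes: GeneModel, peaksets: list[PeakSet],
              profile: ExpressionProfile,
              config: RunConfig | None = None,
              experiment_meta: dict[str, str] | None = None) -> StudyResult:
    """Full pipeline for one TF: every experiment, then atlas assembly."""
    config = config or RunConfig()
    tf_ids = {ps.tf_id for ps in peaksets}
    if len(tf_ids) != 1:
        raise ValueError("run_study expects peak sets for a single TF")
    experiments = [run_experiment(genes, ps, profile, config)
                   for ps in peaksets]
    return run_atlas(experiments, tf_ids.pop(), profile, experiment_meta,
                     universe_size=len(profile))


def run_manifest(config: RunConfig) -> dict:
    """Run parameters recorded next to pipeline outputs."""
    return {"tfregulon_version": __version__, **asdict(config)}
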