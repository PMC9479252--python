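"""Gene-set enrichment of binding targets among induction-responsive genes.

Implements the PAGE z-statistic

    z = (x_set - x_all) * sqrt(n_set) / SD_all

where x is the per-gene log2 expression change after TF induction and
x_set/n_set are the mean and count of target genes inside the tested
universe.  Following the direction-specific modification used for induction
compendia, the statistic is applied to the subset of the top quarter of
genes ranked by expression change (upregulated direction) or the bottom
quarter (downregulated direction) rather than to all genes; by default the
background moments x_all/SD_all are likewise computed within that quarter,
which keeps the statistic centred under a random-target null (a random set's
members inside the quarter are a uniform draw from it).  The classical
variant with all-gene moments is available via ``subset_moments=False``.
For the downregulated direction the sign is flipped so that a positive
reported z always means enrichment in the stated direction.

When per-gene binding scores are available the target set is swept over a
grid of score thresholds and the maximal z is reported, together with the
threshold that attained it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .target_scoring import TargetSet

logger = logging.getLogger(__name__)

#: fraction of genes in the direction-specific tested subset
PAGE_QUARTER = 0.25
#: enrichment significance gate
PAGE_ALPHA = 0.05
#: score-threshold sweep grid: percentiles of target scores
SWEEP_PERCENTILES = tuple(range(0, 100, 10))

DIRECTIONS = ("up", "down")


@dataclass
class ExpressionProfile:
    """Per-gene log2 fold change after TF induction, with responder flags.

    ``table`` is indexed by gene symbol with columns ``log2fc`` (float) and
    ``responder2x`` (bool; stands in for a >= 2-fold change significant at
    FDR < 0.05 versus controls).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not {"log2fc", "responder2x"}.issubset(t.columns):
            raise ValueError("profile needs columns log2fc, responder2x")
        if not np.isfinite(t["log2fc"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite log2fc in expression profile")
        if t.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression profile")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t")
        df["responder2x"] = df["responder2x"].astype(bool)
        return cls(df.set_index("gene")[["log2fc", "responder2x"]])

    def to_tsv(self, path) -> None:
        out = self.table.reset_index()
        out.columns = ["gene", "log2fc", "responder2x"]
        out.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    """Outcome of one PAGE test (optionally after a score sweep)."""

    direction: str
    z: float
    p: float
    n_set: int
    region_mode: str | None = None
    best_threshold: float = 0.0
    computable: bool = True
    target_genes: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def significant(self) -> bool:
        """Enriched in the stated direction at p <= 0.05."""
        return self.computable and self.z > 0 and self.p <= PAGE_ALPHA


def _not_computable(direction: str, region_mode: str | None = None
                    ) -> EnrichmentResult:
    return EnrichmentResult(direction=direction, z=float("nan"),
                            p=1.0, n_set=0, region_mode=region_mode,
                            computable=False)


def _sorted_profile(profile: ExpressionProfile) -> pd.DataFrame:
    # ascending by log2fc, ties broken by symbol for determinism
    return (profile.table.reset_index(names="gene")
            .sort_values(["log2fc", "gene"], kind="mergesort"))


def page_z(profile: ExpressionProfile, target_genes, direction: str,
           quarter: float = PAGE_QUARTER,
           subset_moments: bool = True) -> EnrichmentResult:
    """PAGE z for a target-gene set in one response direction.

    ``x_all``/``SD_all`` are computed within the tested quarter by default
    (``subset_moments=False`` uses all-gene moments as in the classical
    statistic).  The tested subset is the top ``quarter`` of genes by log2fc
    for ``direction='up'`` and the bottom quarter for ``'down'``; targets
    outside the subset do not contribute.  For the down direction the raw z
    (negative for enrichment of low values) is negated, so positive z means
    enrichment in the stated direction.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    total = len(profile)
    n_sub = int(np.floor(quarter * total))
    if n_sub < 1:
        return _not_computable(direction)
    s = _sorted_profile(profile)
    sub = s.tail(n_sub) if direction == "up" else s.head(n_sub)
    if subset_moments:
        x_all = float(sub["log2fc"].mean())
        sd_all = float(sub["log2fc"].std(ddof=1))
    else:
        x_all = float(profile.log2fc.mean())
        sd_all = float(profile.log2fc.std(ddof=1))
    in_set = sub["gene"].isin(set(target_genes))
    n_set = int(in_set.sum())
    if n_set == 0 or not np.isfinite(sd_all) or sd_all == 0:
        return _not_computable(direction)
    x_set = float(sub.loc[in_set, "log2fc"].mean())
    z_raw = (x_set - x_all) * np.sqrt(n_set) / sd_all
    z = z_raw if direction == "up" else -z_raw
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return EnrichmentResult(direction=direction, z=float(z), p=p,
                            n_set=n_set,
                            target_genes=frozenset(sub.loc[in_set, "gene"]))


def page_with_score_sweep(profile: ExpressionProfile, target_set: TargetSet,
                          direction: str, quarter: float = PAGE_QUARTER,
                          percentiles=SWEEP_PERCENTILES,
                          subset_moments: bool = True) -> EnrichmentResult:
    """Maximal PAGE z over a grid of binding-score thresholds.

    Thresholds are the given percentiles of the target scores (deciles by
    default); at each threshold the set is restricted to genes scoring at or
    above it, so the lowest threshold reproduces the unswept test.  The
    result carries the best threshold and the target genes retained at it.
    The enrichment gate downstream is ``result.significant`` (p <= 0.05 and
    z > 0); no multiple-testing correction is applied across the sweep.
    """
    scores = target_set.scores
    if len(scores) == 0:
        return _not_computable(direction, target_set.region_mode)
    thresholds = np.unique(np.percentile(scores.to_numpy(), percentiles))
    best: EnrichmentResult | None = None
    for thr in thresholds:
        genes = scores.index[scores.to_numpy() >= thr]
        if len(genes) == 0:
            continue
        res = page_z(profile, genes, direction, quarter=quarter,
                     subset_moments=subset_moments)
        if not res.computable:
            continue
        if best is None or res.z > best.z:
            res.best_threshold = float(thr)
            best = res
    if best is None:
        return _not_computable(direction, target_set.region_mode)
    best.region_mode = target_set.region_mode
    logger.info("PAGE sweep %s/%s %s %s: z=%.2f p=%.3g n_set=%d thr=%.3g",
                target_set.tf_id, target_set.experiment_id,
                target_set.region_mode, direction, best.z, best.p,
                best.n_set, best.best_threshold)
    return best


def rank_plot_curve(profile: ExpressionProfile, target_genes,
                    window: int = 300) -> pd.DataFrame:
    """Sliding-window proportion of target genes along the response ranking.

    Genes are sorted ascending by log2fc (downregulated on the left); the
    curve gives, for each window start position (1-based ``rank``), the
    proportion of target genes among the ``window`` consecutive genes.
    """
    total = len(profile)
    if total < window:
        raise ValueError(f"profile has {total} genes < window {window}")
    s = _sorted_profile(profile)
    member = s["gene"].isin(set(target_genes)).to_numpy(dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(member)])
    prop = (cs[window:] - cs[:-window]) / window
    return pd.DataFrame({"rank": np.arange(1, total - window + 2),
                         "proportion": prop})
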