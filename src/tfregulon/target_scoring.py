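"""Peak-to-gene association and target-set construction.

Each ChIP-seq peak is associated with at most 3 genes whose TSS lies within
100 kb of the peak centre.  The association score is

    assoc = Q * S / max(d_kb, 1)

where Q is the symbol quality (1 or 3), S the peak binding score, and d_kb
the peak-centre-to-TSS distance in kb with the divisor floored at 1 kb (so
promoter-proximal binding is not inflated by tiny distances).  Candidate
genes scoring below 20% of the peak's best candidate are dropped.  Binding
within 500 bp of the TSS counts as promoter binding; 0.5–100 kb as enhancer
binding (a distal site, not a curated enhancer).

Per-gene target scores are then built under one of three methods:
#1 sum of association scores per region class, #2 maximum association score
per region class, #3 sum over promoter and enhancer sites combined.  Target
sets are capped at 5,000 genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, PeakSet

#: maximum peak-centre-to-TSS distance considered (bp)
ASSOC_WINDOW = 100_000
#: promoter/enhancer boundary (bp); d <= 500 is promoter
PROMOTER_MAX_DIST = 500
#: max genes associated with one peak
MAX_GENES_PER_PEAK = 3
#: candidates below this fraction of the peak's best score are dropped
REL_SCORE_MIN = 0.2
#: target sets larger than this keep only the top-scoring genes
MAX_TARGET_GENES = 5_000

REGION_MODES = ("promoter", "enhancer", "combined")


def classify_region(d: float) -> str:
    """Promoter (d <= 500 bp from TSS) vs enhancer (0.5–100 kb)."""
    if d < 0 or d > ASSOC_WINDOW:
        raise ValueError(f"distance {d} outside 0..{ASSOC_WINDOW} bp")
    return "promoter" if d <= PROMOTER_MAX_DIST else "enhancer"


def associate_peaks(peaks: PeakSet, genes: GeneModel,
                    window: int = ASSOC_WINDOW,
                    max_genes_per_peak: int = MAX_GENES_PER_PEAK,
                    rel_score_min: float = REL_SCORE_MIN) -> pd.DataFrame:
    """Associate peaks with nearby genes by distance-weighted scoring.

    Returns one row per retained (peak, gene) pair with columns
    ``peak_id`` (row index into the PeakSet), ``gene``, ``distance`` (bp,
    centre to the gene's nearest TSS), ``region`` and ``assoc_score``.
    Per peak: candidates are genes with a TSS within ``window`` bp of the
    peak centre (nearest TSS per gene); those scoring below
    ``rel_score_min`` of the best candidate are dropped, then the top
    ``max_genes_per_peak`` by score are kept.
    """
    gtab = genes.genes
    ptab = peaks.peaks
    if len(ptab) == 0 or len(gtab) == 0:
        return pd.DataFrame(columns=["peak_id", "gene", "distance", "region",
                                     "assoc_score"])
    pairs = []
    for chrom, grp in ptab.groupby("chrom"):
        gt = gtab[gtab["chrom"] == chrom]
        if gt.empty:
            continue
        order = np.argsort(gt["tss"].to_numpy(), kind="stable")
        tss = gt["tss"].to_numpy()[order]
        sym = gt["symbol"].to_numpy()[order]
        qual = gt["quality"].to_numpy()[order]
        centers = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        score = grp["score"].to_numpy()
        peak_id = grp.index.to_numpy()
        lo = np.searchsorted(tss, centers - window, side="left")
        hi = np.searchsorted(tss, centers + window, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        prow = np.repeat(np.arange(len(grp)), counts)
        within = np.arange(counts.sum()) - np.repeat(
            np.cumsum(counts) - counts, counts)
        trow = np.repeat(lo, counts) + within
        d = np.abs(centers[prow] - tss[trow])
        pairs.append(pd.DataFrame({
            "peak_id": peak_id[prow], "gene": sym[trow],
            "quality": qual[trow], "distance": d, "S": score[prow]}))
    if not pairs:
        return pd.DataFrame(columns=["peak_id", "gene", "distance", "region",
                                     "assoc_score"])
    df = pd.concat(pairs, ignore_index=True)
    # one TSS per (peak, gene): the nearest
    df = (df.sort_values(["peak_id", "gene", "distance"], kind="mergesort")
            .drop_duplicates(["peak_id", "gene"]))
    df = df[df["distance"] <= window]
    d_kb = np.maximum(df["distance"].to_numpy() / 1000.0, 1.0)
    df["assoc_score"] = df["quality"].to_numpy() * df["S"].to_numpy() / d_kb
    df = df[df["assoc_score"] > 0]
    # 20%-of-max filter, then top-N genes per peak
    best = df.groupby("peak_id")["assoc_score"].transform("max")
    df = df[df["assoc_score"] >= rel_score_min * best]
    df = (df.sort_values(["peak_id", "assoc_score", "gene"],
                         ascending=[True, False, True], kind="mergesort")
            .groupby("peak_id").head(max_genes_per_peak))
    df["region"] = np.where(df["distance"] <= PROMOTER_MAX_DIST,
                            "promoter", "enhancer")
    return df[["peak_id", "gene", "distance", "region",
               "assoc_score"]].reset_index(drop=True)


@dataclass
class TargetSet:
    """Per-gene binding scores for one TF/experiment/region mode/method."""

    tf_id: str
    experiment_id: str
    region_mode: str     # promoter | enhancer | combined
    method: int          # 1 = sum per region, 2 = max per region, 3 = sum combined
    scores: pd.Series    # index: gene symbol, values > 0

    def __post_init__(self) -> None:
        if self.region_mode not in REGION_MODES:
            raise ValueError(f"bad region_mode {self.region_mode!r}")
        if self.method not in (1, 2, 3):
            raise ValueError(f"bad method {self.method!r}")
        if (self.region_mode == "combined") != (self.method == 3):
            raise ValueError("region_mode 'combined' is used iff method is 3")
        if len(self.scores) > MAX_TARGET_GENES:
            raise ValueError("target set exceeds gene cap")
        if len(self.scores) and (self.scores <= 0).any():
            raise ValueError("target scores must be positive")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


def build_target_set(assocs: pd.DataFrame, method: int, region_mode: str,
                     cap: int = MAX_TARGET_GENES, tf_id: str = "",
                     experiment_id: str = "") -> TargetSet:
    """Aggregate peak–gene associations into a per-gene target score.

    Method 1 sums association scores over peaks of the requested region
    class, method 2 takes the maximum, method 3 sums over all peaks with
    promoter and enhancer sites combined (``region_mode='combined'``).
    When more than ``cap`` genes score, the top ``cap`` by score are kept
    (ties broken by symbol).
    """
    if method == 3:
        if region_mode != "combined":
            raise ValueError("method 3 requires region_mode='combined'")
        sub = assocs
    else:
        if region_mode not in ("promoter", "enhancer"):
            raise ValueError("methods 1/2 require promoter or enhancer mode")
        sub = assocs[assocs["region"] == region_mode]
    if len(sub) == 0:
        scores = pd.Series(dtype=float)
    else:
        agg = "max" if method == 2 else "sum"
        scores = sub.groupby("gene")["assoc_score"].agg(agg)
        if len(scores) > cap:
            ranked = scores.reset_index().sort_values(
                ["assoc_score", "gene"], ascending=[False, True],
                kind="mergesort").head(cap)
            scores = ranked.set_index("gene")["assoc_score"]
        scores = scores.sort_index()
    return TargetSet(tf_id=tf_id, experiment_id=experiment_id,
                     region_mode=region_mode, method=method, scores=scores)
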