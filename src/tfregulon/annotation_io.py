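"""Gene annotation and ChIP-seq peak input.

Reads tab-delimited gene tables (UCSC refGene-like) into a :class:`GeneModel`
with strand-aware transcription start sites and a per-symbol quality weight,
and reads peak calls (BED3/BED5/BED6, ENCODE narrowPeak, or generic TSV) into
a :class:`PeakSet`.  Peak post-processing follows the conventions used for
large ChIP-seq compendia: peaks separated by less than 500 bp are combined
into one, and at most 25,000 peaks are kept per data set.  A TSS-centred
peak-frequency profile serves as a quality-control check that binding is
concentrated near promoters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum gap (bp) between retained peaks; closer peaks are combined
PEAK_MERGE_GAP = 500
#: maximum number of peaks analysed per ChIP-seq data set
MAX_PEAKS = 25_000
#: alternative TSSs of one gene closer than this (bp) collapse to one
MIN_TSS_SEPARATION = 1_000

_WEAK_DIGITS = re.compile(r"\d{4}")
# FAM/MIR/MRP match uppercase as written in gene nomenclature; "orf" matches
# case-insensitively (C9orf72-style names).
_WEAK_SUBSTRINGS = ("FAM", "MIR", "MRP")
_PEAK_COLUMNS = ["chrom", "start", "end", "score"]


@dataclass
class GeneModel:
    """Gene symbols with strand-aware TSS positions and symbol quality.

    ``genes`` has one row per (symbol, TSS): columns ``symbol``, ``chrom``,
    ``strand`` (+/−), ``tss`` (bp, 0-based), ``quality`` (1 for "weak"
    symbols, 3 otherwise).  Alternative TSSs of the same symbol are
    guaranteed to be separated by more than 1 kb.
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["symbol", "chrom", "strand", "tss", "quality"]))

    def __post_init__(self) -> None:
        g = self.genes
        if len(g):
            bad_q = set(g["quality"]) - {1, 3}
            if bad_q:
                raise ValueError(f"symbol quality must be 1 or 3, got {bad_q}")
            bad_s = set(g["strand"]) - {"+", "-"}
            if bad_s:
                raise ValueError(f"unknown strand value(s): {bad_s}")

    @property
    def symbols(self) -> np.ndarray:
        return self.genes["symbol"].unique()

    @property
    def n_genes(self) -> int:
        return self.genes["symbol"].nunique()

    def __len__(self) -> int:
        return self.n_genes


@dataclass
class PeakSet:
    """Merged, capped, scored binding intervals from one ChIP-seq data set.

    ``peaks`` columns: ``chrom``, ``start`` (0-based), ``end`` (exclusive),
    ``score`` (non-negative binding strength, e.g. a MACS score).
    """

    tf_id: str
    experiment_id: str
    peaks: pd.DataFrame
    cell_state: str = "unknown"

    def __post_init__(self) -> None:
        if self.cell_state not in {"pluripotent", "differentiated", "unknown"}:
            raise ValueError(f"bad cell_state {self.cell_state!r}")
        p = self.peaks
        if len(p):
            if (p["start"] >= p["end"]).any():
                raise ValueError("peak with start >= end")
            if (p["score"] < 0).any():
                raise ValueError("negative peak score")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        p = self.peaks
        return ((p["start"].to_numpy() + p["end"].to_numpy()) // 2)


def symbol_quality(symbol: str) -> int:
    """Quality weight of a gene symbol: 1 for "weak" symbols, else 3.

    Weak symbols contain four consecutive digits (LOC/clone-style names) or
    one of the substrings FAM, MIR, MRP (uppercase) or orf (any case).
    """
    if not symbol:
        raise ValueError("empty gene symbol")
    if _WEAK_DIGITS.search(symbol):
        return 1
    if any(s in symbol for s in _WEAK_SUBSTRINGS) or "orf" in symbol.lower():
        return 1
    return 3


def load_gene_table(path) -> GeneModel:
    """Read a tab-delimited gene table into a :class:`GeneModel`.

    Expects columns ``symbol, chrom, strand, txStart, txEnd`` (header row, or
    headerless in that order).  TSS is txStart on the + strand and txEnd on
    the − strand.  Per symbol, the first TSS encountered is the main TSS;
    alternative TSSs are kept only if separated by more than 1 kb from every
    TSS already kept for that symbol.
    """
    required = ["symbol", "chrom", "strand", "txStart", "txEnd"]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("gene table %s is empty", path)
        return GeneModel()
    if not set(required).issubset(df.columns):
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
        if df.shape[1] < 5:
            raise ValueError(
                f"gene table needs >=5 columns {required}, got {df.shape[1]}")
        df = df.iloc[:, :5]
        df.columns = required
    if df.empty:
        logger.warning("gene table %s has no rows", path)
        return GeneModel()

    rows = []
    kept: dict[str, list[int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        symbol, chrom, strand = row.symbol, row.chrom, row.strand
        try:
            tx_start, tx_end = int(row.txStart), int(row.txEnd)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed gene table row {i}: {exc}") from exc
        if not symbol or pd.isna(symbol):
            raise ValueError(f"malformed gene table row {i}: missing symbol")
        if strand not in ("+", "-"):
            raise ValueError(f"gene table row {i}: unknown strand {strand!r}")
        tss = tx_start if strand == "+" else tx_end
        prior = kept.setdefault(symbol, [])
        if any(abs(tss - t) < MIN_TSS_SEPARATION for t in prior):
            continue
        prior.append(tss)
        rows.append((symbol, chrom, strand, tss, symbol_quality(symbol)))
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "tss",
                                        "quality"])
    return GeneModel(genes)


def merge_close_peaks(peaks: pd.DataFrame,
                      min_gap: int = PEAK_MERGE_GAP) -> pd.DataFrame:
    """Combine peaks whose boundary gap is below ``min_gap`` bp.

    The merged interval spans all members and carries the sum of member
    scores (total binding evidence is preserved).  Idempotent.
    """
    if len(peaks) == 0:
        return peaks.reset_index(drop=True)
    p = peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    for _, grp in p.groupby("chrom", sort=True):
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        # running max handles contained intervals
        run_end = np.maximum.accumulate(end)
        new_block = np.ones(len(grp), dtype=bool)
        new_block[1:] = start[1:] - run_end[:-1] >= min_gap
        block = np.cumsum(new_block) - 1
        g = grp.assign(_block=block)
        merged = g.groupby("_block").agg(
            chrom=("chrom", "first"), start=("start", "min"),
            end=("end", "max"), score=("score", "sum"))
        out.append(merged)
    res = pd.concat(out, ignore_index=True)
    return res[_PEAK_COLUMNS]


def cap_peaks(peaks: pd.DataFrame, max_n: int = MAX_PEAKS) -> pd.DataFrame:
    """Keep at most ``max_n`` peaks, preferring the highest scores.

    Ties at the cut score resolve by genome order (chrom, start).  Output is
    returned in genome order.
    """
    if len(peaks) <= max_n:
        return peaks.sort_values(["chrom", "start"],
                                 kind="mergesort").reset_index(drop=True)
    top = peaks.sort_values(["score", "chrom", "start"],
                            ascending=[False, True, True],
                            kind="mergesort").head(max_n)
    return top.sort_values(["chrom", "start"],
                           kind="mergesort").reset_index(drop=True)


def load_peaks(path, format: str = "bed", score_column: int | None = None,
               tf_id: str = "", experiment_id: str = "",
               cell_state: str = "unknown") -> PeakSet:
    """Read peak calls, then merge close peaks and cap the count.

    ``format`` is one of ``bed`` (BED3/BED5/BED6; score from column 5 when
    present), ``narrowPeak`` (score from column 7, the signal value, by
    default) or ``tsv`` (header with chrom/start/end and optional score).
    ``score_column`` (1-based) overrides the default score column.  When no
    score is available all scores are set to 1.  Rows with start >= end are
    rejected with a warning.
    """
    if format not in ("bed", "narrowPeak", "tsv"):
        raise ValueError(f"unknown peak format {format!r}")
    header = 0 if format == "tsv" else None
    try:
        df = pd.read_csv(path, sep="\t", header=header, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_PEAK_COLUMNS)
    if format == "tsv" and len(df):
        cols = {c.lower(): c for c in df.columns}
        for need in ("chrom", "start", "end"):
            if need not in cols:
                raise ValueError(f"tsv peak file lacks column {need!r}")
        score = (df[cols["score"]] if "score" in cols and score_column is None
                 else df.iloc[:, score_column - 1] if score_column
                 else 1.0)
        df = pd.DataFrame({"chrom": df[cols["chrom"]],
                           "start": df[cols["start"]],
                           "end": df[cols["end"]], "score": score})
    elif len(df):
        if df.shape[1] < 3:
            raise ValueError("peak file needs at least 3 columns")
        sc = score_column
        if sc is None:
            sc = 7 if format == "narrowPeak" else (5 if df.shape[1] >= 5 else None)
        score = df.iloc[:, sc - 1] if sc and df.shape[1] >= sc else 1.0
        df = pd.DataFrame({"chrom": df.iloc[:, 0], "start": df.iloc[:, 1],
                           "end": df.iloc[:, 2], "score": score})
    else:
        df = pd.DataFrame(columns=_PEAK_COLUMNS)

    if len(df):
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
        df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
        df["score"] = pd.to_numeric(df["score"]).astype(float)
        bad = df["start"] >= df["end"]
        if bad.any():
            logger.warning("%s: rejecting %d peak row(s) with start >= end",
                           path, int(bad.sum()))
            df = df[~bad]
    df = cap_peaks(merge_close_peaks(df.reset_index(drop=True)))
    return PeakSet(tf_id=tf_id, experiment_id=experiment_id, peaks=df,
                   cell_state=cell_state)


@dataclass
class TssProfile:
    """Binned peak-centre offsets from the nearest TSS, with a QC verdict."""

    bin_edges: np.ndarray    # length n_bins + 1, bp offsets (signed)
    counts: np.ndarray       # length n_bins
    qc_pass: bool

    @property
    def mode_offset(self) -> float:
        i = int(np.argmax(self.counts))
        return float(self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0


def tss_peak_profile(peaks: PeakSet, genes: GeneModel,
                     half_window: int = 100_000, bin_size: int = 1_000,
                     qc_mode_window: int = 5_000) -> TssProfile:
    """Histogram of signed peak-centre distances to the nearest TSS.

    The sign is strand-aware (negative = upstream of the gene).  The QC flag
    fails when the modal bin lies outside ±``qc_mode_window`` bp of the TSS —
    for TF ChIP-seq, binding frequency is expected to peak near promoters,
    and a flat or displaced profile indicates a problem (e.g. a genome-build
    mismatch).
    """
    if len(peaks) == 0 or len(genes.genes) == 0:
        raise ValueError("tss_peak_profile needs non-empty peaks and genes")
    edges = np.arange(-half_window, half_window + bin_size, bin_size)
    offsets = []
    gtab = genes.genes
    for chrom, grp in peaks.peaks.groupby("chrom"):
        gt = gtab[gtab["chrom"] == chrom]
        if gt.empty:
            continue
        order = np.argsort(gt["tss"].to_numpy(), kind="stable")
        tss = gt["tss"].to_numpy()[order]
        sign = np.where(gt["strand"].to_numpy()[order] == "+", 1, -1)
        centers = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        j = np.searchsorted(tss, centers)
        j_left = np.clip(j - 1, 0, len(tss) - 1)
        j_right = np.clip(j, 0, len(tss) - 1)
        d_left = np.abs(centers - tss[j_left])
        d_right = np.abs(centers - tss[j_right])
        nearest = np.where(d_left <= d_right, j_left, j_right)
        off = (centers - tss[nearest]) * sign[nearest]
        offsets.append(off[np.abs(off) <= half_window])
    off = np.concatenate(offsets) if offsets else np.array([], dtype=int)
    counts, _ = np.histogram(off, bins=edges)
    mid = (edges[:-1] + edges[1:]) / 2.0
    qc = len(off) > 0 and abs(mid[int(np.argmax(counts))]) <= qc_mode_window
    if not qc:
        logger.warning("TSS profile QC failed for %s/%s: mode at %s bp",
                       peaks.tf_id, peaks.experiment_id,
                       mid[int(np.argmax(counts))] if len(off) else "n/a")
    return TssProfile(bin_edges=edges, counts=counts, qc_pass=bool(qc))
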