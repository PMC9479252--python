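"""Synthetic joint ChIP-seq + TF-induction studies with known ground truth.

Emulates the structure of the real inputs — a gene annotation with TSSs and
symbol qualities, per-experiment peak sets whose high-scoring peaks sit near
planted true target genes over a background of non-functional binding, and a
post-induction expression profile where the planted targets shift by a set
effect size over Gaussian noise — so that every pipeline stage and the EPFP
calibration claim can be tested against planted truth without any download.

Each planted target is assigned a binding geometry: promoter (peak within
500 bp of its TSS), enhancer (distal peak, 2–30 kb), or both (an
enhancer–promoter "loop" target with one peak of each kind).  Background
peaks land uniformly outside promoter windows of planted targets, so the
planted region assignments remain the ground truth.  All randomness flows
from a single seed through named child streams; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation_io import GeneModel, PeakSet, cap_peaks, merge_close_peaks
from .enrichment_page import ExpressionProfile

# letters F and R are excluded so "normal" symbols can never contain the
# weak-symbol substrings (FAM, MIR, MRP, orf)
_SYMBOL_ALPHABET = "ABCDEGHIJKLMNOPQSTUVWXYZ"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic TF induction + ChIP-seq study.

    Defaults describe a desk-scale study: 2,000 genes on one 300-Mb
    chromosome (one gene per 150 kb, matching human gene density), 200
    planted true targets shifting by 1.5 log2 units over a 0.4-SD noise
    background, and two replicate ChIP-seq experiments.
    """

    n_genes: int = 2_000
    chrom_length: int = 300_000_000
    chrom_name: str = "chrS"
    min_tss_spacing: int = 10_000
    n_true_targets: int = 200
    #: 'up', 'down', or 'mixed' (direction per target ~ activator_fraction)
    effect_direction: str = "up"
    activator_fraction: float = 1.0
    effect_size: float = 1.5          # mean |log2fc| of true targets
    noise_sd: float = 0.4             # log2fc SD of all genes
    frac_promoter_binding: float = 0.3
    frac_both_binding: float = 0.1    # enhancer-promoter "loop" targets
    n_background_peaks: int = 150
    true_score_mean: float = 20.0     # exponential mean, true-target peaks
    background_score_mean: float = 5.0
    peak_width: int = 200
    peaks_per_target: int = 1         # peaks per target per region
    enhancer_offset_range: tuple = (2_000, 30_000)
    promoter_offset_max: int = 300
    weak_symbol_fraction: float = 0.05
    n_experiments: int = 2
    tf_id: str = "TFSIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need n_genes >= 10")
        if self.n_true_targets > self.n_genes:
            raise ValueError("more true targets than genes")
        if not (0 <= self.frac_promoter_binding <= 1
                and 0 <= self.frac_both_binding <= 1
                and self.frac_promoter_binding + self.frac_both_binding <= 1):
            raise ValueError("binding fractions must be in [0,1] and sum <= 1")
        if self.effect_direction not in ("up", "down", "mixed"):
            raise ValueError("effect_direction must be up/down/mixed")
        span = (self.n_genes - 1) * self.min_tss_spacing
        if span >= self.chrom_length:
            raise ValueError("chromosome too short for TSS spacing")

    def rng(self, *stream: int) -> np.random.Generator:
        """Child generator for a named stream; deterministic under seed."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=tuple(stream)))


@dataclass
class TruthBundle:
    """A complete simulated study with planted ground truth."""

    config: SimulationConfig
    genes: GeneModel
    peaksets: list[PeakSet]
    profile: ExpressionProfile
    #: per-gene labels: is_target, direction ('', 'up', 'down'),
    #: region ('', 'promoter', 'enhancer', 'both')
    truth: pd.DataFrame

    @property
    def true_targets(self) -> set:
        return set(self.truth.loc[self.truth["is_target"], "gene"])


def _symbols(config: SimulationConfig, rng: np.random.Generator
             ) -> tuple[list[str], np.ndarray]:
    """Unique symbols; a stated fraction are 'weak' (quality-1) names."""
    n = config.n_genes
    n_weak = int(round(config.weak_symbol_fraction * n))
    weak_idx = set(rng.choice(n, size=n_weak, replace=False).tolist())
    base = len(_SYMBOL_ALPHABET)
    symbols = []
    for i in range(n):
        if i in weak_idx:
            # alternate nomenclature-style weak names: digit runs and FAM
            sym = f"LOC9{i:04d}" if i % 2 == 0 else f"FAM{i:04d}"
        else:
            j, letters = i, []
            for _ in range(4):
                letters.append(_SYMBOL_ALPHABET[j % base])
                j //= base
            sym = "G" + "".join(reversed(letters))
        symbols.append(sym)
    weak = np.zeros(n, dtype=bool)
    weak[list(weak_idx)] = True
    return symbols, weak


def simulate_genome(config: SimulationConfig) -> GeneModel:
    """Genes with uniform TSSs (minimum spacing) on one synthetic chromosome."""
    rng = config.rng(1)
    n, spacing = config.n_genes, config.min_tss_spacing
    slack = config.chrom_length - (n - 1) * spacing
    u = np.sort(rng.uniform(0, slack, size=n))
    tss = (u + np.arange(n) * spacing).astype(np.int64)
    strand = rng.choice(["+", "-"], size=n)
    symbols, weak = _symbols(config, rng)
    genes = pd.DataFrame({"symbol": symbols, "chrom": config.chrom_name,
                          "strand": strand, "tss": tss,
                          "quality": np.where(weak, 1, 3)})
    return GeneModel(genes)


def assign_truth(genes: GeneModel, config: SimulationConfig) -> pd.DataFrame:
    """Choose true targets and give each a direction and binding region."""
    rng = config.rng(2)
    syms = genes.genes["symbol"].to_numpy()
    n = len(syms)
    idx = rng.choice(n, size=config.n_true_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[idx] = True
    direction = np.array([""] * n, dtype=object)
    if config.effect_direction == "mixed":
        up = rng.random(config.n_true_targets) < config.activator_fraction
        direction[idx] = np.where(up, "up", "down")
    else:
        direction[idx] = config.effect_direction
    region = np.array([""] * n, dtype=object)
    u = rng.random(config.n_true_targets)
    reg = np.where(u < config.frac_promoter_binding, "promoter",
                   np.where(u < config.frac_promoter_binding
                            + config.frac_both_binding, "both", "enhancer"))
    region[idx] = reg
    return pd.DataFrame({"gene": syms, "is_target": is_target,
                         "direction": direction, "region": region})


def simulate_chipseq(genes: GeneModel, truth: pd.DataFrame,
                     config: SimulationConfig,
                     experiment_index: int = 0) -> PeakSet:
    """One replicate peak set: true-target peaks plus uniform background.

    Promoter-assigned targets get peaks centred within ±300 bp of their
    TSS, enhancer-assigned targets within 2–30 kb, loop ('both') targets one
    of each.  True-peak scores are exponential with a higher mean than
    background scores.  Background peaks avoid ±1.5 kb of planted-target
    TSSs so planted region labels stay truthful.  Replicates redraw
    positions and scores from experiment-specific streams.
    """
    rng = config.rng(3, experiment_index)
    gtab = genes.genes.set_index("symbol")
    half_w = config.peak_width // 2
    lo_off, hi_off = config.enhancer_offset_range
    centers, scores = [], []
    t = truth[truth["is_target"]]
    for gene, region in zip(t["gene"], t["region"]):
        tss = int(gtab.loc[gene, "tss"])
        kinds = {"promoter": ["promoter"], "enhancer": ["enhancer"],
                 "both": ["promoter", "enhancer"]}[region]
        for kind in kinds:
            for _ in range(config.peaks_per_target):
                if kind == "promoter":
                    off = int(rng.integers(-config.promoter_offset_max,
                                           config.promoter_offset_max + 1))
                else:
                    off = int(rng.integers(lo_off, hi_off + 1))
                    if rng.random() < 0.5:
                        off = -off
                centers.append(tss + off)
                scores.append(rng.exponential(
                    config.true_score_mean / config.peaks_per_target))
    # background binding, kept clear of planted-target promoter windows
    target_tss = gtab.loc[t["gene"], "tss"].to_numpy()
    n_bg = config.n_background_peaks
    bg = np.empty(0, dtype=np.int64)
    while len(bg) < n_bg:
        draw = rng.integers(half_w, config.chrom_length - half_w,
                            size=2 * (n_bg - len(bg)) + 8)
        if len(target_tss):
            near = np.min(np.abs(draw[:, None] - target_tss[None, :]), axis=1)
            draw = draw[near > 1_500]
        bg = np.concatenate([bg, draw])
    centers.extend(bg[:n_bg].tolist())
    scores.extend(rng.exponential(config.background_score_mean,
                                  size=n_bg).tolist())
    c = np.clip(np.asarray(centers, dtype=np.int64), half_w,
                config.chrom_length - half_w)
    peaks = pd.DataFrame({"chrom": config.chrom_name, "start": c - half_w,
                          "end": c + half_w,
                          "score": np.asarray(scores, dtype=float)})
    peaks = cap_peaks(merge_close_peaks(peaks))
    return PeakSet(tf_id=config.tf_id,
                   experiment_id=f"exp{experiment_index}",
                   peaks=peaks, cell_state="pluripotent")


def simulate_expression(genes: GeneModel, truth: pd.DataFrame,
                        config: SimulationConfig) -> ExpressionProfile:
    """Log2 fold changes: noise for non-targets, shifted for true targets.

    ``responder2x`` is granted deterministically at |linear fold| >= 2
    (the differential-expression significance machinery is out of scope).
    """
    rng = config.rng(4)
    n = len(truth)
    x = rng.normal(0.0, config.noise_sd, size=n)
    shift = np.where(truth["direction"].to_numpy() == "up",
                     config.effect_size,
                     np.where(truth["direction"].to_numpy() == "down",
                              -config.effect_size, 0.0))
    x = x + shift
    table = pd.DataFrame({"log2fc": x, "responder2x": np.abs(x) >= 1.0},
                         index=pd.Index(truth["gene"], name="gene"))
    return ExpressionProfile(table)


def simulate_study(config: SimulationConfig,
                   outdir: str | Path | None = None) -> TruthBundle:
    """Compose genome, truth, replicate peak sets and expression profile.

    With ``outdir`` the bundle is also written as plain-text files (gene
    table TSV, per-experiment BED5, profile TSV, truth TSV, config YAML)
    in the formats the I/O layer reads back.
    """
    genes = simulate_genome(config)
    truth = assign_truth(genes, config)
    peaksets = [simulate_chipseq(genes, truth, config, i)
                for i in range(config.n_experiments)]
    profile = simulate_expression(genes, truth, config)
    bundle = TruthBundle(config=config, genes=genes, peaksets=peaksets,
                         profile=profile, truth=truth)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = bundle.genes.genes
    pd.DataFrame({"symbol": g["symbol"], "chrom": g["chrom"],
                  "strand": g["strand"],
                  "txStart": np.where(g["strand"] == "+", g["tss"], 0),
                  "txEnd": np.where(g["strand"] == "-", g["tss"], 0)}
                 ).to_csv(out / "genes.tsv", sep="\t", index=False)
    for ps in bundle.peaksets:
        bed = ps.peaks.assign(name=[f"peak{i}" for i in range(len(ps.peaks))])
        bed[["chrom", "start", "end", "name", "score"]].to_csv(
            out / f"peaks_{ps.experiment_id}.bed", sep="\t",
            index=False, header=False)
    bundle.profile.to_tsv(out / "profile.tsv")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)


def evaluate_calls(entries: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score atlas entries against planted truth.

    Returns n_calls, n_false, realized false-discovery proportion (NaN when
    nothing was called) and sensitivity (called true targets, in their
    planted direction, over all planted targets).
    """
    true_dir = dict(zip(truth.loc[truth["is_target"], "gene"],
                        truth.loc[truth["is_target"], "direction"]))
    n_calls = len(entries)
    correct = sum(true_dir.get(g) == d
                  for g, d in zip(entries["gene"], entries["direction"]))
    n_false = n_calls - correct
    return {"n_calls": n_calls, "n_false": n_false,
            "fdp": n_false / n_calls if n_calls else float("nan"),
            "sensitivity": correct / len(true_dir) if true_dir else float("nan")}
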