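"""TF-level characterisation from the assembled atlas.

Classifies each TF by the balance of up- vs downregulated targets
(q = n_up / (n_up + n_down)): strong activator at q >= 0.8, strong repressor
at q <= 0.2, moderate activator/repressor in between, unclassified below 10
targets.  Also quantifies promoter-only / enhancer-only / both binding among
dominant-direction targets, the fraction of induction responders explained
as regulated targets, and a 1-df chi-square comparison of target counts
between scoring methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_page import ExpressionProfile

#: below this many regulated targets a TF is left unclassified
MIN_TARGETS = 10

ACTIVITY_CLASSES = ("strong_activator", "moderate_activator",
                    "moderate_repressor", "strong_repressor", "unclassified")


def activity_class(n_up: int, n_down: int,
                   min_targets: int = MIN_TARGETS) -> str:
    """Activation/repression class from up/down regulated-target counts."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total < min_targets:
        return "unclassified"
    q = n_up / total
    if q >= 0.8:
        return "strong_activator"
    if q <= 0.2:
        return "strong_repressor"
    return "moderate_activator" if q >= 0.5 else "moderate_repressor"


def dominant_direction(n_up: int, n_down: int) -> str:
    """'up' for activators (q >= 0.5), 'down' for repressors."""
    total = n_up + n_down
    return "up" if total == 0 or n_up / total >= 0.5 else "down"


def region_usage(entries: pd.DataFrame, direction: str
                 ) -> tuple[float, float, float]:
    """(frac_promoter_only, frac_enhancer_only, frac_both) among
    dominant-direction atlas entries."""
    sub = entries[entries["direction"] == direction]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no atlas entries in direction {direction!r}")
    counts = sub["region_category"].value_counts()
    return (counts.get("promoter_only", 0) / n,
            counts.get("enhancer_only", 0) / n,
            counts.get("both", 0) / n)


def responder_fraction(entries: pd.DataFrame, profile: ExpressionProfile,
                       direction: str) -> float:
    """Share of direction-consistent induction responders that are
    regulated targets; NaN when there are no responders."""
    t = profile.table
    sign_ok = t["log2fc"] > 0 if direction == "up" else t["log2fc"] < 0
    responders = set(t.index[t["responder2x"] & sign_ok])
    if not responders:
        return float("nan")
    targets = set(entries.loc[entries["direction"] == direction, "gene"])
    return len(targets & responders) / len(responders)


def chi_square_method_compare(count_a: int, count_b: int
                              ) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of two counts vs equal expectation."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a + count_b == 0:
        raise ValueError("both counts are zero")
    chi2, p = stats.chisquare([count_a, count_b])
    return float(chi2), float(p)


@dataclass
class TFSummary:
    """Per-TF characterisation row."""

    tf_id: str
    n_up: int
    n_down: int
    q: float
    activity_class: str
    dominant_direction: str
    frac_promoter_only: float
    frac_enhancer_only: float
    frac_both: float
    responder_fraction: float

    @property
    def frac_enhancer_any(self) -> float:
        """Targets with any enhancer support (enhancer-only or both)."""
        return self.frac_enhancer_only + self.frac_both


def summarize_tf(entries: pd.DataFrame, profile: ExpressionProfile,
                 tf_id: str, min_targets: int = MIN_TARGETS) -> TFSummary:
    """Build the TF summary from its atlas entries and induction profile."""
    n_up = int((entries["direction"] == "up").sum())
    n_down = int((entries["direction"] == "down").sum())
    total = n_up + n_down
    q = n_up / total if total else float("nan")
    dom = dominant_direction(n_up, n_down)
    if total:
        fp, fe, fb = region_usage(entries, dom)
        rf = responder_fraction(entries, profile, dom)
    else:
        fp = fe = fb = rf = float("nan")
    return TFSummary(tf_id=tf_id, n_up=n_up, n_down=n_down, q=q,
                     activity_class=activity_class(n_up, n_down, min_targets),
                     dominant_direction=dom, frac_promoter_only=fp,
                     frac_enhancer_only=fe, frac_both=fb,
                     responder_fraction=rf)


def summary_table(summaries: list[TFSummary]) -> pd.DataFrame:
    rows = [{**vars(s), "frac_enhancer_any": s.frac_enhancer_any}
            for s in summaries]
    return pd.DataFrame(rows)
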