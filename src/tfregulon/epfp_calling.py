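"""Expected-proportion-of-false-positives (EPFP) calling of regulated targets.

Once a target set shows significant direction-specific enrichment (PAGE
p <= 0.05), every target gene whose expression changed at least 1.5-fold in
that direction becomes a candidate regulated target.  For a candidate g:

    EPFP(g) = p_c / p_r(g)

where p_c is the proportion of targets among "control" genes presumed
unaffected by the induction (absolute change below 1.2-fold), and p_r(g) is
the proportion of targets among all genes that responded in the same
direction at least as strongly as g.  Raw EPFP values are then adjusted to
increase monotonically with decreasing expression change (a running maximum
from the strongest responder down), and genes with adjusted EPFP <= 0.3 are
called regulated targets.

This is an empirical FDR control: if targets were scattered at random, the
target frequency among strong responders would match the frequency among
unchanged genes and EPFP would sit near 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment_page import (ExpressionProfile, PAGE_QUARTER,
                              page_with_score_sweep)
from .target_scoring import TargetSet

logger = logging.getLogger(__name__)

#: minimum direction-consistent linear fold change for a candidate call
FC_MIN = 1.5
#: genes below this absolute linear fold change are the unaffected controls
CONTROL_FC = 1.2
#: adjusted-EPFP acceptance level for regulated-target calls
EPFP_MAX = 0.3

CALL_COLUMNS = ["gene", "tf", "experiment", "direction", "region",
                "fold_change", "epfp_raw", "epfp_adjusted", "called"]


def _direction_magnitude(log2fc: np.ndarray, direction: str) -> np.ndarray:
    """Direction-consistent log2 response; positive = responded that way."""
    return log2fc if direction == "up" else -log2fc


def epfp_per_gene(profile: ExpressionProfile, target_genes, direction: str,
                  fc_min: float = FC_MIN,
                  control_fc: float = CONTROL_FC) -> pd.DataFrame:
    """Raw per-gene EPFP for candidate regulated targets.

    Returns a DataFrame sorted by decreasing response magnitude with columns
    ``gene``, ``fold_change`` (direction-consistent linear fold) and
    ``epfp_raw``.  Controls are two-sided (|linear fold| < ``control_fc``);
    the responder set R(g) uses a weak inequality, so a candidate always
    belongs to its own R(g) and p_r(g) > 0.
    """
    targets = set(target_genes)
    t = profile.table
    x = t["log2fc"].to_numpy(dtype=float)
    gene = t.index.to_numpy()
    is_target = np.asarray(t.index.isin(list(targets)))

    controls = np.abs(x) < np.log2(control_fc)
    n_c = int(controls.sum())
    if n_c == 0:
        raise ValueError("degenerate profile: no unaffected control genes")
    p_c = float((controls & is_target).sum()) / n_c

    mag = _direction_magnitude(x, direction)
    # strongest responders first; ties broken by symbol for determinism
    order = np.lexsort((gene, -mag))
    mag_s, gene_s, targ_s = mag[order], gene[order], is_target[order]
    cum_targets = np.cumsum(targ_s)

    cand = targ_s & (mag_s >= np.log2(fc_min))
    if not cand.any():
        return pd.DataFrame(columns=["gene", "fold_change", "epfp_raw"])
    # R(g): all genes with magnitude >= mag(g), ties included
    r_size = np.searchsorted(-mag_s, -mag_s[cand], side="right")
    p_r = cum_targets[r_size - 1] / r_size
    epfp_raw = p_c / p_r
    return pd.DataFrame({"gene": gene_s[cand],
                         "fold_change": 2.0 ** mag_s[cand],
                         "epfp_raw": epfp_raw})


def monotonic_adjust(epfp_raw: np.ndarray) -> np.ndarray:
    """Running maximum over candidates ordered strongest-responder first.

    Makes EPFP non-decreasing with decreasing expression change, so the
    called set is a contiguous head of the response ranking.
    """
    return np.maximum.accumulate(np.asarray(epfp_raw, dtype=float))


def call_regulated_targets(profile: ExpressionProfile, target_set: TargetSet,
                           direction: str, epfp_max: float = EPFP_MAX,
                           fc_min: float = FC_MIN,
                           control_fc: float = CONTROL_FC,
                           quarter: float = PAGE_QUARTER,
                           subset_moments: bool = True) -> pd.DataFrame:
    """Full per-experiment calling for one target set and direction.

    Runs the score-threshold PAGE sweep as the significance gate; when the
    gate fails, returns an empty table (attrs['reason'] = 'not significant').
    Otherwise the targets retained at the best threshold are EPFP-scored,
    monotonically adjusted, and called at ``epfp_adjusted <= epfp_max``.
    The returned table keeps all candidates with a boolean ``called``
    column; ``attrs['enrichment']`` holds the gate result.
    """
    empty = pd.DataFrame(columns=CALL_COLUMNS)
    enr = page_with_score_sweep(profile, target_set, direction,
                                quarter=quarter,
                                subset_moments=subset_moments)
    empty.attrs["enrichment"] = enr
    if not enr.significant:
        empty.attrs["reason"] = "not significant"
        logger.info("gate failed for %s/%s %s %s (z=%.2f p=%.3g)",
                    target_set.tf_id, target_set.experiment_id,
                    target_set.region_mode, direction, enr.z, enr.p)
        return empty
    retained = target_set.scores.index[
        target_set.scores.to_numpy() >= enr.best_threshold]
    cand = epfp_per_gene(profile, retained, direction,
                         fc_min=fc_min, control_fc=control_fc)
    if cand.empty:
        empty.attrs["reason"] = "no candidates"
        return empty
    cand["epfp_adjusted"] = monotonic_adjust(cand["epfp_raw"].to_numpy())
    cand["called"] = cand["epfp_adjusted"] <= epfp_max
    cand.insert(1, "tf", target_set.tf_id)
    cand.insert(2, "experiment", target_set.experiment_id)
    cand.insert(3, "direction", direction)
    cand.insert(4, "region", target_set.region_mode)
    cand = cand[CALL_COLUMNS].reset_index(drop=True)
    cand.attrs["enrichment"] = enr
    logger.debug("EPFP trace %s/%s %s %s:\n%s", target_set.tf_id,
                 target_set.experiment_id, target_set.region_mode, direction,
                 cand.to_string())
    return cand
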