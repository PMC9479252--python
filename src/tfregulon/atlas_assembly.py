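"""Combining regulated-target calls across ChIP-seq experiments.

Per-experiment calls for one TF are merged per (gene, direction): the lowest
adjusted EPFP across supporting experiments is kept, support counts distinct
experiments (promoter and enhancer calls from the same experiment count
once), and the region category records whether supporting binding was in the
promoter only, the enhancer only, or both.  Entries supported by a single
experiment are dropped when the TF has two or more experiments that yielded
calls — except when only one experiment was successful, in which case its
calls are kept.  Entries supported only by surrogate (indirect) ChIP-seq
experiments are flagged.
"""

from __future__ import annotations

import pandas as pd

ATLAS_COLUMNS = ["tf", "gene", "direction", "min_epfp", "support",
                 "region_category", "indirect_only"]


def _region_category(regions) -> str:
    r = set(regions)
    if "promoter" in r and "enhancer" in r:
        return "both"
    return "promoter_only" if "promoter" in r else "enhancer_only"


def combine_calls(calls: pd.DataFrame,
                  experiment_meta: dict[str, str] | None = None
                  ) -> pd.DataFrame:
    """Merge called rows (``called == True``) for one TF into atlas entries.

    ``experiment_meta`` maps experiment id -> 'direct' | 'indirect';
    unlisted experiments count as direct.  Returns one row per
    (gene, direction) with columns ``tf, gene, direction, min_epfp,
    support, region_category, indirect_only``, sorted by (direction, gene)
    so the result is independent of input order.
    """
    meta = experiment_meta or {}
    if len(calls) == 0:
        return pd.DataFrame(columns=ATLAS_COLUMNS)
    c = calls[calls["called"]] if "called" in calls.columns else calls
    if len(c) == 0:
        return pd.DataFrame(columns=ATLAS_COLUMNS)
    if c["tf"].nunique() > 1:
        raise ValueError("combine_calls expects calls for a single TF")

    def _indirect_only(exps) -> bool:
        return all(meta.get(e, "direct") == "indirect" for e in exps)

    g = c.groupby(["gene", "direction"], sort=True)
    out = g.agg(tf=("tf", "first"),
                min_epfp=("epfp_adjusted", "min"),
                support=("experiment", "nunique"),
                region_category=("region", _region_category),
                indirect_only=("experiment", _indirect_only)).reset_index()
    out = out[ATLAS_COLUMNS].sort_values(["direction", "gene"],
                                         kind="mergesort")
    return out.reset_index(drop=True)


def apply_support_filter(entries: pd.DataFrame,
                         n_successful_experiments: int) -> pd.DataFrame:
    """Drop single-experiment entries unless only one experiment succeeded.

    ``n_successful_experiments`` is the number of ChIP-seq experiments that
    yielded at least one call for this TF.
    """
    if n_successful_experiments >= 2:
        entries = entries[entries["support"] >= 2]
    return entries.reset_index(drop=True)
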