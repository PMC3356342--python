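"""Upper-quartile expression normalization, high-expression-gene (HEG)
calling, pathway-level HEG fractions, and the two kinds of fold change
used in the downstream reports.

Normalization: the 75th percentile of each sample's sense counts is
computed after excluding genes whose counts are zero in every sample
(linear interpolation between order statistics — the numpy/pandas default
percentile convention, fixed here because the choice is material at small
gene numbers).  Every cell, sense and antisense alike, is divided by its
sample's quartile, so both strand classes stay on one comparable scale.

A gene is a HEG in a sample when its normalized sense value is strictly
greater than 10 (roughly the top 2% of genes under a log-normal
expression distribution).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    NormalizedCounts,
    PipelineConfig,
    PipelineError,
    StrandedCounts,
)


def uq_normalize(counts: StrandedCounts) -> NormalizedCounts:
    """Divide every count by its sample's upper quartile.

    The quartile is computed per sample over the sense counts of genes
    that are nonzero in at least one sample; all-zero genes are excluded
    from the quartile but still reported (their normalized value is 0).
    A zero quartile is a hard error naming the offending sample.
    """
    sense = counts.sense
    if sense.shape[1] < 1:
        raise PipelineError("need at least one sample")
    retained = sense.index[(sense != 0).any(axis=1)]
    if not len(retained):
        raise PipelineError("no gene has a nonzero count in any sample")
    uq = sense.loc[retained].quantile(0.75)
    zero = uq[uq <= 0]
    if len(zero):
        raise PipelineError(
            f"upper quartile is zero in sample(s) {list(zero.index)}"
        )
    return NormalizedCounts(
        sense=sense / uq,
        antisense=counts.antisense / uq,
        upper_quartile=uq,
    )


def call_heg(norm: NormalizedCounts,
             config: PipelineConfig) -> dict[str, set[str]]:
    """Per-sample set of genes with normalized sense value strictly > 10."""
    out = {}
    for sample in norm.sense.columns:
        col = norm.sense[sample]
        out[sample] = set(col.index[col > config.heg_uq_threshold])
    return out


def pathway_heg_fraction(heg_sets: Mapping[str, set[str]],
                         pathway_map: Mapping[str, set[str]],
                         config: PipelineConfig) -> pd.DataFrame:
    """Fraction of each pathway's members that are HEGs, per sample, with
    a ``reported`` flag for fractions strictly above the 10% cut.  Empty
    pathways are skipped with a warning."""
    rows = []
    for pw in sorted(pathway_map):
        members = pathway_map[pw]
        if not members:
            warnings.warn(f"pathway {pw}: no members, skipped")
            continue
        for sample, hegs in sorted(heg_sets.items()):
            frac = len(members & hegs) / len(members)
            rows.append({
                "pathway_id": pw,
                "sample": sample,
                "n_members": len(members),
                "n_heg": len(members & hegs),
                "fraction": frac,
                "reported": frac > config.pathway_heg_fraction,
            })
    return pd.DataFrame(rows)


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio with explicit degenerate flags: inf when only the
    denominator is zero, nan when both are zero."""
    if denominator == 0:
        return float("nan") if numerator == 0 else float("inf")
    return numerator / denominator


def fold_changes(norm: NormalizedCounts, counts: StrandedCounts,
                 pairs: Sequence[tuple[str, str]] = (("stationary", "log"),),
                 ) -> pd.DataFrame:
    """Ratio table mirroring the two ways expression ratios are used.

    Cross-phase comparisons (each (numerator, denominator) sample pair)
    are computed on *normalized* values, separately for sense and
    antisense; the within-phase antisense:sense comparison is computed on
    *raw* tag counts.
    """
    rows = []
    for num, den in pairs:
        for klass, mat in (("sense", norm.sense), ("antisense", norm.antisense)):
            for gid in mat.index:
                rows.append({
                    "gene_id": gid,
                    "comparison": f"{num}_vs_{den}",
                    "strand_class": klass,
                    "ratio": fold_change(mat.loc[gid, num], mat.loc[gid, den]),
                })
    for sample in counts.sense.columns:
        for gid in counts.sense.index:
            rows.append({
                "gene_id": gid,
                "comparison": f"antisense_vs_sense_{sample}",
                "strand_class": "raw",
                "ratio": fold_change(counts.antisense.loc[gid, sample],
                                     counts.sense.loc[gid, sample]),
            })
    return pd.DataFrame(rows)
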