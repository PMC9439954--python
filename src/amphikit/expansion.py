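"""Depth-ratio detection of lineage-specific gene-family expansion.

Per-site read depths of a focal group and an outgroup are each normalized so
a sample's genome-wide median maps to 1.0 per baseline genome; a site
qualifies when the minimum normalized depth over focal samples exceeds twice
the maximum over outgroup samples, and a gene is called expanded when more
than 60% of its assayed CDS sites qualify.  Calls are invariant to
per-sample scaling of the raw depths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_FOCAL = "focal"
GROUP_OUTGROUP = "outgroup"

RATIO_CUT = 2.0     # strict: focal min must exceed twice the outgroup max
FRACTION_CUT = 0.6  # strict: more than 60% of assayed CDS sites


@dataclass
class DepthMatrix:
    """Normalized per-site depths (rows: (chrom, pos) 0-based; cols: samples)."""

    values: pd.DataFrame
    groups: dict[str, str]
    scale: dict[str, float]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def normalize_depths(
    raw: pd.DataFrame,
    groups: Mapping[str, str],
) -> DepthMatrix:
    """Scale each sample so its genome-wide median depth maps to 1.0.

    ``raw`` is a sites x samples table indexed by (chrom, pos); ``groups``
    assigns each sample to "focal" or "outgroup".  The scaling constants are
    retained on the result, and a zero median is an error (the sample
    carries no usable depth signal).
    """
    unknown = set(groups.values()) - {GROUP_FOCAL, GROUP_OUTGROUP}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    missing = set(raw.columns) - set(groups)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)}")
    scale = {}
    for s in raw.columns:
        med = float(raw[s].median())
        if not med > 0:
            raise ValueError(f"sample {s!r} has zero median depth")
        scale[s] = med
    values = raw / pd.Series(scale)
    if (values.to_numpy() < 0).any():
        raise ValueError("negative depths in input")
    logger.info("normalize_depths scales: %s", scale)
    return DepthMatrix(values=values, groups=dict(groups), scale=scale)


def qualifying_sites(matrix: DepthMatrix) -> pd.Series:
    """Boolean site mask: min(focal) > 2 x max(outgroup), normalized scale.

    Sites with missing data in any sample are excluded (False) and counted
    in ``mask.attrs["n_missing"]``.
    """
    focal = matrix.samples_in(GROUP_FOCAL)
    outgroup = matrix.samples_in(GROUP_OUTGROUP)
    if not focal or not outgroup:
        raise ValueError("need at least one focal and one outgroup sample")
    v = matrix.values
    complete = v.notna().all(axis=1)
    focal_min = v[focal].min(axis=1)
    out_max = v[outgroup].max(axis=1)
    mask = complete & (focal_min > RATIO_CUT * out_max)
    mask.attrs["n_missing"] = int((~complete).sum())
    return mask


@dataclass(frozen=True)
class ExpansionCall:
    gene: str
    chrom: str
    n_assayed_sites: int
    qualifying_fraction: float
    mean_depth_ratio: float
    expanded: bool
    copy_number: int
    copy_number_unrounded: float
    status: str = "assayed"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def call_expanded_genes(
    mask: pd.Series,
    genes: Sequence,
    matrix: DepthMatrix,
    baseline_copies: int = 1,
) -> list[ExpansionCall]:
    """Per-gene expansion calls from the qualifying-site mask.

    ``genes`` are intervals with chrom/start/end/name attributes (0-based
    half-open) on the matrix coordinate system.  The qualifying fraction is
    over assayed (complete-data) CDS sites; a gene is expanded iff the
    fraction strictly exceeds 0.6.  The copy-number estimate is the mean
    focal normalized depth over the CDS times ``baseline_copies``, rounded
    half-up (the unrounded value is retained).
    """
    focal = matrix.samples_in(GROUP_FOCAL)
    outgroup = matrix.samples_in(GROUP_OUTGROUP)
    v = matrix.values
    complete = v.notna().all(axis=1)
    chrom_level = v.index.get_level_values(0)
    pos_level = v.index.get_level_values(1).to_numpy()

    calls = []
    for g in genes:
        sel = ((chrom_level == g.chrom) & (pos_level >= g.start)
               & (pos_level < g.end))
        assayed = sel & complete.to_numpy()
        n = int(assayed.sum())
        if n == 0:
            calls.append(ExpansionCall(g.name, g.chrom, 0, float("nan"),
                                       float("nan"), False, 0, float("nan"),
                                       status="unassayed"))
            continue
        frac = float(mask.to_numpy()[assayed].mean())
        focal_mean = float(v.loc[assayed, focal].mean(axis=1).mean())
        out_mean = float(v.loc[assayed, outgroup].mean(axis=1).mean())
        ratio = focal_mean / out_mean if out_mean > 0 else float("inf")
        unrounded = focal_mean * baseline_copies
        calls.append(ExpansionCall(
            gene=g.name, chrom=g.chrom, n_assayed_sites=n,
            qualifying_fraction=frac, mean_depth_ratio=ratio,
            expanded=frac > FRACTION_CUT,
            copy_number=_round_half_up(unrounded),
            copy_number_unrounded=unrounded))
    return calls


def heatmap_matrix(matrix: DepthMatrix, genes: Sequence) -> pd.DataFrame:
    """Genes x samples mean normalized depth, for heat-map style export."""
    v = matrix.values
    chrom_level = v.index.get_level_values(0)
    pos_level = v.index.get_level_values(1).to_numpy()
    rows = {}
    for g in genes:
        sel = ((chrom_level == g.chrom) & (pos_level >= g.start)
               & (pos_level < g.end))
        rows[g.name] = v.loc[sel].mean(axis=0)
    return pd.DataFrame(rows).T
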