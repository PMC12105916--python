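"""Composite genetic value (G-value) per management unit.

The raw G-value of a unit is a weighted sum of its genetic metrics,

    G_raw = Σ_i w_i · v_i ,

and the final G-value divides by the per-species maximum,

    G_final = G_raw / max over the species' units of G_raw ,

so values lie in [0, 1] and the best unit of each species scores exactly 1.
Because the metrics live on very different scales (allele proportions vs.
genotype distances), each variable is by default first divided by its maximum
across the species' units, making equal weights scale-free; the strict
unnormalized sum is available with ``normalize_variables=False``.  G-values
of species co-occurring in one unit add to give the multispecies value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["compute_gvalue", "multispecies_gvalue"]

METRIC_COLUMNS = ("allele_prop", "heterozygosity", "dist_between", "dist_within",
                  "n_members")


def compute_gvalue(metrics: pd.DataFrame, weights: dict[str, float],
                   normalize_variables: bool = True) -> pd.DataFrame:
    """Raw and final G-value per (unit, species).

    ``metrics`` is indexed by unit_id with a ``species_id`` column and one
    column per metric named in ``weights``.  Undefined metrics (NaN, e.g.
    within-distance of a single-member unit) contribute 0 and are recorded
    in the ``undefined_metrics`` column.
    """
    if not weights or all(w == 0 for w in weights.values()):
        raise ValueError("weights must include at least one positive entry")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    missing = [m for m in weights if m not in metrics.columns]
    if missing:
        raise ValueError(f"metric columns absent from table: {missing}")
    if "species_id" not in metrics.columns:
        raise ValueError("metrics table requires a species_id column")

    out = []
    for sp, sub in metrics.groupby("species_id", sort=True):
        if sub.empty:
            raise ValueError(f"species {sp!r} has zero units")
        vals = sub[list(weights)].astype(float).copy()
        undef = vals.isna()
        vals = vals.fillna(0.0)
        if normalize_variables:
            mx = vals.abs().max(axis=0)
            for c in vals.columns:
                if mx[c] > 0:
                    vals[c] = vals[c] / mx[c]
        w = np.array([weights[c] for c in vals.columns], dtype=float)
        g_raw = vals.to_numpy() @ w
        g_max = g_raw.max() if len(g_raw) else 0.0
        if g_max <= 0:
            logger.warning("species %s: all-zero raw G-values; G_final set to 0", sp)
            g_final = np.zeros_like(g_raw)
        else:
            g_final = g_raw / g_max
        res = pd.DataFrame({
            "species_id": sp,
            "g_raw": g_raw,
            "g_final": g_final,
            "undefined_metrics": [",".join(r[r].index) for _, r in undef.iterrows()],
        }, index=sub.index)
        out.append(res)
    table = pd.concat(out)
    table.index.name = "unit_id"
    return table


def multispecies_gvalue(gvt: pd.DataFrame) -> pd.Series:
    """Per-unit sum of final G-values over the species present in the unit."""
    s = gvt.groupby(level=0)["g_final"].sum()
    s.name = "g_multispecies"
    return s
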