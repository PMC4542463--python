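"""Population-level descriptive summaries of per-site results."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: default tonotopic band edges (Hz): <500, 500–1000, >1000
DEFAULT_BAND_EDGES = (500.0, 1000.0)


def _band_label(f: float, edges: Tuple[float, float]) -> str:
    lo, hi = edges
    if f < lo:
        return f"<{lo:g}"
    if f <= hi:
        return f"{lo:g}-{hi:g}"
    return f">{hi:g}"


def summarize_population(results: pd.DataFrame,
                         band_edges: Tuple[float, float] = DEFAULT_BAND_EDGES) -> dict:
    """Descriptive statistics of best ITDs, CDs, CPs and slope midpoints.

    ``results`` is the per-site table (columns ``frequency``, ``best_itd``
    and optionally ``cd``, ``cp``, ``slope_midpoint``, ``slope_direction``).
    Best-ITD statistics are reported per tonotopic band; lateral counts
    split sites into ipsilateral-leading (< 0), contralateral-leading (> 0)
    and exactly zero.
    """
    if results.empty:
        raise ValueError("empty results table")
    out: dict = {"n_sites": int(len(results)), "bands": {}}
    bands = results["frequency"].map(lambda f: _band_label(f, band_edges))
    for label, grp in results.groupby(bands, sort=False):
        itd = grp["best_itd"].dropna().to_numpy()
        entry = {
            "n": int(len(grp)),
            "n_ipsi": int(np.sum(itd < 0)),
            "n_contra": int(np.sum(itd > 0)),
            "n_zero": int(np.sum(itd == 0)),
        }
        if itd.size:
            q1, med, q3 = np.percentile(itd, [25, 50, 75])
            entry.update(median_best_itd=float(med),
                         iqr_best_itd=[float(q1), float(q3)])
        out["bands"][label] = entry
    for col in ("cd", "cp"):
        if col in results:
            vals = results[col].dropna().to_numpy()
            if vals.size:
                out[f"{col}_median"] = float(np.median(vals))
                out[f"{col}_range"] = [float(vals.min()), float(vals.max())]
                out[f"{col}_n"] = int(vals.size)
    if "slope_midpoint" in results:
        sm = results.dropna(subset=["slope_midpoint"])
        out["slope_midpoints"] = sm[
            [c for c in ("frequency", "slope_midpoint", "slope_direction")
             if c in sm]].to_dict("records")
    return out


def two_sample_ks(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Generic two-sample Kolmogorov–Smirnov comparison (statistic, p-value).

    Exposed for comparing best-ITD distributions between synthetic cohorts
    or recording types; purely descriptive here.
    """
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
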