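"""Univariate feature-importance measures for hotspot vs non-hotspot residues.

Two complementary measures:

* the F score, |mean_h - mean_n| / (sd_h + sd_n): how far apart the class
  means are relative to the spread of the two class distributions (this is
  a univariate separation measure, distinct from the F1 classification
  score);
* the Jensen-Shannon divergence between the two class histograms, which is
  sensitive to any distributional difference, not just a mean shift.
  Estimated on shared-range histograms (20 bins by default) with base-2
  logarithms, so it lies in [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .structure import FEATURE_GROUPS


def f_score(values_h, values_n) -> float:
    """|mean difference| over the sum of sample standard deviations.

    Returns NaN (with a warning) when both classes are constant, since the
    measure is undefined for a feature with zero spread.
    """
    h = np.asarray(values_h, dtype=float)
    n = np.asarray(values_n, dtype=float)
    if h.size == 0 or n.size == 0:
        raise ValueError("both classes must be non-empty")
    sd = h.std(ddof=1) + n.std(ddof=1)
    if sd == 0:
        warnings.warn("constant feature in both classes; F score undefined")
        return float("nan")
    return float(abs(h.mean() - n.mean()) / sd)


def jsd(values_h, values_n, bins: int = 20) -> float:
    """Base-2 Jensen-Shannon divergence between shared-range histograms."""
    h = np.asarray(values_h, dtype=float)
    n = np.asarray(values_n, dtype=float)
    if h.size == 0 or n.size == 0:
        raise ValueError("both classes must be non-empty")
    lo = min(h.min(), n.min())
    hi = max(h.max(), n.max())
    if lo == hi:
        warnings.warn("degenerate value range; JSD set to 0")
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(h, bins=edges)
    q, _ = np.histogram(n, bins=edges)
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def rank_features(matrix: pd.DataFrame, bins: int = 20) -> pd.DataFrame:
    """Per-feature importance table, sorted by descending F score.

    ``matrix`` is a residue x feature DataFrame with a binary ``label``
    column; both classes must be present. Columns outside the canonical
    registry keep group 'other'.
    """
    labels = matrix["label"].to_numpy(dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; importance undefined")
    features = [c for c in matrix.columns if c != "label"]
    hmask = labels == 1
    rows = []
    for feat in features:
        vh = matrix.loc[hmask, feat].to_numpy(dtype=float)
        vn = matrix.loc[~hmask, feat].to_numpy(dtype=float)
        rows.append({
            "feature": feat,
            "group": FEATURE_GROUPS.get(feat, "other"),
            "mean_hotspot": vh.mean(),
            "mean_non_hotspot": vn.mean(),
            "sd_hotspot": vh.std(ddof=1),
            "sd_non_hotspot": vn.std(ddof=1),
            "f_score": f_score(vh, vn),
            "jsd": jsd(vh, vn, bins=bins),
        })
    df = pd.DataFrame(rows)
    df["rank_f"] = df["f_score"].rank(ascending=False, method="min").astype("Int64")
    df["rank_jsd"] = df["jsd"].rank(ascending=False, method="min").astype("Int64")
    return df.sort_values("f_score", ascending=False).reset_index(drop=True)


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean F score and JSD per feature group (physicochemical/local/global)."""
    return (records.groupby("group")[["f_score", "jsd"]]
            .agg(["mean", "max"]).sort_index())
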