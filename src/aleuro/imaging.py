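"""Quantification of tonoplast imaging statistics.

The central statistic is the fold enrichment of a tagged protein at the
tonoplast domain engulfing a storage protein body, relative to the rest of
the tonoplast: the mean intensity over unsaturated engulfment positions
divided by the mean over unsaturated positions elsewhere.  Because the
engulfing domain consists of two closely apposed tonoplast membranes, a
protein evenly distributed per membrane gives an expected ratio of exactly
2 - the analytic null against which measured ratios are compared.  Ratios
above 2 indicate genuine per-membrane enrichment at microautophagy sites.

Also provided: bulb (rounded tonoplast invagination) frequency per construct
with fold change against a control, and Pearson co-localization of two
fluorescence channels restricted to a region-of-interest mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def domain_fold_enrichment(profile: pd.DataFrame,
                           background: float = 0.0) -> float:
    """Engulfment / other mean-intensity ratio over unsaturated positions.

    ``profile`` needs columns ``intensity``, ``domain`` (labels
    "engulfment" / "other") and ``saturated``; saturated positions are
    excluded.  An optional constant ``background`` is subtracted first (the
    ratio is not background-invariant).  Raises if either domain has no
    unsaturated positions.
    """
    for col in ("intensity", "domain", "saturated"):
        if col not in profile.columns:
            raise ValueError(f"profile lacks column {col!r}")
    usable = profile.loc[~profile["saturated"].astype(bool)]
    means = {}
    for dom in ("engulfment", "other"):
        sel = usable.loc[usable["domain"] == dom, "intensity"]
        if len(sel) == 0:
            raise ValueError(
                f"domain {dom!r} has no unsaturated positions; "
                "ratio undefined")
        means[dom] = float(sel.mean()) - background
    if means["other"] == 0:
        raise ValueError("zero mean intensity outside the engulfment domain")
    return means["engulfment"] / means["other"]


def bulb_frequency(observations: pd.DataFrame,
                   control_label: str) -> pd.DataFrame:
    """Percent of protoplasts with bulbs per construct, and fold vs control.

    ``observations`` needs columns ``construct`` and boolean ``has_bulbs``.
    Fold change is construct percent / control percent, NaN (flagged
    ``fold_defined=False``) when the control shows no bulbs.
    """
    for col in ("construct", "has_bulbs"):
        if col not in observations.columns:
            raise ValueError(f"observations lack column {col!r}")
    if control_label not in set(observations["construct"]):
        raise ValueError(f"unknown control label {control_label!r}")
    grouped = observations.groupby("construct")["has_bulbs"]
    pct = 100.0 * grouped.mean()
    n = grouped.size()
    control_pct = float(pct[control_label])
    defined = control_pct > 0
    fold = pct / control_pct if defined else pd.Series(np.nan, index=pct.index)
    out = pd.DataFrame({"n_protoplasts": n, "percent_with_bulbs": pct,
                        "fold_vs_control": fold,
                        "fold_defined": defined})
    out.index.name = "construct"
    return out


def roi_pearson(channel_a: np.ndarray, channel_b: np.ndarray,
                roi_mask: np.ndarray) -> float:
    """Pearson correlation of two channels over the ROI mask pixels."""
    a, b = np.asarray(channel_a, float), np.asarray(channel_b, float)
    mask = np.asarray(roi_mask, bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("channels and mask must share one shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    av, bv = a[mask], b[mask]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant channel within the ROI: "
                         "correlation undefined")
    return float(np.corrcoef(av, bv)[0, 1])


def profile_from_trace(image: np.ndarray, trace: pd.DataFrame,
                       saturation_level: float | None = None) -> pd.DataFrame:
    """Sample a 2-D image along a traced membrane into a 1-D profile.

    ``trace`` holds ordered (row, col) points with a ``domain`` label per
    point; intensities are read with nearest-pixel sampling, reducing the
    2-D case to the 1-D ratio computation.
    """
    img = np.asarray(image, float)
    rows = np.clip(np.round(trace["row"]).astype(int), 0, img.shape[0] - 1)
    cols = np.clip(np.round(trace["col"]).astype(int), 0, img.shape[1] - 1)
    intensity = img[rows, cols]
    if saturation_level is None:
        saturation_level = float(img.max()) + 1.0
    return pd.DataFrame({
        "position": np.arange(len(trace), dtype=float),
        "intensity": intensity,
        "domain": trace["domain"].to_numpy(),
        "saturated": intensity >= saturation_level,
    })
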