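"""Co-IP proteomics confidence tiering and tonoplast-proteome enrichment.

Proteins pulled down with anti-H+-PPase antibodies are compared, replicate
by replicate, against the pre-immune serum control.  One is added to every
abundance before dividing (so empty denominators never occur):

    fold_difference[r] = (a_ip[r] + 1) / (a_preimmune[r] + 1)

Tiers follow the three-replicate rule: *high* when at least two of three
replicates have fold differences >= 2; *medium* when exactly one replicate
does and the protein is never detected in pre-immune serum; *low* otherwise.

Enrichment of predicted tonoplast proteins among the detected set is a
one-sided (greater) Fisher's exact test on the 2x2 detection/prediction
table, with the sample odds ratio ``a*d / (b*c)`` as the headline
fold-enrichment statistic and the conditional MLE odds ratio reported as a
secondary field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FOLD_THRESHOLD = 2.0


def _pivot(records: pd.DataFrame) -> pd.DataFrame:
    """Long (protein, replicate, assay, abundance) -> wide per protein."""
    needed = {"protein", "replicate", "assay", "abundance"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    if (records["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")
    wide = records.pivot_table(index="protein", columns=["assay", "replicate"],
                               values="abundance", fill_value=0.0)
    return wide


def replicate_fold_differences(records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein, per-replicate add-one pseudocount fold differences.

    Returns a per-protein DataFrame with columns ``fd_1..fd_3``,
    ``detected_ip_r`` / ``detected_pi_r`` booleans and ``detected``
    (present in any IP replicate).
    """
    wide = _pivot(records)
    reps = sorted({r for a, r in wide.columns if a == "ip"})
    if sorted({r for a, r in wide.columns if a == "preimmune"}) != reps:
        raise ValueError("ip and preimmune must cover the same replicates")
    out = pd.DataFrame(index=wide.index)
    for r in reps:
        ip = wide[("ip", r)]
        pi = wide[("preimmune", r)]
        out[f"fd_{r}"] = (ip + 1.0) / (pi + 1.0)
        out[f"detected_ip_{r}"] = ip > 0
        out[f"detected_pi_{r}"] = pi > 0
    ip_cols = [f"detected_ip_{r}" for r in reps]
    out["detected"] = out[ip_cols].any(axis=1)
    out.attrs["replicates"] = reps
    return out


def classify_confidence_tier(fd_table: pd.DataFrame) -> pd.DataFrame:
    """Assign high / medium / low tiers from the three-replicate rule."""
    reps = fd_table.attrs.get("replicates") or sorted(
        int(c.split("_")[1]) for c in fd_table.columns if c.startswith("fd_"))
    if len(reps) != 3:
        raise ValueError(
            f"the tier rule is defined for exactly 3 replicates, got "
            f"{len(reps)}")
    fd = fd_table[[f"fd_{r}" for r in reps]].to_numpy()
    n_over = (fd >= FOLD_THRESHOLD).sum(axis=1)
    never_pi = ~fd_table[[f"detected_pi_{r}" for r in reps]].any(axis=1)
    tier = np.where(n_over >= 2, "high",
                    np.where((n_over == 1) & never_pi, "medium", "low"))
    out = fd_table.copy()
    out["tier"] = tier
    out.attrs["replicates"] = reps
    return out


def detection_overlap_summary(fd_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of proteins detected in exactly 1, 2, 3 replicates per assay."""
    reps = fd_table.attrs.get("replicates", [1, 2, 3])
    rows = []
    for assay, prefix in (("ip", "detected_ip_"), ("preimmune",
                                                   "detected_pi_")):
        flags = fd_table[[f"{prefix}{r}" for r in reps]]
        n_det = flags.sum(axis=1)
        counts = {k: int((n_det == k).sum()) for k in (1, 2, 3)}
        total = sum(counts.values())
        frac2 = (100.0 * (counts[2] + counts[3]) / total if total else 0.0)
        rows.append({"assay": assay, "in_1": counts[1], "in_2": counts[2],
                     "in_3": counts[3], "total_detected": total,
                     "pct_in_2_or_more": frac2})
    return pd.DataFrame(rows)


@dataclass
class Enrichment2x2:
    """One-sided Fisher's exact enrichment of predicted among detected."""

    a: int  # detected & predicted
    b: int  # detected & not predicted
    c: int  # not detected & predicted
    d: int  # not detected & not predicted
    odds_ratio: float
    odds_ratio_cmle: float
    p: float
    infinite_or: bool

    @property
    def table(self):
        return [[self.a, self.b], [self.c, self.d]]


def fisher_enrichment(detected, predicted, universe_size: int) -> Enrichment2x2:
    """One-sided (greater) Fisher's exact test on detection x prediction.

    ``p`` is the hypergeometric upper tail; the headline ``odds_ratio`` is
    the sample odds ratio a*d/(b*c) (infinite, flagged, when b*c = 0) and
    ``odds_ratio_cmle`` the conditional maximum-likelihood estimate.
    """
    detected, predicted = set(detected), set(predicted)
    a = len(detected & predicted)
    b = len(detected) - a
    c = len(predicted) - a
    d = universe_size - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("sets inconsistent with universe_size")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        orr, infinite = float("inf"), True
    else:
        orr, infinite = a * d / (b * c), False
    return Enrichment2x2(a=a, b=b, c=c, d=d, odds_ratio=orr,
                         odds_ratio_cmle=float(res.statistic),
                         p=float(res.pvalue), infinite_or=infinite)


def fisher_enrichment_counts(n_overlap: int, n_detected: int,
                             n_predicted: int,
                             universe_size: int) -> Enrichment2x2:
    """fisher_enrichment from printed counts rather than explicit sets."""
    a = n_overlap
    b = n_detected - a
    c = n_predicted - a
    d = universe_size - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("counts inconsistent with universe_size")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        orr, infinite = float("inf"), True
    else:
        orr, infinite = a * d / (b * c), False
    return Enrichment2x2(a=a, b=b, c=c, d=d, odds_ratio=orr,
                         odds_ratio_cmle=float(res.statistic),
                         p=float(res.pvalue), infinite_or=infinite)


def run_coip(records: pd.DataFrame, predicted=None,
             universe_size: int | None = None):
    """Fold differences -> tiers (+ optional Fisher enrichment).

    Returns ``(tier_table, enrichment_or_None)``; enrichment uses IP-detected
    proteins vs the predicted tonoplast list over ``universe_size``.
    """
    tiers = classify_confidence_tier(replicate_fold_differences(records))
    enrich = None
    if predicted is not None:
        if universe_size is None:
            raise ValueError("universe_size required for enrichment")
        detected = set(tiers.index[tiers["detected"]])
        enrich = fisher_enrichment(detected, predicted, universe_size)
    return tiers, enrich
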