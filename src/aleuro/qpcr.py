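"""Comparative-Ct (ddCt) relative quantification against a reference gene.

Technical replicates are averaged per (gene, tissue, biological replicate);
dCt = Ct_target - Ct_reference within a tissue; ddCt = dCt_a - dCt_b; the
fold change of tissue a over tissue b is ``E ** (-ddCt)`` with amplification
efficiency E = 2 (perfect doubling) by default.  The summary fold change is
the mean of the per-biological-replicate fold changes; the fold computed
from the mean ddCt is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FoldChangeResult:
    gene: str
    tissue_a: str
    tissue_b: str
    per_replicate: pd.Series  # fold change per biological replicate
    mean_fold: float          # mean of per-replicate folds (headline)
    fold_of_mean_ddct: float
    efficiency: float


def _tech_means(records: pd.DataFrame) -> pd.DataFrame:
    needed = {"gene", "tissue", "bio_rep", "ct"}
    if not needed.issubset(records.columns):
        raise ValueError(f"Ct table must have columns {sorted(needed)}")
    return (records.groupby(["gene", "tissue", "bio_rep"])["ct"]
            .mean().rename("ct"))


def ddct_fold_change(records: pd.DataFrame, target: str, reference: str,
                     tissue_a: str = "AL", tissue_b: str = "ST",
                     efficiency: float = 2.0) -> FoldChangeResult:
    """Fold change of ``target`` in tissue_a vs tissue_b via ddCt."""
    ct = _tech_means(records)
    folds = {}
    for tissue in (tissue_a, tissue_b):
        for gene in (target, reference):
            if (gene, tissue) not in ct.index.droplevel("bio_rep"):
                raise ValueError(
                    f"gene {gene!r} missing in tissue {tissue!r}")
    bio_reps = sorted(
        set(ct.loc[target, tissue_a].index) &
        set(ct.loc[target, tissue_b].index))
    if not bio_reps:
        raise ValueError("no shared biological replicates between tissues")
    for br in bio_reps:
        try:
            ref_a = ct.loc[(reference, tissue_a, br)]
            ref_b = ct.loc[(reference, tissue_b, br)]
        except KeyError:
            raise ValueError(
                f"reference {reference!r} missing for biological replicate "
                f"{br}") from None
        dct_a = ct.loc[(target, tissue_a, br)] - ref_a
        dct_b = ct.loc[(target, tissue_b, br)] - ref_b
        ddct = dct_a - dct_b
        folds[br] = float(efficiency ** (-ddct))
    per_rep = pd.Series(folds, name="fold")
    log_e = np.log(efficiency)
    mean_ddct = float(np.mean([-np.log(f) / log_e for f in folds.values()]))
    return FoldChangeResult(
        gene=target, tissue_a=tissue_a, tissue_b=tissue_b,
        per_replicate=per_rep, mean_fold=float(per_rep.mean()),
        fold_of_mean_ddct=float(efficiency ** (-mean_ddct)),
        efficiency=efficiency)


def fold_change_table(records: pd.DataFrame, reference: str,
                      tissue_a: str = "AL", tissue_b: str = "ST",
                      efficiency: float = 2.0) -> pd.DataFrame:
    """ddct_fold_change for every non-reference gene in the table."""
    genes = sorted(set(records["gene"]) - {reference})
    rows = []
    for g in genes:
        res = ddct_fold_change(records, g, reference, tissue_a, tissue_b,
                               efficiency)
        row = {"gene": g, "mean_fold": res.mean_fold,
               "fold_of_mean_ddct": res.fold_of_mean_ddct}
        for br, f in res.per_replicate.items():
            row[f"fold_rep{br}"] = f
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
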