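"""Transcript-abundance summaries: TPM, the expressed rule, and CS scores.

TPM is computed from counts and annotated transcript lengths,
``TPM_gi = 1e6 * (c_gi / L_g) / sum_h (c_hi / L_h)``, a deliberate
simplification of alignment-level abundance estimation (which is out of
scope here).  Per (tissue, timepoint), a gene is called *expressed* only when
every biological replicate has TPM > 0; otherwise its mean TPM is set to 0 -
the replicate-consistency rule applied throughout the study.

The Compartment Correlation (CS) score of a gene for a tissue is the share
of its summed mean TPM attributable to that tissue across the analyzed
timepoints: ``CS(ST) = sum TPM_ST / (sum TPM_ST + sum TPM_AL)``, so
``CS(ST) + CS(AL) = 1`` whenever the gene is expressed at all, and 0.5 marks
perfect tissue symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from aleuro.containers import CountMatrix, TISSUES


@dataclass
class TpmTable:
    """Per-sample TPM plus per-(tissue, timepoint) means and expressed flags.

    ``mean_tpm`` and ``expressed`` are gene x (tissue, timepoint) frames with
    a two-level column MultiIndex; they are filled by
    :func:`summarize_expression` and are ``None`` before that.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame
    mean_tpm: pd.DataFrame | None = None
    expressed: pd.DataFrame | None = None


@dataclass
class CsScore:
    gene: str
    cs_st: float
    cs_al: float
    defined: bool


def compute_tpm(cm: CountMatrix) -> TpmTable:
    """Length-normalize counts to transcripts per million.

    Every non-empty sample column sums to 1e6; an all-zero sample yields an
    all-zero column with a warning.
    """
    rate = cm.counts.div(cm.gene_lengths, axis=0)
    colsum = rate.sum(axis=0)
    empty = colsum == 0
    if empty.any():
        warnings.warn(
            f"all-zero sample(s): {list(colsum.index[empty])}; "
            "TPM set to 0", stacklevel=2)
    safe = colsum.replace(0, np.nan)
    tpm = rate.div(safe, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return TpmTable(tpm=tpm, samples=cm.samples)


def summarize_expression(table: TpmTable) -> TpmTable:
    """Fill mean TPM and the expressed flag per (tissue, timepoint).

    Mean over biological replicates applies if, and only if, all replicates
    have TPM > 0; otherwise the gene is treated as not expressed there
    (mean TPM = 0).
    """
    groups = table.samples.groupby(["tissue", "timepoint"], sort=True)
    means, flags, keys = [], [], []
    for (tissue, tp), sub in groups:
        cols = sub.index
        block = table.tpm[cols]
        all_pos = (block > 0).all(axis=1)
        mean = block.mean(axis=1).where(all_pos, 0.0)
        means.append(mean)
        flags.append(all_pos)
        keys.append((tissue, tp))
    columns = pd.MultiIndex.from_tuples(keys, names=["tissue", "timepoint"])
    table.mean_tpm = pd.concat(means, axis=1)
    table.mean_tpm.columns = columns
    table.expressed = pd.concat(flags, axis=1)
    table.expressed.columns = columns
    return table


def _require_summary(table: TpmTable) -> None:
    if table.mean_tpm is None:
        raise ValueError("call summarize_expression first")


def cs_score(table: TpmTable, gene: str, timepoints=None) -> CsScore:
    """Compartment Correlation score for one gene.

    ``cs_st = sum mean_TPM in ST / sum mean_TPM in (ST + AL)`` over the
    requested timepoints (default: all present).  Flagged undefined when the
    gene has zero summed TPM in both tissues.
    """
    _require_summary(table)
    if gene not in table.mean_tpm.index:
        raise KeyError(f"unknown gene id {gene!r}")
    row = table.mean_tpm.loc[gene]
    if timepoints is not None:
        timepoints = set(timepoints)
        keep = [c for c in row.index if c[1] in timepoints]
        row = row[keep]
    st = float(row.get("ST", pd.Series(dtype=float)).sum())
    al = float(row.get("AL", pd.Series(dtype=float)).sum())
    total = st + al
    if total <= 0:
        return CsScore(gene, float("nan"), float("nan"), defined=False)
    return CsScore(gene, st / total, al / total, defined=True)


def cs_score_table(table: TpmTable, genes=None, timepoints=None) -> pd.DataFrame:
    """Vectorized CS scores for many genes (same semantics as cs_score)."""
    _require_summary(table)
    mt = table.mean_tpm if genes is None else table.mean_tpm.loc[list(genes)]
    if timepoints is not None:
        timepoints = set(timepoints)
        mt = mt[[c for c in mt.columns if c[1] in timepoints]]
    st = mt.get("ST", pd.DataFrame(index=mt.index)).sum(axis=1)
    al = mt.get("AL", pd.DataFrame(index=mt.index)).sum(axis=1)
    total = st + al
    defined = total > 0
    cs_st = st.where(defined) / total.where(defined)
    out = pd.DataFrame({"cs_st": cs_st, "cs_al": 1.0 - cs_st,
                        "defined": defined})
    out.index.name = "gene"
    return out


def class_fraction(table: TpmTable, class_map: dict) -> pd.DataFrame:
    """Percent of total mean TPM per transcript class and tissue/timepoint.

    Unmapped genes default to class "other".  Returns a long DataFrame with
    columns (tissue, timepoint, class, percent, within_storage_percent,
    defined); ``within_storage_percent`` is each storage class's share of
    all storage-class TPM (the prolamin-share statistic), NaN for "other".
    """
    _require_summary(table)
    classes = pd.Series(
        [class_map.get(g, "other") for g in table.mean_tpm.index],
        index=table.mean_tpm.index)
    storage = {"prolamin", "non-prolamin-storage"}
    rows = []
    for tissue, tp in table.mean_tpm.columns:
        col = table.mean_tpm[(tissue, tp)]
        total = float(col.sum())
        by_class = col.groupby(classes).sum()
        storage_total = float(by_class.reindex(sorted(storage),
                                               fill_value=0.0).sum())
        for cls in sorted(set(classes) | storage | {"other"}):
            val = float(by_class.get(cls, 0.0))
            pct = 100.0 * val / total if total > 0 else float("nan")
            if cls in storage:
                within = (100.0 * val / storage_total
                          if storage_total > 0 else float("nan"))
            else:
                within = float("nan")
            rows.append({"tissue": tissue, "timepoint": tp, "class": cls,
                         "percent": pct, "within_storage_percent": within,
                         "defined": total > 0})
    return pd.DataFrame(rows)


def correlation_suite(table: TpmTable, gene_subset=None,
                      mode: str = "replicate_spearman",
                      timepoint: int | None = None,
                      log_base: float = 10.0) -> pd.DataFrame:
    """Replicate Spearman or cross-tissue Pearson correlation summaries.

    ``replicate_spearman``: Spearman rho of log(TPM + 1) between every pair
    of biological replicate columns within each (tissue, timepoint).

    ``cross_tissue_pcc``: Pearson r of log mean TPM (default log10) between
    AL and ST over ``gene_subset`` at each (or one) timepoint; genes with
    mean TPM = 0 in either tissue are dropped, since log 0 is undefined.
    """
    if mode == "replicate_spearman":
        data = np.log(table.tpm + 1.0)
        if gene_subset is not None:
            data = data.loc[list(gene_subset)]
        if len(data) < 3:
            raise ValueError("need >= 3 genes for a correlation")
        rows = []
        for (tissue, tp), sub in table.samples.groupby(
                ["tissue", "timepoint"], sort=True):
            cols = list(sub.index)
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    rho = stats.spearmanr(data[cols[i]],
                                          data[cols[j]]).statistic
                    rows.append({"tissue": tissue, "timepoint": tp,
                                 "sample_a": cols[i], "sample_b": cols[j],
                                 "spearman_rho": float(rho)})
        return pd.DataFrame(rows)

    if mode == "cross_tissue_pcc":
        _require_summary(table)
        mt = table.mean_tpm
        if gene_subset is not None:
            mt = mt.loc[list(gene_subset)]
        tps = sorted({c[1] for c in mt.columns})
        if timepoint is not None:
            tps = [timepoint]
        rows = []
        for tp in tps:
            al, st = mt[("AL", tp)], mt[("ST", tp)]
            keep = (al > 0) & (st > 0)
            if int(keep.sum()) < 3:
                raise ValueError(
                    f"fewer than 3 usable genes at timepoint {tp}")
            la = np.log(al[keep]) / np.log(log_base)
            ls = np.log(st[keep]) / np.log(log_base)
            r = stats.pearsonr(la, ls).statistic
            rows.append({"timepoint": tp, "pearson_r": float(r),
                         "n_genes": int(keep.sum())})
        return pd.DataFrame(rows)

    raise ValueError(f"unknown mode {mode!r}")
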