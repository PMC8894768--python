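"""Synthetic inputs with the statistical structure the analysis assumes.

Each generator draws from an independent, seeded random stream and returns
its dataset together with a :class:`~aleuro.containers.SimTruth` carrying the
planted ground truth, so every downstream stage can be scored for recovery.

The generative models, briefly:

* RNA-seq counts are negative binomial with a quadratic mean-variance
  relationship (Var = mu + phi * mu^2), log-normal relative gene abundances
  (heavy tail, as in a storage-protein-dominated transcriptome), a paired
  AL/ST design in which each replicate block shares a gene-specific additive
  effect on the log mean, planted differential expression with signed log2
  effects, and a storage-protein gene class whose starchy-endosperm share
  grows along the 8-22 DAP axis.
* Co-IP abundances are log-normal baselines; planted tonoplast proteins are
  multiplied by an IP enrichment factor in the antibody pull-down only, and
  every measurement is independently zeroed at a configurable dropout rate.
* The GO universe is a rooted, layered acyclic DAG with genes annotated to
  leaf terms and a study set that over-represents the planted enriched leaves.
* Tonoplast intensity profiles have an engulfment domain whose expected
  intensity is 2 x factor x the per-membrane baseline - two apposed
  membranes - plus Gaussian noise and a saturation ceiling.
* Ct tables follow Ct = base - log2(expression) + noise with a reference
  gene expressed equally in both tissues.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from aleuro.containers import CountMatrix, SimConfig, SimTruth, TISSUES

# fixed per-generator stream tags so datasets are independent but reproducible
_STREAMS = {"rnaseq": 1, "proteomics": 2, "go": 3, "profile": 4, "qpcr": 5}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2; phi = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    # numpy parameterization: n = size, p = size / (size + mu)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------

def simulate_rnaseq_counts(config: SimConfig):
    """Generate paired AL/ST NB counts across timepoints.

    Returns
    -------
    (CountMatrix, SimTruth)
        Counts for ``2 * n_replicates_per_tissue * len(timepoints)`` samples;
        truth carries the signed log2 effects of planted DE genes and the
        storage-class map.
    """
    rng = _rng(config, "rnaseq")
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")

    lengths = pd.Series(
        np.exp(rng.normal(config.gene_length_meanlog,
                          config.gene_length_sdlog, n)).round().clip(min=100),
        index=genes, name="length")

    base = np.exp(rng.normal(config.abundance_meanlog,
                             config.abundance_sdlog, n))
    denom = base.sum()  # fixed composition denominator: ratios stay exact

    # storage-protein classes
    class_map = {}
    n_storage = config.n_storage_prolamin + config.n_storage_other
    storage_idx = rng.choice(n, size=min(n_storage, n), replace=False)
    for k, gi in enumerate(storage_idx):
        cls = ("prolamin" if k < config.n_storage_prolamin
               else "non-prolamin-storage")
        class_map[genes[gi]] = cls
    class_arr = np.array(
        [class_map.get(g, "other") for g in genes], dtype=object)

    # planted DE genes with signed effects (AL relative to ST)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    # balanced up/down split (order randomized) so both directions are
    # equally represented at any de_fraction
    signs = rng.permutation(
        np.where(np.arange(n_de) < n_de // 2, -1.0, 1.0))
    log2fc = np.zeros(n)
    log2fc[de_idx] = signs * config.log2fc_effect
    de_genes = {genes[i]: float(log2fc[i]) for i in de_idx}

    tps = list(config.timepoints)
    nrep = config.n_replicates_per_tissue
    lo, hi = config.library_size_range

    cols, rows = [], []
    sheet = []
    for ti, tp in enumerate(tps):
        # storage class boost: ST share grows with development; AL grows
        # more modestly (documented generator choice)
        st_boost = np.where(class_arr != "other",
                            config.storage_st_boost ** ti, 1.0)
        al_boost = np.where(class_arr != "other",
                            config.storage_st_boost ** (0.75 * ti), 1.0)
        for b in range(1, nrep + 1):
            # gene-specific block effect shared by the AL/ST pair
            eps = rng.normal(0.0, config.block_sd, n)
            block_mult = 2.0 ** eps
            for tissue in TISSUES:
                tissue_mult = 2.0 ** log2fc if tissue == "AL" else 1.0
                boost = al_boost if tissue == "AL" else st_boost
                lib = int(rng.integers(lo, hi + 1))
                mu = lib * base * tissue_mult * boost * block_mult / denom
                counts = _nb_sample(rng, mu, config.nb_dispersion)
                sid = f"{tissue}_t{tp}_r{b}"
                cols.append(sid)
                rows.append(counts)
                sheet.append({"sample": sid, "tissue": tissue,
                              "timepoint": tp, "replicate_block": f"t{tp}_b{b}"})

    counts = pd.DataFrame(np.column_stack(rows), index=genes, columns=cols)
    samples = pd.DataFrame(sheet).set_index("sample")
    cm = CountMatrix(counts, lengths, samples)
    truth = SimTruth(de_genes=de_genes, expression_class_map=class_map)
    return cm, truth


# ---------------------------------------------------------------------------
# Co-IP proteomics
# ---------------------------------------------------------------------------

def simulate_proteomics_ip(config: SimConfig):
    """Generate IP vs pre-immune abundance tables with a planted tonoplast set.

    Returns a long-format DataFrame with columns ``protein``, ``replicate``
    (1-3), ``assay`` (``ip``/``preimmune``) and ``abundance``, plus truth
    whose ``tonoplast_proteins`` is the planted set.
    """
    rng = _rng(config, "proteomics")
    n = config.n_proteins
    proteins = [f"p{i:04d}" for i in range(n)]
    baseline = np.exp(rng.normal(config.protein_abundance_meanlog,
                                 config.protein_abundance_sdlog, n))
    n_tono = int(round(config.tonoplast_fraction * n))
    tono_idx = rng.choice(n, size=n_tono, replace=False)
    is_tono = np.zeros(n, dtype=bool)
    is_tono[tono_idx] = True

    recs = []
    for r in (1, 2, 3):
        for assay in ("ip", "preimmune"):
            mult = np.where(is_tono & (assay == "ip"),
                            config.ip_enrichment_factor, 1.0)
            noise = np.exp(rng.normal(0.0, config.protein_noise_sdlog, n))
            ab = baseline * mult * noise
            keep = rng.random(n) >= config.dropout_rate
            ab = np.where(keep, ab, 0.0)
            for p, a in zip(proteins, ab):
                recs.append((p, r, assay, float(a)))
    table = pd.DataFrame(recs,
                         columns=["protein", "replicate", "assay", "abundance"])
    truth = SimTruth(tonoplast_proteins={proteins[i] for i in tono_idx})
    return table, truth


# ---------------------------------------------------------------------------
# GO universe
# ---------------------------------------------------------------------------

def simulate_go_universe(config: SimConfig):
    """Generate a rooted layered GO-like DAG with planted enriched leaves.

    Returns
    -------
    (annotations, edges, study_genes, SimTruth)
        ``annotations``: DataFrame (gene, term) of direct annotations to
        leaf terms; ``edges``: DataFrame (child, parent); ``study_genes``:
        the designated study set over-representing the planted terms;
        ``truth.enriched_terms``: the planted leaf term ids.
    """
    if config.go_terms < 1:
        raise ValueError("go_terms must be >= 1")
    rng = _rng(config, "go")
    root = "T:0000"
    n_terms = config.go_terms
    terms = [f"T:{i + 1:04d}" for i in range(n_terms)]

    depth = max(1, min(config.go_depth, n_terms))
    # distribute terms across levels, widening toward the leaves
    level_sizes = np.maximum(
        1, np.diff(np.round(np.linspace(0, n_terms, depth + 1))).astype(int))
    # fix rounding so sizes sum to n_terms
    while level_sizes.sum() > n_terms:
        level_sizes[np.argmax(level_sizes)] -= 1
    while level_sizes.sum() < n_terms:
        level_sizes[np.argmin(level_sizes)] += 1

    levels, k = [[root]], 0
    for sz in level_sizes:
        levels.append(terms[k:k + sz])
        k += sz
    edges = []
    for li in range(1, len(levels)):
        parents = levels[li - 1]
        for t in levels[li]:
            n_par = 1 if len(parents) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(parents), size=min(n_par, len(parents)),
                                replace=False)
            for ci in chosen:
                edges.append((t, parents[ci]))
    edges_df = pd.DataFrame(edges, columns=["child", "parent"])

    dag = nx.DiGraph(edges)  # child -> parent
    assert nx.is_directed_acyclic_graph(dag), "generator produced a cycle"

    leaves = levels[-1]
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    ann = []
    for leaf in leaves:
        size = min(config.go_genes_per_leaf, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        for gi in members:
            ann.append((genes[gi], leaf))
    # every gene annotated to >= 1 leaf
    annotated = {g for g, _ in ann}
    for g in genes:
        if g not in annotated:
            leaf = leaves[int(rng.integers(len(leaves)))]
            ann.append((g, leaf))
    ann_df = pd.DataFrame(sorted(set(ann)), columns=["gene", "term"])

    n_enriched = min(config.go_enriched_terms, len(leaves))
    planted = [leaves[i] for i in
               rng.choice(len(leaves), size=n_enriched, replace=False)]
    study = set()
    for t in planted:
        members = ann_df.loc[ann_df["term"] == t, "gene"].tolist()
        take = max(1, int(round(0.6 * len(members))))
        study.update(rng.choice(members, size=take, replace=False).tolist())
    n_bg = max(1, len(study) // 2)
    background = [g for g in genes if g not in study]
    study.update(rng.choice(background, size=min(n_bg, len(background)),
                            replace=False).tolist())

    truth = SimTruth(enriched_terms=set(planted))
    return ann_df, edges_df, sorted(study), truth


# ---------------------------------------------------------------------------
# Tonoplast intensity profiles
# ---------------------------------------------------------------------------

def simulate_tonoplast_profile(config: SimConfig, with_engulfment: bool = True):
    """Generate a 1-D traced-membrane intensity profile.

    The engulfment domain models two apposed tonoplast membranes, so its
    expected intensity is ``2 * membrane_enrichment_factor * baseline``;
    everywhere else a single membrane contributes ``baseline``.  Values at or
    above ``saturation_level`` are clipped there and flagged saturated.
    """
    rng = _rng(config, "profile")
    n = config.profile_length
    position = np.arange(n, dtype=float)
    domain = np.full(n, "other", dtype=object)
    if with_engulfment:
        a, b = config.engulfment_span
        if not (0 <= a < b <= n):
            raise ValueError("engulfment_span out of profile bounds")
        domain[a:b] = "engulfment"
    base = np.where(domain == "engulfment",
                    2.0 * config.membrane_enrichment_factor
                    * config.profile_baseline,
                    config.profile_baseline)
    intensity = base + rng.normal(0.0, config.noise_sd, n)
    intensity = np.clip(intensity, 0.0, None)
    saturated = intensity >= config.saturation_level
    intensity = np.where(saturated, config.saturation_level, intensity)
    profile = pd.DataFrame({"position": position, "intensity": intensity,
                            "domain": domain, "saturated": saturated})
    truth = SimTruth(
        membrane_enrichment_factor=float(config.membrane_enrichment_factor))
    return profile, truth


def render_profile_image(config: SimConfig, size: int = 129):
    """Render the 1-D profile model as a synthetic 2-D vacuole ring.

    Returns ``(image, trace)`` where ``trace`` is a DataFrame of (row, col)
    points along the ring with the same domain labels as the 1-D generator.
    The imaging module's 2-D path samples intensities along this trace,
    reducing to the 1-D case.
    """
    rng = _rng(config, "profile")
    c = size // 2
    radius = 0.35 * size
    thickness = max(2.0, 0.03 * size)
    n = config.profile_length
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b = config.engulfment_span
    domain = np.full(n, "other", dtype=object)
    domain[a:b] = "engulfment"
    ring_int = np.where(
        domain == "engulfment",
        2.0 * config.membrane_enrichment_factor * config.profile_baseline,
        config.profile_baseline)

    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    ang = np.mod(np.arctan2(yy - c, xx - c), 2.0 * np.pi)
    bins = np.minimum((ang / (2.0 * np.pi) * n).astype(int), n - 1)
    image = np.where(np.abs(r - radius) <= thickness, ring_int[bins], 0.0)
    image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0.0, config.saturation_level)

    rows = c + radius * np.sin(theta)
    cols = c + radius * np.cos(theta)
    trace = pd.DataFrame({"row": rows, "col": cols, "domain": domain})
    return image, trace


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr_ct(config: SimConfig, n_bio: int = 3, n_tech: int = 3):
    """Generate triplicate Ct tables with a tissue-invariant reference gene.

    Ct = base - log2(expression) + noise; target genes carry true AL/ST
    expression ratios drawn log-normally, the reference gene has ratio 1.
    """
    rng = _rng(config, "qpcr")
    genes = [f"q{i:03d}" for i in range(config.qpcr_genes)]
    l2r = rng.normal(0.0, config.qpcr_ratio_log2_sd, config.qpcr_genes)
    ratios = {g: float(2.0 ** l) for g, l in zip(genes, l2r)}
    ratios[config.qpcr_reference] = 1.0
    bases = {g: float(rng.uniform(18.0, 28.0))
             for g in genes + [config.qpcr_reference]}

    recs = []
    for g in genes + [config.qpcr_reference]:
        l = np.log2(ratios[g])
        for tissue, expr_l2 in (("AL", l / 2.0), ("ST", -l / 2.0)):
            for br in range(1, n_bio + 1):
                for tr in range(1, n_tech + 1):
                    ct = (bases[g] - expr_l2
                          + rng.normal(0.0, config.qpcr_ct_noise_sd))
                    recs.append((g, tissue, br, tr, float(ct)))
    table = pd.DataFrame(
        recs, columns=["gene", "tissue", "bio_rep", "tech_rep", "ct"])
    truth = SimTruth(qpcr_ratios=ratios)
    return table, truth


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_rnaseq(cm: CountMatrix, truth: SimTruth, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    cm.counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    cm.gene_lengths.to_frame().to_csv(
        os.path.join(outdir, "gene_lengths.tsv"), sep="\t")
    cm.samples.to_csv(os.path.join(outdir, "samples.csv"))
    rows = [{"gene": g, "true_log2fc": truth.de_genes.get(g, 0.0),
             "class": truth.expression_class_map.get(g, "other")}
            for g in cm.genes]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "truth_rnaseq.tsv"), sep="\t", index=False)


def read_rnaseq(indir: str) -> CountMatrix:
    counts = pd.read_csv(os.path.join(indir, "counts.tsv"),
                         sep="\t", index_col=0)
    lengths = pd.read_csv(os.path.join(indir, "gene_lengths.tsv"),
                          sep="\t", index_col=0)["length"]
    samples = pd.read_csv(os.path.join(indir, "samples.csv"), index_col=0)
    return CountMatrix(counts, lengths, samples)


def write_proteomics(table: pd.DataFrame, truth: SimTruth,
                     outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "abundances.tsv"),
                 sep="\t", index=False)
    pd.Series(sorted(truth.tonoplast_proteins), name="protein").to_csv(
        os.path.join(outdir, "predicted_tonoplast.tsv"),
        sep="\t", index=False)


def write_go(ann: pd.DataFrame, edges: pd.DataFrame, study,
             truth: SimTruth, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    ann.to_csv(os.path.join(outdir, "annotations.tsv"),
               sep="\t", index=False)
    edges.to_csv(os.path.join(outdir, "edges.tsv"), sep="\t", index=False)
    pd.Series(list(study), name="gene").to_csv(
        os.path.join(outdir, "study_genes.tsv"), sep="\t", index=False)
    pd.Series(sorted(truth.enriched_terms), name="term").to_csv(
        os.path.join(outdir, "truth_enriched_terms.tsv"),
        sep="\t", index=False)


def write_profile(profile: pd.DataFrame, truth: SimTruth,
                  outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    profile.to_csv(os.path.join(outdir, "profile.csv"), index=False)
    pd.DataFrame(
        {"membrane_enrichment_factor": [truth.membrane_enrichment_factor]}
    ).to_csv(os.path.join(outdir, "truth_profile.tsv"),
             sep="\t", index=False)


def write_qpcr(table: pd.DataFrame, truth: SimTruth, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "ct.csv"), index=False)
    pd.DataFrame(sorted(truth.qpcr_ratios.items()),
                 columns=["gene", "true_ratio"]).to_csv(
        os.path.join(outdir, "truth_qpcr.tsv"), sep="\t", index=False)
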