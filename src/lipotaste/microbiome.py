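"""Feature-table stages for the papillae microbiome: filtering, rank
aggregation, relative abundance, alpha diversity, ordination, taxon-covariate
regression, and a two-class LDA-effect-size (LEfSe-style) screen.

The central container is :class:`FeatureTable`, a samples x features integer
count table with optional per-feature taxonomic lineages.  All downstream
statistics operate on relative abundances.

The effect-size screen is the two-class, no-subclass reduction of the LEfSe
procedure: a Kruskal-Wallis test at alpha, followed, for significant taxa, by
an effect size computed as the bootstrap-averaged log10 absolute difference of
class means on a per-million abundance scale, thresholded at a log10 score of
2.0.  It is an approximation of, not a byte-match to, the Galaxy LEfSe tool
(which fits a one-against-all LDA); the subclass Wilcoxon stage is omitted
because the two-group designs here have no subclasses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureTable",
    "RankAbundance",
    "OrdinationResult",
    "filter_low_count_otus",
    "aggregate_to_rank",
    "relative_abundance",
    "shannon_index",
    "rarefaction_curve",
    "effect_size_lda",
    "kw_test",
    "taxa_covariate_regression",
    "bray_curtis_pcoa",
]

RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


@dataclass
class FeatureTable:
    """Samples x features non-negative integer counts with optional lineages.

    ``counts`` is a pandas DataFrame indexed by sample id with feature ids as
    columns.  ``lineages``, when present, is indexed by feature id with rank
    columns (phylum ... genus); missing assignments are "unclassified".
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in feature table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate feature ids in feature table")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lineages is not None:
            missing = self.counts.columns.difference(self.lineages.index)
            if len(missing):
                raise ValueError(f"features without lineage: {list(missing)[:5]}")

    @property
    def sample_ids(self):
        return list(self.counts.index)

    @property
    def feature_ids(self):
        return list(self.counts.columns)

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class RankAbundance:
    """Relative abundances (rows sum to 1) at a taxonomic rank.

    Rows whose counts were all zero stay all-zero and are listed in
    ``zero_samples``.
    """

    rank: str
    values: pd.DataFrame
    zero_samples: list = field(default_factory=list)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    explained_fraction: np.ndarray
    dissimilarity_name: str


def filter_low_count_otus(table: FeatureTable, min_total: int = 3) -> FeatureTable:
    """Drop features whose total count across all samples is below ``min_total``.

    The default of 3 removes features supported by fewer than 3 sequences in
    the whole cohort, the usual guard against residual sequencing error.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    keep = table.counts.sum(axis=0) >= min_total
    counts = table.counts.loc[:, keep]
    lineages = None
    if table.lineages is not None:
        lineages = table.lineages.loc[counts.columns]
    return FeatureTable(counts, lineages)


def aggregate_to_rank(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum feature counts over a taxonomic rank label.

    Features lacking an assignment at ``rank`` are pooled under
    "unclassified".  Column order follows first appearance.
    """
    if table.lineages is None:
        raise ValueError("feature table has no lineages")
    if rank not in table.lineages.columns:
        raise ValueError(f"unknown rank {rank!r}; available: {list(table.lineages.columns)}")
    labels = (
        table.lineages.loc[table.counts.columns, rank]
        .fillna(UNCLASSIFIED)
        .replace("", UNCLASSIFIED)
    )
    agg = table.counts.T.groupby(labels.values, sort=False).sum().T
    agg.columns.name = rank
    return FeatureTable(agg)


def relative_abundance(table: FeatureTable | pd.DataFrame, rank: str = "feature") -> RankAbundance:
    """Convert counts to per-sample proportions; zero-total rows are flagged."""
    counts = table.counts if isinstance(table, FeatureTable) else table
    totals = counts.sum(axis=1)
    zero = list(counts.index[totals == 0])
    safe = totals.replace(0, 1)
    values = counts.div(safe, axis=0).astype(float)
    return RankAbundance(rank=rank, values=values, zero_samples=zero)


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of one sample's counts.

    Reported in nats by default; pass ``base=2`` for bits.  Zero counts
    contribute nothing; an all-zero sample is an error.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def rarefaction_curve(
    counts, depths, n_reps: int = 10, seed: int | None = None
) -> np.ndarray:
    """Mean number of distinct features observed in without-replacement
    subsamples of one sample, per requested depth."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths > total):
        raise ValueError("rarefaction depth exceeds sample total")
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    out = np.empty(len(depths), dtype=float)
    for i, d in enumerate(depths):
        obs = [
            int((rng.multivariate_hypergeometric(c, int(d)) > 0).sum())
            for _ in range(n_reps)
        ]
        out[i] = float(np.mean(obs))
    return out


def kw_test(values, class_labels):
    """Kruskal-Wallis rank test of ``values`` across classes.

    Returns ``(H, p)`` with tie correction and a chi-square null, via scipy.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(class_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two classes")
    if all(np.all(g == groups[0][0]) for g in groups if g.size) and values.size:
        # scipy raises on all-identical data; identical classes are maximally null
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def effect_size_lda(
    abundance: RankAbundance | pd.DataFrame,
    classes,
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-class LDA-effect-size screen over all taxa of an abundance table.

    Per taxon: a Kruskal-Wallis test between the two classes; when
    ``p < alpha``, an effect size equal to the mean over ``n_boot`` bootstrap
    rounds (resampling within class) of log10 of the absolute class-mean
    difference on a sum-to-1e6 per-sample scale, floored at 0.  A taxon passes
    when ``p < alpha`` and the score is at least ``lda_cutoff``.

    Returns a DataFrame with columns ``taxon, kw_p, lda_score_log10,
    enriched_class, passed``.
    """
    values = abundance.values if isinstance(abundance, RankAbundance) else abundance
    labels = pd.Series(np.asarray(classes), index=values.index)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(
            f"effect_size_lda supports exactly two classes, got {len(uniq)}"
        )
    idx0 = labels.index[labels == uniq[0]]
    idx1 = labels.index[labels == uniq[1]]
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("each class needs at least 2 samples")

    # rescale each sample to one million, LEfSe's internal normalisation
    totals = values.sum(axis=1).replace(0, 1)
    scaled = values.div(totals, axis=0) * 1e6
    rng = np.random.default_rng(seed)

    rows = []
    a0 = scaled.loc[idx0].to_numpy()
    a1 = scaled.loc[idx1].to_numpy()
    n0, n1 = len(idx0), len(idx1)
    for j, taxon in enumerate(scaled.columns):
        x0, x1 = a0[:, j], a1[:, j]
        _, p = kw_test(np.concatenate([x0, x1]), np.array([0] * n0 + [1] * n1))
        m0, m1 = x0.mean(), x1.mean()
        enriched = uniq[0] if m0 >= m1 else uniq[1]
        if p < alpha:
            boots = np.empty(n_boot)
            for b in range(n_boot):
                r0 = x0[rng.integers(0, n0, n0)]
                r1 = x1[rng.integers(0, n1, n1)]
                diff = abs(r0.mean() - r1.mean())
                boots[b] = np.log10(max(diff, 1e-12))
            lda = max(0.0, float(boots.mean()))
        else:
            lda = float("nan")
        passed = bool(p < alpha and lda >= lda_cutoff)
        rows.append((taxon, p, lda, enriched, passed))
    return pd.DataFrame(
        rows, columns=["taxon", "kw_p", "lda_score_log10", "enriched_class", "passed"]
    )


def taxa_covariate_regression(
    abundance: RankAbundance | pd.DataFrame, covariate
) -> pd.DataFrame:
    """Per-taxon ordinary least squares of abundance on one covariate.

    Returns slope, intercept, Pearson r, two-sided p (t distribution), plus
    Spearman rho and its p, one row per taxon.  The covariate is typically BMI
    (untransformed) or log10 detection threshold.
    """
    values = abundance.values if isinstance(abundance, RankAbundance) else abundance
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(values):
        raise ValueError("covariate length must match number of samples")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; regression undefined")
    rows = []
    for taxon in values.columns:
        y = values[taxon].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append((taxon, 0.0, float(y[0]), 0.0, 1.0, 0.0, 1.0))
            continue
        res = stats.linregress(x, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, rho_p = stats.spearmanr(x, y)
        rows.append(
            (taxon, res.slope, res.intercept, res.rvalue, res.pvalue, rho, rho_p)
        )
    return pd.DataFrame(
        rows,
        columns=["taxon", "slope", "intercept", "r", "p", "spearman_rho", "spearman_p"],
    )


def bray_curtis_pcoa(
    abundance: RankAbundance | pd.DataFrame,
    n_axes: int = 2,
    metric: str = "braycurtis",
) -> OrdinationResult:
    """Principal coordinates analysis of Bray-Curtis dissimilarities.

    Classical metric MDS: eigendecomposition of the double-centred
    -D**2 / 2 matrix; negative eigenvalues are dropped from the explained
    fractions.  Axes are ordered by non-increasing explained fraction.
    ``metric="clr"`` instead embeds Euclidean distances of centred-log-ratio
    transformed proportions (with a 0.5-count pseudofraction), i.e. a
    compositional PCA.
    """
    values = abundance.values if isinstance(abundance, RankAbundance) else abundance
    if len(values) < 2:
        raise ValueError("ordination needs at least 2 samples")
    rel = values.div(values.sum(axis=1).replace(0, 1), axis=0)
    if metric == "braycurtis":
        d = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    elif metric == "clr":
        pseudo = rel.to_numpy() + 0.5 / max(values.shape[1], 1)
        logp = np.log(pseudo)
        clr = logp - logp.mean(axis=1, keepdims=True)
        d = squareform(pdist(clr, metric="euclidean"))
    else:
        raise ValueError(f"unknown ordination metric {metric!r}")

    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as _pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _pcoa(DistanceMatrix(d, ids=[str(s) for s in values.index]))
    eig = np.asarray(res.eigvals, dtype=float)
    pos = eig > 0
    expl = np.zeros_like(eig)
    if pos.any():
        expl[pos] = eig[pos] / eig[pos].sum()
    avail = int(pos.sum())
    if n_axes > avail:
        warnings.warn(
            f"requested {n_axes} axes but only {avail} positive eigenvalues; truncating"
        )
        n_axes = max(avail, 1)
    coords = pd.DataFrame(
        np.asarray(res.samples)[:, :n_axes],
        index=values.index,
        columns=[f"PCo{i+1}" for i in range(n_axes)],
    )
    name = "bray-curtis" if metric == "braycurtis" else "clr-euclidean"
    return OrdinationResult(coords, expl[:n_axes], name)
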