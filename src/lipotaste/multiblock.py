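"""Multiblock PLS discriminant analysis (MB-PLS-DA).

The model relates several named predictor blocks X_1..X_B (biological
determinants, stimulated saliva, resting saliva, microbiota families)
measured on the same subjects to a two-class outcome y (e.g. taster vs
non-taster).  Preprocessing autoscales every variable (mean 0, unit
variance) and then divides each block by the square root of its variable
count, so every block contributes the same total sum of squares — no block
dominates merely by having more variables.

Fitting uses NIPALS on the preprocessed concatenated super-matrix.  Per
component *a*: the super weight ``w_a = X'u / ||X'u||`` is iterated with the
Y score ``u`` to convergence, the super score is ``t_a = X w_a``, X is
deflated by ``t_a``, and y by its regression on ``t_a``.  The classic
super-score identity makes these super scores equal (up to sign) to ordinary
NIPALS PLS run on the concatenated matrix, which is exploited as an
independent oracle in the tests.  Block-level quantities come from the
partition of ``w_a``: block scores ``t_b = X_b w_b / ||w_b||`` and block
importances ``sum(w_b^2) / sum(w^2)``, which sum to 1 per component.

Variable selection follows the chemometric convention: variable importance
in the projection (VIP) on the first component with a strict threshold of 1,
a correlation-loading display threshold of 0.3 over the first two
components, and a per-variable two-sided Mann-Whitney post-hoc between the
classes with significance bands § (p<0.1), * (p<0.05), ** (p<0.01).

Usage::

    model = MBPLS(blocks, y, n_components=2)
    res = model.fit()
    res.vip()                  # per-variable VIP on component 1
    report = res.select_variables()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockSet",
    "PreprocessModel",
    "MBPLS",
    "MBPLSResults",
    "preprocess_blocks",
    "fit_mbpls",
    "explained_variance",
    "select_components",
    "vip_scores",
    "select_variables",
    "mann_whitney_posthoc",
    "significance_band",
]

DEFAULT_BLOCK_ORDER = (
    "biological_determinants",
    "stimulated_saliva",
    "resting_saliva",
    "microbiota",
)


@dataclass
class BlockSet:
    """Named predictor blocks over a shared, identically ordered sample set.

    ``matrices`` maps block name to a samples x variables DataFrame; all
    blocks must share the same index in the same order, and variable names
    must be unique within a block.
    """

    matrices: "dict[str, pd.DataFrame]"

    def __post_init__(self):
        names = list(self.matrices)
        if not names:
            raise ValueError("BlockSet needs at least one block")
        ref = self.matrices[names[0]].index
        for name, m in self.matrices.items():
            if not m.index.equals(ref):
                raise ValueError(
                    f"block {name!r} sample ids differ from block {names[0]!r}"
                )
            if m.columns.has_duplicates:
                dup = m.columns[m.columns.duplicated()][0]
                raise ValueError(f"duplicate variable {dup!r} in block {name!r}")

    @property
    def block_names(self):
        return list(self.matrices)

    @property
    def sample_ids(self):
        first = next(iter(self.matrices.values()))
        return list(first.index)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.matrices.values())))

    def variable_names(self, block: str):
        return list(self.matrices[block].columns)

    def concat(self) -> pd.DataFrame:
        """Concatenate blocks column-wise, in block order."""
        return pd.concat(self.matrices.values(), axis=1)

    def variable_blocks(self) -> pd.Series:
        """Block membership of each concatenated variable, in order."""
        pairs = [
            (v, b) for b, m in self.matrices.items() for v in m.columns
        ]
        return pd.Series(dict(pairs)).loc[[v for v, _ in pairs]]

    def subset(self, sample_ids) -> "BlockSet":
        return BlockSet({b: m.loc[sample_ids] for b, m in self.matrices.items()})


@dataclass
class PreprocessModel:
    """Autoscaling parameters plus block scale factors.

    Applying the model to its training data leaves every column with mean 0
    and every block with the same total sum of squares.
    """

    means: pd.Series
    scales: pd.Series
    block_factors: "dict[str, float]"

    def transform(self, blocks: BlockSet) -> BlockSet:
        out = {}
        for name, m in blocks.matrices.items():
            z = (m - self.means[m.columns]) / self.scales[m.columns]
            out[name] = z / self.block_factors[name]
        return BlockSet(out)


def preprocess_blocks(blocks: BlockSet) -> tuple[BlockSet, PreprocessModel]:
    """Autoscale every variable, then balance block sums of squares.

    Each column is centred and scaled to unit variance (ddof=1); each block is
    then divided by the square root of its variable count so that all block
    total sums of squares are equal.  Constant columns and missing values are
    errors (run a complete-case filter first for the latter).
    """
    if blocks.n_samples < 2:
        raise ValueError("preprocessing needs at least 2 samples")
    means, scales, factors = {}, {}, {}
    for name, m in blocks.matrices.items():
        if m.isna().to_numpy().any():
            raise ValueError(
                f"block {name!r} contains missing values; apply a complete-case "
                "filter before preprocessing"
            )
        sd = m.std(axis=0, ddof=1)
        const = sd.index[sd == 0]
        if len(const):
            raise ValueError(
                f"constant column {const[0]!r} in block {name!r}; remove it first"
            )
        for v in m.columns:
            means[v] = m[v].mean()
            scales[v] = sd[v]
        factors[name] = float(np.sqrt(m.shape[1]))
    model = PreprocessModel(pd.Series(means), pd.Series(scales), factors)
    return model.transform(blocks), model


def _encode_y(y, coding: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Centred class indicator matrix; returns (Y, binary g, class order)."""
    y = np.asarray(y)
    classes = list(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"discriminant fit requires exactly 2 classes, got {len(classes)}")
    g = (y == classes[1]).astype(float)
    if coding == "single":
        Y = (g - g.mean())[:, None]
    elif coding == "dummy":
        D = np.column_stack([1.0 - g, g])
        Y = D - D.mean(axis=0)
    else:
        raise ValueError("y coding must be 'single' or 'dummy'")
    return Y, g, classes


class MBPLS:
    """Multiblock PLS discriminant model for a two-class outcome.

    Parameters
    ----------
    blocks : BlockSet
        Raw (unpreprocessed) predictor blocks.
    y : array-like
        One class label per sample, exactly two distinct values.
    n_components : int
        Number of latent components to extract.
    y_coding : {"single", "dummy"}
        Two-class response coding: a single centred 0/1 indicator (default)
        or a centred two-column dummy matrix; both give identical
        first-component scores.
    """

    def __init__(self, blocks: BlockSet, y, n_components: int = 2,
                 y_coding: str = "single"):
        self.blocks = blocks
        self.y = np.asarray(y)
        if len(self.y) != blocks.n_samples:
            raise ValueError("y length must match number of samples")
        self.n_components = int(n_components)
        self.y_coding = y_coding

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, block_map: "dict[str, list]",
                       y_column: str, **kwargs) -> "MBPLS":
        """Build from one wide DataFrame and a block -> columns mapping."""
        blocks = BlockSet({b: data[cols].copy() for b, cols in block_map.items()})
        return cls(blocks, data[y_column].to_numpy(), **kwargs)

    def fit(self, tol: float = 1e-12, max_iter: int = 1000) -> "MBPLSResults":
        Xblocks, pre = preprocess_blocks(self.blocks)
        Xc = Xblocks.concat()
        X = Xc.to_numpy(dtype=float)
        var_names = list(Xc.columns)
        var_blocks = Xblocks.variable_blocks()
        Y, g, classes = _encode_y(self.y, self.y_coding)
        n, p = X.shape
        A = self.n_components
        if A < 1:
            raise ValueError("n_components must be >= 1")
        rank = min(n - 1, p)
        if A > rank:
            raise ValueError(f"n_components={A} exceeds rank bound {rank}")

        ss_y_total = float((Y ** 2).sum())
        ss_x_total = float((X ** 2).sum())
        Xd, Yd = X.copy(), Y.copy()

        T = np.zeros((n, A))
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((Y.shape[1], A))
        expl_y = np.zeros(A)
        expl_x = np.zeros(A)
        block_importance = {}
        block_weights = {}
        block_scores = {}
        for b in Xblocks.block_names:
            nb = len(Xblocks.variable_names(b))
            block_importance[b] = np.zeros(A)
            block_weights[b] = np.zeros((nb, A))
            block_scores[b] = np.zeros((n, A))
        mask = {b: (var_blocks == b).to_numpy() for b in Xblocks.block_names}

        for a in range(A):
            u = Yd[:, 0].copy()
            if not np.any(u):
                raise RuntimeError(f"Y exhausted before component {a + 1}")
            w = np.zeros(p)
            for it in range(max_iter):
                w_new = Xd.T @ u
                nw = np.linalg.norm(w_new)
                if nw == 0:
                    raise RuntimeError(
                        f"zero weight vector at component {a + 1}: X carries no "
                        "covariance with Y"
                    )
                w_new /= nw
                t = Xd @ w_new
                tt = float(t @ t)
                if tt == 0:
                    raise RuntimeError(f"degenerate score at component {a + 1}")
                q = Yd.T @ t / tt
                u_new = Yd @ q / float(q @ q)
                if np.linalg.norm(w_new - w) < tol:
                    w, u = w_new, u_new
                    break
                w, u = w_new, u_new
            else:
                raise RuntimeError(
                    f"NIPALS did not converge in {max_iter} iterations "
                    f"at component {a + 1}"
                )
            t = Xd @ w
            tt = float(t @ t)
            pvec = Xd.T @ t / tt
            q = Yd.T @ t / tt
            for b in Xblocks.block_names:
                wb = w[mask[b]]
                nwb = float(np.linalg.norm(wb))
                block_importance[b][a] = float(wb @ wb)  # ||w|| == 1
                block_weights[b][:, a] = wb
                block_scores[b][:, a] = (
                    Xd[:, mask[b]] @ wb / nwb if nwb > 0 else 0.0
                )
            T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pvec, q
            expl_y[a] = tt * float(q @ q) / ss_y_total
            expl_x[a] = tt * float(pvec @ pvec) / ss_x_total
            Xd = Xd - np.outer(t, pvec)
            Yd = Yd - np.outer(t, q)

        return MBPLSResults(
            model=self,
            preprocess=pre,
            classes=classes,
            var_names=var_names,
            var_blocks=var_blocks,
            super_scores=T,
            super_weights=W,
            x_loadings=P,
            y_loadings=Q,
            explained_y_variance=expl_y,
            explained_x_variance=expl_x,
            block_importance={b: v for b, v in block_importance.items()},
            block_weights=block_weights,
            block_scores=block_scores,
            _X_preprocessed=X,
        )


@dataclass
class MBPLSResults:
    """Fitted MB-PLS-DA model: scores, weights, importances, diagnostics."""

    model: MBPLS
    preprocess: PreprocessModel
    classes: list
    var_names: list
    var_blocks: pd.Series
    super_scores: np.ndarray
    super_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_y_variance: np.ndarray
    explained_x_variance: np.ndarray
    block_importance: "dict[str, np.ndarray]"
    block_weights: "dict[str, np.ndarray]"
    block_scores: "dict[str, np.ndarray]"
    _X_preprocessed: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.super_scores.shape[1]

    def explained_variance(self) -> pd.DataFrame:
        """Per-component fractions of Y and X sum of squares captured."""
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "explained_Y": self.explained_y_variance,
                "explained_X": self.explained_x_variance,
            }
        )

    def select_components(self, min_fraction: float = 0.10) -> int:
        """Largest prefix of components each explaining >= ``min_fraction``
        of Y variance; at least 1."""
        return select_components(self, min_fraction)

    def vip(self, n_components_used: int = 1) -> pd.Series:
        """Variable importance in the projection over the first components."""
        return vip_scores(self, n_components_used)

    def correlation_loadings(self, n_components_used: int = 2) -> pd.DataFrame:
        """Correlation of each (preprocessed) variable with each super score."""
        A = min(n_components_used, self.n_components)
        X = self._X_preprocessed
        out = np.zeros((X.shape[1], A))
        for a in range(A):
            t = self.super_scores[:, a]
            for j in range(X.shape[1]):
                xj = X[:, j]
                denom = np.linalg.norm(xj) * np.linalg.norm(t)
                out[j, a] = float(xj @ t) / denom if denom > 0 else 0.0
        return pd.DataFrame(
            out, index=self.var_names, columns=[f"comp{a+1}" for a in range(A)]
        )

    def select_variables(
        self,
        vip_threshold: float = 1.0,
        loading_threshold: float = 0.3,
        vip_components: int = 1,
        loading_components: int = 2,
    ) -> pd.DataFrame:
        """VIP-based discriminant variable selection with post-hoc tests."""
        return select_variables(
            self, vip_threshold, loading_threshold, vip_components,
            loading_components,
        )

    def mann_whitney_posthoc(self, variables=None) -> pd.DataFrame:
        """Two-sided Mann-Whitney per variable between the two classes."""
        return mann_whitney_posthoc(self.model.blocks, self.model.y, variables)

    def to_dict(self) -> dict:
        """JSON-serialisable dump of the fitted model."""
        return {
            "classes": [str(c) for c in self.classes],
            "n_components": self.n_components,
            "variables": list(self.var_names),
            "variable_blocks": [str(b) for b in self.var_blocks],
            "super_scores": self.super_scores.tolist(),
            "super_weights": self.super_weights.tolist(),
            "explained_Y_variance": self.explained_y_variance.tolist(),
            "explained_X_variance": self.explained_x_variance.tolist(),
            "block_importance": {
                b: v.tolist() for b, v in self.block_importance.items()
            },
            "vip_component1": self.vip(1).tolist(),
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = []
        lines.append("Multiblock PLS-DA results")
        lines.append("=" * 60)
        lines.append(
            f"classes: {self.classes[0]} vs {self.classes[1]}   "
            f"n = {len(self.model.y)}   components = {self.n_components}"
        )
        lines.append("")
        lines.append("component   explained Y   explained X")
        for a in range(self.n_components):
            lines.append(
                f"{a+1:>9d}   {self.explained_y_variance[a]:>10.3f}   "
                f"{self.explained_x_variance[a]:>10.3f}"
            )
        lines.append("")
        lines.append("block importance (component 1):")
        for b, v in self.block_importance.items():
            lines.append(f"  {b:<28s} {v[0]:.3f}")
        rep = self.select_variables()
        sel = rep[rep["selected"]]
        lines.append("")
        lines.append(f"variables with VIP > 1 on component 1 ({len(sel)}):")
        for _, row in sel.iterrows():
            lines.append(
                f"  {row['variable']:<28s} VIP={row['vip']:.2f}  "
                f"p={row['posthoc_p']:.4f} {row['band']}"
            )
        return "\n".join(lines)


def fit_mbpls(blocks: BlockSet, y, n_components: int = 2,
              y_coding: str = "single") -> MBPLSResults:
    """Convenience wrapper: ``MBPLS(blocks, y, n_components).fit()``."""
    return MBPLS(blocks, y, n_components=n_components, y_coding=y_coding).fit()


def explained_variance(results: MBPLSResults) -> pd.DataFrame:
    return results.explained_variance()


def select_components(results: MBPLSResults, min_fraction: float = 0.10) -> int:
    """Number of interpretable components: the longest prefix in which every
    component explains at least ``min_fraction`` of Y variance (minimum 1)."""
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must lie in (0, 1)")
    a = 0
    for frac in results.explained_y_variance:
        if frac >= min_fraction:
            a += 1
        else:
            break
    return max(a, 1)


def vip_scores(results: MBPLSResults, n_components_used: int = 1) -> pd.Series:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ).

    ``p`` is the total variable count across blocks and SSY_a the Y variance
    explained by component a.  Identity: sum_j VIP_j^2 == p.
    """
    if n_components_used < 1:
        raise ValueError("n_components_used must be >= 1")
    A = min(n_components_used, results.n_components)
    W = results.super_weights[:, :A]
    ssy = results.explained_y_variance[:A]
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    denom = ssy.sum()
    if denom <= 0:
        # no Y variance explained: fall back to equal component weights
        ssy = np.ones(A)
        denom = float(A)
    vip = np.sqrt(p * (wn ** 2 @ ssy) / denom)
    return pd.Series(vip, index=results.var_names, name="vip")


def significance_band(p: float) -> str:
    """Render a p value as the significance band used in the figures."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "§"
    return "ns"


def mann_whitney_posthoc(blocks: BlockSet, y, variables=None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per variable between the two classes.

    Exact p for combined n <= 20 without ties; otherwise the normal
    approximation with tie and continuity correction.  No multiplicity
    adjustment is applied.
    """
    y = np.asarray(y)
    classes = list(pd.unique(y))
    if len(classes) != 2:
        raise ValueError("post-hoc test requires exactly two classes")
    data = blocks.concat()
    vb = blocks.variable_blocks()
    if variables is None:
        variables = list(data.columns)
    g0 = y == classes[0]
    g1 = y == classes[1]
    if g0.sum() == 0 or g1.sum() == 0:
        raise ValueError("each class needs at least one sample")
    rows = []
    for v in variables:
        x0 = data.loc[g0, v].to_numpy(dtype=float)
        x1 = data.loc[g1, v].to_numpy(dtype=float)
        n = len(x0) + len(x1)
        has_ties = len(np.unique(np.concatenate([x0, x1]))) < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
        p = min(float(res.pvalue), 1.0)
        rows.append((vb[v], v, p, significance_band(p)))
    return pd.DataFrame(rows, columns=["block", "variable", "posthoc_p", "band"])


def select_variables(
    results: MBPLSResults,
    vip_threshold: float = 1.0,
    loading_threshold: float = 0.3,
    vip_components: int = 1,
    loading_components: int = 2,
) -> pd.DataFrame:
    """Discriminant variable report: VIP, loadings, selection, post-hoc.

    ``selected`` is strict VIP > ``vip_threshold`` on the first component(s);
    ``display`` flags variables whose absolute correlation loading with any
    of the first two super scores exceeds ``loading_threshold``.  Post-hoc
    Mann-Whitney p values and significance bands (§ p<0.1, * p<0.05,
    ** p<0.01) are attached per variable.
    """
    if vip_threshold <= 0 or loading_threshold <= 0:
        raise ValueError("thresholds must be positive")
    vip = vip_scores(results, vip_components)
    loads = results.correlation_loadings(loading_components)
    posthoc = mann_whitney_posthoc(results.model.blocks, results.model.y)
    posthoc = posthoc.set_index("variable")
    rows = []
    for v in results.var_names:
        l = loads.loc[v]
        rows.append(
            {
                "block": results.var_blocks[v],
                "variable": v,
                "vip": float(vip[v]),
                "loading_comp1": float(l.iloc[0]),
                "loading_comp2": float(l.iloc[1]) if len(l) > 1 else float("nan"),
                "selected": bool(vip[v] > vip_threshold),
                "display": bool((l.abs() > loading_threshold).any()),
                "posthoc_p": float(posthoc.loc[v, "posthoc_p"]),
                "band": posthoc.loc[v, "band"],
            }
        )
    return pd.DataFrame(rows)
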