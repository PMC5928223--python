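"""Readers, writers, run configuration, and the end-to-end comparison runner.

All interchange is tab-separated UTF-8 text with a header row and the
subject/sample id as first column: ``metadata.tsv``, ``counts.tsv``,
``saliva_resting.tsv``, ``saliva_stimulated.tsv``, plus an optional
``lineage.tsv`` sidecar (feature_id, phylum..genus) for OTU-level tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .microbiome import (
    FeatureTable,
    effect_size_lda,
    relative_abundance,
    shannon_index,
)
from .multiblock import (
    BlockSet,
    MBPLS,
    DEFAULT_BLOCK_ORDER,
)
from .synthetic import MICROBIOTA_FAMILIES

log = logging.getLogger("lipotaste")

__all__ = [
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_table",
    "assemble_blocks",
    "run_comparison",
    "COMPARISONS",
]

#: comparison name -> (subset column, subset value or None, class column)
COMPARISONS = {
    "NW_vs_O": (None, None, "group_bmi"),
    "T_vs_NT": (None, None, "group_taste"),
    "OT_vs_ONT": ("group_bmi", "O", "group_taste"),
    "NWNT_vs_ONT": ("group_taste", "NT", "group_bmi"),
}


@dataclass
class RunConfig:
    """Paths, comparison choice and analysis thresholds for one run."""

    metadata: str
    counts: str
    saliva_resting: str
    saliva_stimulated: str
    comparison: str = "T_vs_NT"
    lineage: str | None = None
    out_dir: str = "lipotaste_out"
    cutoff: float = 0.5
    alpha: float = 0.05
    lda_cutoff: float = 2.0
    vip_threshold: float = 1.0
    loading_threshold: float = 0.3
    n_components: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.comparison not in COMPARISONS:
            raise ValueError(
                f"unknown comparison {self.comparison!r}; "
                f"choose from {sorted(COMPARISONS)}"
            )
        for name in ("cutoff", "alpha", "lda_cutoff", "vip_threshold",
                     "loading_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("metadata", "counts", "saliva_resting", "saliva_stimulated"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_table(path, index_name: str | None = None) -> pd.DataFrame:
    """Read a TSV with the first column as index; duplicate ids are errors."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate id {dup!r} in {path}")
    if index_name:
        df.index.name = index_name
    return df


def read_feature_table(path, lineage_path=None) -> FeatureTable:
    """Read a counts TSV (first column sample_id) into a FeatureTable.

    Cells must be non-negative integers; violations are reported with their
    row and column.
    """
    df = read_table(path, "sample_id")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    for col in df.columns:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][num.isna() | (num < 0) | (num % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"non-integer or negative count at sample {bad.index[0]!r}, "
                f"feature {col!r} in {path}"
            )
    counts = df.astype(np.int64)
    lineages = None
    if lineage_path is not None:
        lineages = read_table(lineage_path, "feature_id")
    return FeatureTable(counts, lineages)


def write_feature_table(table: FeatureTable, path, lineage_path=None) -> None:
    table.counts.rename_axis("sample_id").to_csv(path, sep="\t")
    if lineage_path is not None and table.lineages is not None:
        table.lineages.rename_axis("feature_id").to_csv(lineage_path, sep="\t")


def assemble_blocks(
    metadata: pd.DataFrame,
    stimulated: pd.DataFrame,
    resting: pd.DataFrame,
    family_abundance: pd.DataFrame,
    families=None,
) -> BlockSet:
    """Inner-join the tables on subject id and build the four named blocks.

    The microbiota block holds family-level relative abundances restricted to
    the canonical family inventory (columns absent from the data are
    dropped).  Subjects missing from any table are excluded complete-case,
    with the dropped count logged.
    """
    if families is None:
        families = MICROBIOTA_FAMILIES
    det_cols = ["BMI", "Waist", "Blood_LPS", "Age"]
    missing = [c for c in det_cols if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks determinant columns: {missing}")
    shared = metadata.index
    for other in (stimulated, resting, family_abundance):
        shared = shared.intersection(other.index)
    n_dropped = len(metadata) - len(shared)
    if len(shared) == 0:
        raise ValueError("no subjects shared across all input tables")
    if n_dropped:
        log.info("complete-case filter dropped %d subjects", n_dropped)
    shared = [s for s in metadata.index if s in set(shared)]  # keep order
    fam_cols = [f for f in families if f in family_abundance.columns]
    return BlockSet(
        {
            "biological_determinants": metadata.loc[shared, det_cols].astype(float),
            "stimulated_saliva": stimulated.loc[shared].astype(float),
            "resting_saliva": resting.loc[shared].astype(float),
            "microbiota": family_abundance.loc[shared, fam_cols].astype(float),
        }
    )


def run_comparison(config: RunConfig) -> dict:
    """Execute the full pipeline for one comparison and write its outputs.

    Stages: taster classification from thresholds, alpha diversity,
    LEfSe-style effect size, block assembly, MB-PLS-DA fit, VIP selection and
    Mann-Whitney post-hoc.  Writes thresholds.tsv, diversity.tsv,
    lefse_results.tsv, vip_report.tsv, mbpls_model.json and summary.json to
    ``config.out_dir`` and returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    metadata = _stage("read_metadata", lambda: read_table(config.metadata, "subject_id"))
    counts = _stage("read_counts", lambda: read_feature_table(config.counts, config.lineage))
    stim = _stage("read_stimulated", lambda: read_table(config.saliva_stimulated, "subject_id"))
    rest = _stage("read_resting", lambda: read_table(config.saliva_resting, "subject_id"))

    # taster classification from thresholds (recomputed, not trusted)
    def _classify():
        from .psychophysics import classify_taster

        thr = metadata["la_threshold"].astype(float)
        cens = metadata.get("censored", pd.Series(0, index=metadata.index)).astype(bool)
        labels = [
            classify_taster(t, config.cutoff, bool(c))
            for t, c in zip(thr, cens)
        ]
        df = pd.DataFrame(
            {
                "threshold_pct": thr,
                "censored": cens.astype(int),
                "taster_label": labels,
            },
            index=metadata.index,
        )
        df.rename_axis("subject_id").to_csv(out / "thresholds.tsv", sep="\t")
        return df

    thresholds = _stage("classify", _classify)
    metadata = metadata.copy()
    metadata["group_taste"] = thresholds["taster_label"]

    def _diversity():
        h = counts.counts.apply(lambda row: shannon_index(row.to_numpy()), axis=1)
        df = pd.DataFrame({"shannon_nats": h})
        df.rename_axis("sample_id").to_csv(out / "diversity.tsv", sep="\t")
        return df

    diversity = _stage("diversity", _diversity)

    subset_col, subset_val, class_col = COMPARISONS[config.comparison]
    meta_sel = metadata
    if subset_col is not None:
        meta_sel = metadata[metadata[subset_col] == subset_val]
        if len(meta_sel) == 0:
            raise RuntimeError(
                f"stage 'subset' failed: no subjects with "
                f"{subset_col}={subset_val!r} for comparison {config.comparison}"
            )
    classes = meta_sel[class_col]
    if classes.nunique() != 2:
        raise RuntimeError(
            f"stage 'subset' failed: comparison {config.comparison} needs two "
            f"classes in {class_col!r}, found {sorted(classes.unique())}"
        )

    abundance = relative_abundance(counts).values

    def _lefse():
        idx = [s for s in meta_sel.index if s in abundance.index]
        res = effect_size_lda(
            abundance.loc[idx],
            classes.loc[idx],
            alpha=config.alpha,
            lda_cutoff=config.lda_cutoff,
            seed=config.seed,
        )
        res.to_csv(out / "lefse_results.tsv", sep="\t", index=False)
        return res

    lefse = _stage("lefse", _lefse)

    blocks = _stage(
        "assemble",
        lambda: assemble_blocks(meta_sel, stim, rest, abundance),
    )
    y = classes.loc[blocks.sample_ids].to_numpy()

    results = _stage(
        "fit_mbpls",
        lambda: MBPLS(blocks, y, n_components=config.n_components).fit(),
    )
    report = _stage(
        "select",
        lambda: results.select_variables(
            config.vip_threshold, config.loading_threshold
        ),
    )
    report.to_csv(out / "vip_report.tsv", sep="\t", index=False)
    (out / "mbpls_model.json").write_text(json.dumps(results.to_dict(), indent=2))

    summary = {
        "comparison": config.comparison,
        "n_subjects": int(len(blocks.sample_ids)),
        "classes": {str(c): int((y == c).sum()) for c in pd.unique(y)},
        "explained_Y_variance": results.explained_y_variance.tolist(),
        "block_importance_comp1": {
            b: float(v[0]) for b, v in results.block_importance.items()
        },
        "selected_variables": report.loc[report["selected"], "variable"].tolist(),
        "lefse_passed": lefse.loc[lefse["passed"], "taxon"].tolist(),
        "mean_shannon": float(diversity["shannon_nats"].mean()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
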