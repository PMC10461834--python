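"""Experimental comparison protocols: ablation, cross-species, Wilcoxon tests.

Three protocols mirror how methylation predictors are benchmarked:

* **encoding ablation** — train the BPF-only, NCP-only, DPCP-only and
  fused Multi-Fe models on one shared split/seed of a dataset, so the
  four metric rows are paired by construction;
* **cross-species validation** — train on the training split of one
  species and evaluate on the test split of every species (columns =
  training species, rows = testing species);
* **paired Wilcoxon signed-rank comparison** of two methods' per-dataset
  metric columns: zero differences dropped, mid-ranks on |d|, statistic
  min(W+, W-), two-sided p (exact for small tie-free n, otherwise the
  normal approximation with continuity and tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .encoders import DinucPropertyTable, load_property_table
from .metrics import MetricsReport, evaluate
from .model import MedcnnClassifier, ModelConfig
from .sequence_io import LabeledDataset, SplitSpec, split_dataset

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "compare_result_tables",
    "load_result_table",
    "encoding_ablation",
    "cross_species_matrix",
    "ABLATION_ENCODINGS",
]

#: Column order of the ablation row: the three single encodings, then the fusion.
ABLATION_ENCODINGS = ("BPF", "NCP", "DPCP", "Multi-Fe")

_ENCODING_SELECTORS = {
    "BPF": ("bpf",),
    "NCP": ("ncp",),
    "DPCP": ("dpcp",),
    "Multi-Fe": ("bpf", "ncp", "dpcp"),
}


@dataclass(frozen=True)
class WilcoxonResult:
    """min(W+, W-) signed-rank statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    n_effective: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def wilcoxon_signed_rank(x, y, alpha: float = 0.05) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Differences ``x - y`` equal to zero are dropped; the absolute
    differences are mid-ranked; the statistic is min(W+, W-). The p-value
    is exact for small samples without tied |d| and uses the
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n_eff = d.size
    if n_eff == 0:
        raise ValueError("degenerate comparison: all differences are zero")
    if n_eff < 3:
        raise ValueError("need at least 3 non-zero differences")
    has_ties = np.unique(np.abs(d)).size < n_eff
    method = "exact" if (n_eff <= 25 and not has_ties) else "approx"
    res = _scipy_wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", method=method,
        correction=(method == "approx"),
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_effective=n_eff,
        alpha=alpha,
    )


def load_result_table(path) -> pd.DataFrame:
    """Read a tab-separated result table (rows: datasets, columns: methods).

    Cells may be proportions or percentages; percent scale is detected by
    any value exceeding 1 and rescaled to proportions.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.to_numpy(dtype=float) > 1.0).any():
        table = table / 100.0
    return table


def compare_result_tables(table: pd.DataFrame, method_a: str, method_b: str,
                          metric: str = "ACC", alpha: float = 0.05
                          ) -> WilcoxonResult:
    """Wilcoxon signed-rank comparison of two methods' paired dataset rows."""
    for col in (method_a, method_b):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in result table")
    a = table[method_a]
    b = table[method_b]
    if a.isna().any() or b.isna().any():
        keep = ~(a.isna() | b.isna())
        a, b = a[keep], b[keep]
    if not a.index.equals(b.index):
        raise ValueError("paired comparison requires identical row sets")
    return wilcoxon_signed_rank(a.to_numpy(float), b.to_numpy(float),
                                alpha=alpha)


def _train_eval(ds_train: LabeledDataset, ds_val: LabeledDataset,
                ds_test: LabeledDataset, config: ModelConfig,
                table: DinucPropertyTable, encodings: tuple[str, ...]
                ) -> MetricsReport:
    est = MedcnnClassifier.from_config(
        config, encodings=encodings, property_table=table
    )
    est.fit(ds_train, validation_data=(ds_val, None) if len(ds_val) else None)
    probs = est.predict_proba(ds_test)[:, 1]
    return evaluate(probs, ds_test.labels, threshold=config.threshold)


def encoding_ablation(ds: LabeledDataset, config: ModelConfig,
                      table: DinucPropertyTable | None = None,
                      split: SplitSpec | None = None
                      ) -> dict[str, MetricsReport]:
    """Train the four encoding variants on one shared split and seed.

    Single-encoding models use one branch whose embedding feeds the fully
    connected head directly (no fusion); Multi-Fe is the fused three-branch
    model. The shared split makes the four reports a paired observation for
    the signed-rank test.
    """
    if table is None:
        table = load_property_table()
    if split is None:
        split = SplitSpec(seed=config.seed)
    ds_train, ds_val, ds_test = split_dataset(ds, split)
    return {
        name: _train_eval(ds_train, ds_val, ds_test, config, table,
                          _ENCODING_SELECTORS[name])
        for name in ABLATION_ENCODINGS
    }


def ablation_row(reports: dict[str, MetricsReport], metric: str = "ACC"
                 ) -> pd.Series:
    """One paired result row (method -> metric value) from ablation reports."""
    return pd.Series({k: getattr(v, metric) for k, v in reports.items()})


def cross_species_matrix(datasets: dict[str, LabeledDataset],
                         config: ModelConfig,
                         table: DinucPropertyTable | None = None,
                         split: SplitSpec | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Train per species, evaluate on every species' held-out test split.

    Returns one square DataFrame per metric (SN, SP, ACC, AUC) whose
    columns are the training species and rows the testing species; the
    diagonal is the within-species evaluation. Each species keeps its own
    pinned split; no re-balancing across species.
    """
    if len(datasets) < 2:
        raise ValueError("cross-species validation needs at least 2 datasets")
    if table is None:
        table = load_property_table()
    if split is None:
        split = SplitSpec(seed=config.seed)
    names = list(datasets)
    lengths = {datasets[n].L for n in names}
    if len(lengths) != 1:
        raise ValueError("all datasets must share one window length")

    splits = {n: split_dataset(datasets[n], split) for n in names}
    matrices = {m: pd.DataFrame(index=names, columns=names, dtype=float)
                for m in ("SN", "SP", "ACC", "AUC")}
    for train_name in names:
        tr, va, _ = splits[train_name]
        est = MedcnnClassifier.from_config(config, property_table=table)
        est.fit(tr, validation_data=(va, None) if len(va) else None)
        for test_name in names:
            _, _, te = splits[test_name]
            probs = est.predict_proba(te)[:, 1]
            report = evaluate(probs, te.labels, threshold=config.threshold)
            for m in matrices:
                matrices[m].loc[test_name, train_name] = getattr(report, m)
    return matrices
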