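"""Benchmark evaluation: confusion metrics, AUC, scenario grid, ANOVA.

A method's per-gene output is scored against the simulator's truth table.
Binary calls use the significance level alpha (strict ``p < alpha``);
accuracy, sensitivity and specificity come from the confusion counts, and
the rank-based AUC (Mann-Whitney) measures how well a method orders true
positives above true negatives without committing to a cutoff.  On
balanced truth (equal TP and TN counts), the accuracy of a binary call
equals (sensitivity + specificity)/2, which is the AUC of the 0/1 call
vector.

``benchmark_grid`` runs every method over every scenario of the factorial
design; ``anova_parameter_influence`` then asks which design factors
(group sizes, exons per gene, expression intensity, percent spliced
samples) significantly move a method's accuracy, via a main-effects ANOVA
over replicate simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import MethodResult, ScenarioSpec, TruthTable
from .ds_methods import METHODS, SCORE_METHODS, run_method
from .permutation import PermutationConfig
from .simulator import SimulationConfig, make_scenario_grid, scenario_name, simulate_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "BenchmarkGrid",
    "classify",
    "confusion_metrics",
    "auc",
    "benchmark_grid",
    "anova_parameter_influence",
]

FACTORS = ("expr", "enum", "pcnt", "snum")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class BenchmarkGrid:
    """Method x scenario matrix of evaluation metrics."""

    table: pd.DataFrame  # columns: method, scenario, acc, auc, sensitivity, specificity, is_max_acc
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-method averages


def classify(result: MethodResult, alpha: float = 0.05, fdr: bool = False) -> dict[str, bool]:
    """Binary DS call per gene: p strictly below alpha.

    Genes without a p-value are excluded (logged), i.e. never called.
    With ``fdr=True`` the p-values are Benjamini-Hochberg adjusted across
    genes first (off by default: classification is per gene at alpha).
    """
    if result.p_value is None:
        raise ValueError(f"method {result.method!r} result carries no p-values")
    genes, ps = [], []
    for g, p in zip(result.gene_ids, result.p_value):
        if np.isnan(p):
            logger.info("gene %s has no p-value (%s); counted as not called", g, result.method)
            continue
        genes.append(g)
        ps.append(p)
    ps = np.asarray(ps)
    if fdr and ps.size:
        from statsmodels.stats.multitest import multipletests

        ps = multipletests(ps, method="fdr_bh")[1]
    return {g: bool(p < alpha) for g, p in zip(genes, ps)}


def confusion_metrics(
    calls: dict[str, bool], truth: TruthTable
) -> tuple[ConfusionCounts, float | None, float | None, float | None]:
    """Confusion counts plus accuracy, sensitivity and specificity.

    Genes present in the truth but absent from ``calls`` count as not
    called.  Ratios with zero denominator are returned as None.
    """
    unknown = set(calls) - set(truth.entries)
    if unknown:
        raise ValueError(f"calls contain genes absent from truth: {sorted(unknown)[:5]}")
    tp = fp = tn = fn = 0
    for g, entry in truth.entries.items():
        called = calls.get(g, False)
        if entry.is_ds:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else None
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return counts, acc, sens, spec


def auc(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    larger_is_ds: bool = True,
) -> float:
    """Rank-based AUC: P(random TP outranks random TN), ties count 1/2.

    Equivalent to the Mann-Whitney U statistic divided by (#TP x #TN).
    Set ``larger_is_ds=False`` for p-values, where smaller means more
    evidence.  NaN entries are dropped pairwise.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must align")
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one TP and one TN")
    if not larger_is_ds:
        v = -v
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _evaluate_result(
    result: MethodResult, truth: TruthTable, alpha: float
) -> dict[str, float | None]:
    calls = classify(result, alpha=alpha)
    _, acc, sens, spec = confusion_metrics(calls, truth)
    labels = truth.labels(result.gene_ids)
    # score-based ranking where available (avoids cutoff choice), p otherwise
    if result.score is not None:
        auc_val = auc(result.score, labels, larger_is_ds=True)
    else:
        auc_val = auc(result.p_value, labels, larger_is_ds=False)
    return {"acc": acc, "auc": auc_val, "sensitivity": sens, "specificity": spec}


def benchmark_grid(
    methods: Sequence[str] = METHODS,
    scenarios: Sequence[ScenarioSpec] | None = None,
    sim_config: SimulationConfig = SimulationConfig(),
    perm_config: PermutationConfig = PermutationConfig(),
    alpha: float = 0.05,
) -> BenchmarkGrid:
    """Simulate every scenario, run every method, tabulate all metrics.

    Each scenario draws its dataset from a seed derived from the master
    ``sim_config.seed`` and the scenario's position, so the grid is
    reproducible end to end.  A failed method x scenario cell is recorded
    with NaN metrics and the run continues.  ``is_max_acc`` flags the
    per-scenario accuracy maxima (several methods can tie).
    """
    if scenarios is None:
        scenarios = make_scenario_grid()
    rows = []
    for s_idx, spec in enumerate(scenarios):
        cfg = replace(sim_config, seed=sim_config.seed + 1000 * s_idx)
        dataset, truth = simulate_scenario(spec, cfg)
        pcfg = replace(perm_config, seed=perm_config.seed + 1000 * s_idx)
        for method in methods:
            try:
                result = run_method(
                    dataset, method, perm_config=pcfg if method in SCORE_METHODS else None
                )
                metrics = _evaluate_result(result, truth, alpha)
            except Exception as exc:  # record and continue
                logger.warning("cell %s x %s failed: %s", method, scenario_name(spec), exc)
                metrics = {"acc": np.nan, "auc": np.nan, "sensitivity": np.nan, "specificity": np.nan}
            rows.append({"method": method, "scenario": scenario_name(spec), **metrics})

    table = pd.DataFrame(rows)
    table["is_max_acc"] = False
    for scen, grp in table.groupby("scenario"):
        best = grp["acc"].max()
        if pd.notna(best):
            table.loc[(table["scenario"] == scen) & (table["acc"] == best), "is_max_acc"] = True
    summary = (
        table.groupby("method")[["acc", "auc", "sensitivity", "specificity"]]
        .mean()
        .reset_index()
    )
    return BenchmarkGrid(table=table, summary=summary)


def anova_parameter_influence(
    accuracies: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Main-effects ANOVA of accuracy on the four binary design factors.

    ``accuracies`` must hold one row per (method, scenario, replicate)
    with columns ``method``, ``acc`` and the factor columns ``expr``,
    ``enum``, ``pcnt``, ``snum``; at least 2 replicates per scenario and
    method are required (independent simulation seeds).  Returns one row
    per method x factor with F, p and a '+'/'-' significance flag.
    """
    required = {"method", "acc", *FACTORS}
    missing = required - set(accuracies.columns)
    if missing:
        raise ValueError(f"accuracy table lacks columns: {sorted(missing)}")
    counts = accuracies.groupby(["method", *FACTORS]).size()
    if (counts < 2).any():
        raise ValueError(
            "unreplicated design: provide >= 2 replicate accuracies per scenario "
            "per method (run the benchmark with >= 2 seeds)"
        )

    out = []
    for method, grp in accuracies.groupby("method"):
        y = grp["acc"].to_numpy(dtype=float)
        n = y.size
        grand = y.mean()
        # residuals from the full main-effects fit, via one-hot least squares
        cols = [np.ones(n)]
        for f in FACTORS:
            levels = sorted(grp[f].astype(str).unique())
            if len(levels) != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels, got {levels}")
            cols.append((grp[f].astype(str) == levels[1]).to_numpy(dtype=float))
        design = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse_full = float(((y - design @ beta) ** 2).sum())
        df_resid = n - design.shape[1]
        tss = float(((y - grand) ** 2).sum())
        tol = 1e-12 * max(tss, 1.0)  # lstsq residuals are never exactly 0
        for j, f in enumerate(FACTORS):
            reduced = np.delete(design, j + 1, axis=1)
            beta_r, *_ = np.linalg.lstsq(reduced, y, rcond=None)
            sse_red = float(((y - reduced @ beta_r) ** 2).sum())
            if sse_full <= tol:
                fstat, p = (np.inf, 0.0) if sse_red - sse_full > tol else (0.0, 1.0)
            else:
                fstat = (sse_red - sse_full) / (sse_full / df_resid)
                p = float(stats.f.sf(fstat, 1, df_resid))
            out.append(
                {
                    "method": method,
                    "factor": f,
                    "F": fstat,
                    "p": p,
                    "flag": "+" if p < alpha else "-",
                }
            )
    return pd.DataFrame(out)
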