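"""Recovery scoring against planted ground truth.

Each true module is matched to the predicted module with the maximum
Jaccard index on the chosen dimension (phenotype columns by default,
ranking of gene sets ignored); confusion metrics are then computed per
matched true module over the full item universe and macro-averaged, so
small modules remain visible in the pooled numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AssociationMatrix, GAParams
from .extract import ModuleSet, run_ibbig
from .simulate import GroundTruth, SimulationConfig, make_artificial

__all__ = [
    "jaccard_index",
    "match_modules",
    "confusion_metrics",
    "EvaluationReport",
    "evaluate_against_truth",
    "noise_robustness_experiment",
]


def jaccard_index(a, b) -> float:
    """|a n b| / |a u b|; two empty sets have index 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def match_modules(
    predicted: ModuleSet, truth: GroundTruth, dimension: str = "columns"
) -> dict[str, tuple[int | None, float]]:
    """Best-matching predicted module (by max JI) for every true module.

    Returns ``{true_name: (predicted_iteration | None, ji)}``.  Ties are
    broken in favour of the earlier-extracted module; with no predictions
    every true module is unmatched with JI 0.
    """
    if dimension not in ("columns", "rows"):
        raise ValueError("dimension must be 'columns' or 'rows'")
    out: dict[str, tuple[int | None, float]] = {}
    for name in truth.names():
        true_set = truth.cols(name) if dimension == "columns" else truth.rows(name)
        best: tuple[int | None, float] = (None, 0.0)
        for mod in predicted.modules:
            pred_set = mod.column_set() if dimension == "columns" else mod.member_rows()
            ji = jaccard_index(pred_set, true_set)
            if ji > best[1]:
                best = (mod.iteration, ji)
        out[name] = best
    return out


def confusion_metrics(
    predicted: set[int], true: set[int], universe_size: int
) -> dict[str, float]:
    """Sensitivity, specificity, precision and accuracy for one module.

    Computed over the full item universe.  A metric with a zero
    denominator is reported as NaN (undefined), not 0.
    """
    tp = len(predicted & true)
    fp = len(predicted - true)
    fn = len(true - predicted)
    tn = universe_size - tp - fp - fn

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "precision": _ratio(tp, tp + fp),
        "accuracy": _ratio(tp + tn, universe_size),
    }


_METRICS = ("sensitivity", "specificity", "precision", "accuracy")


@dataclass
class EvaluationReport:
    """Per-module matches and macro-averaged recovery metrics."""

    per_module: "object"  # DataFrame: one row per true module
    phenotype: dict[str, float]
    geneset: dict[str, float]

    def summary(self) -> str:
        lines = ["Recovery vs ground truth (macro-averaged)", ""]
        lines.append(f"{'metric':<12}{'phenotypes':>12}{'gene sets':>12}")
        for met in _METRICS:
            lines.append(
                f"{met:<12}{self.phenotype[met]:>12.4f}{self.geneset[met]:>12.4f}"
            )
        return "\n".join(lines)


def _macro(per_module_metrics: list[dict[str, float]]) -> dict[str, float]:
    out = {}
    for met in _METRICS:
        vals = [m[met] for m in per_module_metrics if np.isfinite(m[met])]
        out[met] = float(np.mean(vals)) if vals else float("nan")
    return out


def evaluate_against_truth(predicted: ModuleSet, truth: GroundTruth) -> EvaluationReport:
    """Match predicted to true modules and pool confusion metrics.

    Phenotype matching uses column membership; the matched module's
    gene-set membership calls are then scored against the true rows.
    An unmatched true module counts as an empty prediction: zero
    sensitivity, but no false positives to poison specificity.
    """
    import pandas as pd

    n_rows = len(predicted.row_ids)
    n_cols = len(predicted.col_ids)
    col_match = match_modules(predicted, truth, "columns")
    by_iter = {mod.iteration: mod for mod in predicted.modules}

    records = []
    ph_metrics, gs_metrics = [], []
    for name in truth.names():
        it, ji_cols = col_match[name]
        mod = by_iter.get(it)
        pred_cols = mod.column_set() if mod is not None else set()
        pred_rows = mod.member_rows() if mod is not None else set()
        ph = confusion_metrics(pred_cols, truth.cols(name), n_cols)
        gs = confusion_metrics(pred_rows, truth.rows(name), n_rows)
        ji_rows = jaccard_index(pred_rows, truth.rows(name))
        ph_metrics.append(ph)
        gs_metrics.append(gs)
        records.append(
            {
                "true_module": name,
                "predicted": f"M{it}" if it is not None else None,
                "ji_columns": ji_cols,
                "ji_rows": ji_rows,
                **{f"phenotype_{k}": v for k, v in ph.items()},
                **{f"geneset_{k}": v for k, v in gs.items()},
            }
        )
    return EvaluationReport(
        per_module=pd.DataFrame(records),
        phenotype=_macro(ph_metrics),
        geneset=_macro(gs_metrics),
    )


def noise_robustness_experiment(
    noise_levels,
    reps: int,
    params: GAParams | None = None,
    rng: np.random.Generator | None = None,
    config: SimulationConfig | None = None,
):
    """Mean recovery metrics per background-noise level.

    For each level, ``reps`` fresh matrices are generated with the
    default planted layout at that background noise, the full iterative
    extraction is run, and the macro-averaged phenotype metrics (plus
    per-module column JIs) are averaged over replicates.
    """
    import pandas as pd

    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = params or GAParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    base = config or SimulationConfig()
    records = []
    for level in noise_levels:
        for _ in range(reps):
            cfg = SimulationConfig(
                n_rows=base.n_rows,
                n_cols=base.n_cols,
                background_noise=float(level),
                modules=list(base.modules),
            )
            matrix, truth = make_artificial(cfg, rng)
            result = run_ibbig(matrix, params, rng)
            report = evaluate_against_truth(result, truth)
            rec = {"noise": float(level)}
            rec.update({f"phenotype_{k}": v for k, v in report.phenotype.items()})
            rec.update({f"geneset_{k}": v for k, v in report.geneset.items()})
            for _, row in report.per_module.iterrows():
                rec[f"ji_{row['true_module']}"] = row["ji_columns"]
                rec[f"sens_{row['true_module']}"] = row["phenotype_sensitivity"]
                rec[f"spec_{row['true_module']}"] = row["phenotype_specificity"]
            records.append(rec)
    df = pd.DataFrame(records)
    return df.groupby("noise", as_index=False).mean()
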