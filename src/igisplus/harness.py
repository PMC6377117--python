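"""Nested stratified cross-validation experiment driver.

The outer loop (stratified 5-fold by default) estimates generalization:
each outer training partition is rescaled and discretized using its own
statistics, the selector runs with an inner (4-fold) plan on those rows
only, the best prefix of the selected genes (by mean inner validation
accuracy) is chosen, a classifier is fitted on the full outer-training rows
with that prefix, and the held-out fold is scored. Held-out rows never
influence selection, discretization statistics, or rescaling. Repeating
the whole procedure over several seeded runs and averaging gives the
reported accuracy, macro-F, gene counts and wrapper-evaluation costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_io import LabeledExpressionMatrix, rescale_unit_interval
from .metrics import accuracy, macro_f_score
from .selectors import (
    SelectorConfig,
    choose_best_prefix,
    igis_original,
    igis_plus,
)
from .significance import EffectThresholds
from .wrapper_cv import ClassifierSpec, make_folds, train_and_test

__all__ = [
    "ExperimentConfig",
    "FoldOutcome",
    "RunOutcome",
    "ExperimentReport",
    "run_nested_cv",
    "average_rank",
]

SELECTORS = {"igis+": igis_plus, "igis": igis_original}


@dataclass(frozen=True)
class ExperimentConfig:
    """Nested-CV experiment settings (outer 5-fold, inner 4-fold, 10 runs)."""

    outer_k: int = 5
    inner_k: int = 4
    runs: int = 10
    base_seed: int = 0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    selector: str = "igis+"
    thresholds: EffectThresholds = field(default_factory=EffectThresholds)
    alpha: float = 0.1
    selector_config: SelectorConfig = field(default_factory=SelectorConfig)

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.selector not in SELECTORS:
            raise ValueError(
                f"unknown selector {self.selector!r}; choose from {sorted(SELECTORS)}"
            )

    def run_seed(self, run: int) -> int:
        return (self.base_seed + run) % (2**31)


@dataclass
class FoldOutcome:
    run: int
    fold: int
    test_accuracy: float
    test_macro_f: float
    genes_used: list[str]
    selected_count: int
    wrapper_evaluations: int
    stop_reason: str


@dataclass
class RunOutcome:
    run: int
    seed: int
    folds: list[FoldOutcome]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.test_accuracy for f in self.folds]))

    @property
    def mean_macro_f(self) -> float:
        return float(np.mean([f.test_macro_f for f in self.folds]))


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    runs: list[RunOutcome]

    def _all_folds(self) -> list[FoldOutcome]:
        return [f for r in self.runs for f in r.folds]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.mean_accuracy for r in self.runs]))

    @property
    def mean_macro_f(self) -> float:
        return float(np.mean([r.mean_macro_f for r in self.runs]))

    @property
    def mean_selected_genes(self) -> float:
        return float(np.mean([f.selected_count for f in self._all_folds()]))

    @property
    def total_wrapper_evaluations(self) -> int:
        return int(sum(f.wrapper_evaluations for f in self._all_folds()))

    @property
    def mean_wrapper_evaluations(self) -> float:
        """Average wrapper evaluations per run (summed over outer folds)."""
        return float(
            np.mean([sum(f.wrapper_evaluations for f in r.folds) for r in self.runs])
        )

    def summary(self) -> str:
        lines = [
            f"selector: {self.config.selector}   classifier: {self.config.classifier.name}",
            f"runs: {len(self.runs)}   outer folds: {self.config.outer_k}   "
            f"inner folds: {self.config.inner_k}",
            f"mean test accuracy: {100 * self.mean_accuracy:.2f}%",
            f"mean macro F-score: {self.mean_macro_f:.3f}",
            f"mean genes selected (per outer fold): {self.mean_selected_genes:.1f}",
            f"mean wrapper evaluations (per run): {self.mean_wrapper_evaluations:.1f}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "run\tseed\tfold\ttest_accuracy\ttest_macro_f\tselected_count\t"
                "wrapper_evaluations\tstop_reason\tgenes\n"
            )
            for r in self.runs:
                for f in r.folds:
                    fh.write(
                        f"{r.run}\t{r.seed}\t{f.fold}\t{f.test_accuracy:.6f}\t"
                        f"{f.test_macro_f:.6f}\t{f.selected_count}\t"
                        f"{f.wrapper_evaluations}\t{f.stop_reason}\t"
                        f"{','.join(f.genes_used)}\n"
                    )


def _run_selector(config: ExperimentConfig, train, folds):
    if config.selector == "igis+":
        return igis_plus(
            train,
            None,
            config.classifier,
            folds,
            thresholds=config.thresholds,
            config=config.selector_config,
        )
    return igis_original(
        train,
        None,
        config.classifier,
        folds,
        alpha=config.alpha,
        config=config.selector_config,
    )


def run_nested_cv(
    data: LabeledExpressionMatrix, config: ExperimentConfig
) -> ExperimentReport:
    """Full nested-CV assessment of a selector on one dataset."""
    runs: list[RunOutcome] = []
    for run in range(config.runs):
        seed = config.run_seed(run)
        outer = make_folds(data.labels, config.outer_k, seed=seed)
        fold_outcomes: list[FoldOutcome] = []
        for fold in range(config.outer_k):
            train_rows = outer.complement_rows(fold)
            test_rows = outer.fold_rows(fold)
            # selection sees only the training rows; rescaling statistics are
            # train-only and applied as an affine map to the held-out rows
            scaled = rescale_unit_interval(data, stats_rows=train_rows)
            train = scaled.subset_rows(train_rows)
            inner_seed = (seed * 31 + fold + 1) % (2**31)
            inner = make_folds(train.labels, config.inner_k, seed=inner_seed)
            result = _run_selector(config, train, inner)
            prefix = choose_best_prefix(result)
            y_pred = train_and_test(
                scaled, prefix, config.classifier, train_rows, test_rows, seed=seed
            )
            y_test = scaled.labels[test_rows]
            fold_outcomes.append(
                FoldOutcome(
                    run=run,
                    fold=fold,
                    test_accuracy=accuracy(y_test, y_pred),
                    test_macro_f=macro_f_score(y_test, y_pred),
                    genes_used=[data.gene_ids[g] for g in prefix],
                    selected_count=len(prefix),
                    wrapper_evaluations=result.wrapper_evaluations,
                    stop_reason=result.stop_reason,
                )
            )
        runs.append(RunOutcome(run=run, seed=seed, folds=fold_outcomes))
    return ExperimentReport(config=config, runs=runs)


def average_rank(
    values: dict[str, list[float]], higher_is_better: bool = True
) -> dict[str, float]:
    """Mean rank of each algorithm across datasets (1 = best; ties share ranks).

    ``values`` maps algorithm name -> one value per dataset; all algorithms
    must cover the same datasets.
    """
    names = sorted(values)
    if len(names) < 2:
        raise ValueError("need at least two algorithms to rank")
    lengths = {len(values[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("all algorithms must be scored on the same datasets")
    (n_datasets,) = lengths
    table = np.array([values[n] for n in names], dtype=float)
    sign = -1.0 if higher_is_better else 1.0
    ranks = np.vstack(
        [rankdata(sign * table[:, d]) for d in range(n_datasets)]
    ).T
    return {name: float(ranks[i].mean()) for i, name in enumerate(names)}
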