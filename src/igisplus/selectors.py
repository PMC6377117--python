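"""The IGIS+ and original IGIS hybrid filter-wrapper selection algorithms.

Both algorithms grow a gene subset S one gene at a time. A filter step
ranks the remaining candidates by the JMI criterion (individual relevance
plus average interaction information with S, computed on discretized
data); a wrapper step then evaluates S plus the top candidate with k-fold
cross-validation on the raw values and keeps the candidate only if the
accuracy improves enough.

IGIS+ accepts a candidate iff Cohen's d between the new and the best
per-fold accuracy vectors reaches a medium effect (>= 0.40) on the training
rates and a small effect (>= 0.15) on the validation rates; a rejected
candidate is simply discarded and the search continues. It terminates when
(a) every gene has been explored, (b) no remaining candidate has a
positive JMI score (all remaining genes are redundant), or (c) the mean
training or validation accuracy reaches 100%.

The original IGIS selects its first gene by mutual information alone,
gates additions with paired t-tests at the 0.1 level (right-tailed on
training rates), and stops outright the first time a provisionally
accepted candidate significantly decreases the validation rates
(left-tailed test) -- the early-stopping behaviour IGIS+ removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import LabeledExpressionMatrix, discretize
from .info_theory import JmiRanker, JmiScore, mutual_information
from .significance import EffectThresholds, paired_t_test, passes_gate
from .wrapper_cv import (
    ClassifierSpec,
    FoldPlan,
    WrapperEvaluation,
    build_classifier,
    cv_accuracies,
)

__all__ = [
    "SelectorConfig",
    "StepRecord",
    "SelectionResult",
    "select_first_gene",
    "igis_plus",
    "igis_original",
    "choose_best_prefix",
]

# plug-in JMI totals are algebraically >= 0; a total within this tolerance of
# zero means every remaining candidate is exactly redundant given S
_JMI_REDUNDANCY_TOL = 1e-12

_PERFECT = 1.0 - 1e-12


@dataclass(frozen=True)
class SelectorConfig:
    """Tunable conventions of the selection loop.

    ddof : degrees-of-freedom convention for the discretization sigma.
    first_gene_method : "resubstitution" fits and scores each single gene on
        the full training rows (the fast default); "cv" uses the mean
        cross-validated validation accuracy instead.
    """

    ddof: int = 1
    first_gene_method: str = "resubstitution"


@dataclass
class StepRecord:
    """One audit-trail entry: a candidate (or the first gene) and its fate."""

    gene: int
    gene_id: str
    score: JmiScore | None
    train_acc: np.ndarray | None
    val_acc: np.ndarray | None
    accepted: bool
    reason: str


@dataclass
class SelectionResult:
    """Ordered selected genes plus the full decision trace of one run."""

    selected: list[int]
    step_log: list[StepRecord]
    stop_reason: str
    wrapper_evaluations: int
    best_train_acc: np.ndarray
    best_val_acc: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def accepted_steps(self) -> list[StepRecord]:
        return [s for s in self.step_log if s.accepted]

    def write_trace(self, path: str) -> None:
        """Dump the per-candidate decision log as tab-delimited text."""
        with open(path, "w") as fh:
            fh.write(
                "gene\tgene_id\trelevance\tmean_interaction\tjmi_total\t"
                "train_acc\tval_acc\taccepted\treason\n"
            )
            for s in self.step_log:
                sc = s.score
                fh.write(
                    "\t".join(
                        [
                            str(s.gene),
                            s.gene_id,
                            f"{sc.relevance:.6f}" if sc else "",
                            f"{sc.mean_interaction:.6f}" if sc else "",
                            f"{sc.total:.6f}" if sc else "",
                            ",".join(f"{a:.4f}" for a in s.train_acc)
                            if s.train_acc is not None
                            else "",
                            ",".join(f"{a:.4f}" for a in s.val_acc)
                            if s.val_acc is not None
                            else "",
                            str(int(s.accepted)),
                            s.reason,
                        ]
                    )
                    + "\n"
                )


def _training_view(
    data: LabeledExpressionMatrix, rows: np.ndarray | None
) -> LabeledExpressionMatrix:
    if rows is None:
        return data
    return data.subset_rows(np.asarray(rows))


def select_first_gene(
    data: LabeledExpressionMatrix,
    rows: np.ndarray | None,
    clf: ClassifierSpec,
    *,
    folds: FoldPlan | None = None,
    config: SelectorConfig = SelectorConfig(),
) -> int:
    """The gene whose single-gene classifier scores highest on the training rows.

    With the default resubstitution method each gene's classifier is fitted
    and evaluated on all training rows. Ties are broken by the larger mutual
    information with the class (on discretized values), then by the smaller
    gene index.
    """
    train = _training_view(data, rows)
    accs = _single_gene_accuracies(train, clf, folds=folds, config=config)
    best = accs.max()
    tied = np.flatnonzero(accs >= best - 1e-12)
    if tied.size == 1:
        return int(tied[0])
    states = discretize(train, ddof=config.ddof).states
    mis = np.array(
        [mutual_information(states[:, g], train.labels) for g in tied]
    )
    # first occurrence of the max MI among the (ascending) tied indices
    return int(tied[int(np.argmax(mis))])


def _single_gene_accuracies(
    train: LabeledExpressionMatrix,
    clf: ClassifierSpec,
    *,
    folds: FoldPlan | None,
    config: SelectorConfig,
) -> np.ndarray:
    y = train.labels
    n = train.n_genes
    accs = np.empty(n)
    if config.first_gene_method == "resubstitution":
        for g in range(n):
            model = build_classifier(clf, seed=folds.seed if folds else 0)
            col = train.values[:, [g]]
            model.fit(col, y)
            accs[g] = float(np.mean(model.predict(col) == y))
    elif config.first_gene_method == "cv":
        if folds is None:
            raise ValueError("first_gene_method='cv' requires a fold plan")
        for g in range(n):
            accs[g] = cv_accuracies(train, [g], clf, folds).val_acc.mean()
    else:
        raise ValueError(f"unknown first_gene_method {config.first_gene_method!r}")
    return accs


def _initialize(
    data: LabeledExpressionMatrix,
    rows: np.ndarray | None,
    clf: ClassifierSpec,
    folds: FoldPlan,
    config: SelectorConfig,
    first_gene: int,
) -> tuple[LabeledExpressionMatrix, JmiRanker, list[StepRecord], WrapperEvaluation]:
    train = _training_view(data, rows)
    if folds.assignments.shape[0] != train.n_samples:
        raise ValueError(
            "fold plan does not match the training rows "
            f"({folds.assignments.shape[0]} assignments for {train.n_samples} rows)"
        )
    states = discretize(train, ddof=config.ddof).states
    ranker = JmiRanker(states, train.labels)
    ranker.remove(first_gene)
    ranker.add_selected(first_gene)
    ev = cv_accuracies(train, [first_gene], clf, folds)
    log = [
        StepRecord(
            gene=first_gene,
            gene_id=train.gene_ids[first_gene],
            score=None,
            train_acc=ev.train_acc,
            val_acc=ev.val_acc,
            accepted=True,
            reason="first_gene",
        )
    ]
    return train, ranker, log, ev


def igis_plus(
    data: LabeledExpressionMatrix,
    rows: np.ndarray | None,
    clf: ClassifierSpec,
    folds: FoldPlan,
    thresholds: EffectThresholds = EffectThresholds(),
    config: SelectorConfig = SelectorConfig(),
) -> SelectionResult:
    """Run the improved selection algorithm on the given training rows.

    Parameters
    ----------
    data : LabeledExpressionMatrix
        Rescaled expression data; discretization for the filter happens
        internally on the training rows only.
    rows : array of sample indices or None
        Training rows (None = all rows). Held-out rows are never touched.
    clf : ClassifierSpec
        Wrapper classifier ("knn" with K=3 or "cart").
    folds : FoldPlan
        Fixed inner fold plan over the training rows, reused for every
        candidate so accuracy vectors stay fold-aligned.
    thresholds : EffectThresholds
        Cohen's d effect-size levels (defaults 0.15 / 0.40 / 0.75).
    """
    first = select_first_gene(data, rows, clf, folds=folds, config=config)
    train, ranker, log, ev = _initialize(data, rows, clf, folds, config, first)
    selected = [first]
    best_train, best_val = ev.train_acc, ev.val_acc
    evaluations = 1
    stop_reason = None

    if best_train.mean() >= _PERFECT or best_val.mean() >= _PERFECT:
        stop_reason = "perfect_accuracy"
    elif ranker.n_remaining == 0:
        stop_reason = "candidates_empty"

    while stop_reason is None:
        pick = ranker.best()
        if pick is None:
            stop_reason = "exhausted_all_genes"
            break
        gene, score = pick
        if score.total <= _JMI_REDUNDANCY_TOL:
            # every remaining candidate is (at best) exactly redundant given S
            stop_reason = "all_jmi_negative"
            break
        ranker.remove(gene)
        ev = cv_accuracies(train, selected + [gene], clf, folds)
        evaluations += 1
        train_ok = passes_gate(ev.train_acc, best_train, "medium", thresholds)
        if not train_ok:
            log.append(
                StepRecord(
                    gene=gene,
                    gene_id=train.gene_ids[gene],
                    score=score,
                    train_acc=ev.train_acc,
                    val_acc=None,
                    accepted=False,
                    reason="train_gate_failed",
                )
            )
            continue
        val_ok = passes_gate(ev.val_acc, best_val, "small", thresholds)
        if not val_ok:
            log.append(
                StepRecord(
                    gene=gene,
                    gene_id=train.gene_ids[gene],
                    score=score,
                    train_acc=ev.train_acc,
                    val_acc=ev.val_acc,
                    accepted=False,
                    reason="val_gate_failed",
                )
            )
            continue
        selected.append(gene)
        best_train, best_val = ev.train_acc, ev.val_acc
        ranker.add_selected(gene)
        log.append(
            StepRecord(
                gene=gene,
                gene_id=train.gene_ids[gene],
                score=score,
                train_acc=ev.train_acc,
                val_acc=ev.val_acc,
                accepted=True,
                reason="accepted",
            )
        )
        if best_train.mean() >= _PERFECT or best_val.mean() >= _PERFECT:
            stop_reason = "perfect_accuracy"

    return SelectionResult(
        selected=selected,
        step_log=log,
        stop_reason=stop_reason,
        wrapper_evaluations=evaluations,
        best_train_acc=best_train,
        best_val_acc=best_val,
        gene_ids=[train.gene_ids[g] for g in selected],
    )


def igis_original(
    data: LabeledExpressionMatrix,
    rows: np.ndarray | None,
    clf: ClassifierSpec,
    folds: FoldPlan,
    alpha: float = 0.1,
    config: SelectorConfig = SelectorConfig(),
) -> SelectionResult:
    """Run the predecessor algorithm (t-test gates, early stopping).

    The first gene maximizes I(X; C) (ties to the smaller index). A
    candidate is provisionally accepted when the right-tailed paired t-test
    on training accuracies is significant at ``alpha``; it is then kept
    unless the left-tailed paired t-test shows a significant validation
    decrease, in which case the whole search terminates (``igis_early_stop``).
    """
    train = _training_view(data, rows)
    states = discretize(train, ddof=config.ddof).states
    mis = np.array(
        [mutual_information(states[:, g], train.labels) for g in range(train.n_genes)]
    )
    first = int(np.argmax(mis))  # first max = smallest index on ties

    _, ranker, log, ev = _initialize(data, rows, clf, folds, config, first)
    selected = [first]
    best_train, best_val = ev.train_acc, ev.val_acc
    evaluations = 1
    stop_reason = None
    if ranker.n_remaining == 0:
        stop_reason = "candidates_empty"

    while stop_reason is None:
        pick = ranker.best()
        if pick is None:
            stop_reason = "exhausted_all_genes"
            break
        gene, score = pick
        ranker.remove(gene)
        ev = cv_accuracies(train, selected + [gene], clf, folds)
        evaluations += 1
        p_train = paired_t_test(ev.train_acc, best_train, "right")
        if p_train >= alpha:
            log.append(
                StepRecord(
                    gene=gene,
                    gene_id=train.gene_ids[gene],
                    score=score,
                    train_acc=ev.train_acc,
                    val_acc=None,
                    accepted=False,
                    reason="train_t_test_not_significant",
                )
            )
            continue
        p_val = paired_t_test(ev.val_acc, best_val, "left")
        if p_val < alpha:
            # significant validation decrease: terminate the whole search
            log.append(
                StepRecord(
                    gene=gene,
                    gene_id=train.gene_ids[gene],
                    score=score,
                    train_acc=ev.train_acc,
                    val_acc=ev.val_acc,
                    accepted=False,
                    reason="validation_decrease",
                )
            )
            stop_reason = "igis_early_stop"
            break
        selected.append(gene)
        best_train, best_val = ev.train_acc, ev.val_acc
        ranker.add_selected(gene)
        log.append(
            StepRecord(
                gene=gene,
                gene_id=train.gene_ids[gene],
                score=score,
                train_acc=ev.train_acc,
                val_acc=ev.val_acc,
                accepted=True,
                reason="accepted",
            )
        )

    return SelectionResult(
        selected=selected,
        step_log=log,
        stop_reason=stop_reason,
        wrapper_evaluations=evaluations,
        best_train_acc=best_train,
        best_val_acc=best_val,
        gene_ids=[train.gene_ids[g] for g in selected],
    )


def choose_best_prefix(result: SelectionResult) -> list[int]:
    """The prefix of the selected genes with the best mean validation accuracy.

    Genes are considered in acceptance order; ties go to the shorter prefix
    (fewer genes).
    """
    accepted = result.accepted_steps()
    if len(accepted) != len(result.selected):
        raise ValueError("step log does not cover every accepted gene")
    means = np.array([s.val_acc.mean() for s in accepted])
    best_len = int(np.argmax(means)) + 1  # first max = shortest prefix
    return result.selected[:best_len]
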