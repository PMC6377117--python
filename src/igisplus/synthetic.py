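"""Synthetic expression matrices with known ground truth.

Emulates the shape of microarray classification problems -- few samples,
many genes, 2-5 possibly imbalanced classes -- with a handful of planted
discriminative genes hidden among label-independent Gaussian noise genes:

* ``informative`` genes have class-conditional Gaussian means separated by
  a stated effect size (in units of the within-class SD);
* ``xor_pair`` genes (binary problems only) realize pure two-gene synergy:
  two latent bits whose XOR is the class, each gene being its bit plus
  Gaussian noise, so each gene alone is nearly independent of the class
  while the pair is strongly predictive;
* ``redundant_of`` genes are noisy copies of another planted gene;
* everything else is label-independent standard-normal noise.

The finished matrix is min-max rescaled to [0, 1] per gene, like real
preprocessed expression data.

A note on the XOR bits: they are drawn with probability ``xor_bit_prob``
(default 0.4) rather than 0.5. With exactly equiprobable bits the two value
clusters of each gene sit precisely at the mu +/- sigma discretization
thresholds, so half of each cluster lands in the ambiguous middle state and
the discretized pair interaction saturates near 0.25 bits. Nudging the bit
probability moves the clusters off the thresholds, preserving the synergy
through discretization (interaction information ~0.5 bits) while keeping
each gene's individual mutual information with the class below 0.05 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import LabeledExpressionMatrix, rescale_unit_interval
from .selectors import SelectionResult
from .wrapper_cv import make_folds

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "parameter_recovery_suite",
    "RecoveryStats",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    n_samples, n_genes : int
        Matrix shape (desk-scale defaults; real microarray data runs to
        tens of thousands of genes, which is configurable but slow).
    n_classes : int
        2-5 classes.
    class_proportions : tuple of float, optional
        Class prevalences (sum to 1); uniform when omitted.
    informative : mapping gene index -> effect size
        Class-conditional mean separation in SD units for each planted
        individually-informative gene.
    xor_pairs : sequence of (gene index, gene index)
        Planted synergistic pairs (binary problems only).
    xor_noise_sd : float
        SD of the Gaussian noise added to each XOR gene's latent bit.
    xor_bit_prob : float
        Marginal probability of the latent bit being 1 (see module note).
    redundant : mapping gene index -> (source gene index, noise SD)
        Noisy copies of other planted genes.
    seed : int
        Generator seed; identical specs yield identical matrices.
    """

    n_samples: int = 100
    n_genes: int = 200
    n_classes: int = 2
    class_proportions: tuple[float, ...] | None = None
    informative: dict[int, float] = field(default_factory=dict)
    xor_pairs: tuple[tuple[int, int], ...] = ()
    xor_noise_sd: float = 0.1
    xor_bit_prob: float = 0.4
    redundant: dict[int, tuple[int, float]] = field(default_factory=dict)
    seed: int = 0

    def planted_indices(self) -> list[int]:
        idx = list(self.informative)
        for a, b in self.xor_pairs:
            idx += [a, b]
        idx += list(self.redundant)
        return idx

    def __post_init__(self) -> None:
        idx = self.planted_indices()
        if len(idx) != len(set(idx)):
            raise ValueError("planted gene indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_genes):
            raise ValueError("planted gene indices must lie in [0, n_genes)")
        if self.xor_pairs and self.n_classes != 2:
            raise ValueError("xor_pair genes require a binary class")
        if self.class_proportions is not None:
            if len(self.class_proportions) != self.n_classes:
                raise ValueError("one proportion per class required")
            if abs(sum(self.class_proportions) - 1.0) > 1e-9:
                raise ValueError("class proportions must sum to 1")


@dataclass
class GroundTruth:
    """Per-gene roles and the minimal truly-relevant gene set."""

    roles: list[str]
    relevant: list[int]


def _assign_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    props = (
        np.full(spec.n_classes, 1.0 / spec.n_classes)
        if spec.class_proportions is None
        else np.asarray(spec.class_proportions)
    )
    # largest-remainder apportionment keeps class sizes deterministic
    raw = props * spec.n_samples
    counts = np.floor(raw).astype(int)
    rem = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples; increase n_samples")
    labels = np.repeat(np.arange(spec.n_classes), counts)
    return labels[rng.permutation(spec.n_samples)]


def _xor_bits(
    labels: np.ndarray, q: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent bits (b1, b2) with XOR(b1, b2) = label and P(bit = 1) close to q."""
    m = labels.shape[0]
    b1 = np.empty(m, dtype=int)
    pos = labels == 1
    # label 1: (0,1) or (1,0), equally likely for independent bits
    b1[pos] = rng.random(pos.sum()) < 0.5
    # label 0: (1,1) with probability q^2 / (q^2 + (1-q)^2), else (0,0)
    p11 = q * q / (q * q + (1 - q) * (1 - q))
    b1[~pos] = rng.random((~pos).sum()) < p11
    b2 = np.where(pos, 1 - b1, b1)
    return b1, b2


def generate(spec: SyntheticSpec) -> tuple[LabeledExpressionMatrix, GroundTruth]:
    """Draw one dataset from the recipe; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    labels = _assign_labels(spec, rng)
    values = rng.standard_normal((spec.n_samples, spec.n_genes))
    roles = ["noise"] * spec.n_genes

    for g, effect in spec.informative.items():
        values[:, g] = labels * float(effect) + rng.standard_normal(spec.n_samples)
        roles[g] = "informative"

    for a, b in spec.xor_pairs:
        b1, b2 = _xor_bits(labels, spec.xor_bit_prob, rng)
        values[:, a] = b1 + rng.normal(0.0, spec.xor_noise_sd, spec.n_samples)
        values[:, b] = b2 + rng.normal(0.0, spec.xor_noise_sd, spec.n_samples)
        roles[a] = roles[b] = "xor_pair"

    for g, (source, sd) in spec.redundant.items():
        values[:, g] = values[:, source] + rng.normal(0.0, sd, spec.n_samples)
        roles[g] = f"redundant_of_{source}"

    data = LabeledExpressionMatrix(
        values=values,
        gene_ids=[f"g{j}" for j in range(spec.n_genes)],
        labels=labels,
    )
    data = rescale_unit_interval(data)
    relevant = sorted(
        set(spec.informative) | {g for pair in spec.xor_pairs for g in pair}
    )
    return data, GroundTruth(roles=roles, relevant=relevant)


@dataclass
class RecoveryStats:
    """Ground-truth recovery summary across seeded runs of a selector."""

    n_runs: int
    recovered: int
    precisions: list[float]
    results: list[SelectionResult]

    @property
    def recovery_fraction(self) -> float:
        return self.recovered / self.n_runs if self.n_runs else 0.0

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions)) if self.precisions else 0.0


def parameter_recovery_suite(
    selector,
    spec: SyntheticSpec,
    seeds: list[int],
    clf,
    *,
    inner_k: int = 4,
) -> RecoveryStats:
    """Run a selector across seeded datasets and score ground-truth recovery.

    For each seed the spec is re-seeded, a dataset generated, an inner fold
    plan built, and ``selector(data, None, clf, folds)`` run. A run counts
    as recovered when the selected set contains every truly-relevant gene;
    precision is the fraction of selected genes that are truly relevant.
    """
    recovered = 0
    precisions: list[float] = []
    results: list[SelectionResult] = []
    for seed in seeds:
        data, truth = generate(replace(spec, seed=int(seed)))
        folds = make_folds(data.labels, inner_k, seed=int(seed))
        result = selector(data, None, clf, folds)
        results.append(result)
        chosen = set(result.selected)
        if set(truth.relevant) <= chosen:
            recovered += 1
        if truth.relevant:
            precisions.append(
                len(chosen & set(truth.relevant)) / len(chosen) if chosen else 0.0
            )
    return RecoveryStats(
        n_runs=len(seeds),
        recovered=recovered,
        precisions=precisions,
        results=results,
    )
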