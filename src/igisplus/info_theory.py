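"""Plug-in information measures on discrete gene states.

All quantities are in bits (log base 2) and use maximum-likelihood
(empirical-frequency) probability estimates with no smoothing. The
three-way interaction information follows the synergy-positive convention

    II(Xj; Xi; C) = I(Xj; C | Xi) - I(Xj; C),

so a positive value means Xi and Xj are jointly more informative about the
class than Xj alone (synergy, e.g. an XOR pair) and a negative value means
redundancy. The candidate-ranking criterion for a gene Xj given the
selected set S is

    J(Xj) = I(Xj; C) + (1/|S|) * sum_{Xi in S} II(Xj; Xi; C),

the joint-mutual-information (JMI) score: individual relevance plus average
interaction with what has already been selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "entropy",
    "joint_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "JmiScore",
    "jmi_criterion",
    "argmax_jmi",
    "JmiRanker",
]


def _encode(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary discrete values to 0..k-1 integer codes."""
    _, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if codes.size else 0


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(x: np.ndarray) -> float:
    """Shannon entropy H(X) in bits of a discrete sample."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("entropy of an empty sample is undefined")
    _, counts = np.unique(x, return_counts=True)
    return _entropy_from_counts(counts.astype(float))


def joint_entropy(*variables: np.ndarray) -> float:
    """Joint entropy H(X1, ..., Xk) in bits."""
    if not variables:
        raise ValueError("need at least one variable")
    n = len(np.asarray(variables[0]))
    code = np.zeros(n, dtype=np.intp)
    for v in variables:
        v = np.asarray(v)
        if v.shape != (n,):
            raise ValueError("all variables must be 1-D of equal length")
        c, k = _encode(v)
        code = code * k + c
    _, counts = np.unique(code, return_counts=True)
    return _entropy_from_counts(counts.astype(float))


def mutual_information(x: np.ndarray, c: np.ndarray) -> float:
    """I(X; C) = H(X) + H(C) - H(X, C), in bits (non-negative, symmetric)."""
    x, c = np.asarray(x), np.asarray(c)
    if x.shape != c.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {c.shape}")
    return max(0.0, entropy(x) + entropy(c) - joint_entropy(x, c))


def conditional_mutual_information(
    x: np.ndarray, c: np.ndarray, z: np.ndarray
) -> float:
    """I(X; C | Z) = H(X,Z) + H(C,Z) - H(X,C,Z) - H(Z), in bits."""
    return max(
        0.0,
        joint_entropy(x, z) + joint_entropy(c, z) - joint_entropy(x, c, z) - entropy(z),
    )


def interaction_information(
    xj: np.ndarray, xi: np.ndarray, c: np.ndarray
) -> float:
    """Three-way interaction information II(Xj; Xi; C) in bits.

    Synergy-positive: ``I(Xj; C | Xi) - I(Xj; C)``. Symmetric under swapping
    Xj and Xi; may be negative (redundancy).
    """
    xj, xi, c = np.asarray(xj), np.asarray(xi), np.asarray(c)
    if not (xj.shape == xi.shape == c.shape):
        raise ValueError("length mismatch among xj, xi, c")
    return conditional_mutual_information(xj, c, xi) - mutual_information(xj, c)


@dataclass(frozen=True)
class JmiScore:
    """JMI criterion value for one candidate gene.

    ``total = relevance + mean_interaction`` exactly (both in bits).
    """

    gene: int
    relevance: float
    mean_interaction: float

    @property
    def total(self) -> float:
        return self.relevance + self.mean_interaction


def jmi_criterion(
    xj: int,
    selected: list[int],
    states: np.ndarray,
    c: np.ndarray,
) -> JmiScore:
    """Score candidate gene ``xj`` against the selected set on discretized data.

    Parameters
    ----------
    xj : int
        Candidate gene column index (must not be in ``selected``).
    selected : list of int
        Non-empty list of already-selected gene column indices.
    states : ndarray, shape (M, N)
        Discretized matrix (entries in {-1, 0, +1}).
    c : ndarray, shape (M,)
        Class labels.
    """
    if len(selected) == 0:
        raise ValueError("JMI criterion is undefined for an empty selected set")
    if xj in selected:
        raise ValueError(f"candidate {xj} already selected")
    rel = mutual_information(states[:, xj], c)
    inter = np.mean(
        [interaction_information(states[:, xj], states[:, xi], c) for xi in selected]
    )
    return JmiScore(gene=int(xj), relevance=rel, mean_interaction=float(inter))


def argmax_jmi(
    candidates: list[int] | np.ndarray,
    selected: list[int],
    states: np.ndarray,
    c: np.ndarray,
) -> tuple[int, JmiScore]:
    """The candidate with the largest JMI total; ties go to the smallest index."""
    candidates = sorted(int(g) for g in candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    if set(candidates) & set(selected):
        raise ValueError("candidates must be disjoint from the selected set")
    best: JmiScore | None = None
    for g in candidates:
        score = jmi_criterion(g, selected, states, c)
        if best is None or score.total > best.total:
            best = score
    assert best is not None
    return best.gene, best


class JmiRanker:
    """Incremental JMI bookkeeping for the selection loop.

    Relevance I(Xj; C) is computed once per gene; the running interaction sum
    sum_{Xi in S} II(Xj; Xi; C) is updated for all remaining candidates only
    when a gene is accepted into S, so one selection run costs
    O(N * |S|) interaction evaluations rather than O(N^2).
    """

    def __init__(self, states: np.ndarray, labels: np.ndarray) -> None:
        self.states = np.asarray(states)
        self._m, self._n = self.states.shape
        self._c_codes, self._nc = _encode(labels)
        # states are in {-1,0,+1}; shift to 0..2 for bincount encoding
        self._s_codes = (self.states.astype(np.intp) + 1)
        self._h_c = entropy(labels)
        self.relevance = np.array(
            [mutual_information(self.states[:, j], labels) for j in range(self._n)]
        )
        self._interaction_sum = np.zeros(self._n)
        self._n_selected = 0
        self.remaining = np.ones(self._n, dtype=bool)
        self.labels = np.asarray(labels)

    def remove(self, gene: int) -> None:
        self.remaining[gene] = False

    def add_selected(self, gene: int) -> None:
        """Register an accepted gene: update every remaining candidate's sum."""
        xi = self._s_codes[:, gene]
        c = self._c_codes
        # H(Xi), H(Xi,C) shared across candidates
        h_xi = _entropy_from_counts(np.bincount(xi, minlength=3).astype(float))
        h_xic = _entropy_from_counts(
            np.bincount(xi * self._nc + c, minlength=3 * self._nc).astype(float)
        )
        idx = np.flatnonzero(self.remaining)
        for j in idx:
            xj = self._s_codes[:, j]
            h_xj_xi = _entropy_from_counts(
                np.bincount(xj * 3 + xi, minlength=9).astype(float)
            )
            h_xj_xi_c = _entropy_from_counts(
                np.bincount((xj * 3 + xi) * self._nc + c).astype(float)
            )
            cond_mi = max(0.0, h_xj_xi + h_xic - h_xj_xi_c - h_xi)
            self._interaction_sum[j] += cond_mi - self.relevance[j]
        self._n_selected += 1

    def score(self, gene: int) -> JmiScore:
        if self._n_selected == 0:
            raise ValueError("no selected genes yet; JMI is undefined")
        return JmiScore(
            gene=int(gene),
            relevance=float(self.relevance[gene]),
            mean_interaction=float(self._interaction_sum[gene] / self._n_selected),
        )

    def best(self) -> tuple[int, JmiScore] | None:
        """Highest-total remaining candidate (smallest index on ties), or None."""
        idx = np.flatnonzero(self.remaining)
        if idx.size == 0:
            return None
        totals = self.relevance[idx] + self._interaction_sum[idx] / self._n_selected
        j = idx[int(np.argmax(totals))]  # argmax returns the first (smallest) index
        return int(j), self.score(int(j))

    @property
    def n_remaining(self) -> int:
        return int(self.remaining.sum())
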