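"""AHP-TOPSIS composite weighting and comprehensive-value ranking.

Candidate compounds are scored against several receptor-protein criteria
(docking scores).  Each criterion is tagged *positive* (a larger raw score
is better: herbicidal function, degradability) or *negative* (a larger raw
score is worse: toxicity).  Subjective criterion weights come from an AHP
pairwise-judgment matrix; objective weights come from a TOPSIS-style
relative-error-cosine construction; the two are fused by a minimum-entropy
compound weighting.  The weighted sum of min-max-normalized scores is the
*comprehensive value* (CV) used to rank the candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoreMatrix", "NormalizedMatrix", "BestWorstVectors",
    "RelativeErrorMatrices", "CriterionCosines", "WeightVector",
    "PairwiseMatrix", "CompositeRanking",
    "ahp_weights", "normalize_scores", "best_worst_vectors",
    "relative_error_cosines", "objective_weights", "compound_weights",
    "composite_value", "percent_vs_reference",
]

POSITIVE = "positive"
NEGATIVE = "negative"

# Saaty random-consistency indices, indexed by matrix order.
_SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
             7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}


@dataclass
class ScoreMatrix:
    """Raw docking scores, compounds x criteria.

    ``indicator_types[j]`` is ``"positive"`` or ``"negative"`` and decides
    the normalization direction for criterion ``j``.
    """

    compound_ids: list[str]
    criterion_ids: list[str]
    indicator_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.compound_ids):
            raise ValueError("row count does not match compound_ids")
        if m != len(self.criterion_ids):
            raise ValueError("column count does not match criterion_ids")
        if len(self.indicator_types) != m:
            raise ValueError("indicator_types length must equal criterion count")
        for t in self.indicator_types:
            if t not in (POSITIVE, NEGATIVE):
                raise ValueError(f"unknown indicator type {t!r}")
        if n < 2:
            raise ValueError("need at least 2 compounds")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains missing or non-finite entries")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix:
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)


@dataclass
class BestWorstVectors:
    best: np.ndarray   # a_j+ : ideal value per criterion
    worst: np.ndarray  # a_j- : anti-ideal value per criterion


@dataclass
class RelativeErrorMatrices:
    positive: np.ndarray  # r_ij+ = (X_ij - a_j+) / column range
    negative: np.ndarray  # r_ij- = (X_ij - a_j-) / column range


@dataclass
class CriterionCosines:
    theta: np.ndarray
    theta_abs: np.ndarray


@dataclass
class WeightVector:
    """Nonnegative criterion weights summing to one.

    ``kind`` records the provenance: subjective AHP weights (``"W1"``),
    objective TOPSIS weights (``"W2"``) or fused compound weights (``"w"``).
    """

    kind: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")


@dataclass
class PairwiseMatrix:
    """Square positive reciprocal matrix of criterion-importance ratios."""

    judgments: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.judgments, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("judgment matrix must be square")
        if np.any(a <= 0):
            raise ValueError("judgment matrix must be strictly positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise ValueError("judgment matrix must be reciprocal (a_ji = 1/a_ij)")
        self.judgments = a

    @property
    def order(self) -> int:
        return self.judgments.shape[0]


@dataclass
class CompositeRanking:
    compound_ids: list[str]
    cv: np.ndarray
    rank: np.ndarray  # 1 = best; permutation of 1..n

    def ordered(self) -> list[tuple[str, float, int]]:
        """(compound_id, cv, rank) triples sorted best-first."""
        order = np.argsort(self.rank)
        return [(self.compound_ids[i], float(self.cv[i]), int(self.rank[i]))
                for i in order]


def ahp_weights(pairwise: PairwiseMatrix) -> tuple[WeightVector, float]:
    """Subjective weights W1 from the principal eigenvector of an AHP matrix.

    Returns the normalized principal right eigenvector and the Saaty
    consistency ratio CR = ((lambda_max - n)/(n - 1)) / RI(n).  CR is
    reported, not enforced; a warning is emitted above 0.10.
    """
    a = pairwise.judgments
    n = pairwise.order
    if n == 1:
        return WeightVector("W1", np.array([1.0])), 0.0
    eigvals, eigvecs = np.linalg.eig(a)
    k = int(np.argmax(eigvals.real))
    lam = float(eigvals[k].real)
    v = np.abs(eigvecs[:, k].real)
    w = v / v.sum()
    if n == 2:
        cr = 0.0
    else:
        ri = _SAATY_RI.get(n)
        if ri is None:
            raise ValueError(f"no Saaty RI tabulated for order {n}")
        ci = (lam - n) / (n - 1)
        cr = max(ci / ri, 0.0)  # guard tiny negative eigenvalue noise
    if cr > 0.10:
        warnings.warn(f"AHP consistency ratio {cr:.3f} exceeds 0.10", stacklevel=2)
    return WeightVector("W1", w), cr


def _column_ranges(scores: ScoreMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = scores.values.min(axis=0)
    hi = scores.values.max(axis=0)
    rng = hi - lo
    for j, r in enumerate(rng):
        if r <= 0:
            raise ValueError(
                f"criterion {scores.criterion_ids[j]!r} is constant (zero range)")
    return lo, hi, rng


def normalize_scores(scores: ScoreMatrix) -> NormalizedMatrix:
    """Min-max normalize each criterion so that larger always means better.

    Positive criteria use (X - min)/(max - min); negative criteria use
    (max - X)/(max - min).
    """
    lo, hi, rng = _column_ranges(scores)
    z = np.empty_like(scores.values)
    prov = []
    for j, tag in enumerate(scores.indicator_types):
        col = scores.values[:, j]
        if tag == POSITIVE:
            z[:, j] = (col - lo[j]) / rng[j]
            prov.append(f"{scores.criterion_ids[j]}: positive, (X-min)/(max-min)")
        else:
            z[:, j] = (hi[j] - col) / rng[j]
            prov.append(f"{scores.criterion_ids[j]}: negative, (max-X)/(max-min)")
    return NormalizedMatrix(values=z, provenance=prov)


def best_worst_vectors(scores: ScoreMatrix) -> BestWorstVectors:
    """Ideal (best) and anti-ideal (worst) raw value per criterion.

    Best = column max for positive criteria, column min for negative;
    worst is the complement.
    """
    lo, hi, _ = _column_ranges(scores)
    pos = np.array([t == POSITIVE for t in scores.indicator_types])
    best = np.where(pos, hi, lo)
    worst = np.where(pos, lo, hi)
    return BestWorstVectors(best=best, worst=worst)


def relative_error_cosines(
    scores: ScoreMatrix, bw: BestWorstVectors | None = None
) -> tuple[RelativeErrorMatrices, CriterionCosines]:
    """Relative-error matrices against the ideal/anti-ideal and their angle.

    r_ij+ = (X_ij - a_j+)/range_j and r_ij- = (X_ij - a_j-)/range_j; the
    per-criterion cosine theta_j is the angle between the two error columns,
    summed over compounds.  Both the raw (possibly negative) cosine and its
    absolute value are returned.
    """
    if bw is None:
        bw = best_worst_vectors(scores)
    _, _, rng = _column_ranges(scores)
    rpos = (scores.values - bw.best) / rng
    rneg = (scores.values - bw.worst) / rng
    theta = np.empty(scores.n_criteria)
    for j in range(scores.n_criteria):
        np_pos = np.linalg.norm(rpos[:, j])
        np_neg = np.linalg.norm(rneg[:, j])
        if np_pos == 0 or np_neg == 0:
            raise ValueError(
                f"criterion {scores.criterion_ids[j]!r}: all compounds sit at an "
                "extreme, relative-error cosine undefined")
        theta[j] = float(rpos[:, j] @ rneg[:, j]) / (np_pos * np_neg)
    return (RelativeErrorMatrices(positive=rpos, negative=rneg),
            CriterionCosines(theta=theta, theta_abs=np.abs(theta)))


def objective_weights(cosines: CriterionCosines) -> WeightVector:
    """Objective TOPSIS weights W2(j) = |theta_j| / sum_j |theta_j|."""
    t = cosines.theta_abs
    s = t.sum()
    if s == 0:
        raise ValueError("all relative-error cosines are zero: no objective signal")
    if np.any(t == 0):
        raise ValueError("zero cosine for some criterion: objective weight would vanish")
    return WeightVector("W2", t / s)


def compound_weights(
    w1: WeightVector, w2: WeightVector, mode: str = "printed-product"
) -> WeightVector:
    """Fuse subjective and objective weights by the minimum-entropy principle.

    ``printed-product`` computes w(j) = W1(j)W2(j) / sum W1(j)W2(j).
    ``entropy-sqrt`` computes the Lagrange minimizer of
    F(w) = sum_j w_j ln(w_j/W1_j) + sum_j w_j ln(w_j/W2_j) on the simplex,
    namely w(j) proportional to sqrt(W1(j) W2(j)).  The product form is the
    default; both are provided because the two disagree whenever W1 != W2.
    """
    a, b = w1.weights, w2.weights
    if a.shape != b.shape:
        raise ValueError("weight vectors must have the same length")
    if mode == "printed-product":
        p = a * b
    elif mode == "entropy-sqrt":
        p = np.sqrt(a * b)
    else:
        raise ValueError(f"unknown weighting mode {mode!r}")
    return WeightVector("w", p / p.sum())


def composite_value(
    normalized: NormalizedMatrix,
    weights: WeightVector,
    compound_ids: list[str] | None = None,
    renormalize: bool = True,
) -> CompositeRanking:
    """Comprehensive value CV_i = sum_j w(j) Z_ij, ranked descending.

    With ``renormalize`` (default) the CV vector is itself min-max
    normalized across compounds so the best compound scores 1 and the
    worst 0.  Ties are broken by input order (stable sort).
    """
    z = normalized.values
    w = weights.weights
    if z.shape[1] != w.shape[0]:
        raise ValueError("criterion count mismatch between matrix and weights")
    cv = z @ w
    if renormalize:
        rng = cv.max() - cv.min()
        if rng > 0:
            cv = (cv - cv.min()) / rng
    if compound_ids is None:
        compound_ids = [f"C{i+1}" for i in range(z.shape[0])]
    # stable: among equal CVs the earlier input compound ranks better
    order = np.argsort(-cv, kind="stable")
    rank = np.empty(len(cv), dtype=int)
    rank[order] = np.arange(1, len(cv) + 1)
    return CompositeRanking(compound_ids=list(compound_ids), cv=cv, rank=rank)


def percent_vs_reference(cv: CompositeRanking, reference_id: str) -> dict[str, float]:
    """Percent difference of each compound's CV against a reference compound."""
    try:
        ref_idx = cv.compound_ids.index(reference_id)
    except ValueError:
        raise ValueError(f"reference compound {reference_id!r} not found") from None
    ref = cv.cv[ref_idx]
    if ref == 0:
        raise ValueError("reference compound has zero CV")
    return {cid: float(100.0 * (v - ref) / ref)
            for cid, v in zip(cv.compound_ids, cv.cv)}
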