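"""PLS-based QSAR fitting and validation statistics.

Implements a NIPALS PLS1 regression engine, leave-one-out cross-validation
(q²), component selection, internal fit statistics (R², SEE, F), external
prediction (r²_pred with the training-mean denominator), the overfit ratio
100·(R²−q²)/R², pass/fail gates, per-field-block contribution fractions,
and a simplified Gaussian similarity-field descriptor generator.

Conventions follow the classic molecular-field QSAR literature: descriptors
and activity are mean-centered (no autoscaling, since similarity-field
blocks share units), SEE and F use n_train − n − 1 degrees of freedom, and
r²_pred = (SD − PRESS)/SD with SD taken about the training-set mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QsarDataset", "PlsModel", "ModelMetrics", "FieldContributions",
    "FieldGridSpec", "pls_fit", "loo_q2", "select_components",
    "regression_stats", "prediction_r2",
    "internal_metrics", "external_r2pred", "overfit_ratio",
    "acceptance_check", "field_contributions", "similarity_fields",
]


@dataclass
class QsarDataset:
    """Descriptor matrix + activity vector with a train/test split.

    ``block_labels`` assigns each descriptor column to a named field block
    (e.g. hydrophobic ``H``, acceptor ``A``, donor ``D``, electrostatic
    ``E``, steric ``S``); ``split`` tags each compound ``train`` or
    ``test``.
    """

    compound_ids: list[str]
    descriptors: np.ndarray
    activity: np.ndarray
    block_labels: list[str]
    split: list[str]

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        n, p = self.descriptors.shape
        if len(self.compound_ids) != n or len(self.activity) != n:
            raise ValueError("compound count mismatch")
        if len(self.block_labels) != p:
            raise ValueError("block_labels must label every descriptor column")
        if len(self.split) != n:
            raise ValueError("split must tag every compound")
        for s in self.split:
            if s not in ("train", "test"):
                raise ValueError(f"unknown split tag {s!r}")

    @property
    def train_mask(self) -> np.ndarray:
        return np.array([s == "train" for s in self.split])

    @property
    def test_mask(self) -> np.ndarray:
        return ~self.train_mask

    def training(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.train_mask
        return self.descriptors[m], self.activity[m]

    def testing(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.test_mask
        return self.descriptors[m], self.activity[m]


@dataclass
class PlsModel:
    """Fitted PLS1 model on mean-centered data.

    ``coef`` acts on raw (uncentered) descriptors:
    prediction = x @ coef + intercept.
    """

    n_components: int
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray    # W, p x n
    x_loadings: np.ndarray   # P, p x n
    y_loadings: np.ndarray   # q, n
    dropped_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.coef + self.intercept


@dataclass
class ModelMetrics:
    q2: float
    n: int
    r2: float
    see: float
    f: float
    r2pred: float
    overfit_ratio_pct: float

    def as_dict(self) -> dict[str, float]:
        return {"q2": self.q2, "n": self.n, "R2": self.r2, "SEE": self.see,
                "F": self.f, "r2pred": self.r2pred,
                "overfit_ratio_pct": self.overfit_ratio_pct}


@dataclass
class FieldContributions:
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("contribution fractions must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("contribution fractions must sum to 1")


@dataclass
class FieldGridSpec:
    """Grid for the simplified similarity-field descriptor generator."""

    spacing: float = 2.0          # Angstrom
    attenuation: float = 0.3      # alpha, 1/Angstrom^2
    probe_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.attenuation <= 0:
            raise ValueError("attenuation factor must be positive")


def _nipals_pls1(xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered data; stops early on degenerate deflation.

    Returns (W, P, q) with as many columns as components actually
    extracted (may be fewer than requested on exactly low-rank data).
    """
    n, p = xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    x = xc.copy()
    y = yc.copy()
    scale = max(np.linalg.norm(xc.T @ yc), 1.0)
    k = 0
    for a in range(n_components):
        w = x.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * scale:
            break  # residual covariance numerically zero
        w /= nw
        t = x @ w
        tt = t @ t
        if tt <= 1e-300:
            break
        pvec = (x.T @ t) / tt
        qa = (y @ t) / tt
        W[:, a], P[:, a], q[a] = w, pvec, qa
        x = x - np.outer(t, pvec)
        y = y - qa * t
        k += 1
    return W[:, :k], P[:, :k], q[:k]


def pls_fit(data: QsarDataset, n_components: int) -> PlsModel:
    """Fit a PLS1 model on the training split.

    Descriptors and activity are mean-centered internally; zero-variance
    descriptor columns are dropped with a warning.  ``n_components`` must
    lie in [1, min(n_train − 1, n_descriptors)]; fewer components are kept
    if the training data are exactly low-rank.
    """
    xt, yt = data.training()
    n_train, p = xt.shape
    if n_train < 2:
        raise ValueError("need at least 2 training compounds")
    bound = min(n_train - 1, p)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components must be in [1, {bound}] for this training set")
    sd = xt.std(axis=0)
    dropped = np.where(sd == 0)[0]
    kept = np.where(sd > 0)[0]
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} zero-variance descriptor column(s)",
            stacklevel=2)
    if kept.size == 0:
        raise ValueError("all descriptor columns have zero variance")
    x_mean = xt.mean(axis=0)
    y_mean = float(yt.mean())
    xc = xt[:, kept] - x_mean[kept]
    yc = yt - y_mean
    W, P, q = _nipals_pls1(xc, yc, n_components)
    if W.shape[1] == 0:
        coef_kept = np.zeros(kept.size)
    else:
        # B = W (P'W)^{-1} q on centered data
        coef_kept = W @ np.linalg.solve(P.T @ W, q)
    coef = np.zeros(p)
    coef[kept] = coef_kept
    intercept = y_mean - float(x_mean @ coef)
    return PlsModel(
        n_components=W.shape[1], coef=coef, intercept=intercept,
        x_mean=x_mean, y_mean=y_mean, x_weights=W, x_loadings=P,
        y_loadings=q, dropped_columns=dropped)


def loo_q2(data: QsarDataset, n_components: int) -> float:
    """Leave-one-out cross-validated q² = 1 − PRESS / TSS on the training set.

    Each training compound is held out in turn, the model is refit on the
    remainder, and the held-out residual accumulates into PRESS.  TSS is
    about the full training-set mean.
    """
    xt, yt = data.training()
    n_train = xt.shape[0]
    if n_train < 3:
        raise ValueError("need at least 3 training compounds for LOO")
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant activity: zero total sum of squares")
    press = 0.0
    ids = [str(i) for i in range(n_train)]
    labels = ["?"] * xt.shape[1]
    for i in range(n_train):
        mask = np.ones(n_train, dtype=bool)
        mask[i] = False
        sub = QsarDataset(
            compound_ids=[ids[j] for j in range(n_train) if mask[j]],
            descriptors=xt[mask], activity=yt[mask],
            block_labels=labels, split=["train"] * (n_train - 1))
        k = min(n_components, xt[mask].shape[0] - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pls_fit(sub, k)
        press += float((model.predict(xt[i:i + 1])[0] - yt[i]) ** 2)
    return 1.0 - press / tss


def select_components(data: QsarDataset, max_n: int = 10) -> int:
    """Component count maximizing LOO q² over 1..max_n (ties -> smallest)."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    xt, _ = data.training()
    bound = min(max_n, xt.shape[0] - 2, xt.shape[1])
    bound = max(bound, 1)
    q2s = [loo_q2(data, k) for k in range(1, bound + 1)]
    return int(np.argmax(q2s)) + 1


def regression_stats(y_true: np.ndarray, y_pred: np.ndarray,
                     n_components: int) -> tuple[float, float, float]:
    """R², SEE and F for a fit with ``n_components`` latent variables.

    SEE = sqrt(RSS/(n − k − 1)) and F = (R²/k) / ((1 − R²)/(n − k − 1))
    with n observations and k components.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.shape[0]
    k = n_components
    dof = n - k - 1
    if dof <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    resid = y_true - y_pred
    rss = float(resid @ resid)
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant activity")
    r2 = 1.0 - rss / tss
    see = float(np.sqrt(rss / dof))
    if r2 >= 1.0:
        f = float("inf")
    else:
        f = (r2 / k) / ((1.0 - r2) / dof)
    return r2, see, f


def prediction_r2(y_true: np.ndarray, y_pred: np.ndarray, center: float) -> float:
    """(SD − PRESS)/SD with SD = Σ(y_true − center)²."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sd = float(np.sum((y_true - center) ** 2))
    if sd == 0:
        raise ValueError("zero SD denominator in r2pred")
    press = float(np.sum((y_true - y_pred) ** 2))
    return (sd - press) / sd


def internal_metrics(model: PlsModel, data: QsarDataset) -> tuple[float, float, float]:
    """Training-set R², SEE and F statistic (see :func:`regression_stats`)."""
    xt, yt = data.training()
    return regression_stats(yt, model.predict(xt), model.n_components)


def external_r2pred(model: PlsModel, data: QsarDataset,
                    denominator: str = "train-mean") -> float:
    """External prediction coefficient r²_pred = (SD − PRESS)/SD.

    SD is the sum of squared deviations of the test activities about the
    *training*-set mean (the classic convention); pass
    ``denominator="test-mean"`` for the alternative.
    """
    xs, ys = data.testing()
    if xs.shape[0] == 0:
        raise ValueError("empty test split")
    _, yt = data.training()
    center = float(yt.mean()) if denominator == "train-mean" else float(ys.mean())
    return prediction_r2(ys, model.predict(xs), center)


def overfit_ratio(r2: float, q2: float) -> float:
    """Overfit ratio 100·(R² − q²)/R², in percent."""
    if r2 <= 0:
        raise ValueError("overfit ratio undefined for R2 <= 0")
    return 100.0 * (r2 - q2) / r2


def acceptance_check(metrics: ModelMetrics) -> tuple[bool, list[str]]:
    """Model pass/fail against the standard QSAR validation gates.

    Pass requires q² > 0.5, r²_pred > 0.6 and overfit ratio < 30%
    (all strict).  Returns (passed, list of failed-gate reasons).
    """
    reasons = []
    if not metrics.q2 > 0.5:
        reasons.append("q2 <= 0.5")
    if not metrics.r2pred > 0.6:
        reasons.append("r2pred <= 0.6")
    if not metrics.overfit_ratio_pct < 30.0:
        reasons.append("overfit ratio >= 30%")
    return (len(reasons) == 0, reasons)


def field_contributions(model: PlsModel, data: QsarDataset) -> FieldContributions:
    """Per-field-block contribution fractions of a fitted model.

    Block k contributes sum_{j in k} |b_j|·s_j, where b_j is the regression
    coefficient and s_j the training standard deviation of descriptor j,
    normalized over all blocks.
    """
    xt, _ = data.training()
    s = xt.std(axis=0)
    mass = np.abs(model.coef) * s
    total = mass.sum()
    if total == 0:
        raise ValueError("all coefficients are zero: contributions undefined")
    fractions: dict[str, float] = {}
    for label, m in zip(data.block_labels, mass):
        fractions[label] = fractions.get(label, 0.0) + float(m)
    return FieldContributions({k: v / total for k, v in fractions.items()})


def similarity_fields(
    coordinates: np.ndarray,
    atom_weights: dict[str, np.ndarray],
    grid_points: np.ndarray,
    spec: FieldGridSpec | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Gaussian similarity-field descriptors on a grid.

    The descriptor for field ``k`` at grid point ``q`` is
    ``w_probe,k · sum_i w_ik · exp(−alpha · r_iq²)`` over atoms ``i`` with
    per-atom field weights ``w_ik``.  Returns a row vector of descriptors
    (one column per grid point and field) plus block labels, ready to stack
    into a :class:`QsarDataset`.
    """
    spec = spec or FieldGridSpec()
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coords.shape[0] == 0:
        raise ValueError("empty molecule")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    grid = np.atleast_2d(np.asarray(grid_points, dtype=float))
    # pairwise squared distances, grid x atoms
    d2 = np.sum((grid[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    gauss = np.exp(-spec.attenuation * d2)
    cols, labels = [], []
    for fname, w in atom_weights.items():
        w = np.asarray(w, dtype=float)
        if w.shape[0] != coords.shape[0]:
            raise ValueError(f"field {fname!r}: one weight per atom required")
        probe = spec.probe_weights.get(fname, 1.0)
        vals = probe * (gauss @ w)
        cols.append(vals)
        labels.extend([fname] * grid.shape[0])
    return np.concatenate(cols), labels
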