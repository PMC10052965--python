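"""Two-level experimental designs and effect decomposition.

Builds Taguchi-style two-level orthogonal arrays (Sylvester–Hadamard
construction) and 2^k full factorials, estimates main and interaction
effects from binding-energy responses, classifies them as
promoting/inhibiting or synergistic/antagonistic, and screens run schemes
for the strongest binding (largest |binding energy|) against a blank
control run.

Responses are |binding energy| in kJ/mol; a more negative binding energy
means stronger receptor binding, which in the screening context reads as
better microbial accessibility of the compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import hadamard

__all__ = [
    "DesignMatrix", "ResponseTable", "EffectEstimates", "Effect",
    "taguchi_oa", "full_factorial", "factorial_effects",
    "classify_interactions", "screen_min_energy",
]


@dataclass
class DesignMatrix:
    """Run plan: rows are runs, columns are two-level factors (0/1)."""

    run_ids: list[str]
    factor_ids: list[str]
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.shape != (len(self.run_ids), len(self.factor_ids)):
            raise ValueError("levels shape must be (n_runs, n_factors)")
        if not np.isin(self.levels, (0, 1)).all():
            raise ValueError("levels must be 0 or 1")

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def is_balanced(self) -> bool:
        """Every factor column has equally many 0s and 1s."""
        counts = self.levels.sum(axis=0)
        return bool(np.all(counts * 2 == self.n_runs))

    def is_orthogonal(self) -> bool:
        """Every factor pair shows each of the 4 level combinations equally often."""
        n = self.n_runs
        for a, b in combinations(range(self.n_factors), 2):
            pairs = self.levels[:, a] * 2 + self.levels[:, b]
            counts = np.bincount(pairs, minlength=4)
            if not np.all(counts == n // 4):
                return False
        return True


@dataclass
class ResponseTable:
    """Binding-energy responses per run; response value = |binding energy|."""

    run_ids: list[str]
    binding_energy: np.ndarray  # kJ/mol, negative = stronger binding

    def __post_init__(self) -> None:
        self.binding_energy = np.asarray(self.binding_energy, dtype=float)
        if len(self.run_ids) != self.binding_energy.shape[0]:
            raise ValueError("one binding energy per run required")

    @property
    def response_value(self) -> np.ndarray:
        return np.abs(self.binding_energy)


@dataclass
class Effect:
    term: tuple[str, ...]
    order: int
    effect: float       # high-contrast mean minus low-contrast mean
    coefficient: float  # regression coefficient on ±1 coding (= effect/2)
    label: str = ""


@dataclass
class EffectEstimates:
    effects: list[Effect]

    def by_term(self) -> dict[tuple[str, ...], Effect]:
        return {e.term: e for e in self.effects}


def taguchi_oa(n_factors: int, n_runs: int = 32) -> DesignMatrix:
    """Two-level orthogonal array OA(n_runs, 2^n_factors, strength 2).

    Columns are drawn from the Sylvester–Hadamard matrix of order
    ``n_runs`` (the all-ones column dropped, ±1 mapped to 1/0), taking the
    first ``n_factors`` columns in Yates order.  ``n_runs`` must be a power
    of two and ``n_factors <= n_runs - 1``.
    """
    if n_runs < 4 or n_runs & (n_runs - 1):
        raise ValueError("n_runs must be a power of two >= 4")
    if not 1 <= n_factors <= n_runs - 1:
        raise ValueError(f"n_factors must be in [1, {n_runs - 1}]")
    h = hadamard(n_runs)
    levels = ((1 + h[:, 1:n_factors + 1]) // 2).astype(int)
    return DesignMatrix(
        run_ids=[str(i + 1) for i in range(n_runs)],
        factor_ids=[f"F{j + 1}" for j in range(n_factors)],
        levels=levels)


def full_factorial(k: int, factor_ids: list[str] | None = None) -> DesignMatrix:
    """Full 2^k factorial in Yates standard order (run 1 = all zeros)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if factor_ids is None:
        factor_ids = [chr(ord("A") + j) for j in range(k)]
    if len(factor_ids) != k:
        raise ValueError("need exactly k factor ids")
    n = 2 ** k
    # Yates order: first factor alternates fastest
    levels = np.array([[(i >> j) & 1 for j in range(k)] for i in range(n)])
    return DesignMatrix(
        run_ids=[str(i + 1) for i in range(n)],
        factor_ids=list(factor_ids), levels=levels)


def factorial_effects(design: DesignMatrix, response: ResponseTable) -> EffectEstimates:
    """Main and interaction effects from a complete 2^k factorial.

    Levels are recoded 0 -> −1, 1 -> +1; the effect of a term is the mean
    response at the +1 contrast minus the mean at the −1 contrast, with
    interaction contrasts as elementwise products (Yates' algorithm
    equivalently).  Responses are |binding energy|.
    """
    k = design.n_factors
    n = design.n_runs
    if n != 2 ** k:
        raise ValueError("design is not a complete 2^k factorial")
    if design.run_ids != response.run_ids:
        raise ValueError("design and response run ids do not match")
    rows = {tuple(r) for r in design.levels}
    if len(rows) != n:
        raise ValueError("design contains duplicated runs")
    y = response.response_value
    signed = 2 * design.levels - 1
    effects = []
    for order in range(1, k + 1):
        for idx in combinations(range(k), order):
            contrast = np.prod(signed[:, idx], axis=1)
            eff = float(y[contrast == 1].mean() - y[contrast == -1].mean())
            effects.append(Effect(
                term=tuple(design.factor_ids[j] for j in idx),
                order=order, effect=eff, coefficient=eff / 2.0))
    return EffectEstimates(effects)


def classify_interactions(effects: EffectEstimates, tol: float = 0.0) -> EffectEstimates:
    """Attach a reading to each effect estimated on |binding energy|.

    A positive main effect promotes degradation (the additive strengthens
    binding); a positive interaction is synergistic, a negative one
    antagonistic; a positive third-order effect additionally reads as the
    three factors jointly suppressing lower-order antagonism.
    """
    for e in effects.effects:
        if abs(e.effect) <= tol:
            e.label = "no effect"
        elif e.order == 1:
            e.label = ("promotes degradation" if e.effect > 0
                       else "inhibits degradation")
        elif e.order == 2:
            e.label = "synergistic" if e.effect > 0 else "antagonistic"
        else:
            e.label = ("synergistic (inhibits lower-order antagonism)"
                       if e.effect > 0 else "antagonistic")
    return effects


def screen_min_energy(
    responses: ResponseTable, blank_run_id: str | None = None
) -> dict:
    """Pick the run with the strongest binding and report reductions vs blank.

    The blank (control) run defaults to the first run id.  For every run
    the percent reduction is 100·(|E_run| − |E_blank|)/|E_blank|: positive
    means the binding energy moved further below the control (the paper's
    'reduction').  The best run has minimum binding energy, i.e. maximum
    |E|; ties go to the lowest run id position.
    """
    if blank_run_id is None:
        blank_run_id = responses.run_ids[0]
    try:
        blank_idx = responses.run_ids.index(blank_run_id)
    except ValueError:
        raise ValueError(f"blank run {blank_run_id!r} not found") from None
    e = responses.binding_energy
    blank_abs = abs(e[blank_idx])
    if blank_abs == 0:
        raise ValueError("blank run has zero binding energy")
    reductions = {rid: float(100.0 * (abs(v) - blank_abs) / blank_abs)
                  for rid, v in zip(responses.run_ids, e)}
    best_idx = int(np.argmin(e))
    return {
        "best_run": responses.run_ids[best_idx],
        "best_binding_energy": float(e[best_idx]),
        "blank_run": blank_run_id,
        "blank_binding_energy": float(e[blank_idx]),
        "best_reduction_pct": reductions[responses.run_ids[best_idx]],
        "reductions_pct": reductions,
    }
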