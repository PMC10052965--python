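"""Degradation-pathway energy-barrier bookkeeping.

Tracks stepwise reaction energy barriers (ΔE, kJ/mol, all > 0 — a smaller
barrier means the step is more accessible), stage totals, and signed
change rates of a candidate compound against a reference, plus the 1:1
SOD/CAT docking-score composite used as a fish-antioxidant toxicity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReactionStep", "EnergyProfile", "AntioxidantScores",
    "stage_total", "change_rate", "compare_profiles",
    "antioxidant_composite",
]


@dataclass
class ReactionStep:
    reactant: str
    product: str
    delta_e: float  # kJ/mol, must be > 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_e) or self.delta_e <= 0:
            raise ValueError(
                f"step {self.reactant}->{self.product}: energy barrier must be > 0")


@dataclass
class EnergyProfile:
    compound: str
    steps: list[ReactionStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("profile needs at least one step")

    @property
    def barriers(self) -> np.ndarray:
        return np.array([s.delta_e for s in self.steps])


@dataclass
class AntioxidantScores:
    compound: str
    sod: float
    cat: float

    @property
    def composite(self) -> float:
        return self.sod + self.cat  # 1:1 weighting


def stage_total(profile: EnergyProfile) -> float:
    """Total ΔE over the stage: arithmetic sum of the step barriers."""
    return float(profile.barriers.sum())


def change_rate(reference: float, candidate: float) -> float:
    """Signed percent change 100·(candidate − reference)/reference.

    Negative means the candidate's barrier is lower, i.e. the reaction is
    easier than for the reference compound.
    """
    if reference <= 0:
        raise ValueError("reference barrier must be > 0")
    return 100.0 * (candidate - reference) / reference


def compare_profiles(reference: EnergyProfile, candidate: EnergyProfile) -> dict:
    """Step-wise and total comparison of two degradation profiles.

    Returns per-step change rates, stage totals, total change rate and a
    verdict: 'more degradable' iff the candidate's total barrier is lower.
    """
    if len(reference.steps) != len(candidate.steps):
        raise ValueError("profiles must have the same number of steps")
    step_rates = [change_rate(r.delta_e, c.delta_e)
                  for r, c in zip(reference.steps, candidate.steps)]
    ref_total = stage_total(reference)
    cand_total = stage_total(candidate)
    total_rate = change_rate(ref_total, cand_total)
    if total_rate < 0:
        verdict = "more degradable"
    elif total_rate > 0:
        verdict = "less degradable"
    else:
        verdict = "unchanged"
    return {
        "reference": reference.compound,
        "candidate": candidate.compound,
        "steps": [
            {"step": i + 1,
             "reference_reactant": r.reactant, "reference_product": r.product,
             "candidate_reactant": c.reactant, "candidate_product": c.product,
             "reference_delta_e": r.delta_e, "candidate_delta_e": c.delta_e,
             "change_rate_pct": rate}
            for i, (r, c, rate) in enumerate(
                zip(reference.steps, candidate.steps, step_rates))],
        "reference_total": ref_total,
        "candidate_total": cand_total,
        "total_change_rate_pct": total_rate,
        "verdict": verdict,
    }


def antioxidant_composite(
    sod: float, cat: float, reference_composite: float | None = None
) -> dict:
    """1:1 SOD+CAT docking-score composite, optionally vs a reference.

    A higher composite means stronger predicted inhibition of the fish
    antioxidant enzymes, i.e. higher toxicity.  When a reference composite
    is given, the percent reduction 100·(ref − composite)/ref is included.
    """
    if not (np.isfinite(sod) and np.isfinite(cat)):
        raise ValueError("scores must be finite")
    composite = sod + cat
    out = {"composite": float(composite)}
    if reference_composite is not None:
        if reference_composite == 0:
            raise ValueError("zero reference composite")
        out["reduction_pct"] = float(
            100.0 * (reference_composite - composite) / reference_composite)
    return out
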