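"""Seeded generators emulating the external-tool outputs the pipeline consumes.

The real pipeline ingests docking scores (ligand-receptor binding), MD-based
binding energies for design runs, molecular-field descriptor tables, and
DFT reaction energy barriers — all produced by commercial or HPC tools.
These generators emulate each of those outputs with a known planted
structure, so every downstream stage has a recoverable ground truth:

* docking scores follow a single-latent-quality model (better compounds
  score higher on positive criteria, lower on the toxicity criterion);
* design-run binding energies carry planted main/interaction effects on
  the ±1 contrast scale around a −93.414 kJ/mol blank baseline;
* QSAR descriptor tables have low-rank latent structure with activity
  linear in the latent factors;
* degradation profiles default to a reference/candidate barrier pair from
  the hydrolysis stage of a triazine herbicide and its substitute.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs, and distinct generators draw from independent
seeded streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from herbiscreen.degradation import EnergyProfile, ReactionStep
from herbiscreen.doe import DesignMatrix, ResponseTable
from herbiscreen.mcda import ScoreMatrix
from herbiscreen.qsar import QsarDataset

__all__ = [
    "SyntheticConfig", "gen_docking_scores", "gen_doe_responses",
    "gen_qsar_dataset", "gen_energy_profiles",
]


def _default_doe_effects() -> dict[tuple[str, ...], float]:
    # Planted on the ±1 contrast scale (value = high-mean minus low-mean).
    # Mains all promote binding; one pairwise antagonism; a positive
    # three-way term sized so the all-additives run sits 58.32% below the
    # blank control, mirroring the strongest printed field scheme.
    return {
        ("Q",): 24.0, ("R",): 14.0, ("S",): 12.0,
        ("Q", "R"): 4.0, ("Q", "S"): 3.0, ("R", "S"): -2.0,
        ("Q", "R", "S"): 4.479,
    }


@dataclass
class SyntheticConfig:
    """All knobs for the synthetic generators, with one seed.

    Docking: ``n_compounds`` latent qualities drawn N(0, spread²); criterion
    j scores ``baseline_j + loading_j * quality + noise``.  The toxicity
    loading is negative so better compounds are less toxic.  Defaults give
    scores in a plausible docking-score range (roughly 60–160).

    DOE: binding energy = −(response), response = blank baseline plus the
    planted contrast contributions (shifted so the all-zeros run equals the
    baseline exactly) plus Gaussian noise.

    QSAR: descriptors = latent factors x loadings + noise, activity linear
    in the latent factors; 3:1 train/test split stratified by activity
    quartile, template compound pinned to the training set.
    """

    seed: int = 0
    # docking-score matrix
    n_compounds: int = 26
    criterion_ids: tuple[str, ...] = ("herbicidal", "degradability", "toxicity")
    indicator_types: tuple[str, ...] = ("positive", "positive", "negative")
    loadings: tuple[float, ...] = (20.0, 15.0, -12.0)
    baselines: tuple[float, ...] = (110.0, 100.0, 110.0)
    quality_spread: float = 1.0
    docking_noise: tuple[float, ...] = (2.0, 2.0, 2.0)
    # DOE responses
    doe_baseline: float = 93.414  # |binding energy| of the blank run, kJ/mol
    doe_effects: dict[tuple[str, ...], float] = field(
        default_factory=_default_doe_effects)
    doe_noise_sd: float = 1.0
    # QSAR dataset
    qsar_n_compounds: int = 28
    qsar_rank: int = 3
    qsar_n_descriptors: int = 60
    qsar_noise_sd: float = 0.05
    qsar_blocks: tuple[str, ...] = ("H", "A", "D", "E", "S")
    # degradation profiles
    reference_barriers: tuple[float, ...] = (160.893, 39.913)
    candidate_barriers: tuple[float, ...] = (60.147, 34.386)
    profile_multipliers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.docking_noise):
            raise ValueError("noise scales must be >= 0")
        if self.doe_noise_sd < 0 or self.qsar_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def gen_docking_scores(config: SyntheticConfig) -> tuple[ScoreMatrix, np.ndarray]:
    """Docking-score matrix with a planted latent compound quality.

    Returns (scores, latent_quality); with zero noise the composite-value
    ranking of the scores recovers the latent-quality order exactly.
    """
    if config.n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    m = len(config.criterion_ids)
    if not (len(config.indicator_types) == len(config.loadings)
            == len(config.baselines) == len(config.docking_noise) == m):
        raise ValueError("per-criterion settings must all have the same length")
    rng = _rng(config, 1)
    quality = rng.normal(0.0, config.quality_spread, config.n_compounds)
    x = np.empty((config.n_compounds, m))
    for j in range(m):
        noise = rng.normal(0.0, config.docking_noise[j], config.n_compounds)
        x[:, j] = config.baselines[j] + config.loadings[j] * quality + noise
    scores = ScoreMatrix(
        compound_ids=[f"S-{i + 1}" for i in range(config.n_compounds)],
        criterion_ids=list(config.criterion_ids),
        indicator_types=list(config.indicator_types),
        values=x)
    return scores, quality


def gen_doe_responses(design: DesignMatrix, config: SyntheticConfig) -> ResponseTable:
    """Binding-energy responses for a two-level design with planted effects.

    Planted terms are keyed by factor-id tuples and specified on the ±1
    contrast scale, so a downstream factorial-effect analysis recovers them
    exactly at zero noise.  An additive offset puts the all-zeros (blank)
    run at exactly −baseline kJ/mol.
    """
    for term in config.doe_effects:
        for fid in term:
            if fid not in design.factor_ids:
                raise ValueError(f"planted term references unknown factor {fid!r}")
    signed = 2 * design.levels - 1
    col = {fid: j for j, fid in enumerate(design.factor_ids)}

    def contribution(srow: np.ndarray) -> float:
        total = 0.0
        for term, eff in config.doe_effects.items():
            contrast = np.prod([srow[col[f]] for f in term])
            total += (eff / 2.0) * contrast
        return total

    blank = contribution(-np.ones(design.n_factors))
    rng = _rng(config, 2)
    noise = rng.normal(0.0, config.doe_noise_sd, design.n_runs) \
        if config.doe_noise_sd > 0 else np.zeros(design.n_runs)
    response = np.array([
        config.doe_baseline + contribution(signed[i]) - blank + noise[i]
        for i in range(design.n_runs)])
    return ResponseTable(run_ids=list(design.run_ids),
                         binding_energy=-response)


def gen_qsar_dataset(config: SyntheticConfig) -> QsarDataset:
    """Low-rank descriptor/activity dataset with a 3:1 train/test split.

    Descriptors are latent factors times loadings plus noise; activity is
    linear in the latent factors plus noise.  The split is stratified by
    activity quartile; the designated template compound (the first) is
    pinned to the training set.
    """
    r, p, n = config.qsar_rank, config.qsar_n_descriptors, config.qsar_n_compounds
    if r > p:
        raise ValueError("latent rank cannot exceed descriptor count")
    if n < 8:
        raise ValueError("need at least 8 compounds for a 3:1 split")
    rng = _rng(config, 3)
    t = rng.normal(size=(n, r))
    load = rng.normal(size=(r, p))
    x = t @ load
    if config.qsar_noise_sd > 0:
        x = x + rng.normal(0.0, config.qsar_noise_sd, size=(n, p))
    c = rng.normal(size=r)
    y = t @ c
    if config.qsar_noise_sd > 0:
        y = y + rng.normal(0.0, config.qsar_noise_sd, size=n)
    blocks = [config.qsar_blocks[j % len(config.qsar_blocks)] for j in range(p)]
    # stratified 3:1 split by activity quartile; compound 0 pinned to train
    split = np.array(["train"] * n, dtype=object)
    order = np.argsort(y, kind="stable")
    quartiles = np.array_split(order, 4)
    n_test = max(1, round(n / 4))
    # interleave across quartiles to keep the test set spread over activity
    per_q = [[int(i) for i in q if i != 0] for q in quartiles]
    for q in per_q:
        rng.shuffle(q)
    chosen: list[int] = []
    while len(chosen) < n_test:
        for q in per_q:
            if q and len(chosen) < n_test:
                chosen.append(q.pop())
    split[np.array(chosen, dtype=int)] = "test"
    return QsarDataset(
        compound_ids=[f"M-{i + 1}" for i in range(n)],
        descriptors=x, activity=y, block_labels=blocks,
        split=list(split))


def gen_energy_profiles(config: SyntheticConfig) -> tuple[EnergyProfile, EnergyProfile]:
    """(reference, candidate) two-step degradation profiles.

    Defaults reproduce the hydrolysis-stage barrier pair of the reference
    herbicide and its substitute; ``profile_multipliers`` instead derives
    the candidate barriers as multiples of the reference ones.
    """
    ref_b = config.reference_barriers
    if config.profile_multipliers is not None:
        if len(config.profile_multipliers) != len(ref_b):
            raise ValueError("one multiplier per step required")
        if any(m <= 0 for m in config.profile_multipliers):
            raise ValueError("barrier multipliers must be > 0")
        cand_b = tuple(b * m for b, m in zip(ref_b, config.profile_multipliers))
    else:
        cand_b = config.candidate_barriers
    ref = EnergyProfile("REF", [
        ReactionStep("REF" if i == 0 else f"REF-{i}", f"REF-{i + 1}", b)
        for i, b in enumerate(ref_b)])
    cand = EnergyProfile("CAND", [
        ReactionStep("CAND" if i == 0 else f"CAND-{i}", f"CAND-{i + 1}", b)
        for i, b in enumerate(cand_b)])
    return ref, cand
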