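"""Configuration, table I/O and end-to-end orchestration.

The pipeline runs three largely independent stages on configured inputs:

1. *ranking* — docking scores -> AHP/TOPSIS weights -> composite-value
   ranking (with percent difference against a reference compound);
2. *screening* — design matrix + binding-energy responses -> factorial
   effects and best-scheme screening;
3. *degradation* — reference/candidate energy profiles -> step-wise and
   total change-rate report.

Any input not configured is generated synthetically from the run seed, so
``run_all`` always produces a complete report bundle.  All machine outputs
are written at full precision; the human-readable log records every
normalization and weighting decision taken.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from herbiscreen import doe as _doe
from herbiscreen import mcda as _mcda
from herbiscreen import synthetic as _syn
from herbiscreen.degradation import EnergyProfile, ReactionStep, compare_profiles

logger = logging.getLogger("herbiscreen")

__all__ = [
    "PipelineConfig", "load_score_table", "load_ahp_matrix",
    "load_design", "load_responses", "load_profiles", "run_all",
]

WEIGHTING_MODES = ("printed-product", "entropy-sqrt")


@dataclass
class PipelineConfig:
    """Everything ``run_all`` needs; paths may be None to use synthetic data."""

    criteria: dict[str, str] = field(default_factory=lambda: {
        "herbicidal": "positive", "degradability": "positive",
        "toxicity": "negative"})
    scores_path: str | None = None
    ahp_matrix_path: str | None = None
    ahp_matrix: list[list[float]] | None = None
    weighting_mode: str = "printed-product"
    reference_compound: str | None = None
    design_path: str | None = None
    responses_path: str | None = None
    profiles_path: str | None = None
    output_dir: str = "herbiscreen_out"
    seed: int = 0
    report_precision: int = 3
    synthetic: _syn.SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if self.weighting_mode not in WEIGHTING_MODES:
            raise ValueError(
                f"unknown weighting mode {self.weighting_mode!r}; "
                f"expected one of {WEIGHTING_MODES}")
        if self.report_precision < 0:
            raise ValueError("report precision must be >= 0")
        for p in (self.scores_path, self.ahp_matrix_path,
                  self.design_path, self.responses_path, self.profiles_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "doe_effects" in syn:
                syn["doe_effects"] = {
                    tuple(k.split(":")): float(v)
                    for k, v in syn["doe_effects"].items()}
            cfg.synthetic = _syn.SyntheticConfig(**syn)
        return cfg


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs the dialect, so TSV and CSV load identically
    return pd.read_csv(path, sep=None, engine="python")


def load_score_table(path: str | Path, criteria: dict[str, str]) -> _mcda.ScoreMatrix:
    """Read a compound x criterion score table (CSV or TSV).

    The header must start with ``compound_id``; every other column must be
    tagged positive/negative in ``criteria``.  Blank or non-numeric cells
    are reported by row and column.
    """
    df = _read_table(path)
    if df.columns[0] != "compound_id":
        raise ValueError("first column must be 'compound_id'")
    crit_cols = list(df.columns[1:])
    for c in crit_cols:
        if c not in criteria:
            raise ValueError(f"criterion {c!r} has no positive/negative tag")
    values = df[crit_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or blank cell at row {i + 2} (compound "
            f"{df.iloc[i, 0]!r}), column {crit_cols[j]!r}")
    return _mcda.ScoreMatrix(
        compound_ids=[str(c) for c in df["compound_id"]],
        criterion_ids=crit_cols,
        indicator_types=[criteria[c] for c in crit_cols],
        values=values)


def load_ahp_matrix(path: str | Path) -> _mcda.PairwiseMatrix:
    """Read an AHP judgment matrix from a headerless CSV of ratios."""
    a = pd.read_csv(path, header=None).to_numpy(float)
    return _mcda.PairwiseMatrix(a)


def load_design(path: str | Path) -> _doe.DesignMatrix:
    df = _read_table(path)
    if df.columns[0] != "run_id":
        raise ValueError("first column must be 'run_id'")
    return _doe.DesignMatrix(
        run_ids=[str(r) for r in df["run_id"]],
        factor_ids=list(df.columns[1:]),
        levels=df[df.columns[1:]].to_numpy(int))


def load_responses(path: str | Path) -> _doe.ResponseTable:
    df = _read_table(path)
    if "run_id" not in df.columns or "binding_energy_kj_mol" not in df.columns:
        raise ValueError("responses need 'run_id' and 'binding_energy_kj_mol'")
    return _doe.ResponseTable(
        run_ids=[str(r) for r in df["run_id"]],
        binding_energy=df["binding_energy_kj_mol"].to_numpy(float))


def load_profiles(path: str | Path) -> dict[str, EnergyProfile]:
    """Read pathway steps: columns compound,step,reactant,product,delta_e_kj_mol."""
    df = _read_table(path)
    need = {"compound", "step", "reactant", "product", "delta_e_kj_mol"}
    if not need.issubset(df.columns):
        raise ValueError(f"pathway table needs columns {sorted(need)}")
    profiles = {}
    for comp, grp in df.groupby("compound", sort=False):
        grp = grp.sort_values("step")
        profiles[str(comp)] = EnergyProfile(str(comp), [
            ReactionStep(str(r.reactant), str(r.product), float(r.delta_e_kj_mol))
            for r in grp.itertuples()])
    return profiles


def _default_ahp_matrix(n: int) -> _mcda.PairwiseMatrix:
    # consistent stand-in emphasizing the first (herbicidal) criterion 2:1
    ratios = np.array([2.0] + [1.0] * (n - 1))
    return _mcda.PairwiseMatrix(np.outer(ratios, 1.0 / ratios))


def _ranking_stage(config: PipelineConfig, outdir: Path) -> dict:
    syn = config.synthetic or _syn.SyntheticConfig(seed=config.seed)
    if config.scores_path:
        scores = load_score_table(config.scores_path, config.criteria)
        logger.info("loaded scores from %s", config.scores_path)
    else:
        scores, _ = _syn.gen_docking_scores(syn)
        logger.info("generated synthetic docking scores (seed=%d)", syn.seed)
    if config.ahp_matrix is not None:
        pairwise = _mcda.PairwiseMatrix(np.asarray(config.ahp_matrix, float))
    elif config.ahp_matrix_path:
        pairwise = load_ahp_matrix(config.ahp_matrix_path)
    else:
        pairwise = _default_ahp_matrix(scores.n_criteria)
        logger.info("using default consistent AHP stand-in matrix")
    w1, cr = _mcda.ahp_weights(pairwise)
    logger.info("AHP consistency ratio: %.4f", cr)
    normalized = _mcda.normalize_scores(scores)
    for line in normalized.provenance:
        logger.info("normalization: %s", line)
    bw = _mcda.best_worst_vectors(scores)
    _, cosines = _mcda.relative_error_cosines(scores, bw)
    w2 = _mcda.objective_weights(cosines)
    w = _mcda.compound_weights(w1, w2, mode=config.weighting_mode)
    logger.info("weighting mode: %s", config.weighting_mode)
    ranking = _mcda.composite_value(normalized, w, scores.compound_ids)
    ref = config.reference_compound or scores.compound_ids[0]
    pct = _mcda.percent_vs_reference(ranking, ref)
    rows = [{"compound_id": cid, "cv": cv, "rank": rk,
             "pct_vs_reference": pct[cid]}
            for cid, cv, rk in ranking.ordered()]
    pd.DataFrame(rows).to_csv(outdir / "ranking.csv", index=False)
    weights_out = {
        "W1": w1.weights.tolist(), "W2": w2.weights.tolist(),
        "w": w.weights.tolist(), "theta": cosines.theta.tolist(),
        "consistency_ratio": cr, "mode": config.weighting_mode,
        "criteria": scores.criterion_ids,
    }
    (outdir / "weights.json").write_text(json.dumps(weights_out, indent=2))
    return {"ranking": ranking, "weights": weights_out,
            "reference": ref, "pct_vs_reference": pct}


def _screening_stage(config: PipelineConfig, outdir: Path) -> dict:
    syn = config.synthetic or _syn.SyntheticConfig(seed=config.seed)
    if config.design_path:
        design = load_design(config.design_path)
    else:
        design = _doe.full_factorial(3, ["Q", "R", "S"])
        logger.info("using default 2^3 full factorial (Q, R, S)")
    if config.responses_path:
        responses = load_responses(config.responses_path)
    else:
        responses = _syn.gen_doe_responses(design, syn)
        logger.info("generated synthetic binding-energy responses (seed=%d)",
                    syn.seed)
    effects = _doe.factorial_effects(design, responses)
    _doe.classify_interactions(effects)
    pd.DataFrame([{"term": "*".join(e.term), "order": e.order,
                   "effect": e.effect, "coefficient": e.coefficient,
                   "label": e.label} for e in effects.effects]
                 ).to_csv(outdir / "effects.csv", index=False)
    screening = _doe.screen_min_energy(responses)
    (outdir / "screening.json").write_text(json.dumps(screening, indent=2))
    return {"effects": effects, "screening": screening}


def _degradation_stage(config: PipelineConfig, outdir: Path) -> dict:
    syn = config.synthetic or _syn.SyntheticConfig(seed=config.seed)
    if config.profiles_path:
        profiles = load_profiles(config.profiles_path)
        if len(profiles) != 2:
            raise ValueError("pathway table must describe exactly 2 compounds "
                             "(reference first)")
        ref, cand = profiles.values()
    else:
        ref, cand = _syn.gen_energy_profiles(syn)
        logger.info("using default degradation profile pair")
    report = compare_profiles(ref, cand)
    (outdir / "degradation.json").write_text(json.dumps(report, indent=2))
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run ranking, screening and degradation stages; write the report bundle.

    Returns the in-memory results; on disk the output directory receives
    ranking.csv, weights.json, effects.csv, screening.json,
    degradation.json and run.log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("seed: %d", config.seed)
        results = {}
        for name, stage in (("ranking", _ranking_stage),
                            ("screening", _screening_stage),
                            ("degradation", _degradation_stage)):
            try:
                results[name] = stage(config, outdir)
            except Exception:
                logger.exception("stage %s failed", name)
                raise
        logger.info("run complete")
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
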