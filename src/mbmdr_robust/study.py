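"""Robustness-study orchestration: FWER, false-positive and power estimation.

A study grid crosses 18 simulation settings (3 residual families x
{equal, unequal} variances x g2 in {0, 0.05, 0.1}) with analysis arms
(internal test x trait transformation).  For each replicate the dataset is
simulated once and every arm re-analyzes the same data with the same
permutation indices, so that arm contrasts are paired.  Per replicate three
indicators are recorded: the causal pair (SNP1, SNP2) significant, any
non-causal pair significant, and any pair significant.  Under g2 = 0 the
"any pair" fraction estimates the familywise error rate; under g2 > 0 the
causal fraction is power and the non-causal fraction the false-positive
rate (familywise-style by default: fraction of replicates with at least one
significant non-causal pair).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnalysisConfig, _pair_scan, stepdown_maxt
from .simulate import FAMILIES, SimulationConfig, _setting_code, simulate_replicate
from .transforms import apply_transform

__all__ = [
    "StudyCell",
    "StudyTables",
    "TABLE_ARMS",
    "arm_name",
    "run_replicate",
    "run_setting",
    "estimate_rates",
    "bradley_check",
    "run_study",
    "render_tables",
    "PRESETS",
]

log = logging.getLogger(__name__)

#: the eight analysis arms reported as table columns, in column order
TABLE_ARMS: tuple[tuple[str, str], ...] = (
    ("student", "raw"), ("welch", "raw"),
    ("student", "rank"), ("welch", "rank"),
    ("student", "log"), ("welch", "log"),
    ("student", "rtn"), ("welch", "rtn"),
)

_ARM_NAMES = {
    ("student", "raw"): "ST", ("welch", "raw"): "WT",
    ("student", "stz"): "Stz_ST", ("welch", "stz"): "Stz_WT",
    ("student", "rank"): "Rank_ST", ("welch", "rank"): "Rank_WT",
    ("student", "log"): "Log_ST", ("welch", "log"): "Log_WT",
    ("student", "rtn"): "Rtn_ST", ("welch", "rtn"): "Rtn_WT",
}

#: reduced-scale and full-scale study presets (replicates, permutations, SNPs)
PRESETS = {
    "desk": {"n_replicates": 100, "n_permutations": 199, "n_snps": 100},
    "full": {"n_replicates": 1000, "n_permutations": 999, "n_snps": 100},
}


def arm_name(test_kind: str, transform_tag: str) -> str:
    """Table column name of an analysis arm, e.g. ('student','rank') -> 'Rank_ST'."""
    return _ARM_NAMES[(test_kind, transform_tag)]


@dataclass(frozen=True)
class StudyCell:
    """One estimated proportion of the study grid with its Monte-Carlo se."""

    scenario: str
    homoscedastic: bool
    g2: float
    test_kind: str
    transform_tag: str
    measure: str  # 'fwer' | 'power' | 'false_positive'
    n_replicates: int
    estimate: float

    @property
    def mc_se(self) -> float:
        p = self.estimate
        return float(np.sqrt(p * (1.0 - p) / self.n_replicates))


@dataclass
class StudyTables:
    """Flat collection of study cells plus run metadata."""

    cells: list[StudyCell] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "scenario": c.scenario,
            "variances": "Equal" if c.homoscedastic else "Unequal",
            "g2": c.g2,
            "arm": arm_name(c.test_kind, c.transform_tag),
            "measure": c.measure,
            "estimate": c.estimate,
            "mc_se": c.mc_se,
            "n_replicates": c.n_replicates,
        } for c in self.cells]
        return pd.DataFrame(rows)


def bradley_check(rate: float, alpha: float) -> bool:
    """Liberal robustness criterion: 0.5*alpha <= rate <= 1.5*alpha (inclusive)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 0.5 * alpha <= rate <= 1.5 * alpha


def _permutation_indices(cfg: SimulationConfig, acfg: AnalysisConfig,
                         replicate_index: int, n: int) -> np.ndarray:
    """Per-replicate permutation index matrix, shared across analysis arms."""
    ss = np.random.SeedSequence(
        [int(acfg.seed), _setting_code(cfg), int(replicate_index), 7])
    rng = np.random.default_rng(ss)
    return rng.permuted(np.tile(np.arange(n), (acfg.n_permutations, 1)), axis=1)


def _replicate_indicators(values: np.ndarray, trait: np.ndarray,
                          perm_idx: np.ndarray, acfg: AnalysisConfig,
                          transform_tag: str) -> tuple[bool, bool, bool]:
    x = apply_transform(transform_tag, trait)
    T = np.concatenate([x[:, None], x[perm_idx].T], axis=1)
    F = _pair_scan(values, T, acfg)
    adjusted = stepdown_maxt(F[:, 0], F[:, 1:])
    sig = adjusted <= acfg.alpha_overall
    causal = bool(sig[0])  # pair (0, 1) is the first lexicographic pair
    noncausal = bool(sig[1:].any())
    return causal, noncausal, causal or noncausal


def run_replicate(cfg: SimulationConfig, acfg: AnalysisConfig,
                  transform: str = "raw", replicate_index: int = 0
                  ) -> tuple[bool, bool, bool]:
    """Simulate one dataset and analyze it with a single arm.

    Returns (causal_significant, any_noncausal_significant, any_significant)
    at ``acfg.alpha_overall`` on maxT-adjusted p-values.  Deterministic given
    (cfg.seed, acfg.seed, replicate_index).
    """
    G, trait, _ = simulate_replicate(cfg, replicate_index)
    perm_idx = _permutation_indices(cfg, acfg, replicate_index, cfg.n_individuals)
    return _replicate_indicators(G.values, trait, perm_idx, acfg, transform)


def run_setting(cfg: SimulationConfig, acfg: AnalysisConfig,
                arms=(("student", "raw"),), n_replicates: int | None = None,
                progress: bool = False) -> dict[tuple[str, str], np.ndarray]:
    """Run all requested arms over the replicates of one simulation setting.

    Each replicate's dataset and permutation indices are shared across arms.
    Returns, per arm, a boolean (R, 3) array with columns
    (causal_significant, any_noncausal_significant, any_significant).
    """
    R = cfg.n_replicates if n_replicates is None else int(n_replicates)
    if R < 1:
        raise ValueError("replicate count must be at least 1")
    arms = [tuple(a) for a in arms]
    out = {arm: np.zeros((R, 3), dtype=bool) for arm in arms}
    acfgs = {test: replace(acfg, test_kind=test) for test in {a[0] for a in arms}}
    for r in range(R):
        G, trait, _ = simulate_replicate(cfg, r)
        perm_idx = _permutation_indices(cfg, acfg, r, cfg.n_individuals)
        for test, tag in arms:
            out[(test, tag)][r] = _replicate_indicators(
                G.values, trait, perm_idx, acfgs[test], tag)
        if progress and (r + 1) % 10 == 0:
            log.info("setting %s/%s/g2=%.2f: replicate %d/%d",
                     cfg.scenario, "eq" if cfg.homoscedastic else "uneq", cfg.g2,
                     r + 1, R)
    return out


def _cells_from_indicators(cfg: SimulationConfig, test: str, tag: str,
                           ind: np.ndarray) -> list[StudyCell]:
    R = ind.shape[0]
    common = dict(scenario=cfg.scenario, homoscedastic=cfg.homoscedastic,
                  g2=cfg.g2, test_kind=test, transform_tag=tag, n_replicates=R)
    if cfg.g2 == 0.0:
        return [StudyCell(measure="fwer", estimate=float(ind[:, 2].mean()), **common)]
    return [
        StudyCell(measure="power", estimate=float(ind[:, 0].mean()), **common),
        StudyCell(measure="false_positive", estimate=float(ind[:, 1].mean()), **common),
    ]


def estimate_rates(cfg: SimulationConfig, acfg: AnalysisConfig,
                   transform: str = "raw", n_replicates: int | None = None
                   ) -> list[StudyCell]:
    """Estimate the rates of one grid cell: FWER under g2=0, else power + FP."""
    ind = run_setting(cfg, acfg, arms=[(acfg.test_kind, transform)],
                      n_replicates=n_replicates)[(acfg.test_kind, transform)]
    return _cells_from_indicators(cfg, acfg.test_kind, transform, ind)


def _checkpoint_key(cfg: SimulationConfig, acfg: AnalysisConfig, R: int) -> str:
    payload = json.dumps({
        "scenario": cfg.scenario, "homo": cfg.homoscedastic, "g2": cfg.g2,
        "n": cfg.n_individuals, "snps": cfg.n_noise_snps + 2, "seed": cfg.seed,
        "aseed": acfg.seed, "B": acfg.n_permutations, "alpha": acfg.alpha_overall,
        "alpha_label": acfg.alpha_label, "min_cell": acfg.min_cell, "R": R,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(cfg: SimulationConfig, acfg: AnalysisConfig,
              scenarios=FAMILIES, variance_settings=(True, False),
              g2_values=(0.0, 0.05, 0.1), arms=TABLE_ARMS,
              n_replicates: int | None = None,
              checkpoint_dir: str | Path | None = None,
              progress: bool = False) -> StudyTables:
    """Run the full grid: settings x arms, with optional per-setting checkpoints.

    Interrupted studies resume: each (setting, arm-set) indicator block is
    written to ``checkpoint_dir`` as JSON and reloaded when the configuration
    hash matches.
    """
    R = cfg.n_replicates if n_replicates is None else int(n_replicates)
    tables = StudyTables(metadata={
        "seed": cfg.seed, "analysis_seed": acfg.seed, "n_replicates": R,
        "n_permutations": acfg.n_permutations, "n_individuals": cfg.n_individuals,
        "n_snps": cfg.n_noise_snps + 2, "alpha": acfg.alpha_overall,
    })
    ckdir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckdir is not None:
        ckdir.mkdir(parents=True, exist_ok=True)
    for scenario in scenarios:
        for homo in variance_settings:
            for g2 in g2_values:
                setting = replace(cfg, scenario=scenario, homoscedastic=homo, g2=g2)
                ind_by_arm = None
                ckfile = None
                if ckdir is not None:
                    ckfile = ckdir / f"setting_{_checkpoint_key(setting, acfg, R)}.json"
                    if ckfile.exists():
                        payload = json.loads(ckfile.read_text())
                        ind_by_arm = {
                            tuple(k.split("|")): np.array(v, dtype=bool)
                            for k, v in payload["indicators"].items()}
                        missing = [a for a in arms if tuple(a) not in ind_by_arm]
                        if missing:
                            ind_by_arm = None
                if ind_by_arm is None:
                    ind_by_arm = run_setting(setting, acfg, arms=arms,
                                             n_replicates=R, progress=progress)
                    if ckfile is not None:
                        ckfile.write_text(json.dumps({"indicators": {
                            "|".join(arm): ind.astype(int).tolist()
                            for arm, ind in ind_by_arm.items()}}))
                for (test, tag) in arms:
                    tables.cells.extend(_cells_from_indicators(
                        setting, test, tag, ind_by_arm[(test, tag)]))
    return tables


def render_tables(tables: StudyTables) -> dict[str, pd.DataFrame]:
    """Pivot study cells into the three report layouts.

    'fwer' (rows: distribution x variances), 'power' and 'false_positive'
    (rows: g2 x distribution x variances); columns are the analysis arms.
    Raises if the grid is empty or a pivot cell is missing.
    """
    frame = tables.to_frame()
    if frame.empty:
        raise ValueError("study grid is empty")
    order = [arm_name(*a) for a in TABLE_ARMS if arm_name(*a) in set(frame["arm"])]
    out: dict[str, pd.DataFrame] = {}
    for measure, index in (("fwer", ["scenario", "variances"]),
                           ("power", ["g2", "scenario", "variances"]),
                           ("false_positive", ["g2", "scenario", "variances"])):
        sub = frame[frame["measure"] == measure]
        if sub.empty:
            continue
        piv = sub.pivot_table(index=index, columns="arm", values="estimate",
                              sort=False)
        if piv.isna().any().any():
            raise ValueError(f"incomplete study grid for measure {measure!r}")
        out[measure] = piv[order]
    if not out:
        raise ValueError("no recognized measures in study grid")
    return out
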