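"""Synthetic genotypes and quantitative traits for two-locus epistasis studies.

The generator emulates a pure-epistasis ("checkerboard") two-locus model: an
individual's trait mean is elevated by an effect size ``beta`` if and only if
it is heterozygous at exactly one of the two causal SNPs and homozygous at the
other.  With both causal minor-allele frequencies at 0.5 under Hardy-Weinberg
equilibrium the four elevated cells of the 3x3 two-locus genotype grid carry
half the population, and neither SNP shows a marginal (main) effect — the
signal is purely interactive.

Residual trait variation is drawn, conditionally on the two-locus genotype
cell, from one of three families:

* ``normal``      — Gaussian; heteroscedastic settings draw the nine per-cell
  variances from U(1, 10), homoscedastic settings use their average.
* ``chi_square``  — central chi-square with 2 df (homoscedastic) or noncentral
  chi-square with per-cell df ~ U(2, 10) and ncp = maxncp - df so that every
  cell keeps mean maxncp = 10 while variances 2*df + 4*ncp span (20, 36].
* ``t_dist``      — Student's t with 3 df; heteroscedastic settings rescale to
  per-cell target variances drawn from U(3, 10).

The effect size is calibrated so that the epistatic component explains a
requested fraction ``g2`` of the total phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "ScenarioSpec",
    "GenotypeMatrix",
    "FAMILIES",
    "draw_noise_mafs",
    "simulate_genotypes",
    "m170_high_indicator",
    "make_scenario",
    "calibrate_effect",
    "p_high_from_mafs",
    "simulate_trait",
    "simulate_replicate",
    "replicate_rng",
]

#: canonical distribution-family tags (aliases accepted on input)
FAMILIES = ("normal", "chi_square", "t_dist")

_FAMILY_ALIASES = {
    "normal": "normal",
    "gaussian": "normal",
    "chi_square": "chi_square",
    "chisq": "chi_square",
    "chi2": "chi_square",
    "t_dist": "t_dist",
    "t": "t_dist",
    "student_t": "t_dist",
}


def canonical_family(name: str) -> str:
    try:
        return _FAMILY_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown distribution family {name!r}; expected one of {FAMILIES}") from None


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation setting of the robustness study.

    Defaults are the study conditions: 500 unrelated individuals, 2 causal
    SNPs at MAF 0.5 plus 98 noise SNPs with MAF ~ U(0.05, 0.5), 1000
    replicates per setting.
    """

    n_individuals: int = 500
    n_noise_snps: int = 98
    causal_maf: float = 0.5
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    g2: float = 0.0
    scenario: str = "normal"
    homoscedastic: bool = True
    n_replicates: int = 1000
    seed: int = 0
    #: heteroscedastic t-family mode: "variance" (rescale t(3) draws to
    #: per-cell variances ~ U(3,10)) or "df" (per-cell df ~ U(3,10))
    t_hetero_mode: str = "variance"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_noise_snps < 0:
            raise ValueError("n_noise_snps must be nonnegative")
        if not 0.0 < self.causal_maf <= 0.5:
            raise ValueError("causal_maf must be in (0, 0.5]")
        lo, hi = self.noise_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("noise_maf_range must be ordered and within (0, 0.5]")
        if not 0.0 <= self.g2 < 1.0:
            raise ValueError("g2 must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.t_hetero_mode not in ("variance", "df"):
            raise ValueError("t_hetero_mode must be 'variance' or 'df'")
        object.__setattr__(self, "scenario", canonical_family(self.scenario))


@dataclass
class ScenarioSpec:
    """Per-cell residual distribution parameters for one simulation setting.

    All per-cell arrays are 3x3, indexed by the genotype codes of the two
    causal SNPs.  ``effect_size`` is the calibrated mean shift added to the
    four checkerboard "high" cells.
    """

    family: str
    per_cell_variance: np.ndarray  # 3x3 residual variances
    per_cell_df: np.ndarray | None = None
    per_cell_ncp: np.ndarray | None = None
    per_cell_scale: np.ndarray | None = None  # t-family rescaling factors
    max_ncp: float = 10.0
    effect_size: float = 0.0

    @property
    def mean_residual_variance(self) -> float:
        """Average of the nine per-cell residual variances."""
        return float(np.mean(self.per_cell_variance))


@dataclass
class GenotypeMatrix:
    """n x m matrix of minor-allele counts (0/1/2).

    Wild-type (homozygous major) individuals are coded 0, heterozygotes 1,
    homozygous-minor 2.  In simulated data columns 0 and 1 are the causal
    pair (SNP1, SNP2) by convention.
    """

    values: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.isin(v, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        self.values = v.astype(np.int8, copy=False)
        if not self.snp_ids:
            self.snp_ids = [f"SNP{j + 1}" for j in range(v.shape[1])]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(v.shape[0])]
        if len(self.snp_ids) != v.shape[1]:
            raise ValueError("snp_ids length does not match number of columns")
        if len(self.individual_ids) != v.shape[0]:
            raise ValueError("individual_ids length does not match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def draw_noise_mafs(
    k: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> np.ndarray:
    """Draw ``k`` noise-SNP minor-allele frequencies i.i.d. uniform on ``maf_range``."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    lo, hi = maf_range
    return rng.uniform(lo, hi, size=k)


def simulate_genotypes(n: int, mafs: np.ndarray, rng: np.random.Generator) -> GenotypeMatrix:
    """Simulate unlinked SNP genotypes under Hardy-Weinberg equilibrium.

    Each genotype is the minor-allele count Binomial(2, maf); columns are
    mutually independent (linkage equilibrium).
    """
    if n < 1:
        raise ValueError("n must be positive")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1:
        raise ValueError("mafs must be a 1-D vector")
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("every maf must lie in (0, 0.5]")
    values = rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)
    return GenotypeMatrix(values=values)


def m170_high_indicator(g1, g2):
    """Checkerboard high-trait indicator: heterozygous at exactly one locus.

    True for cells (0,1), (2,1), (1,0), (1,2); false for the double
    heterozygote (1,1) and all double homozygotes.  Accepts scalars or
    arrays of genotype codes in {0, 1, 2}.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if not (np.isin(g1, (0, 1, 2)).all() and np.isin(g2, (0, 1, 2)).all()):
        raise ValueError("genotype codes must be in {0, 1, 2}")
    out = (g1 == 1) ^ (g2 == 1)
    return bool(out) if out.ndim == 0 else out


def make_scenario(
    scenario: str,
    homoscedastic: bool,
    rng: np.random.Generator,
    *,
    max_ncp: float = 10.0,
    t_hetero_mode: str = "variance",
) -> ScenarioSpec:
    """Draw the per-cell residual-distribution parameters for one replicate.

    normal:      heteroscedastic — nine variances ~ U(1,10);
                 homoscedastic — all nine set to the average of one such draw.
    chi_square:  homoscedastic — central chi2(2) in every cell;
                 heteroscedastic — df ~ U(2,10), ncp = max_ncp - df, giving a
                 constant cell mean max_ncp and variances 2*df + 4*ncp.
    t_dist:      homoscedastic — t(3) in every cell; heteroscedastic — either
                 per-cell target variances ~ U(3,10) imposed by rescaling t(3)
                 draws (default) or per-cell df ~ U(3,10).
    """
    family = canonical_family(scenario)
    shape = (3, 3)
    if family == "normal":
        variances = rng.uniform(1.0, 10.0, size=shape)
        if homoscedastic:
            variances = np.full(shape, variances.mean())
        return ScenarioSpec(family=family, per_cell_variance=variances)
    if family == "chi_square":
        if homoscedastic:
            df = np.full(shape, 2.0)
            ncp = np.zeros(shape)
        else:
            df = rng.uniform(2.0, 10.0, size=shape)
            ncp = max_ncp - df
        variances = 2.0 * df + 4.0 * ncp
        return ScenarioSpec(
            family=family, per_cell_variance=variances, per_cell_df=df,
            per_cell_ncp=ncp, max_ncp=max_ncp,
        )
    # t_dist
    if homoscedastic:
        df = np.full(shape, 3.0)
        scale = np.ones(shape)
        variances = np.full(shape, 3.0)  # var of t(3) = df/(df-2)
    elif t_hetero_mode == "variance":
        df = np.full(shape, 3.0)
        variances = rng.uniform(3.0, 10.0, size=shape)
        scale = np.sqrt(variances / 3.0)
    elif t_hetero_mode == "df":
        df = rng.uniform(3.0, 10.0, size=shape)
        scale = np.ones(shape)
        variances = df / (df - 2.0)
    else:
        raise ValueError("t_hetero_mode must be 'variance' or 'df'")
    return ScenarioSpec(
        family=family, per_cell_variance=variances, per_cell_df=df, per_cell_scale=scale,
    )


def p_high_from_mafs(maf1: float, maf2: float) -> float:
    """P(exactly one heterozygous locus) under HWE at the two causal SNPs."""
    h1 = 2.0 * maf1 * (1.0 - maf1)
    h2 = 2.0 * maf2 * (1.0 - maf2)
    return h1 * (1.0 - h2) + h2 * (1.0 - h1)


def calibrate_effect(g2: float, p_high: float, residual_variance: float) -> float:
    """Mean shift beta such that the epistatic component explains fraction g2.

    Adding beta to a Bernoulli(p_high) indicator on top of residual variance
    sigma2 gives genetic variance beta^2 * p*(1-p) and total variance
    beta^2 * p*(1-p) + sigma2, so

        beta = sqrt( g2/(1-g2) * sigma2 / (p_high*(1-p_high)) ).
    """
    if not 0.0 <= g2 < 1.0:
        raise ValueError("g2 must be in [0, 1)")
    if not 0.0 < p_high < 1.0:
        raise ValueError("p_high must be in (0, 1)")
    if residual_variance <= 0.0:
        raise ValueError("residual_variance must be positive")
    if g2 == 0.0:
        return 0.0
    return float(np.sqrt(g2 / (1.0 - g2) * residual_variance / (p_high * (1.0 - p_high))))


def simulate_trait(G: GenotypeMatrix, spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one quantitative trait vector conditional on the causal pair.

    trait_i = beta * I(high cell) + residual_i, with the residual drawn from
    the cell's distribution per ``spec``; residuals independent across
    individuals.  The causal pair is columns 0 and 1 of ``G``.
    """
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if values.shape[1] < 2:
        raise ValueError("genotype matrix needs at least the two causal columns")
    g1 = values[:, 0].astype(np.intp)
    g2 = values[:, 1].astype(np.intp)
    n = values.shape[0]
    if spec.family == "normal":
        sd = np.sqrt(spec.per_cell_variance)[g1, g2]
        residual = rng.normal(0.0, sd)
    elif spec.family == "chi_square":
        df = spec.per_cell_df[g1, g2]
        ncp = spec.per_cell_ncp[g1, g2]
        if np.any(ncp > 0):
            residual = rng.noncentral_chisquare(df, ncp)
        else:
            residual = rng.chisquare(df)
    elif spec.family == "t_dist":
        df = spec.per_cell_df[g1, g2]
        scale = spec.per_cell_scale[g1, g2]
        residual = rng.standard_t(df) * scale
    else:  # pragma: no cover - guarded by canonical_family
        raise ValueError(f"unknown family {spec.family!r}")
    high = m170_high_indicator(g1, g2)
    assert residual.shape == (n,)
    return spec.effect_size * high + residual


def _setting_code(cfg: SimulationConfig) -> int:
    """Stable nonnegative integer identifying a simulation setting."""
    fam = FAMILIES.index(cfg.scenario)
    return (
        fam * 1_000_000
        + int(cfg.homoscedastic) * 100_000
        + int(round(cfg.g2 * 1000.0)) * 10
        + (0 if cfg.t_hetero_mode == "variance" else 1)
    )


def replicate_rng(cfg: SimulationConfig, replicate_index: int) -> np.random.Generator:
    """Deterministic per-replicate random stream derived from the master seed."""
    ss = np.random.SeedSequence([int(cfg.seed), _setting_code(cfg), int(replicate_index)])
    return np.random.default_rng(ss)


def simulate_replicate(
    cfg: SimulationConfig, replicate_index: int = 0
) -> tuple[GenotypeMatrix, np.ndarray, ScenarioSpec]:
    """Generate one full replicate: genotypes, trait and the realized spec.

    Noise-SNP MAFs and the scenario's per-cell parameters are redrawn per
    replicate; everything is reproducible given (cfg.seed, replicate_index).
    """
    rng = replicate_rng(cfg, replicate_index)
    mafs = np.concatenate([
        np.full(2, cfg.causal_maf),
        draw_noise_mafs(cfg.n_noise_snps, rng, cfg.noise_maf_range),
    ])
    G = simulate_genotypes(cfg.n_individuals, mafs, rng)
    spec = make_scenario(
        cfg.scenario, cfg.homoscedastic, rng, t_hetero_mode=cfg.t_hetero_mode
    )
    p_high = p_high_from_mafs(cfg.causal_maf, cfg.causal_maf)
    spec.effect_size = calibrate_effect(cfg.g2, p_high, spec.mean_residual_variance)
    trait = simulate_trait(G, spec, rng)
    return G, trait, spec
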