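"""The MB-MDR engine for quantitative traits.

For every unordered SNP pair the method proceeds in two steps:

1. *Dimensionality reduction.*  The nine two-locus genotype cells are each
   compared against the pooled remaining individuals with a two-group test
   (pooled-variance Student's t or Welch's t).  A cell is labeled H (high) if
   the test is significant at ``alpha_label`` with the cell mean above the
   rest, L (low) if significant below, and O otherwise.  Cells contributing
   fewer than ``min_cell`` individuals to either side of the comparison are
   labeled O without testing.

2. *Association on the reduced construct.*  The pooled H individuals are
   tested against everyone else, and likewise the pooled L individuals; the
   per-pair evidence is the larger of the two squared statistics (an ANOVA F
   value).  A branch with no labeled cells, or violating the ``min_cell``
   rule, contributes F = 0.

Familywise error across all pairs is controlled by the Westfall-Young
step-down maxT permutation procedure: the trait vector is permuted across
individuals (genotypes fixed), the *entire* two-step analysis is re-run per
permutation, and adjusted p-values are formed from successive maxima of the
permutation statistics with the +1 numerator/denominator convention.

Public operations mirror the procedure (``partition_pair``, ``label_cells``,
``step2_statistic``, ``analyze_all_pairs``, ``maxt_adjust``, ``run_mbmdr``,
``export_null_statistics``).  Internally a single vectorized scan computes
per-cell trait sums and sums of squares for all pairs and all permutations
at once via genotype-grouped matrix products, which is what makes exhaustive
relabeling inside every permutation affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri, stdtr

from .assoc import get_test
from .simulate import GenotypeMatrix

__all__ = [
    "AnalysisConfig",
    "CellPartition",
    "LabelGrid",
    "partition_pair",
    "label_cells",
    "step2_statistic",
    "analyze_all_pairs",
    "maxt_adjust",
    "stepdown_maxt",
    "run_mbmdr",
    "export_null_statistics",
    "pair_index",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of one MB-MDR analysis.

    ``alpha_label`` is the two-sided level of the cell-vs-rest labeling tests
    (an MB-MDR convention; 0.1 by default).  ``min_cell`` is the minimum
    number of individuals required on *both* sides of every internal
    comparison (default 10).  ``n_permutations`` is the number B of trait
    permutations for the maxT correction (999 at full scale), and
    ``alpha_overall`` the significance level applied to adjusted p-values.
    """

    test_kind: str = "student"
    alpha_label: float = 0.1
    min_cell: int = 10
    n_permutations: int = 999
    alpha_overall: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_kind not in ("student", "welch"):
            raise ValueError("test_kind must be 'student' or 'welch'")
        if not 0.0 < self.alpha_label < 1.0:
            raise ValueError("alpha_label must be in (0, 1)")
        if self.min_cell < 2:
            raise ValueError("min_cell must be at least 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if not 0.0 < self.alpha_overall < 1.0:
            raise ValueError("alpha_overall must be in (0, 1)")


@dataclass
class CellPartition:
    """Membership of the nine two-locus genotype cells for one SNP pair."""

    indices: list  # indices[a][b] -> integer index array of individuals
    counts: np.ndarray  # 3x3 cell sizes
    n: int


@dataclass
class LabelGrid:
    """3x3 assignment of H/L/O to the two-locus genotype cells."""

    labels: np.ndarray  # 3x3 array of 'H'/'L'/'O'
    cell_counts: np.ndarray  # 3x3 nonnegative integers


def _genotype_values(G) -> np.ndarray:
    return G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)


def pair_index(m: int):
    """Lexicographic (i, j) with i < j for all m*(m-1)/2 SNP pairs."""
    iu = np.triu_indices(m, k=1)
    return iu[0], iu[1]


def partition_pair(G, i: int, j: int) -> CellPartition:
    """Assign each individual to one of the nine cells of SNP pair (i, j)."""
    values = _genotype_values(G)
    if i == j:
        raise ValueError("pair requires two distinct SNPs")
    g1 = values[:, i]
    g2 = values[:, j]
    indices = [[np.flatnonzero((g1 == a) & (g2 == b)) for b in range(3)] for a in range(3)]
    counts = np.array([[idx.size for idx in row] for row in indices])
    return CellPartition(indices=indices, counts=counts, n=values.shape[0])


def label_cells(cells: CellPartition, t, cfg: AnalysisConfig) -> LabelGrid:
    """Label each genotype cell H/L/O via the cell-vs-rest association test."""
    t = np.asarray(t, dtype=float)
    test = get_test(cfg.test_kind)
    labels = np.full((3, 3), "O", dtype="U1")
    for a in range(3):
        for b in range(3):
            idx = cells.indices[a][b]
            n1 = idx.size
            n0 = cells.n - n1
            if n1 < cfg.min_cell or n0 < cfg.min_cell:
                continue
            mask = np.zeros(cells.n, dtype=bool)
            mask[idx] = True
            res = test(t[mask], t[~mask])
            if res.valid and res.p_value <= cfg.alpha_label:
                if res.statistic > 0:
                    labels[a, b] = "H"
                elif res.statistic < 0:
                    labels[a, b] = "L"
    return LabelGrid(labels=labels, cell_counts=cells.counts.copy())


def step2_statistic(grid: LabelGrid, cells: CellPartition, t, cfg: AnalysisConfig) -> float:
    """max(F_H, F_L): pooled H (or L) individuals versus everyone else."""
    t = np.asarray(t, dtype=float)
    test = get_test(cfg.test_kind)
    best = 0.0
    for lab in ("H", "L"):
        members = [cells.indices[a][b] for a in range(3) for b in range(3)
                   if grid.labels[a, b] == lab]
        if not members:
            continue
        idx = np.concatenate(members)
        if idx.size < cfg.min_cell or cells.n - idx.size < cfg.min_cell:
            continue
        mask = np.zeros(cells.n, dtype=bool)
        mask[idx] = True
        res = test(t[mask], t[~mask])
        if res.valid:
            best = max(best, res.f_value)
    return best


# ---------------------------------------------------------------------------
# vectorized scan: all pairs x all trait columns at once
# ---------------------------------------------------------------------------

def _pair_scan(values: np.ndarray, T: np.ndarray, cfg: AnalysisConfig,
               collect_cell: tuple[int, int] | None = None):
    """Step-2 F values for every SNP pair and every trait column.

    ``T`` is an (n, K) matrix whose columns are trait vectors (e.g. the
    observed trait followed by permutations).  Returns an (n_pairs, K) array
    in lexicographic pair order; when ``collect_cell`` is given, also returns
    the cell-vs-rest F values for that fixed genotype cell.

    Per SNP i the individuals are grouped by their genotype at i; grouped
    matrix products against genotype indicators of SNPs j > i produce the
    per-cell trait sums and sums of squares for all pairs (i, j) and all K
    columns simultaneously.  The two-group statistics are then evaluated
    from these moments, exactly as the per-pair reference operations do.
    """
    n, m = values.shape
    if m < 2:
        raise ValueError("at least two SNPs are required")
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T[:, None]
    K = T.shape[1]
    TT = np.concatenate([T, T * T], axis=1)  # (n, 2K)
    stot = T.sum(axis=0)  # (K,)
    qtot = (T * T).sum(axis=0)
    min_cell = cfg.min_cell
    student = cfg.test_kind == "student"
    alpha = cfg.alpha_label
    if student:
        crit2 = float(stats.t.isf(alpha / 2.0, n - 2)) ** 2
    else:
        zcrit2 = float(ndtri(1.0 - alpha / 2.0)) ** 2  # lower bound over all df
    n_pairs = m * (m - 1) // 2
    F = np.zeros((n_pairs, K))
    cellF = np.zeros((n_pairs, K)) if collect_cell is not None else None
    codes = np.arange(3, dtype=values.dtype)
    row0 = 0
    for i in range(m - 1):
        mj = m - i - 1
        Gs = values[:, i + 1:]
        gcol = values[:, i]
        counts = np.zeros((3, 3, mj))
        csum = np.empty((3, 3, mj, K))
        csq = np.empty((3, 3, mj, K))
        for a in range(3):
            rows = np.flatnonzero(gcol == a)
            if rows.size == 0:
                counts[a] = 0.0
                csum[a] = 0.0
                csq[a] = 0.0
                continue
            Gsub = Gs[rows]
            Z = (Gsub[:, None, :] == codes[None, :, None]).reshape(rows.size, 3 * mj)
            Zf = np.ascontiguousarray(Z, dtype=np.float64)
            counts[a] = Zf.sum(axis=0).reshape(3, mj)
            R = (Zf.T @ TT[rows]).reshape(3, mj, 2 * K)
            csum[a] = R[:, :, :K]
            csq[a] = R[:, :, K:]

        n1 = counts[..., None]  # (3,3,mj,1)
        n0 = float(n) - n1
        size_ok = (n1 >= min_cell) & (n0 >= min_cell)
        with np.errstate(divide="ignore", invalid="ignore"):
            dm = csum / n1 - (stot - csum) / n0
            ss1 = csq - csum * csum / n1
            ss0 = (qtot - csq) - (stot - csum) ** 2 / n0
            if student:
                se2 = (ss1 + ss0) / (n - 2) * (1.0 / n1 + 1.0 / n0)
                t2 = dm * dm / se2
                sig = size_ok & (se2 > 0) & (t2 >= crit2)
            else:
                v1 = ss1 / (n1 - 1.0)
                v0 = ss0 / (n0 - 1.0)
                w1 = v1 / n1
                w0 = v0 / n0
                se2 = w1 + w0
                t2 = dm * dm / se2
                cand = size_ok & (se2 > 0) & (t2 >= zcrit2)
                sig = np.zeros(t2.shape, dtype=bool)
                if cand.any():
                    df = se2 * se2 / (w1 * w1 / (n1 - 1.0) + w0 * w0 / (n0 - 1.0))
                    pv = 2.0 * stdtr(df[cand], -np.sqrt(t2[cand]))
                    sig[cand] = pv <= alpha
            labels = np.zeros(t2.shape, dtype=np.int8)
            labels[sig & (dm > 0)] = 1
            labels[sig & (dm < 0)] = -1

            if collect_cell is not None:
                a0, b0 = collect_cell
                fcell = np.where(
                    size_ok[a0, b0] & (se2[a0, b0] > 0) & np.isfinite(t2[a0, b0]),
                    t2[a0, b0], 0.0)
                cellF[row0:row0 + mj] = fcell

            branch = []
            for lab in (1, -1):
                mask = labels == lab
                nG = (mask * counts[..., None]).sum(axis=(0, 1))  # (mj, K)
                sG = np.where(mask, csum, 0.0).sum(axis=(0, 1))
                qG = np.where(mask, csq, 0.0).sum(axis=(0, 1))
                nC = float(n) - nG
                ok = (nG >= min_cell) & (nC >= min_cell)
                dmG = sG / nG - (stot - sG) / nC
                ssG = qG - sG * sG / nG
                ssC = (qtot - qG) - (stot - sG) ** 2 / nC
                if student:
                    se2G = (ssG + ssC) / (n - 2) * (1.0 / nG + 1.0 / nC)
                else:
                    se2G = ssG / (nG - 1.0) / nG + ssC / (nC - 1.0) / nC
                fG = dmG * dmG / se2G
                branch.append(np.where(ok & (se2G > 0) & np.isfinite(fG), fG, 0.0))
        F[row0:row0 + mj] = np.maximum(branch[0], branch[1])
        row0 += mj
    if collect_cell is not None:
        return F, cellF
    return F


def _permutation_matrix(t: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """(n, B) matrix whose columns are independent permutations of ``t``."""
    n = t.size
    idx = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)
    return t[idx].T


def analyze_all_pairs(G, t, cfg: AnalysisConfig) -> np.ndarray:
    """Observed step-2 F statistic for every SNP pair (lexicographic order)."""
    values = _genotype_values(G)
    t = np.asarray(t, dtype=float)
    return _pair_scan(values, t[:, None], cfg)[:, 0]


def stepdown_maxt(observed: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values.

    ``observed`` has one statistic per hypothesis; ``perm`` is (P, B) with
    the same statistics recomputed on B permuted datasets.  Hypotheses are
    ranked by decreasing observed statistic (stable order breaks ties); rank
    r is compared against the successive maxima over ranks >= r within each
    permutation; p = (1 + exceedances)/(B + 1); monotonicity is enforced down
    the ranking.
    """
    observed = np.asarray(observed, dtype=float)
    perm = np.asarray(perm, dtype=float)
    P, B = perm.shape
    if observed.shape != (P,):
        raise ValueError("observed and permutation statistics must align")
    order = np.argsort(-observed, kind="stable")
    succ = np.maximum.accumulate(perm[order][::-1], axis=0)[::-1]
    exceed = (succ >= observed[order][:, None]).sum(axis=1)
    p_sorted = (1.0 + exceed) / (B + 1.0)
    p_sorted = np.maximum.accumulate(p_sorted)
    adjusted = np.empty(P)
    adjusted[order] = p_sorted
    return adjusted


def maxt_adjust(G, t, observed: np.ndarray, cfg: AnalysisConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Adjusted p-values for ``observed`` via full re-analysis per permutation.

    The trait is permuted across individuals (genotypes fixed) B times; cell
    labeling and the step-2 statistic are recomputed from scratch inside every
    permutation before the step-down maxT adjustment is applied.
    """
    values = _genotype_values(G)
    t = np.asarray(t, dtype=float)
    perms = _permutation_matrix(t, cfg.n_permutations, rng)
    Fperm = _pair_scan(values, perms, cfg)
    return stepdown_maxt(np.asarray(observed, dtype=float), Fperm)


def _result_table(G, F_obs: np.ndarray, adjusted: np.ndarray,
                  cfg: AnalysisConfig) -> pd.DataFrame:
    values = _genotype_values(G)
    m = values.shape[1]
    ii, jj = pair_index(m)
    snp_ids = (G.snp_ids if isinstance(G, GenotypeMatrix)
               else [f"SNP{j + 1}" for j in range(m)])
    return pd.DataFrame({
        "snp_i": [snp_ids[i] for i in ii],
        "snp_j": [snp_ids[j] for j in jj],
        "step2_F": F_obs,
        "adjusted_p": adjusted,
        "significant": adjusted <= cfg.alpha_overall,
    })


def run_mbmdr(G, t, cfg: AnalysisConfig) -> pd.DataFrame:
    """Full MB-MDR screen: per-pair step-2 F and maxT-adjusted p-values.

    A pair is declared significant when its adjusted p-value does not exceed
    ``cfg.alpha_overall``.  Deterministic given inputs and ``cfg.seed``.
    """
    values = _genotype_values(G)
    t = np.asarray(t, dtype=float)
    if t.size != values.shape[0]:
        raise ValueError("trait length does not match genotype rows")
    rng = np.random.default_rng(cfg.seed)
    perms = _permutation_matrix(t, cfg.n_permutations, rng)
    T = np.concatenate([t[:, None], perms], axis=1)
    F = _pair_scan(values, T, cfg)
    adjusted = stepdown_maxt(F[:, 0], F[:, 1:])
    return _result_table(G, F[:, 0], adjusted, cfg)


def export_null_statistics(G, t, cfg: AnalysisConfig, which="step2",
                           cell: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Pooled permutation F values across all pairs, for qq diagnostics.

    ``which="cell"`` returns the cell-vs-rest squared test statistic for the
    fixed genotype ``cell`` (e.g. (0, 0) or (2, 2)); ``which="step2"``
    returns the per-pair step-2 statistic.  One value per (pair, permutation)
    is emitted, for comparison against the theoretical F(1, n-2) reference.
    """
    if which not in ("step2", "cell"):
        raise ValueError("which must be 'step2' or 'cell'")
    values = _genotype_values(G)
    t = np.asarray(t, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    perms = _permutation_matrix(t, cfg.n_permutations, rng)
    if which == "step2":
        F = _pair_scan(values, perms, cfg)
    else:
        a, b = cell
        if not (0 <= a <= 2 and 0 <= b <= 2):
            raise ValueError("cell indices must be in {0, 1, 2}")
        _, F = _pair_scan(values, perms, cfg, collect_cell=(a, b))
    return F.ravel()
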