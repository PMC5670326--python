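"""Distance-based multivariate and variance-partition statistics.

Implements the binary-marker toolchain used for dominant (presence/absence)
molecular data: pairwise squared-Euclidean distances, principal coordinates
analysis (PCoA), hierarchical analysis of molecular variance (AMOVA) with the
PhiPT fixation analogue, pairwise PhiPT matrices, and Mantel matrix
correlation — all with permutation significance.

PhiPT follows the dominant-marker convention: a distance-based AMOVA with no
within-individual level, variance components solved from expected mean
squares with unequal group sizes, and significance from permuting individuals
among populations.  Permutation p-values use the +1/+1 correction so p is
never exactly zero, and ties count as "at least as extreme".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix.

    ``kind`` records provenance (molecular, geographic, environmental) for
    report labelling only.
    """

    values: np.ndarray
    labels: list[str]
    kind: str = "molecular"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v
        self.labels = [str(x) for x in self.labels]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class AmovaResult:
    """AMOVA variance components with PhiPT and its permutation p-value.

    ``components`` maps level name -> dict(df, SS, MS, sigma2, pct).
    For a two-level analysis the levels are among/within groups; with a
    region layer they are among-regions, among-groups-within-regions and
    within-groups.  ``phi_pt`` is the among-population share of total
    variance (both hierarchy levels above individuals when regions are
    present, matching the dominant-marker convention); ``phi_rt`` and
    ``phi_pr`` are reported for the hierarchical case.
    """

    components: dict[str, dict[str, float]]
    phi_pt: float
    p_value: float
    n_permutations: int
    phi_rt: float | None = None
    phi_pr: float | None = None
    negative_components_floored: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.components).T
        df.index.name = "source"
        return df


@dataclass
class PhiPTMatrix:
    phipt: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int

    def table2_style(self) -> pd.DataFrame:
        """PhiPT with the permutation p in parentheses, lower triangle."""
        out = self.phipt.copy().astype(object)
        for i, a in enumerate(out.index):
            for j, b in enumerate(out.columns):
                if i == j:
                    out.iloc[i, j] = "-"
                else:
                    out.iloc[i, j] = f"{self.phipt.iloc[i, j]:.3f} ({self.p_values.iloc[i, j]:.4g})"
        return out


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    alternative: str = "greater"


@dataclass
class Ordination:
    """PCoA / discriminant coordinates with per-axis variance shares."""

    coordinates: pd.DataFrame
    proportion_explained: np.ndarray
    eigenvalues: np.ndarray | None = None


# ---------------------------------------------------------------------------
# distances

def binary_distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise squared-Euclidean (mismatch-count) distance on binary profiles.

    d(i, j) is the number of loci at which i and j carry different non-missing
    calls, rescaled by L / L_shared so pairs with missing data stay on the
    all-loci scale.  This is the squared Euclidean distance convention used
    for dominant binary markers feeding AMOVA and PCoA.
    """
    x = profiles.values.astype(float)
    n, n_loci = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    mask = ~np.isnan(x)
    x0 = np.where(mask, x, 0.0)
    maskf = mask.astype(float)
    # mismatches over shared loci: |xi - xj| summed where both present
    shared = maskf @ maskf.T
    agree11 = x0 @ x0.T
    present_i = (x0 * maskf) @ maskf.T  # count of xi==1 over shared loci
    present_j = present_i.T
    mism = present_i + present_j - 2 * agree11
    if np.any((shared == 0) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"samples {profiles.index[i]!r} and {profiles.index[j]!r} share no "
            "non-missing loci"
        )
    with np.errstate(invalid="ignore"):
        d = mism * (n_loci / shared)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return DistanceMatrix(d, list(profiles.index.astype(str)), kind="molecular")


# ---------------------------------------------------------------------------
# PCoA

def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    Centers -d**2 / 2, eigendecomposes, and keeps axes sorted by eigenvalue.
    Percent variance is each positive eigenvalue over the sum of positive
    eigenvalues; negative eigenvalues (non-Euclidean input) are retained in
    ``eigenvalues`` rather than silently dropped.
    """
    n = d.n
    a = -0.5 * d.values ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ a @ centerer
    evals, evecs = linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    if not pos.any():
        logger.warning("all-zero distance matrix: degenerate ordination")
        coords = np.zeros((n, 1))
        return Ordination(
            coordinates=pd.DataFrame(coords, index=d.labels, columns=["PCo1"]),
            proportion_explained=np.zeros(1),
            eigenvalues=evals,
        )
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    n_neg = int((evals < -1e-9 * max(1.0, evals.max())).sum())
    if n_neg:
        logger.info("PCoA: %d negative eigenvalues (non-Euclidean distances)", n_neg)
    return Ordination(
        coordinates=pd.DataFrame(coords, index=d.labels, columns=cols),
        proportion_explained=prop,
        eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# AMOVA / PhiPT

def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    """Sum over groups of (sum of pairwise squared distances) / n_g."""
    total = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2 * len(idx))
    return total


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _two_level_components(d2: np.ndarray, groups: np.ndarray):
    """Variance components for a one-layer hierarchy (groups over individuals)."""
    n = d2.shape[0]
    idx = _group_indices(groups)
    sizes = np.array([len(i) for i in idx], dtype=float)
    g = len(idx)
    ss_total = d2.sum() / (2 * n)
    ss_within = _ss_within(d2, idx)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes ** 2).sum() / n) / (g - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    return {
        "among": {"df": df_among, "SS": ss_among, "MS": ms_among, "sigma2": sigma_among},
        "within": {"df": df_within, "SS": ss_within, "MS": ms_within, "sigma2": sigma_within},
    }


def _three_level_components(d2: np.ndarray, pops: np.ndarray, regions: np.ndarray):
    """Components for regions > populations > individuals (no within-individual level)."""
    n = d2.shape[0]
    pop_idx = _group_indices(pops)
    reg_idx = _group_indices(regions)
    n_pops, n_regs = len(pop_idx), len(reg_idx)
    ss_total = d2.sum() / (2 * n)
    ss_wp = _ss_within(d2, pop_idx)
    ss_wr = _ss_within(d2, reg_idx)  # within regions (pops pooled)
    ss_ap = ss_wr - ss_wp  # among pops within regions
    ss_ar = ss_total - ss_wr
    df_ar, df_ap, df_wp = n_regs - 1, n_pops - n_regs, n - n_pops
    ms_ar, ms_ap, ms_wp = ss_ar / df_ar, ss_ap / df_ap, ss_wp / df_wp

    # EMS coefficients for unequal sizes (Excoffier-style)
    pop_sizes = {}
    for i, g in zip(pop_idx, pd.unique(pops)):
        pop_sizes[g] = len(i)
    reg_of_pop = {}
    for g in pd.unique(pops):
        r = pd.unique(regions[pops == g])
        reg_of_pop[g] = r[0]
    reg_sizes = {r: len(i) for r, i in zip(pd.unique(regions), reg_idx)}

    sum_np2_over_nr = 0.0
    for g, npop in pop_sizes.items():
        sum_np2_over_nr += npop ** 2 / reg_sizes[reg_of_pop[g]]
    sum_np2_over_n = sum(v ** 2 for v in pop_sizes.values()) / n
    sum_nr2_over_n = sum(v ** 2 for v in reg_sizes.values()) / n

    n1 = (n - sum_np2_over_nr) / df_ap
    n2 = (sum_np2_over_nr - sum_np2_over_n) / df_ar
    n3 = (n - sum_nr2_over_n) / df_ar

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ar - sigma_c - n2 * sigma_b) / n3
    return {
        "among_regions": {"df": df_ar, "SS": ss_ar, "MS": ms_ar, "sigma2": sigma_a},
        "among_pops_within_regions": {"df": df_ap, "SS": ss_ap, "MS": ms_ap, "sigma2": sigma_b},
        "within_pops": {"df": df_wp, "SS": ss_wp, "MS": ms_wp, "sigma2": sigma_c},
    }


def _phipt_from_d2(d2: np.ndarray, groups: np.ndarray) -> float:
    comp = _two_level_components(d2, groups)
    sa = max(comp["among"]["sigma2"], 0.0)
    sw = max(comp["within"]["sigma2"], 0.0)
    tot = sa + sw
    return sa / tot if tot > 0 else 0.0


def _validate_grouping(groups: np.ndarray) -> None:
    vals, counts = np.unique(groups, return_counts=True)
    if len(vals) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = vals[counts < 2]
        raise ValueError(f"groups with a single sample: {list(bad)}")


def amova(
    profiles: pd.DataFrame,
    groups: pd.Series | dict,
    regions: pd.Series | dict | None = None,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> AmovaResult:
    """Distance-based AMOVA with PhiPT and permutation significance.

    Sums of squares come from pairwise squared distances (the binary
    mismatch-count matrix of :func:`binary_distance_matrix`); variance
    components are solved from expected mean squares with unequal group
    sizes.  With a ``regions`` layer the hierarchy is regions > groups >
    individuals and PhiPT is the share of total variance above the
    individual level.  Significance permutes individuals among groups; the
    +1/+1 correction keeps p in (0, 1].

    Negative variance components are floored at zero (flagged in the result)
    before percentages, following common dominant-marker practice.
    """
    rng = np.random.default_rng(seed)
    d2 = binary_distance_matrix(profiles).values
    groups = pd.Series(groups).loc[profiles.index].to_numpy()
    _validate_grouping(groups)

    floored = False
    if regions is None:
        comp = _two_level_components(d2, groups)
        order = ["among", "within"]
    else:
        regions = pd.Series(regions).loc[profiles.index].to_numpy()
        comp = _three_level_components(d2, groups, regions)
        order = ["among_regions", "among_pops_within_regions", "within_pops"]

    sigmas = {}
    for k in order:
        s = comp[k]["sigma2"]
        if s < 0:
            floored = True
            s = 0.0
        sigmas[k] = s
    total = sum(sigmas.values())
    if total <= 0:
        raise ValueError("total molecular variance is not positive")
    for k in order:
        comp[k]["pct"] = 100.0 * sigmas[k] / total

    if regions is None:
        phi_pt = sigmas["among"] / total
        phi_rt = phi_pr = None
    else:
        phi_rt = sigmas["among_regions"] / total
        denom_pr = sigmas["among_pops_within_regions"] + sigmas["within_pops"]
        phi_pr = sigmas["among_pops_within_regions"] / denom_pr if denom_pr > 0 else 0.0
        phi_pt = (sigmas["among_regions"] + sigmas["among_pops_within_regions"]) / total

    # permutation of individuals among populations
    p_value = np.nan
    if n_perm > 0:
        obs = _phipt_from_d2(d2, groups)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            if _phipt_from_d2(d2, perm) >= obs - 1e-12:
                count += 1
        p_value = (count + 1) / (n_perm + 1)

    return AmovaResult(
        components=comp,
        phi_pt=float(phi_pt),
        p_value=float(p_value),
        n_permutations=n_perm,
        phi_rt=None if phi_rt is None else float(phi_rt),
        phi_pr=None if phi_pr is None else float(phi_pr),
        negative_components_floored=floored,
    )


def pairwise_phipt(
    profiles: pd.DataFrame,
    groups: pd.Series | dict,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> PhiPTMatrix:
    """Pairwise-population PhiPT matrix with permutation p-values.

    Each population pair is analysed as a two-level AMOVA on the sample
    subset; p-values are reported unadjusted.  ``n_perm=0`` skips the
    permutation test (point estimates only, p = NaN).
    """
    rng = np.random.default_rng(seed)
    groups = pd.Series(groups).loc[profiles.index]
    pops = list(pd.unique(groups))
    k = len(pops)
    phipt = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    pvals = pd.DataFrame(np.full((k, k), np.nan), index=pops, columns=pops)
    d2_all = binary_distance_matrix(profiles).values
    group_arr = groups.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            sel = np.flatnonzero((group_arr == pops[i]) | (group_arr == pops[j]))
            d2 = d2_all[np.ix_(sel, sel)]
            sub_groups = group_arr[sel]
            _validate_grouping(sub_groups)
            obs = _phipt_from_d2(d2, sub_groups)
            phipt.iloc[i, j] = phipt.iloc[j, i] = obs
            if n_perm > 0:
                count = 0
                for _ in range(n_perm):
                    if _phipt_from_d2(d2, rng.permutation(sub_groups)) >= obs - 1e-12:
                        count += 1
                p = (count + 1) / (n_perm + 1)
                pvals.iloc[i, j] = pvals.iloc[j, i] = p
    np.fill_diagonal(phipt.values, 0.0)
    return PhiPTMatrix(phipt=phipt, p_values=pvals, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Mantel

def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel matrix-correlation test by row/column permutation.

    r is the Pearson correlation of the vectorised upper triangles; the null
    distribution permutes rows and columns of ``b`` simultaneously.  One-sided
    ``greater`` by default (isolation-by-distance expects a positive
    correlation); p carries the +1/+1 correction.
    """
    if a.labels != b.labels:
        raise ValueError("Mantel requires identical labels in identical order")
    n = a.n
    if n < 4:
        raise ValueError("Mantel needs at least 4 objects")
    va, vb = _triangle(a.values), _triangle(b.values)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError(
            "degenerate input: a constant distance matrix has no defined "
            "Mantel correlation"
        )
    rng = np.random.default_rng(seed)

    def _corr(x, y):
        xc, yc = x - x.mean(), y - y.mean()
        return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))

    r_obs = _corr(va, vb)
    count = 0
    iu = np.triu_indices(n, k=1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = b.values[np.ix_(perm, perm)][iu]
        r_p = _corr(va, vp)
        if alternative == "greater":
            extreme = r_p >= r_obs - 1e-12
        elif alternative == "less":
            extreme = r_p <= r_obs + 1e-12
        else:  # two-sided
            extreme = abs(r_p) >= abs(r_obs) - 1e-12
        if extreme:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, r_squared=r_obs ** 2, p_value=p, n_permutations=n_perm,
        alternative=alternative,
    )
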