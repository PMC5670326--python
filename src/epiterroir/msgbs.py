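"""Count-based differential methylation from methylation-sensitive GBS.

msGBS sequences fragments anchored at MspI cut sites, so the read count at a
locus reports how often the enzyme cut there: more CHG methylation means less
cutting and fewer reads.  Differential methylation between two regions is
therefore a two-group count comparison per locus.

The inference chain is: library-size normalisation to counts-per-million
(CPM); an abundance filter requiring a minimum CPM in a minimum number of
samples within each compared region; a negative-binomial two-group exact test
with a single common dispersion estimated by conditional maximum likelihood
on library-size-equalised pseudo-counts; log2 fold changes from shrunken
group mean CPMs; and Bonferroni / Benjamini-Hochberg adjustment.

Because counts fall with methylation, the sign convention is inverted
relative to expression analysis: a locus with *lower* CPM in a region is
*hyper*-methylated there.  :func:`differential_methylation` reports direction
for ``region_b`` relative to ``region_a`` under this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .popgen import Ordination

logger = logging.getLogger(__name__)

LOCUS_COLUMNS = ("chrom", "pos", "strand")


@dataclass
class CountMatrix:
    """msGBS locus x sample read counts with coordinates and region labels.

    Attributes
    ----------
    counts : pandas.DataFrame
        loci x samples non-negative integer read counts.
    loci : pandas.DataFrame
        One row per locus: chrom, pos (1-based cut-site position), strand.
    regions : pandas.Series
        sample -> region label.
    """

    counts: pd.DataFrame
    loci: pd.DataFrame
    regions: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("read counts must be integers")
        missing = set(self.counts.columns) - set(self.regions.index)
        if missing:
            raise ValueError(f"samples without a region label: {sorted(missing)}")
        self.regions = self.regions.loc[self.counts.columns]
        if (self.library_sizes <= 0).any():
            bad = self.counts.columns[self.library_sizes <= 0]
            raise ValueError(f"zero library size for samples: {list(bad)}")
        extra = set(self.counts.index) - set(self.loci.index)
        if extra:
            raise ValueError(f"counts contain loci absent from the locus table: {sorted(extra)[:5]}")
        self.loci = self.loci.loc[self.counts.index]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Counts per million: count * 1e6 / library size, per sample."""
        return self.counts * (1e6 / self.library_sizes)

    def subset_regions(self, *names: str) -> "CountMatrix":
        keep = self.regions.index[self.regions.isin(names)]
        return CountMatrix(self.counts[keep], self.loci.copy(), self.regions.loc[keep])


def filter_loci(
    cm: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 15,
    regions: tuple[str, str] | None = None,
    per_region: str = "each",
) -> CountMatrix:
    """Abundance filter: CPM >= ``min_cpm`` in >= ``min_samples`` samples per region.

    With ``per_region="each"`` (default) a locus must clear the threshold
    within each of the two compared regions; ``"any"`` keeps a locus passing
    in at least one.  Defaults (1 CPM, 15 samples) suit region sizes of a few
    dozen samples.
    """
    if regions is None:
        names = list(pd.unique(cm.regions))
        if len(names) != 2:
            raise ValueError(
                "filter_loci needs exactly two regions (pass `regions=` to select)"
            )
        regions = (names[0], names[1])
    if per_region not in ("each", "any"):
        raise ValueError(f"per_region must be 'each' or 'any': {per_region!r}")
    cm = cm.subset_regions(*regions)
    for name in regions:
        n_avail = int((cm.regions == name).sum())
        if n_avail < min_samples:
            raise ValueError(
                f"region {name!r} has {n_avail} samples < min_samples={min_samples}: "
                "filter unsatisfiable"
            )
    cpm = cm.cpm()
    passing = []
    for name in regions:
        cols = cm.regions.index[cm.regions == name]
        passing.append((cpm[cols] >= min_cpm).sum(axis=1) >= min_samples)
    keep = (passing[0] & passing[1]) if per_region == "each" else (passing[0] | passing[1])
    logger.info("abundance filter kept %d of %d loci", int(keep.sum()), len(keep))
    return CountMatrix(cm.counts.loc[keep], cm.loci.loc[keep], cm.regions)


# ---------------------------------------------------------------------------
# common dispersion by conditional maximum likelihood

def _equalized_pseudocounts(counts: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Scale each sample's counts to the geometric-mean library size."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = counts.to_numpy(dtype=float) * (common / lib)[None, :]
    return pseudo, common

def _cml_loglik(r: float, group_counts: list[np.ndarray]) -> float:
    """Conditional log-likelihood of a common NB size ``r`` given group sums.

    For n iid NB(r, p) samples the counts given their sum z follow a
    Dirichlet-multinomial with all concentrations r; p cancels, leaving a
    likelihood in r alone — summed here over loci and groups.
    """
    ll = 0.0
    for y in group_counts:  # loci x samples within one group
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            (gammaln(y + r) - gammaln(r)).sum()
            + (gammaln(n * r) - gammaln(z + n * r)).sum()
        )
    return ll


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: pd.Series
) -> float:
    """Common NB dispersion (1/size) by conditional maximum likelihood.

    Counts are first scaled to a common library size (geometric mean) so the
    within-group NB means are exchangeable; the conditional likelihood given
    group sums then depends only on the dispersion.  Returns 0.0 when the
    likelihood prefers the Poisson limit.
    """
    pseudo, _ = _equalized_pseudocounts(counts)
    groups = groups.loc[counts.columns]
    group_counts = [
        pseudo[:, (groups == g).to_numpy()] for g in pd.unique(groups)
    ]

    def neg_ll(log_r: float) -> float:
        return -_cml_loglik(np.exp(log_r), group_counts)

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-4), np.log(1e6)), method="bounded")
    r_hat = float(np.exp(res.x))
    if r_hat >= 1e6 * 0.99:
        return 0.0  # Poisson limit
    if not np.isfinite(res.fun):
        logger.warning("dispersion likelihood non-finite; falling back to Poisson")
        return 0.0
    return 1.0 / r_hat


# ---------------------------------------------------------------------------
# exact test

def _exact_test_pvalue(za: float, zb: float, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact p for group sums (za, zb) under a common-mean NB null.

    Conditional on the total z = za + zb, the group-A sum follows a
    beta-binomial-type distribution with shapes (n_a/phi, n_b/phi); in the
    Poisson limit (phi = 0) it is Binomial(z, n_a/(n_a+n_b)).  The p-value
    sums the probability of every outcome no more likely than the observed
    one (double-tail by likelihood ordering).
    """
    za_i, zb_i = int(round(za)), int(round(zb))
    z = za_i + zb_i
    if z == 0:
        return 1.0
    k = np.arange(z + 1, dtype=float)
    if dispersion <= 0:
        f = n_a / (n_a + n_b)
        logp = (
            gammaln(z + 1) - gammaln(k + 1) - gammaln(z - k + 1)
            + k * np.log(f) + (z - k) * np.log1p(-f)
        )
    else:
        r = 1.0 / dispersion
        a, b = n_a * r, n_b * r
        logp = (
            gammaln(k + a) - gammaln(k + 1)
            + gammaln(z - k + b) - gammaln(z - k + 1)
        )
        logp -= logsumexp(logp)
    obs = logp[za_i]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


def differential_methylation(
    cm: CountMatrix,
    region_a: str,
    region_b: str,
    alpha: float = 0.01,
    adjust: str = "bonferroni",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-locus differential-methylation test between two regions.

    Returns a DataFrame (one row per locus, sorted by adjusted p) with
    coordinates, ``logFC`` (log2 of region-B over region-A shrunken mean
    CPM, pseudo-count 0.5), raw and adjusted p-values (both Bonferroni and
    BH are recorded; ``adjust`` selects which drives ``significant``), mean
    CPM per region, and ``direction``: the methylation status of
    ``region_b`` relative to ``region_a`` ("hyper" when region B has fewer
    reads, i.e. more methylation).

    ``dispersion`` overrides the conditional-ML common-dispersion estimate
    (useful for calibration studies with known simulation parameters).
    """
    if adjust not in ("bonferroni", "BH"):
        raise ValueError(f"adjust must be 'bonferroni' or 'BH': {adjust!r}")
    cm = cm.subset_regions(region_a, region_b)
    for name in (region_a, region_b):
        if int((cm.regions == name).sum()) < 2:
            raise ValueError(f"region {name!r} needs at least 2 samples")
    counts = cm.counts
    groups = cm.regions
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, groups)
    logger.info("common dispersion: %.4g", dispersion)

    pseudo, common_lib = _equalized_pseudocounts(counts)
    in_a = (groups == region_a).to_numpy()
    in_b = (groups == region_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    za = pseudo[:, in_a].sum(axis=1)
    zb = pseudo[:, in_b].sum(axis=1)
    if ((za + zb) == 0).any():
        raise AssertionError("zero-count locus survived filtering")

    p_raw = np.array(
        [_exact_test_pvalue(za[i], zb[i], n_a, n_b, dispersion) for i in range(len(za))]
    )
    # shrunken group mean on the common-library scale -> CPM
    mean_a = (za / n_a + 0.5) * 1e6 / common_lib
    mean_b = (zb / n_b + 0.5) * 1e6 / common_lib
    logfc = np.log2(mean_b / mean_a)

    p_bonf = np.minimum(p_raw * len(p_raw), 1.0)
    p_bh = multipletests(p_raw, method="fdr_bh")[1]
    p_adj = p_bonf if adjust == "bonferroni" else p_bh

    out = pd.DataFrame(
        {
            "chrom": cm.loci["chrom"],
            "pos": cm.loci["pos"],
            "strand": cm.loci["strand"],
            "logFC": logfc,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "p_bh": p_bh,
            "p_adj": p_adj,
            "mean_cpm_a": za / n_a * 1e6 / common_lib,
            "mean_cpm_b": zb / n_b * 1e6 / common_lib,
            # fewer reads in B = more methylation in B
            "direction": np.where(logfc < 0, "hyper", "hypo"),
            "significant": p_adj < alpha,
        },
        index=counts.index,
    )
    out.attrs["region_a"] = region_a
    out.attrs["region_b"] = region_b
    out.attrs["dispersion"] = dispersion
    out.attrs["alpha"] = alpha
    out.attrs["adjust"] = adjust
    return out.sort_values("p_adj", kind="stable")


def significant_dmms(dm_table: pd.DataFrame) -> pd.DataFrame:
    return dm_table[dm_table["significant"]]


def dmms_to_bed(dm_table: pd.DataFrame) -> pd.DataFrame:
    """Significant DMMs as BED (0-based half-open single-base intervals)."""
    sig = significant_dmms(dm_table)
    return pd.DataFrame(
        {
            "chrom": sig["chrom"],
            "start": sig["pos"].astype(int) - 1,
            "end": sig["pos"].astype(int),
            "name": sig.index,
            "score": sig["logFC"],
            "strand": sig["strand"],
        }
    )


# ---------------------------------------------------------------------------
# PC-LDA ordination

def pc_lda(
    cm: CountMatrix,
    groups: pd.Series | None = None,
    n_components: int = 10,
) -> Ordination:
    """Principal components then linear discriminant ordination of samples.

    log2(CPM + 1) profiles are reduced by PCA to ``n_components`` (capped at
    n_samples - n_groups to keep the within-group scatter non-singular) and
    projected onto linear discriminant axes; per-axis percentages are the
    shares of between-group discrimination.
    """
    groups = cm.regions if groups is None else groups.loc[cm.counts.columns]
    n_groups = groups.nunique()
    n_samples = cm.counts.shape[1]
    if n_groups < 2:
        raise ValueError("PC-LDA needs at least 2 groups")
    max_pc = n_samples - n_groups
    if n_components > max_pc:
        logger.info("reducing PCA components %d -> %d (singular scatter guard)",
                    n_components, max_pc)
        n_components = max_pc
    x = np.log2(cm.cpm().to_numpy().T + 1.0)
    pcs = PCA(n_components=n_components, random_state=0).fit_transform(x)
    lda = LinearDiscriminantAnalysis(n_components=min(n_groups - 1, pcs.shape[1]))
    coords = lda.fit_transform(pcs, groups.to_numpy())
    cols = [f"DF{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=cm.counts.columns, columns=cols),
        proportion_explained=lda.explained_variance_ratio_,
    )
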