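"""Synthetic vineyard datasets with known planted truth.

Every pipeline stage gets a recovery test from data generated here:

* :func:`simulate_msap_dataset` — paired HpaII/MspI presence/absence
  matrices over a set of vineyards laid out on a north-south axis, with a
  planted epigenetic gradient (per-km shift in methylation probability at
  methylation-susceptible loci) over genetically unstructured samples
  (non-methylated loci share one band frequency across regions).
* :func:`simulate_msgbs_dataset` — negative-binomial read counts at cut-site
  loci with a planted set of differentially methylated markers scaled by a
  known fold change along the region gradient.
* :func:`simulate_annotation` — a toy genome of non-overlapping genes on
  both strands plus a gene-to-GO map with one designated
  environment-response-like term whose recovery by the enrichment stage is
  testable.

All generators are deterministic given their seed, and each returns a
:class:`SyntheticTruth` carrying the planted parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gff3_genes
from .enrichment import GeneToGO, write_gene2go
from .msap import EpilocusDataset
from .msgbs import CountMatrix

logger = logging.getLogger(__name__)

KM_PER_DEG_LAT = 111.195  # spherical Earth, R = 6371 km

#: default hemi : internal-CG split among methylated, non-fully-methylated
#: draws, and the fully-methylated share of methylated draws; both chosen to
#: echo commonly observed MSAP state frequencies (full > hemi > internal).
HEMI_SPLIT = 0.55
FULL_FRACTION = 0.52


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic dataset (for recovery tests)."""

    seed: int | None
    kind: str
    gradient_slope_per_km: float | None = None
    baseline_probs: list[float] | None = None
    n_clipped_draws: int = 0
    n_draws: int = 0
    sites: dict | None = None
    planted_dmms: dict[str, dict] | None = None
    dispersion: float | None = None
    libsize_range: tuple[float, float] | None = None
    enriched_term: str | None = None
    enriched_term_genes: list[str] | None = None

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# MSAP

def _layout_sites(
    rng: np.random.Generator,
    vineyards_per_region: list[int],
    region_spacing_km: float,
    vineyard_jitter_km: float,
) -> pd.DataFrame:
    """Vineyard sites on a 1-D north-south axis (region centroids spaced evenly)."""
    lat0, lon0 = -34.45, 138.95  # Barossa-like origin; axis runs south
    rows = []
    v = 0
    for r, n_v in enumerate(vineyards_per_region):
        centre = r * region_spacing_km
        for _ in range(n_v):
            v += 1
            km = centre + rng.normal(0.0, vineyard_jitter_km)
            rows.append(
                {
                    "vineyard": f"V{v:02d}",
                    "subregion": f"R{r + 1}",
                    "km_south": km,
                    "lat": lat0 - km / KM_PER_DEG_LAT,
                    "lon": lon0 + rng.normal(0.0, 0.02),
                    "alt_m": 300.0 - 3.0 * km + rng.normal(0.0, 5.0),
                }
            )
    return pd.DataFrame(rows).set_index("vineyard")


def simulate_msap_dataset(
    n_regions: int = 6,
    vineyards_per_region: int | list[int] = 4,
    plants_per_vineyard: int = 4,
    n_msl: int = 160,
    n_nml: int = 55,
    gradient_slope: float | None = None,
    error_rate: float = 0.01,
    seed: int | None = 0,
    region_spacing_km: float = 5.0,
    vineyard_jitter_km: float = 1.0,
    delta_p: float = 0.2,
) -> tuple[EpilocusDataset, SyntheticTruth]:
    """Paired-enzyme MSAP matrices with a planted north-south methylation gradient.

    At each methylation-susceptible locus a sample is methylated with
    probability ``p0 + slope * km_south`` (p0 per-locus baseline, uniform on
    0.25-0.75); methylated draws map to (hpa, msp) band pairs through the
    inverse of the state truth table.  Non-methylated loci carry one band
    frequency shared by all regions — no genetic structure.  Symmetric call
    errors flip each enzyme call independently at ``error_rate``.

    ``gradient_slope`` is in probability units per km; when None it is sized
    so the extreme regions differ by ``delta_p`` (default 0.2).  Defaults
    mirror a six-sub-region, 4-vineyard, 4-plant vineyard survey with ~215
    fragments.
    """
    if isinstance(vineyards_per_region, int):
        vineyards_per_region = [vineyards_per_region] * n_regions
    if len(vineyards_per_region) != n_regions:
        raise ValueError("vineyards_per_region length must equal n_regions")
    if min(vineyards_per_region) < 1 or plants_per_vineyard < 1 or n_msl < 1 or n_nml < 0:
        raise ValueError("all design counts must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)

    sites = _layout_sites(rng, vineyards_per_region, region_spacing_km, vineyard_jitter_km)
    span_km = region_spacing_km * max(n_regions - 1, 1)
    slope = gradient_slope if gradient_slope is not None else delta_p / span_km

    samples = []
    meta_rows = []
    clones = np.array(["1654", "R6V28", "BVRC12"])
    prunings = np.array(["spur", "cane"])
    for vineyard, site in sites.iterrows():
        clone = rng.choice(clones)
        pruning = rng.choice(prunings)
        for p in range(plants_per_vineyard):
            s = f"{vineyard}_p{p + 1}"
            samples.append(s)
            meta_rows.append(
                {
                    "sample": s,
                    "vineyard": vineyard,
                    "subregion": site["subregion"],
                    "clone": clone,
                    "pruning": pruning,
                    "lat": site["lat"],
                    "lon": site["lon"],
                    "alt_m": site["alt_m"],
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    km = sites.loc[metadata["vineyard"], "km_south"].to_numpy()

    sizes_msl = rng.integers(95, 501, size=n_msl)
    sizes_nml = rng.integers(95, 501, size=n_nml)
    msl_ids = [f"msl{i:03d}_{sizes_msl[i]}" for i in range(n_msl)]
    nml_ids = [f"nml{i:03d}_{sizes_nml[i]}" for i in range(n_nml)]

    n = len(samples)
    p0 = rng.uniform(0.25, 0.75, size=n_msl)
    p = p0[None, :] + slope * km[:, None]
    clipped = int(((p < 0) | (p > 1)).sum())
    if clipped > 0.05 * p.size:
        logger.warning(
            "methylation probability clipped on %.1f%% of draws; "
            "consider a smaller gradient slope", 100 * clipped / p.size,
        )
    p = np.clip(p, 0.0, 1.0)

    meth = rng.random((n, n_msl)) < p
    full = meth & (rng.random((n, n_msl)) < FULL_FRACTION)
    hemi = meth & ~full & (rng.random((n, n_msl)) < HEMI_SPLIT)
    internal = meth & ~full & ~hemi
    # inverse state table: unmethylated (1,1); hemi (1,0); internal (0,1); full (0,0)
    hpa_msl = (~meth | hemi).astype(float)
    msp_msl = (~meth | internal).astype(float)

    band_freq = rng.uniform(0.3, 0.95, size=n_nml)
    band = (rng.random((n, n_nml)) < band_freq[None, :]).astype(float)
    hpa_nml = band.copy()
    msp_nml = band.copy()

    hpa = np.concatenate([hpa_msl, hpa_nml], axis=1)
    msp = np.concatenate([msp_msl, msp_nml], axis=1)
    if error_rate > 0:
        hpa = np.where(rng.random(hpa.shape) < error_rate, 1 - hpa, hpa)
        msp = np.where(rng.random(msp.shape) < error_rate, 1 - msp, msp)

    loci = msl_ids + nml_ids
    ds = EpilocusDataset(
        hpa=pd.DataFrame(hpa, index=samples, columns=loci),
        msp=pd.DataFrame(msp, index=samples, columns=loci),
        sizes=pd.Series(np.concatenate([sizes_msl, sizes_nml]), index=loci, name="size_bp"),
        metadata=metadata,
    )
    truth = SyntheticTruth(
        seed=seed,
        kind="msap",
        gradient_slope_per_km=float(slope),
        baseline_probs=[float(x) for x in p0],
        n_clipped_draws=clipped,
        n_draws=int(p.size),
        sites=sites.reset_index().to_dict(orient="list"),
    )
    return ds, truth


def write_msap_bundle(ds: EpilocusDataset, truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the standard MSAP input files (hpa.csv, msp.csv, samples.tsv, truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hpa": outdir / "hpa.csv",
        "msp": outdir / "msp.csv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth_msap.json",
    }
    ds.hpa.to_csv(paths["hpa"])
    ds.msp.to_csv(paths["msp"])
    ds.metadata.to_csv(paths["samples"], sep="\t")
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# toy annotation

def simulate_annotation(
    n_chroms: int = 2,
    n_genes: int = 200,
    n_terms: int = 20,
    seed: int | None = 0,
    n_enriched_genes: int = 30,
) -> tuple[list[GeneModel], GeneToGO, SyntheticTruth]:
    """Toy genome annotation with a designated environment-response-like term.

    Non-overlapping genes (1-4 kb) alternate strands along each chromosome
    with intergenic gaps large enough that 5-kb flanks rarely overlap.  Each
    gene gets 1-4 random GO terms; ``n_enriched_genes`` genes additionally
    carry the designated term, which downstream enrichment tests should
    recover when markers are planted near those genes.
    """
    if min(n_chroms, n_genes, n_terms) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    strands = np.array(["+", "-"])[
        rng.permutation(np.arange(n_genes) % 2)
    ]
    per_chrom = np.array_split(np.arange(n_genes), n_chroms)
    g = 0
    for c, idx in enumerate(per_chrom):
        pos = 10_000
        for _ in idx:
            length = int(rng.integers(1000, 4001))
            start = pos + int(rng.integers(12_000, 20_001))
            genes.append(
                GeneModel(f"gene{g:04d}", f"chr{c + 1}", start, start + length, strands[g])
            )
            pos = start + length
            g += 1

    term_ids = [f"GO:{7000000 + t}" for t in range(n_terms)]
    enriched_term = "GO:0009605"  # environment-response-like designated term
    gene_ids = [gm.gene_id for gm in genes]
    enriched_genes = sorted(
        rng.choice(gene_ids, size=min(n_enriched_genes, n_genes), replace=False)
    )
    gene_terms: dict[str, set[str]] = {}
    for gid in gene_ids:
        k = int(rng.integers(1, 5))
        gene_terms[gid] = set(rng.choice(term_ids, size=k, replace=False))
    for gid in enriched_genes:
        gene_terms[gid].add(enriched_term)
    names = {t: f"synthetic process {i}" for i, t in enumerate(term_ids)}
    names[enriched_term] = "response to external stimulus (synthetic)"
    namespaces = {t: "biological_process" for t in list(term_ids) + [enriched_term]}
    mapping = GeneToGO(gene_terms, names, namespaces)
    truth = SyntheticTruth(
        seed=seed,
        kind="annotation",
        enriched_term=enriched_term,
        enriched_term_genes=[str(g) for g in enriched_genes],
    )
    return genes, mapping, truth


# ---------------------------------------------------------------------------
# msGBS

def simulate_msgbs_dataset(
    n_regions: int = 3,
    samples_per_region: int = 30,
    n_loci: int = 2000,
    n_dmm: int = 100,
    fold_change: float = 4.0,
    dispersion: float = 0.2,
    libsize_range: tuple[float, float] = (8e5, 1.2e6),
    seed: int | None = 0,
    annotation: tuple[list[GeneModel], SyntheticTruth] | None = None,
    near_gene_fraction: float = 0.7,
    mean_count: float = 50.0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial msGBS counts with planted differential methylation.

    Per-locus baseline means are log-normal around ``mean_count`` (at the
    nominal 1e6 library size); counts are NB with common ``dispersion``.
    The ``n_dmm`` planted loci scale linearly in log space along the
    north-south region gradient so the extreme regions differ by exactly
    ``fold_change``; most planted loci gain reads southward (the southern
    region is hypomethylated), a minority run the other way.

    With ``annotation`` given (gene models plus their truth), planted marker
    positions land near genes — preferentially near the designated
    enriched-term genes — while a ``1 - near_gene_fraction`` share is placed
    far from any gene, so gene assignment and enrichment recovery are both
    exercised.
    """
    if n_dmm > n_loci:
        raise ValueError("n_dmm cannot exceed n_loci")
    if fold_change <= 0 or dispersion < 0:
        raise ValueError("fold_change must be > 0 and dispersion >= 0")
    rng = np.random.default_rng(seed)

    regions = [f"R{i + 1}" for i in range(n_regions)]  # R1 = northmost
    sample_region = {}
    for r in regions:
        for j in range(samples_per_region):
            sample_region[f"{r}_s{j + 1:02d}"] = r
    sample_names = list(sample_region)
    region_idx = np.array([regions.index(sample_region[s]) for s in sample_names])

    # toy genome geometry
    if annotation is not None:
        genes, ann_truth = annotation
        chrom_len = {}
        for g in genes:
            chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end + 20_000)
        enriched = set(ann_truth.enriched_term_genes or [])
    else:
        genes, ann_truth, enriched = [], None, set()
        chrom_len = {"chr1": 1_000_000, "chr2": 1_000_000}
    chroms = sorted(chrom_len)

    def random_position() -> tuple[str, int]:
        c = chroms[int(rng.integers(len(chroms)))]
        return c, int(rng.integers(1, chrom_len[c]))

    def far_position(min_gap: int = 6000) -> tuple[str, int]:
        for _ in range(200):
            c, p = random_position()
            if all(g.chrom != c or p < g.start - min_gap or p > g.end + min_gap
                   for g in genes):
                return c, p
        return random_position()

    def near_gene_position() -> tuple[str, int]:
        pool = [g for g in genes if g.gene_id in enriched] or genes
        if genes and rng.random() > 0.8:
            pool = genes  # occasional non-enriched neighbour
        g = pool[int(rng.integers(len(pool)))]
        return g.chrom, int(rng.integers(max(1, g.start - 3000), g.end + 3001))

    locus_ids = [f"ms{i:05d}" for i in range(n_loci)]
    planted = sorted(rng.choice(n_loci, size=n_dmm, replace=False))
    planted_set = set(planted)
    coords = []
    planted_info: dict[str, dict] = {}
    for i in range(n_loci):
        if i in planted_set and genes:
            if rng.random() < near_gene_fraction:
                chrom, pos = near_gene_position()
            else:
                chrom, pos = far_position()
        else:
            chrom, pos = random_position()
        coords.append((chrom, pos, "+" if rng.random() < 0.5 else "-"))

    base = rng.lognormal(mean=np.log(mean_count), sigma=1.0, size=n_loci)
    # planted gradient: log-linear in region index, extreme ratio = fold_change
    log_step = np.zeros(n_loci)
    south_up = rng.random(n_dmm) < 0.7  # most loci gain reads southward
    denom = max(n_regions - 1, 1)
    for j, i in enumerate(planted):
        sign = 1.0 if south_up[j] else -1.0
        log_step[i] = sign * np.log(fold_change) / denom
        planted_info[locus_ids[i]] = {
            "fold_change": float(fold_change if south_up[j] else 1 / fold_change),
            "direction_southmost_vs_northmost": "hypo" if south_up[j] else "hyper",
        }

    lib = rng.uniform(*libsize_range, size=len(sample_names))
    mu = (
        base[:, None]
        * np.exp(log_step[:, None] * region_idx[None, :])
        * (lib[None, :] / 1e6)
    )
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=locus_ids, columns=sample_names),
        loci=pd.DataFrame(coords, index=locus_ids, columns=["chrom", "pos", "strand"]),
        regions=pd.Series(sample_region, name="region"),
    )
    truth = SyntheticTruth(
        seed=seed,
        kind="msgbs",
        planted_dmms=planted_info,
        dispersion=dispersion,
        libsize_range=tuple(float(x) for x in libsize_range),
        enriched_term=ann_truth.enriched_term if ann_truth else None,
        enriched_term_genes=ann_truth.enriched_term_genes if ann_truth else None,
    )
    return cm, truth


def write_msgbs_bundle(
    cm: CountMatrix,
    truth: SyntheticTruth,
    outdir: str | Path,
    genes: list[GeneModel] | None = None,
    mapping: GeneToGO | None = None,
) -> dict[str, Path]:
    """Write counts.tsv, regions.tsv and (optionally) genes.gff3 + gene2go.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "regions": outdir / "regions.tsv",
        "truth": outdir / "truth_msgbs.json",
    }
    table = pd.concat([cm.loci, cm.counts], axis=1)
    table.index.name = "locus"
    table.to_csv(paths["counts"], sep="\t")
    cm.regions.rename_axis("sample").to_frame().to_csv(paths["regions"], sep="\t")
    truth.to_json(paths["truth"])
    if genes is not None:
        paths["gff3"] = outdir / "genes.gff3"
        write_gff3_genes(genes, paths["gff3"])
    if mapping is not None:
        paths["gene2go"] = outdir / "gene2go.tsv"
        write_gene2go(mapping, paths["gene2go"])
    return paths


def read_msgbs_bundle(counts_path: str | Path, regions_path: str | Path) -> CountMatrix:
    """Read the counts.tsv / regions.tsv pair written by :func:`write_msgbs_bundle`."""
    table = pd.read_csv(counts_path, sep="\t", index_col=0)
    loci = table[["chrom", "pos", "strand"]]
    counts = table.drop(columns=["chrom", "pos", "strand"])
    regions = pd.read_csv(regions_path, sep="\t", index_col=0)["region"]
    return CountMatrix(counts=counts, loci=loci, regions=regions)
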