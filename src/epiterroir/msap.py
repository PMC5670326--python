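"""Methylation-sensitive amplified polymorphism (MSAP) core analysis.

MSAP fingerprints a genome with two isoschizomers, HpaII and MspI, that share
the CCGG recognition site but differ in sensitivity to cytosine methylation.
Comparing band presence/absence between the two enzyme profiles at each
fragment (epilocus) classifies loci as methylation-susceptible (MSL, the
epigenetic signal) or non-methylated (NML, the genetic signal), and assigns
each sample a four-way methylation state at every MSL.

The entry point is :func:`load_epilocus_dataset`, which reads paired binary
matrices plus a sample sheet and applies the fragment-size filter; downstream
are :func:`classify_loci`, :func:`call_methylation_states` and
:func:`shannon_diversity`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Locus classes
MSL = "MSL"
NML = "NML"
UNINFORMATIVE = "UNINFORMATIVE"

# Methylation states called from the (hpa, msp) band pair at an MSL
UNMETHYLATED = "UNMETHYLATED"
HEMIMETHYLATED = "HEMIMETHYLATED"
INTERNAL_CG = "INTERNAL_CG"
FULL_OR_MUTATION = "FULL_OR_MUTATION"

STATES = (UNMETHYLATED, HEMIMETHYLATED, INTERNAL_CG, FULL_OR_MUTATION)

#: (hpa, msp) band pair -> methylation state.  HpaII is blocked by full CpG
#: methylation but cuts hemimethylated external cytosines; MspI cuts when the
#: internal cytosine is methylated but not when the external one is.  Both
#: enzymes failing to cut indicates full methylation or loss of the CCGG site
#: (MSAP cannot distinguish the two).
STATE_TABLE: dict[tuple[int, int], str] = {
    (1, 1): UNMETHYLATED,
    (1, 0): HEMIMETHYLATED,
    (0, 1): INTERNAL_CG,
    (0, 0): FULL_OR_MUTATION,
}

METADATA_COLUMNS = ("vineyard", "subregion", "clone", "pruning", "lat", "lon", "alt_m")


class AlignmentError(ValueError):
    """Sample or locus axes disagree between the two enzyme matrices."""


@dataclass
class EpilocusDataset:
    """Paired per-enzyme presence/absence matrices with sample metadata.

    Attributes
    ----------
    hpa, msp : pandas.DataFrame
        samples x loci matrices of band presence (1.0), absence (0.0) or
        missing (NaN) for the EcoRI/HpaII and EcoRI/MspI digests.  Axes are
        identical between the two.
    sizes : pandas.Series
        Fragment size in bp, indexed by locus id.
    metadata : pandas.DataFrame
        One row per sample: vineyard, subregion, clone, pruning, lat, lon,
        alt_m.
    """

    hpa: pd.DataFrame
    msp: pd.DataFrame
    sizes: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.hpa.index) != list(self.msp.index):
            raise AlignmentError(
                "sample axes differ between enzymes: "
                f"{sorted(set(self.hpa.index) ^ set(self.msp.index))}"
            )
        if list(self.hpa.columns) != list(self.msp.columns):
            raise AlignmentError(
                "locus axes differ between enzymes: "
                f"{sorted(set(self.hpa.columns) ^ set(self.msp.columns))}"
            )
        for name, m in (("hpa", self.hpa), ("msp", self.msp)):
            bad = ~(m.isna() | m.isin([0, 1]))
            if bad.any().any():
                r, c = np.argwhere(bad.values)[0]
                raise ValueError(
                    f"non-binary cell in {name} matrix at sample "
                    f"{m.index[r]!r}, locus {m.columns[c]!r}: {m.iloc[r, c]!r}"
                )
        missing_meta = set(self.hpa.index) - set(self.metadata.index)
        if missing_meta:
            raise AlignmentError(f"samples missing from sample sheet: {sorted(missing_meta)}")
        self.metadata = self.metadata.loc[self.hpa.index]

    @property
    def samples(self) -> list[str]:
        return list(self.hpa.index)

    @property
    def loci(self) -> list[str]:
        return list(self.hpa.columns)

    def groups(self, level: str) -> pd.Series:
        """Sample -> group map for a metadata column (vineyard, subregion, ...)."""
        return self.metadata[level]


@dataclass
class LocusClassification:
    locus: str
    klass: str
    discordance_fraction: float
    error_threshold: float
    n_informative: int


@dataclass
class MethylationStateMatrix:
    """Per sample x MSL-locus methylation states with a binary projection.

    ``states`` holds one of the four state strings or NaN when either enzyme
    call is missing.
    """

    states: pd.DataFrame
    #: how FULL_OR_MUTATION projects into the binary (methylated) view
    full_policy: str = "methylated"

    def frequencies(self) -> pd.Series:
        """Percentage of each state over all non-missing sample x locus calls."""
        flat = self.states.values.ravel()
        flat = flat[~pd.isna(flat)]
        n = len(flat)
        counts = pd.Series(flat).value_counts()
        return pd.Series(
            {s: 100.0 * counts.get(s, 0) / n if n else np.nan for s in STATES},
            name="percent",
        )

    def binary(self, full_policy: str | None = None) -> pd.DataFrame:
        """Binary methylated view: UNMETHYLATED -> 0, HEMIMETHYLATED and
        INTERNAL_CG -> 1, FULL_OR_MUTATION -> 1 (policy ``"methylated"``,
        default) or NaN (policy ``"missing"``)."""
        policy = full_policy or self.full_policy
        if policy not in ("methylated", "missing"):
            raise ValueError(f"unknown FULL_OR_MUTATION policy: {policy!r}")
        mapping = {
            UNMETHYLATED: 0.0,
            HEMIMETHYLATED: 1.0,
            INTERNAL_CG: 1.0,
            FULL_OR_MUTATION: 1.0 if policy == "methylated" else np.nan,
        }
        out = self.states.copy()
        for k, v in mapping.items():
            out = out.where(out != k, v)
        return out.astype(float)


@dataclass
class DiversityResult:
    group: str
    marker_class: str
    n_samples: int
    n_loci: int
    percent_polymorphic: float
    shannon_mean: float
    shannon_sd: float


def _read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a CSV or TSV by extension (``.csv`` -> comma, otherwise tab)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


_SIZE_RE = re.compile(r"(\d+)\s*(?:bp)?$")


def parse_fragment_sizes(loci: list[str]) -> pd.Series:
    """Fragment sizes from the trailing integer of each locus id.

    Ids like ``frag_0150`` or ``L12_95bp`` parse to 150 and 95.  A locus id
    without a trailing integer is an error, never a silent drop.
    """
    sizes = {}
    for locus in loci:
        m = _SIZE_RE.search(str(locus))
        if m is None:
            raise ValueError(f"cannot parse fragment size from locus id {locus!r}")
        sizes[locus] = int(m.group(1))
    return pd.Series(sizes, name="size_bp")


def load_epilocus_dataset(
    hpa_path: str | Path,
    msp_path: str | Path,
    samples_path: str | Path,
    min_size: int = 95,
    max_size: int = 500,
) -> EpilocusDataset:
    """Load paired MSAP binary matrices and apply the fragment-size filter.

    Fragments outside ``[min_size, max_size]`` bp (defaults 95-500) are
    dropped to limit size co-migration artefacts of capillary electrophoresis.
    Fragment sizes come from a matrix row indexed ``size`` if present,
    otherwise from the trailing integer of each locus id.

    Raises
    ------
    AlignmentError
        If the two matrices or the sample sheet disagree on sample labels.
    ValueError
        On a non-binary cell (reported with its coordinates) or an
    unparseable fragment size.
    """
    hpa = _read_table(hpa_path)
    msp = _read_table(msp_path)
    meta = _read_table(samples_path)
    meta.index = meta.index.astype(str)

    sizes = None
    for m in (hpa, msp):
        m.index = m.index.astype(str)
        if "size" in m.index:
            row = m.loc["size"]
            if sizes is None:
                sizes = row.astype(int)
            m.drop(index="size", inplace=True)

    only_hpa = set(hpa.index) - set(msp.index)
    only_msp = set(msp.index) - set(hpa.index)
    if only_hpa or only_msp:
        raise AlignmentError(
            "sample labels differ between enzyme matrices; "
            f"only in hpa: {sorted(only_hpa)}, only in msp: {sorted(only_msp)}"
        )
    msp = msp.loc[hpa.index, hpa.columns] if set(hpa.columns) == set(msp.columns) else msp

    if sizes is None:
        sizes = parse_fragment_sizes(list(hpa.columns))
    keep = sizes[(sizes >= min_size) & (sizes <= max_size)].index
    dropped = len(hpa.columns) - len(keep)
    if dropped:
        logger.info("size filter %d-%d bp dropped %d of %d fragments",
                    min_size, max_size, dropped, len(hpa.columns))
    return EpilocusDataset(
        hpa=hpa[keep].astype(float),
        msp=msp[keep].astype(float),
        sizes=sizes[keep],
        metadata=meta,
    )


def classify_loci(ds: EpilocusDataset, error_threshold: float = 0.05) -> list[LocusClassification]:
    """Split loci into MSL (epigenetic) and NML (genetic) by enzyme discordance.

    A locus whose HpaII and MspI calls differ in more than ``error_threshold``
    of the samples with calls from both enzymes is methylation-susceptible
    (MSL); a concordant locus is non-methylated (NML); a locus with no band in
    any sample with either enzyme is UNINFORMATIVE.  The default threshold
    0.05 absorbs scoring error without diluting the methylation signal.
    """
    if not 0 <= error_threshold < 1:
        raise ValueError(f"error_threshold must be in [0, 1): {error_threshold}")
    out = []
    for locus in ds.loci:
        h = ds.hpa[locus]
        m = ds.msp[locus]
        both = h.notna() & m.notna()
        n_inf = int(both.sum())
        any_band = ((h == 1) | (m == 1)).any()
        if not any_band or n_inf == 0:
            if n_inf == 0:
                logger.warning("locus %s has no sample with calls from both enzymes", locus)
            out.append(LocusClassification(locus, UNINFORMATIVE, np.nan, error_threshold, n_inf))
            continue
        disc = float((h[both] != m[both]).mean())
        klass = MSL if disc > error_threshold else NML
        out.append(LocusClassification(locus, klass, disc, error_threshold, n_inf))
    return out


def classification_frame(classification: list[LocusClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [c.locus for c in classification],
            "class": [c.klass for c in classification],
            "discordance": [c.discordance_fraction for c in classification],
            "n_informative": [c.n_informative for c in classification],
        }
    ).set_index("locus")


def call_methylation_states(
    ds: EpilocusDataset,
    classification: list[LocusClassification],
    full_policy: str = "methylated",
) -> MethylationStateMatrix:
    """Call the four-way methylation state at every MSL for every sample.

    The (hpa, msp) band pair maps through :data:`STATE_TABLE`; a missing call
    in either enzyme gives a missing state.  ``frequencies()`` on the result
    yields the dataset-wide percentage of each state.
    """
    msl = [c.locus for c in classification if c.klass == MSL]
    h = ds.hpa[msl].values
    m = ds.msp[msl].values
    states = np.full(h.shape, np.nan, dtype=object)
    for (hv, mv), state in STATE_TABLE.items():
        states[(h == hv) & (m == mv)] = state
    states[np.isnan(h.astype(float)) | np.isnan(m.astype(float))] = np.nan
    return MethylationStateMatrix(
        states=pd.DataFrame(states, index=ds.samples, columns=msl),
        full_policy=full_policy,
    )


def nml_binary_view(ds: EpilocusDataset, classification: list[LocusClassification]) -> pd.DataFrame:
    """Binary genetic view over NML loci: band presence with either enzyme.

    The two enzymes agree at an NML up to the error threshold; the rare
    discordant cell counts as band presence (one enzyme saw the fragment).
    Missing in both enzymes stays missing.
    """
    nml = [c.locus for c in classification if c.klass == NML]
    h = ds.hpa[nml]
    m = ds.msp[nml]
    out = pd.DataFrame(
        np.fmax(h.values, m.values), index=ds.samples, columns=nml
    )
    return out


def per_locus_shannon(binary_view: pd.DataFrame) -> pd.Series:
    """Shannon index S = -(p ln p + q ln q) per locus.

    p is the band frequency among non-missing calls; S = 0 for a monomorphic
    locus and peaks at ln 2 when p = 0.5.  Loci with no informative call are
    NaN.
    """
    p = binary_view.mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 1.0 - p
        s = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    s = pd.Series(s, index=binary_view.columns, name="shannon")
    s[p.isna()] = np.nan
    return s


def shannon_diversity(
    binary_view: pd.DataFrame,
    groups: pd.Series,
    marker_class: str = MSL,
) -> list[DiversityResult]:
    """Per-group Shannon diversity and polymorphism over a binary marker view.

    Groups with fewer than two samples carry no within-group frequency
    information and are excluded with a warning.  A locus is polymorphic
    within a group when both presence and absence are observed there.
    """
    results = []
    for group, idx in groups.groupby(groups).groups.items():
        sub = binary_view.loc[idx]
        if len(sub) < 2:
            logger.warning("group %s has < 2 samples; excluded from diversity", group)
            continue
        s = per_locus_shannon(sub)
        informative = s.notna()
        p = sub.mean(axis=0, skipna=True)
        poly = ((p > 0) & (p < 1))[informative]
        results.append(
            DiversityResult(
                group=str(group),
                marker_class=marker_class,
                n_samples=len(sub),
                n_loci=int(informative.sum()),
                percent_polymorphic=100.0 * float(poly.mean()) if informative.any() else np.nan,
                shannon_mean=float(s[informative].mean()),
                shannon_sd=float(s[informative].std(ddof=1)),
            )
        )
    return results


def diversity_table(results: list[DiversityResult]) -> pd.DataFrame:
    """Report table with one row per group x marker class (MSL/NML)."""
    rows = [
        {
            "group": r.group,
            "marker_class": r.marker_class,
            "n_samples": r.n_samples,
            "n_loci": r.n_loci,
            "percent_polymorphic": round(r.percent_polymorphic, 1),
            "shannon": f"{r.shannon_mean:.3f} ({r.shannon_sd:.3f})",
        }
        for r in results
    ]
    return pd.DataFrame(rows)
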