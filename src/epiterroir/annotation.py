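"""Mapping differentially methylated markers onto gene models.

A gene within 5 kb of a significant differentially methylated marker (DMM)
is a differentially methylated gene (DMG).  The positional distribution of
DMMs around genes is tallied into eleven strand-oriented bins: five 1-kb
windows upstream of the transcription start site (bins -5..-1), the gene
body between TSS and TES (bin 0), and five 1-kb windows downstream of the
transcription end site (bins +1..+5).

Coordinates are 1-based inclusive internally (GFF3 convention); BED
input/output converts explicitly at the boundary (0-based half-open).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINS = tuple(range(-5, 6))


@dataclass(frozen=True)
class GeneModel:
    """One gene span: 1-based inclusive start <= end, strand-aware TSS/TES."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Gene features from a GFF3 file (feature type ``gene``, ID attribute)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, feat.strand))
    if not genes:
        raise ValueError(f"no gene features found in {path}")
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tepiterroir\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_bed_positions(path: str | Path) -> pd.DataFrame:
    """BED intervals -> 1-based positions (midpoint of each interval)."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    pos = (bed["start"] + bed["end"] + 1) // 2  # 0-based half-open -> 1-based
    return pd.DataFrame({"chrom": bed["chrom"], "pos": pos, "name": bed["name"]})


def _signed_bin(pos: int, gene: GeneModel, flank: int = 5000) -> int | None:
    """Strand-oriented 1-kb bin of a position relative to a gene, or None.

    Bin 0 is the gene body (TSS..TES inclusive; a marker exactly at the TSS
    or TES is body).  Upstream distance d in (0, flank] maps to -ceil(d/1000),
    downstream likewise to +ceil(d/1000); beyond ``flank`` returns None.
    """
    if gene.start <= pos <= gene.end:
        return 0
    if pos < gene.start:
        d = gene.start - pos
        side = -1 if gene.strand == "+" else 1
    else:
        d = pos - gene.end
        side = 1 if gene.strand == "+" else -1
    if d > flank:
        return None
    return side * math.ceil(d / 1000)


def _pairs_in_range(
    dmms: pd.DataFrame, genes: list[GeneModel], flank: int
) -> pd.DataFrame:
    """All (DMM, gene) pairs with the DMM within ``flank`` bp of the gene span."""
    required = {"chrom", "pos"}
    if not required <= set(dmms.columns):
        raise ValueError(f"DMM table needs columns {sorted(required)}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    unknown = set(dmms["chrom"]) - set(by_chrom)
    if unknown:
        n = int(dmms["chrom"].isin(unknown).sum())
        logger.warning(
            "%d DMMs on chromosomes absent from the annotation (%s) are unassigned",
            n, sorted(unknown),
        )
    rows = []
    for chrom, sub in dmms.groupby("chrom", sort=False):
        gl = by_chrom.get(chrom)
        if not gl:
            continue
        starts = np.array([g.start for g in gl])
        ends = np.array([g.end for g in gl])
        pos = sub["pos"].to_numpy(dtype=int)
        hit = (pos[:, None] >= starts[None, :] - flank) & (pos[:, None] <= ends[None, :] + flank)
        for i, j in np.argwhere(hit):
            g = gl[j]
            rows.append(
                {
                    "dmm": sub.index[i],
                    "gene_id": g.gene_id,
                    "bin": _signed_bin(int(pos[i]), g, flank),
                    "direction": sub["direction"].iloc[i] if "direction" in sub else None,
                }
            )
    return pd.DataFrame(rows, columns=["dmm", "gene_id", "bin", "direction"])


def assign_dmgs(
    dmms: pd.DataFrame, genes: list[GeneModel], flank: int = 5000
) -> pd.DataFrame:
    """Differentially methylated genes: any gene with a DMM within ``flank`` bp.

    ``dmms`` is a table of significant markers with columns chrom, pos and
    optionally direction (hyper/hypo).  A marker may support several genes.
    Returns one row per DMG: supporting DMM count, per-direction counts, and
    a ``direction`` summary ("hyper", "hypo" or "both" — genes carrying
    markers of both signs belong to both sets and are flagged).
    """
    pairs = _pairs_in_range(dmms, genes, flank)
    if pairs.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_dmms", "n_hyper", "n_hypo", "direction"]
        ).set_index("gene_id")
    rows = []
    for gene_id, sub in pairs.groupby("gene_id", sort=False):
        n_hyper = int((sub["direction"] == "hyper").sum())
        n_hypo = int((sub["direction"] == "hypo").sum())
        if n_hyper and n_hypo:
            direction = "both"
        elif n_hyper:
            direction = "hyper"
        elif n_hypo:
            direction = "hypo"
        else:
            direction = "unknown"
        rows.append(
            {
                "gene_id": gene_id,
                "n_dmms": len(sub),
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id").sort_index()


def dmg_sets(dmg_table: pd.DataFrame) -> dict[str, set[str]]:
    """Hyper- and hypo-methylated DMG sets; "both" genes appear in each."""
    hyper = set(dmg_table.index[dmg_table["direction"].isin(["hyper", "both"])])
    hypo = set(dmg_table.index[dmg_table["direction"].isin(["hypo", "both"])])
    return {"hyper": hyper, "hypo": hypo}


def window_profile(
    dmms: pd.DataFrame, genes: list[GeneModel], flank: int = 5000
) -> pd.Series:
    """DMM counts per strand-oriented 1-kb bin around genes (bins -5..+5).

    Each in-range (DMM, gene) pair contributes to exactly one bin, so the bin
    sum equals the number of in-range pairs; a marker flanked by two genes
    counts once per gene.
    """
    pairs = _pairs_in_range(dmms, genes, flank)
    n_bins = math.ceil(flank / 1000) if flank > 0 else 0
    bins = list(range(-n_bins, n_bins + 1))
    counts = pd.Series(0, index=bins, name="n_dmms")
    if not pairs.empty:
        vc = pairs["bin"].value_counts()
        for b in bins:
            counts[b] = int(vc.get(b, 0))
    return counts
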