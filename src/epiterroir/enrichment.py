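"""GO-term over-representation of differentially methylated gene sets.

One-sided hypergeometric (upper-tail) test per GO term with Bonferroni
control: does the DMG set contain more genes annotated to a term than random
draws from the annotated universe would give?  Hyper- and hypo-methylated
sets are tested separately.

The gene universe is the set of genes with at least one GO annotation —
unannotated genes carry no information under the hypergeometric model.
Terms with no overlap with the query set are excluded from testing and from
the Bonferroni divisor.  No ancestor propagation is applied in the core; a
pre-propagated mapping can be supplied via ``propagate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneToGO:
    """gene id -> set of GO term ids, with term names and namespaces."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}

    @property
    def universe(self) -> set[str]:
        """All genes carrying at least one annotation."""
        return set(self.gene_terms)

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out

    def propagate(self, parents: dict[str, set[str]]) -> "GeneToGO":
        """Return a copy with each annotation extended to its ancestors."""
        new = {}
        for gene, terms in self.gene_terms.items():
            closed = set(terms)
            frontier = list(terms)
            while frontier:
                t = frontier.pop()
                for p in parents.get(t, ()):  # walk upward
                    if p not in closed:
                        closed.add(p)
                        frontier.append(p)
            new[gene] = closed
        return GeneToGO(new, dict(self.term_names), dict(self.term_namespaces))


def read_gene2go(path: str | Path) -> GeneToGO:
    """Read a gene2go TSV with columns gene, term[, name, namespace]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "term"}
    if not required <= set(df.columns):
        raise ValueError(f"gene2go file needs columns {sorted(required)}")
    gene_terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        gene_terms.setdefault(gene, set()).add(term)
    names = {}
    namespaces = {}
    if "name" in df.columns:
        names = dict(zip(df["term"].astype(str), df["name"].astype(str)))
    if "namespace" in df.columns:
        namespaces = dict(zip(df["term"].astype(str), df["namespace"].astype(str)))
    return GeneToGO(gene_terms, names, namespaces)


def write_gene2go(mapping: GeneToGO, path: str | Path) -> None:
    rows = []
    for gene in sorted(mapping.gene_terms):
        for term in sorted(mapping.gene_terms[gene]):
            rows.append(
                {
                    "gene": gene,
                    "term": term,
                    "name": mapping.term_names.get(term, ""),
                    "namespace": mapping.term_namespaces.get(term, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def enrich_go(
    dmg_set: set[str],
    mapping: GeneToGO,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms in a gene set.

    For each term with overlap k >= 1: p = P[X >= k] with
    X ~ Hypergeom(N=len(universe), K=term size, n=len(dmg_set)).  Bonferroni
    uses the number of tested terms; BH is recorded alongside.  Genes in
    ``dmg_set`` outside the universe are an error — the caller must restrict
    the query set to annotated genes first.
    """
    universe = mapping.universe if universe is None else set(universe)
    stray = set(dmg_set) - universe
    if stray:
        raise ValueError(f"query genes absent from the universe: {sorted(stray)[:10]}")
    dmg_set = set(dmg_set)
    n, n_universe = len(dmg_set), len(universe)
    rows = []
    for term, genes in sorted(mapping.term_genes().items()):
        genes = genes & universe
        k = len(genes & dmg_set)
        if k == 0:
            continue
        big_k = len(genes)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n))
        rows.append(
            {
                "term": term,
                "name": mapping.term_names.get(term, ""),
                "namespace": mapping.term_namespaces.get(term, ""),
                "k_overlap": k,
                "K_term": big_k,
                "n_set": n,
                "N_universe": n_universe,
                "p_raw": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "namespace", "k_overlap", "K_term", "n_set",
                     "N_universe", "p_raw", "p_bonferroni", "p_bh", "significant"]
        ).set_index("term")
    out = pd.DataFrame(rows).set_index("term")
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    out["p_bh"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values(["p_bonferroni", "p_raw"], kind="stable")


def revigo_export(enrichment: pd.DataFrame, path: str | Path) -> None:
    """Two-column (term id, adjusted p) export for semantic-summary tools."""
    enrichment.reset_index()[["term", "p_bonferroni"]].to_csv(
        path, sep="\t", index=False, header=False
    )
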