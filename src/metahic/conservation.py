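"""Cross-species network comparison over 1:1 orthologs.

Contact conservation asks, for every ortholog gene, how well one species'
ranked contact edges predict the gene's top-10% contact edges in the other
species; both directions are averaged.  Contact-coexpression conservation
is one-directional: species-A contacts predicting species-B top-1%
coexpression.  The edge universe is restricted to pairs whose cis/trans
status agrees in *both* species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UsageError
from .metrics import AUCResult, network_prediction_auc
from .networks import EdgeMask, GeneNetwork

log = logging.getLogger("metahic")


@dataclass
class OrthologMap:
    """1:1 ortholog pairs between two species (bijective)."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self):
        if list(self.pairs.columns[:2]) != ["gene_a", "gene_b"]:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns[:2], ["gene_a", "gene_b"]))
            )
        if self.pairs["gene_a"].duplicated().any() or self.pairs["gene_b"].duplicated().any():
            raise InvalidInputError("ortholog map is not 1:1 (duplicated ids)")

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def identity(cls, gene_ids):
        return cls(pd.DataFrame({"gene_a": list(gene_ids), "gene_b": list(gene_ids)}))

    def __len__(self):
        return len(self.pairs)


def _chrom_lookup(genes: pd.DataFrame) -> dict:
    return dict(zip(genes["gene_id"], genes["chrom"]))


def restrict_networks(net_a: GeneNetwork, net_b: GeneNetwork, orthologs: OrthologMap,
                      genes_a: pd.DataFrame, genes_b: pd.DataFrame, scope: str):
    """Align two networks on their ortholog pairs and scope-consistent edges.

    Returns ``(sub_a, sub_b, mask)``: both networks reindexed to the common
    ortholog order (entity ids are species-A gene ids) and an
    :class:`~metahic.networks.EdgeMask` keeping pairs that are cis in both
    species (scope='cis') or trans in both (scope='trans').
    """
    if scope not in ("cis", "trans"):
        raise UsageError(f"scope must be 'cis' or 'trans', got {scope!r}")
    ca = _chrom_lookup(genes_a)
    cb = _chrom_lookup(genes_b)
    kept = []
    for p in orthologs.pairs.itertuples(index=False):
        if (
            p.gene_a in net_a._index and p.gene_b in net_b._index
            and p.gene_a in ca and p.gene_b in cb
        ):
            kept.append((p.gene_a, p.gene_b))
    n_drop = len(orthologs) - len(kept)
    if n_drop:
        log.info("restrict_networks: dropped %d ortholog pairs missing from inputs", n_drop)
    if not kept:
        raise UsageError("no usable ortholog pairs")
    ids_a = [a for a, _ in kept]
    ids_b = [b for _, b in kept]
    sub_a = net_a.subset(ids_a)
    sub_b = net_b.subset(ids_b)
    chrom_a = np.array([ca[a] for a in ids_a], dtype=object)
    chrom_b = np.array([cb[b] for b in ids_b], dtype=object)
    cis_a = chrom_a[:, None] == chrom_a[None, :]
    cis_b = chrom_b[:, None] == chrom_b[None, :]
    mat = (cis_a & cis_b) if scope == "cis" else (~cis_a & ~cis_b)
    np.fill_diagonal(mat, False)
    if not mat.any():
        raise UsageError(f"no {scope}-in-both-species gene pairs")
    # sub_b re-keyed to species-A ids so the two networks share an index
    sub_b = GeneNetwork(
        gene_ids=np.array(ids_a, dtype=object), weights=sub_b.weights,
        kind=sub_b.kind, genome=sub_b.genome,
    )
    mask = EdgeMask(gene_ids=np.array(ids_a, dtype=object), matrix=mat,
                    description=f"{scope}-in-both")
    return sub_a, sub_b, mask


def contact_conservation(net_a: GeneNetwork, net_b: GeneNetwork, orthologs: OrthologMap,
                         genes_a: pd.DataFrame, genes_b: pd.DataFrame,
                         fraction: float = 0.10, scope: str = "trans",
                         tie_seed: int = 0, gene_subset=None) -> AUCResult:
    """Direction-averaged contact conservation.

    Per ortholog gene: A-edges predict B's top-``fraction`` edges (A→B) and
    vice versa; the reported score is the mean over all per-gene AUCs from
    both directions.  ``gene_subset`` (species-A ids) supports same-
    ortholog-set control comparisons.
    """
    if gene_subset is not None:
        keep = set(gene_subset)
        orthologs = OrthologMap(
            orthologs.pairs[orthologs.pairs["gene_a"].isin(keep)].reset_index(drop=True)
        )
    sub_a, sub_b, mask = restrict_networks(net_a, net_b, orthologs, genes_a, genes_b, scope)
    fwd = network_prediction_auc(sub_a, sub_b, mask=mask, fraction=fraction,
                                 tie_seed=tie_seed, entity_suffix=":A>B")
    rev = network_prediction_auc(sub_b, sub_a, mask=mask, fraction=fraction,
                                 tie_seed=tie_seed, entity_suffix=":B>A")
    combined = AUCResult()
    for part in (fwd, rev):
        for e, a in part.per_entity.items():
            combined.add(e, a, part.n_pos[e], part.n_neg[e])
        for e, r in part.skipped.items():
            combined.skip(e, r)
    return combined


def contact_coexpression_conservation(hic_a: GeneNetwork, coexp_b: GeneNetwork,
                                      orthologs: OrthologMap,
                                      genes_a: pd.DataFrame, genes_b: pd.DataFrame,
                                      fraction: float = 0.01, scope: str = "trans",
                                      tie_seed: int = 0,
                                      coexp_quantile: float | None = None) -> AUCResult:
    """Species-B contact-coexpression conservation with species A: A's Hi-C
    edges predict B's top-``fraction`` coexpression partners.

    ``coexp_quantile`` optionally restricts the candidate pair universe to
    pairs whose B-coexpression weight is at or above that quantile of the
    defined weights (coexpression-strength threshold sweeps).
    """
    sub_a, sub_b, mask = restrict_networks(hic_a, coexp_b, orthologs,
                                           genes_a, genes_b, scope)
    if coexp_quantile is not None:
        if not 0 <= coexp_quantile < 1:
            raise InvalidInputError("coexp_quantile must be in [0, 1)")
        w = sub_b.weights[mask.matrix]
        w = w[~np.isnan(w)]
        thr = np.quantile(w, coexp_quantile)
        mat = mask.matrix & (np.nan_to_num(sub_b.weights, nan=-np.inf) >= thr)
        mask = EdgeMask(gene_ids=mask.gene_ids, matrix=mat,
                        description=mask.description + f",coexp_q>={coexp_quantile}")
    return network_prediction_auc(sub_a, sub_b, mask=mask, fraction=fraction,
                                  tie_seed=tie_seed)
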