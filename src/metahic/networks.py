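"""Gene–gene networks built from contacts or expression.

A :class:`GeneNetwork` is a symmetric gene-pair weight matrix with an
undefined (NaN) diagonal.  Contact networks take the *maximum* contact
frequency over the bins each gene occupies; coexpression networks follow
the aggregate-network recipe: per-dataset Spearman correlations, rank
standardization with NAs at the median rank, then averaging across
datasets.  Edge masks scope the pair universe to cis/trans and minimum
linear distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidInputError, UnknownIdError, UsageError
from .genome import BinnedGenome, gene_bin_range
from .contacts import ContactMatrix

log = logging.getLogger("metahic")


@dataclass
class GeneNetwork:
    gene_ids: np.ndarray
    weights: np.ndarray  # (n, n) float64, symmetric, NaN diagonal
    kind: str = "contact"  # {contact, coexpression, shared-unit}
    genome: BinnedGenome | None = None
    gene_chroms: np.ndarray | None = None  # chromosome name per gene, if known

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise InvalidInputError("weights shape does not match gene_ids")
        np.fill_diagonal(self.weights, np.nan)
        self._index = {g: k for k, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index(self, gene_id) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise UnknownIdError(f"gene {gene_id!r} not in network") from None

    def subset(self, gene_ids) -> "GeneNetwork":
        idx = np.array([self.index(g) for g in gene_ids])
        chroms = self.gene_chroms[idx] if self.gene_chroms is not None else None
        return GeneNetwork(
            gene_ids=np.asarray(gene_ids, dtype=object),
            weights=self.weights[np.ix_(idx, idx)].copy(),
            kind=self.kind,
            genome=self.genome,
            gene_chroms=chroms,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (gene_a, gene_b, weight) upper-triangle export."""
        n = self.n_genes
        iu = np.triu_indices(n, 1)
        return pd.DataFrame(
            {
                "gene_a": self.gene_ids[iu[0]],
                "gene_b": self.gene_ids[iu[1]],
                "weight": self.weights[iu],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class EdgeMask:
    """Boolean indicator per gene pair (symmetric, False diagonal)."""

    gene_ids: np.ndarray
    matrix: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=bool)
        np.fill_diagonal(self.matrix, False)
        self._index = {g: k for k, g in enumerate(self.gene_ids)}

    def reindex(self, gene_ids) -> np.ndarray:
        idx = np.array([self._index[g] for g in gene_ids])
        return self.matrix[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# contact → gene network

def contact_network(cm: ContactMatrix, genes: pd.DataFrame) -> GeneNetwork:
    """Gene-pair weight = max contact frequency over the genes' bin ranges."""
    if genes.empty:
        raise UsageError("contact_network(): empty gene table")
    genome = cm.genome
    mappable, ranges = [], []
    for g in genes.itertuples(index=False):
        if g.chrom not in genome.chrom_names:
            continue
        try:
            ranges.append(gene_bin_range(genome, g))
        except InvalidInputError:
            continue
        mappable.append(g)
    dropped = len(genes) - len(mappable)
    if dropped:
        log.info("contact_network: dropped %d unmappable genes", dropped)
    if not mappable:
        raise UsageError("contact_network(): no mappable genes")
    G = len(mappable)
    dense = cm.dense_symmetric()
    # two-pass max: rectangle max = max over rows then over columns
    M = np.empty((G, genome.n_bins))
    for k, (b0, b1) in enumerate(ranges):
        M[k] = dense[b0:b1 + 1, :].max(axis=0)
    W = np.empty((G, G))
    for k, (b0, b1) in enumerate(ranges):
        W[:, k] = M[:, b0:b1 + 1].max(axis=1)
    W = np.maximum(W, W.T)
    return GeneNetwork(
        gene_ids=np.array([g.gene_id for g in mappable], dtype=object),
        weights=W,
        kind="contact",
        genome=genome,
        gene_chroms=np.array([g.chrom for g in mappable], dtype=object),
    )


# ---------------------------------------------------------------------------
# rank standardization

def _rank_standardize_values(v: np.ndarray) -> np.ndarray:
    """Rank values (average ties), NaNs at the median rank, divide by the
    number of defined values."""
    out = np.empty_like(v, dtype=np.float64)
    defined = ~np.isnan(v)
    m = int(defined.sum())
    if m == 0:
        raise UsageError("rank standardization of an all-undefined edge set")
    out[defined] = rankdata(v[defined])
    out[~defined] = (m + 1) / 2.0
    return out / m


def rank_standardize(net: GeneNetwork) -> GeneNetwork:
    """Replace off-diagonal weights by rank/max-rank (each pair ranked once)."""
    n = net.n_genes
    iu = np.triu_indices(n, 1)
    std = _rank_standardize_values(net.weights[iu])
    W = np.full((n, n), np.nan)
    W[iu] = std
    W[(iu[1], iu[0])] = std
    return GeneNetwork(
        gene_ids=net.gene_ids.copy(), weights=W, kind=net.kind,
        genome=net.genome,
        gene_chroms=None if net.gene_chroms is None else net.gene_chroms.copy(),
    )


# ---------------------------------------------------------------------------
# coexpression

def coexpression_network(datasets, min_samples: int = 3) -> GeneNetwork:
    """Aggregate coexpression network from one or more expression matrices.

    Each dataset is a genes×samples DataFrame (index = gene ids).  Per
    dataset: Spearman correlation for every gene pair; undefined pairs
    (constant gene, gene absent from the dataset) take the median rank; the
    network is rank standardized; all standardized networks are averaged on
    the union gene set.
    """
    usable = []
    for k, df in enumerate(datasets):
        if df.shape[1] < min_samples:
            log.warning("coexpression dataset %d skipped (<%d samples)", k, min_samples)
            continue
        usable.append(df)
    if not usable:
        raise UsageError("no usable expression datasets (need >= 3 samples each)")
    union = sorted(set().union(*(df.index for df in usable)))
    gid = {g: k for k, g in enumerate(union)}
    n = len(union)
    iu = np.triu_indices(n, 1)
    acc = np.zeros(len(iu[0]))
    for df in usable:
        # Spearman = Pearson on within-gene sample ranks (average ties)
        ranks = df.rank(axis=1).to_numpy(dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(ranks)
        corr = np.atleast_2d(corr)
        full = np.full((n, n), np.nan)
        idx = np.array([gid[g] for g in df.index])
        full[np.ix_(idx, idx)] = corr
        acc += _rank_standardize_values(full[iu])
    mean = acc / len(usable)
    W = np.full((n, n), np.nan)
    W[iu] = mean
    W[(iu[1], iu[0])] = mean
    return GeneNetwork(gene_ids=np.array(union, dtype=object), weights=W, kind="coexpression")


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression TSV: first column gene_id, remaining columns samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# top-fraction labels & masks

def _top_fraction_labels(weights: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Binary labels marking the k = max(1, ceil(fraction*m)) largest weights;
    threshold ties broken by a seeded permutation."""
    m = len(weights)
    k = max(1, math.ceil(fraction * m))
    perm = rng.permutation(m)
    order = np.lexsort((perm, -weights))
    labels = np.zeros(m, dtype=np.int8)
    labels[order[:k]] = 1
    return labels


def top_partners(net: GeneNetwork, gene_id, fraction: float,
                 mask: EdgeMask | None = None, tie_seed: int = 0):
    """Label the gene's top-``fraction`` partners in the network.

    Returns ``(partner_indices, labels)`` over masked partners with defined
    weights, or ``None`` when the gene has no eligible partners (skip
    signal).  Tie-breaking at the threshold uses a deterministic shuffle
    keyed by ``tie_seed`` and the gene's index.
    """
    if not 0 < fraction < 1:
        raise InvalidInputError(f"fraction must be in (0,1), got {fraction}")
    gi = net.index(gene_id)
    row = net.weights[gi]
    valid = ~np.isnan(row)
    valid[gi] = False
    if mask is not None:
        valid &= mask.reindex(net.gene_ids)[gi]
    if not valid.any():
        return None
    partners = np.nonzero(valid)[0]
    rng = np.random.default_rng([int(tie_seed), int(gi)])
    labels = _top_fraction_labels(row[partners], fraction, rng)
    return partners, labels


def distance_mask(genes: pd.DataFrame, min_distance: int, scope: str,
                  distance: str = "span") -> EdgeMask:
    """Edge mask over a gene table.

    ``scope='cis'`` keeps same-chromosome pairs with pair distance strictly
    greater than ``min_distance``; ``scope='trans'`` keeps different-
    chromosome pairs (``min_distance`` ignored).
    """
    if min_distance < 0:
        raise InvalidInputError("min_distance must be >= 0")
    if scope not in ("cis", "trans"):
        raise UsageError(f"scope must be 'cis' or 'trans', got {scope!r}")
    chroms = genes["chrom"].to_numpy()
    same = chroms[:, None] == chroms[None, :]
    if scope == "trans":
        mat = ~same
    else:
        if distance == "tss":
            t = genes["tss"].to_numpy(dtype=np.int64)
            d = np.abs(t[:, None] - t[None, :])
        elif distance == "span":
            s = np.minimum(genes["tss"], genes["tes"]).to_numpy(dtype=np.int64)
            e = np.maximum(genes["tss"], genes["tes"]).to_numpy(dtype=np.int64)
            d = np.maximum(0, np.maximum(s[:, None], s[None, :]) - np.minimum(e[:, None], e[None, :]))
        else:
            raise InvalidInputError(f"unknown distance mode {distance!r}")
        mat = same & (d > min_distance)
    return EdgeMask(
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        matrix=mat,
        description=f"{scope},min_distance={min_distance},{distance}",
    )
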