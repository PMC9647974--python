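"""Chromatin structural units: A/B compartments, TADs, shared-unit networks.

Compartments use the classic observed/expected → correlation-matrix → first
principal component procedure; the PC1 sign groups are oriented by gene
density (the gene-dense group is A).  TADs use a simplified TopDom-style
caller ("topdom-lite"): a diamond binSignal whose strict local minima are
domain boundaries; the rank-sum false-boundary filter of full TopDom is
deliberately omitted.  Per-experiment categorical labels are binarized per
gene pair (same unit = 1) and averaged across experiments into a
shared-unit probability network.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
import scipy.sparse as sp

from .errors import InvalidInputError, NoCompartmentsError, UsageError
from .genome import BinnedGenome, tss_bin
from .networks import GeneNetwork

log = logging.getLogger("metahic")

CALLER_NAME = "topdom-lite"


@dataclass
class CategoricalAssignment:
    """Per-experiment gene → structural-unit labels."""

    experiment_id: str
    labels: dict  # gene_id -> label (A/B, subcompartment name, or TAD id)
    kind: str = "compartment"  # note: TAD ids are only valid within a chromosome


@dataclass
class TadSet:
    experiment_id: str
    resolution: int
    intervals: list = field(default_factory=list)  # (chrom, start_bin, end_bin) half-open
    caller: str = CALLER_NAME

    def __post_init__(self):
        for chrom, s, e in self.intervals:
            if s >= e:
                raise InvalidInputError(f"TAD on {chrom} with start >= end ({s}, {e})")


@dataclass
class SharedUnitNetwork:
    """Fraction of experiments in which each gene pair shares a unit label."""

    network: GeneNetwork  # kind shared-unit; NaN where support == 0
    support: np.ndarray  # per-pair count of experiments with both genes labelled


# ---------------------------------------------------------------------------
# observed / expected

def expected_by_distance(block: np.ndarray) -> np.ndarray:
    """Mean contact weight at each diagonal offset of a square cis block."""
    block = np.asarray(block, dtype=np.float64)
    n = block.shape[0]
    if block.shape != (n, n):
        raise InvalidInputError("expected_by_distance needs a square block")
    exp = np.full(n, np.nan)
    for d in range(n):
        exp[d] = block.diagonal(d).mean()
    return exp


def oe_matrix(block: np.ndarray) -> np.ndarray:
    """Observed/expected transform; offsets with zero expected map to 0."""
    block = np.asarray(block, dtype=np.float64)
    n = block.shape[0]
    exp = expected_by_distance(block)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    e = exp[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(e > 0, block / e, 0.0)
    return oe


# ---------------------------------------------------------------------------
# compartments

def call_compartments(block: np.ndarray, gene_density: np.ndarray,
                      min_bins: int = 3) -> np.ndarray:
    """A/B labels per bin of one chromosome's cis block.

    O/E → Pearson correlation over unmasked (nonzero-row) bins → first
    principal component (computed per connected component of the contact
    graph); the PC1 sign group with the higher mean gene density is A.
    Zero-row bins and bins in components smaller than ``min_bins`` stay
    unlabelled ('').
    """
    block = np.asarray(block, dtype=np.float64)
    n = block.shape[0]
    gene_density = np.asarray(gene_density, dtype=np.float64)
    if gene_density.shape != (n,):
        raise InvalidInputError("gene_density length must match block size")
    labels = np.full(n, "", dtype=object)
    unmasked = block.sum(axis=1) > 0
    if unmasked.sum() < min_bins:
        raise NoCompartmentsError("fewer than %d unmasked bins" % min_bins)
    oe = oe_matrix(block)
    sub_idx = np.nonzero(unmasked)[0]
    adj = sp.csr_matrix((block[np.ix_(sub_idx, sub_idx)] > 0).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    called_any = False
    for c in range(n_comp):
        members = sub_idx[comp == c]
        if len(members) < min_bins:
            continue
        sub = oe[np.ix_(members, members)]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        if not np.isfinite(corr).all() or np.allclose(corr, corr.flat[0]):
            raise NoCompartmentsError("degenerate (constant) correlation matrix")
        centered = corr - corr.mean(axis=0, keepdims=True)
        cov = centered.T @ centered
        _, vecs = np.linalg.eigh(cov)
        pc1 = centered @ vecs[:, -1]
        pos = pc1 >= 0
        if pos.all() or (~pos).all():
            raise NoCompartmentsError("PC1 does not partition the bins")
        dens_pos = gene_density[members[pos]].mean()
        dens_neg = gene_density[members[~pos]].mean()
        a_group = pos if dens_pos >= dens_neg else ~pos
        labels[members[a_group]] = "A"
        labels[members[~a_group]] = "B"
        called_any = True
    if not called_any:
        raise NoCompartmentsError("no component large enough to call compartments")
    return labels


def call_compartments_genome(cm, gene_density: np.ndarray) -> np.ndarray:
    """Per-bin A/B labels across all chromosomes of a contact matrix."""
    g = cm.genome
    dense = cm.dense_symmetric()
    labels = np.full(g.n_bins, "", dtype=object)
    for chrom in g.chrom_names:
        b0, b1 = g.chrom_bins(chrom)
        try:
            labels[b0:b1] = call_compartments(dense[b0:b1, b0:b1], gene_density[b0:b1])
        except NoCompartmentsError as exc:
            log.warning("no compartments on %s: %s", chrom, exc)
    return labels


def gene_density_per_bin(genes: pd.DataFrame, genome: BinnedGenome) -> np.ndarray:
    """Number of gene TSSs per bin (the density used to orient compartments)."""
    density = np.zeros(genome.n_bins)
    for gene in genes.itertuples(index=False):
        if gene.chrom in genome.chrom_names:
            density[tss_bin(genome, gene)] += 1
    return density


# ---------------------------------------------------------------------------
# TADs (topdom-lite)

def bin_signal(block: np.ndarray, window: int) -> np.ndarray:
    """TopDom binSignal: mean of the window×window diamond spanning
    rows (i-window+1..i) × cols (i+1..i+window), clipped at the edges.
    Undefined (NaN) at the last bin."""
    block = np.asarray(block, dtype=np.float64)
    n = block.shape[0]
    sig = np.full(n, np.nan)
    for i in range(n - 1):
        r0 = max(0, i - window + 1)
        c1 = min(n, i + 1 + window)
        sig[i] = block[r0:i + 1, i + 1:c1].mean()
    return sig


def call_tads(block: np.ndarray, window: int, chrom: str = "chr?",
              experiment_id: str = "exp", resolution: int = 1) -> TadSet:
    """Simplified TopDom domain calling on one chromosome block.

    Boundaries are bins whose binSignal is strictly lower than every other
    defined binSignal within ±``window`` bins; domains span the intervals
    between consecutive boundaries.  Blocks smaller than 2×window yield an
    empty TadSet with a warning.
    """
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    block = np.asarray(block, dtype=np.float64)
    n = block.shape[0]
    if n < 2 * window:
        log.warning("call_tads: block of %d bins smaller than 2*window=%d; no TADs",
                    n, 2 * window)
        return TadSet(experiment_id, resolution, [])
    sig = bin_signal(block, window)
    boundaries = []
    for i in range(1, n - 2):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neighbors = np.concatenate([sig[lo:i], sig[i + 1:hi]])
        neighbors = neighbors[~np.isnan(neighbors)]
        if len(neighbors) and np.isfinite(sig[i]) and (sig[i] < neighbors).all():
            boundaries.append(i)
    edges = [0] + [b + 1 for b in boundaries] + [n]
    intervals = [(chrom, s, e) for s, e in zip(edges[:-1], edges[1:]) if s < e]
    return TadSet(experiment_id, resolution, intervals)


def call_tads_genome(cm, window: int, experiment_id: str = "exp") -> TadSet:
    g = cm.genome
    dense = cm.dense_symmetric()
    intervals = []
    for chrom in g.chrom_names:
        b0, b1 = g.chrom_bins(chrom)
        ts = call_tads(dense[b0:b1, b0:b1], window, chrom=chrom,
                       experiment_id=experiment_id, resolution=g.resolution)
        intervals.extend(ts.intervals)
    return TadSet(experiment_id, g.resolution, intervals)


def tad_overlap(tadsets) -> dict:
    """Count, for every distinct (chrom, start, end) TAD, how many experiments
    contain it exactly (same start and end bins)."""
    tadsets = list(tadsets)
    if not tadsets:
        raise UsageError("tad_overlap() needs at least one TadSet")
    resolutions = {t.resolution for t in tadsets}
    if len(resolutions) > 1:
        raise UsageError(f"TadSets at mixed resolutions: {sorted(resolutions)}")
    counts = Counter()
    for ts in tadsets:
        counts.update(set(ts.intervals))
    return dict(counts)


# ---------------------------------------------------------------------------
# gene labelling & shared-unit aggregation

def gene_compartment_labels(bin_labels: np.ndarray, genes: pd.DataFrame,
                            genome: BinnedGenome, experiment_id: str,
                            kind: str = "compartment") -> CategoricalAssignment:
    """Assign each gene the label of its TSS bin (unlabelled bins skipped)."""
    labels = {}
    for gene in genes.itertuples(index=False):
        if gene.chrom not in genome.chrom_names:
            continue
        lab = bin_labels[tss_bin(genome, gene)]
        if lab:
            labels[gene.gene_id] = lab
    return CategoricalAssignment(experiment_id, labels, kind=kind)


def gene_tad_labels(tads: TadSet, genes: pd.DataFrame,
                    genome: BinnedGenome) -> CategoricalAssignment:
    """Assign each gene a chromosome-scoped TAD id from its TSS bin.

    Labels are ``chrom:k`` so ids never collide across chromosomes; genes on
    different chromosomes therefore never share a TAD label.
    """
    per_chrom = {}
    for chrom, s, e in tads.intervals:
        per_chrom.setdefault(chrom, []).append((s, e))
    labels = {}
    for gene in genes.itertuples(index=False):
        if gene.chrom not in genome.chrom_names:
            continue
        b0, _ = genome.chrom_bins(gene.chrom)
        local = tss_bin(genome, gene) - b0
        for k, (s, e) in enumerate(per_chrom.get(gene.chrom, [])):
            if s <= local < e:
                labels[gene.gene_id] = f"{gene.chrom}:{k}"
                break
    return CategoricalAssignment(tads.experiment_id, labels, kind="tad")


def read_assignments_tsv(path) -> list:
    """Assignment TSV: experiment_id, gene_id, label (one row per gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for exp, sub in df.groupby(df.columns[0], sort=True):
        out.append(CategoricalAssignment(str(exp), dict(zip(sub.iloc[:, 1], sub.iloc[:, 2]))))
    return out


def shared_unit_network(assignments, gene_ids) -> SharedUnitNetwork:
    """Binarize shared-unit membership per experiment and average.

    weight(g, h) = (#experiments with both genes labelled and labels equal)
    / (#experiments with both labelled); NaN where no experiment labels both.
    """
    assignments = list(assignments)
    if not assignments:
        raise UsageError("shared_unit_network() needs at least one assignment")
    gene_ids = np.asarray(gene_ids, dtype=object)
    n = len(gene_ids)
    agree = np.zeros((n, n))
    support = np.zeros((n, n), dtype=np.int64)
    for asn in assignments:
        lab = np.array([asn.labels.get(g) for g in gene_ids], dtype=object)
        has = np.array([x is not None for x in lab])
        both = has[:, None] & has[None, :]
        same = (lab[:, None] == lab[None, :]) & both
        agree += same
        support += both
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(support > 0, agree / np.maximum(support, 1), np.nan)
    net = GeneNetwork(gene_ids=gene_ids, weights=weights, kind="shared-unit")
    return SharedUnitNetwork(network=net, support=support)
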