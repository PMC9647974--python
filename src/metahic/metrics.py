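"""Per-entity AUROC metrics.

Every evaluation in the package is the same prediction task: rank a gene's
(or variant's) candidate partners by one signal and score how well that
ranking retrieves a binary label set, as a Mann–Whitney AUROC with mid-rank
tie handling.  Metrics differ only in where scores and labels come from:

* contact coexpression — Hi-C edge weights predict the gene's top-1%
  coexpression partners;
* compartment / subcompartment / TAD coexpression — shared-unit
  probabilities predict the same labels;
* contact-eQTL — contact frequency between a variant's bin and candidate
  genes predicts the significant eGene;
* proximity-eQTL — inverse variant–TSS distance predicts the same eGene.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidInputError, UndefinedAUCError, UsageError
from .genome import BinnedGenome, gene_bin_range, locate_bin, tss_bin, tss_position
from .networks import EdgeMask, GeneNetwork, _top_fraction_labels, top_partners
from .structure import SharedUnitNetwork

log = logging.getLogger("metahic")


# ---------------------------------------------------------------------------
# AUROC core

def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC with average-rank tie handling.

    AUC = (R_pos − n_pos(n_pos+1)/2) / (n_pos · n_neg) where R_pos is the
    sum of average ranks of the positive items.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise InvalidInputError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"AUC undefined (n_pos={n_pos}, n_neg={n_neg})")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class AUCResult:
    """Per-entity AUCs with skip accounting and mean/median summaries."""

    per_entity: dict = field(default_factory=dict)
    n_pos: dict = field(default_factory=dict)
    n_neg: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)  # entity -> reason code

    def add(self, entity, auc, n_pos, n_neg):
        self.per_entity[entity] = float(auc)
        self.n_pos[entity] = int(n_pos)
        self.n_neg[entity] = int(n_neg)

    def skip(self, entity, reason):
        self.skipped[entity] = reason

    @property
    def n_scored(self) -> int:
        return len(self.per_entity)

    @property
    def mean_auc(self) -> float:
        v = list(self.per_entity.values())
        return float(np.mean(v)) if v else float("nan")

    @property
    def median_auc(self) -> float:
        v = list(self.per_entity.values())
        return float(np.median(v)) if v else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity": list(self.per_entity),
                "auc": list(self.per_entity.values()),
                "n_pos": [self.n_pos[e] for e in self.per_entity],
                "n_neg": [self.n_neg[e] for e in self.per_entity],
            }
        )

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "median_auc": self.median_auc,
            "n_scored": self.n_scored,
            "n_skipped": len(self.skipped),
        }

    def write(self, tsv_path=None, json_path=None):
        if tsv_path:
            self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=1)


# ---------------------------------------------------------------------------
# network-vs-network prediction

def network_prediction_auc(score_net: GeneNetwork, label_net: GeneNetwork,
                           mask: EdgeMask | None = None, fraction: float = 0.01,
                           tie_seed: int = 0, entity_suffix: str = "") -> AUCResult:
    """Per-gene AUROC of one network's edge weights predicting another
    network's top-``fraction`` partners, over the common gene set."""
    common = [g for g in label_net.gene_ids if g in score_net._index]
    dropped = len(set(score_net.gene_ids) ^ set(common)) + (len(label_net.gene_ids) - len(common))
    if not common:
        raise UsageError("networks share no genes")
    if dropped:
        log.info("network_prediction_auc: %d genes outside the common set", dropped)
    sn = score_net.subset(common)
    ln = label_net.subset(common)
    mask_mat = mask.reindex(common) if mask is not None else None
    result = AUCResult()
    score_nan = np.isnan(sn.weights)
    for gi, gene in enumerate(ln.gene_ids):
        valid = ~np.isnan(ln.weights[gi]) & ~score_nan[gi]
        valid[gi] = False
        if mask_mat is not None:
            valid &= mask_mat[gi]
        entity = f"{gene}{entity_suffix}"
        if not valid.any():
            result.skip(entity, "no-edges")
            continue
        partners = np.nonzero(valid)[0]
        rng = np.random.default_rng([int(tie_seed), gi])
        labels = _top_fraction_labels(ln.weights[gi, partners], fraction, rng)
        scores = sn.weights[gi, partners]
        try:
            auc = auroc(scores, labels)
        except UndefinedAUCError:
            result.skip(entity, "no-negatives" if labels.all() else "no-positives")
            continue
        result.add(entity, auc, labels.sum(), len(labels) - labels.sum())
    return result


def contact_coexpression(hic: GeneNetwork, coexp: GeneNetwork,
                         mask: EdgeMask | None = None, fraction: float = 0.01,
                         tie_seed: int = 0) -> AUCResult:
    """Mean per-gene AUROC of Hi-C edge weights predicting each gene's
    top-``fraction`` coexpression partners."""
    return network_prediction_auc(hic, coexp, mask=mask, fraction=fraction,
                                  tie_seed=tie_seed)


def unit_coexpression(shared: SharedUnitNetwork, coexp: GeneNetwork,
                      mask: EdgeMask | None = None, fraction: float = 0.01,
                      tie_seed: int = 0) -> AUCResult:
    """Compartment/subcompartment/TAD coexpression: shared-unit probabilities
    predicting top coexpression partners (support-0 pairs excluded)."""
    return network_prediction_auc(shared.network, coexp, mask=mask,
                                  fraction=fraction, tie_seed=tie_seed)


# ---------------------------------------------------------------------------
# eQTL table

EQTL_COLUMNS = ("variant_id", "chrom", "pos", "gene_id", "tss_distance", "significant")


@dataclass
class EQTLTable:
    """Variant–gene association records (tissue-collapsed, GTEx-style)."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = set(EQTL_COLUMNS) - set(self.records.columns)
        if missing:
            raise InvalidInputError(f"EQTL table missing columns: {sorted(missing)}")
        if self.records.duplicated(["variant_id", "gene_id"]).any():
            raise InvalidInputError("duplicate (variant, gene) pairs in EQTL table")

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path):
        self.records.to_csv(path, sep="\t", index=False)

    def variants(self) -> pd.DataFrame:
        return self.records.drop_duplicates("variant_id")[["variant_id", "chrom", "pos"]]


def filter_eqtls(table: EQTLTable, genes: pd.DataFrame,
                 coding: pd.DataFrame, margin: int = 1000) -> EQTLTable:
    """Remove variants inside coding intervals or within ``margin`` bp of any
    gene TSS/TES.  Removal is variant-level: all the variant's records go."""
    removed = set()
    var = table.variants()
    tss_tes = {}
    for g in genes.itertuples(index=False):
        pts = tss_tes.setdefault(g.chrom, [])
        pts.append(tss_position(g))
        pts.append(int(g.tes))
    tss_tes = {c: np.sort(np.array(p)) for c, p in tss_tes.items()}
    coding_by_chrom = {}
    if coding is not None and len(coding):
        for c, sub in coding.groupby("chrom"):
            iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
            iv = iv[np.argsort(iv[:, 0])]
            coding_by_chrom[c] = iv
    for v in var.itertuples(index=False):
        pos = int(v.pos)
        pts = tss_tes.get(v.chrom)
        if pts is not None and len(pts):
            k = np.searchsorted(pts, pos)
            near = min(
                abs(pos - pts[k - 1]) if k > 0 else np.inf,
                abs(pts[k] - pos) if k < len(pts) else np.inf,
            )
            if near <= margin:
                removed.add(v.variant_id)
                continue
        iv = coding_by_chrom.get(v.chrom)
        if iv is not None and len(iv):
            k = np.searchsorted(iv[:, 0], pos, side="right") - 1
            if (k >= 0 and iv[k, 0] <= pos < iv[k, 1]) or (
                k + 1 < len(iv) and iv[k + 1, 0] <= pos < iv[k + 1, 1]
            ):
                removed.add(v.variant_id)
    if removed:
        log.info("filter_eqtls: removed %d variants", len(removed))
    kept = table.records[~table.records["variant_id"].isin(removed)].reset_index(drop=True)
    return EQTLTable(kept)


def candidate_genes(variant, genes: pd.DataFrame, genome: BinnedGenome) -> list:
    """Same-chromosome genes in *unique* TSS bins at the matrix resolution.

    Genes whose TSS bin also contains another gene's TSS are all excluded,
    avoiding order-dependent picks among bin-sharing genes.
    """
    sub = genes[genes["chrom"] == variant.chrom]
    if sub.empty:
        return []
    bins = np.array([tss_bin(genome, g) for g in sub.itertuples(index=False)])
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    unique = counts[inverse] == 1
    return list(sub["gene_id"].to_numpy()[unique])


def _eqtl_entities(genes: pd.DataFrame, table: EQTLTable, genome: BinnedGenome,
                   min_distance: int):
    """Shared candidate construction for both eQTL metrics: per variant, the
    candidate genes (unique bins, |distance| > min_distance), their signed
    TSS distances, and significance labels.  Yields (variant, gene_ids,
    distances, labels) or a skip reason; skip sets are identical for the
    contact and proximity metrics by construction."""
    gene_rows = {g.gene_id: g for g in genes.itertuples(index=False)}
    rec = table.records
    sig = {}
    dist = {}
    for r in rec.itertuples(index=False):
        sig[(r.variant_id, r.gene_id)] = bool(r.significant)
        dist[(r.variant_id, r.gene_id)] = float(r.tss_distance)
    for v in table.variants().itertuples(index=False):
        cands = candidate_genes(v, genes, genome)
        if not cands:
            yield v, None, None, None, "no-candidates"
            continue
        ds, labels, kept = [], [], []
        for gid in cands:
            d = dist.get((v.variant_id, gid))
            if d is None:
                d = float(int(v.pos) - tss_position(gene_rows[gid]))
            if abs(d) <= min_distance:
                continue
            kept.append(gid)
            ds.append(d)
            labels.append(sig.get((v.variant_id, gid), False))
        labels = np.array(labels, dtype=bool)
        if len(kept) == 0 or not labels.any():
            yield v, None, None, None, "no-positives"
            continue
        if labels.all():
            yield v, None, None, None, "no-negatives"
            continue
        yield v, kept, np.array(ds), labels, None


def contact_eqtl(cm, genes: pd.DataFrame, table: EQTLTable,
                 min_distance: int = 0) -> AUCResult:
    """Per-variant AUROC of contact frequency (variant bin vs candidate gene
    bins, max over the gene's bins) predicting the significant eGene."""
    genome = cm.genome
    sym = cm.symmetric()
    gene_rows = {g.gene_id: g for g in genes.itertuples(index=False)}
    result = AUCResult()
    for v, kept, _ds, labels, reason in _eqtl_entities(genes, table, genome, min_distance):
        if reason:
            result.skip(v.variant_id, reason)
            continue
        vbin = locate_bin(genome, v.chrom, int(v.pos))
        row = np.asarray(sym[vbin, :].todense()).ravel()
        scores = np.empty(len(kept))
        for k, gid in enumerate(kept):
            b0, b1 = gene_bin_range(genome, gene_rows[gid])
            scores[k] = row[b0:b1 + 1].max()
        try:
            auc = auroc(scores, labels)
        except UndefinedAUCError:
            result.skip(v.variant_id, "no-negatives")
            continue
        result.add(v.variant_id, auc, labels.sum(), (~labels).sum())
    return result


def proximity_eqtl(genes: pd.DataFrame, table: EQTLTable, genome: BinnedGenome,
                   min_distance: int = 0) -> AUCResult:
    """Per-variant AUROC of inverse variant–TSS distance predicting the
    eGene; candidate and skip sets match :func:`contact_eqtl` exactly."""
    result = AUCResult()
    for v, kept, ds, labels, reason in _eqtl_entities(genes, table, genome, min_distance):
        if reason:
            result.skip(v.variant_id, reason)
            continue
        if (ds == 0).any():
            raise InvalidInputError(
                f"zero variant-TSS distance for variant {v.variant_id} "
                "(should have been removed by filter_eqtls)"
            )
        scores = 1.0 / np.abs(ds)
        try:
            auc = auroc(scores, labels)
        except UndefinedAUCError:
            result.skip(v.variant_id, "no-negatives")
            continue
        result.add(v.variant_id, auc, labels.sum(), (~labels).sum())
    return result
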