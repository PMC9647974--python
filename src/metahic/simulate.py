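"""Synthetic genomes, contact structures, expression, eQTLs, species pairs.

The generator emulates the qualitative features the analysis relies on:

* cis contact probability decays with genomic distance as a power law,
  modulated by a plaid A/B compartment pattern (alternating blocks, with a
  within-compartment boost);
* trans contacts are a sparse uniform background plus *planted* functional
  gene pairs whose TSS-bin cells are boosted;
* reads are drawn multinomially at a controllable total depth, so depth is
  exact for depth-sweep experiments and subsampling is exact hypergeometric
  thinning;
* expression couples to the contact structure through shared latent
  factors: each gene loads with weight sqrt(kappa) on its module factor
  (its per-chromosome compartment, or its planted functional-pair group)
  and sqrt(1-kappa) on private noise;
* eQTL variants are planted in non-coding bins with a boosted contact to
  their true eGene's TSS bin;
* a second species copies the probability structure with a fraction
  ``divergence`` of the planted pairs rewired to random pairs, linked by an
  identity 1:1 ortholog map.

All randomness derives deterministically from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError
from .genome import BinnedGenome, locate_bin, make_bins, tss_bin, tss_position
from .contacts import ContactMatrix
from .metrics import EQTLTable

log = logging.getLogger("metahic")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (desk scale by default:
    3 chromosomes x 2 Mb at 10-kb bins, 200 genes, 200 samples, 1e6 reads)."""

    n_chroms: int = 3
    chrom_length: int = 2_000_000
    resolution: int = 10_000
    n_genes: int = 200
    decay_exponent: float = 1.0       # alpha: cis p ~ (1+|i-j|)^-alpha
    compartment_block: int = 10       # bins per alternating A/B block
    plaid_boost: float = 3.0          # same-compartment cis multiplier
    a_gene_density: float = 2.0       # gene-placement propensity of A vs B bins
    trans_base: float = 0.01          # relative weight of a background trans cell
    n_functional_pairs: int = 40
    functional_boost: float = 30.0    # multiplier on planted trans pair cells
    coupling: float = 0.6             # kappa: expression-contact coupling in [0,1]
    n_samples: int = 200
    depth: int = 1_000_000
    divergence: float = 0.0           # delta: fraction of planted pairs rewired in species B
    n_variants: int = 50
    decoys_per_variant: int = 8
    eqtl_boost: float = 30.0          # multiplier on variant-bin x eGene-bin cells
    gene_length_range: tuple = (2_000, 8_000)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "resolution", "n_genes", "n_samples"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be > 0")
        if not 0 <= self.coupling <= 1:
            raise ConfigError("coupling must be in [0, 1]")
        if not 0 <= self.divergence <= 1:
            raise ConfigError("divergence must be in [0, 1]")
        if self.plaid_boost < 1:
            raise ConfigError("plaid_boost must be >= 1")
        if self.trans_base < 0:
            raise ConfigError("trans_base must be >= 0")
        if self.depth < 0:
            raise ConfigError("depth must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
        if "gene_length_range" in d:
            d = dict(d, gene_length_range=tuple(d["gene_length_range"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class SyntheticTruth:
    """Planted ground truth backing a simulated dataset."""

    genome: BinnedGenome
    genes: pd.DataFrame
    bin_compartments: np.ndarray      # 'A'/'B' per bin
    functional_pairs: list            # [(gene_a, gene_b), ...] trans pairs
    pair_group: dict                  # gene_id -> functional group id
    variants: pd.DataFrame            # variant_id, chrom, pos, bin, egene
    config: SimulationConfig

    def gene_compartments(self) -> dict:
        out = {}
        for g in self.genes.itertuples(index=False):
            out[g.gene_id] = str(self.bin_compartments[tss_bin(self.genome, g)])
        return out


# ---------------------------------------------------------------------------
# genome / genes / plantings

def _bin_compartments(genome: BinnedGenome, block: int) -> np.ndarray:
    labels = np.empty(genome.n_bins, dtype=object)
    for chrom in genome.chrom_names:
        b0, b1 = genome.chrom_bins(chrom)
        local = np.arange(b1 - b0)
        labels[b0:b1] = np.where((local // block) % 2 == 0, "A", "B")
    return labels


def _simulate_genes(genome: BinnedGenome, comp: np.ndarray,
                    config: SimulationConfig, rng) -> pd.DataFrame:
    """One gene per bin, placement biased toward A bins (A is gene-dense)."""
    rows = []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    lmin, lmax = config.gene_length_range
    gid = 0
    for ci, chrom in enumerate(genome.chrom_names):
        b0, b1 = genome.chrom_bins(chrom)
        nb = b1 - b0
        need = int(per_chrom[ci])
        if need > nb:
            raise ConfigError(f"more genes than bins on {chrom} ({need} > {nb})")
        w = np.where(comp[b0:b1] == "A", config.a_gene_density, 1.0)
        chosen = rng.choice(nb, size=need, replace=False, p=w / w.sum())
        length_chrom = genome.chrom_length(chrom)
        for local in np.sort(chosen):
            length = int(rng.integers(lmin, lmax + 1))
            start = local * genome.resolution + int(rng.integers(0, genome.resolution // 2 + 1))
            start = min(start, length_chrom - length - 1)
            start = max(start, 0)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tes = start, start + length
            else:
                tss, tes = start + length, start
            rows.append((f"g{gid:04d}", chrom, tss, tes, strand))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "tes", "strand"])


def _sample_trans_pairs(genes: pd.DataFrame, n_pairs: int, rng,
                        forbidden=()) -> list:
    """Distinct random different-chromosome gene pairs."""
    ids = genes["gene_id"].to_numpy()
    chroms = dict(zip(genes["gene_id"], genes["chrom"]))
    pairs, seen = [], set(frozenset(p) for p in forbidden)
    attempts = 0
    while len(pairs) < n_pairs and attempts < 100 * max(n_pairs, 1):
        attempts += 1
        a, b = rng.choice(len(ids), size=2, replace=False)
        ga, gb = ids[a], ids[b]
        if chroms[ga] == chroms[gb]:
            continue
        key = frozenset((ga, gb))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((ga, gb))
    if len(pairs) < n_pairs:
        log.warning("could only plant %d/%d trans pairs", len(pairs), n_pairs)
    return pairs


def _plant_variants(genome: BinnedGenome, genes: pd.DataFrame,
                    config: SimulationConfig, rng) -> pd.DataFrame:
    """Place variants in non-coding bins, >1 kb from every TSS/TES, each with
    a true eGene a few bins away on the same chromosome."""
    covered = set()
    points = {c: [] for c in genome.chrom_names}
    for g in genes.itertuples(index=False):
        lo = min(g.tss, g.tes) // genome.resolution
        hi = (max(g.tss, g.tes) - 1) // genome.resolution
        b0, _ = genome.chrom_bins(g.chrom)
        covered.update(range(b0 + lo, b0 + hi + 1))
        points[g.chrom].extend([tss_position(g), int(g.tes)])
    points = {c: np.sort(np.array(p)) if p else np.array([]) for c, p in points.items()}
    max_off = max(3, 100_000 // genome.resolution)
    rows = []
    gene_list = list(genes.itertuples(index=False))
    for k in range(config.n_variants):
        for _ in range(200):
            g = gene_list[int(rng.integers(len(gene_list)))]
            gbin = tss_bin(genome, g)
            off = int(rng.integers(2, max_off + 1)) * (1 if rng.random() < 0.5 else -1)
            vbin = gbin + off
            b0, b1 = genome.chrom_bins(g.chrom)
            if not b0 <= vbin < b1 or vbin in covered:
                continue
            chrom, s, e = genome.bin_span(vbin)
            pos = (s + e) // 2
            pts = points[chrom]
            if len(pts):
                i = np.searchsorted(pts, pos)
                near = min(
                    abs(pos - pts[i - 1]) if i > 0 else np.inf,
                    abs(pts[i] - pos) if i < len(pts) else np.inf,
                )
                if near <= 1000:
                    continue
            rows.append((f"v{k:04d}", chrom, pos, vbin, g.gene_id))
            break
        else:
            log.warning("could not place variant %d; skipped", k)
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "bin", "egene"])


# ---------------------------------------------------------------------------
# probability structure

def _build_probability(genome: BinnedGenome, genes: pd.DataFrame,
                       comp: np.ndarray, pairs, variants: pd.DataFrame,
                       config: SimulationConfig) -> np.ndarray:
    n = genome.n_bins
    P = np.zeros((n, n))
    for chrom in genome.chrom_names:
        b0, b1 = genome.chrom_bins(chrom)
        nb = b1 - b0
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        block = (1.0 + d) ** (-config.decay_exponent)
        same = comp[b0:b1, None] == comp[None, b0:b1]
        block = block * np.where(same, config.plaid_boost, 1.0)
        P[b0:b1, b0:b1] = block
    if config.trans_base > 0:
        chrom_of = genome.chrom_of_bin
        trans = chrom_of[:, None] != chrom_of[None, :]
        P[trans] = config.trans_base
    tbin = {g.gene_id: tss_bin(genome, g) for g in genes.itertuples(index=False)}
    for ga, gb in pairs:
        i, j = tbin[ga], tbin[gb]
        base = P[i, j] if P[i, j] > 0 else config.trans_base
        P[i, j] = P[j, i] = base * config.functional_boost
    if len(variants):
        for v in variants.itertuples(index=False):
            i, j = int(v.bin), tbin[v.egene]
            P[i, j] = P[j, i] = P[i, j] * config.eqtl_boost
    total = P.sum()
    if total <= 0:
        raise ConfigError("probability structure sums to zero")
    return P / total


def simulate_contact_probabilities(config: SimulationConfig):
    """Dense contact probability matrix (sums to 1) plus the planted truth."""
    rng = np.random.default_rng([int(config.seed), 0])
    genome = make_bins(
        {f"chr{c + 1}": config.chrom_length for c in range(config.n_chroms)},
        config.resolution,
    )
    comp = _bin_compartments(genome, config.compartment_block)
    genes = _simulate_genes(genome, comp, config, rng)
    pairs = _sample_trans_pairs(genes, config.n_functional_pairs, rng)
    variants = _plant_variants(genome, genes, config, rng)
    P = _build_probability(genome, genes, comp, pairs, variants, config)
    pair_group = {}
    for k, (ga, gb) in enumerate(pairs):
        gid = min(pair_group.get(ga, k), pair_group.get(gb, k))
        pair_group[ga] = pair_group[gb] = gid
    truth = SyntheticTruth(
        genome=genome, genes=genes, bin_compartments=comp,
        functional_pairs=pairs, pair_group=pair_group,
        variants=variants, config=config,
    )
    return P, truth


# ---------------------------------------------------------------------------
# sampling

def sample_contacts(P: np.ndarray, depth: int, seed, genome: BinnedGenome,
                    provenance: str = "sim") -> ContactMatrix:
    """Multinomial draw of ``depth`` unordered contacts over the matrix cells;
    total weight equals ``depth`` exactly."""
    if depth < 0:
        raise InvalidInputError("depth must be >= 0")
    n = genome.n_bins
    if P.shape != (n, n):
        raise InvalidInputError("probability matrix does not match the genome")
    iu = np.triu_indices(n)
    w = P[iu].astype(np.float64).copy()
    w[iu[0] != iu[1]] *= 2.0  # unordered pair mass of symmetric off-diagonal cells
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), p)
    nz = counts > 0
    return ContactMatrix.from_coo(
        genome, iu[0][nz], iu[1][nz], counts[nz].astype(np.float64),
        provenance=[provenance],
    )


def subsample_contacts(cm: ContactMatrix, depth: int, seed) -> ContactMatrix:
    """Exact downsampling to ``depth`` contacts (sampling without replacement),
    so nested depth sweeps share their low-depth contacts with high depth."""
    i, j, w = cm.coo()
    counts = np.rint(w).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise InvalidInputError(f"cannot subsample {depth} from {total} contacts")
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(counts, int(depth), method="marginals")
    nz = sub > 0
    return ContactMatrix.from_coo(
        cm.genome, i[nz], j[nz], sub[nz].astype(np.float64),
        provenance=list(cm.provenance) + [f"subsample:{depth}"],
    )


# ---------------------------------------------------------------------------
# expression

def simulate_expression(truth: SyntheticTruth, config: SimulationConfig,
                        seed_key: int = 1) -> pd.DataFrame:
    """Genes×samples expression: sqrt(kappa)·module factor + sqrt(1-kappa)·noise.

    A gene's module is its planted functional-pair group when it has one
    (trans signal), else its (chromosome, compartment) block (cis signal).
    """
    if config.n_samples < 3:
        raise ConfigError("n_samples must be >= 3")
    rng = np.random.default_rng([int(config.seed), int(seed_key)])
    comp = truth.gene_compartments()
    modules = {}
    for g in truth.genes.itertuples(index=False):
        if g.gene_id in truth.pair_group:
            modules[g.gene_id] = ("pair", truth.pair_group[g.gene_id])
        else:
            modules[g.gene_id] = ("block", g.chrom, comp[g.gene_id])
    factor_ids = sorted(set(modules.values()), key=str)
    factors = {m: rng.standard_normal(config.n_samples) for m in factor_ids}
    k = float(config.coupling)
    data = np.empty((len(truth.genes), config.n_samples))
    for row, g in enumerate(truth.genes["gene_id"]):
        noise = rng.standard_normal(config.n_samples)
        data[row] = np.sqrt(k) * factors[modules[g]] + np.sqrt(1.0 - k) * noise
    return pd.DataFrame(
        data, index=truth.genes["gene_id"].to_numpy(),
        columns=[f"s{t:03d}" for t in range(config.n_samples)],
    )


# ---------------------------------------------------------------------------
# eQTL table

def simulate_eqtls(truth: SyntheticTruth, genes: pd.DataFrame,
                   config: SimulationConfig, seed_key: int = 2) -> EQTLTable:
    """Materialize the GTEx-style association table from the planted truth:
    one significant record per variant (its true eGene) plus non-significant
    decoy records for other same-chromosome genes."""
    rng = np.random.default_rng([int(config.seed), int(seed_key)])
    gene_rows = {g.gene_id: g for g in genes.itertuples(index=False)}
    rows = []
    for v in truth.variants.itertuples(index=False):
        eg = gene_rows[v.egene]
        rows.append((v.variant_id, v.chrom, int(v.pos), v.egene,
                     int(v.pos) - tss_position(eg), 1))
        same = [g for g in gene_rows.values()
                if g.chrom == v.chrom and g.gene_id != v.egene]
        n_decoys = min(config.decoys_per_variant, len(same))
        for idx in rng.choice(len(same), size=n_decoys, replace=False):
            d = same[int(idx)]
            rows.append((v.variant_id, v.chrom, int(v.pos), d.gene_id,
                         int(v.pos) - tss_position(d), 0))
    return EQTLTable(pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "gene_id",
                       "tss_distance", "significant"],
    ))


# ---------------------------------------------------------------------------
# second species

@dataclass
class SpeciesPair:
    truth_b: SyntheticTruth
    probabilities_b: np.ndarray
    orthologs: pd.DataFrame  # gene_a, gene_b (identity over shared ids)


def simulate_species_pair(truth: SyntheticTruth, config: SimulationConfig,
                          seed_key: int = 3) -> SpeciesPair:
    """Species B copies species A's probability structure with a fraction
    ``config.divergence`` of the planted trans pair boosts rewired to random
    new pairs; orthologs are the identity map over shared gene ids."""
    rng = np.random.default_rng([int(config.seed), int(seed_key)])
    pairs = list(truth.functional_pairs)
    n_rewire = int(round(config.divergence * len(pairs)))
    if n_rewire:
        drop = set(rng.choice(len(pairs), size=n_rewire, replace=False).tolist())
        kept = [p for k, p in enumerate(pairs) if k not in drop]
    else:
        kept = pairs
    new = _sample_trans_pairs(truth.genes, n_rewire, rng, forbidden=kept)
    pairs_b = kept + new
    # eQTL plantings are species-A specific; species B carries none
    variants_b = truth.variants.iloc[0:0]
    P_b = _build_probability(truth.genome, truth.genes, truth.bin_compartments,
                             pairs_b, variants_b, truth.config)
    pair_group = {}
    for k, (ga, gb) in enumerate(pairs_b):
        gid = min(pair_group.get(ga, k), pair_group.get(gb, k))
        pair_group[ga] = pair_group[gb] = gid
    truth_b = SyntheticTruth(
        genome=truth.genome, genes=truth.genes,
        bin_compartments=truth.bin_compartments,
        functional_pairs=pairs_b, pair_group=pair_group,
        variants=variants_b, config=config,
    )
    orthologs = pd.DataFrame({
        "gene_a": truth.genes["gene_id"].to_numpy(),
        "gene_b": truth.genes["gene_id"].to_numpy(),
    })
    return SpeciesPair(truth_b=truth_b, probabilities_b=P_b, orthologs=orthologs)


# ---------------------------------------------------------------------------
# one-call bundle

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: SyntheticTruth
    probabilities: np.ndarray
    contacts: ContactMatrix
    expression: pd.DataFrame
    eqtls: EQTLTable

    @property
    def genome(self):
        return self.truth.genome

    @property
    def genes(self):
        return self.truth.genes


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full bundle: probabilities, sampled contacts at
    ``config.depth``, coupled expression, and the eQTL table."""
    P, truth = simulate_contact_probabilities(config)
    contacts = sample_contacts(P, config.depth, [int(config.seed), 10],
                               truth.genome, provenance=f"sim-seed{config.seed}")
    expression = simulate_expression(truth, config)
    eqtls = simulate_eqtls(truth, truth.genes, config)
    return SyntheticDataset(config=config, truth=truth, probabilities=P,
                            contacts=contacts, expression=expression, eqtls=eqtls)
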