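"""Genome coordinate model: chromosomes, fixed-width bins, genes, variants.

All coordinates are 0-based, half-open internally.  GTF input (1-based,
closed intervals) is converted on parse.  A :class:`BinnedGenome` fixes a
resolution (bin width in bp) and assigns every chromosome a contiguous,
0-based block of global bin indices; the last bin of each chromosome is
truncated at the chromosome end.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, UnknownIdError

log = logging.getLogger("metahic")

#: Marker returned by :func:`gene_pair_distance` for inter-chromosomal pairs.
TRANS = None

#: Autosome allow-lists per species ("autosome" is species-specific).
DEFAULT_AUTOSOMES = {
    "human": tuple(f"chr{i}" for i in range(1, 23)),
    "mouse": tuple(f"chr{i}" for i in range(1, 20)),
    "fly": ("chr2L", "chr2R", "chr3L", "chr3R", "chr4"),
}

GENE_COLUMNS = ("gene_id", "chrom", "tss", "tes", "strand")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the fields the contact pipeline needs.

    ``tss``/``tes`` follow strand orientation: for a minus-strand gene the
    TSS is the (exclusive) end of the genomic span, so the occupied span is
    always ``[min(tss, tes), max(tss, tes))``.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "+"

    def __post_init__(self):
        if self.tss == self.tes:
            raise InvalidInputError(f"gene {self.gene_id}: tss == tes ({self.tss})")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass(frozen=True)
class GenomicVariant:
    variant_id: str
    chrom: str
    pos: int


@dataclass
class BinnedGenome:
    """Chromosome/bin coordinate system at a fixed resolution."""

    chrom_names: tuple
    chrom_lengths: tuple
    resolution: int
    # derived, filled in __post_init__
    n_bins_per_chrom: np.ndarray = field(init=False, repr=False)
    bin_offset: np.ndarray = field(init=False, repr=False)
    chrom_of_bin: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.chrom_names = tuple(self.chrom_names)
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        if self.resolution <= 0:
            raise InvalidInputError(f"resolution must be positive, got {self.resolution}")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise InvalidInputError(f"chromosome {name!r} has non-positive length {length}")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise InvalidInputError("duplicate chromosome names")
        self.n_bins_per_chrom = np.array(
            [math.ceil(l / self.resolution) for l in self.chrom_lengths], dtype=np.int64
        )
        self.bin_offset = np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)[:-1]]).astype(np.int64)
        self.chrom_of_bin = np.repeat(
            np.arange(len(self.chrom_names)), self.n_bins_per_chrom
        )
        self._chrom_index = {c: i for i, c in enumerate(self.chrom_names)}

    # -- identity -----------------------------------------------------------
    def __eq__(self, other):
        return (
            isinstance(other, BinnedGenome)
            and self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.resolution == other.resolution
        )

    def __hash__(self):
        return hash((self.chrom_names, self.chrom_lengths, self.resolution))

    # -- lookups ------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.n_bins_per_chrom.sum())

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._chrom_index[chrom]
        except KeyError:
            raise UnknownIdError(f"unknown chromosome {chrom!r}") from None

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_index(chrom)]

    def chrom_bins(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin index range of a chromosome."""
        ci = self.chrom_index(chrom)
        start = int(self.bin_offset[ci])
        return start, start + int(self.n_bins_per_chrom[ci])

    def bin_span(self, bin_index: int) -> tuple[str, int, int]:
        """(chrom, start_bp, end_bp) of a global bin, end truncated."""
        if not 0 <= bin_index < self.n_bins:
            raise InvalidInputError(f"bin {bin_index} outside genome (n_bins={self.n_bins})")
        ci = int(self.chrom_of_bin[bin_index])
        local = bin_index - int(self.bin_offset[ci])
        start = local * self.resolution
        end = min(start + self.resolution, self.chrom_lengths[ci])
        return self.chrom_names[ci], start, end

    def is_cis(self, i, j):
        """Vectorized same-chromosome test for global bin indices."""
        return self.chrom_of_bin[np.asarray(i)] == self.chrom_of_bin[np.asarray(j)]


def make_bins(chrom_table, resolution: int) -> BinnedGenome:
    """Divide chromosomes into fixed-width bins.

    ``chrom_table`` may be a mapping name->length, a DataFrame with columns
    (name, length), or an iterable of pairs.  Autosome filtering is the
    caller's responsibility (see :func:`filter_autosomes`).
    """
    if isinstance(chrom_table, dict):
        items = list(chrom_table.items())
    elif isinstance(chrom_table, pd.DataFrame):
        items = list(zip(chrom_table.iloc[:, 0], chrom_table.iloc[:, 1]))
    else:
        items = [(n, l) for n, l in chrom_table]
    if not items:
        raise InvalidInputError("empty chromosome table")
    return BinnedGenome(
        chrom_names=tuple(n for n, _ in items),
        chrom_lengths=tuple(int(l) for _, l in items),
        resolution=int(resolution),
    )


def filter_autosomes(chrom_table, allow=None, species: str = "human"):
    """Restrict a chromosome table to a named allow-list (default species preset)."""
    allow = set(allow if allow is not None else DEFAULT_AUTOSOMES[species])
    if isinstance(chrom_table, dict):
        return {n: l for n, l in chrom_table.items() if n in allow}
    if isinstance(chrom_table, pd.DataFrame):
        return chrom_table[chrom_table.iloc[:, 0].isin(allow)]
    return [(n, l) for n, l in chrom_table if n in allow]


def locate_bin(genome: BinnedGenome, chrom: str, pos: int) -> int:
    """Global bin index containing 0-based position ``pos`` on ``chrom``."""
    ci = genome.chrom_index(chrom)
    length = genome.chrom_lengths[ci]
    if not 0 <= pos < length:
        raise InvalidInputError(f"position {pos} out of range [0, {length}) on {chrom}")
    return int(genome.bin_offset[ci]) + int(pos) // genome.resolution


def tss_position(gene) -> int:
    """0-based position of the first transcribed base.

    For minus-strand genes the stored TSS is the exclusive span end, so the
    transcribed base sits one bp upstream of it.
    """
    tss, tes = int(gene.tss), int(gene.tes)
    return tss - 1 if tss > tes else tss


def tss_bin(genome: BinnedGenome, gene) -> int:
    """Bin containing the gene's first transcribed base."""
    return locate_bin(genome, gene.chrom, tss_position(gene))


def gene_bin_range(genome: BinnedGenome, gene) -> tuple[int, int]:
    """Inclusive global bin range the gene's span occupies (strand-agnostic)."""
    start = min(gene.tss, gene.tes)
    end = max(gene.tss, gene.tes)
    return (
        locate_bin(genome, gene.chrom, start),
        locate_bin(genome, gene.chrom, end - 1),
    )


def gene_pair_distance(a, b, mode: str = "span"):
    """Distance between two genes in bp, or :data:`TRANS` on different chromosomes.

    ``mode='span'`` (default) is the gap between the genomic spans (0 when
    they overlap); ``mode='tss'`` is the absolute TSS-to-TSS distance.
    """
    if a.chrom != b.chrom:
        return TRANS
    if mode == "tss":
        return abs(int(a.tss) - int(b.tss))
    if mode != "span":
        raise InvalidInputError(f"unknown distance mode {mode!r}")
    s1, e1 = min(a.tss, a.tes), max(a.tss, a.tes)
    s2, e2 = min(b.tss, b.tes), max(b.tss, b.tes)
    return max(0, max(s1, s2) - min(e1, e2))


# ---------------------------------------------------------------------------
# readers

_GTF_ATTR = re.compile(r'(\w+)[ =]+"?([^";]+)"?')


def read_gtf(path, genome: BinnedGenome | None = None) -> pd.DataFrame:
    """Extract gene records from a GTF file.

    Only ``gene`` feature lines are used.  Attribute values may be quoted or
    unquoted.  1-based closed coordinates are converted to the internal
    0-based half-open convention; TSS/TES follow strand.  Genes extending
    beyond their chromosome (when ``genome`` is given) are rejected with a
    warning; genes on chromosomes absent from ``genome`` are dropped.
    """
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, strand, attrs = parts[0], parts[3], parts[4], parts[6], parts[8]
            m = dict(_GTF_ATTR.findall(attrs))
            gid = m.get("gene_id")
            if gid is None:
                raise FormatError(f"GTF gene line without gene_id: {line[:80]!r}")
            start0, end0 = int(start) - 1, int(end)
            if genome is not None:
                if chrom not in genome.chrom_names:
                    n_dropped += 1
                    continue
                if end0 > genome.chrom_length(chrom) or start0 < 0:
                    log.warning("gene %s extends beyond %s; rejected", gid, chrom)
                    continue
            if strand == "-":
                tss, tes = end0, start0
            else:
                tss, tes = start0, end0
            rows.append((gid, chrom, tss, tes, strand))
    if n_dropped:
        log.info("read_gtf: dropped %d genes on excluded chromosomes", n_dropped)
    df = pd.DataFrame(rows, columns=list(GENE_COLUMNS))
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id in GTF: {dup!r}")
    return df


def write_gtf(genes: pd.DataFrame, path) -> None:
    """Write a gene table back out as minimal GTF ``gene`` lines."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            start = min(g.tss, g.tes) + 1
            end = max(g.tss, g.tes)
            fh.write(
                f"{g.chrom}\tmetahic\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


def read_chrom_sizes(path) -> pd.DataFrame:
    """Two-column TSV (name, length), UCSC chrom.sizes style."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"], comment="#")
    return df


def genes_from_frame(df: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(g.gene_id, g.chrom, int(g.tss), int(g.tes), g.strand)
        for g in df.itertuples(index=False)
    ]
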