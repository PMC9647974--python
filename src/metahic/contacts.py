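"""Contact-matrix data model, I/O, aggregation, depth accounting, balancing.

A :class:`ContactMatrix` stores binned pair counts upper-triangularly
(``i <= j``) with symmetric semantics.  Matrices from individual runs are
entrywise-summed into project matrices and project matrices into a
species-level meta map — the core of the meta-analytic design.  Balancing
(Knight–Ruiz with a Sinkhorn–Knopp fallback) is applied separately to the
cis (per-chromosome blocks) and trans (inter-chromosomal, genome-wide)
entries to correct coverage bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    FormatError,
    InvalidInputError,
    UnknownIdError,
    UsageError,
)
from .genome import BinnedGenome, gene_bin_range

log = logging.getLogger("metahic")


@dataclass
class DepthRecord:
    """Total contact weight in cis and in trans (the sequencing depth proxy)."""

    cis_depth: float
    trans_depth: float

    @property
    def total(self) -> float:
        return self.cis_depth + self.trans_depth


@dataclass
class ContactMatrix:
    """Sparse symmetric bin-pair contact counts over a :class:`BinnedGenome`.

    ``matrix`` holds the upper triangle (``i <= j``) as CSR; symmetric
    semantics apply everywhere.  ``balanced_mask`` flags, after balancing,
    the bins that actually took part (zero-row bins are left out).
    """

    genome: BinnedGenome
    matrix: sp.csr_matrix
    provenance: list = field(default_factory=list)
    normalized: bool = False
    balanced_mask: np.ndarray | None = None

    @classmethod
    def from_coo(cls, genome, bin_i, bin_j, weight, provenance=(), normalized=False):
        """Build from COO triplets; lower-triangle records are folded into the
        upper triangle and duplicates summed."""
        bin_i = np.asarray(bin_i, dtype=np.int64)
        bin_j = np.asarray(bin_j, dtype=np.int64)
        weight = np.asarray(weight, dtype=np.float64)
        n = genome.n_bins
        if bin_i.size:
            if bin_i.min() < 0 or bin_j.min() < 0 or bin_i.max() >= n or bin_j.max() >= n:
                raise InvalidInputError(f"bin index outside genome (n_bins={n})")
            if (weight < 0).any():
                raise InvalidInputError("negative contact weight")
        lo = np.minimum(bin_i, bin_j)
        hi = np.maximum(bin_i, bin_j)
        m = sp.coo_matrix((weight, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        return cls(genome=genome, matrix=m, provenance=list(provenance), normalized=normalized)

    @classmethod
    def empty(cls, genome, provenance=()):
        n = genome.n_bins
        return cls(genome=genome, matrix=sp.csr_matrix((n, n)), provenance=list(provenance))

    # -- views --------------------------------------------------------------
    def coo(self):
        c = self.matrix.tocoo()
        return c.row, c.col, c.data

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric CSR view (diagonal counted once)."""
        u = self.matrix
        return (u + u.T - sp.diags(u.diagonal())).tocsr()

    def dense_symmetric(self) -> np.ndarray:
        return self.symmetric().toarray()

    @property
    def total_weight(self) -> float:
        return float(self.matrix.sum())

    def cis_trans_flags(self):
        i, j, _ = self.coo()
        return self.genome.is_cis(i, j)


def read_contacts(path, genome: BinnedGenome, fmt: str | None = None) -> ContactMatrix:
    """Read a contact matrix (``coo-tsv`` or ``hicmatrix-h5``; auto by suffix)."""
    path = str(path)
    if fmt is None:
        fmt = "hicmatrix-h5" if path.endswith((".h5", ".hdf5")) else "coo-tsv"
    if fmt == "coo-tsv":
        return _read_coo_tsv(path, genome)
    if fmt == "hicmatrix-h5":
        return _read_h5(path, genome)
    raise UsageError(f"unknown contact format {fmt!r}")


def _read_coo_tsv(path, genome):
    resolution = None
    rows_i, rows_j, w = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#resolution="):
                    resolution = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"bad COO-TSV record: {line!r}")
            rows_i.append(int(parts[0]))
            rows_j.append(int(parts[1]))
            w.append(float(parts[2]))
    if resolution is not None and resolution != genome.resolution:
        raise FormatError(
            f"resolution mismatch: file {resolution} vs genome {genome.resolution}"
        )
    return ContactMatrix.from_coo(genome, rows_i, rows_j, w, provenance=[path])


def _read_h5(path, genome):
    with h5py.File(path, "r") as f:
        data = f["matrix/data"][:]
        indices = f["matrix/indices"][:]
        indptr = f["matrix/indptr"][:]
        shape = tuple(f["matrix/shape"][:])
        chroms = [c.decode() if isinstance(c, bytes) else str(c) for c in f["intervals/chr_list"][:]]
        starts = f["intervals/start_list"][:]
        ends = f["intervals/end_list"][:]
        normalized = bool(f.attrs.get("normalized", False))
        provenance = list(f.attrs.get("provenance", [path]))
    if shape[0] != genome.n_bins:
        raise FormatError(f"bin count mismatch: file {shape[0]} vs genome {genome.n_bins}")
    if len(starts) > 1:
        file_res = int(ends[0] - starts[0])
        if file_res != genome.resolution:
            raise FormatError(
                f"resolution mismatch: file {file_res} vs genome {genome.resolution}"
            )
    for k, b in enumerate(range(0, genome.n_bins, max(1, genome.n_bins // 4))):
        if chroms[b] != genome.bin_span(b)[0]:
            raise FormatError(f"chromosome layout mismatch at bin {b}")
    m = sp.csr_matrix((data, indices, indptr), shape=shape)
    coo = sp.triu(m).tocoo()
    cm = ContactMatrix.from_coo(
        genome, coo.row, coo.col, coo.data, provenance=provenance, normalized=normalized
    )
    return cm


def write_contacts(cm: ContactMatrix, path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "hicmatrix-h5" if path.endswith((".h5", ".hdf5")) else "coo-tsv"
    if fmt == "coo-tsv":
        i, j, w = cm.coo()
        with open(path, "w") as fh:
            fh.write(f"#resolution={cm.genome.resolution}\n")
            for a, b, x in zip(i, j, w):
                fh.write(f"{a}\t{b}\t{x:.10g}\n")
        return
    if fmt != "hicmatrix-h5":
        raise UsageError(f"unknown contact format {fmt!r}")
    g = cm.genome
    chrom_list = np.array([g.bin_span(b)[0] for b in range(g.n_bins)], dtype="S32")
    starts = np.array([g.bin_span(b)[1] for b in range(g.n_bins)], dtype=np.int64)
    ends = np.array([g.bin_span(b)[2] for b in range(g.n_bins)], dtype=np.int64)
    m = cm.matrix.tocsr()
    with h5py.File(path, "w") as f:
        mg = f.create_group("matrix")
        mg.create_dataset("data", data=m.data)
        mg.create_dataset("indices", data=m.indices)
        mg.create_dataset("indptr", data=m.indptr)
        mg.create_dataset("shape", data=np.array(m.shape, dtype=np.int64))
        ig = f.create_group("intervals")
        ig.create_dataset("chr_list", data=chrom_list)
        ig.create_dataset("start_list", data=starts)
        ig.create_dataset("end_list", data=ends)
        f.attrs["normalized"] = cm.normalized
        f.attrs["provenance"] = [str(p) for p in cm.provenance]
        f.attrs["resolution"] = g.resolution


# ---------------------------------------------------------------------------
# aggregation & partition

def aggregate(matrices) -> ContactMatrix:
    """Entrywise sum of contact matrices sharing a genome (run→project→meta)."""
    matrices = list(matrices)
    if not matrices:
        raise UsageError("aggregate() needs at least one matrix")
    first = matrices[0]
    flags = {m.normalized for m in matrices}
    if len(flags) > 1:
        raise UsageError("refusing to aggregate a mix of normalized and raw matrices")
    total = first.matrix.copy()
    provenance = list(first.provenance)
    for m in matrices[1:]:
        if m.genome != first.genome:
            raise UsageError("aggregate(): genome mismatch between matrices")
        total = total + m.matrix
        provenance.extend(m.provenance)
    return ContactMatrix(
        genome=first.genome, matrix=total.tocsr(), provenance=provenance,
        normalized=first.normalized,
    )


def split_cis_trans(cm: ContactMatrix):
    """Partition entries into a cis (same-chromosome) and a trans matrix."""
    i, j, w = cm.coo()
    cis = cm.genome.is_cis(i, j) if len(i) else np.array([], dtype=bool)
    make = lambda keep: ContactMatrix.from_coo(
        cm.genome, i[keep], j[keep], w[keep],
        provenance=list(cm.provenance), normalized=cm.normalized,
    )
    return make(cis), make(~cis)


def depth(cm: ContactMatrix) -> DepthRecord:
    """Cis and trans total contact weight (Fig 1D-style depth accounting)."""
    i, j, w = cm.coo()
    if len(i) == 0:
        return DepthRecord(0.0, 0.0)
    cis = cm.genome.is_cis(i, j)
    return DepthRecord(float(w[cis].sum()), float(w[~cis].sum()))


# ---------------------------------------------------------------------------
# balancing

def _sinkhorn_scaling(A, tol, max_iter):
    """Symmetric Sinkhorn–Knopp: find x>0 with x_i (A x)_i = 1 for all i."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        r = A @ x
        if (r <= 0).any():
            return None, np.inf
        dev = np.abs(x * r - 1.0).max()
        if dev <= tol:
            return x, dev
        x = np.sqrt(x / r)
    r = A @ x
    return None, float(np.abs(x * r - 1.0).max())


def _kr_scaling(A, tol, max_outer=100):
    """Knight–Ruiz inner-outer Newton/CG balancing of a symmetric nonnegative
    matrix with positive row sums.  Returns (x, max-deviation) or (None, dev)."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    rt = stop_tol ** 2
    for _ in range(max_outer):
        if not np.isfinite(rout):
            return None, np.inf
        if np.abs(x * (A @ x) - 1.0).max() <= tol:
            return x, float(np.abs(x * (A @ x) - 1.0).max())
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0 or not np.isfinite(denom):
                return None, np.inf
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                if not neg.any():
                    break
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 2 * n + 20:
                break
        x = x * y
        if x.min() <= 0 or not np.isfinite(x).all():
            return None, np.inf
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    dev = float(np.abs(x * (A @ x) - 1.0).max())
    return (x, dev) if dev <= tol else (None, dev)


def _balance_block(A, tol, max_iter):
    """Balance a symmetric block with positive row sums; KR first, Sinkhorn fallback.

    The block is preconditioned by its mean row sum, which makes the whole
    iteration exactly invariant to an overall scaling of the input.
    """
    rs = np.asarray(A.sum(axis=1)).ravel()
    scale = rs.mean()
    A = A / scale
    x, dev = _kr_scaling(A, tol, max_outer=min(max_iter, 100))
    if x is None:
        x, dev = _sinkhorn_scaling(A, tol, max_iter)
    if x is None:
        raise ConvergenceError(
            f"balancing did not converge (final max row-sum deviation {dev:.3g})",
            residual=dev,
        )
    return x / np.sqrt(scale)


def kr_balance(cm: ContactMatrix, mode: str, tolerance: float = 1e-6,
               max_iter: int = 1000) -> ContactMatrix:
    """KR-normalize the matrix restricted to one mode.

    ``mode='cis'`` balances each chromosome block separately; ``mode='trans'``
    balances the genome-wide matrix with cis entries masked out of the row
    sums.  In-mode entries are rescaled so in-mode row sums equal 1 (within
    ``tolerance``) over unmasked bins; out-of-mode entries pass through
    unchanged.  Bins with zero in-mode row sum are masked out and flagged in
    ``balanced_mask``.
    """
    if cm.normalized:
        raise UsageError("matrix already normalized")
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be positive")
    if mode not in ("cis", "trans"):
        raise UsageError(f"mode must be 'cis' or 'trans', got {mode!r}")
    g = cm.genome
    n = g.n_bins
    i, j, w = cm.coo()
    if len(i) == 0:
        raise DegenerateInputError("cannot balance an empty matrix")
    cis = g.is_cis(i, j)
    in_mode = cis if mode == "cis" else ~cis
    if not in_mode.any():
        raise DegenerateInputError(f"no {mode} entries to balance")

    scale = np.ones(n)
    mask = np.zeros(n, dtype=bool)
    sym = sp.coo_matrix(
        (np.concatenate([w[in_mode], w[in_mode]]),
         (np.concatenate([i[in_mode], j[in_mode]]),
          np.concatenate([j[in_mode], i[in_mode]]))),
        shape=(n, n),
    ).tocsr()
    diag = sym.diagonal() / 2.0  # each diagonal entry was added twice
    sym = sym - sp.diags(diag)

    if mode == "cis":
        blocks = [g.chrom_bins(c) for c in g.chrom_names]
    else:
        blocks = [(0, n)]
    for b0, b1 in blocks:
        sub = sym[b0:b1, b0:b1]
        rs = np.asarray(sub.sum(axis=1)).ravel()
        unmasked = rs > 0
        if not unmasked.any():
            continue
        core = sub[unmasked][:, unmasked].tocsr()
        x = _balance_block(core, tolerance, max_iter)
        idx = np.arange(b0, b1)[unmasked]
        scale[idx] = x
        mask[idx] = True

    if not mask.any():
        raise DegenerateInputError("all rows are zero in the requested mode")
    new_w = w.copy()
    new_w[in_mode] = w[in_mode] * scale[i[in_mode]] * scale[j[in_mode]]
    out = ContactMatrix.from_coo(
        g, i, j, new_w, provenance=list(cm.provenance), normalized=True
    )
    out.balanced_mask = mask
    return out


# ---------------------------------------------------------------------------
# per-gene contact vectors

def gene_vector(cm: ContactMatrix, gene_id: str, genes: pd.DataFrame) -> pd.DataFrame:
    """BED-style records of the gene's contact weight with every bin.

    One record per bin with nonzero contact; the score is the maximum weight
    over the bins the gene occupies.
    """
    row = genes.loc[genes["gene_id"] == gene_id]
    if row.empty:
        raise UnknownIdError(f"unknown gene {gene_id!r}")
    gene = next(row.itertuples(index=False))
    b0, b1 = gene_bin_range(cm.genome, gene)
    sym = cm.symmetric()
    block = np.asarray(sym[b0:b1 + 1, :].todense())
    scores = block.max(axis=0)
    hits = np.nonzero(scores > 0)[0]
    recs = []
    for b in hits:
        chrom, start, end = cm.genome.bin_span(int(b))
        recs.append((chrom, start, end, gene_id, scores[b]))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name", "score"])


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
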