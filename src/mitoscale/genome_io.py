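"""Genomic binning, contact-matrix containers, and Hi-C text/HDF5 I/O.

Contact data enters either as 4DN-style ``.pairs`` text, a dense whitespace
matrix with a one-line header, or a single-resolution cooler-dialect HDF5
container.  Cis contacts are aggregated into :class:`ContactMatrix`; trans
contacts are retained in a side table but play no role in distance-decay
analysis, which is cis-only.

Coordinate conventions: bins are 0-based half-open intervals
``[start, start + bin_width)`` tiling each chromosome (the last bin may be
short); pairs-file positions are 1-based base pairs, so position ``pos``
falls in bin ``(pos - 1) // bin_width``.  Strand columns in pairs files are
accepted and discarded -- distance decay is strand-agnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomicBinning",
    "PairList",
    "ContactMatrix",
    "read_contacts",
    "write_contacts",
    "write_ps_table",
    "read_ps_table",
]

_HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"


@dataclass(frozen=True)
class GenomicBinning:
    """Fixed-width tiling of a set of chromosomes.

    Parameters
    ----------
    chromsizes : tuple of (name, length)
        Ordered chromosome names and lengths in bp (positive integers).
    bin_width : int
        Bin width in bp (positive).
    """

    chromsizes: tuple[tuple[str, int], ...]
    bin_width: int

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if not self.chromsizes:
            raise ValueError("at least one chromosome is required")
        seen = set()
        for name, length in self.chromsizes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seen.add(name)

    @classmethod
    def from_dict(cls, chromsizes: dict, bin_width: int) -> "GenomicBinning":
        return cls(tuple((str(k), int(v)) for k, v in chromsizes.items()), int(bin_width))

    @property
    def sizes(self) -> dict:
        return dict(self.chromsizes)

    @property
    def chrom_names(self) -> list:
        return [c for c, _ in self.chromsizes]

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.sizes[chrom] / self.bin_width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin index of a 1-based position."""
        length = self.sizes[chrom]
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside chromosome {chrom!r} (length {length})")
        return (pos - 1) // self.bin_width

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_width
        ends[-1] = min(ends[-1], self.sizes[chrom])
        return ends


@dataclass
class PairList:
    """Valid contact pairs at bp resolution.

    ``df`` holds columns chrom1, pos1, chrom2, pos2 with 1-based positions.
    ``chromsizes`` (if known) enables position validation and pair-level
    distance-decay normalization.
    """

    df: pd.DataFrame
    chromsizes: dict | None = None

    def __post_init__(self):
        required = {"chrom1", "pos1", "chrom2", "pos2"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"PairList missing columns: {sorted(missing)}")
        if self.chromsizes is not None:
            for side in ("1", "2"):
                chroms = self.df[f"chrom{side}"]
                unknown = set(chroms.unique()) - set(self.chromsizes)
                if unknown:
                    raise ValueError(f"unknown chromosome {sorted(unknown)[0]!r} in pairs")
                lengths = chroms.map(self.chromsizes).to_numpy()
                pos = self.df[f"pos{side}"].to_numpy()
                bad = (pos < 1) | (pos > lengths)
                if bad.any():
                    k = int(np.flatnonzero(bad)[0])
                    raise ValueError(
                        f"position {pos[k]} outside chromosome "
                        f"{chroms.iloc[k]!r} (length {lengths[k]})"
                    )

    def __len__(self):
        return len(self.df)

    @property
    def is_cis(self) -> np.ndarray:
        return (self.df["chrom1"] == self.df["chrom2"]).to_numpy()

    @property
    def cis(self) -> pd.DataFrame:
        return self.df[self.is_cis]

    @property
    def trans(self) -> pd.DataFrame:
        return self.df[~self.is_cis]

    def separations(self) -> np.ndarray:
        """|pos2 - pos1| of cis pairs, in bp."""
        cis = self.cis
        return np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy())


class ContactMatrix:
    """Per-chromosome symmetric binned contact counts (upper triangle stored).

    Parameters
    ----------
    binning : GenomicBinning
    counts : dict mapping chromosome name -> scipy sparse upper-triangular matrix
    weights : dict mapping chromosome name -> per-bin balancing weights
        (NaN marks bins flagged invalid), or None for an unbalanced matrix.
    n_masked_diagonals : int
        Number of leading diagonals (|i - j| < n) excluded from balancing
        marginals and from all balanced queries.
    converged : bool or None
        Balancing convergence flag (None when unbalanced).
    trans_pairs : DataFrame or None
        Trans contacts retained at input time; unused by cis-only analyses.
    """

    def __init__(self, binning, counts, weights=None, n_masked_diagonals=0,
                 converged=None, trans_pairs=None):
        self.binning = binning
        self.counts = {}
        for chrom in binning.chrom_names:
            n = binning.n_bins(chrom)
            mat = counts.get(chrom)
            if mat is None:
                mat = sp.csr_matrix((n, n))
            mat = sp.csr_matrix(mat)
            if mat.shape != (n, n):
                raise ValueError(f"matrix shape {mat.shape} != ({n}, {n}) for {chrom!r}")
            coo = mat.tocoo()
            if (coo.col < coo.row).any():
                raise ValueError(f"counts for {chrom!r} must be upper-triangular")
            if len(coo.data) and (not np.isfinite(coo.data).all() or (coo.data < 0).any()):
                raise ValueError(f"counts for {chrom!r} must be finite and non-negative")
            self.counts[chrom] = mat
        unknown = set(counts) - set(binning.chrom_names)
        if unknown:
            raise ValueError(f"counts given for unknown chromosome {sorted(unknown)[0]!r}")
        self.weights = weights
        if weights is not None:
            for chrom in binning.chrom_names:
                w = np.asarray(weights[chrom], dtype=float)
                if w.shape != (binning.n_bins(chrom),):
                    raise ValueError(f"weights shape mismatch for {chrom!r}")
                if np.any(w[np.isfinite(w)] <= 0):
                    raise ValueError("finite weights must be positive")
        self.n_masked_diagonals = int(n_masked_diagonals)
        if self.n_masked_diagonals < 0:
            raise ValueError("n_masked_diagonals must be >= 0")
        self.converged = converged
        self.trans_pairs = trans_pairs

    @property
    def balanced(self) -> bool:
        return self.weights is not None

    @classmethod
    def from_pairs(cls, pairs: PairList, binning: GenomicBinning) -> "ContactMatrix":
        """Aggregate cis pairs into binned counts; retain trans pairs aside."""
        unknown = (set(pairs.df["chrom1"]) | set(pairs.df["chrom2"])) - set(binning.chrom_names)
        if unknown:
            raise ValueError(f"unknown chromosome {sorted(unknown)[0]!r} in pairs")
        counts = {}
        cis = pairs.cis
        bw = binning.bin_width
        for chrom, grp in cis.groupby("chrom1", sort=False):
            n = binning.n_bins(chrom)
            length = binning.sizes[chrom]
            p1 = grp["pos1"].to_numpy(dtype=np.int64)
            p2 = grp["pos2"].to_numpy(dtype=np.int64)
            for p in (p1, p2):
                bad = (p < 1) | (p > length)
                if bad.any():
                    raise ValueError(
                        f"position {p[bad][0]} outside chromosome {chrom!r} (length {length})"
                    )
            b1 = (p1 - 1) // bw
            b2 = (p2 - 1) // bw
            i = np.minimum(b1, b2)
            j = np.maximum(b1, b2)
            counts[chrom] = sp.coo_matrix(
                (np.ones(len(i)), (i, j)), shape=(n, n)
            ).tocsr()
        return cls(binning, counts, trans_pairs=pairs.trans.copy() if len(pairs.trans) else None)

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Symmetric dense matrix for one chromosome.

        With ``balanced=True``, entries are count * w_i * w_j, bins with
        invalid weights are NaN, and masked diagonals are NaN.
        """
        upper = self.counts[chrom].toarray()
        full = upper + np.triu(upper, 1).T
        if balanced:
            if not self.balanced:
                raise ValueError("matrix is not balanced")
            w = self.weights[chrom]
            full = full * np.outer(w, w)
            n = full.shape[0]
            i, j = np.indices((n, n))
            full[np.abs(i - j) < self.n_masked_diagonals] = np.nan
        return full

    def total_contacts(self) -> float:
        return float(sum(m.sum() for m in self.counts.values()))

    def equals(self, other: "ContactMatrix", rtol=1e-9) -> bool:
        if self.binning != other.binning:
            return False
        for chrom in self.binning.chrom_names:
            a = self.counts[chrom].toarray()
            b = other.counts[chrom].toarray()
            if not np.allclose(a, b, rtol=rtol):
                return False
        return True


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_contacts(path, bin_width=None, fmt=None, chromsizes=None) -> ContactMatrix:
    """Read contacts from a cooler-HDF5, pairs-text, or dense-text file.

    Parameters
    ----------
    path : str or Path
    bin_width : int, optional
        Required for pairs-text input.  For cooler input, if given it must
        match the container's bin size.
    fmt : {"cooler-hdf5", "pairs-text", "dense-text"}, optional
        Sniffed from the file when omitted.
    chromsizes : dict, optional
        Chromosome lengths for pairs files lacking ``#chromsize:`` headers.
    """
    path = str(path)
    if fmt is None:
        fmt = _sniff_format(path)
    if fmt == "cooler-hdf5":
        return _read_cooler(path, bin_width)
    if fmt == "pairs-text":
        if bin_width is None:
            raise ValueError("bin_width is required for pairs-text input")
        pairs = read_pairs(path, chromsizes=chromsizes)
        if pairs.chromsizes is None:
            raise ValueError(
                "chromosome sizes unavailable: provide chromsizes= or a pairs "
                "header with '#chromsize:' lines"
            )
        binning = GenomicBinning.from_dict(pairs.chromsizes, bin_width)
        return ContactMatrix.from_pairs(pairs, binning)
    if fmt == "dense-text":
        return _read_dense(path)
    raise ValueError(f"unknown format {fmt!r}")


def _sniff_format(path: str) -> str:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head == _HDF5_MAGIC:
        return "cooler-hdf5"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# mitoscale-dense"):
        return "dense-text"
    return "pairs-text"


def read_pairs(path, chromsizes=None) -> PairList:
    """Parse a 4DN-style pairs text file (header lines start with '#').

    ``#chromsize: name length`` header lines populate chromosome sizes; an
    optional ``#columns:`` line names the data columns.  Without a columns
    line the default layout ``readID chrom1 pos1 chrom2 pos2 [strand1
    strand2 ...]`` is assumed (strands parsed and discarded).
    """
    sizes = dict(chromsizes) if chromsizes else {}
    header_sizes = {}
    columns = None
    rec_c1, rec_p1, rec_c2, rec_p2 = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("chromsize:"):
                    parts = body.split(":", 1)[1].split()
                    if len(parts) != 2:
                        raise ValueError(f"line {lineno}: malformed chromsize header")
                    header_sizes[parts[0]] = int(parts[1])
                elif body.lower().startswith("columns:"):
                    columns = body.split(":", 1)[1].split()
                continue
            fields = line.split()
            try:
                if columns is not None:
                    idx = {name: k for k, name in enumerate(columns)}
                    c1 = fields[idx["chrom1"]]
                    p1 = int(fields[idx["pos1"]])
                    c2 = fields[idx["chrom2"]]
                    p2 = int(fields[idx["pos2"]])
                elif len(fields) >= 5:
                    c1, p1, c2, p2 = fields[1], int(fields[2]), fields[3], int(fields[4])
                elif len(fields) == 4:
                    c1, p1, c2, p2 = fields[0], int(fields[1]), fields[2], int(fields[3])
                else:
                    raise IndexError
            except (ValueError, IndexError, KeyError):
                raise ValueError(f"line {lineno}: malformed pairs record: {line!r}") from None
            rec_c1.append(c1)
            rec_p1.append(p1)
            rec_c2.append(c2)
            rec_p2.append(p2)
    sizes.update(header_sizes)
    df = pd.DataFrame({"chrom1": rec_c1, "pos1": rec_p1, "chrom2": rec_c2, "pos2": rec_p2})
    return PairList(df, chromsizes=sizes or None)


def _read_cooler(path, bin_width=None) -> ContactMatrix:
    with h5py.File(path, "r") as h5:
        if "resolutions" in h5 and "pixels" not in h5:
            wanted = bin_width if bin_width is not None else "<bin_width>"
            raise ValueError(
                "multi-resolution cooler containers are not supported; extract "
                f"the single resolution group 'resolutions/{wanted}' first"
            )
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in h5["chroms/name"][:]]
        lengths = h5["chroms/length"][:].astype(int)
        bw = int(h5.attrs.get("bin-size", 0))
        if bw <= 0:
            starts = h5["bins/start"][:]
            bw = int(starts[1] - starts[0]) if len(starts) > 1 else int(h5["bins/end"][0])
        if bin_width is not None and int(bin_width) != bw:
            raise ValueError(f"requested bin_width {bin_width} != container bin size {bw}")
        binning = GenomicBinning.from_dict(dict(zip(names, lengths)), bw)
        bin_chrom = h5["bins/chrom"][:].astype(int)
        has_weight = "weight" in h5["bins"]
        bin_weight = h5["bins/weight"][:] if has_weight else None
        b1 = h5["pixels/bin1_id"][:].astype(np.int64)
        b2 = h5["pixels/bin2_id"][:].astype(np.int64)
        cnt = h5["pixels/count"][:].astype(float)
        nmask = int(h5.attrs.get("mitoscale-masked-diagonals", 0))

    offsets = np.zeros(len(names) + 1, dtype=np.int64)
    for k, name in enumerate(names):
        offsets[k + 1] = offsets[k] + binning.n_bins(name)
    counts, weights = {}, {}
    c1 = bin_chrom[b1]
    c2 = bin_chrom[b2]
    cis = c1 == c2
    for k, name in enumerate(names):
        sel = cis & (c1 == k)
        n = binning.n_bins(name)
        i = b1[sel] - offsets[k]
        j = b2[sel] - offsets[k]
        counts[name] = sp.coo_matrix((cnt[sel], (i, j)), shape=(n, n)).tocsr()
        if has_weight:
            weights[name] = np.asarray(bin_weight[offsets[k]:offsets[k + 1]], dtype=float)
    trans = None
    if (~cis).any():
        trans = pd.DataFrame({
            "chrom1": [names[c] for c in c1[~cis]],
            "bin1": b1[~cis],
            "chrom2": [names[c] for c in c2[~cis]],
            "bin2": b2[~cis],
            "count": cnt[~cis],
        })
    return ContactMatrix(binning, counts, weights=weights if has_weight else None,
                         n_masked_diagonals=nmask, trans_pairs=trans)


def _read_dense(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
    meta = {}
    for tok in header.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    try:
        bw = int(meta["bin_width"])
        chrom = meta["chrom"]
        length = int(meta["length"])
    except KeyError as exc:
        raise ValueError(f"dense-text header missing field {exc}") from None
    mat = np.loadtxt(path, skiprows=1, ndmin=2)
    binning = GenomicBinning.from_dict({chrom: length}, bw)
    n = binning.n_bins(chrom)
    if mat.shape != (n, n):
        raise ValueError(f"dense matrix shape {mat.shape} != expected ({n}, {n})")
    if not np.allclose(mat, mat.T):
        raise ValueError("dense matrix must be symmetric")
    return ContactMatrix(binning, {chrom: sp.csr_matrix(np.triu(mat))})


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_contacts(m: ContactMatrix, path, fmt=None) -> None:
    """Write a ContactMatrix as cooler-dialect HDF5 or dense text."""
    path = str(path)
    if fmt is None:
        fmt = "dense-text" if path.endswith((".txt", ".tsv", ".dense")) else "cooler-hdf5"
    if fmt == "cooler-hdf5":
        _write_cooler(m, path)
    elif fmt == "dense-text":
        _write_dense(m, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_dense(m: ContactMatrix, path) -> None:
    if len(m.binning.chrom_names) != 1:
        raise ValueError("dense-text output supports a single chromosome only")
    chrom = m.binning.chrom_names[0]
    full = m.dense(chrom)
    with open(path, "w") as fh:
        fh.write(
            f"# mitoscale-dense bin_width={m.binning.bin_width} "
            f"chrom={chrom} length={m.binning.sizes[chrom]}\n"
        )
        np.savetxt(fh, full, fmt="%.12g")


def _write_cooler(m: ContactMatrix, path) -> None:
    binning = m.binning
    names = binning.chrom_names
    offsets = np.zeros(len(names) + 1, dtype=np.int64)
    for k, name in enumerate(names):
        offsets[k + 1] = offsets[k] + binning.n_bins(name)
    bin_chrom, bin_start, bin_end, bin_weight = [], [], [], []
    for k, name in enumerate(names):
        bin_chrom.append(np.full(binning.n_bins(name), k, dtype=np.int32))
        bin_start.append(binning.bin_starts(name))
        bin_end.append(binning.bin_ends(name))
        if m.balanced:
            bin_weight.append(m.weights[name])
    b1, b2, cnt = [], [], []
    for k, name in enumerate(names):
        coo = m.counts[name].tocoo()
        b1.append(coo.row + offsets[k])
        b2.append(coo.col + offsets[k])
        cnt.append(coo.data)
    b1 = np.concatenate(b1) if b1 else np.array([], dtype=np.int64)
    b2 = np.concatenate(b2) if b2 else np.array([], dtype=np.int64)
    cnt = np.concatenate(cnt) if cnt else np.array([], dtype=float)
    order = np.lexsort((b2, b1))
    b1, b2, cnt = b1[order], b2[order], cnt[order]

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-size"] = binning.bin_width
        h5.attrs["nbins"] = int(offsets[-1])
        h5.attrs["nchroms"] = len(names)
        h5.attrs["nnz"] = len(cnt)
        h5.attrs["mitoscale-masked-diagonals"] = m.n_masked_diagonals
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S64"))
        g.create_dataset("length", data=np.array([binning.sizes[c] for c in names], dtype=np.int64))
        g = h5.create_group("bins")
        g.create_dataset("chrom", data=np.concatenate(bin_chrom))
        g.create_dataset("start", data=np.concatenate(bin_start))
        g.create_dataset("end", data=np.concatenate(bin_end))
        if m.balanced:
            g.create_dataset("weight", data=np.concatenate(bin_weight))
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=b1)
        g.create_dataset("bin2_id", data=b2)
        g.create_dataset("count", data=cnt)
        g = h5.create_group("indexes")
        g.create_dataset("chrom_offset", data=offsets)
        g.create_dataset("bin1_offset",
                         data=np.searchsorted(b1, np.arange(offsets[-1] + 1)))


# ---------------------------------------------------------------------------
# Curve tables
# ---------------------------------------------------------------------------

def write_ps_table(curve, path) -> None:
    """Write a P(s) or derivative curve as TSV (12 significant digits).

    P(s) curves produce columns (s_lo, s_hi, s_mid, value, n_obs); derivative
    curves produce (s_mid, slope, smoothed_slope).
    """
    if hasattr(curve, "slope"):  # DerivCurve
        df = pd.DataFrame({
            "s_mid": curve.s,
            "slope": curve.slope,
            "smoothed_slope": curve.smoothed,
        })
    else:  # PsCurve
        df = pd.DataFrame({
            "s_lo": curve.s_lo,
            "s_hi": curve.s_hi,
            "s_mid": curve.s_eff,
            "value": curve.p,
            "n_obs": curve.obs,
        })
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ps_table(path):
    """Read a curve written by :func:`write_ps_table`.

    Returns a :class:`~mitoscale.ps_decay.PsCurve` (reconstructed on a
    matching log-bin scheme) or a :class:`~mitoscale.ps_decay.DerivCurve`.
    """
    from . import ps_decay  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    if "slope" in df.columns:
        return ps_decay.DerivCurve(
            s=df["s_mid"].to_numpy(),
            slope=df["slope"].to_numpy(),
            smoothed=df["smoothed_slope"].to_numpy(),
            span=np.nan,
        )
    return ps_decay.PsCurve.from_table(
        s_lo=df["s_lo"].to_numpy(),
        s_hi=df["s_hi"].to_numpy(),
        s_eff=df["s_mid"].to_numpy(),
        p=df["value"].to_numpy(),
        obs=df["n_obs"].to_numpy(),
    )
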