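"""Contact-matrix data model, I/O, ICE balancing and the noise filter.

A :class:`ContactMatrix` holds one symmetric intra-chromosomal contact
matrix per chromosome on a shared :class:`~hictopo.genome.GenomeBins`
frame, a per-chromosome mask of excluded bins, and a single scalar
summarizing the interchromosomal (trans) contact level.  Only the trans
mean is kept because the sole downstream use of trans contacts is the
low-abundance cutoff rule: entries below ten times the average
interchromosomal contact frequency are treated as nonspecific ligation
noise and removed before contact/loop quantification.

Normalization is iterative correction (ICE): bin biases are iterated
until all non-masked marginals are equal, which removes multiplicative
per-bin visibility biases (GC, mappability, fragment length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBins

__all__ = [
    "ContactMatrix",
    "DistanceDecay",
    "read_contacts",
    "write_contacts",
    "ice_normalize",
    "expected_by_distance",
    "observed_over_expected",
    "filter_low_contacts",
]

_STATES = ("raw", "balanced", "filtered")


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric contact matrices plus a trans-contact scalar."""

    bins: GenomeBins
    mats: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)  # True = excluded
    trans_mean: float | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        for chrom, m in self.mats.items():
            n = self.bins.n_bins(chrom)
            if m.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {m.shape} != ({n},{n})")
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(n, dtype=bool)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.mats)

    def matrix(self, chrom: str) -> np.ndarray:
        return self.mats[chrom]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins,
            {c: m.copy() for c, m in self.mats.items()},
            {c: k.copy() for c, k in self.mask.items()},
            self.trans_mean,
            self.state,
        )

    def check(self, atol: float = 1e-8) -> None:
        """Validate symmetry, non-negativity and mask consistency."""
        for chrom, m in self.mats.items():
            if not np.allclose(m, m.T, atol=atol):
                raise ValueError(f"{chrom}: matrix not symmetric")
            if np.any(m < 0):
                raise ValueError(f"{chrom}: negative entries")
            k = self.mask[chrom]
            if np.any(m[k]) or np.any(m[:, k]):
                raise ValueError(f"{chrom}: masked bins carry contacts")


@dataclass
class DistanceDecay:
    """Expected contact frequency per bin-separation distance, per chromosome."""

    values: dict[str, np.ndarray]

    def expected(self, chrom: str, d: int | np.ndarray) -> np.ndarray:
        return self.values[chrom][d]


# ---------------------------------------------------------------------------
# I/O: bin-pair triplet text + bins BED
# ---------------------------------------------------------------------------

def write_contacts(m: ContactMatrix, triplet_file, bins_file) -> None:
    """Write upper-triangle nonzero entries as (bin_id, bin_id, value) rows
    plus a bins BED (chrom, start, end, global bin id)."""
    bins = m.bins
    with open(bins_file, "w") as fh:
        for chrom in bins.chromosomes:
            off = bins.offset(chrom)
            for i in range(bins.n_bins(chrom)):
                s, e = bins.bin_interval(chrom, i)
                fh.write(f"{chrom}\t{s}\t{e}\t{off + i}\n")
    with open(triplet_file, "w") as fh:
        for chrom in m.chromosomes:
            off = bins.offset(chrom)
            mat = m.mats[chrom]
            iu, ju = np.triu_indices_from(mat)
            vals = mat[iu, ju]
            nz = vals != 0
            for i, j, v in zip(iu[nz] + off, ju[nz] + off, vals[nz]):
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_contacts(triplet_file, bins_file) -> ContactMatrix:
    """Read a bin-pair triplet file against a bins BED.

    Unseen pairs are zero; each (i, j, v) row sets M[i,j] = M[j,i] = v.
    Rows referencing bin ids outside the bins table, negative values, or
    interchromosomal pairs are rejected with the offending line.
    """
    chrom_of: list[tuple[str, int]] = []
    lengths: dict[str, int] = {}
    widths: set[int] = set()
    with open(bins_file) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, gid = line.split("\t")
            s, e, gid = int(s), int(e), int(gid)
            if gid != len(chrom_of):
                raise ValueError(f"bins file not sorted by bin id at line: {line!r}")
            chrom_of.append((chrom, s))
            lengths[chrom] = max(lengths.get(chrom, 0), e)
            widths.add(e - s)
    if not chrom_of:
        raise ValueError("empty bins file")
    bin_width = max(widths)  # last bin of a chromosome may be short
    bins = GenomeBins(lengths, bin_width)
    if bins.total_bins != len(chrom_of):
        raise ValueError("bins file does not tile its chromosomes")

    mats = {c: np.zeros((bins.n_bins(c), bins.n_bins(c))) for c in bins.chromosomes}
    n_total = bins.total_bins
    with open(triplet_file) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, v = line.split("\t")
            a, b, v = int(a), int(b), float(v)
            if not (0 <= a < n_total and 0 <= b < n_total):
                raise ValueError(f"bin id outside bins table in line: {line!r}")
            if v < 0:
                raise ValueError(f"negative contact value in line: {line!r}")
            ca, ia = bins.chrom_of_global(a)
            cb, ib = bins.chrom_of_global(b)
            if ca != cb:
                raise ValueError(f"interchromosomal pair in line: {line!r}")
            mats[ca][ia, ib] = v
            mats[ca][ib, ia] = v
    return ContactMatrix(bins, mats)


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def _marginal_cv(s: np.ndarray) -> float:
    mu = s.mean()
    return float(s.std() / mu) if mu > 0 else 0.0


def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-4,
    low_coverage_fraction: float = 0.02,
    low_coverage_floor: float = 0.10,
) -> ContactMatrix:
    """Iterative-correction balancing, per chromosome.

    Masked before balancing: bins with zero marginal, the lowest
    ``low_coverage_fraction`` of positive marginals, and bins whose marginal
    falls below ``low_coverage_floor`` times the chromosome's median positive
    marginal.  The relative floor exists because iterative correction would
    otherwise re-inflate severely contact-depleted bins (balancing forces
    equal marginals); loci whose DNA barely touches the chromosome — the
    ecDNA situation — must stay masked rather than be normalized into
    apparent typicality.  Rows/columns are then rescaled until the
    coefficient of variation of the non-masked marginals drops below ``tol``
    (or ``max_iter`` is reached).  The total non-masked matrix sum is
    preserved, so balanced entries stay on the raw count scale.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    out_mats: dict[str, np.ndarray] = {}
    out_mask: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        marg = mat.sum(axis=1)
        mask = marg <= 0
        pos = marg[~mask]
        if pos.size and low_coverage_fraction > 0:
            cut = np.quantile(pos, low_coverage_fraction)
            mask |= marg < cut
        if pos.size and low_coverage_floor > 0:
            mask |= marg < low_coverage_floor * np.median(pos)
        if mask.all():
            raise ValueError(f"{chrom}: no usable bins")
        idx = ~mask
        sub = mat[np.ix_(idx, idx)]
        target = sub.sum()
        # accumulate the bias vector via matrix-vector products; the matrix
        # itself is only rescaled once at the end
        b = np.ones(sub.shape[0])
        for _ in range(max_iter):
            s = (sub @ (1.0 / b)) / b
            if _marginal_cv(s) < tol:
                break
            u = s / s.mean()
            u[u == 0] = 1.0
            b *= u
        sub = sub / np.outer(b, b)
        if sub.sum() > 0:
            sub *= target / sub.sum()
        w = np.zeros_like(mat)
        w[np.ix_(idx, idx)] = sub
        out_mats[chrom] = w
        out_mask[chrom] = mask
    return ContactMatrix(m.bins, out_mats, out_mask, m.trans_mean, "balanced")


# ---------------------------------------------------------------------------
# Distance decay and observed/expected
# ---------------------------------------------------------------------------

def expected_by_distance(m: ContactMatrix) -> DistanceDecay:
    """Mean contact at each bin separation over non-masked pairs (0 if none)."""
    values: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        n = mat.shape[0]
        keep = ~m.mask[chrom]
        dec = np.zeros(n)
        for d in range(n):
            i = np.arange(n - d)
            ok = keep[i] & keep[i + d]
            if ok.any():
                dec[d] = mat[i[ok], i[ok] + d].mean()
        values[chrom] = dec
    return DistanceDecay(values)


def observed_over_expected(m: ContactMatrix, decay: DistanceDecay) -> ContactMatrix:
    """Entrywise M[i,j] / decay[|i-j|]; 0/0 -> 0; masked bins stay masked."""
    out: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        n = mat.shape[0]
        dec = decay.values[chrom]
        if dec.shape[0] != n:
            raise ValueError(f"{chrom}: decay length {dec.shape[0]} != {n}")
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        e = dec[d]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(e > 0, mat / np.where(e > 0, e, 1.0), 0.0)
        out[chrom] = oe
    return ContactMatrix(m.bins, out, {c: k.copy() for c, k in m.mask.items()},
                         m.trans_mean, m.state)


# ---------------------------------------------------------------------------
# Noise filter
# ---------------------------------------------------------------------------

def filter_low_contacts(m: ContactMatrix, trans_mean: float | None = None) -> ContactMatrix:
    """Remove low-abundance (nonspecific ligation) contacts.

    Entries below ten times the average interchromosomal contact frequency
    are zeroed (entries equal to the cutoff are kept).  Used only for
    contact/loop quantification downstream, not for TAD or compartment
    calling.
    """
    if trans_mean is None:
        trans_mean = m.trans_mean
    if trans_mean is None:
        raise ValueError("trans_mean neither given nor stored on the matrix")
    if trans_mean < 0:
        raise ValueError("trans_mean must be non-negative")
    cutoff = 10.0 * trans_mean
    out = {c: np.where(mat >= cutoff, mat, 0.0) for c, mat in m.mats.items()}
    return ContactMatrix(m.bins, out, {c: k.copy() for c, k in m.mask.items()},
                         trans_mean, "filtered")
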