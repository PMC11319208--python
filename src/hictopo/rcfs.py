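"""Regional contact frequency sliding-window (RCFS) score and ecDNA nomination.

The RCFS of a bin is the average contact frequency over all bin pairs in
a square window centered on the bin (diagonal excluded).  Loci whose DNA
resides on extrachromosomal circles (ecDNA) barely contact their
chromosome of origin, so their RCFS collapses; a per-sample mean RCFS
over a locus of interest, thresholded at a cohort-level cutoff, nominates
"depleted" (ecDNA-like) versus "typical" samples.  Circularization leaves
a second signature: contact between the two ends of the amplicon far
above the distance-decay expectation (the corner signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix, DistanceDecay
from .tads import _sat, _block_sum

__all__ = [
    "RcfsTrack",
    "LocusCall",
    "rcfs_track",
    "classify_locus",
    "default_cutoff",
    "pair_rcfs",
    "corner_signal",
    "fraction_with_ecdna_support",
]


@dataclass
class RcfsTrack:
    """Per-bin RCFS values per chromosome, with the window size used."""

    values: dict[str, np.ndarray]
    window_bins: int

    def locus_mean(self, chrom: str, bin_lo: int, bin_hi: int) -> float:
        v = self.values[chrom][bin_lo:bin_hi]
        if v.size == 0:
            raise ValueError("locus outside chromosome")
        return float(v.mean())


@dataclass
class LocusCall:
    chrom: str
    bin_lo: int
    bin_hi: int
    mean_rcfs: float
    cutoff: float
    sample_id: str | None = None

    @property
    def depleted(self) -> bool:
        return self.mean_rcfs < self.cutoff

    @property
    def label(self) -> str:
        return "depleted" if self.depleted else "typical"


def rcfs_track(m: ContactMatrix, window_bins: int = 50) -> RcfsTrack:
    """Average contact in a sliding square window of ``window_bins`` bins
    centered on each bin, excluding the main diagonal; masked bins contribute
    nothing and an entirely masked window yields 0."""
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    half = window_bins // 2
    values: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        n = mat.shape[0]
        if window_bins >= n:
            raise ValueError(f"window_bins={window_bins} too large for {chrom}")
        keep = (~m.mask[chrom]).astype(float)
        wm = mat * np.outer(keep, keep)
        sat = _sat(wm)
        diag = np.concatenate([[0.0], np.cumsum(np.diag(wm))])
        out = np.zeros(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            total = _block_sum(sat, lo, hi, lo, hi) - (diag[hi] - diag[lo])
            # geometric pair count: masked bins contribute zero contact but
            # remain part of the window, so depletion lowers the average
            # instead of biasing it toward the surviving near-diagonal pairs
            k = (hi - lo) ** 2 - (hi - lo)
            out[i] = total / k if k > 0 else 0.0
        values[chrom] = out
    return RcfsTrack(values, window_bins)


def classify_locus(track: RcfsTrack, chrom: str, bin_lo: int, bin_hi: int,
                   cutoff: float, sample_id: str | None = None) -> LocusCall:
    """Depleted iff the mean RCFS over the locus is strictly below the cutoff."""
    mean = track.locus_mean(chrom, bin_lo, bin_hi)
    return LocusCall(chrom, bin_lo, bin_hi, mean, cutoff, sample_id)


def default_cutoff(locus_means: np.ndarray) -> float:
    """Cohort-level cutoff: midpoint between the two centers of an exact
    two-class one-dimensional k-means over per-sample locus means."""
    x = np.sort(np.asarray(locus_means, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two samples for a data-driven cutoff")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x**2)])
    best, best_k = np.inf, 1
    for k in range(1, x.size):  # left cluster = x[:k]
        for lo, hi in ((0, k), (k, x.size)):
            n = hi - lo
            s = csum[hi] - csum[lo]
            q = csq[hi] - csq[lo]
            cost = q - s * s / n
            if lo == 0:
                c = cost
            else:
                c += cost
        if c < best:
            best, best_k = c, k
    left = x[:best_k].mean()
    right = x[best_k:].mean()
    return float((left + right) / 2.0)


def pair_rcfs(m: ContactMatrix, chrom: str,
              region_a: tuple[int, int], region_b: tuple[int, int]) -> float:
    """Mean contact between the bins of two same-chromosome bp regions."""
    bins_a = m.bins.region_bins(chrom, *region_a)
    bins_b = m.bins.region_bins(chrom, *region_b)
    return float(m.mats[chrom][np.ix_(bins_a, bins_b)].mean())


def corner_signal(m: ContactMatrix, decay: DistanceDecay, chrom: str,
                  amplicon: tuple[int, int], flank_bins: int = 5) -> float:
    """End-to-end contact enrichment of an amplicon.

    Ratio of the mean contact between the first and last ``flank_bins`` bins
    of the amplicon to the mean distance-decay expectation over the same bin
    separations; > 1 indicates end-to-end (circularization-like) enrichment.
    """
    bins_all = m.bins.region_bins(chrom, *amplicon)
    if bins_all.size <= 2 * flank_bins:
        raise ValueError("amplicon must be longer than 2 x flank")
    head = bins_all[:flank_bins]
    tail = bins_all[-flank_bins:]
    obs = m.mats[chrom][np.ix_(head, tail)]
    seps = np.abs(np.subtract.outer(head, tail))
    exp = decay.values[chrom][seps]
    if np.any(exp <= 0):
        raise ValueError("no decay estimate at separation")
    return float(obs.mean() / exp.mean())


def fraction_with_ecdna_support(depleted: np.ndarray, ecdna_support: np.ndarray) -> float:
    """Among depleted-RCFS samples with orthogonal data available, the
    fraction with ecDNA support.

    Parameters
    ----------
    depleted
        Boolean per-sample flag from :func:`classify_locus`.
    ecdna_support
        Per-sample orthogonal ecDNA evidence: True/False, or NaN when the
        orthogonal assay is unavailable for that sample (float array).
    """
    depleted = np.asarray(depleted, dtype=bool)
    support = np.asarray(ecdna_support, dtype=float)
    avail = depleted & ~np.isnan(support)
    if not avail.any():
        raise ValueError("no depleted samples with orthogonal data")
    return float(np.nansum(support[avail]) / avail.sum())
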