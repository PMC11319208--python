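"""A/B compartment assignment with explicit NA semantics.

Per chromosome, the balanced matrix is converted to observed/expected,
the Pearson correlation matrix of the O/E profiles is computed over the
usable bins, and its leading eigenvector gives the compartment signal.
The sign is oriented so that A (positive eigenvector) is the gene-dense
state, the usual convention.  A bin is NA when the eigenvector is
undefined there: the bin is masked, its raw coverage is a small fraction
of the chromosome's typical coverage (the situation at contact-depleted
ecDNA loci), its O/E profile has zero variance, or the chromosome-level
decomposition is degenerate (fewer than 10 usable bins or a zero-variance
correlation matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix, expected_by_distance, observed_over_expected

__all__ = ["CompartmentTrack", "call_compartments", "ab_log_ratio", "locus_label"]

_LABELS = ("A", "B", "NA")


@dataclass
class CompartmentTrack:
    """Per-bin A/B/NA labels and eigenvector values, per chromosome."""

    labels: dict[str, np.ndarray]  # dtype '<U2', values in {"A","B","NA"}
    eigen: dict[str, np.ndarray]   # NaN where label is NA
    sample_id: str | None = None

    @property
    def chromosomes(self) -> list[str]:
        return list(self.labels)

    def concat_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[c] for c in self.labels])


def call_compartments(
    m: ContactMatrix,
    orientation_track: dict[str, np.ndarray],
    min_usable_bins: int = 10,
    min_coverage_frac: float = 0.10,
) -> CompartmentTrack:
    """Call A/B compartments from a balanced matrix.

    Parameters
    ----------
    orientation_track
        Per-chromosome per-bin orientation values (gene density); the
        eigenvector sign is chosen so A-labeled bins have the higher mean.
    min_coverage_frac
        Bins whose total contact is below this fraction of the chromosome's
        median bin total are treated as undefined (NA).  This captures loci
        whose DNA barely contacts the rest of the chromosome, as when the
        locus resides on amplified extrachromosomal circles.
    """
    labels: dict[str, np.ndarray] = {}
    eigen: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        n = mat.shape[0]
        if chrom not in orientation_track:
            raise ValueError(f"orientation track missing chromosome {chrom}")
        orient = np.asarray(orientation_track[chrom], dtype=float)
        if orient.shape[0] != n:
            raise ValueError(f"{chrom}: orientation track has {orient.shape[0]} bins, matrix {n}")
        lab = np.full(n, "NA", dtype="<U2")
        ev = np.full(n, np.nan)
        usable = ~m.mask[chrom]
        marg = mat.sum(axis=1)
        med = np.median(marg[usable]) if usable.any() else 0.0
        if med > 0:
            usable &= marg >= min_coverage_frac * med
        if usable.sum() >= min_usable_bins:
            sub = ContactMatrix(m.bins, {chrom: mat},
                                {chrom: ~usable}, m.trans_mean, m.state)
            oe = observed_over_expected(sub, expected_by_distance(sub)).mats[chrom]
            idx = np.flatnonzero(usable)
            rows = oe[np.ix_(idx, idx)]
            sd = rows.std(axis=1)
            idx = idx[sd > 0]
            rows = rows[sd > 0][:, sd > 0]
            if idx.size >= min_usable_bins:
                corr = np.corrcoef(rows)
                if np.isfinite(corr).all() and corr.std() > 0:
                    # leading eigenvector of the centered correlation matrix
                    cc = corr - corr.mean(axis=0, keepdims=True)
                    _, _, vt = np.linalg.svd(cc, full_matrices=False)
                    vec = vt[0]
                    a_mean = orient[idx[vec > 0]].mean() if (vec > 0).any() else -np.inf
                    b_mean = orient[idx[vec < 0]].mean() if (vec < 0).any() else -np.inf
                    if b_mean > a_mean:
                        vec = -vec
                    ev[idx] = vec
                    lab[idx[vec > 0]] = "A"
                    lab[idx[vec < 0]] = "B"
        labels[chrom] = lab
        eigen[chrom] = ev
    return CompartmentTrack(labels, eigen)


def ab_log_ratio(cohort_tracks: list[CompartmentTrack]) -> dict[str, np.ndarray]:
    """Per-bin log2((#A + 0.5) / (#B + 0.5)) across samples; NA calls are
    excluded from both counts."""
    if not cohort_tracks:
        raise ValueError("empty cohort")
    chroms = cohort_tracks[0].chromosomes
    out: dict[str, np.ndarray] = {}
    for chrom in chroms:
        stack = np.stack([t.labels[chrom] for t in cohort_tracks])
        n_a = (stack == "A").sum(axis=0)
        n_b = (stack == "B").sum(axis=0)
        out[chrom] = np.log2((n_a + 0.5) / (n_b + 0.5))
    return out


def locus_label(track: CompartmentTrack, chrom: str, bin_lo: int, bin_hi: int) -> str:
    """Label of a locus [bin_lo, bin_hi): NA when more than half its bins are
    NA, else the majority A/B label (ties -> A)."""
    lab = track.labels[chrom][bin_lo:bin_hi]
    if lab.size == 0:
        raise ValueError("empty locus")
    if (lab == "NA").mean() > 0.5:
        return "NA"
    n_a = (lab == "A").sum()
    n_b = (lab == "B").sum()
    return "A" if n_a >= n_b else "B"
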