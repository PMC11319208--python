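"""Compartment-level multi-omic statistics, candidate enhancers,
enhancer-gene contact scores and copy-number classification.

The compartment battery compares, within each sample, a feature summary
computed over A-labeled bins against the same summary over B-labeled bins
(NA bins excluded from both), then tests A versus B across samples with a
paired two-sided Wilcoxon signed-rank test and corrects the battery with
Benjamini-Hochberg.  Three summary modes cover the feature types:

``fraction``
    feature bases overlapping the compartment / compartment bases
    (methylation domains, peaks, gene bodies).
``per_mb``
    point events (mutations, SV breakpoints) per Mb of compartment — the
    normalization that accounts for A compartments covering more of the
    genome than B.
``mean_tpm``
    mean TPM of genes whose TSS bin carries the compartment label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compartments import CompartmentTrack
from .contacts import ContactMatrix
from .genome import GenomeBins
from .intervals import IntervalTrack, bases_per_bin, coverage_regions, overlaps_any

__all__ = [
    "ExpressionTable",
    "CopyNumberProfile",
    "compartment_overlap_stats",
    "overlap_battery",
    "consensus_peaks",
    "call_candidate_enhancers",
    "enhancer_contact_sum",
    "enhancer_expression_tstat",
    "classify_copy_number",
]


@dataclass
class ExpressionTable:
    """Gene-level expression with TSS positions on the shared bin frame."""

    genes: list[str]
    chrom: np.ndarray
    tss: np.ndarray
    tpm: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.tpm < 0):
            raise ValueError("TPM must be non-negative")

    def tpm_of(self, gene: str) -> float:
        return float(self.tpm[self.genes.index(gene)])


@dataclass
class CopyNumberProfile:
    """Per-gene min/max exonic copy number with sample ploidy."""

    genes: list[str]
    min_cn: np.ndarray
    max_cn: np.ndarray
    chrom_type: list[str]  # "autosomal" | "sex" per gene
    ploidy: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if np.any(self.min_cn < 0) or np.any(self.max_cn < 0):
            raise ValueError("negative CN")
        if np.any(self.min_cn > self.max_cn):
            raise ValueError("min CN exceeds max CN")


# ---------------------------------------------------------------------------
# Compartment battery
# ---------------------------------------------------------------------------

def _per_sample_ab(track: CompartmentTrack, bins: GenomeBins, feature, mode: str):
    """(A value, B value) for one sample, or None when undefined."""
    vals = {}
    for comp in ("A", "B"):
        if mode == "fraction":
            feat_bases = 0.0
            comp_bases = 0.0
            for chrom, lab in track.labels.items():
                n = bins.n_bins(chrom)
                sel = lab == comp
                widths = np.full(n, bins.bin_width, dtype=float)
                widths[-1] = bins.lengths[chrom] - (n - 1) * bins.bin_width
                comp_bases += widths[sel].sum()
                ivs = feature.intervals.get(chrom)
                if ivs is not None and ivs.shape[0]:
                    cov = bases_per_bin(ivs, n, bins.bin_width)
                    feat_bases += cov[sel].sum()
            if comp_bases == 0:
                return None
            vals[comp] = feat_bases / comp_bases
        elif mode == "per_mb":
            events = 0.0
            comp_bases = 0.0
            for chrom, lab in track.labels.items():
                n = bins.n_bins(chrom)
                sel = lab == comp
                comp_bases += sel.sum() * bins.bin_width
                ivs = feature.intervals.get(chrom)
                if ivs is not None and ivs.shape[0]:
                    b = np.clip(ivs[:, 0] // bins.bin_width, 0, n - 1)
                    events += sel[b].sum()
            if comp_bases == 0:
                return None
            vals[comp] = events / (comp_bases / 1e6)
        elif mode == "mean_tpm":
            tpms = []
            for chrom, lab in track.labels.items():
                sel = feature.chrom == chrom
                if not sel.any():
                    continue
                b = feature.tss[sel] // bins.bin_width
                ok = lab[b] == comp
                tpms.append(feature.tpm[sel][ok])
            tpms = np.concatenate(tpms) if tpms else np.array([])
            if tpms.size == 0:
                return None
            vals[comp] = float(tpms.mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return vals["A"], vals["B"]


def compartment_overlap_stats(
    tracks: dict[str, CompartmentTrack],
    features: dict,
    bins: GenomeBins,
    mode: str,
) -> dict:
    """Paired A-vs-B feature summary across a cohort.

    ``features`` maps sample id -> IntervalTrack (fraction / per_mb modes)
    or ExpressionTable (mean_tpm mode).  Samples present in only one input
    are dropped.  Returns per-sample paired values and the paired two-sided
    Wilcoxon signed-rank test result.
    """
    samples, a_vals, b_vals = [], [], []
    for s in sorted(tracks):
        if s not in features:
            continue
        pair = _per_sample_ab(tracks[s], bins, features[s], mode)
        if pair is None:
            continue
        samples.append(s)
        a_vals.append(pair[0])
        b_vals.append(pair[1])
    a_arr, b_arr = np.array(a_vals), np.array(b_vals)
    if len(samples) >= 2 and np.any(a_arr - b_arr != 0):
        res = stats.wilcoxon(a_arr, b_arr, zero_method="wilcox", alternative="two-sided")
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        statistic, pvalue = 0.0, 1.0
    return {
        "samples": samples,
        "A": a_arr,
        "B": b_arr,
        "statistic": statistic,
        "pvalue": pvalue,
        "direction": "A>B" if np.median(a_arr - b_arr) > 0 else "B>A",
    }


def overlap_battery(
    tracks: dict[str, CompartmentTrack],
    feature_specs: dict[str, tuple[dict, str]],
    bins: GenomeBins,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the compartment battery over named features and BH-correct.

    ``feature_specs`` maps feature name -> (per-sample features, mode).
    """
    rows = []
    for name, (features, mode) in feature_specs.items():
        r = compartment_overlap_stats(tracks, features, bins, mode)
        rows.append({
            "feature": name,
            "mode": mode,
            "n_samples": len(r["samples"]),
            "median_A": float(np.median(r["A"])) if len(r["samples"]) else np.nan,
            "median_B": float(np.median(r["B"])) if len(r["samples"]) else np.nan,
            "direction": r["direction"],
            "pvalue": r["pvalue"],
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["pvalue"], alpha=alpha, method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    return df


# ---------------------------------------------------------------------------
# Enhancers
# ---------------------------------------------------------------------------

def consensus_peaks(per_sample_peaks: list[IntervalTrack],
                    min_samples: int = 2) -> IntervalTrack:
    """Maximal regions where at least ``min_samples`` samples have an
    overlapping peak."""
    if len(per_sample_peaks) < min_samples:
        raise ValueError("fewer tracks than min_samples")
    chroms: set[str] = set()
    for t in per_sample_peaks:
        chroms |= set(t.intervals)
    out = {}
    for chrom in sorted(chroms):
        tracks = [t.intervals.get(chrom, np.zeros((0, 2), dtype=np.int64))
                  for t in per_sample_peaks]
        out[chrom] = coverage_regions(tracks, min_samples)
    return IntervalTrack(out, role="H3K27ac_peak")


def call_candidate_enhancers(
    h3k27ac: IntervalTrack,
    hypomethylation_by_sample: list[IntervalTrack],
    threshold: float = 0.10,
) -> IntervalTrack:
    """H3K27ac peaks recurrently hypomethylated across the cohort.

    A peak is a candidate enhancer when the fraction of samples with an
    overlapping hypomethylated region is >= threshold (boundary inclusive).
    The returned track's scores hold each enhancer's hypomethylation
    frequency.
    """
    n = len(hypomethylation_by_sample)
    if n == 0:
        raise ValueError("zero samples")
    out_iv: dict[str, np.ndarray] = {}
    out_sc: dict[str, np.ndarray] = {}
    for chrom, peaks in h3k27ac.intervals.items():
        if peaks.shape[0] == 0:
            continue
        counts = np.zeros(peaks.shape[0])
        for t in hypomethylation_by_sample:
            hmr = t.intervals.get(chrom, np.zeros((0, 2), dtype=np.int64))
            counts += overlaps_any(peaks, hmr)
        freq = counts / n
        keep = freq >= threshold
        if keep.any():
            out_iv[chrom] = peaks[keep]
            out_sc[chrom] = freq[keep]
    return IntervalTrack(out_iv, role="enhancer", scores=out_sc)


def enhancer_contact_sum(m: ContactMatrix, enhancers: IntervalTrack) -> dict[str, np.ndarray]:
    """Per bin, the sum of (filtered) contact frequencies with all enhancer
    bins on the same chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, mat in m.mats.items():
        n = mat.shape[0]
        ivs = enhancers.intervals.get(chrom)
        if ivs is None or ivs.shape[0] == 0:
            out[chrom] = np.zeros(n)
            continue
        ebins = np.unique(np.concatenate(
            [m.bins.region_bins(chrom, int(s), int(e)) for s, e in ivs]))
        out[chrom] = mat[:, ebins].sum(axis=1)
    return out


def cohort_enhancer_contact_sum(mats: list[ContactMatrix],
                                enhancers: IntervalTrack) -> dict[str, np.ndarray]:
    """Average of :func:`enhancer_contact_sum` across samples."""
    per = [enhancer_contact_sum(m, enhancers) for m in mats]
    return {c: np.mean([p[c] for p in per], axis=0) for c in per[0]}


def enhancer_expression_tstat(
    expr_by_sample: dict[str, ExpressionTable],
    hypomethylated_samples: set[str],
    gene: str,
) -> tuple[float, float]:
    """Welch t-statistic (and p) of a gene's TPM between samples
    hypomethylated vs not at an enhancer; positive t means hypomethylation
    goes with higher expression.  Requires >= 2 samples per group."""
    hypo, other = [], []
    for s, tab in expr_by_sample.items():
        (hypo if s in hypomethylated_samples else other).append(tab.tpm_of(gene))
    if len(hypo) < 2 or len(other) < 2:
        raise ValueError("need >= 2 samples in each methylation group")
    res = stats.ttest_ind(hypo, other, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Copy-number classification
# ---------------------------------------------------------------------------

def classify_copy_number(p: CopyNumberProfile, gene: str) -> str:
    """Amplified / deleted / biallelic_loss / neutral call for one gene.

    Sex chromosomes: amplified if min exonic CN > ploidy x 0.9; deleted if
    min CN < 0.75.  Autosomes: amplified if min CN > ploidy x 1.95; deleted
    if min CN < 1.1.  Either way biallelic loss requires max CN < 0.5 and
    takes precedence over deleted.
    """
    i = p.genes.index(gene)
    mn, mx = float(p.min_cn[i]), float(p.max_cn[i])
    sex = p.chrom_type[i] == "sex"
    if mx < 0.5:
        return "biallelic_loss"
    if mn < (0.75 if sex else 1.1):
        return "deleted"
    if mn > p.ploidy * (0.9 if sex else 1.95):
        return "amplified"
    return "neutral"
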