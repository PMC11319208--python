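"""SV filtering, size-matched backgrounds, breakpoint Hi-C signatures and
TAD-association tests.

Intra-chromosomal SVs (deletions, duplications, inversions) have two
breakpoints on the same chromosome and leave a characteristic enrichment
in the Hi-C map where the two broken ends are brought together.  To ask
whether 3D topology predisposes to SV formation, each real SV is compared
against ten random segments of the exact same size and type placed
uniformly in the genome outside assembly gaps; the fraction of SVs with
both breakpoints inside one TAD — evaluated against the TADs of *other*
samples, so the SV cannot have created the TAD structure being tested —
is compared between real and background with a paired two-sided Wilcoxon
signed-rank test per SV type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .contacts import ContactMatrix
from .genome import GenomeBins
from .tads import TadSet

__all__ = [
    "SVRecord",
    "SvSignature",
    "filter_svs",
    "size_matched_background",
    "breakpoint_signature",
    "same_tad_fraction",
    "sv_tad_enrichment_test",
    "differential_contact_map",
    "read_bedpe",
    "write_bedpe",
]

SV_TYPES = ("deletion", "duplication", "inversion")


@dataclass(frozen=True)
class SVRecord:
    """Typed intra-chromosomal rearrangement with read-support counts."""

    sv_type: str
    chrom: str
    bp1: int
    bp2: int
    pe_support: int = 0
    spanning_support: int = 0
    germline_support: int = 0
    sample_id: str | None = None
    is_background: bool = False

    def __post_init__(self) -> None:
        if self.bp2 <= self.bp1:
            raise ValueError("breakpoints must satisfy bp1 < bp2")

    @property
    def size(self) -> int:
        return self.bp2 - self.bp1


@dataclass
class SvSignature:
    """Average contact submatrix on a (2F+1)x(2F+1) grid centered at the two
    breakpoints, per SV type."""

    sv_type: str
    matrix: np.ndarray
    n_svs: int
    flank_bins: int


def write_bedpe(svs: list[SVRecord], path) -> None:
    """BEDPE with extra columns: type, sample, PE/spanning/germline supports,
    background flag."""
    with open(path, "w") as fh:
        for s in svs:
            fh.write("\t".join(map(str, (
                s.chrom, s.bp1, s.bp1 + 1, s.chrom, s.bp2, s.bp2 + 1,
                s.sv_type, s.sample_id or ".", s.pe_support,
                s.spanning_support, s.germline_support,
                int(s.is_background)))) + "\n")


def read_bedpe(path) -> list[SVRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] != f[3]:
                raise ValueError(f"interchromosomal record in line: {line!r}")
            out.append(SVRecord(
                f[6], f[0], int(f[1]), int(f[4]), int(f[8]), int(f[9]),
                int(f[10]), None if f[7] == "." else f[7], bool(int(f[11]))))
    return out


def filter_svs(svs: list[SVRecord], max_size: int = 50_000_000,
               min_pe: int = 10, min_spanning: int = 10) -> list[SVRecord]:
    """Keep SVs of the three two-breakpoint types measuring <= 50 Mb with
    >= 10 tumor paired-end reads, >= 10 tumor spanning reads, and zero
    germline reads."""
    return [
        s for s in svs
        if s.sv_type in SV_TYPES
        and s.size <= max_size
        and s.pe_support >= min_pe
        and s.spanning_support >= min_spanning
        and s.germline_support == 0
    ]


def size_matched_background(
    svs: list[SVRecord],
    bins: GenomeBins,
    gaps: dict[str, list[tuple[int, int]]],
    k: int = 10,
    seed: int = 0,
    max_retries: int = 1000,
) -> list[SVRecord]:
    """For each SV, k random segments of the exact same size and type.

    Start positions are uniform over the genome positions where the whole
    segment fits on a chromosome; placements overlapping a gap region are
    rejected and resampled (up to ``max_retries`` per segment).
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    chroms = bins.chromosomes
    lengths = np.array([bins.lengths[c] for c in chroms], dtype=float)
    gap_arrays = {
        c: (np.array([g[0] for g in gaps.get(c, [])]),
            np.array([g[1] for g in gaps.get(c, [])]))
        for c in chroms
    }
    out: list[SVRecord] = []
    for sv in svs:
        size = sv.size
        room = np.maximum(lengths - size, 0.0)
        if room.sum() == 0:
            raise ValueError(f"no placement possible for SV {sv}")
        p = room / room.sum()
        for _ in range(k):
            for _try in range(max_retries):
                ci = rng.choice(len(chroms), p=p)
                chrom = chroms[ci]
                start = int(rng.integers(0, int(room[ci]) + 1))
                end = start + size
                gs, ge = gap_arrays[chrom]
                if gs.size and np.any((start < ge) & (end > gs)):
                    continue
                out.append(replace(sv, chrom=chrom, bp1=start, bp2=end,
                                   is_background=True))
                break
            else:
                raise ValueError(f"could not place background for SV {sv}")
    return out


def breakpoint_signature(
    cohort: list[tuple[ContactMatrix, list[SVRecord]]],
    span_bp: int = 600_000,
) -> dict[str, SvSignature]:
    """Average Hi-C submatrix around SV breakpoints, per SV type.

    For each SV the submatrix rows are centered on bin(bp1) +- F and columns
    on bin(bp2) +- F, where F = span / (2 x bin width); cells falling outside
    the chromosome are ignored via an occupancy count.  Background records
    are averaged the same way (run this separately on background lists).
    """
    sums: dict[str, np.ndarray] = {}
    occ: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    flank = None
    for m, svs in cohort:
        bw = m.bins.bin_width
        f = span_bp // (2 * bw)
        if flank is None:
            flank = f
        elif flank != f:
            raise ValueError("inconsistent bin widths across cohort")
        side = 2 * f + 1
        for sv in svs:
            if sv.chrom not in m.mats:
                continue
            mat = m.mats[sv.chrom]
            n = mat.shape[0]
            b1 = sv.bp1 // bw
            b2 = sv.bp2 // bw
            rows = np.arange(b1 - f, b1 + f + 1)
            cols = np.arange(b2 - f, b2 + f + 1)
            rok = (rows >= 0) & (rows < n)
            cok = (cols >= 0) & (cols < n)
            patch = np.zeros((side, side))
            hit = np.zeros((side, side))
            patch[np.ix_(rok, cok)] = mat[np.ix_(rows[rok], cols[cok])]
            hit[np.ix_(rok, cok)] = 1.0
            t = sv.sv_type
            if t not in sums:
                sums[t] = np.zeros((side, side))
                occ[t] = np.zeros((side, side))
                counts[t] = 0
            sums[t] += patch
            occ[t] += hit
            counts[t] += 1
    out: dict[str, SvSignature] = {}
    for t in sums:
        with np.errstate(invalid="ignore"):
            avg = np.where(occ[t] > 0, sums[t] / np.where(occ[t] > 0, occ[t], 1.0), 0.0)
        out[t] = SvSignature(t, avg, counts[t], flank)
    return out


def same_tad_fraction(svs: list[SVRecord], tads: TadSet) -> float:
    """Fraction of SVs whose two breakpoints fall inside one TAD interval."""
    if not svs:
        return float("nan")
    bw = tads.bins.bin_width
    dom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in tads.bins.chromosomes:
        ivs = sorted((a, b) for c, a, b in tads.domains if c == chrom)
        dom[chrom] = (np.array([a for a, _ in ivs]), np.array([b for _, b in ivs]))
    hits = 0
    for sv in svs:
        starts, ends = dom.get(sv.chrom, (np.array([]), np.array([])))
        if starts.size == 0:
            continue
        b1, b2 = sv.bp1 // bw, sv.bp2 // bw
        i = np.searchsorted(starts, b1, side="right") - 1
        if i >= 0 and b1 < ends[i] and starts[i] <= b2 < ends[i]:
            hits += 1
    return hits / len(svs)


def sv_tad_enrichment_test(
    real_by_sample: dict[str, list[SVRecord]],
    background_by_sample: dict[str, list[SVRecord]],
    tads_by_sample: dict[str, TadSet],
) -> dict[str, dict]:
    """Cross-sample same-TAD enrichment of real SVs over background.

    For each sample and SV type, the real (resp. background) fraction is the
    mean of :func:`same_tad_fraction` over the TadSets of all OTHER samples;
    a paired two-sided Wilcoxon signed-rank test across samples compares real
    versus background per type.  Samples with zero SVs of a type are dropped
    from that type's pairing.
    """
    samples = sorted(tads_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    results: dict[str, dict] = {}
    # precompute per (sample, type) fractions against each other sample's TADs
    for t in SV_TYPES:
        real_fracs, bg_fracs, used = [], [], []
        for s in samples:
            rs = [v for v in real_by_sample.get(s, []) if v.sv_type == t]
            bs = [v for v in background_by_sample.get(s, []) if v.sv_type == t]
            if not rs or not bs:
                continue
            others = [tads_by_sample[o] for o in samples if o != s]
            rf = np.mean([same_tad_fraction(rs, td) for td in others])
            bf = np.mean([same_tad_fraction(bs, td) for td in others])
            real_fracs.append(rf)
            bg_fracs.append(bf)
            used.append(s)
        if not used:
            continue
        real_arr, bg_arr = np.array(real_fracs), np.array(bg_fracs)
        diffs = real_arr - bg_arr
        if np.all(diffs == 0):
            statistic, pvalue = 0.0, 1.0
        else:
            res = stats.wilcoxon(real_arr, bg_arr, zero_method="wilcox",
                                 alternative="two-sided")
            statistic, pvalue = float(res.statistic), float(res.pvalue)
        results[t] = {
            "statistic": statistic,
            "pvalue": pvalue,
            "samples": used,
            "real_fraction": real_arr,
            "background_fraction": bg_arr,
            "median_difference": float(np.median(diffs)),
        }
    return results


def differential_contact_map(
    case: list[ContactMatrix],
    control: list[ContactMatrix],
    chrom: str,
    region: tuple[int, int],
    eps: float | None = None,
) -> np.ndarray:
    """Median-centered log2 ratio of mean case vs mean control contact over a
    region.

    eps defaults to the 5th percentile of the positive control-group means,
    stabilizing empty cells without drowning signal.
    """
    if not case or not control:
        raise ValueError("need at least one matrix per group")
    idx = case[0].bins.region_bins(chrom, *region)
    sel = np.ix_(idx, idx)
    mean_case = np.mean([m.mats[chrom][sel] for m in case], axis=0)
    mean_ctrl = np.mean([m.mats[chrom][sel] for m in control], axis=0)
    if eps is None:
        pos = mean_ctrl[mean_ctrl > 0]
        eps = float(np.percentile(pos, 5)) if pos.size else 1e-6
    ratio = np.log2((mean_case + eps) / (mean_ctrl + eps))
    return ratio - np.median(ratio)
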