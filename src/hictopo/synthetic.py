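"""Synthetic Hi-C cohorts with planted, recorded truth.

The generator emulates the statistical structure the downstream analyses
assume, so that every pipeline stage can be tested end-to-end without any
external data:

* contact maps follow a power-law distance decay ``(1+d)^-alpha`` with
  multiplicative fold-enrichments for same-TAD (``f_tad``) and
  same-compartment (``f_comp``) bin pairs, observed through Poisson
  counting noise at a configurable depth;
* a TAD hierarchy (broad ~1-Mb domains, optionally subdivided by narrow
  boundaries in "narrow"-subtype samples) and an alternating A/B
  compartment layout are planted and recorded as truth;
* SV junctions add local contact enrichment around (bp1, bp2); an ecDNA
  plant combines amplicon-internal amplification, depleted contact with
  the flanking chromosome, and an end-to-end "corner" contact set to a
  fold over the decay expectation (circularization);
* companion omics (expression, mutations, HMR/PMD/5hmC intervals, copy
  number, SV read supports) carry compartment-linked and subtype-linked
  effects with configurable multipliers.

Setting every multiplier to 1 yields a null cohort, which drives the
pipeline-wide calibration checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compartments import CompartmentTrack
from .contacts import ContactMatrix
from .genome import GenomeBins
from .integration import CopyNumberProfile, ExpressionTable
from .intervals import IntervalTrack
from .svtopo import SVRecord, SV_TYPES
from .tads import TadSet

__all__ = [
    "TruthSpec",
    "OmicsTracks",
    "SampleData",
    "CohortBundle",
    "simulate_contact_map",
    "plant_sv_signals",
    "plant_ecdna",
    "simulate_omics",
    "simulate_cohort",
]


@dataclass
class TruthSpec:
    """Generative parameters; defaults give a desk-scale two-chromosome
    genome (2 x 20 Mb at 10 kb) with effect sizes in the range the cohort
    analyses are designed to detect."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    bin_width: int = 10_000
    # TAD layout: broad ~1 Mb domains; narrow-subtype samples subdivide a
    # broad domain with probability p_narrow into ~250-kb pieces
    broad_tad_mean_bins: int = 100
    broad_tad_min_bins: int = 40
    p_narrow: float = 0.7
    narrow_tad_mean_bins: int = 25
    # compartments: alternating A/B segments, ~1.5 Mb
    comp_segment_mean_bins: int = 150
    comp_segment_min_bins: int = 50
    # contact model
    alpha: float = 1.0
    f_tad: float = 3.0
    f_comp: float = 2.0
    depth: float = 40.0
    trans_level: float = 0.05
    # SVs: 10 two-breakpoint SVs per sample on the 40-Mb toy genome --
    # denser per Mb than patient genomes, so cohort statistics have events
    # to work with at desk scale
    sv_per_sample: int = 10
    sv_size_range: tuple[int, int] = (50_000, 1_000_000)
    f_sv: float = 8.0
    sv_taper_bins: float = 3.0
    sv_intra_tad_p: float | None = None  # None -> compartment-weighted placement
    sv_fail_fraction: float = 0.3
    # ecDNA plant: "depletion" scales every local contact of the locus (its
    # DNA is mostly on circles, so chromosomal-context contact collapses);
    # "amplification" additionally scales amplicon-internal contacts and
    # defaults to 1 because balancing removes pure coverage amplification
    ecdna_locus: tuple[str, int, int] | None = None  # None -> auto on last chrom
    ecdna_amplification: float = 1.0
    ecdna_depletion: float = 0.05
    ecdna_corner_fold: float = 10.0
    ecdna_corner_flank_bins: int = 5
    ecdna_fraction: float = 0.0
    # omics effects
    genes_per_chrom: int = 200
    gene_a_multiplier: float = 2.0  # A compartments are gene-dense
    tpm_base: float = 10.0
    tpm_sigma: float = 1.0
    tpm_a_multiplier: float = 3.0
    mutation_rate_per_mb: float = 3.0
    mutation_b_multiplier: float = 2.0
    sv_a_multiplier: float = 1.5
    hmr_rate_per_mb: float = 1.5
    hmr_a_multiplier: float = 2.0
    hmr_size_range: tuple[int, int] = (2_000, 20_000)
    pmd_rate_per_mb: float = 0.15
    pmd_b_multiplier: float = 3.0
    pmd_size_range: tuple[int, int] = (200_000, 1_000_000)
    fivehmc_rate_per_mb: float = 2.0
    fivehmc_a_multiplier: float = 2.0
    fivehmc_size_range: tuple[int, int] = (500, 3_000)
    # subtype effects (applied to narrow-subtype samples)
    narrow_fraction: float = 0.5
    narrow_hmr_multiplier: float = 1.5
    narrow_fivehmc_multiplier: float = 1.5
    narrow_tpm_multiplier: float = 1.3
    myc_gain: float = 1.5
    myc_gain_prob_narrow: float = 0.5
    ploidy: float = 2.0

    def bins(self) -> GenomeBins:
        return GenomeBins(dict(self.chrom_lengths), self.bin_width)

    def resolved_ecdna_locus(self) -> tuple[str, int, int]:
        if self.ecdna_locus is not None:
            return self.ecdna_locus
        chrom = list(self.chrom_lengths)[-1]
        length = self.chrom_lengths[chrom]
        width = min(1_000_000, max(30 * self.bin_width, length // 10))
        center = int(0.5 * length)  # clear of the planted gap regions
        start = (center - width // 2) // self.bin_width * self.bin_width
        return (chrom, start, start + width)

    def gap_track(self) -> IntervalTrack:
        """Two fixed gap intervals per chromosome (centromere/telomere-like),
        exercising background rejection sampling."""
        ivs = {}
        for chrom, length in self.chrom_lengths.items():
            bw = self.bin_width
            g1 = (int(0.30 * length) // bw * bw, int(0.33 * length) // bw * bw)
            g2 = (int(0.62 * length) // bw * bw, int(0.64 * length) // bw * bw)
            ivs[chrom] = np.array([g1, g2])
        return IntervalTrack(ivs, role="gap")


@dataclass
class OmicsTracks:
    expression: ExpressionTable
    hmr: IntervalTrack
    pmd: IntervalTrack
    fivehmc: IntervalTrack
    mutations: IntervalTrack
    copy_number: CopyNumberProfile

    def hmr_genome_fraction(self, genome_bases: int) -> float:
        return self.hmr.merged().total_bases() / genome_bases


@dataclass
class SampleData:
    sample_id: str
    matrix: ContactMatrix | None
    tads_truth: TadSet
    compartments_truth: CompartmentTrack
    svs: list[SVRecord]
    omics: OmicsTracks | None
    subtype: str   # "broad" | "narrow"
    ecdna: bool


@dataclass
class CohortBundle:
    spec: TruthSpec
    bins: GenomeBins
    samples: list[SampleData]
    gaps: IntervalTrack

    def manifest(self) -> dict:
        return {
            "chrom_lengths": self.spec.chrom_lengths,
            "bin_width": self.spec.bin_width,
            "ecdna_locus": list(self.spec.resolved_ecdna_locus()),
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "subtype": s.subtype,
                    "ecdna": s.ecdna,
                    "tad_boundaries": {
                        c: s.tads_truth.edges_bins(c).tolist()
                        for c in self.bins.chromosomes
                    },
                    "n_svs": len(s.svs),
                }
                for s in self.samples
            ],
        }

    def write(self, outdir) -> None:
        """Emit the cohort in the pipeline's on-disk formats plus truth.json."""
        from .contacts import write_contacts
        from .svtopo import write_bedpe

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)
        with open(out / "gaps.bed", "w") as fh:
            for chrom, ivs in self.gaps.intervals.items():
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s}\t{e}\tgap\n")
        for s in self.samples:
            d = out / s.sample_id
            d.mkdir(exist_ok=True)
            if s.matrix is not None:
                write_contacts(s.matrix, d / "contacts.tsv", d / "bins.bed")
            with open(d / "tads_truth.bed", "w") as fh:
                bw = self.bins.bin_width
                for chrom, a, b in s.tads_truth.domains:
                    fh.write(f"{chrom}\t{a * bw}\t{b * bw}\tTAD\n")
            write_bedpe(s.svs, d / "svs.bedpe")
            if s.omics is not None:
                expr = s.omics.expression
                with open(d / "expression.tsv", "w") as fh:
                    fh.write("gene\tchrom\ttss\ttpm\n")
                    for g, c, t, v in zip(expr.genes, expr.chrom, expr.tss, expr.tpm):
                        fh.write(f"{g}\t{c}\t{t}\t{v}\n")
                for name, track in (("hmr", s.omics.hmr), ("pmd", s.omics.pmd),
                                    ("5hmc", s.omics.fivehmc),
                                    ("mutations", s.omics.mutations)):
                    with open(d / f"{name}.bed", "w") as fh:
                        for chrom, ivs in track.intervals.items():
                            for a, b in ivs:
                                fh.write(f"{chrom}\t{a}\t{b}\t{name}\n")


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def _segment_lengths(n_bins: int, mean: int, minimum: int, rng) -> list[int]:
    """Random segment lengths tiling n_bins (uniform in [0.6, 1.4] x mean,
    floor at minimum; remainder merged into the last segment)."""
    out: list[int] = []
    left = n_bins
    while left > 0:
        size = int(rng.uniform(0.6, 1.4) * mean)
        size = max(minimum, size)
        if left - size < minimum:
            size = left
        out.append(min(size, left))
        left -= out[-1]
    return out


def _tad_layout(spec: TruthSpec, rng, narrow: bool) -> dict[str, np.ndarray]:
    """Per-chromosome sorted interior boundary bins."""
    bins = spec.bins()
    layout = {}
    for chrom in bins.chromosomes:
        n = bins.n_bins(chrom)
        bounds: list[int] = []
        pos = 0
        for size in _segment_lengths(n, spec.broad_tad_mean_bins,
                                     spec.broad_tad_min_bins, rng):
            seg_start, pos = pos, pos + size
            if narrow and rng.random() < spec.p_narrow:
                sub = seg_start
                for s2 in _segment_lengths(size, spec.narrow_tad_mean_bins,
                                           max(5, spec.narrow_tad_mean_bins // 3),
                                           rng)[:-1]:
                    sub += s2
                    bounds.append(sub)
            if pos < n:
                bounds.append(pos)
        layout[chrom] = np.array(sorted(set(bounds)), dtype=int)
    return layout


def _comp_layout(spec: TruthSpec, rng,
                 tad_layout: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-chromosome per-bin A/B labels.

    Compartment state switches only at (broad) TAD boundaries — as in real
    genomes, where compartment transitions align with domain boundaries —
    with a switch probability giving segments of about
    ``comp_segment_mean_bins`` bins."""
    bins = spec.bins()
    p_switch = min(1.0, spec.broad_tad_mean_bins / spec.comp_segment_mean_bins)
    layout = {}
    for chrom in bins.chromosomes:
        n = bins.n_bins(chrom)
        cuts = [0, *tad_layout[chrom].tolist(), n]
        lab = np.empty(n, dtype="<U2")
        state = "A" if rng.random() < 0.5 else "B"
        for a, b in zip(cuts, cuts[1:]):
            lab[a:b] = state
            if rng.random() < p_switch:
                state = "B" if state == "A" else "A"
        layout[chrom] = lab
    return layout


def _layout_to_tadset(bins: GenomeBins, layout: dict[str, np.ndarray],
                      sample_id: str | None = None) -> TadSet:
    domains = []
    for chrom, bounds in layout.items():
        cuts = [0, *bounds.tolist(), bins.n_bins(chrom)]
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                domains.append((chrom, a, b))
    return TadSet(bins, domains, sample_id)


def _gap_bins(spec: TruthSpec, chrom: str) -> np.ndarray:
    bins = spec.bins()
    out = []
    for s, e in spec.gap_track().intervals[chrom]:
        out.append(bins.region_bins(chrom, int(s), int(e)))
    return np.unique(np.concatenate(out)) if out else np.array([], dtype=int)


def _layout_to_comptrack(spec: TruthSpec, layout: dict[str, np.ndarray],
                         sample_id: str | None = None) -> CompartmentTrack:
    """Truth compartment track; assembly-gap bins carry no sequence and
    hence no label (NA)."""
    labels, eigen = {}, {}
    for chrom, lab in layout.items():
        lab = lab.copy()
        ev = np.where(lab == "A", 1.0, -1.0)
        gb = _gap_bins(spec, chrom)
        lab[gb] = "NA"
        ev[gb] = np.nan
        labels[chrom] = lab
        eigen[chrom] = ev
    return CompartmentTrack(labels, eigen, sample_id)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def _expected_chrom(spec: TruthSpec, n: int, bounds: np.ndarray,
                    comp: np.ndarray) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = spec.depth * (1.0 + d) ** (-spec.alpha)
    dom = np.searchsorted(bounds, np.arange(n), side="right")
    e *= np.where(np.equal.outer(dom, dom), spec.f_tad, 1.0)
    e *= np.where(np.equal.outer(comp, comp), spec.f_comp, 1.0)
    return e


def _poisson_symmetric(e: np.ndarray, rng) -> np.ndarray:
    n = e.shape[0]
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(e[iu, ju]).astype(float)
    m = np.zeros((n, n))
    m[iu, ju] = counts
    m[ju, iu] = counts
    return m


def simulate_contact_map(
    spec: TruthSpec,
    seed: int,
    narrow: bool = False,
    ecdna: bool = False,
    svs: list[SVRecord] | None = None,
    sample_id: str | None = None,
) -> tuple[ContactMatrix, TadSet, CompartmentTrack]:
    """One sample's raw (Poisson-count) contact map plus its planted truth.

    Layouts are drawn from ``seed``'s own stream, so two calls with the same
    seed are bit-identical; cohort generation draws layouts once and reuses
    them (see :func:`simulate_cohort`).
    """
    rng = np.random.default_rng(seed)
    tad_layout = _tad_layout(spec, rng, narrow)
    comp_layout = _comp_layout(spec, rng, tad_layout)
    mat = _simulate_from_layouts(spec, rng, tad_layout, comp_layout, ecdna, svs)
    return (mat,
            _layout_to_tadset(spec.bins(), tad_layout, sample_id),
            _layout_to_comptrack(spec, comp_layout, sample_id))


def _simulate_from_layouts(spec: TruthSpec, rng, tad_layout, comp_layout,
                           ecdna: bool, svs: list[SVRecord] | None) -> ContactMatrix:
    bins = spec.bins()
    mats = {}
    for chrom in bins.chromosomes:
        n = bins.n_bins(chrom)
        e = _expected_chrom(spec, n, tad_layout[chrom], comp_layout[chrom])
        gb = _gap_bins(spec, chrom)  # assembly gaps produce no reads
        e[gb, :] = 0.0
        e[:, gb] = 0.0
        if svs:
            _plant_sv_arrays(e, [s for s in svs if s.chrom == chrom],
                             bins, spec.f_sv, spec.sv_taper_bins)
        if ecdna:
            locus = spec.resolved_ecdna_locus()
            if locus[0] == chrom:
                # empirical decay of the pre-plant expectation, so the corner
                # fold is on the same scale the analysis estimates from data
                decay = np.array([np.mean(np.diagonal(e, d)) for d in range(n)])
                _plant_ecdna_array(e, bins, chrom, locus, spec, decay)
        mats[chrom] = _poisson_symmetric(e, rng)
    return ContactMatrix(bins, mats, trans_mean=spec.trans_level)


# ---------------------------------------------------------------------------
# Plants (deterministic multiplicative edits)
# ---------------------------------------------------------------------------

def _plant_sv_arrays(e: np.ndarray, svs: list[SVRecord], bins: GenomeBins,
                     f_sv: float, taper: float) -> None:
    n = e.shape[0]
    half = int(np.ceil(3 * taper))
    for sv in svs:
        b1 = sv.bp1 // bins.bin_width
        b2 = sv.bp2 // bins.bin_width
        rows = np.arange(max(0, b1 - half), min(n, b1 + half + 1))
        cols = np.arange(max(0, b2 - half), min(n, b2 + half + 1))
        du = (rows - b1)[:, None]
        dv = (cols - b2)[None, :]
        factor = 1.0 + (f_sv - 1.0) * np.exp(-(du**2 + dv**2) / (2 * taper**2))
        e[np.ix_(rows, cols)] *= factor
        e[np.ix_(cols, rows)] *= factor.T


def plant_sv_signals(m: ContactMatrix, svs: list[SVRecord],
                     f_sv: float, taper_bins: float = 3.0) -> ContactMatrix:
    """Multiply contacts in a Gaussian-tapered neighborhood of each SV's
    (bp1, bp2) junction by ``f_sv`` (exactly ``f_sv`` at the center cell);
    symmetric update."""
    out = m.copy()
    for chrom in out.chromosomes:
        _plant_sv_arrays(out.mats[chrom],
                         [s for s in svs if s.chrom == chrom],
                         out.bins, f_sv, taper_bins)
    return out


def _plant_ecdna_array(e: np.ndarray, bins: GenomeBins, chrom: str,
                       locus: tuple[str, int, int], spec: TruthSpec,
                       decay: np.ndarray) -> None:
    idx = bins.region_bins(chrom, locus[1], locus[2])
    flank = spec.ecdna_corner_flank_bins
    head, tail = idx[:flank], idx[-flank:]
    # every local contact of the locus (internal and with the flanking
    # chromosome) is depleted; internal contacts optionally re-scaled
    e[idx, :] *= spec.ecdna_depletion
    e[:, idx] *= spec.ecdna_depletion
    e[np.ix_(idx, idx)] /= spec.ecdna_depletion  # applied once, not twice
    e[np.ix_(idx, idx)] *= spec.ecdna_amplification
    # end-to-end corner: circularization sets the absolute end-to-end contact
    # to corner_fold x the decay expectation at that separation; corner_fold
    # of 1 means no circularization and leaves the matrix untouched
    if spec.ecdna_corner_fold != 1.0:
        seps = np.abs(np.subtract.outer(head, tail))
        corner = spec.ecdna_corner_fold * decay[seps]
        e[np.ix_(head, tail)] = corner
        e[np.ix_(tail, head)] = corner.T


def plant_ecdna(m: ContactMatrix, spec: TruthSpec) -> ContactMatrix:
    """Apply the ecDNA geometry to a matrix: flank depletion, internal
    amplification, and an end-to-end corner set to ``corner_fold`` x the
    matrix's own distance-decay expectation (a fold of 1 plants nothing)."""
    from .contacts import expected_by_distance

    out = m.copy()
    locus = spec.resolved_ecdna_locus()
    if locus[0] in out.mats:
        decay = expected_by_distance(m).values[locus[0]]
        _plant_ecdna_array(out.mats[locus[0]], out.bins, locus[0], locus, spec,
                           decay)
    return out


# ---------------------------------------------------------------------------
# SVs and omics
# ---------------------------------------------------------------------------

def _draw_svs(spec: TruthSpec, rng, tads: TadSet,
              comp_layout: dict[str, np.ndarray], sample_id: str) -> list[SVRecord]:
    bins = spec.bins()
    chroms = bins.chromosomes
    lo, hi = spec.sv_size_range
    gaps = spec.gap_track().intervals
    # per-bin relative SV rate (compartment multiplier in A), for rejection
    # sampling on top of uniform gap-avoiding placement — the same placement
    # mechanism the size-matched background uses, so a null spec is null
    weights = {c: np.where(comp_layout[c] == "A", spec.sv_a_multiplier, 1.0)
               for c in chroms}
    wmax = max(float(w.max()) for w in weights.values())
    out = []
    for i in range(spec.sv_per_sample):
        sv_type = SV_TYPES[rng.integers(0, 3)]
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        placed = False
        if spec.sv_intra_tad_p is not None and rng.random() < spec.sv_intra_tad_p:
            doms = [(c, a, b) for c, a, b in tads.domains
                    if (b - a) * bins.bin_width > size + 2 * bins.bin_width]
            if doms:
                c, a, b = doms[rng.integers(0, len(doms))]
                start = int(rng.integers(a * bins.bin_width,
                                         b * bins.bin_width - size))
                chrom = c
                placed = True
        if not placed:
            room = np.array([max(0, bins.lengths[c] - size) for c in chroms],
                            dtype=float)
            p = room / room.sum()
            for _try in range(1000):
                ci = rng.choice(len(chroms), p=p)
                chrom = chroms[ci]
                start = int(rng.integers(0, int(room[ci]) + 1))
                gv = gaps.get(chrom)
                if gv is not None and gv.shape[0] and np.any(
                        (start < gv[:, 1]) & (start + size > gv[:, 0])):
                    continue
                w = weights[chrom][min(start // bins.bin_width,
                                       bins.n_bins(chrom) - 1)]
                if rng.random() < w / wmax:
                    break
            else:
                raise ValueError("could not place SV")
        good = rng.random() >= spec.sv_fail_fraction
        if good:
            pe = 10 + int(rng.poisson(15))
            sp = 10 + int(rng.poisson(15))
            germ = 0
        else:
            mode = rng.integers(0, 3)
            pe = int(rng.integers(0, 10)) if mode == 0 else 10 + int(rng.poisson(15))
            sp = int(rng.integers(0, 10)) if mode == 1 else 10 + int(rng.poisson(15))
            germ = 1 + int(rng.poisson(2)) if mode == 2 else 0
        out.append(SVRecord(sv_type, chrom, start, start + size, pe, sp, germ,
                            sample_id=sample_id))
    return out


def simulate_omics(spec: TruthSpec, rng, comp_layout: dict[str, np.ndarray],
                   narrow: bool, sample_id: str) -> OmicsTracks:
    """Expression, methylation, 5hmC, mutation and CN tracks with
    compartment- and subtype-linked effects."""
    bins = spec.bins()
    chroms = bins.chromosomes
    # genes: TSS uniform per chromosome; TPM lognormal, A-multiplied
    genes, gchrom, gtss, gtpm = [], [], [], []
    gmin, gmax, gtype = [], [], []
    for chrom in chroms:
        n = bins.n_bins(chrom)
        w = np.where(comp_layout[chrom] == "A", spec.gene_a_multiplier, 1.0)
        tss_bins = rng.choice(n, size=spec.genes_per_chrom, p=w / w.sum())
        offsets = rng.integers(0, bins.bin_width, size=spec.genes_per_chrom)
        tss = np.sort(np.minimum(tss_bins * bins.bin_width + offsets,
                                 bins.lengths[chrom] - 1))
        for k, t in enumerate(tss):
            name = f"{chrom}_g{k}"
            in_a = comp_layout[chrom][t // bins.bin_width] == "A"
            mu = spec.tpm_base * (spec.tpm_a_multiplier if in_a else 1.0)
            if narrow:
                mu *= spec.narrow_tpm_multiplier
            tpm = float(rng.lognormal(np.log(mu), spec.tpm_sigma))
            genes.append(name)
            gchrom.append(chrom)
            gtss.append(int(t))
            gtpm.append(tpm)
            cn = max(0.1, rng.normal(spec.ploidy, 0.3))
            gmin.append(cn)
            gmax.append(cn + abs(rng.normal(0.0, 0.2)))
            gtype.append("sex" if chrom in ("chrX", "chrY") else "autosomal")
    # MYC-like proxy: first gene of the first chromosome; narrow samples may
    # carry a gain
    if narrow and rng.random() < spec.myc_gain_prob_narrow:
        gmin[0] += spec.myc_gain
        gmax[0] += spec.myc_gain
    expr = ExpressionTable(genes, np.array(gchrom), np.array(gtss),
                           np.array(gtpm), sample_id)
    cn_prof = CopyNumberProfile(list(genes), np.array(gmin), np.array(gmax),
                                gtype, spec.ploidy, sample_id)

    def interval_set(rate_per_mb, a_mult, size_range, mult=1.0, b_biased=False):
        ivs = {}
        for chrom in chroms:
            n = bins.n_bins(chrom)
            lab = comp_layout[chrom]
            w = np.where(lab == ("B" if b_biased else "A"), a_mult, 1.0)
            w = w / w.sum()
            lam = rate_per_mb * bins.lengths[chrom] / 1e6 * mult
            k = rng.poisson(lam)
            if k == 0:
                ivs[chrom] = np.zeros((0, 2), dtype=np.int64)
                continue
            centers = rng.choice(n, size=k, p=w) * bins.bin_width
            sizes = rng.integers(size_range[0], size_range[1] + 1, size=k)
            starts = np.clip(centers - sizes // 2, 0, None)
            ends = np.minimum(starts + sizes, bins.lengths[chrom])
            ok = ends > starts
            ivs[chrom] = np.stack([starts[ok], ends[ok]], axis=1).astype(np.int64)
        return ivs

    hmr = IntervalTrack(
        interval_set(spec.hmr_rate_per_mb, spec.hmr_a_multiplier,
                     spec.hmr_size_range,
                     spec.narrow_hmr_multiplier if narrow else 1.0),
        role="HMR", sample_id=sample_id)
    pmd = IntervalTrack(
        interval_set(spec.pmd_rate_per_mb, spec.pmd_b_multiplier,
                     spec.pmd_size_range, b_biased=True),
        role="PMD", sample_id=sample_id)
    fivehmc = IntervalTrack(
        interval_set(spec.fivehmc_rate_per_mb, spec.fivehmc_a_multiplier,
                     spec.fivehmc_size_range,
                     spec.narrow_fivehmc_multiplier if narrow else 1.0),
        role="5hmC_peak", sample_id=sample_id)
    # mutations: per-bin Poisson, B-multiplied, width-1 intervals
    mut_ivs = {}
    for chrom in chroms:
        n = bins.n_bins(chrom)
        lab = comp_layout[chrom]
        rate = spec.mutation_rate_per_mb * (bins.bin_width / 1e6)
        lam = np.where(lab == "B", spec.mutation_b_multiplier, 1.0) * rate
        counts = rng.poisson(lam)
        pos = []
        for b in np.flatnonzero(counts):
            lo, hi2 = bins.bin_interval(chrom, int(b))
            pos.extend(int(p) for p in rng.integers(lo, hi2, size=counts[b]))
        pos = np.sort(np.array(pos, dtype=np.int64))
        mut_ivs[chrom] = np.stack([pos, pos + 1], axis=1) if pos.size else \
            np.zeros((0, 2), dtype=np.int64)
    mutations = IntervalTrack(mut_ivs, role="mutation", sample_id=sample_id)
    return OmicsTracks(expr, hmr, pmd, fivehmc, mutations, cn_prof)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(n: int, spec: TruthSpec, seed: int,
                    hic: bool = True, omics: bool = True) -> CohortBundle:
    """Generate an n-sample cohort sharing the broad TAD and compartment
    layouts, with per-sample Poisson noise, subtype labels per
    ``narrow_fraction`` and ecDNA plants per ``ecdna_fraction``."""
    bins = spec.bins()
    rng = np.random.default_rng(seed)
    broad_layout = _tad_layout(spec, rng, narrow=False)
    comp_layout = _comp_layout(spec, rng, broad_layout)
    n_narrow = int(round(n * spec.narrow_fraction))
    n_ecdna = int(round(n * spec.ecdna_fraction))
    subtype_flags = np.array([True] * n_narrow + [False] * (n - n_narrow))
    ecdna_flags = np.array([True] * n_ecdna + [False] * (n - n_ecdna))
    rng.shuffle(subtype_flags)
    rng.shuffle(ecdna_flags)
    # the narrow subtype is a recurrent architecture: its extra boundaries
    # subdividing the broad domains are drawn once and shared by all
    # narrow-subtype samples (per-sample variation comes from counting noise
    # and boundary-calling error)
    narrow_layout = {c: np.array(sorted(set(
        broad_layout[c].tolist()
        + _narrow_extra(spec, rng, bins, c, broad_layout[c]))), dtype=int)
        for c in bins.chromosomes}
    samples: list[SampleData] = []
    for i in range(n):
        sid = f"S{i:03d}"
        narrow = bool(subtype_flags[i])
        has_ecdna = bool(ecdna_flags[i])
        layout = narrow_layout if narrow else broad_layout
        tset = _layout_to_tadset(bins, layout, sid)
        ctrack = _layout_to_comptrack(spec, comp_layout, sid)
        svs = _draw_svs(spec, rng, tset, comp_layout, sid)
        mat = None
        if hic:
            good = [s for s in filter_passing(svs)]
            mat = _simulate_from_layouts(spec, rng, layout, comp_layout,
                                         has_ecdna, good)
        om = simulate_omics(spec, rng, comp_layout, narrow, sid) if omics else None
        samples.append(SampleData(sid, mat, tset, ctrack, svs, om,
                                  "narrow" if narrow else "broad", has_ecdna))
    return CohortBundle(spec, bins, samples, spec.gap_track())


def _narrow_extra(spec: TruthSpec, rng, bins: GenomeBins, chrom: str,
                  broad: np.ndarray) -> list[int]:
    cuts = [0, *broad.tolist(), bins.n_bins(chrom)]
    extra: list[int] = []
    for a, b in zip(cuts, cuts[1:]):
        if rng.random() < spec.p_narrow and b - a > 2 * spec.narrow_tad_mean_bins:
            sub = a
            for s2 in _segment_lengths(b - a, spec.narrow_tad_mean_bins,
                                       max(5, spec.narrow_tad_mean_bins // 3),
                                       rng)[:-1]:
                sub += s2
                extra.append(sub)
    return extra


def filter_passing(svs: list[SVRecord]) -> list[SVRecord]:
    """The generator-side view of which planted SVs survive the read-support
    filters (used to decide which junctions leave Hi-C signal)."""
    from .svtopo import filter_svs
    return filter_svs(svs)
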