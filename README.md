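# hictopo

Integrative 3D-genome analysis for tumor Hi-C cohorts: TAD and A/B
compartment calling, ecDNA detection by regional contact depletion,
SV–topology association against size-matched backgrounds, gene–enhancer
contact integration, and TAD-architecture subtyping — with a synthetic
cohort generator that plants known truth so every stage is testable
without any controlled-access data.

## The problem

Deep Hi-C on tumor biopsies, paired with WGS, WGBS, 5hmC-seq and
RNA-seq, lets one ask how the 3D genome interacts with somatic
alteration and expression in cancer — but the analyses sit in several
distinct statistical frames:

- **Compartments.** Per chromosome, the leading eigenvector of the
  Pearson correlation matrix of observed/expected contacts splits bins
  into open (A, eigenvector > 0, gene-dense) and closed (B) chromatin;
  NA where the decomposition is undefined. Within each sample a feature
  summary (base-fraction overlap, events per Mb, mean TPM at TSS bins)
  is computed over A and over B bins, and A vs B is tested across
  samples with a paired two-sided Wilcoxon signed-rank test,
  Benjamini–Hochberg corrected across the feature battery.
- **TADs.** TopDom-style: boundaries are local minima of the diamond
  signal `mean{ M[u,v] : u ∈ (i−w, i], v ∈ (i, i+w] }`, retained when
  their diamond is rank-sum-depleted versus same-shape flanking
  diamonds; `w` is tuned by the median within-TAD correlation of
  contact profiles.
- **RCFS / ecDNA.** The regional contact frequency sliding-window score
  — the mean contact in a `W`-bin square window around each bin — 
  collapses over loci whose DNA resides on extrachromosomal circles.
  Samples whose mean locus RCFS falls below a cohort-level cutoff are
  "depleted" (ecDNA-like); circularization additionally shows up as
  end-to-end amplicon contact far above the distance-decay expectation
  (the corner signal).
- **SV topology.** Do deletions/duplications/inversions form
  preferentially between loci that were already in contact? Each SV is
  compared with ten random gap-avoiding segments of identical size and
  type; the fraction of SVs with both breakpoints in one TAD — scored
  against *other* samples' TADs, so an SV cannot vouch for itself — is
  tested real-vs-background per type (paired Wilcoxon signed-rank).
- **Subtypes.** Samples featurized by TAD edges per Mb in 1-Mb windows
  cluster into broad vs narrow TAD architectures (two-class k-medoids in
  feature space; t-SNE for display only), with rank-sum tests of
  methylation, 5hmC, expression and copy-number differences between
  subtypes.

All of this is driven end-to-end by `hictopo.synthetic`, which generates
cohorts from a power-law contact model with planted TAD hierarchies,
compartment layouts, SV junctions, an ecDNA locus and compartment-linked
omics — and records the truth for every plant.

## Worked example

Simulate a small cohort and push one sample through the pipeline:

```python
import numpy as np
from hictopo.synthetic import TruthSpec, simulate_cohort
from hictopo.contacts import ice_normalize
from hictopo.tads import call_tads, boundary_recovery
from hictopo.rcfs import rcfs_track, default_cutoff

spec = TruthSpec(chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
                 ecdna_fraction=0.25)
bundle = simulate_cohort(8, spec, seed=7)
locus = spec.resolved_ecdna_locus()            # ('chr2', 3600000, 4400000)
lb, ub = locus[1] // 10_000, locus[2] // 10_000

means = {}
for s in bundle.samples:
    m = ice_normalize(s.matrix)
    tads = call_tads(m, w=10)
    r, p = boundary_recovery(tads.edges_bins("chr1"),
                             s.tads_truth.edges_bins("chr1"))
    means[s.sample_id] = rcfs_track(m, 50).locus_mean("chr2", lb, ub)

cut = default_cutoff(np.array(list(means.values())))
for sid, v in means.items():
    truth = next(x.ecdna for x in bundle.samples if x.sample_id == sid)
    print(f"{sid}  mean RCFS {v:6.2f}  {'depleted' if v < cut else 'typical ':8s}"
          f"  planted ecDNA: {truth}")
```

prints (cutoff 12.52):

```
S000  mean RCFS   3.07  depleted  planted ecDNA: True
S001  mean RCFS  23.83  typical   planted ecDNA: False
S002  mean RCFS   2.81  depleted  planted ecDNA: True
S003  mean RCFS  22.05  typical   planted ecDNA: False
S004  mean RCFS  20.44  typical   planted ecDNA: False
S005  mean RCFS  20.11  typical   planted ecDNA: False
S006  mean RCFS  23.44  typical   planted ecDNA: False
S007  mean RCFS  22.74  typical   planted ecDNA: False
```

The two samples carrying the planted ecDNA locus sit an order of
magnitude below the rest: their amplicon's chromosomal contact has
collapsed, which is exactly the signature the score nominates. On the
same samples the raw-count corner signal is ~11× the decay expectation
(planted fold 10) for ecDNA⁺ samples and <1 for the others.

## The analysis, step by step

Numbered drivers under `analysis/` rerun each stage on a demonstration
cohort and write their tables to `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | generate the demo cohort (text formats + truth.json, under `scratch/`) |
| `02_normalize_and_tads.py` | ICE-balance, optimize `w`, call TADs, score boundary recovery |
| `03_compartments.py` | call A/B per sample, build the cohort A:B log-ratio track |
| `04_rcfs_ecdna.py` | RCFS tracks, locus means, data-driven cutoff, corner signals |
| `05_sv_topology.py` | breakpoint signatures, same-TAD enrichment, null calibration |
| `06_integration.py` | compartment multi-omic battery; consensus peaks → candidate enhancers → contact sums |
| `07_subtypes.py` | edge-density features, broad/narrow clustering, omic associations |

The command-line entry point `hictopo` (simulate / normalize / tads /
compartments / rcfs / svtopo / subtype) wraps the same library calls for
shell use.

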