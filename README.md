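# gliosplice

Analysis pipeline linking alternative-splicing (AS) disruption to
PRMT5-inhibitor response in glioblastoma stem-cell (GSC) cohorts.

PRMT5 inhibition destabilises spliceosome function and produces widespread
mis-splicing. Studies of patient-derived GSC lines quantify this along
several computational axes, all implemented here:

- **Splicing-event filtering and consolidation** — per-sample alternative
  splicing events (cassette exons, retained introns, mutually exclusive
  exons, alternative 3'/5' splice sites) are kept when p ≤ 0.05, each of
  inclusion/exclusion has ≥ 1 supporting read, total support is ≥ 10 reads,
  and |ΔΨ| ≥ 0.10 (treated − control). Events are matched across samples
  by ≥ 95% reciprocal coordinate overlap on the same strand and class, and
  their predicted ORF impact (frameshift / in-frame / premature stop) is
  classified against transcript exon chains.
- **PSI from RT-PCR** — percent spliced in is Ψ = L/(L+S) from the
  capillary-electrophoresis concentrations of the long and short
  amplicons, the isoform pair being the two most abundant amplicon sizes
  of each assay across all samples.
- **Dose–response scoring** — the area above the curve
  AAC = ∫(1 − response) d log₁₀(dose) / (log₁₀ d_max − log₁₀ d_min) ∈ [0,1]
  over nine half-log doses (3 nM–30 µM), an EC50 from a Hill fit with top
  fixed at 1, a sensitivity call at EC50 < 250 nM, and good/poor responder
  labels from the cohort AAC.
- **Baseline splicing signature** — events quantified in ≥ 75% of samples,
  with intra-group sd < inter-group sd and |mean Ψ_good − mean Ψ_poor| ≥
  0.20, ranked by |dΨ|.
- **Proteome enrichment** — depletion of AS-affected genes among the top-k
  most downregulated proteins, as fold = k/(n·K/N) with a one-sided
  hypergeometric p, bootstrap SE over 100 row resamples, RNA–protein
  fold-change correlation, and the GSEA ranking statistic
  sign(LFC)·(−log₁₀ adjusted p).
- **Limiting-dilution analysis** — sphere-forming frequency f under the
  single-hit model P(negative | d cells) = e^(−f·d), fitted as a binomial
  GLM with complementary log-log link and log-dose offset; Wald 95% CIs,
  likelihood-ratio group-inequality test, and a free-slope single-hit
  adequacy test.

Because the cohort RNA-seq/proteomics data are controlled-access, the
package ships a first-class synthetic-data module (`gliosplice.simulate`)
that generates every input shape with planted ground truth, so the entire
pipeline is exercisable and testable end to end.

## Worked example

The published top-50 proteome-depletion statistic from its marginals — a
universe of N = 5355 detected proteins, K = 194 proteins of genes with
inclusion events, and k = 12 of them among the n = 50 most downregulated:

```console
$ gliosplice enrich --universe 5355 --set-size 194 --top 50 --overlap 12
fold=6.6 p=1.3e-07 (N=5355 K=194 n=50 k=12)
```

The fold is k over its null expectation n·K/N = 1.81, i.e. the gene set is
6.6× over-represented among the most depleted proteins; p is the one-sided
hypergeometric upper tail.

A limiting-dilution assay on the standard dilution scheme (2000 → 4
cells/well, six wells per dose), simulated at sphere-forming frequencies
0.02 (vehicle) and 0.004 (drug):

```python
from gliosplice import simulate as sim
from gliosplice.lda import fit_single_hit, test_frequency_difference

dmso, _ = sim.gen_lda(0.02, seed=1, arm="DMSO")
drug, _ = sim.gen_lda(0.004, seed=2, arm="LLY-283")
fa, fb = fit_single_hit(dmso), fit_single_hit(drug)
chi2, df, p = test_frequency_difference(dmso, drug)
```

which prints (via the `lda` subcommand on the same counts):

```
DMSO f=0.0263 (1 in 38), CI 0.0155-0.0446
LLY  f=0.0039 (1 in 254), CI 0.0023-0.0066
inequality chi2=24.43 df=1 p=7.70e-07
```

The fitted frequencies bracket their simulated truths, and the
likelihood-ratio test detects the ~5-fold drop in sphere-forming capacity.
A dose–response series simulated at EC50 = 15 nM with 2% response noise
summarises as `AAC=0.806 EC50=14.4 nM` — a sensitive line (EC50 < 250 nM).

Every pipeline stage is also available as a CLI subcommand
(`simulate`, `filter-ase`, `consolidate`, `impact`, `psi-rtpcr`,
`dose-response`, `signature`, `enrich`, `gsea-rank`, `lda`); run
`gliosplice --help`.

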