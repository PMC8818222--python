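# csfcirc

Circular-RNA (circRNA) analysis for cerebrospinal-fluid (CSF) liquid
biopsies, built for cohorts of lung-adenocarcinoma patients with brain
metastases in which CSF, plasma and tumor tissue were RNA-sequenced in
parallel.

CircRNAs arise from back-splicing — a downstream splice donor joined to an
upstream acceptor, producing a covalently closed circle. Because free
circRNAs crossing into the CNS are filtered by the blood–brain barrier,
CSF circRNAs shared with the tumor are attractive brain-metastasis
biomarkers. This package implements the full desk-side analysis:

- **Back-splice calling** (`csfcirc.chimeric`): parse STAR-compatible
  chimeric-junction records; a read is back-splice evidence iff both
  segments share chromosome and strand and the acceptor lies upstream of
  the donor in transcript orientation. Junctions are annotated by
  exon-boundary matching against BED12 gene models and merged into a
  cohort junction × sample count matrix.
- **Quantification** (`csfcirc.quantify`): TMM normalization factors from
  the linear-gene counts; FPKM = count · 10⁹ / (L · N · f) with L the
  exon-union length for genes and the circRNA-specific effective length
  **L = 2·(read_length − anchor_size)** for circles (only junction-spanning
  windows are unbiased evidence for a circle). circRNA FPKM always uses the
  *same sample's linear* library size N and TMM factor f.
- **Profiling** (`csfcirc.profiling`): per-sample species counts
  (junctions with count > 0), compartment comparisons by rank tests,
  shared-species tables (log₂ with pseudocount 1), Pearson correlation
  with t-based p, and an ordinal trend test across therapy lines.
- **Screening** (`csfcirc.screening`): the candidate cascade — CSF-detected
  junctions, minus a normal-brain exclusion list, intersected with
  junctions recurring in tumor tissue of ≥ 2 distinct patients — then
  per-patient candidate-detection burden dichotomized at the top-25%
  nearest-rank cutoff into circRNA-abundant (> cutoff) vs -deficient
  (≤ cutoff) groups.
- **Sponge network** (`csfcirc.sponge`): junction probes (30-nt flanks
  reverse-joined across the back-splice joint), a miRanda-style duplex
  scorer (WC +5 / G:U +1 / mismatch −3, affine gaps −9/−4, seed positions
  2–8 weighted ×4; hits require score > 170 and energy < −30, strict seed),
  7mer-m8/8mer seed matching in 3'UTRs, co-expression edges at
  |r| ≥ 0.70 & p < 0.01, tripartite network assembly, and hypergeometric
  over-representation with BH q-values.
- **Survival** (`csfcirc.survival`): Kaplan–Meier with the NR (not-reached)
  median convention, reverse-KM median follow-up, log-rank tests, Cox
  proportional hazards (Efron ties, via lifelines) in univariate and
  multivariate (age, sex, smoking, extracranial metastasis) modes, and a
  per-candidate survival scan.
- **Synthetic cohorts** (`csfcirc.simulate`): a deterministic generator
  emulating the study structure — 21 patients (19 CSF / 21 plasma / 15
  tissue), CSF with fewer circRNA species but higher abundance and high
  inter-patient heterogeneity, planted candidates that survive the cascade
  by construction, junction-spanning miRNA sites, burden-dependent
  survival hazard, and ctDNA anti-correlated with circRNA abundance.

## Worked example

Simulate a 21-patient cohort, screen for candidates, and test survival:

```sh
csfcirc simulate --outdir full --seed 7
csfcirc screen --circ-counts full/circ_counts.tsv --samples full/samples.csv \
               --exclude full/exclusion.tsv --outdir fullscreen
csfcirc survive --clinical full/clinical.csv --outdir fullsurv
```

The screen step prints

```
cascade: 186 CSF -> 126 after exclusion -> 12 candidates (cutoff 8)
```

meaning 186 circRNA species were detected in CSF, 126 survived the
normal-brain exclusion list, 12 also recurred in ≥ 2 patients' tumor
tissue (exactly the planted candidate set for this seed), and the top-25%
burden cutoff landed at 8 detected candidates. The survival step prints

```
{
  "median_os_months": 8.951,
  "median_followup_months": 25.62,
  "n": 21,
  "n_events": 12,
  "logrank_chi2": 8.69024378564077,
  "logrank_p": 0.0031991783212769746
}
```

— the circRNA-abundant group (simulated true hazard ratio 3) dies faster
than the deficient group (log-rank p ≈ 0.003), and the univariate Cox fit
in `fullsurv/cox_univariate.tsv` estimates HR ≈ 6.4 (95% CI 1.6–26) for
abundance, consistent with the planted effect at this cohort size.

The same steps are available as library calls
(`simulate.simulate_cohort`, `screening.screen`, `survival.cox_fit`, …);
the CLI is a thin wrapper.

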