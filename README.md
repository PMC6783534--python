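# fluorosig

Mutational-signature analysis of fluoropyrimidine (5-FU) mutagenesis in
human cells. 5-FU chemotherapy leaves a characteristic scar in the
genome: T>G mutations in a CTT trinucleotide context (C[T>G]T), the
pattern known as COSMIC signature 17. `fluorosig` implements the full
computational chain used to identify, quantify and interpret such a
signature from somatic variant calls, for researchers analyzing tumor or
organoid whole-genome sequencing:

- **96-context catalogs** — classify SBSs into the 96 pyrimidine-centered
  trinucleotide classes from VCF + reference FASTA, with the clonal VAF
  window (0.3–0.7), autosome restriction, tumor mutational burden
  (SBS / (2,858,674,662/10⁶) per Mbp) and hypermutant (>10/Mbp) exclusion,
  plus 11-base extended-context matrices for logo-style flank analysis.
- **Signature extraction and refitting** — de novo NMF (generalized KL
  divergence, multiplicative updates) with consensus clustering and
  cophenetic rank selection; cosine-similarity matching to reference
  sets; per-sample NNLS refitting into absolute and relative exposures;
  difference spectra and Wilcoxon cohort contrasts.
- **Per-mutation attribution** — the likelihood that signature x caused a
  mutation of class c, eₓpₓ(c)/Σₛeₛpₛ(c); origins assigned above a 0.5
  likelihood; cohort-cumulative attribution; export of assigned variants
  for downstream selection analysis.
- **Clonality timing** — variant ploidy (adjusted VAF × copy number), KDE
  peak detection (bandwidth 0.05) of subclonal modes, clonal/subclonal
  classification, and the clonal-vs-subclonal signature contrast.
- **Strand bias** — replication (leading/lagging) and transcription
  strand assignment of C[N>N]T mutations, 12-category count matrices,
  and the exact two-sided conditional Poisson (binomial) asymmetry test.
- **Paired biopsies** — median-of-ratios normalization per patient pair
  and a per-mutation-type linear mixed-effects scan (patient random
  intercept, dose/time covariates) for treatment enrichment.
- **Driver risk model** — expected driver-activating mutations
  M_active = 0.015 · dp · N · μ · Σ_c P_c n_c / L, scenario fold changes
  (treatment vs baseline mutation rates), treatment-equivalent years,
  and germline-predisposition (second-hit) scenarios.
- **Synthetic data** — seeded generators for every input above with
  planted ground truth, so the entire pipeline is testable without any
  external or controlled-access data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Extract and refit signatures on a synthetic 12-sample cohort whose
mutations were drawn from three known signatures:

```python
import numpy as np
from fluorosig import synthetic_data as syn
from fluorosig import signatures as sig

sigs = syn.make_signature_set(seed=0)              # sig17like, flat, random1
rng = np.random.default_rng(42)
exposures = rng.dirichlet(np.ones(3), 12).T * 3000  # planted mixing
catalog = syn.sample_catalog(sigs, exposures, seed=42)

res = sig.nmf_factorize(catalog, rank=3, seed=7)
matches, _ = sig.match_to_reference(res.signature_matrix(), sigs)
print(matches.to_string(index=False))

rel = sig.relative_contribution(sig.refit_nnls(catalog, sigs))
print(rel.round(3).iloc[:, :4].to_string())
```

```
 denovo best_match   cosine
denovo1  sig17like 0.974904
denovo2       flat 0.891081
denovo3    random1 0.995255
           sample1  sample2  sample3  sample4
sig17like    0.344    0.167    0.292    0.479
flat         0.311    0.043    0.671    0.037
random1      0.346    0.790    0.037    0.484
```

Each de novo NMF component matches its planted signature (the flat
profile scores lowest because it overlaps the sig17like uniform floor),
and the NNLS relative contributions track the planted per-sample mixing
proportions (Pearson r = 0.995 on this cohort). The same objects drive
the command line:

```bash
fluorosig simulate catalog --seed 3 --out sim/
fluorosig catalog --vcf sim/variants.vcf --ref sim/reference.fa --out cat.tsv
fluorosig extract --catalog cat.tsv --rank 3 --runs 20 --seed 7 --out denovo.tsv
fluorosig refit --catalog cat.tsv --signatures sim/signatures.tsv --out exp.tsv
```

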