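# hedratio

HLA evolutionary divergence (HED) scoring and outcome analysis for
allogeneic hematopoietic stem-cell transplantation (HCT) cohorts.

## The problem

The two alleles a person carries at each HLA locus jointly define the set
of peptides their cells can present to T cells. The more physicochemically
divergent the two allele sequences are within their peptide-binding
domains, the broader the presented immunopeptidome — the "divergent allele
advantage". HED quantifies this divergence per locus and per HLA class,
and the class I/class II HED ratio has been proposed as a prognostic
marker for disease-free and overall survival after allogeneic HCT in
acute myeloid leukemia. `hedratio` provides the full toolchain for this
kind of study: the divergence metric, per-subject profiling, and the
survival-analysis pipeline, plus a synthetic-cohort generator so that
every stage is testable without access to patient data.

## The metric

The divergence between two aligned protein sequences is the per-site mean
Grantham distance. For residues *i*, *j* with composition *c*, polarity
*p* and side-chain volume *v*:

```
d(i, j) = ρ · [α (c_i − c_j)² + β (p_i − p_j)² + γ (v_i − v_j)²]^½
```

with α = 1.833, β = 0.1018, γ = 0.000399 and the normalising constant
ρ = 50.723 that calibrates the mean over the 190 distinct residue pairs
to 100 (the scale of the classical integer matrix). A subject's HED at a
locus is this divergence between their two allele sequences over the
peptide-binding domain (exons 2+3 for HLA-A/B/C, exon 2 for
HLA-DRB1/DQB1/DPB1); class means average the loci of each class, and four
ratio scores combine them, the headline one being
`score1 = class I mean / class II mean`.

The analysis pipeline mirrors a registry-style study: exclusion of deaths
before day 14, DFS/OS endpoint derivation, a stratified train/test split,
univariate Cox screening with Benjamini–Hochberg FDR control, a
multivariable Cox screen of each HED variable against fixed clinical
controls, backward-stepwise final models, Aalen–Johansen cumulative
incidence with death as a competing risk, and logistic models of
lymphocyte-subset recovery.

## Worked example

```python
import numpy as np
from hedratio import (build_grantham_matrix, residue_distance,
                      simulate_cohort, apply_exclusions, derive_endpoints,
                      stratify, final_model)

matrix = build_grantham_matrix()
print("d(L, I) =", round(residue_distance("L", "I", matrix), 2))
print("d(C, W) =", round(residue_distance("C", "W", matrix), 2))
print("mean over 190 pairs =", round(matrix.mean_pair_distance(), 2))

res = simulate_cohort(seed=1, n_subjects=1000, score1_log_hr=float(np.log(0.4)))
cohort = derive_endpoints(apply_exclusions(res.cohort))
print("analyzable subjects:", len(cohort))
print("mean class I HED:", round(cohort["classI_mean"].mean(), 2))
print("mean class II HED:", round(cohort["classII_mean"].mean(), 2))

cohort["score1_group"] = stratify(cohort["score1"], "median")
fm = final_model(cohort, "score1_group", "DFS")
row = fm[fm.term == "score1_group"].iloc[0]
print(f"high vs low score1: HR {row.hr:.2f} "
      f"[95% CI {row.ci_lower:.2f}-{row.ci_upper:.2f}], p = {row.p:.1e}")
```

prints

```
d(L, I) = 4.86
d(C, W) = 214.36
mean over 190 pairs = 99.87
analyzable subjects: 955
mean class I HED: 7.2
mean class II HED: 9.94
high vs low score1: HR 0.36 [95% CI 0.31-0.42], p = 7.2e-37
```

Leucine–isoleucine is the most similar residue pair and
cysteine–tryptophan the most distant; the matrix mean sits at its
calibration value. The generated cohort reproduces the expected HED
magnitudes (class II more divergent than class I), and the
backward-stepwise Cox model recovers the injected protective effect of a
high class I/class II ratio (true hazard ratio 0.4) from the simulated
survival data.

The same stages are available from the shell:

```sh
hedratio simulate --seed 1 --n 492 --out sim/
hedratio compute  --genotypes sim/genotypes.tsv --alleles sim/store.fasta \
                  --out profiles.tsv
hedratio analyze  --cohort sim/cohort.tsv --profiles sim/profiles.tsv \
                  --out results/
```

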