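# trbrep

Analysis of T-cell receptor β-chain (TRB) immune repertoires from amplicon
sequencing: read quality control, V(D)J segment annotation with CDR3
junction extraction, clonotype assembly, diversity and V–J gene-usage
statistics, and tumor-vs-normal cohort comparison — plus a ground-truthed
repertoire simulator so the whole pipeline is testable without access to
patient data.

## Who this is for

Immunogenomics analysts profiling the T-cell compartment of paired tissue
samples (for example tumor and adjacent normal liver tissue in
hepatocellular carcinoma), where the questions are: how diverse is the
repertoire in each tissue, which TRBV/TRBJ segments are differentially
used between groups, and how does repertoire diversity track clinical
covariates such as LDH, NLR, or ALC.

## The statistics at the core

A sample's repertoire is a clonotype table keyed by
(CDR3aa, V call, J call), where the CDR3 junction is *anchor-inclusive*:
the amino-acid span from the V segment's conserved second cysteine through
the J segment's conserved phenylalanine, so every productive junction
reads `C…F`. Diversity indices collapse to unique CDR3aa frequencies
`p₁…p_R`:

- Shannon entropy `H = −Σ pᵢ ln pᵢ` (nats)
- clonality `1 − H / ln R`
- Simpson dominance `D = Σ pᵢ²`
- CF100: cumulative frequency of the 100 most abundant clonotypes
- D50: `k / R`, with `k` the smallest number of top clonotypes covering
  half the reads

Usage statistics work on read-level calls over the full 58 V × 14 J gene
space (812 cells), collapsible from 58 V subfamilies to 28 V families.
Group comparisons use the two-sided Mann–Whitney U test (exact by
enumeration for combined n ≤ 12 without ties, otherwise the tie- and
continuity-corrected normal approximation) with Benjamini–Hochberg
adjusted p-values reported alongside raw ones; clinical correlations use
the Spearman rank test; J-family structure comes from average-linkage
hierarchical clustering of usage columns. Segment calls come from an
in-package local aligner (match +1, mismatch −1, gap −2, deterministic
tie-breaking), validated against a brute-force enumeration oracle.

## Worked example

Simulate the default two-group cohort (13 tumor, 9 normal; TRBV16 and
TRBV7-6 usage shifted +0.05 in tumor; Shannon-entropy–LDH rank coupling
−0.8 in tumor) and compare the groups:

```python
from trbrep import (
    CohortEffects, SimulationParams, compare_diversity, compare_usage,
    correlate_clinical, diversity_profile, load_bundled_reference, make_cohort,
)

ref = load_bundled_reference()
params = SimulationParams(n_clones=2000, read_depth=20_000)
cohort, truths, manifest = make_cohort(ref, n_tumor=13, n_normal=9,
                                       effects=CohortEffects(), params=params, seed=42)

profile = diversity_profile(cohort[0])
print(f"{profile.sample_id}: SE={profile.shannon_entropy:.3f} "
      f"clonality={profile.clonality:.3f} CF100={profile.cf100:.3f} "
      f"D50={profile.d50:.3f} clonotypes={profile.n_clonotypes}")

se = compare_diversity(cohort, "shannon_entropy")
print(f"SE tumor {se.mean_a:.2f}+/-{se.sd_a:.2f} vs normal {se.mean_b:.2f}+/-{se.sd_b:.2f}, "
      f"U={se.u_statistic:.0f}, p={se.p_value:.3f}")

usage = compare_usage(cohort, ref, "v_subfamily").set_index("feature")
for v in ("TRBV16", "TRBV7-6"):
    row = usage.loc[v]
    print(f"{v}: tumor {row.mean_a:.4f} vs normal {row.mean_b:.4f}, "
          f"p={row.p_value:.4f}, BH={row.p_adjusted:.4f}")

ldh = correlate_clinical(cohort, "shannon_entropy", "LDH")
print(f"SE~LDH: tumor rho={ldh['tumor'].rho:.3f} (p={ldh['tumor'].p_value:.4f}), "
      f"normal rho={ldh['normal'].rho:.3f} (p={ldh['normal'].p_value:.4f})")
```

Output:

```
T01: SE=6.694 clonality=0.103 CF100=0.369 D50=0.105 clonotypes=1742
SE tumor 6.16+/-0.60 vs normal 6.01+/-0.93, U=55, p=0.841
TRBV16: tumor 0.0555 vs normal 0.0050, p=0.0001, BH=0.0031
TRBV7-6: tumor 0.0908 vs normal 0.0082, p=0.0001, BH=0.0031
SE~LDH: tumor rho=-0.819 (p=0.0006), normal rho=-0.117 (p=0.7650)
```

Reading this: diversity does not differ between the groups (p = 0.84, as
built into the template), the two shifted V segments are detected with
usage ten-fold higher in tumor, and the planted negative entropy–LDH
correlation is recovered in the tumor group (ρ = −0.82) but not in the
normal group.

The same flow is available from the shell:

```bash
trbrep simulate --out cohort_dir --seed 1        # FASTQ + metadata + truth
trbrep annotate --fastq cohort_dir/T01.fastq --sample-id T01 --out run
trbrep stats --airr run/T01/clonotypes.airr.tsv
trbrep compare --metadata cohort_dir/metadata.tsv --out run
trbrep all --out demo --seed 1                   # small end-to-end demo
```

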