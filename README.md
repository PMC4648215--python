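# tcrskin

Analysis of T-cell receptor (TCR) CDR3 repertoires from skin biopsies,
built around a three-group comparison of healthy skin with psoriatic
non-lesional and lesional skin, for both the β-chain (αβ T-cells,
sequenced from genomic DNA) and the γ-chain (γδ T-cells, from cDNA).

The scientific question behind the design: is the dense T-cell
infiltrate of a psoriatic plaque dominated by a handful of expanded
clones responding to a shared antigen, or is it a broad polyclonal
influx? The package answers it with clonotype richness and clonality,
V/J gene usage, within-patient clone tracking between non-lesional and
lesional tissue, pairwise repertoire overlap pooled by group, and
cross-patient public-clone detection — plus group inference (unpaired
Student's t-tests, one-way ANOVA, means ± SEM) and a synthetic cohort
generator so the whole pipeline is testable without any sequencing
data.

## Core statistics

For a sample with `N` unique clones with frequencies `P_i`
(count over total count):

- Shannon entropy `H = −Σ P_i log2 P_i` (bits), maximal at
  `H_max = log2 N` for a uniform repertoire;
- normalized entropy `H_N = H / H_max`, an evenness measure robust to
  sequencing depth;
- clonality `C = 1 − H_N`: 0 for a perfectly even polyclonal
  repertoire, 1 when a single clone carries the whole sample (a
  singleton repertoire is assigned `C = 1` by convention).

Repertoire overlap between two samples is the Jaccard index on unique
clone keys (shared / union; shared-over-smaller and Morisita–Horn are
options). Clone identity is `nt_vj` (CDR3 nucleotide + V + J, the
vendor-style clonotype) for within-cohort and within-patient analyses,
and `aa_only` (CDR3 amino acid) for cross-patient sharing, where
convergent recombination makes the amino-acid junction the meaningful
unit. When all pairwise overlaps are pooled into comparison groups
(NN, N-NL, N-LS, NL-NL, NL-LS, LS-LS), within-patient NL-LS pairs are
excluded so within-patient sharing cannot inflate the between-patient
NL-LS group.

## Worked example

Simulate a γ-chain cohort at the study design (7 normal / 5
non-lesional / 8 lesional samples, 5 patients contributing a paired
non-lesional + lesional biopsy) and run the full pipeline:

```python
import tcrskin as tk

cfg = tk.study_config("TRG", seed=42)          # γ-chain study defaults
cohort = tk.simulate_cohort(cfg)
tk.write_cohort(cohort, "demo/cohort", "immunoseq")
report = tk.run_pipeline(
    tk.RunConfig(manifest="demo/cohort/manifest.tsv", out_dir="demo/results")
)
```

Group means from `demo/results/TRG_diversity.tsv` for this seed:

```
               n_unique  clonality
lesional      1463.2500     0.0814
non_lesional   520.6000     0.0612
normal         403.4286     0.0746
```

Lesional skin carries ~3.6-fold more unique γ clonotypes than normal
skin at comparable (low) clonality — a polyclonal expansion, not the
outgrowth of a few clones. The pipeline's inference block confirms the
richness difference (`unique_count` normal vs lesional: t = −10.910,
p = 6.5e−08) while the clonality tests stay non-significant. Pooled
amino-acid overlap is zero for every comparison involving normal skin
and positive only among psoriatic samples (LS-LS 0.00104, NL-LS
0.00154, NL-NL 0.00295; ANOVA F = 1262.9, p ≈ 1.6e−137), driven by the
three public γ clones the generator injects into every psoriatic
sample; `public_clones.lesional.n_common_clones = 3` recovers them.

The same stages are available from the shell:

```sh
tcrskin simulate --chain TRG --seed 42 --out demo/cohort
tcrskin run --manifest demo/cohort/manifest.tsv --out demo/results
tcrskin diversity --manifest demo/cohort/manifest.tsv
tcrskin public --manifest demo/cohort/manifest.tsv --scope lesional
```

Real data is read from immunoSEQ-style exports (`--dialect immunoseq`)
or AIRR Rearrangement TSVs (`--dialect airr`) via a cohort manifest
(TSV: sample_id, patient_id, group, chain, source_material, path).

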