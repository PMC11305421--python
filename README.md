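# abca4func

Functional scoring and ACMG-AMP classification of *ABCA4* variants.

Biallelic pathogenic variants in *ABCA4*, the retina-specific ATP-binding
cassette transporter that flips *N*-retinylidene-PE out of photoreceptor disc
membranes, cause Stargardt disease and related retinal dystrophies
(ABCA4-RD). Clinical sequencing of these patients routinely surfaces missense
variants of unknown significance (VUS). One productive way to resolve them is
to express each variant in HEK293T cells, measure its protein expression by
Western blot and its substrate-stimulated ATPase activity by a luminescence
assay, condense the result into a single functional index, and feed that
index — together with computational and population evidence — into the
ACMG-AMP classification framework.

`abca4func` implements the desk side of that workflow for geneticists and
variant curators:

* **Assay normalization** (`abca4func.assay`): replicate Western-blot
  densitometry (with a loading control) and ADP-Glo ATPase luminescence
  (basal, substrate-stimulated, 0-hour background) are normalized within each
  experiment to that experiment's wild type, then summarized as mean ± SD
  across independent experiments.
* **The F-index** (`abca4func.findex`): with `E` the variant's relative
  expression (fraction of WT) and
  `S = (stim_var − basal_var) / (stim_WT − basal_WT)` its relative
  substrate-stimulated activity,

  ```
  F = E × S
  ```

  F ≈ 1 is WT-like; F ≈ 0 means no expression and/or no stimulation.
  Severity bands: F < 0.15 severe, 0.15–0.50 moderate, ≥ 0.70 normal/mild,
  with the unnamed gap (0.50, 0.70) reported explicitly as *indeterminate*.
* **Evidence assignment** (`abca4func.evidence`): PS3 for F < 0.5,
  BS3_supporting for F ≥ 0.9; PP3/BP4 from REVEL (≥ 0.7 / ≤ 0.4, missense) or
  SpliceAI (< 0.2 plus no auxiliary novel-splice-site prediction, intronic);
  PM2_supporting from gnomAD (AF ceiling, ≤ 3 homozygotes); PM5 from
  same-residue P/LP ClinVar records gated on REVEL. PVS1, PM3, PP5, BP2, BP5
  and externally derived PS3 strengths are pass-through inputs.
* **Five-tier combination** (`abca4func.combiner`): PM2_supporting is ignored
  when it is the only pathogenic evidence against benign evidence; remaining
  conflicting evidence is scored by points (supporting 1, moderate 2,
  strong 4, very strong 8; bands ≥ 10 / 6–9 / 0–5 / −1..−6 / ≤ −7);
  unidirectional evidence goes through the classical categorical tables.
  Hypomorphic alleles are reported as NA, outside the five-tier system.
* **Nomenclature** (`abca4func.hgvs`): a small, strict HGVS subset parser
  (substitutions, intron offsets, del/dup, protein changes including
  frameshift and dual-effect records). Anything it cannot parse raises rather
  than guessing.
* **Synthetic data** (`abca4func.simulate`): a seeded generator of replicate
  tables with known true (E, S), lognormal measurement noise and
  Monte-Carlo recovery reports, so the whole pipeline is testable without any
  wet-lab data.
* **Study fixtures** (`abca4func.fixtures`): the ten characterized ABCA4
  missense VUS with their published functional summaries, evidence inputs,
  expected classifications and patient genotypes.

## Worked example

Regenerate the functional table from the packaged replicate fixtures and
classify all 23 variants carried by the ten patients:

```bash
python - <<'EOF'
from abca4func import fixtures
from abca4func.io import write_tsv
fixtures.make_fixture_tables("demo")
write_tsv(fixtures.printed_findex_frame(), "demo/findex.tsv")
EOF
abca4func findex --expression demo/expression_replicates.tsv \
                 --atpase demo/atpase_replicates.tsv --out demo/functional.tsv
abca4func classify --annotations demo/annotations.tsv \
                   --findex demo/findex.tsv --out demo/verdicts.tsv
```

`demo/functional.tsv` (excerpt):

```
variant_id   rel_expression  rel_basal  rel_stimulated  F_index  predicted_severity
WT           100             100        171 ± 14        1.00     Normal/mild
c.1244A>C    72 ± 11         58 ± 9     56 ± 10         -0.02    Severe
c.1928T>G    121 ± 12        83 ± 6     115 ± 15        0.48     Moderate
c.2396C>T    43 ± 5          70 ± 13    99 ± 16         0.17     Moderate
c.614G>T     50 ± 11         41 ± 10    42 ± 1          0.00     Severe
```

Each row is a variant's expression and ATPase activity relative to wild type
(mean ± SD over three experiments). `c.614G>T p.(Cys205Phe)` expresses at 50%
of WT and shows no substrate stimulation (42 vs 41), hence F = 0.00 —
functionally severe. `c.1928T>G p.(Val643Gly)` expresses normally but
stimulates at less than half the WT window: F = 0.48, functionally moderate.

`demo/verdicts.tsv` (excerpt):

```
variant_id   subscores                               classification     points
c.317A>T     PM2_sup, BP4, BS3_sup                   Likely benign      .
c.514G>A     PM3_strong, PM2_sup, BP2, BP5, BS3_sup  VUS                2.0
c.614G>T     PS3, PM3, PM5, PM2_sup, PP3, PP5        Pathogenic         .
c.1244A>C    PS3, PM2_sup, PM3_sup, PP3              Likely pathogenic  .
```

`c.317A>T p.(Tyr106Phe)` carries only rarity evidence in the pathogenic
direction, so PM2_sup is dropped and the two supporting benign codes give
*Likely benign*. `c.514G>A p.(Gly172Ser)` has genuinely conflicting evidence
and is scored by points (4 + 1 − 3 = 2 → VUS). The run reproduces the
published verdict census — 7 pathogenic, 4 likely pathogenic, 5 likely
benign, 6 VUS and 1 hypomorphic NA — which `abca4func reproduce-study
--out-dir out/` checks row by row, exiting nonzero on any mismatch.

A per-patient view joining verdicts onto the genotype fixture:

```bash
abca4func genotype-report --genotypes demo/genotypes.tsv \
    --classifications demo/verdicts.tsv --out demo/patients.tsv
```

## Layout

```
src/abca4func/
  assay.py       replicate normalization and summaries
  findex.py      E, S, F = E*S, severity bands, SD propagation
  hgvs.py        strict HGVS subset parser
  annotation.py  annotation records and TSV/VCF input
  evidence.py    ACMG evidence assignment (PS3/BS3, PP3/BP4, PM2, PM5)
  combiner.py    five-tier combination with conflict points
  simulate.py    seeded synthetic-data generator and recovery experiments
  fixtures.py    packaged study tables (synthetic replicate reconstructions)
  cli.py         click CLI: findex / classify / genotype-report / simulate /
                 reproduce-study
docs/methods.md  model, assumptions, numerical choices, limitations
```
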