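# karyomorph

Karyomorphometric analysis of plant chromosome measurements: from
per-chromosome arm lengths measured on mitotic metaphase plates to mean
haploid karyotypes, centromere-position classes, karyotype asymmetry
statistics, idiograms, and distance-based cytotaxonomic comparison
(UPGMA clustering and principal coordinate analysis).

## What it computes

Given a table of short/long arm lengths (µm) per chromosome, per plate,
per accession, the pipeline:

1. canonicalizes arms (short arm `p` ≤ long arm `q`) and validates plates
   against the somatic number 2n;
2. pairs homologs within each plate by minimum-cost matching on length and
   centromeric index, and averages the pairs arm-wise;
3. averages the sorted haploid complements rank-wise across plates into a
   mean haploid karyotype;
4. derives, per accession: the karyotype formula (m/sm/st/t tally by arm
   ratio intervals, boundaries to the less asymmetric class), total haploid
   chromosome length (THCL), chromosome length range (CLR), the asymmetry
   indices CV_CL, CV_CI (coefficients of variation ×100, sample SD by
   default) and M_CA (100 · mean (q−p)/(q+p)), and the two-way
   quali-quantitative symmetry class (1–4 × A–C);
5. compares accessions over the six quantitative parameters
   (x, 2n, THCL, M_CA, CV_CL, CV_CI): Euclidean UPGMA with cophenetic
   correlation, cluster extraction at a cut height, Newick/SVG export, and
   Gower-similarity PCoA with per-axis variance shares;
6. renders mean haploid idiograms (short arm up, decreasing length) as
   deterministic SVG.

A synthetic-measurement generator (`karyomorph.synthetic_data`) produces
datasets with known ground truth (homolog pairs, per-plate condensation
scaling, lognormal arm noise) so every stage is testable without raw data.
The package ships a 16-accession reference karyotype table
(`karyomorph/data/daucus_reference.csv`) of *Daucus* accessions and one
outgroup, used by the comparison pipeline and the acceptance report.

## CLI

```bash
# summarize accessions from a measurement table
karyomorph karyotype measurements.csv --out out/ --sd sample --pairing matched

# compare accessions from a parameter table (UPGMA + PCoA + scatter)
karyomorph compare out/summary.csv --cut 12.5 --out out/

# generate synthetic measurements with ground truth
karyomorph simulate specs.csv --seed 1 --out out/

# idiograms only
karyomorph idiogram measurements.csv --out out/
```

Measurement files are CSV with columns
`accession,plate,chromosome,short_arm_um,long_arm_um`; parameter files need
`accession,2n,thcl,m_ca,cv_cl,cv_ci` (`x` derived as 2n/ploidy when
absent). Lines starting with `#` are comments; every CLI output starts
with a provenance header (version, config hash, seed). A `key = value`
config file can pre-set any flag via `--config`; explicit flags win.

Switchable conventions: `--sd {sample,population}`,
`--pairing {matched,sorted}`, `--averaging {absolute,relative}`,
`--standardize` (z-score before Euclidean distances),
`--gower-distance {sqrt,linear}` and
`--variance-denominator {positive,absolute}` (the latter pair reproduces
the conventions of legacy ordination software).

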