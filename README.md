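# ssadrive

Stochastic simulation and analysis of an X-linked CRISPR homing gene
drive that removes itself by single-strand annealing (SSA), restoring a
marker-bearing, drive-resistant wild-type allele.

The package models the locus as six allele states — susceptible wild
type (`W`), intact drive (`G`), in-frame (`U`) and out-of-frame (`R`)
NHEJ resistant alleles, the SSA excision product carrying the
engineered PAM marker (`V`), and drive with a disrupted internal cut
site (`S`) — and provides:

- **`germline`** — the per-allele repair-outcome probability tree
  (cutting `q`, HR conversion `p`, in-frame split `delta`, sex-specific
  SSA excision `alpha`, cut-site disruption `gamma`, marker retention
  `epsilon`) plus zygotic nuclease effects.
- **`phenotypes`** — genotype → (body colour, EGFP, RFP) scoring for
  plain (`yMCR`) and self-excising (`yReMEDE`) drive variants.
- **`population`** — discrete-generation X-linked dynamics with release
  scenarios and phenotype-dependent mating weights: a stochastic
  fixed-census multinomial engine (`simulate`) and the exact
  infinite-population recursion (`expected_trajectory`) used as its
  oracle.
- **`cage`** — cage-trial protocol emulation (seed pool → brood → two
  disjoint 150-fly score/seed pools) and elimination-time measurement.
- **`crosses`** — pair-mated cross tabulation (phenotypes and sequenced
  allele classes by parental origin), courtship index, and exact
  binomial mating-cost estimation.
- **`calibration`** — multinomial maximum-likelihood fitting of
  germline parameters from cross count tables, with multi-start
  bounded optimisation and parametric-bootstrap intervals.
- **`synth`** — synthetic cross datasets, cage score sheets and
  courtship assay records drawn from the same exact category laws the
  analysis assumes.

## Command line

All verbs live under one entry point:

```sh
ssadrive simulate --preset fig6d --seed 1 --out runs/fig6d
ssadrive plot     --preset fig6d --seed 1 --out runs/fig6d/fig.png
ssadrive cage     --preset cage_yremede --replicates 30 --seed 1 --out runs/cage
ssadrive synth crosses --alpha-female 0.1 --full-span --n-crosses 10 \
    --seed 1 --out crosses.csv
ssadrive analyze-crosses crosses.csv --out summary.json
ssadrive calibrate crosses.csv --free alpha_female,delta --out fit.json
ssadrive synth courtship --n 30 --out courtship.csv
```

`simulate` writes tidy per-replicate trajectories
(`replicate, generation, state, frequency`), the mean trajectory and a
JSON manifest (config + seed + version). `plot` renders the two-panel
figure (five randomly chosen replicates | replicate mean, one line per
allele class).

### Configuration files

YAML mappings; a `preset` key expands to a full parameter set that any
other key overrides, and unknown keys are rejected:

```yaml
preset: fig6d
replicates: 100
germline:
  epsilon: 0.5
```

Release presets (N=1000, 10% release, 100 replicates, no mating
costs): `fig6a` (plain homing drive with resistant alleles), `fig6b`
(10% SSA, full marker retention, resistant alleles on), `fig6c` (30%
SSA, quarter retention), `fig6d` (10% SSA, full retention), `fig6e`
(5% SSA, quarter retention); in `fig6c/d/e` the resistant channel is
off and cutting is held at the calibrated conversion product so
heterozygous-female transmission stays at the empirical ~87%.

Cage presets (200 founders, 75% drive homozygotes, 150/150 score/seed
pools, yellow mating costs 0.97 male / 0.31 female): `cage_ymcr` and
`cage_yremede` (the latter with SSA at 0.1/0.01 and cutting calibrated
to the measured ~54% drive transmission).

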