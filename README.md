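# ldfine

Fine-mapping tools built on an exact identity for the decay of disease
association with declining linkage disequilibrium (LD) from a causal site.

## The problem

A genome-wide association study flags a region, not a variant: markers
linked to a disease-causing site show association through LD, and the
strength of that borrowed signal falls off as the pairwise correlation with
the causal site falls off. For a biallelic causal site *A* (risk allele
frequency *p*, genotype penetrances *f*₁₁, *f*₁₂, *f*₂₂) and a linked marker
*B* (allele frequency *q*), with case/control chi-square statistics defined
at both sites, the expected statistics obey

> χ²_M = r² · χ²_D

where r² = D² / [p(1−p)q(1−q)] is the standard pairwise LD measure and
D = P₁₁P₂₂ − P₁₂P₂₁ is the haplotype-frequency covariance. The identity is
exact and holds for **every** penetrance configuration — additive,
multiplicative, dominant, recessive, or arbitrary. `ldfine` implements the
deterministic two-site model behind this identity and three things built on
top of it:

- **Recombination dynamics** — the per-generation haplotype recursion
  P₁₁,ₜ = P₁₁,ₜ₋₁(1−c) + c·p·q (and analogues), under which D decays as
  D₀(1−c)ᵗ and r² as r²₀(1−c)²ᵗ.
- **Monte Carlo dispersion** — case and control haplotype counts drawn as
  independent multinomials from the disease-stratified frequencies,
  quantifying the finite-sample scatter around χ²_M = r²·χ²_D.
- **Causal effect-size inference** — inverting the identity: given a marker
  statistic, its r² with a known-but-ungenotyped site, and that site's
  population allele frequency, solve for the allelic odds ratio the site
  would need to generate the observed signal.
- **Decay screening** — regress observed region-wide statistics on r² with
  the index variant through the origin, wrap the line in a residual-bootstrap
  95% band, and flag markers whose association exceeds what LD with the
  index can transmit: candidates for an independent causal signal.

Intended users are statistical geneticists prioritising variants within an
associated region and anyone needing a fast, exact reference model for
two-locus case/control association.

## Worked example

Suppose a genotyped marker gives χ² = 20 on the doubled scale (half of it is
1-df chi-square distributed, so p = 1.57×10⁻³) in 500 cases and 500
controls, and sequencing has revealed a nearby non-genotyped variant with
population allele frequency 0.03 and r² = 0.2 with the marker:

```python
from ldfine import AssociationStat, StudyDesign, causal_or_from_marker

eff = causal_or_from_marker(
    AssociationStat(20.0, "pp_doubled"), r2=0.2, p=0.03,
    design=StudyDesign(500, 500),
)
print(round(eff.R, 2), round(eff.pD_implied, 4))
```

prints `5.17 0.1379`: the hidden variant would need an allelic odds ratio of
5.17 (case allele frequency 0.138) to drive the observed marker signal.
The same computation from the shell:

```bash
ldfine infer-or --chi2 20 --convention pp_doubled --r2 0.2 \
    --freq 0.03 --n-cases 500 --n-controls 500 --json
```

Forward prediction works the same way. An index variant at p = 9.3×10⁻³³
(a 1-df chi-square of 142.09, the scale of the strongest signals at the
*FTO* obesity locus) predicts, at a marker with r² = 0.087,

```bash
ldfine predict --index-p 9.3e-33 --r2 0.087 --json
# "predicted_chi2": 12.361718...
```

χ² ≈ 12.36 — so a marker there observed at χ² ≈ 74 carries far more
association than LD with the index can explain, and the screening command
flags it:

```bash
ldfine make-region --markers 120 --noise multinomial \
    --f11 0.05 --f12 0.03 --f22 0.01 --freq 0.3 \
    --n-cases 783 --n-controls 783 \
    --second-r2 0.087 --second-offset 61.62 --seed 4 --out region
ldfine screen --sumstats region.sumstats.tsv --ld region.ld \
    --index snp_index -B 100000 --seed 0 --out-prefix region
```

The screen writes a per-variant table (observed, predicted, band, flag) and
a JSON summary; with this seed the injected marker `snp_second` is the only
flagged variant. Other subcommands: `trajectory` (r² decay over
generations) and `simulate` (multinomial replicate studies). Every
subcommand accepts `--config file.yaml` mirroring its flags, and every
stochastic output records its seed.

## Documentation

See `docs/methods.md` for the model, its assumptions, the statistic scale
conventions, the bootstrap band construction, and known limitations.
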