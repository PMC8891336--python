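# sealdiet

DNA metabarcoding diet analysis for pinniped scat samples, built around the
workflow used for large-scale harbour seal (*Phoca vitulina*) diet studies
in the northeast Pacific. The package takes per-sample amplicon reads (or
synthetic equivalents from its own generator) through taxonomic assignment
to per-sample prey proportions, dual-marker salmonid resolution, hard-parts
life-stage apportionment, bias correction, and population diet summaries.

It is aimed at trophic ecologists and bioinformaticians who need the
quantitative core of a metabarcoding diet pipeline as tested, importable
code: the rules are the conventional ones (edit-distance tag codes,
mismatch-tolerant demultiplexing, greedy centroid clustering, best-hit
assignment against a curated reference database with indistinguishable
species merged into "OR" taxa), and every stage is exercised end-to-end
against a synthetic generator with known ground truth.

## The model

For a samples×taxa read-count table *n*<sub>i,k</sub> (taxon *i*, sample
*k*; *S* samples, *T* taxa; *I*<sub>i,k</sub> = 1 iff *n*<sub>i,k</sub> > 0):

- **%FOO**<sub>i</sub> = (1/S) Σ<sub>k</sub> I<sub>i,k</sub> × 100% — frequency of occurrence
- **POO**<sub>i</sub> = Σ<sub>k</sub> I<sub>i,k</sub> / Σ<sub>i</sub>Σ<sub>k</sub> I<sub>i,k</sub> — percent of occurrence
- **wPOO**<sub>i</sub> = (1/S) Σ<sub>k</sub> I<sub>i,k</sub> / Σ<sub>i</sub> I<sub>i,k</sub> — each sample weighted equally, split among its prey
- **RRA**<sub>i</sub> = (1/S) Σ<sub>k</sub> n<sub>i,k</sub> / Σ<sub>i</sub> n<sub>i,k</sub> × 100% — relative read abundance, the proportional-biomass index

Two markers are combined per sample: a ~260 bp mitochondrial 16S fragment
quantifies all fish and cephalopod prey, and a salmonid-specific COI
mini-barcode resolves the salmon species (notably coho vs steelhead, which
16S cannot separate) *within* the 16S salmonid fraction. Salmonid DNA
percentages are further split into juvenile and adult components using
age-classified salmon bones from the same scat, the bones pooled for the
collection month, or a seasonal rule, in that order of preference.
Amplification bias is corrected by per-species multiplicative factors
(TCF/RCF/DCF); RCFs come from 50/50 biomass mixtures of each test species
against a fixed control, where the observed read ratio *is* the bias.

## Worked example

```python
import pandas as pd
from sealdiet.markers import MarkerPair, integrate_sample
from sealdiet.lifestage import apportion_sample

pair = MarkerPair(
    counts_16s=pd.DataFrame({"Clupea_pallasii": [600],
                             "Oncorhynchus_kisutch_OR_Oncorhynchus_mykiss": [400]},
                            index=["scat1"]),
    counts_coi=pd.DataFrame({"Oncorhynchus_kisutch": [75],
                             "Oncorhynchus_mykiss": [25]}, index=["scat1"]),
)
print(integrate_sample(pair, "scat1"))
#> Clupea_pallasii         0.6
#> Oncorhynchus_kisutch    0.3
#> Oncorhynchus_mykiss     0.1

res = apportion_sample(5.0, sample_bones=(1, 1), month_pool_bones=None, month=9)
print(res.juvenile_percent, res.adult_percent, res.rule_used)
#> 2.5 2.5 sample_bones
```

The first block resolves a 40% salmonid 16S fraction into 30% coho and 10%
steelhead using the COI proportions; the second splits a 5% Chinook DNA
percentage into 2.5% juvenile and 2.5% adult from an equal bone ratio.
The `examples/` directory contains one short runnable script per
capability, from read simulation and demultiplexing through the in-silico
index comparison.

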