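# ncmkit

A toolkit for asking whether a host-associated microbial community is
assembled by **neutral processes** (passive dispersal from a source pool
plus ecological drift) or by **selection** (host filtering, competition).
It was built around the study design used for fish gut microbiomes —
environmental source communities (water, feed) feeding gut compartments
in sequence, or freshwater sources feeding successive life-cycle stages —
but the machinery is generic: any OTU table with a source/target split,
a sample metadata table and a rooted phylogeny will do.

Intended users are microbial ecologists who have a 16S OTU (or ASV)
count table and want the standard community-assembly battery without
stitching together half a dozen R packages.

## What it computes

**Sloan neutral community model.** For a taxon with mean relative
abundance $p_i$ in the source metacommunity, the neutral expectation for
its relative abundance $x$ in a local community of size $N$ with
migration rate $m$ is

$$x \sim \mathrm{Beta}\big(Nm\,p_i,\; Nm\,(1-p_i)\big),$$

so the predicted occurrence frequency across samples, with detection
limit $d$ (by default one read, $d = 1/N$), is

$$\hat f_i \;=\; 1 - I_d\big(Nm\,p_i,\ Nm\,(1-p_i)\big),$$

where $I_d$ is the regularized incomplete beta function.  `ncmkit` fits
$m$ by bounded nonlinear least squares on the observed
(abundance, occurrence) cloud, reports $R^2$ and a bootstrap CI for $m$,
and classifies every OTU as *neutral*, *above* (over-represented —
candidate host-selected taxa) or *below* (under-represented — selected
against) relative to a 95% Wilson band around its prediction.  Fits can
be chained through an ordered series of communities (stepping-stone:
each community is the source for the next) or against one fixed external
source.

**Phylogenetic dispersion.** Per-sample mean pairwise distance (MPD) and
mean nearest-taxon distance (MNTD) on the cophenetic matrix, standardized
against a taxon-shuffle null into NRI and NTI
($\mathrm{NRI} = -\,\mathrm{SES}(\mathrm{MPD})$, positive = clustering /
habitat filtering), with Kruskal–Wallis / Wilcoxon group comparisons.

**Diversity statistics.** Richness, Shannon, Pielou evenness;
generalized UniFrac ($\alpha = 0.5$ by default), one-way PERMANOVA with
seeded permutations, classical PCoA; genus-level differential abundance
with Benjamini–Hochberg control.

**Synthetic data.** A Dirichlet-multinomial generator whose taxon-wise
marginals are *exactly* the beta distribution the Sloan model fits, plus
controlled departures: taxa planted in every sample ("above"), taxa
confined to a fraction of samples ("below"), clade-restricted
communities, and realistic read-depth variation. Every analysis in the
package is validated against this generator.

## Worked example

Generate a synthetic study (300 taxa, 10 deep source samples, 50 target
samples assembled neutrally at $Nm = 1000$) and fit the neutral model:

```sh
$ ncmkit simulate study --outdir demo --seed 7
wrote synthetic study to demo
$ ncmkit ncm fit --source demo/source.tsv --target demo/target.tsv \
    --bootstrap 200 --seed 7 --out demo/fit.json
m=0.118829 Nm=1203.15 R2=0.9484 neutral=73.9%
```

Reading the output: the fitted migration rate $m = 0.119$ at mean depth
$N = 10125$ gives $Nm \approx 1203$, close to the generating value of
1000 (single-study estimates run high by ~10–20% because real read
counts detect taxa softly rather than at a hard $1/N$ threshold — see
`docs/methods.md`). $R^2 = 0.95$ says the occurrence–abundance cloud is
well explained by neutral immigration and drift. About 74% of OTUs fall
inside their 95% neutrality band; the per-OTU classification is written
to `demo/fit.records.tsv`. In a real dataset the "above" rows are the
interesting ones — taxa far more prevalent than their source abundance
predicts, the signature of host-adapted organisms.

The full two-design analysis (stepping-stone gut-compartment chain plus
common-source life-stage design, with dispersion, alpha/beta diversity
and PERMANOVA) runs from one config:

```sh
ncmkit pipeline run --config config.yaml --outdir out --seed 42
```

All outputs are plain TSV/JSON and byte-identical for a fixed seed.

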