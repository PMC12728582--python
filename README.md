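# rhizofun

Soil multifunctionality and microbial co-occurrence network analysis for
rhizosphere amplicon studies.

Agronomic treatments such as straw returning reshape the rhizosphere
microbiome, and a recurring claim in soil ecology is that they improve soil
*multifunctionality* — the soil's simultaneous capacity for nutrient storage,
microbial biomass, and enzyme activity — not only through who is present but
through how densely the community members co-occur. `rhizofun` implements
that analysis chain as a tested, reusable Python pipeline for anyone working
with ASV count tables, a panel of measured soil functions, and a
treatment × replicate design. A fully seeded synthetic-data generator with a
known treatment → connectivity → multifunctionality ground truth makes every
stage verifiable at desk scale.

## What it computes

**Multifunctionality indices.** Each measured function is min–max
standardised across samples, `STD = (X − X_min)/(X_max − X_min)`. Three
indices summarise the samples × functions matrix:

* the single-function indices (the standardised columns themselves);
* the average multifunctionality index `AMI_s = mean_j STD_sj`, with
  carbon/nitrogen/phosphorus group variants AMI.C, AMI.N, AMI.P;
* the principal-coordinate multifunctionality index PMI.1–PMI.5: the first
  five axes of a PCoA of Bray–Curtis distances between standardised
  function profiles.

**Diversity and community structure.** Rarefaction to a common depth,
observed richness, Faith's phylogenetic diversity, a combined microbial
diversity index (mean of standardised bacterial and fungal richness),
genus-level composition, Bray–Curtis PCoA, and one-way PERMANOVA
(pseudo-F, permutation p).

**Co-occurrence networks and complexity.** Core ASVs (mean relative
abundance > 0.5%) are all-pairs Spearman-correlated; edges pass
|r| > 0.70 with p < 0.01 (Benjamini–Hochberg-adjusted by default). Each
sample's subnetwork is the induced subgraph on its present ASVs; seven
topology metrics (nodes, edges, average degree, clustering, average path
length, density, mean betweenness) feed an ordination whose leading axis —
oriented to grow with average degree — is the *network complexity* score.

**Linking statistics.** Pearson/Spearman correlation matrices, OLS
regressions, Mantel tests, random-forest %IncMSE importance, and a piecewise
path model (e.g. diversity → complexity → multifunctionality) judged by
Fisher's C = −2 Σ ln pᵢ over its d-separation independence claims
(χ² with 2k df).

## Worked example

```python
import rhizofun as rf

ds = rf.generate_dataset(rf.SynthConfig(n_replicates=10, seed=42))
mf = rf.multifunctionality(ds.functions)
sub = rf.subnetwork_complexity([ds.bacteria, ds.fungi], ds.metadata)

mf.ami.groupby(ds.metadata.treatments).mean()
# CK 0.156, SBSH 0.493, SBSF 0.833
{t: g.number_of_edges() for t, g in sub.networks.items()}
# {'CK': 63, 'SBSH': 174, 'SBSF': 394}
sub.scores.groupby(ds.metadata.treatments).mean()
# CK -3.06, SBSH 0.14, SBSF 2.92
rf.ols_fit(sub.scores, mf.ami.loc[sub.scores.index])
# slope 0.111, R2 0.96, p 3.5e-21
```

The three treatments were simulated with within-block abundance
correlations 0.2 / 0.5 / 0.8 and a positive connectivity effect on the
twelve soil functions: the per-treatment networks grow denser in that
order, the complexity scores order the treatments accordingly, and
multifunctionality regresses strongly on complexity — the chain the
pipeline is designed to detect.

The same analysis is available from the shell:

```sh
rhizofun run-all --seed 42 --outdir results/
```

which writes the simulated tables, multifunctionality indices, diversity
and ordination tables, GraphML/CSV networks, per-sample topology and
complexity scores, and the linking statistics (correlations, regressions,
Mantel, random-forest importance, path model), along with the resolved
configuration for provenance.

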