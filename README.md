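# karstclpp

Analysis toolkit for functional and taxonomic profiling of cave-sediment
microbial communities. It covers the statistics used in community-level
physiological profiling (CLPP) surveys of karst subsurface sediments —
Biolog EcoPlate color-development metrics, viable plate counts, 16S OTU
diversity, and sediment geochemistry — together with seeded synthetic-data
generators so every stage can be exercised and validated without raw
instrument exports.

## Who this is for

Microbial ecologists running EcoPlate CLPP experiments on sediments or
soils under temperature/oxygen treatment schedules, and anyone needing a
reproducible, scriptable version of the associated downstream statistics
(rarefaction, alpha diversity, standardized complete-linkage clustering of
geochemistry, limit-exceedance screens, Spearman taxon-environment
screens).

## The statistics at the core

An EcoPlate carries 31 carbon sources plus a water control (A1) in three
replicate blocks. Each well is read at 590 nm (tetrazolium color, i.e.
respiration) and 750 nm (turbidity). The per-substrate response is

    R_i = max( max(OD590 - OD750, 0)_substrate - max(OD590 - OD750, 0)_control , 0 )

computed per block and averaged over the blocks present. From the 31
responses:

* **AMR** (average metabolic response, = AWCD):  `AMR = Σ R_i / 31`
* **CMD** (community metabolic diversity, functional richness):
  `CMD = #{ i : R_i > 0.400 }`, also expressed as a percentage of 31
  (so e.g. 29 positive substrates ⇒ 93.5 %).

Supporting analyses: CFU per gram dry mass from serial-dilution plating
(`count·10^d / V_plated · V_suspension / (wet mass · dry-mass fraction)`),
rarefaction to the minimum library size with exact hypergeometric
rarefaction curves, Shannon (`H = −Σ p ln p`) and Gini–Simpson
(`D = 1 − Σ p²`) indices, z-score standardization with Euclidean distance
and complete-linkage clustering for geochemical sample profiles, and
Spearman rank-correlation screens with t-approximation or exact-permutation
p-values.

## Worked example

Simulate a plate in which exactly 17 of the 31 substrates develop color
(logistic kinetics, noiseless), then run the CLPP time course:

```sh
karstclpp simulate plate --n-active 17 --noise-sd 0 --seed 3 --out plate.tsv
mkdir plates && cp plate.tsv plates/
karstclpp clpp --plates plates --out clppout
tail -3 clppout/clpp_plate.tsv
```

prints

```
312.0   0.5483816516162224      17      54.8
324.0   0.5483844463177596      17      54.8
336.0   0.5483858066553446      17      54.8
```

i.e. at the late readings the community metabolizes 17 substrates
(CMD 54.8 % of 31) and the mean response has saturated near
17/31 ≈ 0.548 OD — the planted ground truth recovered by the pipeline.

Clustering the packaged sediment geochemistry table (8 samples, 22
parameters, censored "<x" cells, regulatory soil limits):

```sh
karstclpp envstats cluster --env src/karstclpp/data/sediment_geochemistry.tsv \
    --out-newick dendro.nwk
karstclpp envstats limits --env src/karstclpp/data/sediment_geochemistry.tsv --out lim.tsv
```

The dendrogram isolates the metal-rich palaeo-sediment S4 as the last
singleton and splits the remaining samples into {S1,S2,S3} and
{S5,S6,S7,S8}; the limits report flags Zn in S1, Ni in S1–S4/S6/S7, and
Cr and Cd in S4.

The same operations are available as library calls
(`karstclpp.substrate_profile`, `karstclpp.cmd`, `karstclpp.cluster_samples`,
…), and `karstclpp run --config run.yaml` orchestrates an end-to-end run
with a JSON manifest for byte-identical reproduction.

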