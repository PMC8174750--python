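# mycoassembly

Community-assembly analysis for host-associated mycobiomes (and other
amplicon surveys): permutation statistics for diversity, distance decay
of community similarity, abundance-occupancy core identification, and
Sloan neutral-model fitting with deviation classification — plus a
Dirichlet-multinomial community generator with planted ground truth
that exercises every stage end to end.

The package is aimed at microbial ecologists analysing ASV tables from
geographically structured surveys — the motivating case is a global
survey of fungi on a marine seagrass, sampled as leaves, roots and
adjacent sediment at 16 coastal sites across two ocean basins — who
want the standard analysis stack (Kruskal–Wallis/Dunn, PERMANOVA,
PERMDISP/Tukey, Mantel/correlogram/MRM, rarefaction, clr/Hellinger
transforms) together with assembly inference in one tested library.

## The model at the core

The Sloan neutral community model treats each local community as a
large population undergoing random birth, death and immigration from a
shared metacommunity. For a taxon at metacommunity relative abundance
`p`, the local relative abundance is Beta-distributed,

    x ~ Beta(N·m·p, N·m·(1 − p)),

where `N` is the reads per sample (the detection grain) and `m` the
migration rate — the probability that a local death is replaced by an
immigrant. With detection limit `d = 1/N`, the expected occupancy
(fraction of samples in which the taxon is detected) is

    occ(p) = 1 − BetaCDF(d; N·m·p, N·m·(1 − p)).

`fit_sloan` estimates `m` by bounded least squares of observed against
predicted occupancy over all taxa; taxa whose observed occupancy falls
above the 95% band around the prediction are candidates for host or
environmental selection, those below for selection-against or
dispersal limitation. The companion generator `simulate_neutral_samples`
draws `composition ~ Dirichlet(N·m·p)`, `reads ~ Multinomial(N,
composition)` — the exact finite-sample dual of the fitted model — so
parameter recovery is a testable property, not an assumption.

The core microbiome is identified without an arbitrary abundance
cutoff: taxa are ranked by occupancy and site consistency, the mean
Bray–Curtis contribution of each ranked prefix is accumulated, and the
core is the prefix through the last rank that still adds at least 10%
to the explained beta diversity.

## Worked example

```python
import mycoassembly as ma
from mycoassembly.synthetic_data import StudyDesign, simulate_study
from mycoassembly.multivariate import permanova
from mycoassembly.distance_decay import geo_matrix, mantel

table, meta, tax, truth = simulate_study(StudyDesign(seed=0))   # 576 x 615
filt, rep = ma.filter_by_taxonomy(table, tax, keep="Fungi")     # drops 5 host ASVs
leaf = filt.select_samples(
    [s for s in filt.sample_ids if meta.loc[s, "sample_type"] == "leaf"])
rare, _ = ma.rarefy(leaf, 1000, seed=1)
rare = rare.drop_empty_asvs()                                   # 192 x 207

ao = ma.abundance_occupancy(rare, meta)
fit = ma.fit_sloan(ao)
labels = ma.classify_deviation(ao, fit)
print(f"m={fit.m:.4f}  R2={fit.r_squared:.2f}")                 # m=0.0052  R2=0.39
print(labels.value_counts().to_dict())
# {'neutral': 193, 'above': 7, 'below': 7}

core = ma.core_by_contribution(rare, ma.rank_asvs(ao))
print(len(core.core_set))                                       # 9 core ASVs

dm = ma.beta_distance(rare, "bray_curtis")
res = permanova(dm, meta.loc[rare.sample_ids, "site_code"], n_perm=999, seed=2)
print(f"F={res.statistic:.2f} p={res.p_value}")                 # F=8.30 p=0.001

pac = [s for s in rare.sample_ids if meta.loc[s, "ocean"] == "Pacific"]
sub = rare.select_samples(pac).drop_empty_asvs()
man = mantel(ma.beta_distance(sub, "bray_curtis"), geo_matrix(meta.loc[pac]),
             n_perm=999, seed=3)
print(f"r={man.statistic:.4f} p={man.p_value}")                 # r=0.2711 p=0.001
```

Reading the output: the fitted migration rate (0.005) is of the order
that typifies dispersal-limited fungal communities; R² = 0.39 says the
neutral curve explains part but not all of the occupancy pattern. The
deviation counts recover the generator's planted structure — the five
taxa planted as host-selected are among the "above" labels and the five
planted as dispersal-limited among the "below" labels — and all five
planted ubiquitous taxa sit in the 9-member leaf core. Community
structure differs strongly by site (PERMANOVA), and Pacific leaf
communities show the distance-decay signal the generator encodes
(Mantel r > 0 at the smallest attainable p).

The same pipeline runs from a shell:

```bash
mycoassembly simulate --out demo --seed 0
mycoassembly run-all --config config.yaml --out results
```

(subcommands: simulate, filter, rarefy, diversity, permanova, permdisp,
mantel, correlogram, mrm, core, neutral, summarize, run-all).

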