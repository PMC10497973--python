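# plastcap

Tools for deciding whether a plastome (chloroplast genome) phylogeny that
conflicts with its species tree can be explained by incomplete lineage
sorting (ILS) alone, or requires chloroplast capture (plastome
introgression).

The core workflow:

1. **Simulate** plastome gene trees under the multispecies coalescent,
   contained within a species tree whose branch lengths (coalescent
   units) are multiplied by a ploidy factor (4 for a haploid,
   uniparentally inherited organelle relative to diploid nuclear loci;
   2 under a biparental-inheritance sensitivity setting).
2. **Score** every simulated tree against the species tree with the
   clustering-information variant of the generalized Robinson–Foulds
   distance (normalized to [0, 1]; 0 = identical, 1 = no shared
   clustering information), giving a null distribution of discordance
   under ILS.
3. **Test** the empirical plastome tree's distance against that null:
   a one-sample t-test of the null sample against the empirical distance,
   and an add-one rank-based p-value `(1 + #{d_sim >= d_emp}) / (n + 1)`
   (the calibrated default decision rule).

Also included: plastome CDS pseudogene classification (premature stop
codon / large deletion / intact), the 50%-gap alignment column filter,
supermatrix concatenation with partition output, and synthetic data
generators (Yule species trees, coalescent plastome trees with injected
capture events, toy CDS sets) so the whole pipeline is testable without
external data.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests,
cross-checks against msprime and brute-force oracles, and
`tests/test_acceptance.py` (calibration, power, and paper-scale timing —
a few minutes total).

## CLI

```sh
# simulate the ILS null (multi-tree newick + JSON run log)
plastcap simulate --species-tree species.nwk --n 1000 --ploidy-factor 4 \
    --seed 1 --out null_trees.nwk

# distance between two trees on the same taxon set
plastcap distance --tree1 a.nwk --tree2 b.nwk --raw

# full capture-vs-ILS test (JSON result + null distances + histogram)
plastcap test --species-tree species.nwk --plastome-tree plastome.nwk \
    --n 1000 --ploidy-factor 4 --seed 1 [--label-map map.tsv] \
    [--alpha 0.05] [--one-sided] --out result.json

# synthetic species/plastome pair with k capture events
plastcap synth --n-species 12 --k-events 3 --seed 1 --out-prefix case1

# classify CDS copies against reference CDS (TSV status matrix)
plastcap scan-cds --reference refs.fasta --out status.tsv sample1.fasta sample2.fasta

# filter gap columns and concatenate gene alignments
plastcap concat --out supermatrix.fasta --partitions parts.txt gene*.fasta
```

`--label-map` takes a two-column TSV (plastome tip → species-tree tip)
for when the empirical tree is labelled by accession; tips absent from
the species tree are dropped before computing the distance.

## Library use

```python
import plastcap as pc

species = pc.parse_newick_file("species.nwk")[0]
plastome = pc.parse_newick_file("plastome.nwk")[0]
cfg = pc.SimulationConfig(n_sims=1000, ploidy_factor=4.0, seed=1)
result = pc.run_ils_test(species, plastome, cfg)
print(result.empirical_distance, result.rank_pvalue, result.reject_ils)
```
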