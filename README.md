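# phagehost

Phage–host ecology from wastewater virome data: CRISPR-spacer-based host
assignment, bipartite infection-network statistics, and community-level
diversity and core-set analysis.

Urban sewage concentrates viruses from every microbial habitat a city
touches. Most of those viruses are bacteriophages whose hosts are
unknown, but bacteria keep a record of past infections: CRISPR spacers,
short sequences excised from infecting phage genomes. A spacer that
aligns to a viral contig links that contig to the spacer's source genus.
Aggregating such links over virus clusters (VCs, gene-content groups of
viral genomes) and bacterial genera yields a binary bipartite infection
network whose architecture — nested (generalist-to-specialist
hierarchies) versus modular (separate infection subsets) — reflects the
ecology and evolution of phage–host interactions. `phagehost` implements
that pipeline end to end for analysts of viral metagenomes, together
with the community metrics such studies report and a seeded synthetic
data generator so every stage is testable without sequencing data.

## What it computes

Given a binary genus × VC matrix `A` with row degrees `k_i`, column
degrees `d_j` and `m` edges:

- **NODF** — mean pairwise overlap among rows (and columns) with strictly
  decreasing degree, on the 0–1 scale.
- **Nestedness temperature** `T` and `N_NTC = (100 − T)/100` — mean
  squared unexpectedness of presences/absences relative to the isocline
  of perfect nestedness on the packed matrix.
- **Barber modularity** `Qb = (1/m)·Σ_ij (A_ij − k_i d_j/m)·δ(g_i, h_j)`,
  maximised with LP-BRIM (seeded label propagation + BRIM refinement,
  best of `n_restarts`).
- **Equiprobable null tests** — each cell i.i.d. Bernoulli(fill);
  one-sided empirical p with add-one smoothing and a z-score.

Upstream of the matrix: full-length ungapped spacer matching with the
<2 bp mismatch retention rule, CD-HIT-style greedy clustering statistics,
and greedy best-match host calls (bit score, E value, percent identity,
length, mismatches+gaps, with deterministic tie-breaks). Alongside it:
Gini-Simpson and Pielou alpha diversity, Bray-Curtis beta diversity with
PCoA ordination, a distance-based permutation test for location effects,
UpSet-style exclusive set intersections (the all-location intersection
being the core virome), and the core-feature prevalence/abundance rule
(relative abundance > 0.25 % in ≥ 75 % of samples).

See `docs/methods.md` for models, assumptions and design choices.

## Worked example

```python
import numpy as np
import phagehost as ph

# 1. simulate a small infection system: 30 phage contigs, 6 bacterial genera
contigs = ph.simulate_contigs(30, len_min=1000, len_max=3000, seed=1)
spacers, truth = ph.simulate_crispr_spacers(
    contigs, n_per_genus=20, genera=[f"genus_{i}" for i in range(6)],
    spacer_len=32, mutation_rate=0.01, seed=2,
)

# 2. link spacers to contigs and call hosts
matches = []
for sp in spacers:
    matches.extend(ph.find_spacer_matches(sp, contigs, max_mismatch=1))
assignments = ph.assign_hosts(matches, truth.spacer_to_genus)
accuracy = np.mean([a.host_genus == truth.contig_to_genus[a.contig_id]
                    for a in assignments])
print(f"{len(matches)} retained matches -> {len(assignments)} host calls "
      f"({100 * accuracy:.1f}% correct)")

# 3. build the genus x virus-cluster matrix and test its structure
vc_map = {c.id: f"VC_{i // 2:02d}" for i, c in enumerate(contigs)}
M = ph.build_interaction_matrix(assignments, vc_map)
nest = ph.nestedness(M)
mod = ph.lp_brim(M, seed=3, n_restarts=20)
null = ph.null_test(M, "qb", n_iterations=1000, seed=4)
print(f"matrix {M.shape[0]} genera x {M.shape[1]} VCs, fill {M.fill:.3f}")
print(f"NODF = {nest.nodf:.4f}, N_NTC = {nest.n_ntc:.2f}, "
      f"Qb = {mod.qb:.3f} ({mod.n_modules} modules)")
print(f"modularity vs equiprobable null: z = {null.z:.2f}, p = {null.p_empirical:.4f}")
```

prints

```
114 retained matches -> 30 host calls (100.0% correct)
matrix 6 genera x 15 VCs, fill 0.200
NODF = 0.1000, N_NTC = 0.49, Qb = 0.667 (4 modules)
modularity vs equiprobable null: z = 2.51, p = 0.0130
```

With a 1 % per-base spacer mutation rate, every placement still lands
within the 1-mismatch retention rule, so all 30 contigs get a correct
host call. Each genus infects its own set of VCs, so the network is
modular rather than nested: low NODF, a lukewarm temperature, and a high
Qb whose partition recovers the four modules that survive in this small
matrix, more modular than 98.7 % of equiprobable null draws.

The same stages are available from a shell:

```sh
phagehost simulate --seed 7 --outdir sim/
phagehost pipeline --spacers sim/spacers.fasta --contigs sim/contigs.fasta \
    --spacer-genus sim/spacer_genus.tsv --contig-vc sim/contig_vc.tsv \
    --outdir run/ --seed 7
phagehost diversity --counts sim/counts.tsv --locations sim/locations.tsv \
    --out run/diversity.json
```

Every subcommand writes JSON/TSV results plus a manifest (config, derived
seeds, input checksums); reruns with the same configuration are
byte-identical.

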