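# morphodelim

Species delimitation and cladistics for fossil specimen samples, built
around the workflow used in taxonomic revisions of extinct carnivorans
such as the North American false saber-tooth cats (Nimravidae).

The package answers two coupled questions a revising taxonomist faces:

1. **How many species are in this pile of specimens?**  Under the
   phylogenetic species concept (PSC) a species is the smallest
   aggregation of specimens diagnosable by a unique combination of
   character states.  The package operationalises this as a two-track
   test: candidate *morphogroups* are discovered by UPGMA clustering of
   linear measurements (after multivariate-normal imputation of the
   gaps every fossil table has) and validated by linear discriminant
   accuracy on held-out specimens (90% cutoff); a validated metric split
   becomes a species boundary only when at least one character state is
   *fixed and different* across it.  A perfect metric split without fixed
   characters reads as intraspecific variation (sexual dimorphism,
   regional or temporal trends).
2. **How are the species related?**  Unordered-character maximum
   parsimony with exact (branch-and-bound) and heuristic (random
   addition + TBR) search, majority-rule consensus, ensemble consistency
   and retention indices, Bremer decay and character-jackknife support.

A synthetic-data module generates measurement tables (per-species
multivariate normals with optional sexual-dimorphism mixtures and MCAR
missingness) and discrete character matrices (Mk evolution on a known
tree), so every stage can be tested against planted truth without any
downloads.

## The statistics at the core

* **Imputation** — data augmentation under a joint multivariate normal:
  I-step draws each specimen's missing block from
  N(mu_m + S_mo S_oo^-1 (x_o - mu_o), S_mm - S_mo S_oo^-1 S_om);
  P-step draws (mu, S) from the complete-data posterior under a Jeffreys
  prior; 100 steps by default, EM supplies the start.  Mardia's kurtosis
  statistic b2p = mean(d_i^4) with z = (b2p - p(p+2)) / sqrt(8p(p+2)/n)
  checks the normality assumption.
* **Morphogroup validation** — Gaussian LDA with pooled within-group
  covariance and equal priors; stratified 50/50 train/test splits, or
  leave-one-out jackknife when groups are too small to split.
* **Parsimony** — Fitch length (Hartigan's generalisation on
  polytomies); CI = sum(m_i)/L and RI = (sum(g_i) - L)/(sum(g_i) - sum(m_i))
  where m_i = observed states - 1 and g_i = scored taxa - largest state
  class; Bremer decay via a suboptimal-window sweep plus constrained
  re-search; jackknife with per-character deletion probability e^-1.

## Worked example

```python
import morphodelim as md

# study-shaped synthetic bundle: 85 x 15 measurements (41% missing),
# 27 x 33 characters on a reference tree, published FAD/LAD ages
mm, cm, fad = md.nimravid_fixture(seed=0)
print(round(100 * md.missing_fraction(mm), 2))   # 39.92

# morphometric track: impute -> UPGMA -> cut 2 groups -> split DFA
completed, dendrogram, part = md.morphometric_track(mm, k=2, seed=0)
print(part.validation_mode, round(part.dfa_accuracy, 3))  # split 0.905

# cladistic track: heuristic search, consensus, homoplasy indices
ts = md.heuristic_search(cm, replicates=100, seed=1, hold=2000)
ci, ri = md.ensemble_ci_ri(cm, ts.best_length)
print(ts.best_length, round(ci, 2), round(ri, 2))  # 104 0.47 0.61
cons = md.consensus(ts, cutoff=0.5)
```

The printed numbers mean: the fixture table has 39.92% missing cells
(deleted completely at random at the study-level rate); the two-group
cut is validated with 90.5% held-out classification accuracy (above the
90% support cutoff); the shortest trees found for the character matrix
need 104 steps, with ensemble CI 0.47 and RI 0.61 (moderate homoplasy).

A thin CLI mirrors the library:

```bash
morphodelim simulate fixture --seed 0 --out data/
morphodelim impute --in data/measurements.csv --steps 100 --seed 1 --out completed.csv
morphodelim cluster --in completed.csv --k 2,3,4 --out clusters
morphodelim dfa --in completed.csv --partition clusters.partitions.json --k 2 --seed 1
morphodelim parsimony --in data/characters.nex --replicates 100 --seed 1 --out run/
```

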