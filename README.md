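# crcmicro

A colorectal-cancer (CRC) lifestyle index and the statistical pipeline
that links it to the gut microbiome and to CRC hazard.

Lifestyle and anthropometric risk factors for CRC — body fatness,
height, physical inactivity, low whole-grain and dairy intake, high red
and processed meat, alcohol — tend to cluster within people, and their
*combination* may shape the gut microbiome in ways that single factors
do not.  `crcmicro` is for epidemiologists and microbiome researchers
who want to study that interplay: it scores a nine-component lifestyle
index, relates it to metagenome-derived diversity and composition with
properly adjusted and permutation-calibrated statistics, and validates
the index against cancer incidence by pooled survival analysis.
Because the cohorts such analyses run on are access-controlled, the
package also ships a synthetic-cohort generator with planted effects,
so every stage can be exercised end-to-end against known ground truth.

## The index

Each component earns 0, 0.5 or 1 point (not meeting / partially
meeting / meeting its target):

| Component | 0 | 0.5 | 1 |
|---|---|---|---|
| BMI (kg/m²) | ≥ 30 | 25–<30 | < 25 |
| WC, women / men (cm) | ≥ 88 / ≥ 102 | 80–<88 / 94–<102 | < 80 / < 94 |
| Height (sex-specific) | tertile 3 | tertile 2 | tertile 1 |
| Activity | inactive | moderate | active |
| Whole grains (g/d) | < 45 | 45–<90 | ≥ 90 |
| Dairy (g/d) | < 200 | 200–<400 | ≥ 400 |
| Red/processed meat (g/wk) | red > 350 or proc ≥ 100 | red ≤ 350, proc 21–<100 | red ≤ 350, proc ≤ 21 |
| Alcohol (g/d ethanol) | > 20 | >0–≤20 | 0 |

BMI and WC average into one body-fatness score, the four dietary
components into one dietary score, and

```
total = body_fatness + height + activity + diet  ∈ [0, 4],
```

higher = lower-risk lifestyle.  The downstream chain: Shannon alpha
diversity (adjusted OLS), weighted UniFrac beta diversity (PERMANOVA,
dispersion, dbRDA, PCoA + factor fit), bias-corrected compositional
differential abundance with a pseudo-count robustness screen,
proportionality/Ward clustering with Kelley–Gardner–Sutcliffe cut
selection, and cohort-specific Cox models pooled by DerSimonian–Laird
random-effects meta-analysis (Cochran's Q heterogeneity).  See
`docs/methods.md` for the model details and conventions.

## Worked example

Simulate a cohort at study scale, score it, and run the whole chain:

```sh
crcmicro simulate --out run/ --seed 7
crcmicro score --phenotypes run/phenotypes.tsv --out run/scores.tsv
# -> scored 1228 participants (median 2.12 points)
crcmicro prep --table run/counts.tsv --out run/filtered.tsv
# -> kept 1228/1228 samples and 127/150 taxa
crcmicro diversity --table run/filtered.tsv --tree run/tree.nwk --out run/div
crcmicro associate --phenotypes run/phenotypes.tsv --scores run/scores.tsv \
    --alpha run/div/alpha_diversity.tsv --out run/assoc
# -> analysis  term  estimate       se        p    fdr_p
#       alpha index  0.063581 0.012974 0.000001 0.000001
```

The alpha-diversity line says: after adjusting for sex, age, energy
intake, smoking and medication use, each additional index point is
associated with a 0.064-unit higher Shannon entropy (SE 0.013) — the
planted slope of 0.05 recovered within sampling error, far beyond
chance.  In Python the same runs as

```python
import crcmicro as cm
cfg = cm.SimulationConfig(seed=7)          # 1,228 participants
pheno  = cm.generate_phenotypes(cfg)
scores = cm.compute_index(pheno)           # per-component points + total
table, tree, truth = cm.generate_microbiome(
    pheno, scores["total"].to_numpy(), cfg)
```

or end-to-end with `crcmicro run-all --out run/ --seed 7`, which writes
every intermediate table plus a `run_report.json` of headline
statistics.

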