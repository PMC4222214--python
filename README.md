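# pairodds

Directed odds-ratio association networks from species presence/absence
surveys.

Ecologists often want to know not just *which* species co-occur, but how
strongly, in which direction, and whether one species is a useful
indicator of another. `pairodds` implements an asymmetric pairwise
association measure for binary survey data: for species A and B observed
over a set of surveys,

```
OR(A | B) = Odds(A present | B present) / Odds(A present)
```

— the odds of A given B's presence over A's marginal odds. Unlike the
classical symmetric odds ratio (the 2×2 cross-product `cf/de`) this
measure differs between the two directions and reflects how common each
species is, so a rare species can strongly *indicate* a common one while
the reverse indication is weak. It equals the positive likelihood ratio
of B's presence viewed as a diagnostic test for A, and applying it to
any baseline presence percentage via the logit scale gives a directly
interpretable change in presence (an OR of 3 lifts 10% → 25%, 50% → 75%).

The package provides, for survey × species 0/1 tables with a site label
per survey:

- **Closed-form contingency mathematics** (`pairodds.contingency`):
  directed and symmetric odds ratios, conditional presence, likelihood
  ratio identities, odds-to-percentage conversion.
- **Model-based estimation** (`pairodds.estimation`, `pairodds.mixed`):
  per-pair logistic regression for independent surveys, and a
  binomial-logit mixed model with a random site intercept for repeated
  surveys of the same sites, with delta-method standard errors, Wald
  intervals and p-values for each directed log odds ratio. Zero and
  infinite odds ratios (species never / perfectly co-occurring) are kept
  as special values without standard errors.
- **Network assembly** (`pairodds.assemble`): a 10%-prevalence species
  filter, classification into indications (OR > 3) and
  contraindications (OR < 1/3), unadjusted and Bonferroni (α/n species)
  significance flags, GraphML and CSV export.
- **Simulation** (`pairodds.simulate`): a null-distribution study that
  counts spurious substantial associations under species independence,
  and a synthetic-community generator with planted associations for
  parameter-recovery studies.
- **Visualization** (`pairodds.viz`): the association diagram —
  prevalence-banded nodes, red/blue direction arrows with thickness
  proportional to association strength, magenta/black styling for
  infinite/zero ratios, seeded force-directed layout with manual pinning.
- **A CLI and sklearn facade** (`pairodds.cli`, `pairodds.estimator`):
  `pairodds run` drives the whole pipeline from a CSV and a YAML config;
  `SpeciesAssociation().fit(X)` exposes the same analysis to
  scikit-learn pipelines.

## Worked example

The package's running example is a pair of species observed in 100
surveys: A present in 50, B in 20, both in 15 (cells c=15, d=35, e=5,
f=45):

```python
import pairodds as po

t = po.PairContingency(c=15, d=35, e=5, f=45)
print("indication of A by B :", po.directed_odds_ratio(t, target="A"))
print("indication of B by A :", po.directed_odds_ratio(t, target="B"))
print("symmetric odds ratio :", po.symmetric_odds_ratio(t))
print("P(A | B present)     :", po.conditional_presence(t, target="A"))
print("P(B | A present)     :", po.conditional_presence(t, target="B"))
print("OR 3 applied to 10%  :", po.apply_or_to_baseline(3.0, 0.10))
```

prints

```
indication of A by B : 3.0
indication of B by A : 1.7142857142857142
symmetric odds ratio : 3.857142857142857
P(A | B present)     : 0.75
P(B | A present)     : 0.3
OR 3 applied to 10%  : 0.25
```

B's presence triples A's odds (lifting A from 50% to 75% presence),
while A's presence raises B's odds by only 1.71 (20% → 30%): the
asymmetry says the rarer species B is the better indicator. The
symmetric cross-product ratio (3.86) would give both directions the same
weight.

On full survey tables the same quantities come with uncertainty:

```python
model = po.SpeciesAssociation(estimator="glmm").fit(presence_frame, sites=site_labels)
model.network_.edge_frame()      # directed edges with OR, CI, p, class
```

or from the shell:

```sh
pairodds run --input surveys.csv --estimator glmm --seed 1 --out-dir out/
```

which writes node/edge tables, `network.graphml`, the association
diagram (`diagram.svg`/`.png`), the layout coordinates and a
`manifest.json` with per-stage counts and output checksums.

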