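# fsmatrix

A furniture fire-safety matrix: score domestic upholstered furniture
product types for **relative fire risk** (injury and property damage)
and **relative chemical flame-retardant (CFR) exposure potential** from
structured evaluator questionnaires, then reconcile the two models —
ranking, quadrant classification, Euclidean-distance clustering with a
dendrogram cut, and a systematic-error sensitivity analysis — to find
clusters of product types that combine low fire risk with high exposure
potential. It is written for researchers and regulators weighing which
furniture types actually need chemical flame retardancy.

## The models

**Fire risk** follows a failure chain — ignition-source contact must
precede ignition, ignition must precede spread, and spread must meet a
user who cannot react. Each link is a 1–5 dimension score:

- contact likelihood (Likert);
- ignition: junction count transformed by 0→1, 1→2, 2→3, 3→4, ≥4→5
  (four junctions make an open box), combined with ornateness — the
  junction term counts only when the evaluators' ignition narrative
  mentions candles or smokers' materials;
- spread: combustible volume *V* (m³) mapped as
  `1 + 4·min(V, 0.009)/0.009` (a small-cushion volume saturates the
  scale);
- reactive capacity of the likely user.

The aggregate is the lowest quartile (type-7) of the dimension scores,

```
injury = Q1(contact, ignition, spread, reactivity)
damage = Q1(contact, ignition, spread)
```

hedging on the weakest links without letting the single lowest score
decide.

**CFR exposure** is the equal-weight mean of five dimensions: young-child
use, bare-skin contact, mouthing, cumulative use (Likert 1–5) and
surface area log-mapped onto 1–5. Scores are relative potentials, not
doses.

Per type, the low- and high-risk variant scores give a mean and range;
types are ranked, placed in injury × exposure quadrants (upper-left =
low fire risk, high exposure), and clustered agglomeratively in
(injury, damage, exposure) space with a dendrogram cut at 0.56.

## Worked example

Rank the packaged reference catalogue (30 product types, 14 of them
small-child products) by mean exposure score:

```python
from fsmatrix import load_fixtures, rank_types, top_k_membership

fx = load_fixtures()
rs = fx.reference_scores.copy()
rs["exposure_mean"] = (rs.exposure_low + rs.exposure_high) / 2
rs["injury_mean"] = (rs.injury_low + rs.injury_high) / 2
rs["damage_mean"] = float("nan")

ranking = rank_types(rs, "exposure_mean")
child = {t.type_id for t in fx.catalogue if t.small_child_product}
print("top of exposure ranking:", ranking[:3])
print("small-child types in top 15:", top_k_membership(ranking, child, 15))
```

```
top of exposure ranking: ['playpens', 'pillow', 'bassinet']
small-child types in top 15: 12
```

Playpens head the exposure ranking (mean 3.90), and 12 of the 14
small-child product types sit in the top 15 — the signature of the
upper-left, high-exposure/low-fire-risk cluster. The same flows run from
the shell on synthetic or real questionnaires:

```sh
fsmatrix simulate --out panel --n-types 30 --seed 1
fsmatrix report --input panel/evaluations_fire.csv \
    --exposure-input panel/evaluations_exposure.csv --out results --seed 1
```

`report` writes `scores.csv`, `summary.csv` (with quadrant and cluster
labels), `sensitivity.csv`, a Newick cluster tree, the ranking /
scatter / dendrogram / jitter figures, and a JSON run log; reruns with
the same configuration are byte-identical. Individual stages are
available as `score-fire`, `score-exposure`, `summarise`, `cluster`,
`quadrants` and `sensitivity`.

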