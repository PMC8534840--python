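# amicoding

Discriminating protein-coding from noncoding DNA using average mutual
information profiles.

Protein-coding DNA carries statistical structure that noncoding DNA does
not: codon-usage bias makes the three codon positions compositionally
distinct, which shows up as period-3 dependence between nucleotides, and
noncoding regions have their own signatures (AT-rich composition, poly-T
runs on the antisense side of poly-A tails). `amicoding` turns these
signals into feature vectors and classifiers for the question *"was this
fixed-length window drawn from coding or noncoding sequence?"* — a
building block for annotation pipelines, and one that transfers across
species because the features are not tied to any particular genome.

## The profiles

For a window of DNA, let p̂⁰(X) be the empirical nucleotide distribution
and p̂ᵏ(X,Y) the empirical joint distribution of nucleotide pairs
separated by a lag of k bases (linear pairing; letters outside A,C,G,T are
dropped). Three feature vectors are built from these, with components
ordered lag-major and pair-major (X outer, Y inner, base order A,C,G,T):

* **AMI** — the average mutual information per lag, in bits:

  AMIₖ = Σ_{X,Y} p̂ᵏ(X,Y) · log₂ [ p̂ᵏ(X,Y) / (p̂⁰(X)·p̂⁰(Y)) ]

  one value per lag, k = 1…K. AMIₖ is a KL divergence, hence ≥ 0.
* **eAMI** ("expanded AMI") — the 16 raw pair probabilities p̂ᵏ(X,Y) per
  lag (16K values).
* **eaAMI** ("expanded adjusted AMI") — the 16 individual summands of
  AMIₖ per lag (16K values; per lag they sum to AMIₖ).

The expanded profiles undo the averaging in AMIₖ and are substantially
stronger classification signals.

## The protocol

Given a genome (FASTA) and its annotation (GTF), all CDS features are
extracted 5′→3′, concatenated and deduplicated into a **coding parent
sequence**; everything not covered by a CDS on either strand becomes the
**noncoding parent** (each noncoding interval contributes its forward and
reverse-complement sequence). Up to 2000 non-overlapping windows of fixed
length are drawn per parent, profiled, and classified with a linear SVM
(standardized features) or a Euclidean-centroid rule, with the convention
*positive score ⇒ coding*. Performance is measured by ROC/AUC from a
threshold sweep over the pooled 5-fold cross-validation scores, plus
sensitivity/specificity at threshold 0; cross-species transfer trains on
one species and scores another. A synthetic-genome module generates
annotated FASTA+GTF genomes from a biased codon-usage table and an
AT-rich Markov background, so the whole protocol runs without downloads.

## Worked example

```python
import numpy as np
from amicoding import (CodonUsageTable, NoncodingModel, ParentSequences,
                       generate_coding_parent, generate_noncoding_parent,
                       build_dataset, cross_validate, centroid_profiles)

table = CodonUsageTable.biased()          # 8:1 preference for G/C-ending codons
background = NoncodingModel.at_rich()     # AT-rich order-1 chain + poly-T runs

parents = ParentSequences(
    "demo",
    generate_coding_parent(table, 120_000, seed=1),
    generate_noncoding_parent(background, 120_000, seed=2),
)
dataset = build_dataset(parents, length=300, n_per_class=400, seed=3)

for kind, K in (("AMI", 16), ("eAMI", 6), ("eaAMI", 6)):
    r = cross_validate(dataset, kind, K, "linear-svm", k=5, seed=3)
    print(f"{kind:>6}  AUC={r.auc:.3f}  SN={r.sensitivity:.3f}  SP={r.specificity:.3f}")

coding, noncoding = centroid_profiles(dataset, "AMI", 10)
print("coding centroid AMI, lags 1-10:")
print(np.array2string(coding.values, precision=4))
```

prints

```
   AMI  AUC=0.994  SN=0.965  SP=0.968
  eAMI  AUC=1.000  SN=1.000  SP=1.000
 eaAMI  AUC=1.000  SN=1.000  SP=1.000
coding centroid AMI, lags 1-10:
[0.0304 0.0305 0.0358 0.0265 0.0268 0.0355 0.027  0.0265 0.0362 0.0267]
```

At 300 bp the expanded profiles separate the classes perfectly while the
averaged AMI profile is already close; the coding-class centroid shows
the period-3 signature (peaks at lags 3, 6, 9). The same operations are
available from the shell via the `ami-coding` CLI
(`simulate`, `extract`, `sample`, `profile`, `train`, `evaluate`,
`cross-species`, `centroids`); run `ami-coding --help`.

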