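# cageprom

Promoter properties from CAGE tag landscapes — with the sampling biases
taken seriously.

CAGE (Cap Analysis of Gene Expression) sequences the 5′ ends of capped
RNAs, so each tag marks one transcription-start event at base resolution
across hundreds of cell and tissue libraries. Two seemingly innocuous
analysis steps bias every downstream conclusion about promoter
architecture:

1. **Distance-based tag clustering** produces wider "promoters" wherever
   there are more tags, manufacturing a spurious correlation between
   expression level and TSS spread.
2. **Plug-in specificity indices** (Shannon entropy, pseudocount entropy,
   max/median expression) all drift with sequencing depth: a limited tag
   sample from a broadly expressed promoter looks spikier than the truth.

`cageprom` implements the bias-aware alternative: promoters are anchored
at locally maximal CAGE start sites near annotated TSSs and collect tags
in a **fixed ±d window** (default d = 50), and expression breadth is the
**entropy of a random sample of exactly n = 100 tags** per promoter, which
pins the sampling depth to a constant. On top of that it computes the
classical per-promoter sequence properties and asks which of their many
pairwise correlations are direct and which are explained away by stronger
ones.

## The quantities

For promoter *g* and sample *t* with x<sub>gt</sub> tags and library size
N<sub>t</sub>:

- expression: e<sub>gt</sub> = 10⁶·x<sub>gt</sub>/N<sub>t</sub> (tags per
  million);
- entropy (bits): H<sub>g</sub> = −Σ<sub>t</sub> p<sub>t</sub> log₂
  p<sub>t</sub>, p<sub>t</sub> = e<sub>gt</sub>/Σ e<sub>gt</sub>; 0 for a
  single-sample promoter, log₂ T for uniform expression;
- pseudocount entropy: the same on e′<sub>gt</sub> = (x<sub>gt</sub>+1) /
  (N<sub>t</sub>+N<sub>g</sub>), N<sub>g</sub> = number of promoters;
- expression breadth: entropy of a multinomial sample of 100 tags from
  x<sub>g·</sub> (the depth-fixed measure used in all correlations);
- richness: R<sub>n</sub> = Σ<sub>t</sub> [1 − (1 − p<sub>t</sub>)ⁿ], the
  expected number of samples holding ≥ 1 of n tags;
- TSS spread: IQR and SD of tag start coordinates in the fixed window;
- sequence features over the length-201 window centered on the anchor:
  %G+C; CpG observed/expected with expected = (L−1)(gc/2)²; best TATA-box
  log₂-odds match (uniform or per-promoter background); percent identity
  to a second species over the 100 bases upstream;
- Kendall tau-b for every property pair, first-order partial correlations
  T<sub>xy·z</sub> = (T<sub>xy</sub> − T<sub>xz</sub>T<sub>yz</sub>) /
  √((1−T<sub>xz</sub>²)(1−T<sub>yz</sub>²)), and a reduction that marks an
  association *indirect* when a third property has strictly stronger
  associations with both of its endpoints.

Because no public cohort is downloaded, the package ships a first-class
synthetic-data generator (`cageprom.synthetic_data`) that emulates a
FANTOM5-style atlas — heterogeneous library sizes, two CpG classes, two
TSS-spread classes, germ-cell samples, and expression breadth planted
independently of maximum expression level — with the direct correlation
network declared in `PLANTED_DIRECT_EDGES` as recoverable ground truth.

## Worked example

```python
import numpy as np
from cageprom import synthetic_data as sd
from cageprom.pipeline import synthetic_property_table, PROPERTY_COLUMNS
from cageprom.correlation_network import correlate_all, reduce_to_direct

cfg = sd.CohortConfig(seed=1)            # 120 samples, 2000 promoters
props, truths, matrix = synthetic_property_table(cfg)
res = correlate_all(props[PROPERTY_COLUMNS])
net = reduce_to_direct(res)
for e in sorted(net.direct_edges(), key=lambda e: -abs(e.tau)):
    print(f"direct  {e.x:>12s} ~ {e.y:<12s} tau={e.tau:+.3f}")
```

prints

```
direct       avg_tpm ~ max_tpm      tau=+0.717
direct       avg_tpm ~ germ_avg_tpm tau=+0.503
direct        gc_pct ~ tata_score   tau=-0.463
direct        cpg_oe ~ germ_avg_tpm tau=+0.397
direct        cpg_oe ~ gc_pct       tau=+0.376
direct  identity_pct ~ max_tpm      tau=+0.355
direct   entropy_100 ~ avg_tpm      tau=+0.286
direct           iqr ~ tata_score   tau=-0.264
direct           iqr ~ max_tpm      tau=-0.255
```

Of the 36 property pairs, 32 are significantly correlated in this cohort;
the reduction keeps exactly the nine directly coupled pairs the generator
planted, each with its planted sign, and discards the rest as indirect.
Reading the surviving edges: average expression is tied arithmetically to
maximum and to germ-cell expression; germ-cell expression preserves CpGs,
which drags %G+C along; TATA boxes are enriched in GC-poor promoters and
sharpen initiation; strong promoters initiate sharply and are better
conserved; and expression breadth raises *average* — not maximum —
expression.

A shell workflow over files (CTSS TSVs, BED, FASTA, JASPAR PFM) is
available through the `cageprom` CLI: `simulate`, `call`, `specificity`,
`bias-exp`, `seqfeat`-style features via the library, `correlate` and
`mosaic`. Run `cageprom --help` for the options.

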