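# aminogram

Estimation of the free amino acid / dipeptide / tripeptide composition of
postprandial blood from paired ninhydrin amine-group assays.

## The problem

After a protein-containing meal, digestion end products enter the blood both
as free amino acids and as short peptides (di- and tripeptides, carried by
the PepT1 transporter). Chromatographic methods struggle to quantify how much
of the circulating amino-acid pool arrived peptide-bound. A cheap alternative
measures free amine groups in a 10 kD plasma filtrate with the ninhydrin
reaction twice: before peptide-bond hydrolysis (**F**) and after complete
hydrolysis (**T**). Every peptide bond broken exposes one new α-amine, so a
dipeptide gains 1 amine group on hydrolysis and a tripeptide gains 2, and the
ratio **W = T/F** carries information about the mixture: W = 1 means pure free
amino acids, while W = 3 is the model ceiling, reached only by tripeptides
with a single amine group. About 30 % of residues (Gln, Arg, …) carry a
second reactive amine, which blurs the picture — a free glutamine reads as 2
amino acids, the tripeptide QQQ as 4.

## The model

Normalising F = 1 and writing `A` for free amino acids, `x = x1+x2+x3` for
dipeptides and `y = y1+y2+y3+y4` for tripeptides (classes indexed by intact
amine-group count), the balance equations are

```
A + x1 + 2x2 + 3x3 + y1 + 2y2 + 3y3 + 4y4 = F = 1
T − F = x + 2y = W − 1
```

With the structural conventions `x1 = (1−α)x, x2 = x3` and
`y1 = (1−β)y, y2 = y3 = y4` (α, β ∈ [0, 0.3] the two-amine fractions), every
composition consistent with a given W is a point `(α, β, A)` of a 3-D
feasible set with

```
max(1 − (1+1.5α)(W−1), 0)  ≤  A  ≤  1 − (1+2β)(W−1)/2
x = [1 − A − (1+2β)(W−1)/2] / [0.5 + 1.5α − β],   y = (W − 1 − x)/2
```

Treating all feasible points as equally probable, the **mean structure** is
the expectation of the share triples — before hydrolysis `(a*, x*, y*)` of F,
after hydrolysis `(a′, x′, y′)` of T — computed either by deterministic
nested quadrature or by rejection Monte-Carlo. For meal-test time series, the
baseline-adjusted total signal at each time point is split by the
after-hydrolysis shares and integrated, giving the additive decomposition
`AUC_T = AUC_F + AUC_DD + AUC_TD` (free, dipeptide-derived,
tripeptide-derived amino-acid equivalents, µg/mL·min).

## Worked example

```python
from aminogram import mean_structure

for W in (1.0, 1.5, 2.0, 2.5, 3.0):
    s = mean_structure(W)
    print(W, s.after)
```

prints (after-hydrolysis shares: free, dipeptide-derived, tripeptide-derived):

```
W = 1.0  after = (1.000, 0.000, 0.000)
W = 1.5  after = (0.351, 0.376, 0.273)
W = 2.0  after = (0.093, 0.356, 0.551)
W = 2.5  after = (0.033, 0.112, 0.855)
W = 3.0  after = (0.000, 0.000, 1.000)
```

At W = 2, an estimated 9 % of the total postprandial amino acids arrived
free, 36 % inside dipeptides and 55 % inside tripeptides. The `examples/`
directory has one short script per capability: amine counting
(`01_amine_counting.py`), mean structures (`02`), the full cohort AUC
pipeline on synthetic meal tests (`03`), and parameter recovery (`04`).

A thin CLI wraps the library:

```bash
aminogram estimate --w 2.0
aminogram simulate --scenario scenario.yaml --output cohort.csv
aminogram decompose --input cohort.csv --output decomp.csv
aminogram summarize --input decomp.csv
```

## Limitations

The uniform-average estimator is an interval summary: a single W pins down a
set of compositions, not a point, so even noise-free recovery carries a
bounded systematic offset (see `docs/methods.md`). Peptides longer than three
residues are deliberately excluded; readings with W > 3 are clamped and
flagged as evidence of such peptides rather than estimated.
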