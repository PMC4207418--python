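# qspr-bioavail

Quantitative structure–property relationship (QSPR) modelling of **percent
oral bioavailability (%F)** for drug-like small molecules. The package is
aimed at computational chemists who want a transparent, fully reproducible
re-implementation of a classic ADME modelling workflow: compute a small
panel of interpretable molecular descriptors from structure, split the
dataset rationally, and map descriptors to %F with a memory-based kernel
regressor, with simple absorption classifiers in the (AlogP, PSA) plane as
a baseline.

## What it computes

**Descriptors** (for each prepared molecule — explicit hydrogens, one
energy-minimised 3D conformer, Gasteiger partial charges):

- *topological*: number of single bonds (NSB, including bonds to H),
  number of aromatic bonds (NAB), counts and relative counts of O and N
  atoms (relative = count / total atoms including H);
- *electronic*: maximum partial charge over hydrogen atoms;
- *geometric*: GRAV-3 = (Σ_{i<j} m_i m_j / r_ij²)^{1/3} over all atom
  pairs; SAAA = mean solvent-accessible surface area per hydrogen-bond
  acceptor (N/O) atom; SHDW-6 = normalized YZ-plane shadow after
  principal-axis alignment;
- *hybrid (CPSA)*: HASA-2 = Σ_A |q_A|·√S_A over acceptor atoms;
- plus **AlogP** (Ghose–Crippen) and **PSA** (Ertl topological polar
  surface area) for the absorption-plane models.

**Models**

- a 95% confidence ellipse for the well-absorbed class in the
  (AlogP, PSA) plane — well-absorbed iff the squared Mahalanobis distance
  (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(0.95) ≈ 5.991;
- a single CART decision tree (Gini impurity) on the same two variables;
- a **general regression neural network** (GRNN, Specht): Nadaraya–Watson
  kernel regression ŷ(x) = Σᵢ yᵢ K(x,xᵢ) / Σᵢ K(x,xᵢ) with Gaussian kernel
  K = exp(−‖x̃−x̃ᵢ‖²/2σ²) on autoscaled descriptors; the single bandwidth σ
  is chosen by golden-section search to minimise test-set RMSE.

**Splitting** is by sphere exclusion: training compounds are picked
farthest-point-first in autoscaled descriptor space and every unassigned
compound within the exclusion radius joins the test set, so training
compounds are mutually dissimilar. An external validation set is selected
beforehand at quantile-spaced positions of %F so it spans the observed
response range.

Because the original 217-compound collection this workflow was built
around is not publicly deposited, the `synthetic_data` module generates
statistically matched substitutes (descriptor ranges, high-%F bias,
labeled absorption clouds) plus a panel of real drug SMILES fixtures.

## Worked example

```bash
$ qspr run --out demo --seed 7
train: R2=0.994 RMSE=0.89 n=159
test: R2=0.329 RMSE=8.05 n=50
external: R2=-0.028 RMSE=18.29 n=8
```

This simulates a 217-compound dataset, splits it 159/50/8 by sphere
exclusion (the 8 external compounds cover the %F range), trains the GRNN
with test-set bandwidth monitoring, and writes `desc.csv`, `split.json`,
`model.json`, `pred.csv`, `report.json`, `corr.csv` and `run.json` into
`demo/`. The printed lines are the per-split coefficient of determination
and root-mean-square error in %F units: the near-perfect training fit with
a markedly larger test error is the expected signature of a memory-based
kernel regressor, and the external error is largest because those eight
compounds sit at the extremes of the response range. Individual stages are
available as `qspr simulate / descriptors / split / ellipse / tree /
train-grnn / predict / evaluate`; for example

```bash
$ qspr split --in demo/desc.csv --out split.json
split 217 rows into 159/50/8 (radius 2.125)
$ qspr train-grnn --desc demo/desc.csv --split split.json --out model.json
selected sigma 0.8809; final test RMSE 8.049 %F units
```

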