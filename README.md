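# phfcorr

Correlation coefficients for **probabilistic hesitant fuzzy sets** (PHFSs)
and a correlation-based **multi-criteria group decision** pipeline, with an
orphan-drug appraisal case study shipped as an executable fixture.

## The scientific problem

When several experts evaluate alternatives, each may hesitate among several
membership degrees, and the group may prefer some degrees over others.  A
PHFS captures this: every item gets a set of `(membership | probability)`
pairs whose probabilities sum to 1.  To rank alternatives one needs a
*correlation coefficient* between two PHFSs — in particular between each
alternative and a synthetic *ideal alternative*.

The classical mean/variance (Pearson-style) coefficient for PHFSs has a
blind spot: it only sees each element's probability-weighted **mean**
membership.  Two very different PHFSs with equal per-element means get
correlation exactly 1.  This package implements a family of coefficients
built on **information energy** — length-normalized sums of squared
`membership × probability` products — which sees the full distribution:

- `rho1` / `rho2`: unweighted, normalized by the geometric mean or the
  maximum of the two self-energies;
- `rho3` / `rho4`: criteria-weighted analogues used for ranking;
- baselines for comparison: the mean/variance coefficient and a
  probability-free hesitant-fuzzy-set coefficient.

On top sits a group-decision pipeline: linguistic expert matrices (terms
`VL` … `VH` on Saaty's 1–9 scale) are weighted, merged, normalized per
criterion (benefit/cost), condensed into a probabilistic hesitant fuzzy
group matrix, and ranked by weighted correlation `rho3` with the ideal
alternative.

## Worked example

Three PHFSs whose per-element means are identical.  The mean/variance
baseline cannot tell them apart; the information-energy coefficient can:

```python
from phfcorr import PHFSet, information_energy, rho1, baseline_mean_variance_rho

A = PHFSet([
    [(0.3, 1/2), (0.5, 1/2)],
    [(0.3, 1/3), (0.6, 1/3), (0.9, 1/3)],
    [(0.1, 1/4), (0.2, 1/4), (0.8, 1/4), (0.9, 1/4)],
])
B = PHFSet([
    [(0.1, 1/2), (0.7, 1/2)],
    [(0.2, 1/3), (0.7, 1/3), (0.9, 1/3)],
    [(0.3, 1/3), (0.5, 1/3), (0.7, 1/3)],
])

print(f"psi(A) = {information_energy(A):.4f}")
print(f"psi(B) = {information_energy(B):.4f}")
print(f"rho1(A, B)     = {rho1(A, B):.4f}")
print(f"mean/var rho   = {baseline_mean_variance_rho(A, B):.4f}")
```

Output:

```
psi(A) = 0.1126
psi(B) = 0.1429
rho1(A, B)     = 0.9302
mean/var rho   = 1.0000
```

Running the full group-decision pipeline on the embedded orphan-drug case
study (four experts, five drugs, four criteria):

```python
from phfcorr import load_fixture, evaluate

res = evaluate(load_fixture("case-study").payload["problem"], rounding="paper")
print("criteria weights:", res.criteria_weights)
for name, c in zip(res.ranking.alternatives, res.ranking.coefficients):
    print(f"  {name}: {c:.4f}")
print("ranking:", str(res.ranking))
```

Output:

```
criteria weights: (0.21, 0.31, 0.39, 0.09)
  A1: 0.7708
  A2: 0.8932
  A3: 0.9589
  A4: 0.6794
  A5: 0.4699
ranking: A3 > A2 > A1 > A4 > A5
```

## Command line

```sh
phfcorr score my_set.json                 # score/deviation per element
phfcorr corr --method rho1 a.json b.csv   # correlation report (JSON)
phfcorr corr --method rho3 --weights 0.5,0.3,0.2 a.json b.json
phfcorr evaluate --rounding paper problem.json   # group-decision ranking
phfcorr fixtures list                     # embedded worked examples
phfcorr fixtures run case-study           # recompute one and compare
```

PHFSets are JSON (`[[{"m": 0.2, "p": 0.6}, ...], ...]`) or CSV
(`0.2|0.6;0.8|0.4` per row); decision problems are JSON (see
`phfcorr.serialize`).  Validation errors exit 1, usage errors exit 2;
`--debug` logs intermediate matrices to stderr.

## Reproduction

All published values the package claims to reproduce are embedded as
fixtures and recomputed at test time — nothing numeric is cached.

```sh
pip install --no-build-isolation -e .[test]
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline target values (scores,
energies, coefficients of the worked examples and the case study) at
runtime and writes them as JSON.  One acceptance test is intentionally
red: a single published comparison-table coefficient (the fourth
alternative's) does not recompute under the stated formulas from the printed
inputs; see `docs/methods.md` ("Known irreproducible published values")
for the analysis.  Everything else is green.

See `docs/methods.md` for the model, formulas, numerical conventions and
limitations.
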