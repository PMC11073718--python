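# Methods

## Model

A **probabilistic hesitant fuzzy element** (PHFE) on one universe item is a
finite set of pairs `h = {γ₁|p₁, …, γ_l|p_l}` with memberships
`γ ∈ [0, 1]`, probabilities `p ∈ [0, 1]`, and `Σp = 1` (tolerance `1e-9`).
A **PHFS** assigns one PHFE to each of `n` universe items.

Two scalar summaries order PHFEs:

- **score** `s(h) = Σ γᵢ pᵢ` — the probability-weighted mean membership;
- **deviation** `δ(h) = Σ (γᵢ − s(h))² pᵢ` — the probability-weighted
  squared dispersion about the score.

`compare(h₁, h₂)` orders by score; at equal score the element with the
*smaller* deviation is greater (less internal disagreement wins).

## Canonical form and length equalization

Correlation sums pair entries positionally, so both elements of a pair are
put in a canonical form first:

1. **Sort** entries ascending by `F = γ·p` (ties broken by `(γ, p)`
   ascending).  Note that `F`-order is not membership order: `0.3|0.3`
   (`F = 0.09`) sorts before `0.2|0.7` (`F = 0.14`).
2. **Pad** the shorter element up to the common length by *prepending*
   copies of an entry whose membership equals the membership of the
   current minimum-`F` entry and whose probability is 0.  The padding
   entry has `F = 0` and therefore sorts first; probability sums and
   scores are unchanged.  This is the **pessimistic** convention (the
   repeated value is the "worst" entry by `F`); an optimistic variant
   (repeat the maximum-`F` entry) is available behind the `Padding` flag.

## Information-energy correlation

For a PHFS `A` with elements `h₁ … h_n` of (unpadded) lengths `lᵢ`:

- **information energy** `ψ(A) = Σᵢ (1/lᵢ) Σⱼ (γᵢⱼ pᵢⱼ)²`;
- **cross-correlation** `C₁(A, B) = Σᵢ (1/Lᵢ) Σⱼ γ^A γ^B p^A p^B`, where
  the pair of elements at item `i` is canonically sorted and padded to the
  common length `Lᵢ = max(l^A_i, l^B_i)`.

A deliberate asymmetry of length conventions: the cross term uses the
**aligned (max) length**, while each self-energy in the denominator uses
that set's **own unpadded lengths**.  This is the convention under which
the published worked examples and decision tables reproduce to four
decimals; using aligned lengths in the denominators does not reproduce
them.  Padding entries contribute 0 to the cross sum (their probability is
0), so only the `1/Lᵢ` normalization feels the alignment.

Coefficients:

- `rho1(A, B) = C₁(A, B) / √(ψ(A) ψ(B))`
- `rho2(A, B) = C₁(A, B) / max(ψ(A), ψ(B))`
- `rho3`, `rho4`: weighted analogues with item weights `wᵢ ≥ 0`, `Σw = 1`,
  multiplying the per-item terms of both the cross sum and the energies.
  Uniform weights `wᵢ = 1/n` degenerate `rho3 → rho1` and `rho4 → rho2`
  exactly (up to float round-off `≤ 1e-12`).

Properties (enforced by tests on ≥10⁴ random pairs): symmetry, range
`[0, 1]`, self-correlation 1, `rho2 ≤ rho1`, `rho4 ≤ rho3`, and the
Cauchy–Schwarz bound `C₁(A,B)² ≤ ψ(A)ψ(B)`.  A set whose energy is 0
(all memberships or probabilities zero) has no defined coefficient;
`ZeroEnergyError` (a `ZeroDivisionError` subclass) is raised.

## Baselines

- **Mean/variance coefficient**: Pearson correlation of the per-element
  score vectors `(s(h₁), …, s(h_n))`.  Its blind spot motivates the energy
  family: any two PHFSs with equal score vectors correlate exactly 1
  regardless of their distributions.  A weighted form multiplies the score
  vectors by the item weights before correlating.  Degenerate (constant)
  score vectors raise `ZeroEnergyError`.
- **HFS coefficient**: for probability-free hesitant elements, values are
  sorted ascending, the shorter element is padded by repeating its
  minimum, and `Σᵢ (1/Lᵢ) Σⱼ γ^A γ^B` is normalized by the geometric mean
  of the self-terms.  Unweighted by default; item weights optional.

## Group-decision pipeline

`evaluate(problem, rounding)` runs, in order:

1. **Linguistic scale**: nine terms `VL, VLL, L, ML, M, MH, H, HVH, VH`
   map to Saaty values 1–9.
2. **Criteria weights**: either supplied directly, or integrated from
   per-expert importance terms — `integrated_j = Σ_k expert_weight_k ×
   saaty(term_kj)`, normalized to sum 1.
3. **Numeric matrices**: each expert's term grid becomes
   `saaty(term) × expert_weight`.
4. **Group matrix**: cell `(alternative, criterion)` collects the k expert
   values, ascending.
5. **Normalization** into `(0, 1]`: benefit columns divide by the column
   maximum; cost columns divide the column minimum by each value.
6. **Probabilistic merge**: equal values within a cell (tolerance `1e-9`)
   merge with probability = frequency / k.
7. **Ideal alternative**: per criterion, the cell with the maximal score;
   score ties (within `1e-9`) broken by minimal deviation, remaining ties
   by lowest alternative index.
8. **Ranking**: descending `rho3` of each alternative's row against the
   ideal; exact coefficient ties keep input order and are reported.

## Numerical choices

- All inner sums use `math.fsum`; no floating-point summation drift at the
  problem sizes involved (n and l are single digits; nothing here warrants
  vectorized numerics, so there is no numpy dependency).
- `rounding="paper"` rounds every normalized matrix value to two decimals
  **half-up** (`decimal.Decimal` quantization — `0.625 → 0.63`, where
  banker's rounding would give `0.62`) before the probabilistic merge.
  This is the convention under which the published two-decimal decision
  tables and their four-decimal coefficients reproduce, and is what the
  shipped fixtures pin.  `rounding="precise"` (the default) carries full
  precision; it yields the same top and bottom alternatives on the case
  study but slightly different coefficients.
- Published four-decimal values are asserted at an absolute tolerance of
  `5e-5` (half a unit in the last printed place).
- The random generator (`GeneratorConfig`) is `random.Random`-seeded and
  byte-deterministic; memberships are uniform on `[0, 1]`, probabilities
  either normalized-uniform ("flat Dirichlet") or equal.

## Known irreproducible published values

The embedded fixtures pin only published values that actually recompute
under the stated formulas.  Three documented exceptions:

- **Comparison coefficient table, A4** (printed 0.7706): recomputes to 0.7769 from
  the printed inputs under the stated conventions; an extensive sweep of
  alternative sort/pad/length conventions reproduces none that also
  preserve the other three entries (0.7755, 0.9092, 0.8626, which all
  reproduce to 4 dp).  The corresponding acceptance test is intentionally
  left red rather than weakened.  The published *ranking* A2 ≻ A3 ≻ A1 ≻
  A4 does reproduce end-to-end when the ideal is recomputed by the
  max-score rule.
- **HFS comparison table, A5** (printed 0.9515): recomputes to ≈0.9509
  under both weighted and unweighted forms; only the A1 entry (0.9943,
  which reproduces exactly) is pinned.
- **Mixed-method comparison table**: its printed ideal selects a
  lower-scoring element for one criterion, contradicting the max-score
  rule; no numeric expectations are pinned for that example (inputs are
  shipped for completeness).

## Limitations

- Probabilities must sum to 1 per element; partial/normalizable
  probability vectors are not auto-normalized (validation rejects them).
- The mixed mean/variance/length-rate coefficient family is out of scope;
  only the mean/variance and HFS baselines are implemented.
- The pipeline assumes one flat criteria level (no hierarchies) and
  crisp expert weights.
- `rounding="paper"` exists to reproduce two-decimal published tables;
  for new analyses use the default full-precision mode.
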