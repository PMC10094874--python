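# biopotency

Quantitative bioactivity accounting for bioactivity-guided purification
campaigns (natural-product fractionation, extract screening).

The central quantities:

- **EDV₅₀** (half-maximal effective dilution volume, L/g) — the reciprocal
  of an IC₅₀/EC₅₀ expressed in g/L. Unlike the IC₅₀ it *increases* with
  potency: an extract with IC₅₀ = 1 µg/mL (10⁻³ g/L) has EDV₅₀ = 10³ L/g,
  meaning 1 g can be diluted into 1000 L and still give half-maximal effect.
- **Total bioactivity (TBA, L)** = EDV₅₀ × solid weight. Because TBA is
  linear in mass it supports mass-balance bookkeeping: summing the TBA of
  fractions against their parent extract measures how much bioactivity
  survived a purification step, and comparing bioactivity recovery to mass
  recovery distinguishes additive mixtures (they match) from ones that lost
  synergy or suffered degradation.

## What's inside

| module | contents |
|---|---|
| `biopotency.potency` | unit-safe concentration parsing (µg/mL, mg/L, mg/mL, g/L), the IC₅₀↔EDV₅₀ transform, 4PL/3PL dose–response fitting from raw serial-dilution readouts, right-censoring of out-of-range potencies, delta-method + Monte-Carlo uncertainty propagation |
| `biopotency.ledger` | `MaterialNode` / `PurificationTree` data model, `compute_tba`, per-gram normalization, rounded/unrounded sums, mass & TBA recovery, additive-vs-reduced-vs-increased interaction classification, full campaign reports |
| `biopotency.io` | campaign CSV and `tba-tree v1` JSON readers/writers, report rendering (csv/json/markdown), chromatogram-overlay export, packaged Grey Myrtle example campaign (solvent extracts + 17 HPLC fractions) |
| `biopotency.synthetic` | ground-truth simulator: dose-additive mixture potency with a tunable synergy factor, fractionation campaigns with known loss, simulated dilution plates |
| `biopotency.cli` | `biopotency convert | fit | report | simulate` |

## CLI examples

```bash
# IC50 -> EDV50
biopotency convert --ic50 14.09 --unit ug/ml          # -> 70.97 (L/g)

# campaign report from the packaged example (mg-scale fraction table style)
biopotency report \
    --input src/biopotency/data/grey_myrtle_fractions.csv \
    --round fraction --format markdown

# fit a dose-response curve from raw readouts
biopotency fit --input plate.csv --model 4PL

# simulate a lossless additive fractionation and verify 100% TBA recovery
biopotency simulate --compounds 10 --fractions 5 --loss 0 --synergy 0 \
    --seed 1 --out scratch/sim
biopotency report --input scratch/sim/campaign.csv --format json
```

Plate CSVs carry the header `concentration,unit,response_pct,replicate`;
campaign CSVs use the schema in `src/biopotency/data/grey_myrtle_extracts.csv`.

## Library quick start

```python
from biopotency import io, compute_tba, sum_tba, recovery

tree = io.grey_myrtle_fractions()
parent = tree["dcm"]
children = tree.children("dcm")
rep = recovery(parent, children, tba_addend_decimals=3)
print(rep.mass_recovery_pct, rep.tba_recovery_pct, rep.interaction_class)
# 2.6125 2.100... InteractionClass.EQUIVALENT  (additive behaviour)
```

Rounding is presentation-only: stored values are never rounded, and
`RoundingPolicy.extract_table()` / `.fraction_table()` exist solely to
reproduce published gram-scale (2-dp) and mg-scale (3-dp, rounded-addend
totals) tables.

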