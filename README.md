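# healthscaling

Rank-size (Zipf) and allometric scaling analysis of urban health-resource
panels — for health-geography and regional-planning researchers who want to
ask, from a plain city–year table of GDP, hospital beds and doctors:

* **How concentrated is a year's resource distribution across cities?**
  The rank-size rule `P_i = P_1 · R_i^(−q)` is fit by OLS on logs,
  `ln P_i = ln P_1 − q·ln R_i` (optionally with the small-sample rank
  correction `R_i − ½`).  `q < 1` indicates a balanced hierarchy, `q = 1`
  the canonical Zipf distribution, `q > 1` a concentrated (primate) one.
* **Do resources grow faster or slower than the urban economy?**  The
  allometric model `A = k·G^b`, fit as `ln A = k + b·ln G`, estimated
  *vertically* (across cities within a year) and *horizontally* (across
  years within a city over two time windows).  The exponent is banded into
  six ordered levels at thresholds 2, 1, 0.85, 0.5 and 0, and each city's
  movement between windows is typed (stable / upgrade / decline, *fast* when
  it jumps two or more grades).

Around that core the package provides panel I/O (CSV/XLSX with schema
validation), map-preparation transforms (percent-of-total normalisation and
exact Jenks natural-breaks classification), headline percent-change
statistics, a synthetic city-panel generator with known ground truth, and a
CLI that runs the whole study end to end.

## Worked example

```python
import healthscaling as hs

cfg = hs.SyntheticConfig(n_cities=41, seed=42)   # 41 cities, 2009-2022
panel = hs.generate_panel(cfg)

fit = hs.rank_size_fit(panel.loc[panel.year == 2009, "beds"], "shifted")
print(f"Zipf q (beds, 2009) = {fit.q:.3f}  R2 = {fit.r2:.3f}  -> {hs.interpret_q(fit.q)}")

vf = hs.vertical_allometry(panel, "beds", 2009)
print(f"vertical b (beds, 2009) = {vf.b:.4f}  R2 = {vf.r2:.4f}  level = {vf.level.label}")

hf1 = hs.horizontal_allometry(panel, "beds", "C001", (2009, 2015))
hf2 = hs.horizontal_allometry(panel, "beds", "C001", (2016, 2022))
ch = hs.change_typology(hf1, hf2)
print(f"city C001: {ch.level_before.label} -> {ch.level_after.label}  ({ch.change_type})")

print(f"percent change of b endpoints: {hs.percent_change(1.2162, 1.1723):.2f}%")
```

prints

```
Zipf q (beds, 2009) = 1.042  R2 = 0.801  -> concentrated
vertical b (beds, 2009) = 1.2048  R2 = 0.9159  level = Positive2
city C001: Positive2 -> Positive2  (stable)
percent change of b endpoints: -3.61%
```

The first line says the 2009 synthetic bed distribution is slightly more
top-heavy than canonical Zipf; the second that beds scale superlinearly with
GDP across cities (`b ≈ 1.20`, close to the generator's ground truth 1.2, a
second-level positive allometry: beds grow faster than the economy); the
third that city `C001` stayed in the same allometric level across the two
windows; the last applies the percent-change statistic to two allometric
coefficients, here a 3.61 % decline.

The same analysis on a real panel:

```sh
healthscaling report --input panel.csv --out-dir out/ \
    --convention shifted --window-a 2009:2015 --window-b 2016:2022
```

writes `ranksize.csv`, `vertical.csv`, `horizontal.csv`, `changes.csv`,
`summary.csv`, `totals.csv` and a `manifest.json` under `out/`.  A synthetic
end-to-end run is `healthscaling run-all --seed 0 --out-dir out/`; see
`healthscaling --help` for the other subcommands (`simulate`, `ranksize`,
`allometry-vertical`, `allometry-horizontal`, `classify-changes`).

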