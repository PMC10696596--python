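# sulfoscan

Tools for telling **sulfotyrosine (sY)** apart from **phosphotyrosine
(pY)** in tandem mass spectrometry data.

The two modifications are near-isobaric — Δm(sY) = +79.956815 Da (SO3)
versus Δm(pY) = +79.966331 Da (HPO3), a gap of only ~9.5 mDa — so at a
typical 25 ppm tolerance a search engine cannot separate them by mass,
and database searches routinely annotate genuine sulfopeptides as
phosphopeptides. What does separate them is gas-phase chemistry: at
gentle HCD activation (10% normalized collision energy) a sulfopeptide
precursor sheds SO3 almost quantitatively, putting 20–100% of the MS2
ion current (population median ≈ 85%) into a −79.9568·k Da loss ladder,
while phosphopeptides lose less than 1% combined of either −80 (HPO3) or
−98 (H3PO4). sulfoscan implements the desk side of a workflow built on
that contrast, for proteomics researchers working on protein
tyrosine sulfation:

* **`sulfoscan.chem`** — monoisotopic mass arithmetic from a hard-coded
  atomic-mass table, a modification registry (sulfo, phospho, oxidation,
  carbamidomethyl, deamidation), and the bracket peptide notation
  (`EDFED[sY]EFDGK`, `M[ox]`).
* **`sulfoscan.spectra`** — a centroided MS2 data model with MGF
  read/write and minimal (MS2-only) mzML reading.
* **`sulfoscan.fragments`** — theoretical a/b/c/y/z ions, ppm peak
  matching, and the site-determining-ion coverage score: the fraction of
  site-containing *cleavage groups* (all series/charge variants of one
  backbone bond, counted once) whose matched ions still carry the Δ80
  mass shift.
* **`sulfoscan.simulate`** — a seeded ground-truth spectrum generator
  reproducing the sY/pY low-NCE loss statistics, the mobile-proton
  dependence (loss collapses to ~20% when charge ≤ #H/K/R), and the
  near-total sulfonate stripping from fragments at 32% NCE.
* **`sulfoscan.neutral_loss`** — the per-scan neutral-loss report
  (−80·k / −98 matches with TIC fractions), the acquisition trigger rule
  (any SO3×k loss at ≥10% base-peak intensity, charge-consistent,
  25 ppm), and the sulfated/phosphorylated/none classifier built on
  −80-versus−98 preference.
* **`sulfoscan.psm`** — the post-search cascade: deduplicate PSMs per
  scan (best −log10 P), filter modified Tyr to the acidic consensus
  (D/E at ±1), collapse to unique sites, and reconcile sulfo/phospho
  annotations against the linked survey-scan evidence; plus charge-state
  and retention-time-shift panel summaries.

## Worked example

```python
from sulfoscan import (SimParams, parse_peptide, simulate_low_nce_scan,
                       neutral_loss_report, trigger, classify)

p = parse_peptide("EDFED[sY]EFDGK")
params = SimParams(seed=42)
scan = simulate_low_nce_scan(p, 2, params, params.rng())

report = neutral_loss_report(scan, tol_ppm=25)
print(f"-80 TIC fraction: {report.so3_fraction:.2f}")
print(f"survivor fraction: {report.survivor_tic_fraction:.2f}")
print(trigger(scan).reason)
print(classify(report).verdict)
```

prints

```
-80 TIC fraction: 0.82
survivor fraction: 0.18
SO3x1 window peak at 100% of base peak
sulfated
```

i.e. 82% of this survey scan's ion current sits on the −80 peak, the
loss-continuation trigger fires (the −80 peak is the base peak), and the
precursor is called sulfated. A phosphopeptide under the same conditions
keeps ~99.5% of its current on the surviving precursor and is never
triggered. The `examples/` scripts walk through each capability:
moiety-mass arithmetic, panel simulation + classification, site-coverage
scoring, and the filter cascade.

A thin CLI mirrors the library:

```bash
sulfoscan simulate --seed 3 --out run.mgf --truth truth.tsv
sulfoscan classify --in run.mgf --out reports.tsv
sulfoscan evaluate --in run.mgf --truth truth.tsv
sulfoscan filter --psms psms.tsv --out-dir out/
```

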