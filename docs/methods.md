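# Methods

## The discrimination problem

Tyrosine sulfation (+SO3, 79.956815 Da) and tyrosine phosphorylation
(+HPO3, 79.966331 Da) shift a peptide's mass by amounts that differ by
9.516 mDa. On a doubly charged tryptic peptide that is a ~5–7 ppm m/z
separation — inside any realistic search or acquisition tolerance — so
neither precursor mass nor search-engine score discriminates the two.
The separable signal is gas-phase lability: the sulfoester bond breaks
far below the energy needed for backbone fragmentation, so a gentle
(10% NCE) HCD scan of a sulfopeptide is essentially a two-peak spectrum
(surviving precursor plus a −79.9568·k Da ladder, one rung per sulfate,
at the precursor charge), whereas phosphopeptides at the same energy
lose almost nothing, and what they lose under stronger activation is
preferentially the 97.9769 Da H3PO4 neutral rather than 80. Every
component of this package is built around that contrast.

## Mass arithmetic

All masses are computed from a hard-coded table of current NIST/CODATA
monoisotopic atomic masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.99491461956, S 31.97207100, P 30.97376163), which reproduces the
literature moiety values exactly at six decimals; slightly older tables
miss the HPO3 value by 1 µDa at the sixth decimal. The proton mass
1.00727646688 Da (not the H-atom mass) carries charge arithmetic.
Fragment series follow the usual conventions: a = b − CO, c = b + NH3,
y = b-complement + H2O, and z is the z-dot radical (y − NH2,
16.018724 Da), the ETD convention on the instrument family modeled.
Positions are 1-based; at most one modification per residue.

## Site-determining-ion coverage

Localization evidence is counted per backbone bond, not per ion: a4, b4
and y(n−4) all witness cleavage of bond 4 and together form one
*cleavage group*. Coverage for a site is the fraction of theoretical
site-containing groups with at least one matched ion that still carries
the modification delta. Neutral-loss fragment variants (site ion minus
SO3/H2SO4 or HPO3/H3PO4) are generated on request but never count
toward the retaining numerator — an ion that lost its sulfate is
indistinguishable from the unmodified fragment and proves nothing about
the site. Heat-map cells report log2(coverage + 1) per cell; a
condition/peptide with no identified spectrum propagates as NaN,
deliberately distinct from an identified spectrum with zero coverage.
(The alternative reading — averaging raw retained-ion counts before the
ratio — was considered and not used; per-cell ratios keep cells
comparable across peptides of different lengths.)

## Synthetic spectrum generator

The simulator exists so the trigger, classifier, and cascade can be
exercised against known ground truth without instrument data. What it
emulates, and its defaults:

* **Panel.** Twelve sulfation-site tryptic peptides: five sequences from
  characterized secreted-protein sulfation sites and seven synthetic
  acidic-consensus peptides constructed for this package (marked
  synthetic in `simulate.py`), plus phospho/unmodified variants of the
  same sequences.
* **Charge states.** Sulfopeptides present at 2+ and reach 3+ only with
  ≥2 basic residues (sulfation suppresses higher charge); phospho and
  unmodified peptides present at 2+ and 3+. This yields 14 sulfopeptide
  precursor ions per panel pass.
* **Low-NCE loss fraction (sY).** Drawn as 0.2 + 0.8·Beta(8, 1.7948).
  The shape was solved once (Brent's method on the Beta quantile) so
  that the default-panel population — including the immobile-proton
  scans pinned near 20% — has a median −80 TIC fraction of exactly 0.85
  and stays within the observed 20–100% band. Multi-site peptides split
  the loss current 0.65/0.25/0.10 across the −80/−160/−240 rungs.
* **Mobile-proton dependence.** When precursor charge ≤ #(H/K/R) the
  sampled fraction is shrunk toward the band floor:
  f′ = 0.2 + 0.05·(f − 0.2), landing immobile precursors at ~20–24%.
  A plain multiplier would leak below the observed 20% floor, which is
  why the shrink acts on the excess above it.
* **Low-NCE loss (pY).** A constant 0.5% of the ion current, split
  80/20 between −98 (H3PO4) and −80 (HPO3) — the "<1%, and 98 over 80"
  regime.
* **High-NCE scans.** A full b/y ladder (charges 1..min(2, z)) with
  log-normal intensities; each site-containing fragment retains the
  labile group with probability 0 for sulfo (every fragment appears at
  the unmodified mass) and 0.6 for phospho.
* **Noise and mass error.** Ten Dirichlet-weighted noise peaks carrying
  1% of the residual current, and 3 ppm Gaussian multiplicative m/z
  jitter on every peak. All randomness flows from one seeded
  `numpy.random.Generator`; a seed determines the MGF byte-for-byte.

What it does **not** emulate: isotope envelopes, chromatographic peak
shape, co-isolation/chimeric spectra, intensity-dependent mass error,
ETD/UVPD physics, and real search-engine scoring. Passing tests
therefore demonstrate the correctness of the measurement and decision
logic under the modeled loss statistics, not performance on raw
instrument files.

## Neutral-loss report, trigger, and classifier

For each survey scan the report searches six candidate losses (SO3×1–3,
H2SO4, HPO3, H3PO4) at `precursor_mz − loss/z` within a 25 ppm window
(the acquisition method's tolerance), assigning each peak to at most one
loss by m/z proximity so TIC fractions conserve:
survivor + Σlosses + unassigned = 1. With an undeclared precursor
charge, charges 2–5 are evaluated and the best-supported kept (largest
matched loss current; ties to lower charge).

Two intensity conventions coexist deliberately: the **trigger** uses
base-peak-relative intensity (threshold 10%), the instrument-style rule,
while the reported statistic is TIC-relative, and the surviving
precursor is included in the TIC denominator. The trigger searches the
SO3×k windows directly on the peak list and is scale-invariant.

Within one 25 ppm window the SO3 and HPO3 losses are not resolvable
(~7 ppm apart at panel m/z), so the classifier's "−80 family" pools
SO3×k with HPO3, and the "−98 family" pools H2SO4 with H3PO4; the
verdict rests on 80-versus-98 preference: *sulfated* when the −80
family holds ≥10% of the ion current and at least matches the −98
family; *phosphorylated* when −98 clears the threshold and dominates;
*none* when both are sub-threshold; *ambiguous* otherwise. The
estimated site count is the deepest matched −80·k rung, capped at 3 to
mirror the acquisition method.

## PSM cascade

Deduplication keeps the best PSM per scan (score, then |Δppm|, then
lexicographic peptide — fully deterministic). The acidic-consensus
filter keeps a PSM iff some modified Tyr has D/E at +1 or −1 *within
the peptide*; a modified Tyr at a tryptic terminus is judged on its
single in-peptide neighbor, since the cleaved-off neighbor is unknowable
at the peptide level. Site collapse keys by (protein, protein position)
when protein sequences are supplied (falling back with a warning when
the peptide is not found) and otherwise by (peptide sequence, position);
oxidation/deamidation elsewhere on the peptide does not split a site.
Because score and mass error cannot separate the isobaric pair,
reconciliation uses only the linked survey-scan classification: a
phospho annotation with sulfated −80 evidence is re-called sulfo (and
vice versa), ambiguous evidence is flagged, and an NL site-count
estimate exceeding the annotated count flags second-site review. Charge
distributions weight by precursor intensity when available, else by
count. RT shifts are modified-minus-unmodified means with SEMs combined
in quadrature.

## Problem sizes and numerics

Population statistics (tests and the acceptance script) use 1000
simulated scans per class, enough to pin the population median to a few
tenths of a percentage point; unit tests use 50–200 scans. Peak lists
are kept strictly ascending (coincident masses merged at 1e-9 Da);
matching tie-breaks go to the most intense peak in the window; ppm
errors are reported signed. Degenerate inputs (empty spectra, empty
panels, charge outside 1–8, sites without theoretical coverage) raise
explicit errors rather than returning sentinels.

## Known limitations

* The classifier's "phosphorylated" verdict requires a −98-dominant
  loss pattern that gentle activation of a phosphopeptide rarely
  produces; at 10% NCE true phosphopeptides are mostly called "none".
  That matches the intended use (vetoing false sulfo calls), not a
  general phospho detector.
* Protein-coordinate mapping uses exact substring search; I/L ambiguity
  and isoforms are not handled.
* The mzML reader is intentionally minimal (centroided MS2, plain or
  zlib 32/64-bit float arrays); indexed mzML wrappers and vendor
  idiosyncrasies are out of scope.
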