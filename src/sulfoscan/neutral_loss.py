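"""Precursor neutral-loss detection, trigger logic, and sY/pY classification.

A gentle (10% NCE) HCD survey scan of a sulfopeptide is dominated by the
surviving precursor and its -80*k Da SO3 losses, while phosphopeptides
preferentially shed 98 Da (H3PO4) and only under stronger activation.
This module measures that evidence per scan (:func:`neutral_loss_report`),
reproduces the instrument's loss-triggered acquisition decision
(:func:`trigger`), and calls each precursor sulfated / phosphorylated /
neither (:func:`classify`).

Two intensity conventions coexist deliberately: the trigger threshold is
relative to the base peak (the instrument rule), whereas the reported
per-loss statistic is a fraction of the total ion current.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import H3PO4_MASS, H2SO4_MASS, HPO3_MASS, SO3_MASS, ppm_error, ppm_window
from .spectra import Run, Spectrum, base_peak_and_tic
from .simulate import GroundTruthRecord

logger = logging.getLogger(__name__)

MAX_SULFO_SITES = 3  # the acquisition method searches 1-3 SO3 losses

#: candidate neutral losses, name -> neutral mass (Da)
LOSS_MASSES: Mapping[str, float] = {
    **{f"SO3x{k}": k * SO3_MASS for k in range(1, MAX_SULFO_SITES + 1)},
    "H2SO4": H2SO4_MASS,
    "HPO3": HPO3_MASS,
    "H3PO4": H3PO4_MASS,
}

SO3_FAMILY = tuple(f"SO3x{k}" for k in range(1, MAX_SULFO_SITES + 1))
FAMILY_98 = ("H2SO4", "H3PO4")


@dataclass(frozen=True)
class LossEntry:
    """Evidence for one candidate neutral loss in one scan."""

    loss: str
    expected_mz: float
    peak_index: int | None
    ppm: float | None
    rel_intensity: float      # vs base peak; 0 when unmatched
    tic_fraction: float       # vs summed intensity; 0 when unmatched

    @property
    def matched(self) -> bool:
        return self.peak_index is not None


@dataclass(frozen=True)
class NLReport:
    """Per-scan neutral-loss evidence.

    TIC fractions satisfy survivor + losses + unassigned = 1.
    """

    scan_id: int
    precursor_mz: float
    precursor_z: int
    entries: tuple[LossEntry, ...]
    survivor_tic_fraction: float
    unassigned_tic_fraction: float

    def entry(self, loss: str) -> LossEntry:
        for e in self.entries:
            if e.loss == loss:
                return e
        raise KeyError(loss)

    def family_fraction(self, losses: Sequence[str]) -> float:
        return sum(e.tic_fraction for e in self.entries if e.loss in losses)

    @property
    def so3_fraction(self) -> float:
        """Ion current on the -80*k ladder.

        The single -80 loss cannot be resolved into SO3 vs HPO3 at the
        25 ppm working tolerance (they differ by ~9.5 mDa), so the HPO3
        entry counts toward this family: the discriminating contrast is
        -80 vs -98 preference, not the species within the -80 window.
        """
        return self.family_fraction(SO3_FAMILY + ("HPO3",))

    @property
    def loss98_fraction(self) -> float:
        return self.family_fraction(FAMILY_98)

    @property
    def total_loss_fraction(self) -> float:
        return sum(e.tic_fraction for e in self.entries)


@dataclass(frozen=True)
class TriggerDecision:
    triggered: bool
    reason: str
    tol_ppm: float
    min_rel_intensity: float


@dataclass(frozen=True)
class Classification:
    verdict: str               # sulfated / phosphorylated / ambiguous / none
    n_sites_estimate: int
    evidence: NLReport


def _report_for_charge(s: Spectrum, z: int, tol_ppm: float) -> NLReport:
    base, tic = base_peak_and_tic(s)
    used: set[int] = set()

    def nearest(expected: float, exclude: set[int]) -> int | None:
        lo, hi = ppm_window(expected, tol_ppm)
        i0, i1 = np.searchsorted(s.mz, (lo, hi))
        candidates = [i for i in range(i0, i1) if i not in exclude]
        if not candidates:
            return None
        return min(candidates, key=lambda i: (abs(s.mz[i] - expected), -s.intensity[i]))

    # assign greedily by m/z proximity so overlapping windows (SO3 vs HPO3
    # at 25 ppm) never double-count one peak
    cand: list[tuple[float, str, float]] = []
    for name, mass in LOSS_MASSES.items():
        expected = s.precursor_mz - mass / z
        cand.append((expected, name, mass))
    assignments: dict[str, int | None] = {name: None for name in LOSS_MASSES}
    pending = [(e, n) for e, n, _ in cand]
    # iterate: each loss proposes its nearest free peak; closest pair wins
    while pending:
        proposals = []
        for expected, name in pending:
            idx = nearest(expected, used)
            if idx is not None:
                proposals.append((abs(s.mz[idx] - expected), name, expected, idx))
        if not proposals:
            break
        _, name, expected, idx = min(proposals)
        assignments[name] = idx
        used.add(idx)
        pending = [(e, n) for e, n in pending if n != name]

    entries = []
    for expected, name, _ in cand:
        idx = assignments[name]
        if idx is None:
            entries.append(LossEntry(name, expected, None, None, 0.0, 0.0))
        else:
            entries.append(
                LossEntry(
                    name,
                    expected,
                    int(idx),
                    ppm_error(float(s.mz[idx]), expected),
                    float(s.intensity[idx] / base),
                    float(s.intensity[idx] / tic),
                )
            )

    surv_idx = nearest(s.precursor_mz, used)
    survivor = float(s.intensity[surv_idx] / tic) if surv_idx is not None else 0.0
    losses = sum(e.tic_fraction for e in entries)
    return NLReport(
        scan_id=s.scan_id,
        precursor_mz=s.precursor_mz,
        precursor_z=z,
        entries=tuple(entries),
        survivor_tic_fraction=survivor,
        unassigned_tic_fraction=max(0.0, 1.0 - survivor - losses),
    )


def neutral_loss_report(s: Spectrum, tol_ppm: float = 25.0) -> NLReport:
    """Search the scan for precursor-loss peaks (SO3 x1-3, H2SO4, HPO3, H3PO4).

    Expected positions are ``precursor_mz - loss/z``.  When the precursor
    charge is undeclared, charges 2-5 are evaluated and the best-supported
    (largest summed matched-loss ion current, ties to lower z) is kept.
    """
    if s.n_peaks == 0:
        raise ValueError(f"spectrum {s.scan_id} is empty")
    if s.precursor_z is not None:
        return _report_for_charge(s, s.precursor_z, tol_ppm)
    reports = [_report_for_charge(s, z, tol_ppm) for z in range(2, 6)]
    return max(reports, key=lambda r: (round(r.total_loss_fraction, 12), -r.precursor_z))


def trigger(
    s: Spectrum,
    tol_ppm: float = 25.0,
    min_rel_intensity: float = 0.10,
) -> TriggerDecision:
    """The loss-continuation decision of the acquisition method.

    Fires iff some charge-consistent SO3 x k loss (k = 1-3) is found within
    tolerance at >= ``min_rel_intensity`` of the base peak.
    """
    report = neutral_loss_report(s, tol_ppm)
    base, _ = base_peak_and_tic(s)
    z = report.precursor_z
    # search the SO3 windows directly: the acquisition rule fires on any
    # peak inside the -79.9568*k window, whatever species it may be
    for k in range(1, MAX_SULFO_SITES + 1):
        expected = s.precursor_mz - k * SO3_MASS / z
        lo, hi = ppm_window(expected, tol_ppm)
        i0, i1 = np.searchsorted(s.mz, (lo, hi))
        if i1 > i0:
            rel = float(s.intensity[i0:i1].max() / base)
            if rel >= min_rel_intensity:
                return TriggerDecision(
                    True,
                    f"SO3x{k} window peak at {rel:.0%} of base peak",
                    tol_ppm,
                    min_rel_intensity,
                )
    return TriggerDecision(False, "no qualifying SO3 loss", tol_ppm, min_rel_intensity)


def classify(
    report: NLReport,
    sulfo_threshold: float = 0.10,
    phospho_dominance: float = 1.0,
) -> Classification:
    """Call the precursor from its low-NCE loss pattern.

    sulfated: the SO3 family holds >= ``sulfo_threshold`` of the ion
    current and at least ``phospho_dominance`` times the -98 family;
    phosphorylated: the -98 family clears the threshold and exceeds the
    SO3 family (preferential loss of 98 rather than 80); none: every
    family is sub-threshold; anything else is ambiguous.
    """
    so3 = report.so3_fraction
    f98 = report.loss98_fraction
    n_sites = 0
    for k in range(1, MAX_SULFO_SITES + 1):
        hit = report.entry(f"SO3x{k}").matched
        if k == 1:  # the single -80 may have been booked as HPO3
            hit = hit or report.entry("HPO3").matched
        if hit:
            n_sites = k
    if so3 >= sulfo_threshold and so3 >= phospho_dominance * f98:
        return Classification("sulfated", max(n_sites, 1), report)
    if f98 >= sulfo_threshold and f98 > so3:
        return Classification("phosphorylated", 0, report)
    if so3 < sulfo_threshold and f98 < sulfo_threshold:
        return Classification("none", 0, report)
    return Classification("ambiguous", n_sites, report)


_VERDICT_OF_MOD = {"sulfo": "sulfated", "phospho": "phosphorylated", "none": "none"}


def evaluate_run(
    run: Run,
    truth: Sequence[GroundTruthRecord],
    tol_ppm: float = 25.0,
    sulfo_threshold: float = 0.10,
    phospho_dominance: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion table and per-class sensitivity/specificity on a truth-
    annotated run.  Low-NCE scans without a truth record are excluded
    with a logged warning."""
    by_scan = run.by_scan()
    truth_scans = {t.low_nce_scan: t for t in truth}
    rows = []
    for t in truth:
        s = by_scan.get(t.low_nce_scan)
        if s is None:
            logger.warning("truth scan %d absent from run", t.low_nce_scan)
            continue
        c = classify(neutral_loss_report(s, tol_ppm), sulfo_threshold, phospho_dominance)
        rows.append((_VERDICT_OF_MOD[t.true_mod], c.verdict))
    classes = ["sulfated", "phosphorylated", "none"]
    called = classes + ["ambiguous"]
    confusion = pd.DataFrame(0, index=pd.Index(classes, name="true"),
                             columns=pd.Index(called, name="called"), dtype=int)
    for true, pred in rows:
        confusion.loc[true, pred] += 1
    if not confusion["ambiguous"].any():
        confusion = confusion[classes]
    stats = []
    for cls in classes:
        is_true = confusion.loc[cls].sum()
        others = confusion.drop(index=cls)
        tp = confusion.loc[cls, cls] if cls in confusion.columns else 0
        fp = others[cls].sum() if cls in confusion.columns else 0
        tn = others.sum().sum() - fp
        stats.append(
            {
                "class": cls,
                "sensitivity": tp / is_true if is_true else float("nan"),
                "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
            }
        )
    return confusion, pd.DataFrame(stats).set_index("class")


def reports_table(run: Run, tol_ppm: float = 25.0, low_nce_only: bool = True) -> pd.DataFrame:
    """Tabulate per-scan loss evidence and classifications for a run."""
    rows = []
    for s in run:
        if low_nce_only and s.energy is not None and s.energy > 20:
            continue
        r = neutral_loss_report(s, tol_ppm)
        c = classify(r)
        t = trigger(s, tol_ppm)
        rows.append(
            {
                "scan": s.scan_id,
                "precursor_mz": s.precursor_mz,
                "z": r.precursor_z,
                "so3_tic_fraction": r.so3_fraction,
                "loss98_tic_fraction": r.loss98_fraction,
                "survivor_tic_fraction": r.survivor_tic_fraction,
                "triggered": t.triggered,
                "verdict": c.verdict,
                "n_sites_estimate": c.n_sites_estimate,
            }
        )
    return pd.DataFrame(rows)
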