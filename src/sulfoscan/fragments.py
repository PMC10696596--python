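"""Theoretical product ions, peak matching, and site-localization coverage.

Site-determining ions are fragments that both contain the modified
residue and still carry its mass delta; coverage is counted over
*cleavage groups* — all series/charge variants arising from breakage of
the same backbone bond count once — so that e.g. a4/b4/y(n-4) constitute
a single piece of localization evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ATOMIC_MASS,
    PROTON_MASS,
    RESIDUE_MASS,
    WATER_MASS,
    ModifiedPeptide,
    ppm_window,
)
from .spectra import Spectrum

# neutral-mass offsets of each series relative to the b/y backbone sums
_CO = ATOMIC_MASS["C"] + ATOMIC_MASS["O"]                      # 27.994915
_NH3 = ATOMIC_MASS["N"] + 3 * ATOMIC_MASS["H"]                 # 17.026549
_NH2 = ATOMIC_MASS["N"] + 2 * ATOMIC_MASS["H"]                 # 16.018724

N_TERMINAL_SERIES = frozenset("abc")
C_TERMINAL_SERIES = frozenset("yz")


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical product ion.

    ``contains_sites`` are modification positions structurally inside the
    fragment; ``retained_sites`` those whose mass delta the ion still
    carries (a neutral-loss variant contains the site but does not retain
    it).  ``index`` counts cleavages from the ion's own terminus.
    """

    series: str
    index: int
    charge: int
    mz: float
    contains_sites: frozenset[int] = frozenset()
    retained_sites: frozenset[int] = frozenset()
    lost_neutral: float | None = None

    def retains(self, site: int) -> bool:
        return site in self.retained_sites

    def cleavage_position(self, peptide_length: int) -> int:
        """Backbone bond index 1..n-1, counted from the N-terminus."""
        if self.series in N_TERMINAL_SERIES:
            return self.index
        return peptide_length - self.index


@dataclass
class CleavageGroup:
    """All fragment ions mapping to one backbone bond."""

    cleavage_position: int
    members: list[FragmentIon]
    contains_site: bool


def _series_neutral(series: str, backbone: float) -> float:
    """Neutral fragment mass from the summed residue+mod mass of one side."""
    if series == "b":
        return backbone
    if series == "a":
        return backbone - _CO
    if series == "c":
        return backbone + _NH3
    if series == "y":
        return backbone + WATER_MASS
    if series == "z":  # z-dot radical: y - NH3 + H
        return backbone + WATER_MASS - _NH2
    raise ValueError(f"unknown ion series {series!r}")


def theoretical_ions(
    p: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
    include_nl_variants: bool = False,
) -> list[FragmentIon]:
    """Enumerate product ions of the requested series and charges.

    Indices run 1..n-1.  With ``include_nl_variants``, each ion containing
    a modified residue is additionally emitted with that modification's
    neutral losses subtracted; those variants no longer retain the site.
    """
    series = set(series)
    bad = series - (N_TERMINAL_SERIES | C_TERMINAL_SERIES)
    if bad:
        raise ValueError(f"unknown ion series {sorted(bad)}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    n = len(p.sequence)
    mods = dict(p.mods)
    res = [RESIDUE_MASS[aa] for aa in p.sequence]
    # prefix[i] = residues 1..i + their mod deltas
    prefix = np.cumsum([res[i] + (mods.get(i + 1).delta_mass if i + 1 in mods else 0.0)
                        for i in range(n)])
    total = prefix[-1]

    ions: list[FragmentIon] = []
    for s in sorted(series):
        n_term = s in N_TERMINAL_SERIES
        for idx in range(1, n):
            if n_term:
                backbone = prefix[idx - 1]
                sites = frozenset(pos for pos in mods if pos <= idx)
            else:
                backbone = total - prefix[n - idx - 1]
                sites = frozenset(pos for pos in mods if pos > n - idx)
            neutral = _series_neutral(s, backbone)
            for z in range(1, max_charge + 1):
                ions.append(
                    FragmentIon(s, idx, z, (neutral + z * PROTON_MASS) / z,
                                contains_sites=sites, retained_sites=sites)
                )
                if include_nl_variants:
                    for pos in sorted(sites):
                        for nl in mods[pos].neutral_losses:
                            ions.append(
                                FragmentIon(
                                    s, idx, z, (neutral - nl + z * PROTON_MASS) / z,
                                    contains_sites=sites,
                                    retained_sites=sites - {pos},
                                    lost_neutral=nl,
                                )
                            )
    return ions


def match_peaks(
    s: Spectrum,
    ions: Sequence[FragmentIon],
    tol_ppm: float = 10.0,
) -> list[tuple[FragmentIon, int]]:
    """Match each theoretical ion to at most one observed peak.

    Ties inside the window go to the most intense peak.  A single peak may
    satisfy several ions (the ambiguity is retained in the output).
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[tuple[FragmentIon, int]] = []
    if s.n_peaks == 0:
        return matches
    for ion in ions:
        lo, hi = ppm_window(ion.mz, tol_ppm)
        i0, i1 = np.searchsorted(s.mz, (lo, hi))
        if i1 > i0:
            best = i0 + int(np.argmax(s.intensity[i0:i1]))
            matches.append((ion, best))
    return matches


def group_by_cleavage(
    ions: Sequence[FragmentIon], peptide_length: int, site: int
) -> dict[int, CleavageGroup]:
    groups: dict[int, CleavageGroup] = {}
    for ion in ions:
        bond = ion.cleavage_position(peptide_length)
        g = groups.setdefault(bond, CleavageGroup(bond, [], False))
        g.members.append(ion)
        if site in ion.contains_sites:
            g.contains_site = True
    return groups


def site_coverage(
    p: ModifiedPeptide,
    site: int,
    matched: Sequence[tuple[FragmentIon, int]],
    theoretical: Sequence[FragmentIon],
) -> float:
    """Fraction of site-containing cleavage groups matched mod-retaining.

    Numerator: groups with at least one matched ion that retains the
    modification delta at ``site``; denominator: all theoretical cleavage
    groups containing the site.  Neutral-loss variants never count toward
    the numerator.
    """
    if site not in dict(p.mods):
        raise ValueError(f"position {site} carries no modification")
    n = len(p.sequence)
    groups = group_by_cleavage(theoretical, n, site)
    denom_bonds = {b for b, g in groups.items() if g.contains_site}
    if not denom_bonds:
        raise ValueError("no theoretical site-containing cleavage groups")
    matched_bonds = {
        ion.cleavage_position(n)
        for ion, _ in matched
        if ion.retains(site)
    }
    return len(matched_bonds & denom_bonds) / len(denom_bonds)


ABSENT = float("nan")  # no confidently identified spectrum, distinct from 0.0


def heatmap_statistic(coverages: pd.DataFrame) -> pd.DataFrame:
    """Per-cell ``log2(coverage + 1)`` for a condition x peptide table.

    Cells with no identified spectrum (NaN) propagate as NaN — absence is
    kept distinct from an identified spectrum with zero site coverage.
    """
    return np.log2(coverages.astype(float) + 1.0)


def coverage_table(
    records: Iterable[Mapping],
    index: str = "condition",
    columns: str = "peptide",
    value: str = "coverage",
) -> pd.DataFrame:
    """Pivot per-PSM coverage records into a Fig-style matrix.

    ``records`` carry one coverage per (condition, peptide[, charge]);
    when several PSMs share a cell the best (max) coverage is kept.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(index=index, columns=columns, values=value, aggfunc="max")
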