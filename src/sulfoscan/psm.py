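"""Post-search PSM filtering cascade and panel summaries.

The cascade mirrors a sulfoproteomics curation workflow: keep one PSM
per scan (highest search score), restrict modified-tyrosine calls to the
tyrosylprotein-sulfotransferase acidic consensus (Asp/Glu at +1 or -1 of
the modified Tyr), collapse to unique modification sites, and reconcile
the search engine's sulfo/phospho annotation — which scores alone cannot
discriminate — against the linked low-NCE neutral-loss evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .chem import ModifiedPeptide, parse_peptide, write_peptide
from .neutral_loss import Classification

logger = logging.getLogger(__name__)

ACIDIC = frozenset("DE")
_YMODS = ("sulfo", "phospho")


@dataclass(frozen=True)
class PSMRecord:
    """One search-engine peptide-spectrum match."""

    scan_id: int
    peptide: ModifiedPeptide
    protein: str = ""
    score: float = 0.0          # -log10 P
    ppm_error: float = 0.0
    precursor_z: int | None = None
    rt: float = 0.0
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def annotations(self) -> tuple[tuple[int, str], ...]:
        return tuple((pos, mod.name) for pos, mod in self.peptide.mods)

    def modified_y_positions(self) -> tuple[int, ...]:
        return tuple(
            pos
            for pos, mod in self.peptide.mods
            if mod.name in _YMODS and self.peptide.sequence[pos - 1] == "Y"
        )


@dataclass
class SiteRecord:
    """A unique modification site collapsed from its supporting PSMs."""

    protein: str
    site_key: tuple               # (protein, protein_pos) or (sequence, pos)
    residue: str
    position: int                 # protein coordinate if mapped, else peptide
    mod_name: str
    best_psm: PSMRecord
    n_psms: int
    consensus_ok: bool
    nl_evidence: Classification | None = None
    flags: tuple[str, ...] = ()


def dedupe_scans(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Keep exactly one PSM per scan: highest score, then smallest
    |ppm error|, then lexicographically smallest peptide string."""
    best: dict[int, PSMRecord] = {}
    for psm in psms:
        cur = best.get(psm.scan_id)
        if cur is None or _rank(psm) < _rank(cur):
            best[psm.scan_id] = psm
    return [best[k] for k in sorted(best)]


def _rank(psm: PSMRecord) -> tuple:
    return (-psm.score, abs(psm.ppm_error), write_peptide(psm.peptide))


def has_acidic_consensus(peptide: ModifiedPeptide, pos: int) -> bool:
    """Asp or Glu at the +1 or -1 neighbor of the given position."""
    seq = peptide.sequence
    left = seq[pos - 2] if pos >= 2 else ""
    right = seq[pos] if pos < len(seq) else ""
    return left in ACIDIC or right in ACIDIC


def acidic_consensus_filter(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Retain PSMs whose modified Tyr sits in the acidic consensus.

    A PSM with no sulfo/phospho-modified Tyr at all is dropped (reason
    logged); otherwise it survives iff at least one modified Tyr has an
    acidic +1/-1 neighbor.  Modified Tyr at a peptide terminus is judged
    on its single in-peptide neighbor (the cleaved-off residue is
    unknowable at the peptide level).
    """
    kept = []
    for psm in psms:
        ys = psm.modified_y_positions()
        if not ys:
            logger.info("scan %d dropped: no modified Tyr", psm.scan_id)
            continue
        if any(has_acidic_consensus(psm.peptide, pos) for pos in ys):
            kept.append(psm)
        else:
            logger.info("scan %d dropped: no acidic consensus", psm.scan_id)
    return kept


def _site_keys(psm: PSMRecord, proteins: Mapping[str, str] | None):
    """One (key, residue, position, mod_name) per modified Tyr of the PSM.

    Oxidation/deamidation elsewhere on the peptide do not enter the key,
    so such variants of the same site merge.
    """
    seq = psm.peptide.sequence
    for pos in psm.modified_y_positions():
        mod = psm.peptide.mod_at(pos).name
        if proteins and psm.protein in proteins:
            start = proteins[psm.protein].find(seq)
            if start >= 0:
                prot_pos = start + pos
                yield (psm.protein, prot_pos), seq[pos - 1], prot_pos, mod
                continue
            logger.warning(
                "peptide %s not found in protein %s; keeping peptide coordinates",
                seq, psm.protein,
            )
        yield (seq, pos), seq[pos - 1], pos, mod


def collapse_unique_sites(
    psms: Sequence[PSMRecord],
    proteins: Mapping[str, str] | None = None,
) -> list[SiteRecord]:
    """One :class:`SiteRecord` per unique modified-Tyr site.

    With a protein sequence map the site is keyed by protein coordinates;
    otherwise by (peptide sequence, position).  The best PSM is the
    highest-scoring contributor.  The sulfo/phospho flavor does not split
    the site (the same position annotated both ways collapses to the best
    PSM's annotation; reconciliation happens downstream).
    """
    groups: dict[tuple, list[tuple[PSMRecord, str, int, str]]] = {}
    for psm in psms:
        for key, residue, position, mod in _site_keys(psm, proteins):
            groups.setdefault(key, []).append((psm, residue, position, mod))
    records = []
    for key in sorted(groups, key=str):
        members = groups[key]
        best, residue, position, mod = min(members, key=lambda m: _rank(m[0]))
        records.append(
            SiteRecord(
                protein=best.protein,
                site_key=key,
                residue=residue,
                position=position,
                mod_name=mod,
                best_psm=best,
                n_psms=len(members),
                consensus_ok=has_acidic_consensus(
                    best.peptide, position if key[0] == best.peptide.sequence else _peptide_pos(best, position, proteins)
                ),
            )
        )
    return records


def _peptide_pos(psm: PSMRecord, prot_pos: int, proteins) -> int:
    start = proteins[psm.protein].find(psm.peptide.sequence)
    return prot_pos - start


def reconcile_with_nl(
    sites: Sequence[SiteRecord],
    classifications: Mapping[int, Classification],
    links: Mapping[int, int] | None = None,
) -> list[SiteRecord]:
    """Correct search-engine sulfo/phospho calls with low-NCE NL evidence.

    ``links`` maps identification scan -> its low-NCE trigger scan (the
    identity map is used when absent).  A phospho annotation whose linked
    survey scan classifies sulfated is re-called sulfated, and vice
    versa; disagreements with ambiguous NL evidence are flagged, never
    dropped.  An NL site-count estimate exceeding the number of annotated
    sites flags the record for second-site review.
    """
    out = []
    for site in sites:
        ident_scan = site.best_psm.scan_id
        low_scan = links.get(ident_scan, ident_scan) if links is not None else ident_scan
        cls = classifications.get(low_scan)
        if cls is None:
            out.append(site)
            continue
        flags = list(site.flags)
        mod = site.mod_name
        if cls.verdict == "sulfated" and mod == "phospho":
            mod = "sulfo"
            flags.append("re-called sulfated from low-NCE -80 evidence")
        elif cls.verdict == "phosphorylated" and mod == "sulfo":
            mod = "phospho"
            flags.append("re-called phosphorylated from low-NCE -98 evidence")
        elif cls.verdict == "ambiguous":
            flags.append("ambiguous low-NCE evidence")
        n_annotated = len(site.best_psm.modified_y_positions())
        if cls.n_sites_estimate > n_annotated:
            flags.append(
                f"NL suggests {cls.n_sites_estimate} sites vs {n_annotated} annotated:"
                " second-site review"
            )
        out.append(replace(site, mod_name=mod, nl_evidence=cls, flags=tuple(flags)))
    return out


def charge_state_distribution(
    groups: Mapping[str, Sequence[PSMRecord]],
    weight: str = "intensity",
) -> pd.DataFrame:
    """Relative abundance per precursor charge for each mod-state group.

    ``weight='intensity'`` uses precursor intensity where every record has
    one, falling back to counting otherwise; fractions sum to 1 per group.
    """
    rows = {}
    for name, psms in groups.items():
        if not psms:
            raise ValueError(f"group {name!r} is empty")
        use_intensity = weight == "intensity" and all(
            p.intensity is not None for p in psms
        )
        acc: dict[int, float] = {}
        for p in psms:
            z = p.precursor_z if p.precursor_z is not None else 0
            acc[z] = acc.get(z, 0.0) + (p.intensity if use_intensity else 1.0)
        total = sum(acc.values())
        rows[name] = {z: v / total for z, v in acc.items()}
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def rt_shift(psms: Sequence[PSMRecord]) -> pd.DataFrame:
    """Retention-time shift of each modified peptide vs its unmodified
    counterpart (seconds; positive = later elution), with standard error.

    Modified peptides lacking an unmodified counterpart in the table are
    skipped with a warning.  SE combines the replicate SEMs of the two
    groups in quadrature.
    """
    unmod: dict[str, list[float]] = {}
    modded: dict[tuple[str, str], list[float]] = {}
    for p in psms:
        if p.peptide.mods:
            key = (p.peptide.sequence, write_peptide(p.peptide))
            modded.setdefault(key, []).append(p.rt)
        else:
            unmod.setdefault(p.peptide.sequence, []).append(p.rt)
    rows = []
    for (seq, label), rts in sorted(modded.items()):
        if seq not in unmod:
            logger.warning("no unmodified counterpart for %s; skipped", label)
            continue
        ref = unmod[seq]
        shift = _mean(rts) - _mean(ref)
        se = (_sem(rts) ** 2 + _sem(ref) ** 2) ** 0.5
        rows.append(
            {"peptide": label, "n_mod": len(rts), "n_unmod": len(ref),
             "rt_shift_s": shift, "se_s": se}
        )
    return pd.DataFrame(rows)


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


def _sem(xs: Sequence[float]) -> float:
    n = len(xs)
    if n < 2:
        return 0.0
    m = _mean(xs)
    var = sum((x - m) ** 2 for x in xs) / (n - 1)
    return (var / n) ** 0.5


def cascade(
    psms: Sequence[PSMRecord],
    proteins: Mapping[str, str] | None = None,
    classifications: Mapping[int, Classification] | None = None,
    links: Mapping[int, int] | None = None,
) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Run the full filter cascade and report the funnel.

    Stages: total PSMs -> PSMs with a modified S/T/Y -> one per scan ->
    acidic consensus -> unique sites.  Counts are monotone non-increasing.
    """
    modified = [p for p in psms if p.peptide.mod_positions("sulfo", "phospho")]
    deduped = dedupe_scans(modified)
    consensus = acidic_consensus_filter(deduped)
    sites = collapse_unique_sites(consensus, proteins)
    if classifications is not None:
        sites = reconcile_with_nl(sites, classifications, links)
    funnel = pd.DataFrame(
        {
            "stage": ["total", "modified", "deduplicated", "acidic_consensus",
                      "unique_sites"],
            "count": [len(psms), len(modified), len(deduped), len(consensus),
                      len(sites)],
        }
    )
    return sites, funnel


# ---------------------------------------------------------------------------
# Tabular I/O: a documented TSV dialect (unknown columns ignored)
# ---------------------------------------------------------------------------

PSM_COLUMNS = ("scan", "peptide", "protein", "score", "ppm_error", "z", "rt",
               "intensity")


def read_psm_tsv(path) -> list[PSMRecord]:
    """Read PSMs from TSV with columns scan, peptide (bracket notation),
    and optionally protein, score, ppm_error, z, rt, intensity."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            PSMRecord(
                scan_id=int(d["scan"]),
                peptide=parse_peptide(str(d["peptide"])),
                protein=str(d.get("protein", "") or ""),
                score=float(d.get("score", 0.0) or 0.0),
                ppm_error=float(d.get("ppm_error", 0.0) or 0.0),
                precursor_z=int(d["z"]) if d.get("z") == d.get("z") and "z" in d else None,
                rt=float(d.get("rt", 0.0) or 0.0),
                intensity=float(d["intensity"]) if d.get("intensity") == d.get("intensity") and "intensity" in d else None,
            )
        )
    return records


def sites_to_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "protein": s.protein,
                "residue": s.residue,
                "position": s.position,
                "mod": s.mod_name,
                "peptide": write_peptide(s.best_psm.peptide),
                "score": s.best_psm.score,
                "ppm_error": s.best_psm.ppm_error,
                "z": s.best_psm.precursor_z,
                "n_psms": s.n_psms,
                "consensus_ok": s.consensus_ok,
                "nl_verdict": s.nl_evidence.verdict if s.nl_evidence else "",
                "flags": "; ".join(s.flags),
            }
        )
    return pd.DataFrame(rows)
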