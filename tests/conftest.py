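"""Shared fixtures: random peptides and programmatically built spectra files."""

from __future__ import annotations

import base64

import numpy as np
import pytest
from hypothesis import settings

from sulfoscan import SimParams, default_panel, simulate_run

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, n_min: int = 6, n_max: int = 20) -> str:
    n = int(rng.integers(n_min, n_max + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


@pytest.fixture(scope="session")
def sim_run():
    """One simulated 12 sY + 12 pY panel run with ground truth."""
    panel = default_panel("sulfo") + default_panel("phospho")
    return simulate_run(panel, SimParams(seed=11))


# ---------------------------------------------------------------------------
# minimal mzML document builder (test-only; the package has no mzML writer)
# ---------------------------------------------------------------------------

def _b64(values) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def mzml_spectrum(
    index: int,
    scan: int,
    ms_level: int,
    mz,
    intensity,
    precursor_mz: float | None = None,
    charge: int | None = None,
    profile: bool = False,
) -> str:
    mode = (
        '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
        if profile
        else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
    )
    prec = ""
    if precursor_mz is not None:
        chg = (
            f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>'
            if charge
            else ""
        )
        prec = f"""<precursorList count="1"><precursor>
          <selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor_mz}"/>
            {chg}
          </selectedIon></selectedIonList>
          <activation>
            <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>
            <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="10.0"/>
          </activation>
        </precursor></precursorList>"""
    return f"""<spectrum index="{index}" id="scan={scan}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
      {mode}
      <scanList count="1"><scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="1.5" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
      </scan></scanList>
      {prec}
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(_b64(mz))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(_b64(intensity))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(intensity)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


def mzml_document(spectra_xml: list[str]) -> str:
    body = "".join(spectra_xml)
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="{len(spectra_xml)}">
      {body}
    </spectrumList>
  </run>
</mzML>"""
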