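"""Shared fixtures: small alphabets, synthetic spectra and file fixtures.

All fixtures are generated programmatically at test time; nothing is read
from checked-in data files.
"""

import base64

import numpy as np
import pytest

from appscore import (
    MassWindow,
    ROBINSON_ROBINSON,
    STANDARD_RESIDUE_MASSES,
    SpectrumSimConfig,
    build_alphabet,
    build_evidence,
    preprocess,
    synthetic_spectrum,
)


@pytest.fixture(scope="session")
def standard_alphabet():
    return build_alphabet()


@pytest.fixture(scope="session")
def ga_alphabet():
    """Two-residue glycine/alanine alphabet with equal emission."""
    return build_alphabet(
        {"G": 57.02146, "A": 71.03711}, {"G": 0.5, "A": 0.5}
    )


@pytest.fixture(scope="session")
def small_alphabet():
    """Five-residue alphabet (renormalized background frequencies)."""
    toks = "GASVK"
    return build_alphabet(
        {t: STANDARD_RESIDUE_MASSES[t] for t in toks},
        {t: ROBINSON_ROBINSON[t] for t in toks},
    )


@pytest.fixture(scope="session")
def small_spectrum(small_alphabet):
    """Noisy b/y spectrum of a peptide drawn from the small alphabet."""
    cfg = SpectrumSimConfig(seed=5, noise_peaks=10)
    return synthetic_spectrum(
        "VAGSK", cfg, small_alphabet, np.random.default_rng(5)
    )


@pytest.fixture(scope="session")
def small_window(small_spectrum):
    return MassWindow(small_spectrum.parent_mass, 3.0)


@pytest.fixture
def evidence_for(small_spectrum, small_window):
    """Factory: method tag → EvidenceArray for the small fixture."""

    def make(method):
        ps = preprocess(small_spectrum, method)
        return build_evidence(ps, small_window)

    return make


def make_mzml(path, spectra):
    """Write a minimal mzML 1.1 file: [(mz_array, intensity_array,
    precursor_mz, charge), ...]."""

    def b64(arr, dtype):
        return base64.b64encode(
            np.asarray(arr, dtype=dtype).tobytes()
        ).decode()

    blocks = []
    for i, (mz, inten, pmz, z) in enumerate(spectra):
        mzb, intb = b64(mz, np.float64), b64(inten, np.float32)
        blocks.append(
            f"""
    <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
      <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{pmz}"/>
        <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{z}"/>
      </selectedIon></selectedIonList></precursor></precursorList>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(mzb)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{mzb}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(intb)}">
          <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{intb}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="run1"><spectrumList count="{len(spectra)}">'
        f"{''.join(blocks)}\n  </spectrumList></run>\n</mzML>\n"
    )
    with open(path, "w") as fh:
        fh.write(doc)
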