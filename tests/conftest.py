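"""Shared fixtures: synthetic datasets and small matrices."""
from __future__ import annotations

import base64

import numpy as np
import pytest

from dartlda import (
    align_spectra,
    generate_dataset,
    parchment_only_config,
)


@pytest.fixture(scope="session")
def parchment_spectra():
    """Default three-class parchment dataset (68 spectra), fixed seed."""
    return generate_dataset(parchment_only_config(), seed=7)


@pytest.fixture(scope="session")
def parchment_matrix(parchment_spectra):
    """Aligned raw intensity matrix of the default parchment dataset."""
    return align_spectra(parchment_spectra, tolerance=0.01)


def write_minimal_mzml(path, arrays):
    """Write a tiny centroid mzML file from [(mz, intensity), ...] pairs."""

    def b64(a):
        return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode()

    def one(i, mz, inten):
        return (
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">'
            '<binaryDataArrayList count="2">'
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>'
            f"<binary>{b64(mz)}</binary></binaryDataArray>"
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>'
            f"<binary>{b64(inten)}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )

    body = "".join(one(i, mz, inten) for i, (mz, inten) in enumerate(arrays))
    xml = (
        '<?xml version="1.0"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="r"><spectrumList count="{len(arrays)}">{body}</spectrumList></run></mzML>'
    )
    path.write_text(xml)
    return path
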