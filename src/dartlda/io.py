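"""Reading and writing peak lists, manifests, aligned matrices and configs.

All on-disk formats are plain text: two-column tab-separated peak lists, a
tab-separated sample manifest, a matrix table with an m/z header row plus a
labels sidecar, and YAML run configurations.  Floats are written with
Python's shortest-roundtrip repr so files round-trip bit-exactly.
Centroid-mode mzML input is supported through a lightweight XML reader.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import AlignedMatrix
from .spectra import PeakSpectrum

__all__ = [
    "write_peak_list",
    "read_peak_list",
    "write_dataset",
    "read_dataset",
    "read_mzml",
    "write_matrix",
    "read_matrix",
]


def write_peak_list(spectrum: PeakSpectrum, path: str | Path) -> Path:
    """Write one spectrum as a two-column (mz, intensity) TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(mz)!r}\t{float(inten)!r}\n")
    return path


def read_peak_list(
    path: str | Path,
    sample_id: str | None = None,
    class_label: str = "",
    temperature: float | None = None,
) -> PeakSpectrum:
    """Read a delimited (mz, intensity) peak list (tab/comma, optional header)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mz, intensity)")
    try:  # headerless files parse the first row as column names
        mz0 = float(df.columns[0])
        head = pd.DataFrame([[mz0, float(df.columns[1])]], columns=df.columns)
        df = pd.concat([head, df], ignore_index=True)
    except ValueError:
        pass
    mz = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(mz, kind="stable")
    return PeakSpectrum(
        sample_id or path.stem, class_label, mz[order], inten[order], temperature
    )


def write_dataset(spectra: Sequence[PeakSpectrum], out_dir: str | Path) -> Path:
    """Write per-sample peak lists plus a manifest table; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}.tsv"
        write_peak_list(s, out_dir / fname)
        rows.append(
            {
                "sample_id": s.sample_id,
                "class": s.class_label,
                "temperature": "" if s.temperature is None else repr(float(s.temperature)),
                "file": fname,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> list[PeakSpectrum]:
    """Read a dataset back from its manifest table."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    spectra = []
    for _, row in df.iterrows():
        temp = float(row["temperature"]) if str(row["temperature"]) != "" else None
        spectra.append(
            read_peak_list(
                manifest_path.parent / row["file"],
                sample_id=str(row["sample_id"]),
                class_label=str(row["class"]),
                temperature=temp,
            )
        )
    return spectra


_MZML_CV = {
    "mz": "MS:1000514",
    "intensity": "MS:1000515",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
}


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (kind, values)."""
    import base64
    import zlib as _zlib

    accessions = {
        cv.get("accession") for cv in bda.iter() if cv.tag.endswith("cvParam")
    }
    kind = (
        "mz"
        if _MZML_CV["mz"] in accessions
        else "intensity"
        if _MZML_CV["intensity"] in accessions
        else None
    )
    dtype = "<f4" if _MZML_CV["f32"] in accessions else "<f8"
    raw_el = next((el for el in bda.iter() if el.tag.endswith("binary")), None)
    raw = base64.b64decode(raw_el.text or "") if raw_el is not None else b""
    if _MZML_CV["zlib"] in accessions:
        raw = _zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(
    path: str | Path,
    class_labels: Mapping[str, str] | str = "",
    temperature: float | None = None,
) -> list[PeakSpectrum]:
    """Read centroided spectra from an mzML file.

    A lightweight reader for centroid-mode mzML: per <spectrum>, the m/z and
    intensity <binaryDataArray> elements (64- or 32-bit floats, uncompressed
    or zlib) are decoded by their PSI-MS accessions.  ``class_labels`` is
    either one label applied to every spectrum or a mapping from spectrum id
    to label.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    spectra = []
    for i, spec_el in enumerate(
        el for el in tree.iter() if etree.QName(el).localname == "spectrum"
    ):
        sid = spec_el.get("id", f"scan_{i}")
        mz = inten = None
        for bda in spec_el.iter():
            if not etree.QName(bda).localname == "binaryDataArray":
                continue
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
        order = np.argsort(mz, kind="stable")
        label = (
            class_labels
            if isinstance(class_labels, str)
            else class_labels.get(sid, "")
        )
        spectra.append(
            PeakSpectrum(str(sid), label, mz[order], inten[order], temperature)
        )
    return spectra


def write_matrix(m: AlignedMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write an aligned matrix as <prefix>.tsv plus a <prefix>.labels.tsv sidecar."""
    prefix = Path(prefix)
    mat_path = prefix.with_suffix(".tsv")
    lab_path = prefix.with_name(prefix.name + ".labels.tsv")
    with mat_path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(repr(float(v)) for v in m.mz_axis) + "\n")
        for sid, row in zip(m.sample_ids, m.X):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    rows = {
        "sample_id": m.sample_ids,
        "class": m.labels,
    }
    if m.temperatures is not None:
        rows["temperature"] = [repr(float(t)) for t in m.temperatures]
    pd.DataFrame(rows).to_csv(lab_path, sep="\t", index=False)
    return mat_path, lab_path


def read_matrix(prefix: str | Path) -> AlignedMatrix:
    """Read an aligned matrix written by :func:`write_matrix`."""
    prefix = Path(prefix)
    mat_path = prefix.with_suffix(".tsv")
    lab_path = prefix.with_name(prefix.name + ".labels.tsv")
    with mat_path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        mz_axis = np.array([float(v) for v in header[1:]])
        sample_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    labels_df = pd.read_csv(lab_path, sep="\t", keep_default_na=False)
    labels = [str(v) for v in labels_df["class"]]
    temps = None
    if "temperature" in labels_df.columns:
        temps = np.array([float(v) for v in labels_df["temperature"]])
    return AlignedMatrix(mz_axis, np.asarray(rows), sample_ids, labels, temps)
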