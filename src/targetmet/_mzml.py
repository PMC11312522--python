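"""Minimal mzML I/O for centroided MS1 runs.

Both directions are small and deterministic. The writer emits centroid
MS1 spectra with uncompressed 64-bit little-endian arrays, scan start
times in minutes and one polarity cvParam per spectrum; identical
spectra always serialize to identical bytes, which the pipeline's
determinism contract relies on. The reader is a compact stdlib
(xml.etree) parser for the same class of files: MS1 centroid spectra,
64- or 32-bit float arrays, optional zlib compression, scan start time
in minutes or seconds. Both directions are cross-checked against the
Bioconductor mzR reader in the test suite.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from typing import TYPE_CHECKING, Iterable
from xml.etree import ElementTree

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import SampleRun, Spectrum

_NS = "{http://psi.hupo.org/ms/mzml}"

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{n_spectra}">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

_POLARITY_CV = {
    "+": '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
    "-": '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
}


def _encode(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _binary_array(values: np.ndarray, kind_cv: str) -> str:
    data = _encode(values)
    return (
        f'          <binaryDataArray encodedLength="{len(data)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {kind_cv}\n"
        f"            <binary>{data}</binary>\n"
        "          </binaryDataArray>\n"
    )


_MZ_CV = '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
_INT_CV = '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'


def _spectrum_xml(index: int, spectrum: "Spectrum") -> str:
    n = len(spectrum.mz)
    parts = [
        f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">\n'
        '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
        '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
        '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f"        {_POLARITY_CV[spectrum.polarity]}\n"
        '        <scanList count="1">\n'
        "          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spectrum.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
        "          </scan>\n"
        "        </scanList>\n"
        '        <binaryDataArrayList count="2">\n',
        _binary_array(spectrum.mz, _MZ_CV),
        _binary_array(spectrum.intensity, _INT_CV),
        "        </binaryDataArrayList>\n      </spectrum>\n",
    ]
    return "".join(parts)


def write_mzml(run: "SampleRun", path: str | Path) -> Path:
    """Write a run's centroid MS1 spectra to an mzML file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_HEADER.replace("{run_id}", run.sample_id).replace("{n_spectra}", str(len(run.spectra))))
        for i, spec in enumerate(run.spectra):
            fh.write(_spectrum_xml(i, spec))
        fh.write(_FOOTER)
    return path


def _decode_binary_array(elem: ElementTree.Element) -> np.ndarray | None:
    """Decode one <binaryDataArray>; returns None for non-m/z/intensity
    arrays (the caller keys on the accession)."""
    dtype = "<f8"
    compressed = False
    kind = None
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
    if kind is None:
        return None
    node = elem.find(f"{_NS}binary")
    text = node.text if node is not None and node.text else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_spectra(path: str | Path) -> list["Spectrum"]:
    """Read centroid MS1 spectra (rt in minutes, polarity, arrays) from mzML."""
    from .extraction import Spectrum

    spectra: list[Spectrum] = []
    for _event, elem in ElementTree.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        ms_level = 1
        polarity = "+"
        rt_min = 0.0
        for cv in elem.findall(f"{_NS}cvParam"):
            acc = cv.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value", "1"))
            elif acc == "MS:1000129":
                polarity = "-"
            elif acc == "MS:1000130":
                polarity = "+"
        if ms_level != 1:
            elem.clear()
            continue
        for cv in elem.iter(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000016":
                value = float(cv.get("value", "0"))
                unit = cv.get("unitName", "minute")
                rt_min = value / 60.0 if unit in ("second", "s") else value
                break
        mz = np.empty(0)
        inten = np.empty(0)
        for bda in elem.iter(f"{_NS}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
            values = _decode_binary_array(bda)
            if values is None:
                continue
            if "MS:1000514" in accessions:
                mz = values
            elif "MS:1000515" in accessions:
                inten = values
        spectra.append(Spectrum(rt=rt_min, polarity=polarity, mz=mz, intensity=inten))
        elem.clear()
    spectra.sort(key=lambda s: s.rt)
    return spectra


def iter_run_files(mzml_dir: str | Path) -> Iterable[Path]:
    return sorted(Path(mzml_dir).glob("*.mzML"))
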