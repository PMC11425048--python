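"""Shared fixtures: small synthetic runs and text-format writers."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from pepsearch.index import SpectrumMeta, build_index
from pepsearch.proteome import generate_decoys, stream_candidates
from pepsearch.search import SearchConfig, search_all
from pepsearch.spectra import select_top_k
from pepsearch.synthetic import SyntheticRunSpec, make_proteome, simulate_run


def write_minimal_mzml(path, spectra):
    """Write a minimal but standard-conforming mzML file.

    ``spectra`` is a list of dicts with keys mz (array), intensity (array),
    precursor_mz, charge, rt_seconds. One MS1 scan is included first to
    check that it is skipped.
    """

    def b64(arr):
        return base64.b64encode(
            struct.pack(f"<{len(arr)}d", *[float(v) for v in arr])
        ).decode()

    chunks = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "<run id=\"r\"><spectrumList count=\"%d\">" % (len(spectra) + 1),
        # an MS1 scan that read_spectra must skip
        '<spectrum index="0" id="scan=0" defaultArrayLength="0">',
        '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
        "<binaryDataArrayList count=\"2\">",
        '<binaryDataArray encodedLength="0"><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/><binary></binary></binaryDataArray>',
        '<binaryDataArray encodedLength="0"><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/><binary></binary></binaryDataArray>',
        "</binaryDataArrayList></spectrum>",
    ]
    for i, s in enumerate(spectra, start=1):
        mzb, intb = b64(s["mz"]), b64(s["intensity"])
        chunks += [
            f'<spectrum index="{i}" id="scan={i}" defaultArrayLength="{len(s["mz"])}">',
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>',
            "<scanList count=\"1\"><scan>",
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s["rt_seconds"]}" unitAccession="UO:0000010" unitName="second"/>',
            "</scan></scanList>",
            "<precursorList count=\"1\"><precursor><selectedIonList count=\"1\"><selectedIon>",
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s["precursor_mz"]}"/>',
            f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s["charge"]}"/>',
            "</selectedIon></selectedIonList></precursor></precursorList>",
            "<binaryDataArrayList count=\"2\">",
            f'<binaryDataArray encodedLength="{len(mzb)}"><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/><binary>{mzb}</binary></binaryDataArray>',
            f'<binaryDataArray encodedLength="{len(intb)}"><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/><binary>{intb}</binary></binaryDataArray>',
            "</binaryDataArrayList></spectrum>",
        ]
    chunks.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(chunks))


def prepared_run(spec: SyntheticRunSpec, seed: int, config: SearchConfig | None = None):
    """Simulate a run and prepare everything search_all needs."""
    config = config or SearchConfig()
    proteome = make_proteome(spec, seed=seed)
    spectra, truth = simulate_run(proteome, spec, seed=seed + 1)
    selections = [select_top_k(s, config.top_k) for s in spectra]
    meta = {
        s.spectrum_id: SpectrumMeta(
            s.precursor_neutral_mass,
            s.retention_time,
            s.precursor_charge,
            sel.total_intensity,
        )
        for s, sel in zip(spectra, selections)
    }
    index = build_index(selections, config.scheme, meta)
    database = list(proteome) + generate_decoys(proteome)
    return {
        "proteome": proteome,
        "database": database,
        "spectra": spectra,
        "truth": truth,
        "selections": selections,
        "meta": meta,
        "index": index,
        "config": config,
        "spec": spec,
    }


def run_search_stage(prep):
    candidates = stream_candidates(prep["database"], prep["spec"].modifications)
    return search_all(
        prep["index"], candidates, prep["config"], selections=prep["selections"]
    )


@pytest.fixture(scope="session")
def small_run():
    """A small mixed signal/noise run shared by read-only tests."""
    spec = SyntheticRunSpec(n_proteins=15, n_spectra=80, fraction_true=0.7)
    return prepared_run(spec, seed=11)
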