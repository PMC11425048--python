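"""End-to-end orchestration: search, validation, and report writing.

Each stage appends machine-readable JSON-lines events (config hash, seeds,
counts at every filter) to ``run.log.jsonl`` in the output directory, so a
run is reproducible from its log alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfiguration
from .index import SpectrumMeta, build_index
from .proteome import (
    ModifiedPeptide,
    generate_decoys,
    parse_fasta,
    stream_candidates,
)
from .search import PSMRecord, search_all
from .spectra import read_spectra, select_top_k
from .validation import ValidationResult, run_validation

logger = logging.getLogger(__name__)

__all__ = [
    "run_search", "run_validate", "write_psm_table", "load_psm_table",
    "delta_mass_histogram",
]

PSM_COLUMNS = [
    "spectrum_id", "retention_time", "charge", "peptide", "modifications",
    "proteins", "n_b", "n_y", "sum_ib", "sum_iy", "hyperscore", "xcorr",
    "delta_mass", "is_decoy", "neutral_mass", "n_var_mods",
    "missed_cleavages", "total_intensity",
]


class RunLog:
    def __init__(self, out_dir: Path):
        out_dir.mkdir(parents=True, exist_ok=True)
        self.path = out_dir / "run.log.jsonl"

    def event(self, name: str, **data) -> None:
        rec = {"event": name, "time": round(time.time(), 3), **data}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def write_psm_table(
    psms: Sequence[PSMRecord],
    total_intensity: dict[int, float],
    path,
) -> pd.DataFrame:
    rows = []
    for p in sorted(psms, key=lambda r: r.spectrum_id):
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "retention_time": round(p.retention_time, 4),
                "charge": p.precursor_charge,
                "peptide": p.peptide.sequence,
                "modifications": p.peptide.mod_string(),
                "proteins": ";".join(p.peptide.protein_accessions),
                "n_b": p.n_b,
                "n_y": p.n_y,
                "sum_ib": round(p.sum_ib, 4),
                "sum_iy": round(p.sum_iy, 4),
                "hyperscore": round(p.hyperscore, 6),
                "xcorr": p.xcorr,
                "delta_mass": round(p.delta_mass, 6),
                "is_decoy": int(p.peptide.is_decoy),
                "neutral_mass": round(p.peptide.neutral_mass, 6),
                "n_var_mods": p.peptide.n_var_mods,
                "missed_cleavages": p.peptide.missed_cleavages,
                "total_intensity": round(total_intensity.get(p.spectrum_id, 0.0), 4),
            }
        )
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def _peptide_from_row(row) -> ModifiedPeptide:
    seq = row["peptide"]
    deltas = np.zeros(len(seq))
    mods = row["modifications"]
    if isinstance(mods, str) and mods:
        for item in mods.split(";"):
            pos, _, delta = item.partition(":")
            deltas[int(pos) - 1] += float(delta)
    return ModifiedPeptide(
        sequence=seq,
        position_deltas=deltas,
        neutral_mass=float(row["neutral_mass"]),
        missed_cleavages=int(row["missed_cleavages"]),
        is_decoy=bool(row["is_decoy"]),
        protein_accessions=tuple(str(row["proteins"]).split(";")) if row["proteins"] else (),
        n_var_mods=int(row["n_var_mods"]),
    )


def load_psm_table(path) -> tuple[list[PSMRecord], dict[int, float]]:
    """Rebuild PSM records (and the per-spectrum total-intensity map) from
    a psm.tsv written by :func:`write_psm_table`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    psms = []
    total = {}
    for _, row in df.iterrows():
        pep = _peptide_from_row(row)
        psms.append(
            PSMRecord(
                spectrum_id=int(row["spectrum_id"]),
                peptide=pep,
                hyperscore=float(row["hyperscore"]),
                xcorr=float(row["xcorr"]),
                n_b=int(row["n_b"]),
                n_y=int(row["n_y"]),
                sum_ib=float(row["sum_ib"]),
                sum_iy=float(row["sum_iy"]),
                delta_mass=float(row["delta_mass"]),
                retention_time=float(row["retention_time"]),
                precursor_charge=int(row["charge"]),
            )
        )
        total[int(row["spectrum_id"])] = float(row["total_intensity"])
    return psms, total


def run_search(cfg: RunConfiguration) -> pd.DataFrame:
    """spectra -> top-K selection -> index -> candidate stream -> best PSMs.

    Writes ``psm.tsv`` and log events to the output directory and returns
    the PSM table.
    """
    out = Path(cfg.out_dir)
    log = RunLog(out)
    log.event("search_start", config_hash=cfg.digest(), seed=cfg.seed, mode=cfg.mode)
    scfg = cfg.search_config()

    spectra = read_spectra(cfg.spectra, cfg.format)
    log.event("spectra_read", n_spectra=len(spectra))
    selections = [select_top_k(s, cfg.top_k) for s in spectra]
    meta = {
        s.spectrum_id: SpectrumMeta(
            precursor_neutral_mass=s.precursor_neutral_mass,
            retention_time=s.retention_time,
            precursor_charge=s.precursor_charge,
            total_selected_intensity=sel.total_intensity,
        )
        for s, sel in zip(spectra, selections)
    }
    index = build_index(selections, scfg.scheme, meta)
    log.event(
        "index_built",
        n_bins=index.n_bins,
        n_postings=index.n_postings,
        bin_width=scfg.scheme.bin_width,
    )

    targets = parse_fasta(cfg.fasta)
    decoys = generate_decoys(targets, prefix=cfg.decoy_prefix)
    log.event("database_read", n_targets=len(targets), n_decoys=len(decoys))
    candidates = stream_candidates(
        targets + decoys,
        cfg.modifications,
        enzyme=cfg.enzyme,
        missed_cleavages=cfg.missed_cleavages,
        min_length=cfg.min_length,
        max_length=cfg.max_length,
        cap=cfg.mod_cap,
        open_k=cfg.open_k,
    )
    best = search_all(index, candidates, scfg, selections=selections)
    log.event("search_done", n_psms=len(best))
    total_intensity = {sid: float(index.total_intensity[sid]) for sid in best}
    df = write_psm_table(list(best.values()), total_intensity, out / "psm.tsv")
    return df


def delta_mass_histogram(
    delta_masses, lo: float = -6000.0, hi: float = 4500.0, width: float = 1.0
) -> pd.DataFrame:
    """Counts of precursor mass differences in ``width``-Da bins over
    [lo, hi]; out-of-range values are clipped into the edge bins so the
    histogram total equals the PSM count."""
    dm = np.clip(np.asarray(delta_masses, dtype=np.float64), lo, hi - 1e-9)
    edges = np.arange(lo, hi + width, width)
    counts, _ = np.histogram(dm, bins=edges)
    nz = counts > 0
    return pd.DataFrame(
        {"bin_low": edges[:-1][nz], "bin_high": edges[1:][nz], "count": counts[nz]}
    )


def run_validate(cfg: RunConfiguration, psm_path=None) -> ValidationResult:
    """Validation stage over a psm.tsv: RT model, discriminant, q-values,
    peptide/protein reports, q-value curves, and the mass-difference
    histogram."""
    out = Path(cfg.out_dir)
    log = RunLog(out)
    psm_path = Path(psm_path) if psm_path else out / "psm.tsv"
    psms, total_intensity = load_psm_table(psm_path)
    log.event("validate_start", n_psms=len(psms), seed=cfg.seed, config_hash=cfg.digest())
    result = run_validation(psms, total_intensity, seed=cfg.seed, fdr=cfg.fdr)
    log.event("validate_done", fallback=result.fallback, **{
        k: v for k, v in result.log.items()
        if k != "fallback" and not isinstance(v, (list, dict))
    })
    result.reports["peptides"].to_csv(out / "peptides.tsv", sep="\t", index=False)
    result.reports["proteins"].to_csv(out / "proteins.tsv", sep="\t", index=False)
    result.reports["peptide_q"][["score", "is_decoy", "q"]].to_csv(
        out / "qvalue_curve.tsv", sep="\t", index=False
    )
    delta_mass_histogram(
        [p.delta_mass for p in psms],
        *(cfg.delta_m_window or (-6000.0, 4500.0)),
    ).to_csv(out / "delta_mass_histogram.tsv", sep="\t", index=False)
    log.event(
        "reports_written",
        n_peptides=len(result.reports["peptides"]),
        n_proteins=len(result.reports["proteins"]),
    )
    return result
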