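"""Protein database handling and runtime theoretical-ion generation.

Proteins are digested in silico (trypsin by default: cleave C-terminal of
K/R except before P), decoys are full sequence reversals, and variably
modified peptide forms are enumerated lazily. A peptide with ``n`` eligible
variable-modification sites yields all ``2**n`` site subsets while
``n <= cap`` (default 20); beyond the cap only subsets of at most
``open_k`` (default 3) sites are considered, i.e. ``sum(C(n, i), i=0..3)``
forms. Theoretical b/y ions are produced on the fly per candidate and never
stored, keeping memory independent of the database size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .constants import AA_MASS, PROTON, WATER

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "ModificationSpec",
    "ModifiedPeptide",
    "FragmentSet",
    "parse_fasta",
    "digest",
    "generate_decoys",
    "count_modforms",
    "enumerate_modforms",
    "fragment_ions",
    "peptide_mass",
    "DEFAULT_ENZYME",
]

DECOY_PREFIX = "DECOY_"

#: Trypsin: cleave after K or R, not if the next residue is P.
DEFAULT_ENZYME = r"[KR](?!P)"

_CANONICAL = set(AA_MASS)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False


@dataclass(frozen=True)
class ModificationSpec:
    """A mass delta applied to a residue (or terminus).

    ``kind`` is ``"fixed"`` (applied unconditionally to every target
    residue) or ``"variable"`` (each target residue is an optional site).
    """

    name: str
    target: str          # one residue letter, or "nterm"/"cterm"
    delta_mass: float
    kind: str = "variable"

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError("kind must be 'fixed' or 'variable'")
        if not np.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")


@dataclass
class ModifiedPeptide:
    """A peptide sequence with per-position mass deltas."""

    sequence: str
    position_deltas: np.ndarray
    neutral_mass: float
    missed_cleavages: int = 0
    is_decoy: bool = False
    protein_accessions: tuple[str, ...] = ()
    n_var_mods: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mod_string(self) -> str:
        """Compact 'position:+delta' list (1-based), empty if unmodified."""
        parts = [
            f"{i + 1}:{d:+.6f}"
            for i, d in enumerate(self.position_deltas)
            if d != 0.0
        ]
        return ";".join(parts)

    def key(self) -> str:
        """Identity of the modified peptide (sequence + modification state)."""
        ms = self.mod_string()
        return f"{self.sequence}|{ms}" if ms else self.sequence


@dataclass
class FragmentSet:
    """Theoretical b/y ion m/z ladders, one array per charge state."""

    b_mz: dict[int, np.ndarray]
    y_mz: dict[int, np.ndarray]


def peptide_mass(sequence: str, position_deltas: np.ndarray | None = None) -> float:
    """Monoisotopic neutral mass: residues + deltas + water."""
    m = sum(AA_MASS[aa] for aa in sequence) + WATER
    if position_deltas is not None:
        m += float(np.sum(position_deltas))
    return m


# ---------------------------------------------------------------------------
# FASTA and digestion


def parse_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA protein database.

    The accession is the header token up to the first whitespace. Sequences
    are uppercased and concatenated across wrapped lines. Duplicate
    accessions or an empty file are errors. Records containing
    non-canonical letters are retained (peptides spanning them are skipped
    downstream).
    """
    from pyteomics import fasta as _fasta

    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            accession = header.split()[0] if header.split() else header
            if accession in seen:
                raise ValueError(f"duplicate accession in FASTA: {accession}")
            seen.add(accession)
            seq = sequence.upper()
            extra = set(seq) - _CANONICAL
            if extra:
                logger.warning(
                    "protein %s contains non-canonical residues %s",
                    accession,
                    "".join(sorted(extra)),
                )
            records.append(ProteinRecord(accession=accession, sequence=seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def cleavage_sites(sequence: str, enzyme: str = DEFAULT_ENZYME) -> list[int]:
    """Positions *after* which the enzyme cuts (0-based residue indices)."""
    return [m.start() for m in re.finditer(enzyme, sequence)]


def digest(
    protein: ProteinRecord,
    enzyme: str = DEFAULT_ENZYME,
    missed_cleavages: int = 2,
    min_length: int = 0,
    max_length: int = 10**9,
) -> list[tuple[str, int]]:
    """Enzymatic peptides of one protein as (sequence, n_missed) pairs.

    All peptides with 0..``missed_cleavages`` internal uncleaved sites are
    produced, filtered to the [min_length, max_length] window. Duplicated
    sequences arising at different positions are each reported (callers
    dedupe across the database).
    """
    seq = protein.sequence
    sites = cleavage_sites(seq, enzyme)
    # fragment boundaries: start indices of fully cleaved segments
    bounds = [0] + [s + 1 for s in sites if s + 1 < len(seq)] + [len(seq)]
    out: list[tuple[str, int]] = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for mc in range(missed_cleavages + 1):
            j = i + mc + 1
            if j > n_seg:
                break
            pep = seq[bounds[i]:bounds[j]]
            if min_length <= len(pep) <= max_length:
                out.append((pep, mc))
    return out


def generate_decoys(
    proteins: Iterable[ProteinRecord], prefix: str = DECOY_PREFIX
) -> list[ProteinRecord]:
    """One decoy per target protein by full sequence reversal."""
    return [
        ProteinRecord(
            accession=prefix + p.accession,
            sequence=p.sequence[::-1],
            is_decoy=True,
        )
        for p in proteins
        if not p.is_decoy
    ]


# ---------------------------------------------------------------------------
# Modification enumeration


def count_modforms(n: int, cap: int = 20, open_k: int = 3) -> int:
    """Number of modified forms of a peptide with ``n`` eligible sites.

    ``n <= cap``: the full ``2**n`` site subsets (unmodified included).
    ``n > cap``: truncated to subsets of at most ``open_k`` sites,
    ``sum(C(n, i) for i in 0..open_k)``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n <= cap:
        return 2**n
    return sum(comb(n, i) for i in range(open_k + 1))


def _apply_fixed(
    sequence: str, specs: Sequence[ModificationSpec]
) -> np.ndarray:
    deltas = np.zeros(len(sequence))
    claimed: dict[int, str] = {}
    for spec in specs:
        if spec.kind != "fixed":
            continue
        if spec.target == "nterm":
            positions = [0]
        elif spec.target == "cterm":
            positions = [len(sequence) - 1]
        else:
            positions = [i for i, aa in enumerate(sequence) if aa == spec.target]
        for i in positions:
            if i in claimed and claimed[i] != spec.name:
                raise ValueError(
                    f"conflicting fixed modifications at position {i + 1} "
                    f"of {sequence}: {claimed[i]} vs {spec.name}"
                )
            claimed[i] = spec.name
            deltas[i] += spec.delta_mass
    return deltas


def _variable_sites(
    sequence: str, specs: Sequence[ModificationSpec]
) -> list[tuple[int, float]]:
    """Eligible (position, delta) variable sites, position-ascending.

    Two variable specs targeting the same residue letter are rejected: the
    per-site subset count (2**n) assumes one possible state per site.
    """
    by_residue: dict[str, ModificationSpec] = {}
    for spec in specs:
        if spec.kind != "variable":
            continue
        if spec.target in by_residue:
            raise ValueError(
                f"two variable modifications target {spec.target!r}; "
                "one delta per site is supported"
            )
        by_residue[spec.target] = spec
    sites: list[tuple[int, float]] = []
    for i, aa in enumerate(sequence):
        if aa in by_residue:
            sites.append((i, by_residue[aa].delta_mass))
    for term, pos in (("nterm", 0), ("cterm", len(sequence) - 1)):
        if term in by_residue:
            sites.append((pos, by_residue[term].delta_mass))
    sites.sort()
    return sites


def enumerate_modforms(
    peptide: str,
    specs: Sequence[ModificationSpec] = (),
    cap: int = 20,
    open_k: int = 3,
    missed_cleavages: int = 0,
    is_decoy: bool = False,
    protein_accessions: tuple[str, ...] = (),
) -> Iterator[ModifiedPeptide]:
    """Stream every modified form of one peptide.

    Fixed modifications are applied unconditionally first; variable-site
    subsets are then emitted in subset-size, then position-lexicographic
    order (the unmodified variable state first). Exactly
    ``count_modforms(n_sites, cap, open_k)`` forms are yielded; nothing is
    materialized.
    """
    if any(aa not in _CANONICAL for aa in peptide):
        raise ValueError(f"peptide {peptide!r} contains non-canonical residues")
    base = _apply_fixed(peptide, specs)
    base_mass = peptide_mass(peptide, base)
    sites = _variable_sites(peptide, specs)
    n = len(sites)
    max_size = n if n <= cap else open_k
    for size in range(max_size + 1):
        for subset in combinations(sites, size):
            deltas = base.copy()
            extra = 0.0
            for pos, d in subset:
                deltas[pos] += d
                extra += d
            yield ModifiedPeptide(
                sequence=peptide,
                position_deltas=deltas,
                neutral_mass=base_mass + extra,
                missed_cleavages=missed_cleavages,
                is_decoy=is_decoy,
                protein_accessions=protein_accessions,
                n_var_mods=size,
            )


# ---------------------------------------------------------------------------
# Theoretical fragments


def fragment_ions(
    peptide: ModifiedPeptide, charges: Iterable[int] = (1, 2)
) -> FragmentSet:
    """b/y ion m/z ladders for the requested fragment charge states.

    b_i(z) = (sum of first i residue masses and deltas + z*proton) / z;
    y_j(z) adds water for the C-terminal fragment. Each series has
    length - 1 ions per charge, and b_i(1+) + y_{L-i}(1+) = M + 2*proton.
    """
    seq = peptide.sequence
    if len(seq) < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    residue = np.array([AA_MASS[aa] for aa in seq]) + peptide.position_deltas
    prefix = np.cumsum(residue)[:-1]            # b fragments, i = 1..L-1
    suffix = np.cumsum(residue[::-1])[:-1]      # y fragments, j = 1..L-1
    b_mz: dict[int, np.ndarray] = {}
    y_mz: dict[int, np.ndarray] = {}
    for z in sorted(set(int(z) for z in charges)):
        if z < 1:
            raise ValueError("fragment charge must be >= 1")
        b_mz[z] = (prefix + z * PROTON) / z
        y_mz[z] = (suffix + WATER + z * PROTON) / z
    return FragmentSet(b_mz=b_mz, y_mz=y_mz)


# ---------------------------------------------------------------------------
# Database-level candidate streaming


def digest_database(
    proteins: Sequence[ProteinRecord],
    enzyme: str = DEFAULT_ENZYME,
    missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 50,
) -> dict[str, tuple[int, bool, tuple[str, ...]]]:
    """Unique peptides of a (target+decoy) database.

    Returns ``{sequence: (min_missed_cleavages, is_decoy, accessions)}``.
    A sequence found in both target and decoy proteins is kept as a target
    (its decoy copy carries no independent evidence) and flagged by having
    accessions from both sides. Peptides with non-canonical residues are
    skipped with a warning.
    """
    table: dict[str, tuple[int, bool, set[str]]] = {}
    n_skipped = 0
    for prot in proteins:
        for pep, mc in digest(prot, enzyme, missed_cleavages, min_length, max_length):
            if any(aa not in _CANONICAL for aa in pep):
                n_skipped += 1
                continue
            if pep in table:
                old_mc, old_decoy, accs = table[pep]
                accs.add(prot.accession)
                table[pep] = (min(old_mc, mc), old_decoy and prot.is_decoy, accs)
            else:
                table[pep] = (mc, prot.is_decoy, {prot.accession})
    if n_skipped:
        logger.warning("skipped %d peptides with non-canonical residues", n_skipped)
    return {
        pep: (mc, dec, tuple(sorted(accs)))
        for pep, (mc, dec, accs) in sorted(table.items())
    }


def stream_candidates(
    proteins: Sequence[ProteinRecord],
    specs: Sequence[ModificationSpec] = (),
    enzyme: str = DEFAULT_ENZYME,
    missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 50,
    cap: int = 20,
    open_k: int = 3,
) -> Iterator[ModifiedPeptide]:
    """Stream every candidate modified peptide of a database, lazily."""
    table = digest_database(proteins, enzyme, missed_cleavages, min_length, max_length)
    for pep, (mc, is_decoy, accs) in table.items():
        yield from enumerate_modforms(
            pep,
            specs,
            cap=cap,
            open_k=open_k,
            missed_cleavages=mc,
            is_decoy=is_decoy,
            protein_accessions=accs,
        )
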