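"""Bundled physicochemical constant tables.

All tables are shipped as plain TSV files under ``rmethyl/data`` with their
literature provenance in a comment header: the Kyte-Doolittle hydropathy
scale, the Guruprasad dipeptide instability weights (DIWV), the Bjellqvist
pKa set used for isoelectric-point calculation, average residue masses, the
280 nm molar extinction coefficients, and the residue classes behind the
ProtParam-style secondary-structure fractions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

AA_ALPHABET = sorted("ACDEFGHIKLMNPQRSTVWY")
WATER_MASS = 18.0153


def _read_tsv(name: str) -> list[list[str]]:
    text = (resources.files("rmethyl") / "data" / name).read_text()
    rows = []
    for line in text.splitlines():
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def hydropathy() -> dict[str, float]:
    """Kyte-Doolittle hydropathy value per residue."""
    rows = _read_tsv("hydropathy_kyte_doolittle.tsv")
    return {r: float(v) for r, v in rows[1:]}


@lru_cache(maxsize=None)
def diwv() -> dict[str, float]:
    """Dipeptide instability weight for every ordered standard dipeptide."""
    rows = _read_tsv("diwv_guruprasad.tsv")
    header = rows[0][1:]
    table: dict[str, float] = {}
    for row in rows[1:]:
        first = row[0]
        for second, value in zip(header, row[1:]):
            table[first + second] = float(value)
    if len(table) != 400:
        raise AssertionError(f"DIWV table has {len(table)} entries, expected 400")
    return table


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    """Average molecular weight (Da) of each free amino acid."""
    rows = _read_tsv("residue_masses_average.tsv")
    return {r: float(v) for r, v in rows[1:]}


@lru_cache(maxsize=None)
def pka_set() -> dict[str, dict[str, float]]:
    """Bjellqvist pKa values grouped as pos/neg side chains and termini.

    Terminal groups map residue -> pKa with ``'*'`` as the default when the
    terminal residue has no specific value.
    """
    groups: dict[str, dict[str, float]] = {"pos": {}, "neg": {}, "nterm": {}, "cterm": {}}
    for group, residue, value in _read_tsv("pka_bjellqvist.tsv")[1:]:
        groups[group][residue] = float(value)
    return groups


@lru_cache(maxsize=None)
def extinction_coefficients() -> dict[str, float]:
    """Molar extinction coefficients at 280 nm (M^-1 cm^-1)."""
    rows = _read_tsv("extinction_gill_vonhippel.tsv")
    return {r: float(v) for r, v in rows[1:]}


@lru_cache(maxsize=None)
def secondary_structure_classes() -> dict[str, frozenset[str]]:
    """Residue sets counted toward helix, turn and sheet fractions."""
    rows = _read_tsv("secondary_structure_classes.tsv")
    return {name: frozenset(residues) for name, residues in rows[1:]}
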