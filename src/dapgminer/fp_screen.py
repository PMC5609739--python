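"""Structural screening of false-positive predictions.

Predicted complexes absent from every gold standard are not necessarily
wrong: many small purified complexes sit in the PDB but not in curated
catalogs.  This module flags such predictions whose members co-occur in a
purified structure, using local snapshot tables only (a protein -> PDB
chain map in SIFTS style, and an optional PDB metadata table) — no live
database queries.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .evaluation import overlap_score
from .network import ComplexSet

log = logging.getLogger(__name__)

__all__ = [
    "ChainMap",
    "PotentialComplex",
    "read_chain_map",
    "read_pdb_metadata",
    "false_positives",
    "potential_complexes",
    "write_potential_complexes",
]


@dataclass(frozen=True)
class ChainMap:
    """Rows of (protein_name, pdb_id, chain_id), unique, pdb_id nonempty."""

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate (protein, pdb, chain) rows")
        if any(not pdb for _, pdb, _ in self.rows):
            raise ValueError("empty pdb id in chain map")

    def pdbs_of(self, protein: str) -> set[str]:
        return {pdb for p, pdb, _ in self.rows if p == protein}

    def chains_of(self, pdb: str) -> set[str]:
        return {chain for _, p, chain in self.rows if p == pdb}

    def protein_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for protein, pdb, _ in self.rows:
            idx.setdefault(protein, set()).add(pdb)
        return idx


@dataclass(frozen=True)
class PotentialComplex:
    """Members of one false-positive prediction sharing a purified structure."""

    pdb_id: str
    member_proteins: frozenset[str]
    source_complex_index: int

    def __post_init__(self) -> None:
        if len(self.member_proteins) < 2:
            raise ValueError("a potential complex needs at least two members")


def read_chain_map(path: str | Path) -> ChainMap:
    """Read a TSV snapshot with columns protein_name, pdb_id, chain_id."""
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            row = (parts[0], parts[1].lower(), parts[2])
            if row not in seen:
                seen.add(row)
                rows.append(row)
    return ChainMap(tuple(rows))


def read_pdb_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Optional snapshot: pdb_id -> {form_name, title, release_date}."""
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for parts in reader:
            if not parts or parts[0].startswith("#"):
                continue
            pdb = parts[0].lower()
            meta[pdb] = {
                "form_name": parts[1] if len(parts) > 1 else "",
                "title": parts[2] if len(parts) > 2 else "",
                "release_date": parts[3] if len(parts) > 3 else "",
            }
    return meta


def false_positives(pred: ComplexSet, refs: ComplexSet, w: float = 0.25) -> ComplexSet:
    """Predicted complexes with OS below *w* against every reference complex."""
    out = [
        pc
        for pc in pred
        if all(overlap_score(pc, rc) < w for rc in refs)
    ]
    return ComplexSet(out)


def potential_complexes(
    fps: ComplexSet, chainmap: ChainMap, refs: ComplexSet
) -> list[PotentialComplex]:
    """Groups of >= 2 members of a false-positive complex sharing a pdb id.

    Groups whose member set is contained in some gold-standard complex are
    discarded (those are fragments of known complexes, not new candidates).
    """
    if not chainmap.rows:
        log.warning("empty chain map: no potential complexes can be found")
        return []
    idx = chainmap.protein_index()
    ref_sets = refs.member_sets()
    out: list[PotentialComplex] = []
    for ci, fp in enumerate(fps):
        by_pdb: dict[str, set[str]] = {}
        for protein in fp:
            for pdb in idx.get(protein, ()):
                by_pdb.setdefault(pdb, set()).add(protein)
        for pdb in sorted(by_pdb):
            members = frozenset(by_pdb[pdb])
            if len(members) < 2:
                continue
            if any(members <= rs for rs in ref_sets):
                continue
            out.append(PotentialComplex(pdb, members, ci))
    return out


def write_potential_complexes(
    pcs: list[PotentialComplex],
    chainmap: ChainMap,
    path: str | Path,
    metadata: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write screening results as CSV: pdb_id, form_name, genes "(k/total)", title.

    ``total`` is the number of distinct chains recorded for the pdb id in
    the chain map (the structure's subunit count as far as the snapshot
    knows it), falling back to the group size.
    """
    metadata = metadata or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pdb_id", "form_name", "gene_ids", "title"])
        for pc in pcs:
            total = len(chainmap.chains_of(pc.pdb_id)) or len(pc.member_proteins)
            genes = " ".join(sorted(pc.member_proteins))
            meta = metadata.get(pc.pdb_id, {})
            writer.writerow(
                [
                    pc.pdb_id,
                    meta.get("form_name", ""),
                    f"{genes} ({len(pc.member_proteins)}/{total})",
                    meta.get("title", ""),
                ]
            )
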