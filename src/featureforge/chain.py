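"""Protein chains: sequences, secondary-structure labels, backbone coordinates.

A :class:`Chain` carries, per residue, the three-letter residue code (with
non-canonical codes preserved verbatim), the canonical one-letter code
(non-canonical residues mapped through an extensible table, unknown codes to
``'X'``), an 8-state secondary-structure label, optional backbone N/CA/C
coordinates, and a ``resolved`` flag. Residues without resolved structure
carry the technical mask label :data:`MASK` ("Ø" class): such positions are
excluded from every loss and metric downstream.

Structure files (mmCIF or PDB) are read with gemmi; DSSP v4 classic text
output is parsed directly; FASTA goes through Bio.SeqIO.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The eight DSSP states, in fixed class order.
LABELS8 = ("H", "G", "I", "E", "B", "T", "S", "C")
#: Three-state alphabet.
LABELS3 = ("H", "E", "C")
#: Technical ninth label marking unresolved residues; masked everywhere.
MASK = "-"

#: 8-state -> 3-state collapse: helical states to H, extended states to E,
#: turns/bends/irregular to C. The mask propagates.
EIGHT_TO_THREE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
    MASK: MASK,
}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}
CANONICAL1 = "ACDEFGHIKLMNPQRSTVWY"


def load_ncaa_table(path: Optional[str | Path] = None) -> dict[str, str]:
    """Load the ncAA three-letter -> canonical one-letter mapping table.

    Without ``path``, the packaged default table (MSE->M, HYP->P, MLY->K, ...)
    is used. The file is TSV with columns code/one/parent3; '#' lines are
    comments.
    """
    if path is None:
        text = resources.files("featureforge.data").joinpath("ncaa_map.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("code\t"):
            continue
        parts = line.split("\t")
        table[parts[0]] = parts[1]
    return table


def three_to_one(code: str, ncaa_table: Optional[Mapping[str, str]] = None) -> str:
    """Map a three-letter residue code to one letter; unknown codes -> 'X'."""
    if code in AA3TO1:
        return AA3TO1[code]
    if ncaa_table and code in ncaa_table:
        return ncaa_table[code]
    return "X"


@dataclass
class Chain:
    """Per-residue view of one protein chain.

    backbone, when present, is an (L, 3, 3) array of N/CA/C coordinates in
    Angstrom; ``resolved[i]`` is False when any of the three atoms is absent.
    ``resnums`` keeps author residue numbers purely for reconciliation with
    external per-residue files (DSSP, disorder scores); the API itself is
    0-based.
    """

    chain_id: str
    seq1: str
    seq3: list[str]
    labels8: list[str]
    backbone: Optional[np.ndarray] = None
    resolved: Optional[np.ndarray] = None
    resnums: Optional[list[int]] = None

    def __post_init__(self) -> None:
        n = len(self.seq1)
        if len(self.seq3) != n or len(self.labels8) != n:
            raise ValueError("seq1, seq3 and labels8 must have equal length")
        if self.resolved is None:
            self.resolved = np.ones(n, dtype=bool)
        self.resolved = np.asarray(self.resolved, dtype=bool)
        if self.backbone is not None:
            self.backbone = np.asarray(self.backbone, dtype=float)
            if self.backbone.shape != (n, 3, 3):
                raise ValueError("backbone must have shape (L, 3, 3)")
        for i, ok in enumerate(self.resolved):
            if not ok and self.labels8[i] != MASK:
                raise ValueError(f"unresolved residue {i} must carry the mask label")

    def __len__(self) -> int:
        return len(self.seq1)

    @property
    def labels3(self) -> list[str]:
        return [map_8to3(l) for l in self.labels8]


def map_8to3(label8: str) -> str:
    """Collapse an 8-state label to {H, E, C}; the mask label is preserved."""
    try:
        return EIGHT_TO_THREE[label8]
    except KeyError:
        raise ValueError(f"unknown 8-state label {label8!r}") from None


def parse_structure(
    path: str | Path,
    chain_id: Optional[str] = None,
    ncaa_table: Optional[Mapping[str, str]] = None,
) -> Chain:
    """Read one chain from an mmCIF or PDB file.

    Three-letter codes are preserved verbatim; one-letter codes come from the
    canonical table extended by ``ncaa_table`` (default: packaged table).
    Backbone coordinates are attached where all of N/CA/C are present; other
    residues are marked unresolved and masked. Multi-model files use the
    first model only.
    """
    if ncaa_table is None:
        ncaa_table = load_ncaa_table()
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad files
        raise ValueError(f"cannot read structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    if chain_id is None:
        if len(model) == 0:
            raise ValueError(f"no chains in {path}")
        gchain = model[0]
    else:
        gchain = model.find_chain(chain_id)
        if gchain is None:
            raise KeyError(f"chain {chain_id!r} not found in {path}")

    seq3: list[str] = []
    seq1 = []
    resnums: list[int] = []
    coords = []
    resolved = []
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        is_aa = info.is_amino_acid() if info is not None else (res.name in ncaa_table)
        if not is_aa and res.name not in AA3TO1 and res.name not in ncaa_table:
            continue  # waters, ligands
        seq3.append(res.name)
        seq1.append(three_to_one(res.name, ncaa_table))
        resnums.append(res.seqid.num)
        xyz = np.full((3, 3), np.nan)
        have = 0
        for k, atom_name in enumerate(("N", "CA", "C")):
            atom = res.find_atom(atom_name, "*")
            if atom is not None:
                xyz[k] = [atom.pos.x, atom.pos.y, atom.pos.z]
                have += 1
        coords.append(xyz)
        resolved.append(have == 3)
    if not seq3:
        raise ValueError(f"chain {gchain.name!r} in {path} has no residues")
    resolved_arr = np.array(resolved, dtype=bool)
    labels8 = [MASK] * len(seq3)
    return Chain(
        chain_id=gchain.name,
        seq1="".join(seq1),
        seq3=seq3,
        labels8=labels8,
        backbone=np.array(coords),
        resolved=resolved_arr,
        resnums=resnums,
    )


def parse_dssp(path: str | Path, chain_id: str) -> dict[int, str]:
    """Parse classic DSSP v4 (mkdssp) text output for one chain.

    Returns a mapping author-residue-number -> 8-state label. Blank/irregular
    structure codes map to 'C' (the standard loop/irregular convention);
    chain-break records ('!') are skipped. Residues absent from the returned
    mapping are unresolved and should be masked.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path}: no DSSP residue table header found")
    labels: dict[int, str] = {}
    seen_chain = False
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":
            continue  # chain break / discontinuity marker
        ch = line[11]
        if ch != chain_id:
            continue
        seen_chain = True
        try:
            resnum = int(line[5:10])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed residue number in {line!r}") from exc
        ss = line[16]
        if ss in ("", " ", "-", "~"):
            ss = "C"
        if ss == "P":  # mkdssp v4 polyproline-II state, folded into coil
            ss = "C"
        if ss not in LABELS8:
            raise ValueError(f"{path}: unknown structure code {ss!r}")
        labels[resnum] = ss
    if not seen_chain:
        raise KeyError(f"chain {chain_id!r} not found in DSSP file {path}")
    return labels


def attach_dssp(chain: Chain, dssp_labels: Mapping[int, str]) -> Chain:
    """Return a copy of ``chain`` with 8-state labels merged in by residue number.

    Residues missing from ``dssp_labels`` or unresolved in the structure keep
    the mask label.
    """
    if chain.resnums is None:
        raise ValueError("chain has no residue numbers for DSSP reconciliation")
    labels = []
    for i, num in enumerate(chain.resnums):
        if chain.resolved[i] and num in dssp_labels:
            labels.append(dssp_labels[num])
        else:
            labels.append(MASK)
    out = copy.copy(chain)
    out.labels8 = labels
    return out


@dataclass
class ChainMetadata:
    """Selection-relevant metadata for one deposited chain."""

    pdb_id: str
    chain_id: str
    resolution: float
    r_factor: float
    length: int
    method: str  # xray | nmr | em | other
    identity_cluster: Optional[str] = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class FilterCriteria:
    """Dataset filter predicates; ``None`` disables the predicate.

    :meth:`strict` gives the standard non-redundant-set criteria: X-ray only,
    resolution <= 3.0 A, length in [40, 10000], R-factor <= 0.3.
    """

    max_resolution: Optional[float] = None
    min_length: Optional[int] = None
    max_length: Optional[int] = None
    max_r_factor: Optional[float] = None
    methods: Optional[tuple[str, ...]] = None

    @classmethod
    def strict(cls) -> "FilterCriteria":
        return cls(max_resolution=3.0, min_length=40, max_length=10000,
                   max_r_factor=0.3, methods=("xray",))


def filter_chains(
    meta: Sequence[ChainMetadata],
    criteria: Optional[FilterCriteria] = None,
) -> list[ChainMetadata]:
    """Return the chains satisfying all active predicates, order preserved."""
    if criteria is None:
        return list(meta)
    out = []
    for m in meta:
        if criteria.max_resolution is not None and m.resolution > criteria.max_resolution:
            continue
        if criteria.min_length is not None and m.length < criteria.min_length:
            continue
        if criteria.max_length is not None and m.length > criteria.max_length:
            continue
        if criteria.max_r_factor is not None and m.r_factor > criteria.max_r_factor:
            continue
        if criteria.methods is not None and m.method not in criteria.methods:
            continue
        out.append(m)
    return out


def write_fasta(chains: Iterable[Chain], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.seq1), id=c.chain_id, description="") for c in chains]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_labels_tsv(chain: Chain, path: str | Path) -> None:
    """Write per-residue labels as TSV: chain_id, position, label8, label3."""
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tlabel8\tlabel3\n")
        for i, l8 in enumerate(chain.labels8):
            fh.write(f"{chain.chain_id}\t{i}\t{l8}\t{map_8to3(l8)}\n")
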