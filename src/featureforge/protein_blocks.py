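"""The 16-letter protein-block structural alphabet and RMSD machinery.

Protein blocks (PBs) are 16 canonical pentapeptide backbone conformations
(letters a..p) defined by eight torsion angles each. Reference Cartesian
coordinates for each block are rebuilt from the vendored dihedral table with
ideal peptide geometry; a pentapeptide fragment of a real chain is then
described by its vector of 16 least-squares-superposition RMSDs to the
blocks. Per-pattern-key statistics of those RMSDs (streamed with Welford
accumulation) are the raw material for the t-statistic descriptors.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .alphabets import ReducedAlphabet, pattern_key
from .chain import Chain

# Ideal backbone geometry (Engh-Huber-like constants), Angstrom / degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

PB_LABELS = "abcdefghijklmnop"


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c.

    d is placed at distance ``bond`` from c, with angle b-c-d = ``angle_deg``
    and torsion a-b-c-d = ``torsion_deg``.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis: Sequence[float], psis: Sequence[float],
                   omegas: Optional[Sequence[float]] = None) -> np.ndarray:
    """Build N/CA/C backbone coordinates for L residues from torsions.

    ``phis[0]`` and ``psis[-1]`` are not used (undefined at chain termini).
    Returns an (L, 3, 3) array. Bond lengths and angles are the ideal
    constants above; omega defaults to 180 deg (trans).
    """
    L = len(phis)
    if len(psis) != L:
        raise ValueError("phis and psis must have equal length")
    if omegas is None:
        omegas = [OMEGA] * L
    coords = np.zeros((L, 3, 3))
    # First residue in a canonical frame.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords[0] = [n0, ca0, c0]
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omegas[i - 1])
        c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords[i] = [n_i, ca_i, c_i]
    return coords


def build_pb_reference_coords(dihedrals: Sequence[float]) -> np.ndarray:
    """Build the 15 backbone atoms (N, CA, C of 5 residues) of one block.

    ``dihedrals`` are the eight torsions (psi1, phi2, psi2, phi3, psi3, phi4,
    psi4, phi5) in degrees.
    """
    d = list(dihedrals)
    if len(d) != 8:
        raise ValueError("a protein block is defined by exactly 8 torsions")
    phis = [0.0, d[1], d[3], d[5], d[7]]  # phi1 unused
    psis = [d[0], d[2], d[4], d[6], 0.0]  # psi5 unused
    return build_backbone(phis, psis).reshape(15, 3)


@dataclass
class ProteinBlockSet:
    """The 16 blocks: labels, torsion table (16x8 deg), reference coords."""

    labels: str
    dihedrals: np.ndarray
    ref_coords: np.ndarray  # (16, 15, 3)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def load_pb_set(path: Optional[str | Path] = None) -> ProteinBlockSet:
    """Load the vendored PB torsion table and rebuild reference coordinates."""
    if path is None:
        text = resources.files("featureforge.data").joinpath("pb_dihedrals.tsv").read_text()
    else:
        text = Path(path).read_text()
    labels = []
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pb\t"):
            continue
        parts = line.split("\t")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    dihedrals = np.array(rows)
    ref = np.array([build_pb_reference_coords(row) for row in dihedrals])
    return ProteinBlockSet(labels="".join(labels), dihedrals=dihedrals, ref_coords=ref)


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimal RMSD between two point sets over proper rotations+translations.

    Uses the SVD (Kabsch) solution with the determinant correction so that
    reflections are never applied. Shapes must match, n >= 3.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (n, 3)")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("coordinates must be finite")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt  # optimal proper rotation acting on row vectors of Xc
    # Residual-based evaluation avoids the cancellation of the Gram formula
    # and stays accurate down to machine precision for near-identical sets.
    resid = Xc @ R - Yc
    return float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))


def fragment_rmsd_vectors(chain: Chain, pbset: ProteinBlockSet) -> np.ndarray:
    """Per-position 16-vector of RMSDs to the blocks; NaN where undefined.

    Position p uses residues p-2..p+2 (pentapeptide centered at p). Positions
    within 2 of either chain end, or whose window spans an unresolved
    residue, are NaN.
    """
    if chain.backbone is None:
        raise ValueError("chain has no backbone coordinates")
    L = len(chain)
    out = np.full((L, 16), np.nan)
    for p in range(2, L - 2):
        if not chain.resolved[p - 2:p + 3].all():
            continue
        frag = chain.backbone[p - 2:p + 3].reshape(15, 3)
        for j in range(16):
            out[p, j] = kabsch_rmsd(frag, pbset.ref_coords[j])
    return out


def assign_pb(vectors: np.ndarray, pbset: ProteinBlockSet) -> str:
    """Argmin-block letter per position; '-' where the vector is undefined."""
    letters = []
    for row in vectors:
        if np.isnan(row).any():
            letters.append("-")
        else:
            letters.append(pbset.labels[int(np.argmin(row))])
    return "".join(letters)


class _Welford:
    """Streaming mean/variance for a fixed-length vector of quantities."""

    __slots__ = ("n", "mean", "m2")

    def __init__(self, dim: int = 16):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        """Unbiased sample variance; NaN when n < 2."""
        if self.n < 2:
            return np.full_like(self.mean, np.nan)
        return self.m2 / (self.n - 1)


@dataclass
class PBStats:
    """Accumulated RMSD statistics, globally and per (alphabet, pattern key).

    For each key: occurrence count N_occ, per-block mean/variance of the RMSD
    to each of the 16 blocks, and counts of the argmin-PB letter strings seen
    over the key's fragment window (used by the PB-sequence probability
    descriptors).
    """

    global_stats: _Welford = field(default_factory=lambda: _Welford(16))
    per_key: dict[str, dict[str, _Welford]] = field(default_factory=dict)
    pb_strings: dict[str, dict[str, Counter]] = field(default_factory=dict)
    pb_vocab: dict[str, set] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.global_stats.n

    def key_stats(self, alphabet: str, key: str) -> Optional[_Welford]:
        return self.per_key.get(alphabet, {}).get(key)

    def n_occ(self, alphabet: str, key: str) -> int:
        w = self.key_stats(alphabet, key)
        return 0 if w is None else w.n

    def to_json(self, path: str | Path) -> None:
        doc = {
            "global": {
                "n": self.global_stats.n,
                "mean": self.global_stats.mean.tolist(),
                "m2": self.global_stats.m2.tolist(),
            },
            "alphabets": {},
        }
        for alpha, keys in self.per_key.items():
            doc["alphabets"][alpha] = {
                "keys": {
                    k: {"n": w.n, "mean": w.mean.tolist(), "m2": w.m2.tolist()}
                    for k, w in keys.items()
                },
                "pb_strings": {
                    k: dict(cnt) for k, cnt in self.pb_strings.get(alpha, {}).items()
                },
                "pb_vocab": sorted(self.pb_vocab.get(alpha, set())),
            }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PBStats":
        doc = json.loads(Path(path).read_text())
        st = cls()
        st.global_stats.n = doc["global"]["n"]
        st.global_stats.mean = np.array(doc["global"]["mean"])
        st.global_stats.m2 = np.array(doc["global"]["m2"])
        for alpha, block in doc["alphabets"].items():
            st.per_key[alpha] = {}
            st.pb_strings[alpha] = {}
            st.pb_vocab[alpha] = set(block["pb_vocab"])
            for k, rec in block["keys"].items():
                w = _Welford(16)
                w.n = rec["n"]
                w.mean = np.array(rec["mean"])
                w.m2 = np.array(rec["m2"])
                st.per_key[alpha][k] = w
            for k, cnt in block["pb_strings"].items():
                st.pb_strings[alpha][k] = Counter(cnt)
        return st


def accumulate_pb_stats(
    chains: Iterable[Chain],
    alphabets: Sequence[ReducedAlphabet],
    pbset: Optional[ProteinBlockSet] = None,
) -> PBStats:
    """Single pass over chains accumulating global and per-key RMSD statistics.

    For every defined pentapeptide position the 16-vector enters the global
    accumulator once, and the per-key accumulator of each alphabet whose
    sequence window around the position fits in the chain. The argmin-PB
    letter string over each alphabet's window is counted per key when every
    window position has a defined PB assignment.
    """
    if pbset is None:
        pbset = load_pb_set()
    stats = PBStats()
    for alpha in alphabets:
        stats.per_key.setdefault(alpha.name, {})
        stats.pb_strings.setdefault(alpha.name, {})
        stats.pb_vocab.setdefault(alpha.name, set())
    for chain in chains:
        vectors = fragment_rmsd_vectors(chain, pbset)
        pb_string = assign_pb(vectors, pbset)
        L = len(chain)
        for p in range(L):
            vec = vectors[p]
            if np.isnan(vec).any():
                continue
            stats.global_stats.add(vec)
            for alpha in alphabets:
                h = alpha.fragment_length // 2
                if p - h < 0 or p + h >= L:
                    continue
                frag = chain.seq1[p - h:p + h + 1]
                try:
                    key = pattern_key(frag, alpha)
                except ValueError:
                    continue  # letter outside alphabet, no wildcard
                keyed = stats.per_key[alpha.name].setdefault(key, _Welford(16))
                keyed.add(vec)
                window_pbs = pb_string[p - h:p + h + 1]
                if "-" not in window_pbs:
                    cnt = stats.pb_strings[alpha.name].setdefault(key, Counter())
                    cnt[window_pbs] += 1
                    stats.pb_vocab[alpha.name].add(window_pbs)
    return stats
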