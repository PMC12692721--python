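"""Deterministic synthetic data: chains with known geometry and labels,
planted-signal feature matrices, and random property tables.

``gen_chain`` builds backbone coordinates from ideal per-state dihedrals —
helix (phi, psi) = (-57, -47), strand (-120, +130), coil sampled uniformly
from a broad Ramachandran-plausible region — plus optional Gaussian angular
noise, and assigns the matching H/E/C labels directly (no hydrogen-bond
calculation; the generator's label *is* the ground truth). This emulates
segmentally ideal local geometry; it does not emulate real sheet pairing,
so strand fragments here are geometrically ideal in isolation.

``gen_planted_features`` draws class-labelled rows with a known informative
column subset (class-dependent mean shifts) among pure-noise columns, the
standard testbed for the selection pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chain import AA1TO3, CANONICAL1, Chain
from .physchem import PropertyTable
from .protein_blocks import build_backbone
from .selection import FeatureMatrix

STATE_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 130.0),
}
STATE_LABEL = {"helix": "H", "strand": "E", "coil": "C"}
COIL_PHI_RANGE = (-180.0, -30.0)
COIL_PSI_RANGE = (-90.0, 180.0)


@dataclass(frozen=True)
class SyntheticChainSpec:
    """Segmental recipe: list of (state, length) plus angular noise (deg)."""

    segments: tuple
    dihedral_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for state, length in self.segments:
            if state not in STATE_LABEL:
                raise ValueError(f"unknown state {state!r}")
            if length < 1:
                raise ValueError("segment lengths must be >= 1")
        if self.dihedral_noise_sd < 0:
            raise ValueError("noise must be >= 0")


def gen_chain(spec: SyntheticChainSpec, chain_id: str = "SYN") -> Chain:
    """Generate a fully resolved chain with backbone coordinates and labels.

    Residue identities are drawn uniformly from the canonical alphabet;
    deterministic for a given spec (segments, noise, seed).
    """
    rng = np.random.default_rng(spec.seed)
    phis, psis, labels = [], [], []
    for state, length in spec.segments:
        for _ in range(length):
            if state == "coil":
                phi = rng.uniform(*COIL_PHI_RANGE)
                psi = rng.uniform(*COIL_PSI_RANGE)
            else:
                phi, psi = STATE_DIHEDRALS[state]
            if spec.dihedral_noise_sd > 0:
                phi += rng.normal(0.0, spec.dihedral_noise_sd)
                psi += rng.normal(0.0, spec.dihedral_noise_sd)
            phis.append(phi)
            psis.append(psi)
            labels.append(STATE_LABEL[state])
    backbone = build_backbone(phis, psis)
    L = len(labels)
    seq1 = "".join(rng.choice(list(CANONICAL1), size=L))
    seq3 = [AA1TO3[l] for l in seq1]
    return Chain(chain_id=chain_id, seq1=seq1, seq3=seq3, labels8=labels,
                 backbone=backbone, resolved=np.ones(L, dtype=bool),
                 resnums=list(range(1, L + 1)))


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """Class-labelled rows with a known informative column subset."""

    n_rows: int = 2000
    n_classes: int = 8
    n_informative: int = 5
    n_noise: int = 45
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one column")


def _sign_patterns(n_patterns: int, n_classes: int) -> np.ndarray:
    """Balanced +-1 class dichotomies (Hadamard rows, all-ones row dropped)."""
    size = 1
    while size < max(n_classes, 2):
        size *= 2
    H = np.ones((size, size))
    k = 1
    while k < size:
        H[k:2 * k, :k] = H[:k, :k]
        H[:k, k:2 * k] = H[:k, :k]
        H[k:2 * k, k:2 * k] = -H[:k, :k]
        k *= 2
    rows = H[1:, :n_classes]
    return np.array([rows[i % len(rows)] for i in range(n_patterns)])


def gen_planted_features(spec: PlantedFeatureSpec) -> tuple[FeatureMatrix, list[int]]:
    """Informative columns ~ N(shift_c, 1); noise columns ~ N(0, 1).

    Each informative column separates a different balanced class dichotomy:
    classes on one side sit at +effect_size/2, the other at -effect_size/2,
    so the between-group mean difference is ``effect_size`` standard
    deviations and every informative column carries an equally strong,
    complementary signal. Informative columns are placed at random
    positions; returns (matrix, their sorted indices).
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_rows, spec.n_classes
    y = rng.integers(0, g, size=n)
    d = spec.n_informative + spec.n_noise
    X = rng.normal(0.0, 1.0, size=(n, d))
    positions = rng.permutation(d)[: spec.n_informative]
    patterns = _sign_patterns(spec.n_informative, g)
    order = rng.permutation(len(patterns))
    for i, col in enumerate(positions):
        shifts = 0.5 * spec.effect_size * patterns[order[i]]
        X[:, col] += shifts[y]
    meta = [f"informative_{c}" if c in positions else f"noise_{c}" for c in range(d)]
    fm = FeatureMatrix(X=X, y=y.astype(str), column_meta=meta)
    return fm, sorted(int(c) for c in positions)


def gen_property_table(seed: int = 0, ncaa_codes: Sequence[str] = ()) -> PropertyTable:
    """Random finite property scale over the canonical residues (+ optional
    ncAA codes, each guaranteed distinct from every canonical value)."""
    rng = np.random.default_rng(seed)
    values = {AA1TO3[l]: float(np.round(rng.normal(0.0, 1.0), 6)) for l in CANONICAL1}
    for code in ncaa_codes:
        values[code] = float(np.round(rng.normal(0.0, 1.0) + 5.0, 6))
    return PropertyTable(accession=f"SYNTH{seed:06d}", values=values, source="user")
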