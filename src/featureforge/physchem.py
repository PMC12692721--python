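"""Physicochemical sequence descriptors: periodicity probes, windowed sums,
one-hot identities (including non-canonical residues), terminal proximity,
and externally supplied disorder scores.

The periodicity descriptor measures how strongly a property signal H over a
window of 2n+1 residues resonates at period T (residues):

    F = sqrt( (sum_k H_k cos(2 pi k / T) f(k))^2
            + (sum_k H_k sin(2 pi k / T) f(k))^2 ),   k = -n..n

with the Gaussian-like attenuation f(k) = exp(-A (k/n)^2) and window size
2n+1 = T * n_T (n_T full periods). T near 3.6 probes alpha-helical
amphipathy, T near 3.0 the 3-10 helix — the classical hydrophobic-moment
idea generalized to arbitrary property scales and tunable attenuation.

The windowed descriptor is the simpler decayed sum of a property over a
fixed offset range [left, right] relative to the target residue; offsets
falling off the chain contribute zero.

Property scales are read from AAindex flat files or two-column TSVs, with an
AAindexNC-style extension mechanism for non-canonical residues: a strict
policy keeps an ncAA's own value (and treats absent values as missing),
while the fallback policy inherits the canonical parent's value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .chain import AA1TO3, AA3TO1, CANONICAL1, Chain, load_ncaa_table

_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


@dataclass
class PropertyTable:
    """One property scale: three-letter residue code -> value."""

    accession: str
    values: dict[str, float]
    source: str = "user"  # aaindex | aaindexnc | user

    def __post_init__(self):
        missing = [c for c in AA3TO1 if c not in self.values]
        if missing:
            raise ValueError(f"{self.accession}: missing canonical residues {missing}")
        for code, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.accession}: non-finite value for {code}")

    def value1(self, letter: str, default: float = 0.0) -> float:
        """Value for a canonical one-letter code; 'X'/unknown -> default."""
        code = AA1TO3.get(letter)
        if code is None:
            return default
        return self.values[code]

    def standardized(self) -> "PropertyTable":
        """Z-standardize over the 20 canonical residues (ncAA entries use the
        same affine transform), removing AAindex unit heterogeneity."""
        canon = np.array([self.values[AA1TO3[l]] for l in CANONICAL1])
        mu, sd = canon.mean(), canon.std()
        if sd == 0:
            sd = 1.0
        vals = {c: (v - mu) / sd for c, v in self.values.items()}
        return PropertyTable(self.accession, vals, self.source)


def _parse_aaindex_flat(text: str) -> dict[str, dict[str, float]]:
    """Parse AAindex flat format (H/D/I records, '//' separators)."""
    tables: dict[str, dict[str, float]] = {}
    accession = None
    in_values = False
    rows: list[list[float]] = []
    for line in text.splitlines():
        if line.startswith("*") or not line.strip():
            continue
        if line.startswith("H "):
            accession = line[2:].strip()
            in_values = False
            rows = []
        elif line.startswith("I "):
            in_values = True
        elif line.startswith("//"):
            if accession and len(rows) == 2:
                flat = rows[0] + rows[1]
                letters = _AAINDEX_ROW1 + _AAINDEX_ROW2
                tables[accession] = {
                    AA1TO3[l]: v for l, v in zip(letters, flat)
                }
            accession = None
            in_values = False
        elif in_values and accession:
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError as exc:
                raise ValueError(f"{accession}: malformed value row {line!r}") from exc
    return tables


def _load_ncaa_extension(path: Optional[str | Path]) -> dict[str, dict[str, float]]:
    """Read an AAindexNC-style extension TSV: code, accession, value."""
    if path is None:
        text = resources.files("featureforge.data").joinpath(
            "synthetic_ncaa_properties.tsv").read_text()
    else:
        text = Path(path).read_text()
    out: dict[str, dict[str, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("code\t"):
            continue
        code, accession, value = line.split("\t")
        out.setdefault(accession, {})[code] = float(value)
    return out


def load_property_table(
    path_or_accession: str | Path,
    ncaa_policy: str = "fallback",
    ncaa_extension: Optional[str | Path] = None,
    ncaa_codes: Optional[Sequence[str]] = None,
) -> PropertyTable:
    """Load one property scale and resolve non-canonical residue values.

    ``path_or_accession`` is either a file path (AAindex flat file or
    two-column TSV ``code<TAB>value``) or an accession found in the packaged
    scale files. ncAA handling: values present in the extension file are
    used as-is; for codes in ``ncaa_codes`` without an extension entry,
    policy ``fallback`` inherits the canonical parent's value and policy
    ``strict`` leaves the code absent (callers see the unknown-residue
    default).
    """
    if ncaa_policy not in ("strict", "fallback"):
        raise ValueError("ncaa_policy must be 'strict' or 'fallback'")
    p = Path(str(path_or_accession))
    values: Optional[dict[str, float]] = None
    accession = str(path_or_accession)
    source = "user"
    if p.exists():
        text = p.read_text()
        if any(l.startswith("H ") for l in text.splitlines()):
            tables = _parse_aaindex_flat(text)
            if len(tables) != 1:
                raise ValueError(f"{p}: expected exactly one entry, found {len(tables)}")
            accession, values = next(iter(tables.items()))
            source = "aaindex"
        else:
            values = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                code, val = line.split("\t")[:2]
                if code == "code":
                    continue
                values[code] = float(val)
            accession = p.stem
    else:
        for fname in ("aaindex_kyte_doolittle.txt", "synthetic_property_scales.txt"):
            text = resources.files("featureforge.data").joinpath(fname).read_text()
            tables = _parse_aaindex_flat(text)
            if accession in tables:
                values = tables[accession]
                source = "aaindex"
                break
        if values is None:
            raise FileNotFoundError(f"no file or packaged scale named {accession!r}")

    table = PropertyTable(accession, dict(values), source)

    extension = _load_ncaa_extension(ncaa_extension).get(accession, {})
    ncaa_map = load_ncaa_table()
    codes = list(ncaa_codes) if ncaa_codes is not None else list(ncaa_map)
    for code in codes:
        if code in table.values:
            continue
        if code in extension:
            table.values[code] = extension[code]
            table.source = "aaindexnc"
        elif ncaa_policy == "fallback":
            parent_letter = ncaa_map.get(code)
            if parent_letter and parent_letter in AA1TO3:
                table.values[code] = table.values[AA1TO3[parent_letter]]
    return table


@dataclass(frozen=True)
class PeriodicDescriptorSpec:
    """Periodicity probe: property scale, period T, n_T periods, decay A."""

    accession: str
    T: float
    n_T: int
    A: float = 1.0
    power: int = 1
    rank: Optional[int] = None

    def __post_init__(self):
        if not (1.2 <= self.T <= 15.0):
            raise ValueError("T must lie in [1.2, 15.0]")
        if not (2 <= self.n_T <= 9):
            raise ValueError("n_T must lie in [2, 9]")
        if self.A <= 0:
            raise ValueError("A must be positive")

    @property
    def half_window(self) -> int:
        """n with 2n+1 = T * n_T (rounded window size)."""
        return int(round((self.T * self.n_T - 1) / 2))

    @property
    def fingerprint(self) -> str:
        return f"periodic:{self.accession}:T{self.T}:nT{self.n_T}:A{self.A}:pow{self.power}"


def periodic_descriptor(H: np.ndarray, T: float, A: float) -> float:
    """Resonance amplitude of the property signal H (length 2n+1, index
    k = -n..n centered on the target residue) at period T with attenuation
    exp(-A (k/n)^2). Non-negative; 1-homogeneous in H."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 1 or H.size % 2 != 1 or H.size < 3:
        raise ValueError("H must be a 1-D odd-length window of size >= 3")
    n = H.size // 2
    k = np.arange(-n, n + 1)
    f = np.exp(-A * (k / n) ** 2)
    phase = 2.0 * np.pi * k / T
    c = np.sum(H * np.cos(phase) * f)
    s = np.sum(H * np.sin(phase) * f)
    return float(np.hypot(c, s))


def _property_signal(chain: Chain, table: PropertyTable, standardize: bool) -> np.ndarray:
    tab = table.standardized() if standardize else table
    return np.array([tab.values.get(code, tab.value1(l))
                     for code, l in zip(chain.seq3, chain.seq1)])
    # seq3 lookup first: ncAA codes carry their own values when present.


def periodic_profile(chain: Chain, spec: PeriodicDescriptorSpec,
                     table: PropertyTable, standardize: bool = True) -> np.ndarray:
    """Per-position periodic descriptor over a chain; off-chain window
    positions contribute zero. Returns a length-L array (power applied)."""
    n = spec.half_window
    if n < 1:
        raise ValueError(f"window too small for T={spec.T}, n_T={spec.n_T}")
    signal = _property_signal(chain, table, standardize)
    L = len(chain)
    padded = np.zeros(L + 2 * n)
    padded[n:n + L] = signal
    out = np.empty(L)
    for p in range(L):
        out[p] = periodic_descriptor(padded[p:p + 2 * n + 1], spec.T, spec.A)
    return out ** spec.power


@dataclass(frozen=True)
class WindowDescriptorSpec:
    """Decayed property sum over offsets [left, right] from the target."""

    accession: str
    left: int
    right: int
    A: float = 0.0
    power: int = 1
    rank: Optional[int] = None

    def __post_init__(self):
        if self.left > self.right:
            raise ValueError("left offset must not exceed right offset")

    @property
    def fingerprint(self) -> str:
        return (f"window:{self.accession}:[{self.left},{self.right}]"
                f":A{self.A}:pow{self.power}")


def window_profile(chain: Chain, spec: WindowDescriptorSpec,
                   table: PropertyTable, standardize: bool = True) -> np.ndarray:
    """Per-position windowed descriptor; off-chain offsets contribute zero."""
    signal = _property_signal(chain, table, standardize)
    L = len(chain)
    m = max(abs(spec.left), abs(spec.right))
    ks = np.arange(spec.left, spec.right + 1)
    weights = np.exp(-spec.A * (ks / m) ** 2) if m > 0 else np.ones_like(ks, dtype=float)
    out = np.empty(L)
    for p in range(L):
        total = 0.0
        for k, w in zip(ks, weights):
            q = p + k
            if 0 <= q < L:
                total += signal[q] * w
        out[p] = total
    return out ** spec.power


def categorical_features(
    chain: Chain,
    ncaa_codes: Optional[Sequence[str]] = None,
    end_n_within: int = 3,
    end_c_within: Optional[int] = None,
) -> tuple[np.ndarray, list[str]]:
    """One-hot residue identity (canonical + ncAA codes) and terminal flags.

    Exactly one identity bit is set per position — the ncAA code's own bit
    for listed non-canonical residues, all-zero for unknown codes. End_N_k
    marks the first ``end_n_within`` residues; the symmetric C-terminal flag
    is off unless requested. Returns (matrix, column names).
    """
    if ncaa_codes is None:
        ncaa_codes = sorted(load_ncaa_table())
    columns = [AA1TO3[l] for l in CANONICAL1] + list(ncaa_codes)
    col_index = {c: i for i, c in enumerate(columns)}
    names = [f"onehot_{c}" for c in columns] + [f"End_N_{end_n_within}"]
    n_extra = 1
    if end_c_within is not None:
        names.append(f"End_C_{end_c_within}")
        n_extra = 2
    L = len(chain)
    X = np.zeros((L, len(columns) + n_extra))
    for i, code in enumerate(chain.seq3):
        j = col_index.get(code)
        if j is None and code in AA3TO1:
            j = col_index[code]
        if j is not None:
            X[i, j] = 1.0
    X[:min(end_n_within, L), len(columns)] = 1.0
    if end_c_within is not None:
        X[max(L - end_c_within, 0):, len(columns) + 1] = 1.0
    return X, names


def disorder_descriptor(scores_path: str | Path, length: int, power: int = 1) -> np.ndarray:
    """Load per-residue disorder scores (TSV: 0-based position, score in
    [0, 1]) from an external predictor and raise them to ``power``.

    Positions missing from the file are NaN; out-of-range scores are clamped
    to [0, 1].
    """
    out = np.full(length, np.nan)
    for line in Path(scores_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("position"):
            continue
        pos_s, score_s = line.split("\t")[:2]
        pos = int(pos_s)
        if not (0 <= pos < length):
            continue
        score = min(max(float(score_s), 0.0), 1.0)
        out[pos] = score ** power
    return out


def load_physchem_catalog(path: Optional[str | Path] = None) -> dict:
    """Load the shipped (or a user) YAML catalog of physicochemical recipes."""
    if path is None:
        text = resources.files("featureforge.data").joinpath(
            "catalog_physchem.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    periodic = [PeriodicDescriptorSpec(
        accession=r["accession"], T=float(r["T"]), n_T=int(r["n_T"]),
        A=float(r.get("A", 1.0)), power=int(r.get("power", 1)), rank=r.get("rank"),
    ) for r in doc.get("periodic", [])]
    window = [WindowDescriptorSpec(
        accession=r["accession"], left=int(r["left"]), right=int(r["right"]),
        A=float(r.get("A", 0.0)), power=int(r.get("power", 1)), rank=r.get("rank"),
    ) for r in doc.get("window", [])]
    return {"periodic": periodic, "window": window, "special": doc.get("special", [])}
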