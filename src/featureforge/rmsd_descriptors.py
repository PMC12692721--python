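"""Per-residue descriptors derived from protein-block RMSD statistics.

Two descriptor kinds share the accumulated :class:`~featureforge.protein_blocks.PBStats`:

* ``t_stat`` — a Welch-style two-sample t comparing a pattern key's mean
  RMSD to block j against the corpus mean,

      t_j(seq) = (mu_j - mu_j(seq)) / s_j(seq),
      s_j(seq) = sqrt(sigma2_j(seq) / N_occ(seq) + sigma2_j / N),

  transformed to a probability with the standard normal CDF. For
  N >> N_occ > 1 the corpus term vanishes and t approaches
  (mu_j - mu_j(seq)) * sqrt(N_occ) / sigma_j(seq).

* ``pb_seq_prob`` — a Laplace-smoothed estimate of the probability that a
  key's window adopts a given PB letter string (e.g. 'ddfmm'),

      P = (count(key, s) + 1) / (N_occ(key) + V),

  with V the number of distinct PB strings observed for the alphabet.

Each catalog entry may shift the evaluation point by an integer ``offset``
and raise the transformed value to an integer ``power``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.special import ndtr

from .alphabets import ReducedAlphabet, pattern_key
from .chain import Chain
from .protein_blocks import PBStats

#: Clamp for t when the pooled standard error is exactly zero; the normal
#: CDF saturates to 0/1 well before |t| = 38.
T_CLAMP = 38.0


@dataclass(frozen=True)
class RmsdDescriptorSpec:
    """One RMSD-descriptor recipe producing a single feature column."""

    kind: str  # "t_stat" | "pb_seq_prob"
    alphabet: str
    pb: str  # single block letter (t_stat) or PB letter string (pb_seq_prob)
    offset: int = 0
    power: int = 1
    rank: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("t_stat", "pb_seq_prob"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not set(self.pb) <= set("abcdefghijklmnop"):
            raise ValueError(f"PB string {self.pb!r} contains non-block letters")
        if self.kind == "t_stat" and len(self.pb) != 1:
            raise ValueError("t_stat descriptors address a single block letter")

    @property
    def fingerprint(self) -> str:
        return f"{self.kind}:{self.alphabet}:{self.pb}:off{self.offset}:pow{self.power}"


def load_rmsd_catalog(path: Optional[str | Path] = None) -> list[RmsdDescriptorSpec]:
    """Load the shipped (or a user) YAML catalog of RMSD descriptor recipes.

    Entries with a multi-letter PB string are interpreted as PB-sequence
    probability descriptors, single letters as per-block t-statistics.
    """
    if path is None:
        text = resources.files("featureforge.data").joinpath("catalog_rmsd.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    specs = []
    for row in doc["descriptors"]:
        kind = row.get("kind") or ("t_stat" if len(row["pb"]) == 1 else "pb_seq_prob")
        specs.append(RmsdDescriptorSpec(
            kind=kind, alphabet=row["alphabet"], pb=str(row["pb"]),
            offset=int(row.get("offset", 0)), power=int(row.get("power", 1)),
            rank=row.get("rank"),
        ))
    return specs


def t_statistic(stats: PBStats, alphabet: str, key: str, j: int) -> float:
    """Welch t comparing the corpus mean RMSD to block j with the key's mean.

    Returns NaN when the key has fewer than two occurrences (its variance is
    undefined); a zero pooled standard error clamps t to +-38 (sign of the
    numerator) rather than raising.
    """
    keyed = stats.key_stats(alphabet, key)
    if keyed is None or keyed.n < 2:
        return float("nan")
    n_occ = keyed.n
    mu_seq = keyed.mean[j]
    var_seq = keyed.variance()[j]
    mu_global = stats.global_stats.mean[j]
    var_global = stats.global_stats.variance()[j]
    n = stats.n_total
    s = math.sqrt(var_seq / n_occ + var_global / n)
    num = mu_global - mu_seq
    if s == 0.0:
        return math.copysign(T_CLAMP, num) if num != 0.0 else 0.0
    return num / s


def t_to_probability(t: float) -> float:
    """Standard normal CDF of t: probability the block sits closer than average."""
    if math.isnan(t):
        return float("nan")
    return float(ndtr(t))


def pb_sequence_probability(stats: PBStats, alphabet: str, key: str, pb_string: str) -> float:
    """Laplace-smoothed probability that ``key``'s window folds into ``pb_string``.

    Smoothing uses alpha=1 over the vocabulary of distinct PB strings
    observed for the alphabet, so unseen keys fall back to the uniform prior
    1/V. Defined (in (0, 1)) whenever the vocabulary is non-empty.
    """
    vocab = stats.pb_vocab.get(alphabet, set())
    V = len(vocab)
    if V == 0:
        raise ValueError(f"no PB strings accumulated for alphabet {alphabet!r}")
    counts = stats.pb_strings.get(alphabet, {}).get(key)
    if counts is None:
        return 1.0 / V
    n_strings = sum(counts.values())
    return (counts.get(pb_string, 0) + 1.0) / (n_strings + V)


def _value_at(chain: Chain, pos: int, spec: RmsdDescriptorSpec,
              alphabet: ReducedAlphabet, stats: PBStats) -> float:
    """Raw (pre-power) descriptor value at an absolute position; NaN if undefined."""
    h = alphabet.fragment_length // 2
    if pos - h < 0 or pos + h >= len(chain):
        return float("nan")
    frag = chain.seq1[pos - h:pos + h + 1]
    try:
        key = pattern_key(frag, alphabet)
    except ValueError:
        return float("nan")
    if spec.kind == "t_stat":
        j = "abcdefghijklmnop".index(spec.pb)
        return t_to_probability(t_statistic(stats, spec.alphabet, key, j))
    return pb_sequence_probability(stats, spec.alphabet, key, spec.pb)


def evaluate_rmsd_descriptors(
    chain: Chain,
    specs: Sequence[RmsdDescriptorSpec],
    stats: PBStats,
    alphabets: Mapping[str, ReducedAlphabet],
) -> np.ndarray:
    """Evaluate descriptor columns over a chain: (L, n_specs) array.

    Column order follows ``specs``. The value for position p is computed at
    p + offset; out-of-range or otherwise undefined evaluations yield NaN
    (imputation is a feature-matrix concern, not a descriptor concern).
    """
    for spec in specs:
        if spec.alphabet not in alphabets:
            raise KeyError(f"alphabet {spec.alphabet!r} not provided")
        if spec.alphabet not in stats.per_key:
            raise KeyError(f"alphabet {spec.alphabet!r} absent from statistics")
    L = len(chain)
    out = np.full((L, len(specs)), np.nan)
    for ci, spec in enumerate(specs):
        alpha = alphabets[spec.alphabet]
        for p in range(L):
            q = p + spec.offset
            if q < 0 or q >= L:
                continue
            val = _value_at(chain, q, spec, alpha, stats)
            if not math.isnan(val):
                out[p, ci] = val ** spec.power
    return out
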