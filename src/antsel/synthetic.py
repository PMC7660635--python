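"""Synthetic data generators with known ground truth.

Two generators mirror the two kinds of input the package consumes:

* :func:`make_tabular` — a binary-classification table with a handful of
  *informative* features (class-shifted Gaussians) among class-independent
  noise features, all rescaled to [0, 1] like the physicochemical encoder's
  output. Stands in for encoded phospho-site training tables.
* :func:`make_sequences` — random protein sequences with a position-
  specific residue motif planted around annotated positive sites
  (emulating the conserved flanking structure of real kinase substrates,
  e.g. the proline immediately C-terminal of proline-directed kinase
  sites), emitting exactly the FASTA + annotation-TSV dialect the encoding
  module reads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from antsel._seeds import derive_seed
from antsel.encoding import STANDARD_AA, PHOSPHO_RESIDUES

# Rough background amino-acid frequencies (vertebrate proteome order of
# magnitude); exact values are immaterial, only that all 20 occur and the
# phospho-acceptor residues are common enough to mine negatives from.
_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.058, "K": 0.058, "L": 0.089,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.042,
    "S": 0.081, "T": 0.062, "V": 0.068, "W": 0.013, "Y": 0.032,
}


@dataclass(frozen=True)
class TabularSpec:
    n_samples: int = 500
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 3.0  # class mean shift in within-class SD units
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def make_tabular(spec: TabularSpec) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Balanced two-class table with planted informative features.

    Informative features are Gaussian with a between-class mean shift of
    ``effect_size`` within-class standard deviations; noise features are
    class-independent Gaussians. Every feature is min-max rescaled to
    [0, 1] afterwards. Returns (X, y, informative_index_set).
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "tabular"))
    n_pos = spec.n_samples // 2
    n_neg = spec.n_samples - n_pos
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])

    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    informative = set(range(spec.n_informative))
    shift = spec.effect_size * spec.noise_sd
    for j in informative:
        X[y == 1, j] += shift

    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    X = (X - lo) / span

    perm = rng.permutation(spec.n_samples)
    return X[perm], y[perm], informative


@dataclass(frozen=True)
class MotifSpec:
    n_proteins: int = 30
    protein_length: int = 60
    center_residue: str = "S"
    # relative position -> residue distribution; e.g. {+1: {"P": 1.0}}
    motif: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    background: Mapping[str, float] = field(default_factory=lambda: dict(_BACKGROUND))
    positives_per_protein: int = 3
    window: int = 21
    seed: int = 0

    def __post_init__(self):
        if self.center_residue not in PHOSPHO_RESIDUES:
            raise ValueError("center_residue must be one of S/T/Y")
        half = (self.window - 1) // 2
        for pos, dist in self.motif.items():
            if pos == 0 or abs(pos) > half:
                raise ValueError(
                    f"motif position {pos} outside the +/-{half} window flank"
                )
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"motif distribution at {pos} does not sum to 1")
        if abs(sum(self.background.values()) - 1.0) > 1e-6:
            raise ValueError("background distribution does not sum to 1")


def _draw(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    aas = sorted(dist)
    p = np.array([dist[a] for a in aas])
    return aas[int(rng.choice(len(aas), p=p / p.sum()))]


def make_sequences(spec: MotifSpec) -> tuple[str, str]:
    """Generate FASTA text and annotation TSV text with planted motifs.

    Each protein receives ``positives_per_protein`` positive sites: the
    center residue is forced to ``spec.center_residue`` and each motif
    position draws its residue from the motif distribution. An equal
    number of negative sites per protein is annotated at background
    (non-positive) occurrences of the same residue type, so the output
    round-trips directly through fragment extraction and encoding.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "sequences"))
    half = (spec.window - 1) // 2
    L = spec.protein_length
    k = spec.positives_per_protein
    if L - 2 * half < k:
        raise ValueError(
            f"protein_length {L} too short for {k} positive sites with a "
            f"+/-{half} flank (need >= {2 * half + k})"
        )

    aas = sorted(spec.background)
    bg_p = np.array([spec.background[a] for a in aas])
    bg_p = bg_p / bg_p.sum()

    fasta = io.StringIO()
    tsv = io.StringIO()
    tsv.write("sequence_id\tposition\tresidue\tlabel\n")
    for pi in range(spec.n_proteins):
        sid = f"prot{pi:03d}"
        seq = [aas[i] for i in rng.choice(len(aas), size=L, p=bg_p)]
        # evenly spaced positive centers, fully inside the window flank
        usable = L - 2 * half
        centers = [half + int(round((s + 0.5) * usable / k)) for s in range(k)]
        positive_pos = set()
        for c in centers:
            seq[c] = spec.center_residue
            for off, dist in spec.motif.items():
                seq[c + off] = _draw(dist, rng)
            positive_pos.add(c)
        # negatives: background occurrences of the same residue type; their
        # windows may overlap a positive's flank, but their own motif-offset
        # positions are background by construction
        candidates = [
            i
            for i, aa in enumerate(seq)
            if aa == spec.center_residue and i not in positive_pos
        ]
        n_neg = min(k, len(candidates))
        neg_idx = sorted(
            rng.choice(len(candidates), size=n_neg, replace=False).tolist()
        )
        negatives = [candidates[i] for i in neg_idx]

        fasta.write(f">{sid}\n")
        s = "".join(seq)
        for start in range(0, L, 60):
            fasta.write(s[start : start + 60] + "\n")
        for c in sorted(positive_pos):
            tsv.write(f"{sid}\t{c + 1}\t{seq[c]}\tpositive\n")
        for c in negatives:
            tsv.write(f"{sid}\t{c + 1}\t{seq[c]}\tnegative\n")
    return fasta.getvalue(), tsv.getvalue()
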